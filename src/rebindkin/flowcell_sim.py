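"""Virtual instrument: 2-D flow-cell + hydrogel advection-diffusion-reaction.

A thin rectangular flow cell (height h, length l) carries a steady laminar
flow over a hydrogel film grafted to one wall.  Soluble species (inhibitor A,
target B, complexes AB and AB*) are advected by the parabolic velocity
profile and diffuse in both directions; inside the hydrogel their diffusion
is hindered and the tethered probe P reacts with B to form the detected
complex BP.  The detector reports the average BP mass concentration over the
hydrogel domain, converted at 100 RU per mg/ml.

Numerics: finite-volume discretisation on a structured rectilinear grid with
geometric refinement toward the sensing wall (the hydrogel, ~1% of the
channel height, is resolved by its own uniform sub-grid); first-order upwind
advection; method of lines with the stiff implicit BDF integrator and a
supplied Jacobian sparsity pattern.  The steady Poiseuille profile is imposed
analytically: for a thin straight channel it is the exact steady solution of
the incompressible momentum equation, so no flow solve is needed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core_models import InvalidParameterError, KineticConstants, kt_from_blank_koff
from .ode_simulator import InjectionProgram, IntegrationError, extract_koff
from .sensorgram import Sensorgram

__all__ = [
    "FlowCellGeometry",
    "HydrogelSpec",
    "SpeciesSpec",
    "MeshSpec",
    "DetectionSpec",
    "FlowField",
    "build_flow_profile",
    "species_transport_properties",
    "simulate_injection",
    "estimate_effective_kt",
]


@dataclass(frozen=True)
class FlowCellGeometry:
    """Channel and sensing-region dimensions (metres)."""

    h: float = 20e-6
    l_channel: float = 0.5e-3
    gel_length: float = 0.2e-3
    Hgel: float = 200e-9
    gel_start: float | None = None  # None -> centred along the channel

    def __post_init__(self) -> None:
        if not (0 < self.Hgel < self.h):
            raise InvalidParameterError("require 0 < Hgel < h")
        if self.gel_length > self.l_channel:
            raise InvalidParameterError("sensing region longer than channel")

    @property
    def x_gel0(self) -> float:
        if self.gel_start is not None:
            return self.gel_start
        return 0.5 * (self.l_channel - self.gel_length)


@dataclass(frozen=True)
class HydrogelSpec:
    """Hydrogel probe loading and density profile.

    The polymer density over relative height z in [0, 1] is
    1 - exp(-steepness*(1 - z)): essentially uniform in the bulk of the film
    and vanishing at the gel-liquid interface.  The probe concentration is
    scaled by this density.
    """

    p_nominal: float = 1e-3  # M
    density_steepness: float = 100.0
    viscosity_factor: float = 2.0  # gel viscosity relative to bulk

    def density(self, z) -> np.ndarray:
        return 1.0 - np.exp(-self.density_steepness * (1.0 - np.asarray(z)))


@dataclass(frozen=True)
class SpeciesSpec:
    """Molecular weights and the bulk diffusion anchor D_A."""

    mr_b: float = 30_000.0
    mr_a: float = 200.0
    d_a: float = 5e-10  # m^2/s, bulk diffusion coefficient of the inhibitor
    size_scaling: str = "inverse"  # D falls with Mr ("literal": printed direct form)
    gel_hindrance: str = "divide"  # Dgel = D*Kpart/visc ("literal": 2*D*Kpart)


@dataclass(frozen=True)
class MeshSpec:
    """Grid resolution: nx columns, n_gel rows in the gel, n_bulk above it."""

    nx: int = 96
    n_gel: int = 20
    n_bulk: int = 32

    def refined(self, factor: int = 2) -> "MeshSpec":
        return MeshSpec(self.nx * factor, self.n_gel * factor, self.n_bulk * factor)


@dataclass(frozen=True)
class DetectionSpec:
    """Sampling and baseline-noise settings of the detector."""

    sample_rate: float = 1.0  # Hz
    noise_rms: float = 0.0  # RU; instrument-realistic value is 0.03
    seed: int | None = None


@dataclass
class FlowField:
    """Steady laminar (Poiseuille) profile u(y) = nu_c (1 - (2y/h - 1)^2)."""

    nu_c: float
    h: float

    def u(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return self.nu_c * (1.0 - (2.0 * y / self.h - 1.0) ** 2)

    @property
    def mean(self) -> float:
        return 2.0 / 3.0 * self.nu_c


def build_flow_profile(geometry: FlowCellGeometry, nu_c: float) -> FlowField:
    """Analytic steady laminar profile: no-slip walls, centre-line maximum nu_c."""
    if nu_c < 0:
        raise InvalidParameterError("nu_c must be >= 0")
    return FlowField(nu_c=nu_c, h=geometry.h)


def species_transport_properties(
    mr: float,
    d_a: float = 5e-10,
    mr_a: float = 200.0,
    size_scaling: str = "inverse",
    gel_hindrance: str = "divide",
    viscosity_factor: float = 2.0,
) -> tuple[float, float, float]:
    """Bulk D, hydrogel partition coefficient and in-gel diffusion of a species.

    Kpart = exp(-1e-3 * Mr^(2/3)).  With the default physically consistent
    variants, D = D_A * (Mr_A/Mr)^(1/3) (heavier species diffuse slower) and
    Dgel = D * Kpart / viscosity_factor (gel diffusion slower than bulk).
    ``size_scaling='literal'`` / ``gel_hindrance='literal'`` select the direct
    printed forms D_A*(Mr/Mr_A)^(1/3) and 2*D*Kpart instead.
    """
    if mr <= 0 or mr_a <= 0 or d_a <= 0:
        raise InvalidParameterError("molecular weights and D_A must be > 0")
    ratio = (mr / mr_a) ** (1.0 / 3.0)
    d = d_a * ratio if size_scaling == "literal" else d_a / ratio
    kpart = math.exp(-1e-3 * mr ** (2.0 / 3.0))
    if gel_hindrance == "literal":
        dgel = 2.0 * d * kpart
    else:
        dgel = d * kpart / viscosity_factor
    return d, kpart, dgel


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

class _Mesh:
    """Structured rectilinear grid; gel resolved by a uniform sub-grid, the
    bulk by geometrically growing rows.  Cell (ix, iy) -> index ix*ny + iy."""

    def __init__(self, geom: FlowCellGeometry, spec: MeshSpec):
        self.geom, self.spec = geom, spec
        nx, n_gel, n_bulk = spec.nx, spec.n_gel, spec.n_bulk
        self.nx, self.ny = nx, n_gel + n_bulk
        self.dx = geom.l_channel / nx
        self.xc = (np.arange(nx) + 0.5) * self.dx

        dy0 = geom.Hgel / n_gel
        rem = geom.h - geom.Hgel

        def total(r):
            if abs(r - 1.0) < 1e-12:
                return dy0 * n_bulk
            return dy0 * r * (r**n_bulk - 1.0) / (r - 1.0)

        if total(1.0) >= rem:
            ratio = 1.0
            dy_bulk = np.full(n_bulk, rem / n_bulk)
        else:
            ratio = brentq(lambda r: total(r) - rem, 1.0 + 1e-9, 10.0)
            dy_bulk = dy0 * ratio ** np.arange(1, n_bulk + 1)
            dy_bulk *= rem / dy_bulk.sum()  # exact fill
        self.dy = np.concatenate([np.full(n_gel, dy0), dy_bulk])
        yf = np.concatenate([[0.0], np.cumsum(self.dy)])
        self.yc = 0.5 * (yf[:-1] + yf[1:])

        x0, x1 = geom.x_gel0, geom.x_gel0 + geom.gel_length
        self.gel_x = (self.xc >= x0) & (self.xc <= x1)
        gel2d = np.zeros((nx, self.ny), dtype=bool)
        gel2d[self.gel_x, :n_gel] = True
        self.gel_mask = gel2d.reshape(-1)
        self.gel_idx = np.flatnonzero(self.gel_mask)
        # cell areas (per unit channel width)
        self.cell_area = np.tile(self.dx * self.dy, nx)
        self.gel_area = self.cell_area[self.gel_idx]
        # relative height within the gel for density profile
        self.gel_z = np.tile(self.yc[:n_gel] / geom.Hgel, int(self.gel_x.sum()))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny


def _transport_matrix(mesh: _Mesh, u_row: np.ndarray, d_bulk: float,
                      d_gel: float) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Upwind advection + two-point-flux diffusion operator for one species.

    Returns (L, b_unit) with dc/dt = L c + b_unit * c_inlet.
    """
    nx, ny = mesh.nx, mesh.ny
    dx, dy = mesh.dx, mesh.dy
    n = mesh.n_cells
    dcell = np.where(mesh.gel_mask, d_gel, d_bulk).reshape(nx, ny)

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r); cols.append(c); vals.append(v)

    idx = np.arange(n).reshape(nx, ny)
    # x faces (advection upwind + diffusion)
    for ix in range(nx - 1):
        a, b = idx[ix], idx[ix + 1]
        u = u_row  # per-row velocity
        dface = 2.0 * dcell[ix] * dcell[ix + 1] / (dcell[ix] + dcell[ix + 1])
        kdiff = dface / dx**2
        for j in range(ny):
            add(a[j], a[j], -u[j] / dx - kdiff[j]); add(b[j], a[j], u[j] / dx + kdiff[j])
            add(a[j], b[j], kdiff[j]); add(b[j], b[j], -kdiff[j])
    # outlet (advective outflow only)
    for j in range(ny):
        add(idx[nx - 1, j], idx[nx - 1, j], -u_row[j] / dx)
    # inlet: b_unit carries u*c_in/dx into column 0
    b_unit = np.zeros(n)
    b_unit[idx[0]] = u_row / dx
    # y faces
    for j in range(ny - 1):
        for ix in range(nx):
            a, b = idx[ix, j], idx[ix, j + 1]
            g = 1.0 / (0.5 * dy[j] / dcell[ix, j] + 0.5 * dy[j + 1] / dcell[ix, j + 1])
            add(a, a, -g / dy[j]); add(a, b, g / dy[j])
            add(b, b, -g / dy[j + 1]); add(b, a, g / dy[j + 1])

    L = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return L, b_unit


def simulate_injection(
    geometry: FlowCellGeometry,
    hydrogel: HydrogelSpec,
    k: KineticConstants,
    program: InjectionProgram,
    species: SpeciesSpec | None = None,
    mesh: MeshSpec | None = None,
    nu_c: float = 0.1,
    initial_occupancy: float = 0.0,
    detection: DetectionSpec | None = None,
    rtol: float = 1e-6,
) -> Sensorgram:
    """Run the virtual instrument over an injection program.

    ``initial_occupancy`` pre-loads the probe with target: BP = occ * Ptot.
    Each program segment carries inlet concentrations for target and
    inhibitor; the segment's ``flow_velocity`` overrides ``nu_c``.  Returns a
    two-channel sensorgram: the BP detection channel (RU) and the
    Mr-weighted total soluble+tethered mass channel.
    """
    species = species or SpeciesSpec()
    mesh_spec = mesh or MeshSpec()
    detection = detection or DetectionSpec()
    msh = _Mesh(geometry, mesh_spec)

    mr_ab = species.mr_a + species.mr_b
    props = {
        "A": species_transport_properties(species.mr_a, species.d_a, species.mr_a,
                                          species.size_scaling, species.gel_hindrance,
                                          hydrogel.viscosity_factor),
        "B": species_transport_properties(species.mr_b, species.d_a, species.mr_a,
                                          species.size_scaling, species.gel_hindrance,
                                          hydrogel.viscosity_factor),
        "AB": species_transport_properties(mr_ab, species.d_a, species.mr_a,
                                           species.size_scaling, species.gel_hindrance,
                                           hydrogel.viscosity_factor),
    }
    with_abs = k.kinact > 0
    names = ["A", "B", "AB"] + (["ABs"] if with_abs else [])
    nsol = len(names)
    n = msh.n_cells
    ngel = msh.gel_idx.size
    nstate = nsol * n + ngel
    off = {nm: i * n for i, nm in enumerate(names)}
    off_bp = nsol * n

    ptot = hydrogel.p_nominal * hydrogel.density(msh.gel_z)

    # initial state
    y0 = np.zeros(nstate)
    if initial_occupancy > 0:
        y0[off_bp:] = initial_occupancy * ptot

    gel = msh.gel_idx
    ka, kd = k.ka, k.kd
    ka_p, kd_p = k.ka_p, k.kd_p
    kinact = k.kinact

    # Jacobian sparsity: transport pattern + reaction coupling at gel cells
    def build_ops(velocity: float):
        flow = build_flow_profile(geometry, velocity)
        u_row = flow.u(msh.yc)
        ls, bs = [], []
        for nm in names:
            d, _, dgel = props["AB"] if nm == "ABs" else props[nm]
            L, b = _transport_matrix(msh, u_row, d, dgel)
            ls.append(L); bs.append(b)
        L_full = sparse.block_diag(ls + [sparse.csr_matrix((ngel, ngel))],
                                   format="csr")
        return L_full, bs

    def sparsity(L_full):
        pat = (L_full != 0).astype(np.int8).tolil()
        bp_rows = off_bp + np.arange(ngel)
        blocks = [off[nm] + gel for nm in names] + [bp_rows]
        for ra in blocks:
            for cb in blocks:
                pat[ra, cb] = 1
        return pat.tocsr()

    atol = np.empty(nstate)
    max_a = max((s.conc_inhibitor for s in program.segments), default=0.0)
    max_b = max((s.conc_target for s in program.segments), default=0.0)
    scale_b = max(max_b, hydrogel.p_nominal * 1e-4)
    atol[off["A"]:off["A"] + n] = max(max_a, 1e-9) * 1e-9
    atol[off["B"]:off["B"] + n] = scale_b * 1e-9
    atol[off["AB"]:off["AB"] + n] = scale_b * 1e-9
    if with_abs:
        atol[off["ABs"]:off["ABs"] + n] = scale_b * 1e-9
    atol[off_bp:] = hydrogel.p_nominal * 1e-10

    t_all: list[np.ndarray] = []
    r_bp_all: list[np.ndarray] = []
    r_tot_all: list[np.ndarray] = []
    t_offset = 0.0
    y = y0
    dt_out = 1.0 / detection.sample_rate

    w = msh.gel_area / msh.gel_area.sum()  # detection weights

    def detect(state: np.ndarray) -> tuple[float, float]:
        bp = state[off_bp:]
        r_bp = 100.0 * species.mr_b * float(w @ bp)
        total = species.mr_b * bp.copy()
        total += species.mr_a * state[off["A"] + gel]
        total += species.mr_b * state[off["B"] + gel]
        total += mr_ab * state[off["AB"] + gel]
        if with_abs:
            total += mr_ab * state[off["ABs"] + gel]
        return r_bp, 100.0 * float(w @ total)

    for seg in program.segments:
        velocity = seg.flow_velocity if seg.flow_velocity is not None else nu_c
        L_full, bs = build_ops(velocity)
        pat = sparsity(L_full)
        b_const = np.zeros(nstate)
        b_const[off["A"]:off["A"] + n] = bs[names.index("A")] * seg.conc_inhibitor
        b_const[off["B"]:off["B"] + n] = bs[names.index("B")] * seg.conc_target

        def rhs(t, state):
            dy = L_full @ state + b_const
            a_g = state[off["A"] + gel]
            b_g = state[off["B"] + gel]
            ab_g = state[off["AB"] + gel]
            bp_g = state[off_bp:]
            r_bp = ka_p * b_g * (ptot - bp_g) - kd_p * bp_g
            r_ab = ka * a_g * b_g - kd * ab_g
            dy[off["A"] + gel] += -r_ab
            dy[off["B"] + gel] += -r_bp - r_ab
            dy[off["AB"] + gel] += r_ab - kinact * ab_g
            if with_abs:
                dy[off["ABs"] + gel] += kinact * ab_g
            dy[off_bp:] += r_bp
            return dy

        n_out = max(int(round(seg.duration * detection.sample_rate)), 1)
        t_eval = np.minimum(np.arange(n_out + 1) * dt_out, seg.duration)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = solve_ivp(rhs, (0.0, seg.duration), y, method="BDF",
                            t_eval=t_eval, rtol=rtol, atol=atol,
                            jac_sparsity=pat)
        if not sol.success:
            raise IntegrationError(
                f"flow-cell integration failed: {sol.message} "
                f"(mesh {mesh_spec.nx}x{msh.ny}, segment duration {seg.duration}s, "
                f"{sol.t.size} steps completed)")
        sl = slice(1, None) if t_all else slice(None)
        pairs = [detect(sol.y[:, i]) for i in range(sol.y.shape[1])]
        t_all.append(sol.t[sl] + t_offset)
        r_bp_all.append(np.array([p[0] for p in pairs])[sl])
        r_tot_all.append(np.array([p[1] for p in pairs])[sl])
        y = sol.y[:, -1]
        t_offset += seg.duration

    time = np.concatenate(t_all)
    resp = np.column_stack([np.concatenate(r_bp_all), np.concatenate(r_tot_all)])
    if detection.noise_rms > 0:
        rng = np.random.default_rng(detection.seed)
        resp = resp + rng.normal(0.0, detection.noise_rms, size=resp.shape)

    rmax_ru = 100.0 * species.mr_b * hydrogel.p_nominal * float(
        w @ hydrogel.density(msh.gel_z))
    seg0 = program.segments[0]
    meta_common = {
        "A": seg0.conc_inhibitor, "conc_target": seg0.conc_target,
        "flow_velocity": seg0.flow_velocity if seg0.flow_velocity is not None else nu_c,
        "Mr_B": species.mr_b, "Rmax": rmax_ru,
    }
    meta = [dict(meta_common, label="BP"), dict(meta_common, label="total_mass")]
    prov = {
        "generator": "flowcell", "nu_c": nu_c, "mesh": (mesh_spec.nx, msh.ny),
        "ka": ka, "kd": kd, "ka_p": ka_p, "kd_p": kd_p, "kinact": kinact,
        "P": hydrogel.p_nominal, "initial_occupancy": initial_occupancy,
        "noise_rms": detection.noise_rms, "seed": detection.seed,
        "Rmax": rmax_ru,
    }
    return Sensorgram(time, resp, meta, prov)


def estimate_effective_kt(
    blank: Sensorgram,
    k: KineticConstants,
    p: float,
    skip: float = 5.0,
) -> float:
    """Effective hydrogel escape rate from a blank (A = 0) dissociation curve.

    Fits a single exponential to the blank decay and inverts the blank-curve
    relation koff = kd' kt / (kt + ka' P).  Returns ``inf`` (with a warning)
    when the observed rate is not below kd', i.e. no rebinding is detectable.
    """
    mask = blank.time >= blank.time[0] + skip
    res = extract_koff(blank.time[mask], blank.response[mask, 0])
    kt = kt_from_blank_koff(res.koff, k.kd_p, k.ka_p, p)
    if math.isinf(kt):
        warnings.warn("observed blank off-rate >= kd': no rebinding detected; "
                      "kt is unbounded")
    return kt
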