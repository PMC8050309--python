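"""Two-compartment ODE simulators for mass-transport-limited biosensor binding.

The flow cell is split into a bulk compartment held at the injected
concentration and an inner (hydrogel) compartment exchanging with it at the
transport rate kt (s^-1).  Soluble species (target B, inhibitor A, complexes
AB, AB*) are tracked in molar units inside the inner compartment; the
tethered probe P and complex BP are tracked in molar as well and reported in
RU through R = G * Mr_B * [BP].  With this convention the quasi-steady-state
off-rate of the dissociation phase equals kd' * alpha from
:mod:`rebindkin.core_models` exactly.

Association/dissociation of B with P:

    dB/dt  = kt (Conc - B) - ka' B P + kd' BP
    dBP/dt = ka' B P - kd' BP,   P = Rmax_M - BP

Rebinding inhibition adds the inhibitor reactions and hydrogel escape of the
soluble complexes:

    dAB/dt  = ka A B - kd AB - kinact AB - kt AB
    dAB*/dt = kinact AB - kt AB*
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .core_models import DEFAULT_G, InvalidParameterError, KineticConstants
from .sensorgram import Sensorgram

__all__ = [
    "InjectionSegment",
    "InjectionProgram",
    "IntegrationError",
    "simulate_two_compartment",
    "simulate_rebinding_dissociation",
    "extract_koff",
    "KoffResult",
    "kt_from_response_scaled",
]


class IntegrationError(RuntimeError):
    """Stiff-integration failure, carrying solver diagnostics."""


@dataclass(frozen=True)
class InjectionSegment:
    """One constant-condition segment of an injection program."""

    duration: float
    conc_target: float = 0.0
    conc_inhibitor: float = 0.0
    flow_velocity: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidParameterError("segment duration must be > 0")
        if self.conc_target < 0 or self.conc_inhibitor < 0:
            raise InvalidParameterError("inlet concentrations must be >= 0")


@dataclass
class InjectionProgram:
    """Ordered injection segments (association, dissociation, inhibition...)."""

    segments: list[InjectionSegment] = field(default_factory=list)

    @staticmethod
    def pulse(contact_time: float, conc: float, dissociation_time: float = 0.0,
              flow_velocity: float | None = None) -> "InjectionProgram":
        segs = [InjectionSegment(contact_time, conc_target=conc,
                                 flow_velocity=flow_velocity)]
        if dissociation_time > 0:
            segs.append(InjectionSegment(dissociation_time, conc_target=0.0,
                                         flow_velocity=flow_velocity))
        return InjectionProgram(segs)

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)


def kt_from_response_scaled(kt_resp: float, g: float = DEFAULT_G,
                            mr_b: float = 30_000.0) -> float:
    """Convert a response-scaled transport coefficient (RU M^-1 s^-1) to s^-1.

    The response-scaled coefficient multiplies molar concentrations to give
    RU/s; dividing by G*Mr_B (RU per M) recovers the first-order exchange
    rate of the inner compartment.
    """
    return kt_resp / (g * mr_b)


def _solve(rhs, t_span, y0, t_eval, rtol, atol, method="LSODA"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = solve_ivp(rhs, t_span, y0, method=method, t_eval=t_eval,
                        rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"integration failed: {sol.message} (span={t_span}, n_steps={sol.t.size})")
    return sol


def simulate_two_compartment(
    k: KineticConstants,
    kt: float,
    rmax: float,
    program: InjectionProgram,
    sample_rate: float = 1.0,
    g: float = DEFAULT_G,
    mr_b: float = 30_000.0,
    rtol: float = 1e-8,
) -> Sensorgram:
    """Simulate a 1:1 interaction with finite transport exchange rate kt (s^-1).

    ``kt=np.inf`` collapses the model to ideal (transport-free) 1:1 binding.
    Returns the tethered-complex response BP(t) in RU sampled at
    ``sample_rate`` Hz.  Initial conditions: B = 0, P = Rmax, BP = 0.
    """
    if rmax <= 0:
        raise InvalidParameterError("Rmax must be > 0")
    rmax_m = rmax / (g * mr_b)
    ideal = np.isinf(kt)
    if not ideal and kt <= 0:
        raise InvalidParameterError("kt must be > 0")

    t_out: list[np.ndarray] = []
    r_out: list[np.ndarray] = []
    y = np.array([0.0, 0.0])  # [B, BP] molar
    t_offset = 0.0
    dt = 1.0 / sample_rate
    for seg in program.segments:
        conc = seg.conc_target

        if ideal:
            def rhs(t, y, conc=conc):
                b = conc
                dbp = k.ka_p * b * (rmax_m - y[1]) - k.kd_p * y[1]
                return [0.0, dbp]
        else:
            def rhs(t, y, conc=conc):
                react = k.ka_p * y[0] * (rmax_m - y[1]) - k.kd_p * y[1]
                db = kt * (conc - y[0]) - react
                return [db, react]

        n = max(int(round(seg.duration * sample_rate)), 1)
        t_eval = np.arange(0, n + 1) * dt
        t_eval = t_eval[t_eval <= seg.duration + 1e-12]
        sol = _solve(rhs, (0.0, seg.duration), y, t_eval, rtol, atol=rmax_m * 1e-12)
        sl = slice(1, None) if t_out else slice(None)
        t_out.append(sol.t[sl] + t_offset)
        r_out.append(sol.y[1][sl] * g * mr_b)
        y = sol.y[:, -1]
        t_offset += seg.duration

    time = np.concatenate(t_out)
    resp = np.concatenate(r_out)
    meta = [{
        "label": "BP",
        "Rmax": rmax,
        "Mr_B": mr_b,
        "conc_target": program.segments[0].conc_target,
    }]
    prov = {"generator": "two_compartment", "kt": kt, "ka_p": k.ka_p,
            "kd_p": k.kd_p, "Rmax": rmax, "G": g, "Mr_B": mr_b}
    return Sensorgram(time, resp, meta, prov)


def simulate_rebinding_dissociation(
    k: KineticConstants,
    kt: float,
    rmax: float,
    r0: float,
    a: float,
    t_span: float,
    kinact: float | None = None,
    sample_rate: float = 1.0,
    g: float = DEFAULT_G,
    mr_b: float = 30_000.0,
    rtol: float = 1e-8,
    inhibitor_transport: bool = False,
) -> Sensorgram:
    """Dissociation phase with inhibitor A injected at t = 0.

    The run starts from BP = R0 with the free target at its quasi-steady-state
    level B = kd'*BP/(kt + ka'*P) so that no spurious initial transient is
    introduced.  By default the inhibitor is clamped at its inlet
    concentration (excess reservoir); ``inhibitor_transport=True`` instead
    lets A equilibrate into the hydrogel at rate kt.
    """
    if not (0 < r0 <= rmax):
        raise InvalidParameterError("R0 must satisfy 0 < R0 <= Rmax")
    if kt <= 0:
        raise InvalidParameterError("kt must be > 0")
    ki = k.kinact if kinact is None else kinact
    rmax_m = rmax / (g * mr_b)
    bp0 = r0 / (g * mr_b)
    b0 = k.kd_p * bp0 / (kt + k.ka_p * (rmax_m - bp0))

    def rhs(t, y):
        b, ab, abs_, bp, a_free = y
        p_free = rmax_m - bp
        r_bp = k.ka_p * b * p_free - k.kd_p * bp
        r_ab = k.ka * a_free * b - k.kd * ab
        db = -r_bp - r_ab - kt * b
        dab = r_ab - ki * ab - kt * ab
        dabs = ki * ab - kt * abs_
        dbp = r_bp
        da = kt * (a - a_free) - r_ab if inhibitor_transport else 0.0
        return [db, dab, dabs, dbp, da]

    y0 = [b0, 0.0, 0.0, bp0, 0.0 if inhibitor_transport else a]
    n = max(int(round(t_span * sample_rate)), 1)
    t_eval = np.arange(0, n + 1) / sample_rate
    sol = _solve(rhs, (0.0, t_span), y0, t_eval, rtol, atol=rmax_m * 1e-13,
                 method="LSODA")
    resp = sol.y[3] * g * mr_b
    meta = [{"label": "BP", "A": a, "R0": r0, "Rmax": rmax, "Mr_B": mr_b}]
    prov = {"generator": "two_compartment_rebinding", "kt": kt, "A": a,
            "ka": k.ka, "kd": k.kd, "ka_p": k.ka_p, "kd_p": k.kd_p,
            "kinact": ki, "Rmax": rmax, "R0": r0, "G": g, "Mr_B": mr_b}
    return Sensorgram(sol.t, resp, meta, prov)


@dataclass
class KoffResult:
    koff: float
    r0: float
    rmse: float
    warning: str | None = None


def extract_koff(time: np.ndarray, response: np.ndarray) -> KoffResult:
    """Least-squares single-exponential rate of a decay-phase curve.

    Fits R(t) = R0 * exp(-koff * (t - t[0])).  A non-monotone segment is
    fitted anyway but flagged with a quality warning.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(response, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 samples to extract a rate")
    warning = None
    if np.any(np.diff(y) > np.ptp(y) * 1e-6 + 1e-12):
        warning = "response is not monotone decreasing; rate is an average"
    if np.any(y <= 0):
        warning = (warning or "") + " non-positive responses present"
    tt = t - t[0]
    ypos = np.clip(y, np.max(y) * 1e-12, None)
    # log-linear seed, then nonlinear refinement
    slope, intercept = np.polyfit(tt, np.log(ypos), 1)
    x0 = np.array([max(-slope, 1e-12), np.exp(intercept)])

    def resid(x):
        return x[1] * np.exp(-x[0] * tt) - y

    res = least_squares(resid, x0, bounds=([0, 0], [np.inf, np.inf]))
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    return KoffResult(koff=float(res.x[0]), r0=float(res.x[1]), rmse=rmse,
                      warning=warning)
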