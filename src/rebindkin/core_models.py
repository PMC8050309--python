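"""Closed-form quantities of the inhibition-of-rebinding theory.

A target **B** dissociating from a hydrogel-tethered probe **P** enters a
transient unbound state that is partitioned between three first-order paths:
re-association at rate ka'·P, capture by a soluble inhibitor **A** at rate
ka·A, and escape from the hydrogel at the mass-transport rate kt.  Under a
quasi-steady-state the dissociation phase decays as a single exponential

    R(t) = R0 · exp(-kd' · alpha · t)

where the rebinding factor

    alpha = beta / (beta + ka'·P),   beta = kt + f·ka·A,
    f = 1 / (1 + kd/kt)

quantifies how strongly rebinding slows the observed off-rate
koff = kd'·alpha.  The transient partition function f accounts for inhibitor
complexes **AB** that dissociate before escaping the hydrogel, and an
analogous alkylation factor z = 1 + kinact/kt applies to irreversible
(covalent) inhibitors.

All rates are SI-style (M, s); response-scaled variants are explicit
conversions, never implicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "InvalidParameterError",
    "KineticConstants",
    "TransportSpec",
    "ProbeSurface",
    "RebindingState",
    "damkohler_number",
    "hydrogel_resistance_factor",
    "mass_transport_coefficient",
    "partition_function_f",
    "alkylation_partition_z",
    "rebinding_factor_alpha",
    "rebinding_response",
    "observed_koff",
    "kt_from_blank_koff",
    "probe_concentration_from_rmax",
    "rmax_from_probe_concentration",
    "diffusion_rescale_ka",
    "kt_response_scaled",
    "kt_flow_scaling",
    "tc_from_kt",
    "rebinding_probability",
    "DEFAULT_G",
]

#: response-to-concentration factor typical of SPR hydrogel sensors (RU per g/L)
DEFAULT_G = 100.0


class InvalidParameterError(ValueError):
    """Raised when a rate, concentration or geometry parameter is inadmissible."""


@dataclass(frozen=True)
class KineticConstants:
    """Paired forward/reverse rate constants of the three-species system.

    ka, kd    : inhibitor-target association (M^-1 s^-1) / dissociation (s^-1)
    ka_p, kd_p: target-probe association (M^-1 s^-1) / dissociation (s^-1)
    kinact    : irreversible inactivation rate of the inhibitor complex (s^-1)
    """

    ka: float = 0.0
    kd: float = 0.0
    ka_p: float = 0.0
    kd_p: float = 0.0
    kinact: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ka", "kd", "ka_p", "kd_p", "kinact"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class TransportSpec:
    """Transport quantities of the flow cell / hydrogel system.

    kt is the hydrogel escape rate (s^-1, tau = 1/kt); kt_resp its
    response-scaled companion; tc the flow-rate-independent coefficient in
    kt = tc * u^(1/3).  Geometry lengths in metres.
    """

    kt: float | None = None
    kt_resp: float | None = None
    tc: float | None = None
    D: float = 5e-10
    Dgel: float | None = None
    Kpart: float = 1.0
    nu_c: float = 0.1
    h: float = 20e-6
    l: float = 0.5e-3
    Hgel: float = 200e-9

    def __post_init__(self) -> None:
        if self.kt is not None and self.kt <= 0:
            raise InvalidParameterError("kt must be > 0")
        if not (0 < self.Kpart <= 1):
            raise InvalidParameterError("Kpart must lie in (0, 1]")
        for name in ("D", "nu_c", "h", "l", "Hgel"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @property
    def tau(self) -> float:
        if self.kt is None:
            raise InvalidParameterError("kt is not set")
        return 1.0 / self.kt


@dataclass
class ProbeSurface:
    """Probe-loaded sensing surface.

    Rmax (RU) and the hydrogel probe concentration P (M) are linked through
    P = Rmax / (G * Mr_B); either may be given and the other derived.
    """

    Rmax: float | None = None
    G: float = DEFAULT_G
    Mr_B: float = 30_000.0
    Mr_P: float | None = None
    Mr_A: float | None = None
    P: float | None = None

    def __post_init__(self) -> None:
        if self.G <= 0 or self.Mr_B <= 0:
            raise InvalidParameterError("G and Mr_B must be > 0")
        if self.P is None and self.Rmax is not None:
            self.P = probe_concentration_from_rmax(self.Rmax, self.G, self.Mr_B)
        elif self.Rmax is None and self.P is not None:
            self.Rmax = rmax_from_probe_concentration(self.P, self.G, self.Mr_B)


class AlphaResult(NamedTuple):
    alpha: float
    beta: float
    f: float


@dataclass
class RebindingState:
    """Snapshot of the rebinding system at one instant of the dissociation phase."""

    R: float
    R0: float
    A: float
    alpha: float
    beta: float
    f: float
    z: float = 1.0
    koff: float = field(default=float("nan"))
    Da: float = field(default=float("nan"))


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not np.all(np.asarray(v) > 0):
            raise InvalidParameterError(f"{name} must be > 0, got {v}")


def damkohler_number(ka_p: float, rmax: float, r, kt: float):
    """Damkoehler number Da = ka' * (Rmax - R) / kt.

    Ratio of surface reaction flux to transport flux; Da >> 1 marks strong
    mass-transport limitation.  ``kt`` must be supplied on the same response
    scale as ``ka' * (Rmax - R)`` so that Da is dimensionless.
    """
    _require_positive(kt=kt)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > rmax):
        raise InvalidParameterError("response must satisfy 0 <= R <= Rmax")
    da = ka_p * (rmax - r) / kt
    return float(da) if da.ndim == 0 else da


def hydrogel_resistance_factor(
    hgel: float, dgel: float, kpart: float, ka_p: float, p: float
) -> tuple[float, float]:
    """Hydrogel transport resistance T_gamma = tanh(gamma)/gamma.

    gamma = Hgel / sqrt(Dgel*Kpart / (ka'*P)) compares the hydrogel height to
    the mean free path of the target before recapture.  Returns
    ``(T_gamma, gamma)``.  A vanishing reaction flux (ka'*P == 0) means no
    recapture and hence no extra resistance: T_gamma = 1.
    """
    _require_positive(hgel=hgel, dgel=dgel, kpart=kpart)
    if ka_p < 0 or p < 0:
        raise InvalidParameterError("ka_p and p must be >= 0")
    flux = ka_p * p
    if flux == 0:
        return 1.0, 0.0
    gamma = hgel / math.sqrt(dgel * kpart / flux)
    if gamma == 0:
        return 1.0, 0.0
    return math.tanh(gamma) / gamma, gamma


def mass_transport_coefficient(
    spec: TransportSpec, t_gamma: float = 1.0, *, variant: str = "printed"
) -> float:
    """Flow-cell mass-transport coefficient.

    variant='printed' evaluates 1.281 * T_gamma * (nu_c*D / (2*h*l))^(1/3)
    exactly as the model states it.  variant='leveque' uses the classical
    Leveque-type form 1.281 * T_gamma * (nu_c*D^2 / (h*l))^(1/3), which is
    dimensionally a flux velocity (m/s).  Both scale as nu_c^(1/3) and are
    linear in T_gamma.
    """
    _require_positive(t_gamma=t_gamma)
    if variant == "printed":
        core = (spec.nu_c * spec.D / (2.0 * spec.h * spec.l)) ** (1.0 / 3.0)
    elif variant == "leveque":
        core = (spec.nu_c * spec.D**2 / (spec.h * spec.l)) ** (1.0 / 3.0)
    else:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    return 1.281 * t_gamma * core


def partition_function_f(kd: float, kt: float) -> float:
    """Transient partition function f = 1 / (1 + kd/kt).

    Fraction of inhibition retained when the inhibitor complex dissociates on
    the hydrogel-escape timescale; f = 1/2 at kd = kt (50% loss of inhibition).
    """
    _require_positive(kt=kt)
    if kd < 0:
        raise InvalidParameterError("kd must be >= 0")
    return 1.0 / (1.0 + kd / kt)


def alkylation_partition_z(kinact: float, kt: float) -> float:
    """Alkylation partition factor z = 1 + kinact/kt (z ~ 1 when kinact << kt)."""
    _require_positive(kt=kt)
    if kinact < 0:
        raise InvalidParameterError("kinact must be >= 0")
    return 1.0 + kinact / kt


def rebinding_factor_alpha(
    k: KineticConstants, kt: float, p: float, a: float
) -> AlphaResult:
    """Rebinding factor alpha = beta / (beta + ka'*P) with beta = kt + f*ka*A.

    alpha = 1 when there is no rebinding (P = 0) or rebinding is fully
    inhibited; at A = 0 it reduces to the blank-curve relation
    alpha = kt / (kt + ka'*P).
    """
    _require_positive(kt=kt)
    if p < 0 or a < 0:
        raise InvalidParameterError("P and A must be >= 0")
    f = partition_function_f(k.kd, kt)
    beta = kt + f * k.ka * a
    alpha = beta / (beta + k.ka_p * p)
    return AlphaResult(alpha=alpha, beta=beta, f=f)


def rebinding_response(r0: float, kd_p: float, alpha: float, t):
    """Inhibition-of-rebinding dissociation curve R(t) = R0 * exp(-kd'*alpha*t)."""
    if r0 < 0:
        raise InvalidParameterError("R0 must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("time must be >= 0 relative to injection onset")
    r = r0 * np.exp(-kd_p * alpha * t)
    return float(r) if r.ndim == 0 else r


def observed_koff(kd_p: float, alpha: float) -> float:
    """Observed dissociation rate koff = kd' * alpha."""
    return kd_p * alpha


def kt_from_blank_koff(koff: float, kd_p: float, ka_p: float, p: float) -> float:
    """Invert the blank-curve relation koff = kd'*kt/(kt + ka'*P) for kt.

    Returns ``inf`` when koff >= kd' (no rebinding detectable).
    """
    _require_positive(koff=koff, kd_p=kd_p)
    if koff >= kd_p:
        return float("inf")
    return koff * ka_p * p / (kd_p - koff)


def probe_concentration_from_rmax(
    rmax: float, g: float = DEFAULT_G, mr_b: float = 30_000.0
) -> float:
    """Hydrogel probe concentration P = Rmax / (G * Mr_B), in molar.

    G converts response to mass concentration (default 100 RU per g/L).
    """
    _require_positive(rmax=rmax, g=g, mr_b=mr_b)
    return rmax / (g * mr_b)


def rmax_from_probe_concentration(
    p: float, g: float = DEFAULT_G, mr_b: float = 30_000.0
) -> float:
    """Inverse of :func:`probe_concentration_from_rmax`: Rmax = P * G * Mr_B."""
    _require_positive(p=p, g=g, mr_b=mr_b)
    return p * g * mr_b


def diffusion_rescale_ka(
    ka: float, mr_p: float, mr_b: float, exponent: float = 1.0 / 3.0
) -> float:
    """Rescale a solution-phase ka to the surface-phase ka' of a heavier probe.

    ka' = ka / (Mr_P / Mr_B)^exponent.  The default exponent 1/3 is the
    diffusion (collision-frequency) scaling; the exponent is exposed because
    mass-ratio normalisations in the literature vary between 1/3 and 1.
    """
    _require_positive(mr_p=mr_p, mr_b=mr_b)
    return ka / (mr_p / mr_b) ** exponent


def kt_response_scaled(kt: float, mr_b: float) -> float:
    """Response-scaled transport coefficient kt' = 1e9 * Mr_B * kt.

    1e9 (g*m/mol) converts a flux-velocity kt (m/s) and the target molecular
    weight into the RU-compatible transport coefficient used with
    response-scaled two-compartment models.
    """
    _require_positive(kt=kt, mr_b=mr_b)
    return 1e9 * mr_b * kt


def kt_flow_scaling(tc: float, u: float) -> float:
    """Flow-velocity scaling kt = tc * u^(1/3)."""
    _require_positive(tc=tc, u=u)
    return tc * u ** (1.0 / 3.0)


def tc_from_kt(kt: float, u: float) -> float:
    """Flow-rate-independent coefficient tc = kt / u^(1/3)."""
    _require_positive(kt=kt, u=u)
    return kt / u ** (1.0 / 3.0)


def rebinding_probability(
    hgel: float, dgel: float, kpart: float, ka_p: float, p: float
) -> tuple[float, float]:
    """Probability Pr = 1 - exp(-Hgel/d) that a released target rebinds.

    d = sqrt(Dgel*Kpart / (ka'*P)) is the mean free distance travelled before
    recapture.  Returns ``(d, Pr)``.
    """
    _require_positive(hgel=hgel, dgel=dgel, kpart=kpart, ka_p=ka_p, p=p)
    d = math.sqrt(dgel * kpart / (ka_p * p))
    pr = 1.0 - math.exp(-hgel / d)
    return d, pr
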