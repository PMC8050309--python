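"""Solution-phase competitive kinetics: the Motulsky-Mahan comparator.

A labelled/refractive probe L and an unlabelled inhibitor I are co-injected
at t = 0 over target sites R with zero initial occupancy.  The probe-complex
occupancy admits a closed bi-exponential form (Motulsky & Mahan, 1984):

    KA = k1*L + k2,  KB = k3*I + k4
    S  = sqrt((KA - KB)^2 + 4 k1 k3 L I)
    KF = (KA + KB + S)/2,  KS = (KA + KB - S)/2

    RL(t) = Rmax * k1*L/(KF - KS) * [ k4*(KF - KS)/(KF*KS)
            + (k4 - KF)/KF * exp(-KF t) - (k4 - KS)/KS * exp(-KS t) ]

Only the probe complex contributes to the response (the inhibitor's
refractive contribution is taken as zero).  A numerical ODE oracle of the
three-species network is provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core_models import InvalidParameterError
from .sensorgram import Sensorgram

__all__ = ["CompetitionParams", "motulsky_mahan_curve", "competition_ode_oracle"]


@dataclass(frozen=True)
class CompetitionParams:
    """Probe kinetics (k1, k2), inhibitor kinetics (k3, k4), concentrations."""

    k1: float
    k2: float
    k3: float
    k4: float
    L: float
    I: float
    rmax: float = 100.0

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.k3, self.k4) < 0:
            raise InvalidParameterError("rates must be >= 0")
        if self.L < 0 or self.I < 0 or self.rmax <= 0:
            raise InvalidParameterError("concentrations >= 0 and Rmax > 0 required")


def motulsky_mahan_curve(params: CompetitionParams, t) -> np.ndarray:
    """Closed-form probe-complex response at times ``t`` (s).

    At I = 0 this reduces to 1:1 association with observed rate k1*L + k2.
    The equal-eigenvalue degeneracy (KF == KS) is evaluated by its analytic
    limit rather than by cancelling small differences.
    """
    t = np.asarray(t, dtype=float)
    p = params
    ka_ = p.k1 * p.L + p.k2
    kb_ = p.k3 * p.I + p.k4
    s = np.sqrt((ka_ - kb_) ** 2 + 4.0 * p.k1 * p.k3 * p.L * p.I)
    kf = 0.5 * (ka_ + kb_ + s)
    ks = 0.5 * (ka_ + kb_ - s)
    pref = p.rmax * p.k1 * p.L
    if s <= 1e-10 * kf:
        # degenerate double eigenvalue K = KF = KS
        kk = kf
        g_prime = (-p.k4 / kk**2 - t * (p.k4 - kk) / kk) * np.exp(-kk * t)
        occ = pref * (p.k4 / kk**2 + g_prime)
        return occ
    occ = pref / (kf - ks) * (
        p.k4 * (kf - ks) / (kf * ks)
        + (p.k4 - kf) / kf * np.exp(-kf * t)
        - (p.k4 - ks) / ks * np.exp(-ks * t)
    )
    return occ


def competition_ode_oracle(params: CompetitionParams, t, rtol: float = 1e-11) -> np.ndarray:
    """Probe-complex response by stiff numerical integration of the network.

    Species: free sites R, probe complex RL, inhibitor complex RI with L and I
    in excess (concentrations clamped), matching the closed form's premises.
    Used in tests and cross-checks, not in fitting.
    """
    t = np.asarray(t, dtype=float)
    p = params

    def rhs(_, y):
        rl, ri = y
        r_free = 1.0 - rl - ri  # fraction of sites
        drl = p.k1 * p.L * r_free - p.k2 * rl
        dri = p.k3 * p.I * r_free - p.k4 * ri
        return [drl, dri]

    sol = solve_ivp(rhs, (0.0, float(t[-1]) if t[-1] > 0 else 1e-9), [0.0, 0.0],
                    method="Radau", t_eval=t, rtol=rtol, atol=1e-14)
    if not sol.success:
        raise RuntimeError(f"competition oracle failed: {sol.message}")
    return p.rmax * sol.y[0]


def simulate_competition(params: CompetitionParams, contact_time: float,
                         sample_rate: float = 1.0) -> Sensorgram:
    """Closed-form competition sensorgram over one injection."""
    n = max(int(round(contact_time * sample_rate)), 1)
    t = np.arange(0, n + 1) / sample_rate
    resp = motulsky_mahan_curve(params, t)
    meta = [{"label": "RL", "I": params.I, "L": params.L, "Rmax": params.rmax}]
    prov = {"generator": "motulsky_mahan", **params.__dict__}
    return Sensorgram(t, resp, meta, prov)
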