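"""Global/local nonlinear least-squares fitting of sensorgram curve sets.

Parameters carry a role: ``fixed`` (never moves), ``global`` (one shared
value across the whole curve set) or ``local`` (one value per curve).
Positive rate constants are fitted in log space by default.  Models:

``rebinding``
    Dissociation-phase inhibition of rebinding,
    R = R0 exp(-kd' alpha t) with alpha = beta/(beta + ka' P),
    beta = kt + f ka A, f = 1/(1 + kd/kt), P = Rmax/(G Mr_B).
    The per-curve inhibitor concentration ``A`` comes from curve metadata;
    blank curves (A = 0) contribute to kt through alpha = kt/(kt + ka' P).
    If a parameter ``tc`` is declared instead of ``kt``, each curve's
    transport rate is tied to its metadata flow velocity via kt = tc u^(1/3),
    sharing one flow-rate-independent coefficient across flow rates.

``two_compartment_1to1``
    Numerical two-compartment 1:1 model (association + dissociation) with
    parameters ka_p, kd_p, rmax, kt; injection described by per-curve
    metadata ``conc`` and ``contact_time``.

``simple_1to1``
    Ideal 1:1 binding, closed form, parameters ka, kd, rmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.optimize import least_squares

from .core_models import (
    DEFAULT_G,
    InvalidParameterError,
    KineticConstants,
    kt_flow_scaling,
    probe_concentration_from_rmax,
    rebinding_factor_alpha,
)
from .sensorgram import Sensorgram

__all__ = [
    "Parameter",
    "ParameterEstimate",
    "FitResult",
    "fit_curveset",
    "goodness_stats",
    "chi2_percent",
    "double_reference",
    "time_normalize_at_threshold",
    "estimate_rmax_loading",
    "MODELS",
]

_ROLES = ("fixed", "local", "global")

# default bounds for positive rates when none are given
_RATE_BOUNDS = (1e-12, 1e12)


@dataclass
class Parameter:
    """One model parameter with its fitting role."""

    name: str
    value: float | np.ndarray
    role: str = "fixed"
    bounds: tuple[float, float] | None = None
    log: bool = True

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise InvalidParameterError(f"role must be one of {_ROLES}")
        if self.bounds is None:
            self.bounds = _RATE_BOUNDS if self.log else (-np.inf, np.inf)
        if self.log and np.any(np.asarray(self.value) <= 0):
            raise InvalidParameterError(
                f"{self.name}: log-transformed parameter must be > 0")


@dataclass
class ParameterEstimate:
    value: float | np.ndarray
    se: float | np.ndarray | None
    ci95: float | np.ndarray | None
    role: str

    @property
    def ci_fraction(self):
        """95% confidence interval as a fraction of the estimate."""
        if self.ci95 is None:
            return None
        return self.ci95 / np.abs(self.value)


@dataclass
class FitResult:
    estimates: dict[str, ParameterEstimate]
    chi2_pct: float
    residuals: np.ndarray
    sse: float
    n_obs: int
    n_free: int
    converged: bool
    message: str
    at_bound: list[str] = field(default_factory=list)
    singular_cov: bool = False
    seed: int | None = None

    def __getitem__(self, name: str) -> ParameterEstimate:
        return self.estimates[name]


# ---------------------------------------------------------------------------
# model functions: (t, params_for_curve, metadata_for_curve) -> response
# ---------------------------------------------------------------------------

def _model_rebinding(t: np.ndarray, p: dict[str, float], meta: dict) -> np.ndarray:
    a = float(meta.get("A", 0.0))
    g = float(meta.get("G", DEFAULT_G))
    mr_b = float(meta.get("Mr_B", 30_000.0))
    if "tc" in p:
        u = meta.get("flow_velocity")
        if u is None:
            raise InvalidParameterError(
                "model with tc requires 'flow_velocity' in curve metadata")
        kt = kt_flow_scaling(p["tc"], float(u))
    else:
        kt = p["kt"]
    psite = probe_concentration_from_rmax(p["rmax"], g, mr_b)
    k = KineticConstants(ka=p.get("ka", 0.0), kd=p.get("kd", 0.0),
                         ka_p=p["ka_p"], kd_p=p["kd_p"])
    alpha, _, _ = rebinding_factor_alpha(k, kt, psite, a)
    return p["r0"] * np.exp(-p["kd_p"] * alpha * t)


def _model_simple_1to1(t: np.ndarray, p: dict[str, float], meta: dict) -> np.ndarray:
    conc = float(meta["conc"])
    tc_inj = float(meta.get("contact_time", t[-1]))
    kobs = p["ka"] * conc + p["kd"]
    req = p["rmax"] * conc / (conc + p["kd"] / p["ka"])
    r = np.where(t <= tc_inj,
                 req * (1.0 - np.exp(-kobs * t)),
                 req * (1.0 - np.exp(-kobs * tc_inj))
                 * np.exp(-p["kd"] * np.clip(t - tc_inj, 0, None)))
    return r


def _model_two_compartment(t: np.ndarray, p: dict[str, float], meta: dict) -> np.ndarray:
    # local import avoids a cycle (ode_simulator does not import fitting)
    from .ode_simulator import InjectionProgram, simulate_two_compartment

    conc = float(meta["conc"])
    tc_inj = float(meta.get("contact_time", t[-1]))
    k = KineticConstants(ka_p=p["ka_p"], kd_p=p["kd_p"])
    dissoc = max(float(t[-1]) - tc_inj, 0.0)
    dt = np.median(np.diff(t))
    sg = simulate_two_compartment(
        k, p["kt"], p["rmax"],
        InjectionProgram.pulse(tc_inj, conc, dissoc),
        sample_rate=1.0 / dt,
        g=float(meta.get("G", DEFAULT_G)), mr_b=float(meta.get("Mr_B", 30_000.0)),
        rtol=1e-8)
    return np.interp(t, sg.time, sg.response[:, 0])


MODELS: dict[str, Callable[[np.ndarray, dict, dict], np.ndarray]] = {
    "rebinding": _model_rebinding,
    "simple_1to1": _model_simple_1to1,
    "two_compartment_1to1": _model_two_compartment,
}


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

class _Packer:
    def __init__(self, params: list[Parameter], n_curves: int):
        self.params = {p.name: p for p in params}
        self.n_curves = n_curves
        self.slots: list[tuple[str, int | None]] = []
        for p in params:
            if p.role == "global":
                self.slots.append((p.name, None))
            elif p.role == "local":
                for i in range(n_curves):
                    self.slots.append((p.name, i))

    def x0_and_bounds(self):
        x0, lo, hi = [], [], []
        for name, idx in self.slots:
            p = self.params[name]
            v = np.asarray(p.value, dtype=float)
            val = float(v) if v.ndim == 0 else float(v[idx if idx is not None else 0])
            b0, b1 = p.bounds
            if p.log:
                x0.append(np.log(val)); lo.append(np.log(b0)); hi.append(np.log(b1))
            else:
                x0.append(val); lo.append(b0); hi.append(b1)
        return np.array(x0), (np.array(lo), np.array(hi))

    def unpack(self, x: np.ndarray) -> list[dict[str, float]]:
        """Per-curve parameter dictionaries from the free vector."""
        per_curve = [dict() for _ in range(self.n_curves)]
        for name, p in self.params.items():
            if p.role == "fixed":
                v = np.asarray(p.value, dtype=float)
                for i in range(self.n_curves):
                    per_curve[i][name] = float(v) if v.ndim == 0 else float(v[i])
        for (name, idx), xi in zip(self.slots, x):
            p = self.params[name]
            val = float(np.exp(xi)) if p.log else float(xi)
            if idx is None:
                for i in range(self.n_curves):
                    per_curve[i][name] = val
            else:
                per_curve[idx][name] = val
        return per_curve


def fit_curveset(
    curves: Sensorgram,
    model: str,
    params: list[Parameter],
    multistart: list[dict[str, float]] | None = None,
    max_nfev: int | None = None,
) -> FitResult:
    """Fit a model to a curve set, minimising the summed squared residuals
    over all curves simultaneously.

    ``multistart`` optionally lists extra starting-value dictionaries for the
    free parameters; the start with the lowest final SSE wins (ties broken by
    first encountered).
    """
    if model not in MODELS:
        raise InvalidParameterError(f"unknown model {model!r}; have {sorted(MODELS)}")
    fmodel = MODELS[model]
    packer = _Packer(params, curves.n_curves)
    x0, bounds = packer.x0_and_bounds()
    if x0.size == 0:
        raise InvalidParameterError("no free parameters declared")
    t = curves.time
    # NaN samples mark per-curve exclusion windows: they contribute nothing
    finite = np.isfinite(curves.response)

    def residuals(x: np.ndarray) -> np.ndarray:
        per_curve = packer.unpack(x)
        out = np.zeros(t.size * curves.n_curves)
        for i in range(curves.n_curves):
            m = finite[:, i]
            pred = fmodel(t[m], per_curve[i], curves.metadata[i])
            block = out[i * t.size:(i + 1) * t.size]
            block[m] = pred - curves.response[m, i]
        return out

    starts = [x0]
    if multistart:
        for sd in multistart:
            xs = x0.copy()
            for j, (name, _) in enumerate(packer.slots):
                if name in sd:
                    p = packer.params[name]
                    xs[j] = np.log(sd[name]) if p.log else sd[name]
            starts.append(xs)

    best = None
    for xs in starts:
        res = least_squares(residuals, xs, bounds=bounds, method="trf",
                            x_scale="jac", max_nfev=max_nfev)
        if best is None or res.cost < best.cost:
            best = res
    res = best

    at_bound = []
    lo, hi = bounds
    for j, (name, _) in enumerate(packer.slots):
        span = hi[j] - lo[j]
        if span > 0 and (res.x[j] - lo[j] < 1e-8 * span or hi[j] - res.x[j] < 1e-8 * span):
            at_bound.append(name)

    per_curve = packer.unpack(res.x)
    resid = res.fun.reshape(curves.n_curves, t.size).T
    sse = float(np.sum(res.fun**2))
    n_obs, n_free = int(finite.sum()), res.x.size

    se_x, singular = _se_from_jacobian(res.jac, sse, n_obs, n_free)

    estimates: dict[str, ParameterEstimate] = {}
    for name, p in packer.params.items():
        if p.role == "fixed":
            estimates[name] = ParameterEstimate(p.value, None, None, "fixed")
            continue
        idxs = [j for j, (n, _) in enumerate(packer.slots) if n == name]
        vals = np.array([per_curve[packer.slots[j][1] or 0][name] if packer.slots[j][1] is not None
                         else per_curve[0][name] for j in idxs])
        ses = se_x[idxs]
        if p.log:
            ses = vals * ses  # delta method: SE on p from SE on ln(p)
        if p.role == "global":
            estimates[name] = ParameterEstimate(float(vals[0]),
                                                float(ses[0]) if ses[0] is not None else None,
                                                float(1.96 * ses[0]), "global")
        else:
            estimates[name] = ParameterEstimate(vals, ses, 1.96 * ses, "local")

    chi2 = chi2_percent(resid, curves.response)
    return FitResult(
        estimates=estimates, chi2_pct=chi2, residuals=resid, sse=sse,
        n_obs=n_obs, n_free=n_free,
        converged=bool(res.success), message=str(res.status) + ": " + res.message,
        at_bound=at_bound, singular_cov=singular)


def _se_from_jacobian(jac: np.ndarray, sse: float, n_obs: int, n_free: int):
    """Standard errors from the Jacobian-based covariance; flags singularity."""
    dof = max(n_obs - n_free, 1)
    s2 = sse / dof
    jtj = jac.T @ jac
    singular = False
    try:
        cov = np.linalg.inv(jtj) * s2
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * s2
        singular = True
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    cond = np.linalg.cond(jtj)
    if cond > 1e12:
        singular = True
    return se, singular


def chi2_percent(residuals: np.ndarray, response: np.ndarray,
                 literal_square: bool = False) -> float:
    """Fit quality as a percentage of the maximum response in the curve set.

    Default: 100 * RMS(residual) / max(response), which keeps response units.
    ``literal_square=True`` instead reports 100 * mean(residual^2) / max
    (the squared-average variant).  High-quality fits give values < 5.
    """
    m = np.isfinite(response)
    rmax = float(np.max(np.abs(response[m])))
    if rmax == 0:
        return 0.0
    r = residuals[m]
    if literal_square:
        return 100.0 * float(np.mean(r**2)) / rmax
    return 100.0 * float(np.sqrt(np.mean(r**2))) / rmax


def goodness_stats(result: FitResult) -> dict[str, Any]:
    """Summary table of %chi2 and per-parameter SE / 95% CI fractions."""
    out: dict[str, Any] = {"chi2_pct": result.chi2_pct, "parameters": {}}
    for name, est in result.estimates.items():
        if est.role == "fixed":
            continue
        out["parameters"][name] = {
            "value": est.value, "se": est.se, "ci95": est.ci95,
            "ci_fraction": est.ci_fraction,
        }
    return out


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def double_reference(active: Sensorgram, reference: Sensorgram,
                     blank: Sensorgram) -> Sensorgram:
    """Double referencing: active - reference - blank.

    Reference and blank curves are linearly resampled onto the active time
    base; their time ranges must cover it.
    """
    t = active.time
    for other, name in ((reference, "reference"), (blank, "blank")):
        if other.time[0] > t[0] + 1e-9 or other.time[-1] < t[-1] - 1e-9:
            raise ValueError(f"{name} curve does not cover the active time range")
    ref = np.column_stack([
        np.interp(t, reference.time, reference.response[:, min(i, reference.n_curves - 1)])
        for i in range(active.n_curves)])
    blk = np.column_stack([
        np.interp(t, blank.time, blank.response[:, min(i, blank.n_curves - 1)])
        for i in range(active.n_curves)])
    prov = dict(active.provenance)
    prov["double_referenced"] = True
    return Sensorgram(t.copy(), active.response - ref - blk,
                      [dict(m) for m in active.metadata], prov)


def time_normalize_at_threshold(curves: Sensorgram, threshold: float) -> Sensorgram:
    """Shift each curve's time origin to its downward crossing of ``threshold``.

    The crossing time is linearly interpolated between samples; curves are
    then resampled onto a common grid starting at the crossing, so the
    response at t = 0 equals the threshold to interpolation accuracy.  Curves
    that never cross while decreasing are excluded with a warning.
    """
    t = curves.time
    crossings, kept = [], []
    for i in range(curves.n_curves):
        y = curves.response[:, i]
        above = y >= threshold
        idx = np.flatnonzero(above[:-1] & ~above[1:])
        if idx.size == 0:
            warnings.warn(f"curve {i} never crosses {threshold} RU while "
                          "decreasing; excluded from alignment")
            continue
        j = int(idx[0])
        frac = (y[j] - threshold) / (y[j] - y[j + 1])
        crossings.append(t[j] + frac * (t[j + 1] - t[j]))
        kept.append(i)
    if not kept:
        raise ValueError("no curve crosses the threshold")
    dt = float(np.median(np.diff(t)))
    horizon = min(t[-1] - tc for tc in crossings)
    n = int(np.floor(horizon / dt))
    new_t = np.arange(n + 1) * dt
    resp = np.column_stack([
        np.interp(new_t + tc, t, curves.response[:, i])
        for tc, i in zip(crossings, kept)])
    meta = [dict(curves.metadata[i], t_cross=float(tc))
            for tc, i in zip(crossings, kept)]
    prov = dict(curves.provenance)
    prov["time_normalized_at"] = threshold
    return Sensorgram(new_t, resp, meta, prov)


def estimate_rmax_loading(curves: Sensorgram, ka0: float = 1e6, kd0: float = 0.1,
                          rmax0: float | None = None) -> FitResult:
    """Estimate the saturation response Rmax from association-phase loading
    curves at known analyte concentration (simple 1:1 fit, all global)."""
    if rmax0 is None:
        rmax0 = 2.0 * float(np.max(curves.response))
    params = [
        Parameter("ka", ka0, "global"),
        Parameter("kd", kd0, "global"),
        Parameter("rmax", rmax0, "global"),
    ]
    return fit_curveset(curves, "simple_1to1", params)
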