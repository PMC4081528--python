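"""Two-exponential endolymphatic tracer-uptake model and its fitting.

The endolymph concentration during steady perilymphatic tracer
perfusion follows

    C_e(t) = C0 * [ P'/P''
                    + (a*P' - 0.5*P'*P'') / (P''*(P'' - a)) * exp(-P' t)
                    - 0.5*P' / (P'' - a) * exp(-a t) ]

with P' the perilymph-endolymph exchange rate constant, P'' the
endolymphatic extrusion rate constant and ``a`` (alpha) the slope time
constant, all in 1/min.  The bracket vanishes identically at t = 0 and
tends to P'/P'' as t -> inf.

The expression has a pole at alpha = P''.  Near the pole the two large
terms nearly cancel at small t, so inside a guard band
|P'' - alpha| < GUARD the function is evaluated through a Laurent
expansion in (P'' - alpha), which is accurate to O((P''-alpha)^2) and
free of catastrophic cancellation.  alpha == P'' exactly is rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import NumericalError, ValidationError

__all__ = [
    "GUARD_BAND",
    "KineticParams",
    "FitResult",
    "eval_uptake_model",
    "fit_uptake_model",
    "extract_rate_constant",
]

#: Width of the |P'' - alpha| band inside which the Laurent form is used (1/min).
GUARD_BAND = 1e-6


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the uptake model (all rates in 1/min, C0 in %)."""

    p_prime: float
    p_doubleprime: float
    alpha: float
    c0: float = 100.0

    def __post_init__(self):
        for name in ("p_prime", "p_doubleprime", "alpha", "c0"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValidationError(f"{name} must be strictly positive, got {v}")
        if self.p_doubleprime == self.alpha:
            raise ValidationError(
                "alpha == P'' is a pole of the uptake model; "
                "perturb one of them by more than the guard band")

    @property
    def plateau(self) -> float:
        """Asymptotic concentration C0 * P'/P''."""
        return self.c0 * self.p_prime / self.p_doubleprime


def eval_uptake_model(params: KineticParams, t, method: str = "auto"):
    """Evaluate the uptake model at time(s) ``t`` (min); returns %% of perfusate.

    Accepts a scalar or array ``t``; negative times are rejected.
    ``method`` selects the evaluation path: "auto" (direct form outside
    the guard band, Laurent series inside), "direct" or "series".
    """
    if method not in ("auto", "direct", "series"):
        raise ValidationError(f"unknown evaluation method {method!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be >= 0")
    p1, p2, a, c0 = (params.p_prime, params.p_doubleprime,
                     params.alpha, params.c0)
    eps = p2 - a
    e_p1 = np.exp(-p1 * t_arr)
    use_direct = method == "direct" or (method == "auto" and abs(eps) >= GUARD_BAND)
    if use_direct:
        # grouped direct form: exact cancellation at t = 0 to round-off
        h = (a - 0.5 * p2) * e_p1 - 0.5 * p2 * np.exp(-a * t_arr)
        bracket = (p1 / p2) * (1.0 + h / eps)
    else:
        # Laurent expansion about alpha = P'' (see module docstring)
        e_p2 = np.exp(-p2 * t_arr)
        # (exp(-p1 t) - exp(-p2 t)) via expm1 to avoid cancellation at small t
        diff = e_p2 * np.expm1((p2 - p1) * t_arr)
        h0_over_eps = 0.5 * p2 * diff / eps
        h1 = -e_p1 - 0.5 * p2 * t_arr * e_p2
        h2 = -0.5 * p2 * t_arr ** 2 * e_p2
        bracket = (p1 / p2) * (1.0 + h0_over_eps + h1 + 0.5 * h2 * eps)
    out = c0 * bracket
    if np.ndim(t) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class FitResult:
    params: KineticParams
    rss: float
    converged: bool
    covariance: np.ndarray | None
    stderr: tuple[float, float, float] | None
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "P_prime": self.params.p_prime,
            "P_doubleprime": self.params.p_doubleprime,
            "alpha": self.params.alpha,
            "C0": self.params.c0,
            "rss": self.rss,
            "converged": self.converged,
            "stderr": list(self.stderr) if self.stderr is not None else None,
        }


def _feature_starts(t: np.ndarray, y: np.ndarray, c0: float):
    """Three feature-based starting points (plateau ratio + rise rate)."""
    tail = y[-max(3, len(y) // 5):]
    plateau = float(np.median(tail))
    ratio = min(max(plateau / c0, 1e-3), 0.999)
    # interpolated time of the half-plateau crossing -> rise-rate scale
    half = 0.5 * plateau
    above = np.nonzero(y >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        t50 = float(t[i - 1] + (half - y[i - 1]) * (t[i] - t[i - 1])
                    / max(y[i] - y[i - 1], 1e-12))
    else:
        t50 = max(float(t[1]), 1e-3)
    k_rise = math.log(2.0) / max(t50, 1e-3)
    p1_0 = min(max(k_rise, 1e-3), 20.0)
    p2_0 = p1_0 / ratio
    return [
        (p1_0, p2_0, 0.55 * p2_0),
        (p1_0, 1.4 * p2_0, 0.6 * p2_0),
        (0.9 * ratio, 0.9, 0.45),
    ]


def fit_uptake_model(times_min, conc_pct, c0: float = 100.0,
                     free_c0: bool = False,
                     global_search: bool = False,
                     global_seed: int = 0) -> FitResult:
    """Bounded nonlinear least squares for (P', P'', alpha).

    C0 is fixed at the perfusate normalisation (100 %) unless
    ``free_c0`` is set.  Multi-start from three feature-based initial
    points; ties broken by lowest residual, then lowest P'.  A
    non-convergent fit is returned flagged, never silently.

    The model has a local-minimum ridge at P' = alpha that can trap the
    local optimizer on noisy data; ``global_search`` adds a seeded
    differential-evolution start (deterministic per ``global_seed``)
    whose polished solution competes with the multi-start ones.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(conc_pct, dtype=float)
    if t.size != y.size:
        raise ValidationError("times and concentrations differ in length")
    if t.size < 4:
        raise ValidationError("need at least 4 time points to fit the model")

    def residuals(theta):
        if free_c0:
            p1, p2, a, c = theta
        else:
            p1, p2, a = theta
            c = c0
        eps = p2 - a
        if abs(eps) < GUARD_BAND:  # step over the pole during optimisation
            a = p2 - math.copysign(GUARD_BAND, eps if eps != 0 else 1.0)
        pars = KineticParams(p1, p2, a, c)
        return eval_uptake_model(pars, t) - y

    lb = [1e-4, 1e-4, 1e-4] + ([1e-4] if free_c0 else [])
    ub = [50.0, 50.0, 50.0] + ([1e4] if free_c0 else [])
    starts = _feature_starts(t, y, c0)
    if global_search:
        from scipy.optimize import differential_evolution
        de = differential_evolution(
            lambda th: float(np.sum(residuals(np.concatenate(
                [th, [c0]]) if free_c0 else th) ** 2)),
            [(1e-3, 5.0)] * 3, seed=global_seed, tol=1e-12,
            maxiter=150, polish=False)
        starts = starts + [tuple(de.x)]
    best = None
    for start in starts:
        x0 = list(start) + ([c0] if free_c0 else [])
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(residuals, x0, bounds=(lb, ub),
                                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=5000)
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        rss = float(2.0 * sol.cost)
        key = (rss, sol.x[0])
        if best is None or key < best[0]:
            best = (key, sol, rss)
    if best is None:
        raise NumericalError("all optimizer starts failed")
    _, sol, rss = best
    if free_c0:
        p1, p2, a, c = sol.x
    else:
        p1, p2, a = sol.x
        c = c0
    params = KineticParams(float(p1), float(p2), float(a), float(c))
    converged = bool(sol.success) and bool(np.all(np.isfinite(sol.x)))
    cov = stderr = None
    dof = t.size - sol.x.size
    if converged and dof > 0:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.pinv(jtj) * (rss / dof)
            stderr = tuple(float(s) for s in np.sqrt(np.clip(np.diag(cov), 0, None))[:3])
        except np.linalg.LinAlgError:
            pass
    return FitResult(params=params, rss=rss, converged=converged,
                     covariance=cov, stderr=stderr,
                     message=str(getattr(sol, "message", "")))


def extract_rate_constant(fit: FitResult) -> tuple[float, float | None]:
    """P' (1/min) and its standard error from a converged fit."""
    if not fit.converged:
        raise NumericalError(f"fit did not converge: {fit.message}")
    se = fit.stderr[0] if fit.stderr is not None else None
    return fit.params.p_prime, se
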