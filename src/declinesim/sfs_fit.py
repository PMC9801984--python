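"""Composite-likelihood fitting of simple demographic models to folded SFS.

Four single-population models are fitted per dataset: constant size, a
recent exponential size change, an instantaneous ancient size change, and
both changes combined.  Each timepoint's folded SFS contributes an
independent Poisson composite likelihood (including the monomorphic class),
with the size history truncated at that timepoint's age.  The best model is
chosen by AIC and classified as stable / declining / expanding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .sfs import FoldedSFS, PiecewiseSizeHistory, expected_folded_sfs

__all__ = [
    "DemographyModel",
    "FitResult",
    "MODEL_IDS",
    "SIZE_BOUNDS",
    "T_RC_BOUNDS",
    "T_AC_BOUNDS",
    "composite_loglik",
    "fit_model",
    "fit_all_models",
    "select_model",
    "classify_trend",
]

MODEL_IDS = ("M1_constant", "M2_recent", "M3_ancient", "M4_both")
SIZE_BOUNDS = (10.0, 500_000.0)
T_RC_BOUNDS = (10.0, 120.0)  # ybp
T_AC_BOUNDS = (1_000.0, 100_000.0)  # ybp

_PARAM_NAMES = {
    "M1_constant": ("N_constant",),
    "M2_recent": ("N_contemp", "N_historic", "T_rc"),
    "M3_ancient": ("N_base", "N_ancient", "T_ac"),
    "M4_both": ("N_contemp", "N_historic", "T_rc", "N_ancient", "T_ac"),
}
_N_FREE = {"M1_constant": 1, "M2_recent": 3, "M3_ancient": 3, "M4_both": 5}


@dataclass(frozen=True)
class DemographyModel:
    """A model id plus a concrete parameter assignment (sizes diploid, times ybp)."""

    id: str
    params: dict

    def __post_init__(self) -> None:
        if self.id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.id!r}")
        missing = set(_PARAM_NAMES[self.id]) - set(self.params)
        if missing:
            raise ValueError(f"missing parameters {sorted(missing)} for {self.id}")

    @property
    def k(self) -> int:
        return _N_FREE[self.id]

    @property
    def has_recent_change(self) -> bool:
        return self.id in ("M2_recent", "M4_both")

    def history(self, gen_time: float) -> PiecewiseSizeHistory:
        """Backward-time size history in generations."""
        p = self.params
        if self.id == "M1_constant":
            return PiecewiseSizeHistory.constant(p["N_constant"])
        if self.id == "M2_recent":
            return _recent_history(p["N_contemp"], p["N_historic"], p["T_rc"], gen_time)
        if self.id == "M3_ancient":
            g_ac = p["T_ac"] / gen_time
            return PiecewiseSizeHistory(
                (0.0, g_ac), (p["N_base"], p["N_ancient"]), (0.0, 0.0)
            )
        g_rc = p["T_rc"] / gen_time
        g_ac = p["T_ac"] / gen_time
        beta = np.log(p["N_historic"] / p["N_contemp"]) / g_rc
        return PiecewiseSizeHistory(
            (0.0, g_rc, g_ac),
            (p["N_contemp"], p["N_historic"], p["N_ancient"]),
            (beta, 0.0, 0.0),
        )

    def size_at_ybp(self, ybp: float, gen_time: float) -> float:
        return self.history(gen_time).size_at(ybp / gen_time)


def _recent_history(n_c, n_h, t_rc, gen_time) -> PiecewiseSizeHistory:
    g_rc = t_rc / gen_time
    if abs(np.log(n_h / n_c)) < 1e-12:
        return PiecewiseSizeHistory.constant(n_c)
    beta = np.log(n_h / n_c) / g_rc
    return PiecewiseSizeHistory((0.0, g_rc), (n_c, n_h), (beta, 0.0))


@dataclass
class FitResult:
    model: DemographyModel
    loglik: float
    aic: float
    Ne_C_hat: float
    Ne_H_hat: float
    converged: bool
    bound_hit: bool
    n_starts: int = 0
    message: str = ""


def _poisson_terms(observed: np.ndarray, expected: np.ndarray) -> float:
    if np.any((expected <= 0) & (observed > 0)):
        return -np.inf
    ok = expected > 0
    o, e = observed[ok], expected[ok]
    return float(np.sum(o * np.log(e) - e - gammaln(o + 1.0)))


def composite_loglik(
    model: DemographyModel,
    observed: list[FoldedSFS],
    gen_time: float,
    mu: float,
) -> float:
    """Sum of per-timepoint Poisson log-likelihoods, monomorphic class included."""
    history = model.history(gen_time)
    total = 0.0
    for sfs in observed:
        if sfs.n < 2:
            continue
        expected = expected_folded_sfs(
            history,
            sfs.n,
            sfs.L,
            mu,
            sample_time_generations=sfs.timepoint / gen_time,
            timepoint=sfs.timepoint,
        ).counts
        total += _poisson_terms(sfs.counts, expected)
        e_mono = sfs.L - expected.sum()
        o_mono = sfs.L - sfs.counts.sum()
        if e_mono <= 0:
            return -np.inf
        total += o_mono * np.log(e_mono) - e_mono - gammaln(o_mono + 1.0)
    return total


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def _transform_bounds(model_id: str) -> list[tuple[float, float]]:
    lo_n, hi_n = np.log10(SIZE_BOUNDS[0]), np.log10(SIZE_BOUNDS[1])
    size = (lo_n, hi_n)
    t_rc = T_RC_BOUNDS
    t_ac = (np.log10(T_AC_BOUNDS[0]), np.log10(T_AC_BOUNDS[1]))
    return {
        "M1_constant": [size],
        "M2_recent": [size, size, t_rc],
        "M3_ancient": [size, size, t_ac],
        "M4_both": [size, size, t_rc, size, t_ac],
    }[model_id]


def _decode(model_id: str, x: np.ndarray) -> DemographyModel:
    params = {}
    for name, val in zip(_PARAM_NAMES[model_id], x):
        # sizes and T_ac are optimized in log10 space, T_rc on its natural scale
        params[name] = float(val) if name == "T_rc" else float(10.0**val)
    return DemographyModel(model_id, params)


def fit_model(
    model_id: str,
    observed: list[FoldedSFS],
    gen_time: float,
    mu: float,
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 200,
) -> FitResult:
    """Bounded multi-start truncated-Newton fit of one model."""
    bounds = _transform_bounds(model_id)
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        ll = composite_loglik(_decode(model_id, x), observed, gen_time, mu)
        return 1e18 if not np.isfinite(ll) else -ll

    best = None
    n_ok = 0
    for start in range(n_starts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(
            objective,
            x0,
            method="TNC",
            bounds=bounds,
            options={"maxfun": maxiter * (len(bounds) + 1), "xtol": 1e-8},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e17:
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is not None:
        # simplex polish: TNC stalls on the flat N_contemp/T_rc ridge
        polish = minimize(
            objective,
            best.x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": 100 * len(bounds), "fatol": 1e-6, "xatol": 1e-6},
        )
        if np.isfinite(polish.fun) and polish.fun < best.fun:
            best = polish
    if best is None:
        return FitResult(
            model=DemographyModel(model_id, dict.fromkeys(_PARAM_NAMES[model_id], np.nan)),
            loglik=-np.inf,
            aic=np.inf,
            Ne_C_hat=np.nan,
            Ne_H_hat=np.nan,
            converged=False,
            bound_hit=False,
            n_starts=n_starts,
            message="all starts failed",
        )
    model = _decode(model_id, best.x)
    loglik = -best.fun
    aic = 2 * model.k - 2 * loglik
    bound_hit = any(
        np.isclose(v, lo, atol=1e-6) or np.isclose(v, hi, atol=1e-6)
        for v, (lo, hi) in zip(best.x, bounds)
    )
    return FitResult(
        model=model,
        loglik=loglik,
        aic=aic,
        Ne_C_hat=model.size_at_ybp(0.0, gen_time),
        Ne_H_hat=model.size_at_ybp(120.0, gen_time),
        converged=n_ok > 0,
        bound_hit=bound_hit,
        n_starts=n_starts,
        message=str(best.message),
    )


def fit_all_models(
    observed: list[FoldedSFS],
    gen_time: float,
    mu: float,
    model_ids: tuple[str, ...] = MODEL_IDS,
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 200,
) -> list[FitResult]:
    fits = []
    for i, mid in enumerate(model_ids):
        fits.append(
            fit_model(
                mid, observed, gen_time, mu,
                n_starts=n_starts, seed=seed + 1000 * i, maxiter=maxiter,
            )
        )
    return fits


def select_model(fits: list[FitResult], use_aicc: bool = False, n_obs: int = 0) -> FitResult:
    """Minimum-AIC fit; ties broken toward fewer parameters; non-converged excluded."""
    candidates = [f for f in fits if f.converged]
    if not candidates:
        raise ValueError("no converged fits to select from")

    def criterion(f: FitResult) -> float:
        aic = f.aic
        if use_aicc and n_obs > f.model.k + 1:
            aic += 2 * f.model.k * (f.model.k + 1) / (n_obs - f.model.k - 1)
        return aic

    return min(candidates, key=lambda f: (criterion(f), f.model.k))


def classify_trend(best: FitResult) -> str:
    """stable / declining / expanding based on the selected model."""
    if not best.model.has_recent_change:
        return "stable"
    return "declining" if best.Ne_C_hat < best.Ne_H_hat else "expanding"
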