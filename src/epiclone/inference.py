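"""Likelihood-based fitting of single-progenitor parameters to clone data.

The likelihood of a clone observed at time t with basal size b is the
conditional pmf P(basal = b | basal >= detection_min) under the
single-progenitor process, the conditioning reflecting that extinct (or
sub-detection) clones are never scored in wholemount imaging.  Basal-size
pmfs come from the generating-function route of :mod:`epiclone.sp_model`
(exact in clone size, no truncation), which the test suite cross-checks
against the truncated master equation and Gillespie simulation.

Suprabasal counts are not used in the likelihood; they inform the tissue
model instead.

Model comparison between balanced (delta = 0) and biased fate is by AIC,
with the likelihood-ratio statistic also reported.  The default fit bounds
constrain delta to [0, 2r] — the biased alternative is an excess of
PP divisions — so the null delta = 0 lies on the boundary and the chi-square
reference for the LRT is approximate (a 50:50 chi-bar-square mixture);
bounds are configurable where signed imbalance is of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .params import SPParams
from .sp_model import basal_size_pmf

__all__ = ["FitSpec", "FitResult", "clone_loglik", "fit_sp_params", "compare_models"]

_FREE_PARAMS = ("r", "lam", "delta", "gamma")

_DEFAULT_BOUNDS = {
    "r": (0.02, 0.5),
    "lam": (0.05, 10.0),
    "delta": (0.0, None),  # upper bound 2r applied dynamically
    "gamma": (0.05, 10.0),
}


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``free``: subset of {r, lam, delta, gamma} to optimise; the remaining
    parameters are taken from ``fixed``.  ``detection_min`` is the smallest
    observable basal size (clones below it are unobservable and the
    likelihood conditions on it).
    """

    free: tuple[str, ...] = ("delta",)
    fixed: SPParams = field(default_factory=SPParams)
    detection_min: int = 1
    bounds: dict = field(default_factory=dict)
    n_starts: int = 5
    n_bootstrap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("at least one free parameter is required")
        bad = [p for p in self.free if p not in _FREE_PARAMS]
        if bad:
            raise ValueError(f"unknown free parameters {bad}; valid: {_FREE_PARAMS}")
        if self.detection_min < 1:
            raise ValueError("detection_min must be >= 1")

    def bound(self, name: str, r_value: float) -> tuple[float, float]:
        lo, hi = self.bounds.get(name, _DEFAULT_BOUNDS[name])
        if name == "delta" and hi is None:
            hi = 2.0 * r_value
        return (lo, hi)


@dataclass
class FitResult:
    """Point estimates, log-likelihood and bootstrap intervals."""

    estimates: dict[str, float]
    loglik: float
    n_free: int
    converged: bool
    n_clones: int
    bootstrap_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    bootstrap_samples: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_free - 2.0 * self.loglik

    @property
    def params(self) -> SPParams:
        return SPParams(**{k: self.estimates[k] for k in ("r", "lam", "delta", "gamma", "mu")})

    def to_kv(self) -> dict:
        out = {f"estimate_{k}": v for k, v in self.estimates.items()}
        out["loglik"] = self.loglik
        out["aic"] = self.aic
        out["converged"] = self.converged
        out["n_clones"] = self.n_clones
        for k, (lo, hi) in self.bootstrap_ci.items():
            out[f"ci_{k}_low"] = lo
            out[f"ci_{k}_high"] = hi
        return out


# pmf memo: clone likelihoods are re-evaluated at many nearby parameter
# values during optimisation and bootstrapping.  The optimiser works on a
# parameter lattice (step _QUANT, far below statistical resolution) and the
# required pmf length is rounded up to a power of two, so repeated starts and
# bootstrap refits hit the cache instead of re-solving the generating-function
# ODE.
_PMF_CACHE: dict = {}
_PMF_CACHE_MAX = 4096
_QUANT = 1e-4

# Entries of an FFT-inverted pmf below ~len(pmf) * eps are numerical noise;
# observed sizes out there are scored through a censored tail bin instead.
_NOISE_FLOOR_SCALE = 1e-15


def _cached_basal_pmf(params: SPParams, t: float, n_need: int) -> np.ndarray:
    n_key = 64
    while n_key < 2 * n_need:
        n_key *= 2
    key = (
        round(params.r, 12),
        round(params.lam, 12),
        round(params.delta, 12),
        round(params.gamma, 12),
        round(t, 12),
        n_key,
    )
    pmf = _PMF_CACHE.get(key)
    if pmf is None:
        pmf = basal_size_pmf(params, t, n_max=n_key)
        if len(_PMF_CACHE) >= _PMF_CACHE_MAX:
            _PMF_CACHE.clear()
        _PMF_CACHE[key] = pmf
    return pmf


def _grouped_loglik(params: SPParams, grouped: dict, detection_min: int) -> float:
    """Conditional log-likelihood of collapsed size counts; -inf if impossible.

    Sizes whose pmf entry lies below the FFT noise floor are censored into a
    single tail bin scored with the (accurately computed) survival
    probability beyond the last reliable size.
    """
    total = 0.0
    for t, (sizes, counts) in grouped.items():
        pmf = _cached_basal_pmf(params, t, int(sizes.max()))
        floor = pmf.size * _NOISE_FLOOR_SCALE
        denom = 1.0 - pmf[:detection_min].sum()
        if denom <= floor:
            return -np.inf
        reliable = np.flatnonzero(pmf > floor)
        cut = int(reliable[-1]) + 1 if reliable.size else 0
        in_head = sizes < cut
        if in_head.any():
            p_head = pmf[sizes[in_head]]
            if np.any(p_head <= 0.0):
                return -np.inf
            total += float(counts[in_head] @ np.log(p_head / denom))
        n_tail = int(counts[~in_head].sum())
        if n_tail:
            s_tail = 1.0 - pmf[:cut].sum()
            if s_tail <= floor:
                return -np.inf
            total += n_tail * float(np.log(s_tail / denom))
    return total


def _size_counts(clones: pd.DataFrame, detection_min: int):
    """Collapse a clone table to {time: (sizes, counts, n_max)}."""
    if len(clones) == 0:
        raise ValueError("empty clone table")
    if (clones["n_basal"] < detection_min).any():
        bad = clones.index[clones["n_basal"] < detection_min][:3].tolist()
        raise ValueError(
            f"clones {bad} fall below the detection rule (basal >= {detection_min})"
        )
    out = {}
    for t, grp in clones.groupby("time_weeks"):
        sizes, counts = np.unique(grp["n_basal"].to_numpy(int), return_counts=True)
        out[float(t)] = (sizes, counts)
    return out


def clone_loglik(
    params: SPParams, clones: pd.DataFrame, spec: FitSpec | None = None
) -> float:
    """Log-likelihood of observed basal clone sizes under ``params``.

    Sums, over clones, log P(basal size | basal >= detection_min) at each
    clone's observation time.  Returns ``-inf`` when the data are impossible
    under ``params`` (e.g. clones larger than the model can produce).
    Deterministic given params.
    """
    if spec is None:
        spec = FitSpec()
    grouped = _size_counts(clones, spec.detection_min)
    return _grouped_loglik(params, grouped, spec.detection_min)


def _pack(spec: FitSpec, theta: np.ndarray) -> SPParams:
    values = dict(zip(spec.free, theta))
    return spec.fixed.with_(**values)


def fit_sp_params(clones: pd.DataFrame, spec: FitSpec) -> FitResult:
    """Bounded maximum-likelihood fit with multi-start and clone bootstrap."""
    grouped = _size_counts(clones, spec.detection_min)
    if len(grouped) < 2:
        import warnings

        warnings.warn(
            "fewer than 2 timepoints: parameters may be unidentifiable",
            RuntimeWarning,
            stacklevel=2,
        )

    r_ref = spec.fixed.r
    bounds = [spec.bound(name, r_ref) for name in spec.free]

    def nll(theta, data):
        theta = np.round(np.asarray(theta, dtype=float) / _QUANT) * _QUANT
        try:
            p = _pack(spec, theta)
        except ValueError:
            return 1e10
        ll = _grouped_loglik(p, data, spec.detection_min)
        return -ll if np.isfinite(ll) else 1e10

    rng = np.random.default_rng(spec.seed)
    starts = []
    mid = np.array([(lo + hi) / 2.0 for lo, hi in bounds])
    starts.append(np.array([getattr(spec.fixed, n) for n in spec.free], dtype=float))
    starts[0] = np.clip(starts[0], [b[0] for b in bounds], [b[1] for b in bounds])
    for _ in range(spec.n_starts - 1):
        starts.append(
            np.array([rng.uniform(lo, hi) for lo, hi in bounds], dtype=float)
        )

    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll,
            x0,
            args=(grouped,),
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": _QUANT, "fatol": 1e-7, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e10:
        raise RuntimeError(
            f"optimisation failed after {spec.n_starts} starts "
            f"(last status: {getattr(best, 'message', 'n/a')})"
        )

    # report the lattice point actually evaluated, clipped into bounds
    theta_hat = np.round(np.asarray(best.x, dtype=float) / _QUANT) * _QUANT
    theta_hat = np.clip(theta_hat, [b[0] for b in bounds], [b[1] for b in bounds])
    params_hat = _pack(spec, theta_hat)
    estimates = {
        k: float(getattr(params_hat, k)) for k in ("r", "lam", "delta", "gamma", "mu")
    }
    result = FitResult(
        estimates=estimates,
        loglik=-float(best.fun),
        n_free=len(spec.free),
        converged=bool(best.success),
        n_clones=int(len(clones)),
    )

    if spec.n_bootstrap > 0:
        boots = {name: np.empty(spec.n_bootstrap) for name in spec.free}
        n = len(clones)
        for b in range(spec.n_bootstrap):
            sample = clones.iloc[rng.integers(0, n, n)]
            data_b = _size_counts(sample, spec.detection_min)
            res_b = optimize.minimize(
                nll,
                theta_hat,
                args=(data_b,),
                method="Nelder-Mead",
                bounds=bounds,
                options={"xatol": _QUANT, "fatol": 1e-6, "maxiter": 600},
            )
            theta_b = np.round(np.asarray(res_b.x, dtype=float) / _QUANT) * _QUANT
            for j, name in enumerate(spec.free):
                boots[name][b] = theta_b[j]
        for name in spec.free:
            result.bootstrap_samples[name] = boots[name]
            result.bootstrap_ci[name] = (
                float(np.percentile(boots[name], 2.5)),
                float(np.percentile(boots[name], 97.5)),
            )
    return result


def compare_models(clones: pd.DataFrame, spec: FitSpec) -> dict:
    """Balanced (delta = 0) versus biased (delta free) model comparison.

    Returns the likelihood-ratio statistic 2 * (ll_biased - ll_balanced),
    the AIC difference (balanced minus biased; positive favours biased) and
    the AIC-preferred model.  ``spec.free`` must include "delta".
    """
    if "delta" not in spec.free:
        raise ValueError("spec.free must include 'delta' for model comparison")
    from dataclasses import replace as _replace

    free_null = tuple(p for p in spec.free if p != "delta")
    spec_alt = _replace(spec, n_bootstrap=0)
    fit_alt = fit_sp_params(clones, spec_alt)

    fixed_null = spec.fixed.with_(delta=0.0)
    if free_null:
        spec_null = _replace(spec, free=free_null, fixed=fixed_null, n_bootstrap=0)
        fit_null = fit_sp_params(clones, spec_null)
        ll_null, k_null = fit_null.loglik, fit_null.n_free
        est_null = fit_null.estimates
    else:
        ll_null = clone_loglik(fixed_null, clones, spec)
        k_null, est_null = 0, {k: float(getattr(fixed_null, k)) for k in ("r", "lam", "delta", "gamma", "mu")}

    lrt = 2.0 * (fit_alt.loglik - ll_null)
    aic_null = 2.0 * k_null - 2.0 * ll_null
    aic_diff = aic_null - fit_alt.aic
    return {
        "lrt_statistic": lrt,
        "aic_balanced": aic_null,
        "aic_biased": fit_alt.aic,
        "aic_difference": aic_diff,
        "preferred": "biased" if aic_diff > 0 else "balanced",
        "estimates_biased": fit_alt.estimates,
        "estimates_balanced": est_null,
    }
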