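"""Leave-one-out model comparison, coverage, prior sensitivity, correlations.

``loo_metrics`` is the workhorse: for each observation the model is refit on
the remaining N-1 points and made to predict the held-out force, yielding

    LOO-RMSE  = sqrt( mean_i (y_i - yhat_(-i))^2 )                [pN]
    LOO-R^2   = 1 - sum_i (y_i - yhat_(-i))^2 / sum_i (y_i - ybar)^2
    LOO-LL    = sum_i log Normal(y_i | yhat_(-i), LOO-RMSE)

with the LOO-R^2 spread estimated by the jackknife over leave-one-out
recomputations of R^2.  The remaining utilities measure empirical coverage of
a predictive band, posterior-mean shifts across prior-width regimes
(narrow / original / wide), and pairwise Pearson correlations of the pooled
posterior draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes import MCMCConfig, PosteriorSamples, PriorSpec, sample_posterior
from .datasets import AdhesionDataset

__all__ = ["LooReport", "SensitivityReport", "CorrelationReport",
           "loo_metrics", "empirical_coverage", "prior_sensitivity",
           "posterior_correlations", "NARROW_WIDTHS", "ORIGINAL_WIDTHS",
           "WIDE_WIDTHS"]

# prior-width regimes of the sensitivity sweep: (sigma_F, sigma_tau)
NARROW_WIDTHS = (50.0, 0.5)
ORIGINAL_WIDTHS = (300.0, 1.0)
WIDE_WIDTHS = (600.0, 3.0)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LooReport:
    loo_r2: float
    loo_r2_sd: float
    loo_ll: float
    loo_rmse: float
    predictions: np.ndarray           # LOO prediction per observation (NaN if failed)
    failed_folds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "loo_r2": self.loo_r2,
            "loo_r2_sd": self.loo_r2_sd,
            "loo_ll": self.loo_ll,
            "loo_rmse": self.loo_rmse,
            "failed_folds": list(self.failed_folds),
        }


def loo_metrics(fit_fn, data: AdhesionDataset) -> LooReport:
    """Leave-one-out evaluation of a model-fitting procedure.

    ``fit_fn`` maps an :class:`AdhesionDataset` to a predictor
    ``times -> forces``.  A fold whose refit raises is excluded from all
    metrics and recorded in ``failed_folds``.
    """
    n = len(data)
    if n < 3:
        raise ValueError("loo_metrics requires at least 3 observations")
    y = data.forces
    preds = np.full(n, np.nan)
    failed = []
    for i in range(n):
        fold = data.drop_observation(i)
        try:
            predictor = fit_fn(fold)
            preds[i] = float(np.asarray(predictor(np.array([data.times[i]]))).ravel()[0])
        except Exception as exc:  # fold excluded, not imputed
            failed.append((i, repr(exc)))
    ok = np.isfinite(preds)
    if ok.sum() < 2:
        raise RuntimeError("too many failed LOO folds to compute metrics")

    resid = y[ok] - preds[ok]
    sse = float(np.sum(resid**2))
    loo_rmse = float(np.sqrt(np.mean(resid**2)))
    ybar = float(np.mean(y[ok]))
    sst = float(np.sum((y[ok] - ybar) ** 2))
    loo_r2 = 1.0 - sse / sst if sst > 0 else float("nan")

    # jackknife over leave-one-out recomputations of R^2
    idx = np.flatnonzero(ok)
    m = idx.size
    r2_reps = np.empty(m)
    for k in range(m):
        keep = np.delete(idx, k)
        yk = y[keep]
        rk = yk - preds[keep]
        sst_k = float(np.sum((yk - yk.mean()) ** 2))
        r2_reps[k] = 1.0 - float(np.sum(rk**2)) / sst_k if sst_k > 0 else np.nan
    r2_bar = np.nanmean(r2_reps)
    loo_r2_sd = float(np.sqrt((m - 1) / m * np.nansum((r2_reps - r2_bar) ** 2)))

    if loo_rmse > 0:
        loo_ll = float(np.sum(-0.5 * _LOG_2PI - np.log(loo_rmse)
                              - 0.5 * (resid / loo_rmse) ** 2))
    else:  # perfect predictions: log-density unbounded
        loo_ll = float("inf")

    return LooReport(loo_r2=loo_r2, loo_r2_sd=loo_r2_sd, loo_ll=loo_ll,
                     loo_rmse=loo_rmse, predictions=preds, failed_folds=failed)


def empirical_coverage(data: AdhesionDataset, lower, upper):
    """Fraction of observations inside the closed band [lower, upper].

    Returns ``(fraction, n_inside, n_total)``.
    """
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    if lo.shape != data.forces.shape or hi.shape != data.forces.shape:
        raise ValueError("band must be defined at every observation")
    inside = (data.forces >= lo) & (data.forces <= hi)
    return float(inside.mean()), int(inside.sum()), int(inside.size)


@dataclass
class SensitivityReport:
    """Posterior means per prior-width regime and percent shift vs original."""

    means: dict            # regime -> {param -> posterior mean}
    shifts: dict           # regime -> {param -> % shift vs original}
    absolute_shift_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"means": self.means, "shifts": self.shifts,
                "absolute_shift_flags": list(self.absolute_shift_flags)}


def default_regimes(base: PriorSpec) -> dict[str, PriorSpec]:
    """Narrow / original / wide prior-width regimes around one center."""
    return {
        "narrow": base.with_widths(*NARROW_WIDTHS),
        "original": base.with_widths(*ORIGINAL_WIDTHS),
        "wide": base.with_widths(*WIDE_WIDTHS),
    }


def prior_sensitivity(data: AdhesionDataset, regimes: dict[str, PriorSpec],
                      mcmc: MCMCConfig) -> SensitivityReport:
    """Repeat posterior inference under each prior-width regime.

    ``regimes`` must contain an ``"original"`` entry; shifts are
    ``100 * (mean_regime - mean_original) / mean_original`` per kinetic
    parameter (absolute difference, flagged, when the original mean is zero).
    """
    if "original" not in regimes:
        raise ValueError("regimes must include 'original'")
    params = ("F0", "Fmax", "tau")
    means: dict[str, dict[str, float]] = {}
    for name, spec in regimes.items():
        post = sample_posterior(data, spec, mcmc)
        means[name] = {p: post.mean(p) for p in params}
    shifts: dict[str, dict[str, float]] = {}
    flags = []
    ref = means["original"]
    for name in regimes:
        shifts[name] = {}
        for p in params:
            if ref[p] != 0.0:
                shifts[name][p] = 100.0 * (means[name][p] - ref[p]) / ref[p]
            else:
                shifts[name][p] = means[name][p] - ref[p]
                flags.append((name, p))
    return SensitivityReport(means=means, shifts=shifts,
                             absolute_shift_flags=flags)


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations of pooled posterior draws."""

    r_F0_Fmax: float
    r_F0_tau: float
    r_Fmax_tau: float
    undefined: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"r_F0_Fmax": self.r_F0_Fmax, "r_F0_tau": self.r_F0_tau,
                "r_Fmax_tau": self.r_Fmax_tau,
                "undefined": list(self.undefined)}


def posterior_correlations(samples: PosteriorSamples) -> CorrelationReport:
    """Pearson r for (F0,Fmax), (F0,tau), (Fmax,tau) over pooled draws."""
    pooled = {p: samples.pooled(p) for p in ("F0", "Fmax", "tau")}
    if next(iter(pooled.values())).size < 10:
        raise ValueError("posterior_correlations requires >= 10 pooled draws")
    undefined = [p for p, v in pooled.items() if np.std(v) == 0]

    def r(a, b):
        if a in undefined or b in undefined:
            return float("nan")
        return float(np.corrcoef(pooled[a], pooled[b])[0, 1])

    return CorrelationReport(
        r_F0_Fmax=r("F0", "Fmax"), r_F0_tau=r("F0", "tau"),
        r_Fmax_tau=r("Fmax", "tau"), undefined=undefined,
    )
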