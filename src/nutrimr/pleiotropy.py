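"""Horizontal-pleiotropy diagnostics.

Three complementary checks on a harmonized instrument set:

* the MR-Egger intercept test — a non-zero intercept indicates average
  directional pleiotropy;
* the MR-PRESSO global test — a Monte-Carlo residual-sum-of-squares test of
  whether any instrument's outcome effect departs from the leave-one-out
  causal prediction, with per-SNP outlier p-values;
* funnel-plot data — per-SNP Wald ratios against instrument precision, with
  the IVW and Egger estimates as reference lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimators
from .summary_data import HarmonizedInstrument

__all__ = [
    "PleiotropyReport",
    "PressoResult",
    "egger_intercept_test",
    "mr_presso_global",
    "funnel_data",
    "pleiotropy_report",
]


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global-test result.

    ``global_p`` is the Monte-Carlo p-value (1 + #{RSS_sim ≥ RSS_obs}) /
    (nsim + 1), bounded below by 1/(nsim+1). ``outlier_pvalues`` are per-SNP
    Monte-Carlo tail probabilities of each observed residual under its own
    simulated distribution; ``outlier_flags`` marks Bonferroni-significant
    SNPs at the given alpha.
    """

    rss_obs: float
    global_p: float
    nsim: int
    seed: int
    snp_ids: tuple[str, ...]
    outlier_pvalues: np.ndarray
    outlier_flags: np.ndarray


@dataclass(frozen=True)
class PleiotropyReport:
    """Egger-intercept and MR-PRESSO results for one instrument set."""

    n_snp: int
    egger_intercept: float
    egger_se: float
    egger_p: float
    presso: PressoResult


def egger_intercept_test(instruments) -> tuple[float, float, float]:
    """(intercept, SE, two-sided p) from the MR-Egger regression."""
    fit = estimators.egger(instruments)
    return fit.intercept, fit.intercept_se, fit.intercept_pvalue


def _loo_ivw_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes β_(−j), vectorized via sum subtraction."""
    num = bx * by * w
    den = bx**2 * w
    return (num.sum() - num) / (den.sum() - den)


def mr_presso_global(
    instruments,
    nsim: int = 10_000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global test for horizontal pleiotropy.

    For each SNP j the leave-one-out IVW estimate β_(−j) predicts the
    outcome effect; the observed residual is d_j = by_j − β_(−j)·bx_j and
    RSS_obs = Σ w_j d_j² with outcome weights w_j = 1/sy_j². The null
    distribution is simulated by drawing by*_j ~ N(β_(−j)·bx_j, sy_j) and
    recomputing the same leave-one-out RSS on each simulated dataset.
    Reproducible bit-for-bit given (instruments, nsim, seed).
    """
    if len(instruments) < 4:
        raise ValueError("MR-PRESSO requires at least four instruments")
    if nsim < 100:
        import warnings

        warnings.warn(f"nsim={nsim} is very small for a Monte-Carlo p-value", stacklevel=2)
    ids = tuple(i.snp_id for i in instruments)
    bx = np.array([i.bx for i in instruments])
    by = np.array([i.by for i in instruments])
    sy = np.array([i.sy for i in instruments])
    w = 1.0 / sy**2
    k = bx.size

    beta_loo = _loo_ivw_betas(bx, by, w)
    d = by - beta_loo * bx
    rss_obs = float(np.sum(w * d**2))

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(beta_loo * bx, sy, size=(nsim, k))
    num = by_sim * (bx * w)
    den = bx**2 * w
    beta_loo_sim = (num.sum(axis=1, keepdims=True) - num) / (den.sum() - den)
    d_sim = by_sim - beta_loo_sim * bx
    rss_sim = np.sum(w * d_sim**2, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (nsim + 1))
    # per-SNP: observed weighted squared residual vs its simulated distribution
    obs_j = w * d**2
    sim_j = w * d_sim**2
    outlier_p = (1 + np.sum(sim_j >= obs_j, axis=0)) / (nsim + 1)
    flags = outlier_p < outlier_alpha / k
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        nsim=nsim,
        seed=seed,
        snp_ids=ids,
        outlier_pvalues=outlier_p,
        outlier_flags=flags,
    )


def funnel_data(instruments) -> pd.DataFrame:
    """Per-SNP funnel-plot table: Wald ratio vs precision (=|bx|/sy).

    The returned frame carries the IVW estimate — and, when at least three
    instruments are available, the Egger slope — in ``DataFrame.attrs`` as
    reference lines.
    """
    rs = estimators.wald_ratios(instruments)
    df = pd.DataFrame(
        {
            "snp_id": list(rs.snp_ids),
            "ratio": rs.ratios,
            "precision": 1.0 / rs.ratio_ses,
        }
    )
    if len(instruments) >= 2:
        df.attrs["ivw_beta"] = estimators.ivw(instruments).beta
    if len(instruments) >= 3:
        df.attrs["egger_beta"] = estimators.egger(instruments).slope.beta
    return df


def pleiotropy_report(instruments, nsim: int = 10_000, seed: int = 0) -> PleiotropyReport:
    """Egger intercept + MR-PRESSO global test as a single report row."""
    intercept, se, p = egger_intercept_test(instruments)
    presso = mr_presso_global(instruments, nsim=nsim, seed=seed)
    return PleiotropyReport(
        n_snp=len(instruments),
        egger_intercept=intercept,
        egger_se=se,
        egger_p=p,
        presso=presso,
    )
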