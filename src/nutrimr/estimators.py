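"""Summary-level Mendelian-randomization estimators.

Six causal-effect estimators computed from harmonized instruments
(γ̂_j = bx_j ± sx_j on the exposure, Γ̂_j = by_j ± sy_j on the outcome):

* **IVW** — fixed-effect inverse-variance-weighted mean of the per-SNP Wald
  ratios r_j = by_j/bx_j with first-order weights w_j = bx_j²/sy_j²;
  equivalently the slope of a weighted regression of by on bx through the
  origin with weights 1/sy².
* **Radial IVW** — the same fit in radial coordinates (√w_j·r_j on √w_j),
  with the SE taken from the regression's estimated residual variance and,
  by default, modified second-order weights updated iteratively; exposes
  per-SNP Cochran-Q contributions and outlier flags.
* **MR-Egger** — weighted regression of by on bx with an unconstrained
  intercept after orienting every instrument to bx_j > 0; the intercept
  estimates average directional pleiotropy.
* **Simple / weighted / penalized weighted median** — (weighted) medians of
  the Wald ratios, consistent when up to half the (weight on) instruments is
  invalid; the penalized variant down-weights instruments with large
  one-step heterogeneity contributions. Median SEs come from a parametric
  bootstrap over the per-SNP estimates.

All p-values are two-sided standard normal on beta/se.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .summary_data import HarmonizedInstrument

__all__ = [
    "MrEstimate",
    "RatioSet",
    "RadialFit",
    "EggerFit",
    "BootstrapConfig",
    "DegenerateInstrumentError",
    "wald_ratios",
    "ivw",
    "radial_ivw",
    "egger",
    "simple_median",
    "weighted_median",
    "penalized_weighted_median",
    "run_all_methods",
    "METHOD_NAMES",
]

METHOD_NAMES = (
    "ivw",
    "ivw_radial",
    "egger",
    "penalized_weighted_median",
    "weighted_median",
    "simple_median",
)


class DegenerateInstrumentError(ValueError):
    """An instrument cannot form a Wald ratio (exposure effect is zero)."""


@dataclass(frozen=True)
class MrEstimate:
    """One estimator's causal-effect estimate (one row of a results table)."""

    method: str
    n_snp: int
    beta: float
    se: float
    pvalue: float


@dataclass(frozen=True)
class RatioSet:
    """Per-instrument Wald ratios with first-order SEs and IVW weights."""

    snp_ids: tuple[str, ...]
    ratios: np.ndarray  # r_j = by_j / bx_j
    ratio_ses: np.ndarray  # s_j = sy_j / |bx_j|
    weights: np.ndarray  # w_j = bx_j² / sy_j² = 1 / s_j²


@dataclass(frozen=True)
class RadialFit:
    """Radial-regression IVW fit with per-SNP heterogeneity contributions."""

    beta: float
    se: float
    pvalue: float
    q_statistic: float
    q_contributions: np.ndarray
    outliers: tuple[str, ...]
    weight_order: str
    n_snp: int

    def estimate(self) -> MrEstimate:
        return MrEstimate("ivw_radial", self.n_snp, self.beta, self.se, self.pvalue)


@dataclass(frozen=True)
class EggerFit:
    """MR-Egger slope plus the directional-pleiotropy intercept."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


@dataclass(frozen=True)
class BootstrapConfig:
    """Parametric-bootstrap settings for the median estimators' SEs."""

    n_boot: int = 5000
    seed: int = 0


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([i.bx for i in instruments], dtype=float)
    sx = np.array([i.sx for i in instruments], dtype=float)
    by = np.array([i.by for i in instruments], dtype=float)
    sy = np.array([i.sy for i in instruments], dtype=float)
    ids = tuple(i.snp_id for i in instruments)
    return ids, bx, sx, by, sy


def _two_sided_p(z) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratios(instruments: Sequence[HarmonizedInstrument]) -> RatioSet:
    """Per-SNP Wald ratios by/bx with first-order SEs sy/|bx|."""
    ids, bx, _sx, by, sy = _arrays(instruments)
    zero = np.flatnonzero(bx == 0.0)
    if zero.size:
        raise DegenerateInstrumentError(
            f"zero exposure effect for {[ids[j] for j in zero]}: Wald ratio undefined"
        )
    s = sy / np.abs(bx)
    return RatioSet(snp_ids=ids, ratios=by / bx, ratio_ses=s, weights=1.0 / s**2)


def ivw(instruments: Sequence[HarmonizedInstrument]) -> MrEstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    β = Σ w_j r_j / Σ w_j with w_j = bx_j²/sy_j², SE = (Σ w_j)^(−1/2).
    A single instrument degenerates to its Wald ratio (allowed with a
    warning).
    """
    rs = wald_ratios(instruments)
    k = len(rs.snp_ids)
    if k == 0:
        raise ValueError("IVW requires at least one instrument")
    if k == 1:
        warnings.warn("IVW with a single instrument reduces to the Wald ratio", stacklevel=2)
    wsum = float(rs.weights.sum())
    beta = float(np.sum(rs.weights * rs.ratios) / wsum)
    se = wsum**-0.5
    return MrEstimate("ivw", k, beta, se, _two_sided_p(beta / se))


def radial_ivw(
    instruments: Sequence[HarmonizedInstrument],
    weight_order: Literal["first", "modified_second"] = "modified_second",
    outlier_alpha: float = 0.05,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> RadialFit:
    """Radial (Galbraith) regression IVW with per-SNP Q contributions.

    Regression through the origin of √w_j·r_j on √w_j. With first-order
    weights the coefficient equals the IVW β exactly; the SE is taken from
    the regression's estimated residual variance, SE = √(Q/(k−1)) / √(Σw).
    Modified second-order weights w_j = 1/(sy_j²/bx_j² + β²·sx_j²/bx_j²) are
    refined iteratively from the first-order solution (the default,
    matching the common "radial IVW" usage).
    """
    ids, bx, sx, by, sy = _arrays(instruments)
    k = len(ids)
    if k < 2:
        raise ValueError("radial IVW requires at least two instruments")
    rs = wald_ratios(instruments)
    r, w = rs.ratios, rs.weights.copy()
    beta = float(np.sum(w * r) / np.sum(w))
    if weight_order == "modified_second":
        for _ in range(max_iter):
            w = 1.0 / (sy**2 / bx**2 + beta**2 * sx**2 / bx**2)
            new_beta = float(np.sum(w * r) / np.sum(w))
            if abs(new_beta - beta) < tol:
                beta = new_beta
                break
            beta = new_beta
    elif weight_order != "first":
        raise ValueError(f"unknown weight_order {weight_order!r}")
    q_j = w * (r - beta) ** 2
    q = float(q_j.sum())
    se = float(np.sqrt(q / (k - 1)) / np.sqrt(w.sum()))
    crit = stats.chi2.isf(outlier_alpha, df=1)
    outliers = tuple(ids[j] for j in np.flatnonzero(q_j > crit))
    return RadialFit(
        beta=beta,
        se=se,
        pvalue=_two_sided_p(beta / se),
        q_statistic=q,
        q_contributions=q_j,
        outliers=outliers,
        weight_order=weight_order,
        n_snp=k,
    )


def egger(
    instruments: Sequence[HarmonizedInstrument],
    residual_scale: Literal["floored", "estimated", "none"] = "floored",
) -> EggerFit:
    """MR-Egger regression: weighted fit of by on bx with an intercept.

    Instruments are first re-oriented so every bx_j > 0 (joint sign flip of
    (bx_j, by_j), which leaves Wald ratios unchanged); weights are 1/sy².
    Standard errors scale the weighted-regression covariance by the estimated
    residual variance with a floor of 1 (``floored``, the default); the
    alternatives use the raw estimate (``estimated``) or no scaling
    (``none``).
    """
    ids, bx, _sx, by, sy = _arrays(instruments)
    k = len(ids)
    if k < 3:
        raise ValueError("MR-Egger requires at least three instruments")
    if np.any(bx == 0.0):
        raise DegenerateInstrumentError("zero exposure effect: cannot orient instrument")
    sign = np.sign(bx)
    bx, by = bx * sign, by * sign

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (X * w[:, None])
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    scale = {"floored": max(sigma2, 1.0), "estimated": sigma2, "none": 1.0}[residual_scale]
    cov = np.linalg.inv(xtwx) * scale
    ses = np.sqrt(np.diag(cov))
    slope = MrEstimate("egger", k, float(coef[1]), float(ses[1]), _two_sided_p(coef[1] / ses[1]))
    return EggerFit(
        slope=slope,
        intercept=float(coef[0]),
        intercept_se=float(ses[0]),
        intercept_pvalue=_two_sided_p(coef[0] / ses[0]),
    )


def _median_even_mean(sorted_vals: np.ndarray) -> float:
    # median with the documented even-count convention (mean of middle two)
    return float(np.median(sorted_vals))


def _weighted_median_value(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``ratios`` under ``weights``.

    Sort ratios ascending, normalize weights to sum 1, form the cumulative
    mid-point scores s_j = Σ_{i≤j} w_i − w_j/2, and interpolate linearly to
    the ratio at s = 0.5.
    """
    if np.all(weights == 0):
        raise ValueError("all-zero weights")
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights[order].sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def _bootstrap_median_se(
    instruments: Sequence[HarmonizedInstrument],
    estimator,
    boot: BootstrapConfig,
) -> float:
    """Parametric bootstrap SE: resample (bx_j, by_j) from their normals."""
    _ids, bx, sx, by, sy = _arrays(instruments)
    rng = np.random.default_rng(boot.seed)
    bx_star = rng.normal(bx, sx, size=(boot.n_boot, bx.size))
    by_star = rng.normal(by, sy, size=(boot.n_boot, by.size))
    # Guard: a resampled bx crossing zero makes the ratio blow up; the median
    # is robust to the tails so the draw is kept as-is.
    ratios = by_star / bx_star
    vals = np.empty(boot.n_boot)
    for b in range(boot.n_boot):
        vals[b] = estimator(ratios[b], bx_star[b], by_star[b])
    return float(vals.std(ddof=1))


def simple_median(
    instruments: Sequence[HarmonizedInstrument],
    boot: BootstrapConfig = BootstrapConfig(),
) -> MrEstimate:
    """Unweighted median of the Wald ratios; bootstrap SE."""
    rs = wald_ratios(instruments)
    k = len(rs.snp_ids)
    if k < 3:
        raise ValueError("simple median requires at least three instruments")
    beta = _median_even_mean(np.sort(rs.ratios))

    def est(ratios, _bx, _by):
        return np.median(ratios)

    se = _bootstrap_median_se(instruments, est, boot)
    return MrEstimate("simple_median", k, beta, se, _two_sided_p(beta / se))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    boot: BootstrapConfig = BootstrapConfig(),
) -> MrEstimate:
    """IVW-weighted median of the Wald ratios; bootstrap SE."""
    rs = wald_ratios(instruments)
    k = len(rs.snp_ids)
    if k < 3:
        raise ValueError("weighted median requires at least three instruments")
    beta = _weighted_median_value(rs.ratios, rs.weights)
    _ids, _bx, _sx, _by, sy = _arrays(instruments)

    def est(ratios, bx_star, _by):
        return _weighted_median_value(ratios, bx_star**2 / sy**2)

    se = _bootstrap_median_se(instruments, est, boot)
    return MrEstimate("weighted_median", k, beta, se, _two_sided_p(beta / se))


def penalized_weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    penalty_scale: float = 20.0,
    boot: BootstrapConfig = BootstrapConfig(),
) -> MrEstimate:
    """Weighted median with outlier penalization.

    One-step heterogeneity contributions Q_j = w_j (r_j − β_wm)² about the
    weighted-median estimate give upper-tail χ²(1) probabilities q_j; weights
    are down-weighted to w_j · min(1, penalty_scale · q_j) and the weighted
    median recomputed. With no outliers (all q_j near 1) the penalty is
    inactive and the estimate equals the plain weighted median.
    """
    rs = wald_ratios(instruments)
    k = len(rs.snp_ids)
    if k < 3:
        raise ValueError("penalized weighted median requires at least three instruments")

    def penalized(ratios, weights):
        b0 = _weighted_median_value(ratios, weights)
        q_j = weights * (ratios - b0) ** 2
        pen = np.minimum(1.0, penalty_scale * stats.chi2.sf(q_j, df=1))
        return _weighted_median_value(ratios, weights * pen)

    beta = penalized(rs.ratios, rs.weights)
    _ids, _bx, _sx, _by, sy = _arrays(instruments)

    def est(ratios, bx_star, _by):
        return penalized(ratios, bx_star**2 / sy**2)

    se = _bootstrap_median_se(instruments, est, boot)
    return MrEstimate("penalized_weighted_median", k, beta, se, _two_sided_p(beta / se))


def run_all_methods(
    instruments: Sequence[HarmonizedInstrument],
    seed: int = 0,
    n_boot: int = 5000,
    radial_weight_order: Literal["first", "modified_second"] = "modified_second",
    methods: Iterable[str] = METHOD_NAMES,
) -> list[MrEstimate]:
    """Run the estimator suite on one instrument set.

    Bootstrap methods share the given seed, so repeated runs are identical.
    A method that fails (e.g. too few instruments) is skipped with a warning
    and the remaining results are returned.
    """
    boot = BootstrapConfig(n_boot=n_boot, seed=seed)
    dispatch = {
        "ivw": lambda: ivw(instruments),
        "ivw_radial": lambda: radial_ivw(instruments, weight_order=radial_weight_order).estimate(),
        "egger": lambda: egger(instruments).slope,
        "penalized_weighted_median": lambda: penalized_weighted_median(instruments, boot=boot),
        "weighted_median": lambda: weighted_median(instruments, boot=boot),
        "simple_median": lambda: simple_median(instruments, boot=boot),
    }
    results: list[MrEstimate] = []
    for name in methods:
        if name not in dispatch:
            raise ValueError(f"unknown method {name!r}")
        try:
            results.append(dispatch[name]())
        except (ValueError, DegenerateInstrumentError) as exc:
            warnings.warn(f"{name} skipped: {exc}", stacklevel=2)
    return results
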