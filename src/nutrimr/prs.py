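"""Polygenic-score construction and instrument-validity regression.

A polygenic risk score is the weighted sum of effect-allele dosages,
PRS_s = Σ_i β_i · dosage_{s,i}, with GWAS effect sizes as weights (no
standardization). Regressing measured intake on the score checks that the
selected instruments jointly predict the exposure they are meant to proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WeightSet", "PrsAssociation", "compute_prs", "prs_trait_association"]


@dataclass(frozen=True)
class WeightSet:
    """Per-SNP GWAS weights: parallel tuples of id, effect allele, beta."""

    snp_ids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_id in weight set")
        if not (len(self.snp_ids) == len(self.effect_alleles) == len(self.betas)):
            raise ValueError("weight-set fields must have equal length")

    @classmethod
    def from_instruments(cls, instruments, effect_allele: str = "A") -> "WeightSet":
        return cls(
            snp_ids=tuple(i.snp_id for i in instruments),
            effect_alleles=tuple(effect_allele for _ in instruments),
            betas=tuple(i.bx for i in instruments),
        )


@dataclass(frozen=True)
class PrsAssociation:
    """Simple-regression summary of trait on score."""

    slope: float
    se: float
    pvalue: float
    r_squared: float
    intercept: float
    n: int


def compute_prs(
    dosages: pd.DataFrame,
    weights: WeightSet,
    missing: Literal["error", "mean"] = "mean",
) -> pd.Series:
    """Per-subject polygenic score from a subjects × SNPs dosage frame.

    Dosage entries must lie in [0, 2]; NaN marks missing genotypes. Missing
    entries are mean-imputed per SNP under the default policy (count
    recorded in ``Series.attrs['n_imputed']``) or raise under ``'error'``;
    a weight SNP absent from the matrix always raises.
    """
    absent = [s for s in weights.snp_ids if s not in dosages.columns]
    if absent:
        raise KeyError(f"weight SNP(s) absent from dosage matrix: {absent}")
    sub = dosages[list(weights.snp_ids)].astype(float)
    valid = sub.to_numpy()
    finite = np.isfinite(valid)
    if not np.nanmin(np.where(finite, valid, 0)) >= 0 or not np.nanmax(np.where(finite, valid, 0)) <= 2:
        raise ValueError("dosages must lie in [0, 2]")
    n_missing = int((~finite).sum())
    if n_missing:
        if missing == "error":
            raise ValueError(f"{n_missing} missing dosage entries (strict mode)")
        sub = sub.fillna(sub.mean())
    scores = sub.to_numpy() @ np.asarray(weights.betas)
    out = pd.Series(scores, index=dosages.index, name="prs")
    out.attrs["n_imputed"] = n_missing
    return out


def prs_trait_association(scores: pd.Series, trait) -> PrsAssociation:
    """Simple least-squares regression of measured trait on the score.

    Closed-form slope = cov/var, SE from residual variance, p from the t
    reference with n−2 degrees of freedom.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(trait, dtype=float)
    if x.size != y.size:
        raise ValueError("scores and trait must have equal length")
    if x.size < 3:
        raise ValueError("need at least three subjects")
    if np.ptp(x) == 0:
        raise ValueError("scores are constant; association is undefined")
    fit = stats.linregress(x, y)
    return PrsAssociation(
        slope=float(fit.slope),
        se=float(fit.stderr),
        pvalue=float(fit.pvalue),
        r_squared=float(fit.rvalue**2),
        intercept=float(fit.intercept),
        n=int(x.size),
    )
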