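"""Instrument-selection cascade for summary-level Mendelian randomization.

Four stages, each deterministic and each logging what it drops:

1. suggestive-significance filter on the exposure GWAS (p < 1e-5);
2. greedy LD clumping — keep the most significant SNP, discard linked
   neighbours (r² ≥ threshold within a window on the same chromosome);
3. outcome-association screen — drop instruments whose outcome association
   is itself significant (they cannot serve as instruments for the outcome);
4. mapped-phenotype screen — drop instruments whose previously reported
   phenotypes contain no dietary-intake trait (potential pleiotropy),
   keeping unannotated SNPs by default.

Every stage returns a subset of its input, so the cascade is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_data import HarmonizedInstrument, SummaryStats, ValidationError

__all__ = [
    "SelectionConfig",
    "LdMatrix",
    "filter_by_exposure_p",
    "ld_clump",
    "screen_outcome_association",
    "screen_mapped_phenotypes",
    "read_annotations",
    "read_ld_matrix",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the selection cascade.

    Defaults: suggestive exposure threshold 1e-5 (strict inequality), LD
    clumping at r² ≥ 0.1 within 250 kb, outcome exclusion at p < 1e-5
    (mirroring the exposure threshold), and substring patterns identifying
    dietary-intake phenotypes.
    """

    exposure_p_threshold: float = 1e-5
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    outcome_p_exclusion: float = 1e-5
    allowed_phenotype_patterns: tuple[str, ...] = ("intake",)

    def __post_init__(self) -> None:
        for name in ("exposure_p_threshold", "outcome_p_exclusion"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ValidationError(f"clump_r2 must be in [0, 1], got {self.clump_r2}")
        if not self.clump_window_kb > 0:
            raise ValidationError("clump_window_kb must be positive")


@dataclass(frozen=True)
class LdMatrix:
    """Squared-correlation matrix over an ordered SNP panel."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if r2.shape != (n, n):
            raise ValidationError(f"r2 matrix shape {r2.shape} does not match {n} SNP ids")
        if not np.allclose(r2, r2.T, atol=1e-10):
            raise ValidationError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-10):
            raise ValidationError("r2 matrix diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValidationError("r2 values must lie in [0, 1]")
        object.__setattr__(self, "r2", r2)

    def lookup(self, a: str, b: str) -> float | None:
        try:
            i = self.snp_ids.index(a)
            j = self.snp_ids.index(b)
        except ValueError:
            return None
        return float(self.r2[i, j])


def filter_by_exposure_p(stats_in: SummaryStats, threshold: float = 1e-5) -> SummaryStats:
    """Retain records with pvalue strictly below ``threshold`` (order kept)."""
    out = SummaryStats(trait_name=stats_in.trait_name, n_samples=stats_in.n_samples)
    for rec in stats_in:
        if rec.pvalue < threshold:
            out.add(rec)
    return out


def ld_clump(
    stats_in: SummaryStats,
    ld: LdMatrix | None,
    config: SelectionConfig = SelectionConfig(),
) -> SummaryStats:
    """Greedy p-value clumping.

    Repeatedly take the remaining SNP with the smallest p-value (ties broken
    by (chrom, pos, snp_id) for determinism) and discard all remaining SNPs
    on the same chromosome within ``clump_window_kb`` whose r² against it is
    at least ``clump_r2``. SNPs absent from the LD matrix are treated as
    unlinked. The result does not depend on the input record order.
    """
    idx = {s: i for i, s in enumerate(ld.snp_ids)} if ld is not None else {}
    recs = sorted(stats_in, key=lambda r: (r.pvalue, r.chrom, r.pos, r.snp_id))
    window = config.clump_window_kb * 1000.0
    kept: list = []
    discarded: set[str] = set()
    for rec in recs:
        if rec.snp_id in discarded:
            continue
        kept.append(rec)
        i = idx.get(rec.snp_id)
        for other in recs:
            if other.snp_id == rec.snp_id or other.snp_id in discarded:
                continue
            if other.chrom != rec.chrom or abs(other.pos - rec.pos) > window:
                continue
            j = idx.get(other.snp_id)
            if i is None or j is None:
                continue  # unlinked by convention
            if ld.r2[i, j] >= config.clump_r2:
                discarded.add(other.snp_id)
    out = SummaryStats(trait_name=stats_in.trait_name, n_samples=stats_in.n_samples)
    for rec in stats_in:  # preserve the caller's record order
        if rec.snp_id in {k.snp_id for k in kept}:
            out.add(rec)
    return out


def outcome_pvalue(inst: HarmonizedInstrument) -> float:
    """Two-sided normal p of the instrument's outcome association |by/sy|."""
    return float(2.0 * stats.norm.sf(abs(inst.by / inst.sy)))


def screen_outcome_association(
    instruments: Sequence[HarmonizedInstrument],
    outcome_p_exclusion: float = 1e-5,
) -> tuple[list[HarmonizedInstrument], list[dict[str, str]]]:
    """Drop instruments whose outcome association p < threshold.

    An instrument strongly associated with the outcome cannot be assumed to
    act only through the exposure; such SNPs are removed and logged.
    """
    kept: list[HarmonizedInstrument] = []
    log: list[dict[str, str]] = []
    for inst in instruments:
        p = outcome_pvalue(inst)
        if p < outcome_p_exclusion:
            log.append({"snp_id": inst.snp_id, "reason": "outcome-associated", "outcome_p": f"{p:.3g}"})
        else:
            kept.append(inst)
    return kept, log


def screen_mapped_phenotypes(
    instruments: Sequence[HarmonizedInstrument],
    annotations: Mapping[str, Sequence[str]] | None = None,
    config: SelectionConfig = SelectionConfig(),
    keep_unannotated: bool = True,
) -> tuple[list[HarmonizedInstrument], list[dict[str, str]]]:
    """Keep instruments with at least one allowed (dietary-intake) phenotype.

    Phenotype lists come from the instrument's own ``mapped_phenotypes``
    unless an ``annotations`` table overrides them. SNPs with no annotation
    at all are kept under the default policy (no positive evidence of
    pleiotropy); matching is case-insensitive substring containment.
    """
    patterns = tuple(p.lower() for p in config.allowed_phenotype_patterns)
    kept: list[HarmonizedInstrument] = []
    log: list[dict[str, str]] = []
    for inst in instruments:
        phen = tuple((annotations or {}).get(inst.snp_id, inst.mapped_phenotypes))
        if not phen:
            if keep_unannotated:
                kept.append(inst)
            else:
                log.append({"snp_id": inst.snp_id, "reason": "unannotated"})
            continue
        blob = ";".join(phen).lower()
        if any(pat in blob for pat in patterns):
            kept.append(inst)
        else:
            log.append({"snp_id": inst.snp_id, "reason": "no-allowed-phenotype", "phenotypes": ";".join(phen)})
    return kept, log


def read_annotations(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a SNP→phenotypes table (columns snp_id, phenotypes ';'-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"snp_id", "phenotypes"} <= set(df.columns):
        raise ValidationError(f"{path}: annotation file needs columns snp_id, phenotypes")
    return {
        str(r.snp_id): tuple(p for p in str(r.phenotypes).split(";") if p)
        for r in df.itertuples(index=False)
    }


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read an LD matrix from square (header row+column) or long format.

    Long format has columns snp_a, snp_b, r2; unlisted pairs default to 0
    and the diagonal to 1.
    """
    df = pd.read_csv(path, sep="\t")
    if {"snp_a", "snp_b", "r2"} <= set(df.columns):
        ids = sorted(set(df["snp_a"].astype(str)) | set(df["snp_b"].astype(str)))
        idx = {s: i for i, s in enumerate(ids)}
        r2 = np.eye(len(ids))
        for r in df.itertuples(index=False):
            i, j = idx[str(r.snp_a)], idx[str(r.snp_b)]
            r2[i, j] = r2[j, i] = float(r.r2)
        return LdMatrix(snp_ids=tuple(ids), r2=r2)
    first = df.columns[0]
    ids = tuple(df[first].astype(str))
    return LdMatrix(snp_ids=ids, r2=df[list(df.columns[1:])].to_numpy(dtype=float))
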