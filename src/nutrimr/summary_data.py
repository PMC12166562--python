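"""GWAS summary statistics: data model, delimited-text I/O and allele harmonization.

The atoms of every downstream computation live here. A :class:`SnpAssociation`
is one variant's association with one trait; a :class:`SummaryStats` is a
keyed collection of them for a single trait; a :class:`HarmonizedInstrument`
is the exposure/outcome pair (bx, sx, by, sy) expressed on a common effect
allele — the quantity all Mendelian-randomization estimators consume.

Harmonization aligns an outcome association to the exposure's effect allele,
resolving swapped allele labels (sign flip + frequency complement) and strand
flips (base complement), and drops palindromic A/T or C/G variants whose
effect-allele frequency is too close to 0.5 for the strand to be resolved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "SnpAssociation",
    "SummaryStats",
    "HarmonizedInstrument",
    "SummaryDataError",
    "FormatError",
    "ValidationError",
    "DEFAULT_DIALECT",
    "read_summary_stats",
    "is_palindromic",
    "harmonize",
    "write_instruments",
    "read_instruments",
    "write_exclusion_log",
]

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryDataError(Exception):
    """Base class for summary-data problems."""


class FormatError(SummaryDataError):
    """A file does not have the expected layout (e.g. a mandatory column is absent)."""


class ValidationError(SummaryDataError):
    """A record violates a field invariant (e.g. non-positive standard error)."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association with one trait.

    ``beta`` is the additive per-effect-allele estimate (trait units for a
    continuous trait, log-odds for a binary one); ``se`` its standard error.
    ``eaf`` is the effect-allele frequency and may be ``None`` when the source
    does not report it.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float

    def __post_init__(self) -> None:
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            if a not in _VALID_BASES:
                raise ValidationError(f"{self.snp_id}: {name} {a!r} is not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValidationError(f"{self.snp_id}: pvalue {self.pvalue} outside (0, 1]")


@dataclass
class SummaryStats:
    """GWAS summary statistics for one trait, keyed by SNP id."""

    trait_name: str
    records: dict[str, SnpAssociation] = field(default_factory=dict)
    n_samples: int | None = None
    #: SNPs excluded from ``records`` with a reason (e.g. "monomorphic").
    flags: dict[str, str] = field(default_factory=dict)

    def add(self, rec: SnpAssociation) -> None:
        if rec.snp_id in self.records:
            raise ValidationError(f"duplicate snp_id {rec.snp_id!r} in {self.trait_name!r}")
        self.records[rec.snp_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self.records.values())

    def __getitem__(self, snp_id: str) -> SnpAssociation:
        return self.records[snp_id]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure/outcome effect pair on a common effect allele.

    ``bx``/``sx`` are the SNP-exposure estimate and SE, ``by``/``sy`` the
    SNP-outcome estimate and SE, both for the same effect allele (the
    harmonization contract). ``mapped_phenotypes`` carries previously reported
    trait annotations used by the pleiotropy screen; it may be empty.
    """

    snp_id: str
    bx: float
    sx: float
    by: float
    sy: float
    eaf: float | None = None
    mapped_phenotypes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sx > 0:
            raise ValidationError(f"{self.snp_id}: sx must be > 0")
        if not self.sy > 0:
            raise ValidationError(f"{self.snp_id}: sy must be > 0")


#: Column-name map used when a file already follows the package's own headers.
DEFAULT_DIALECT: dict[str, str] = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
}

_MANDATORY = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue")


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    n_samples: int | None = None,
) -> SummaryStats:
    """Read a tab- or comma-delimited summary-statistics file.

    ``dialect`` maps canonical field names (keys of :data:`DEFAULT_DIALECT`)
    to the column headers actually present, so PheWeb-style and generic
    headers both parse. Rows that fail type coercion are rejected with their
    1-based data-row numbers listed in the error message.
    """
    path = Path(path)
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [dialect[k] for k in _MANDATORY if dialect[k] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    has_eaf = dialect["eaf"] in df.columns

    stats = SummaryStats(trait_name=trait_name or path.stem, n_samples=n_samples)
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = dict(zip(df.columns, row))
        try:
            eaf_raw = r.get(dialect["eaf"]) if has_eaf else None
            rec = SnpAssociation(
                snp_id=str(r[dialect["snp_id"]]).strip(),
                chrom=str(r[dialect["chrom"]]).strip(),
                pos=int(float(r[dialect["pos"]])),
                effect_allele=str(r[dialect["effect_allele"]]).strip().upper(),
                other_allele=str(r[dialect["other_allele"]]).strip().upper(),
                eaf=None if eaf_raw in (None, "") or pd.isna(eaf_raw) else float(eaf_raw),
                beta=float(r[dialect["beta"]]),
                se=float(r[dialect["se"]]),
                pvalue=float(r[dialect["pvalue"]]),
            )
        except (TypeError, ValueError, ValidationError) as exc:
            bad_rows.append((i, str(exc)))
            continue
        stats.add(rec)  # duplicate ids propagate as their own error
    if bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows)
        raise ValidationError(f"{path}: {len(bad_rows)} row(s) rejected — {detail}")
    return stats


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    pair = {effect_allele, other_allele}
    if not pair <= _VALID_BASES or len(pair) != 2:
        raise ValidationError(f"alleles must be distinct A/C/G/T, got {effect_allele}/{other_allele}")
    return pair == {"A", "T"} or pair == {"C", "G"}


def _complemented(rec: SnpAssociation) -> SnpAssociation:
    return replace(
        rec,
        effect_allele=_COMPLEMENT[rec.effect_allele],
        other_allele=_COMPLEMENT[rec.other_allele],
    )


def _flipped(rec: SnpAssociation) -> SnpAssociation:
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    intermediate_af_band: tuple[float, float] = (0.40, 0.60),
    annotations: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[HarmonizedInstrument], list[dict[str, str]]]:
    """Align outcome associations to the exposure's effect allele.

    Returns ``(instruments, exclusion_log)``. Each exclusion-log entry is a
    dict with ``snp_id`` and ``reason`` (``palindromic-intermediate``,
    ``palindromic-missing-eaf`` or ``allele-mismatch``). The number of
    instruments plus exclusions always equals the size of the SNP-id
    intersection.
    """
    lo, hi = intermediate_af_band
    if not (0.0 <= lo <= 0.5 <= hi <= 1.0):
        raise ValidationError(f"intermediate_af_band {intermediate_af_band} must contain 0.5 within [0,1]")
    annotations = annotations or {}

    instruments: list[HarmonizedInstrument] = []
    exclusions: list[dict[str, str]] = []
    for snp_id, exp in exposure.records.items():
        if snp_id not in outcome:
            continue
        out = outcome[snp_id]

        if is_palindromic(exp.effect_allele, exp.other_allele):
            if exp.eaf is None:
                exclusions.append({"snp_id": snp_id, "reason": "palindromic-missing-eaf"})
                continue
            if lo <= exp.eaf <= hi:
                exclusions.append({"snp_id": snp_id, "reason": "palindromic-intermediate"})
                continue

        aligned = _align(exp, out)
        if aligned is None:
            exclusions.append({"snp_id": snp_id, "reason": "allele-mismatch"})
            continue
        instruments.append(
            HarmonizedInstrument(
                snp_id=snp_id,
                bx=exp.beta,
                sx=exp.se,
                by=aligned.beta,
                sy=aligned.se,
                eaf=exp.eaf,
                mapped_phenotypes=tuple(annotations.get(snp_id, ())),
            )
        )
    return instruments, exclusions


def _align(exp: SnpAssociation, out: SnpAssociation) -> SnpAssociation | None:
    """Express ``out`` on ``exp``'s effect allele, or None if irreconcilable."""
    for candidate in (out, _complemented(out)):
        if (candidate.effect_allele, candidate.other_allele) == (exp.effect_allele, exp.other_allele):
            return candidate
        swapped = _flipped(candidate)
        if (swapped.effect_allele, swapped.other_allele) == (exp.effect_allele, exp.other_allele):
            return swapped
    return None


_INSTRUMENT_COLUMNS = ["snp_id", "bx", "sx", "by", "sy", "eaf", "mapped_phenotypes"]


def write_instruments(instruments: Iterable[HarmonizedInstrument], path: str | Path) -> None:
    """Write instruments as a tab-delimited table (lossless round-trip)."""
    rows = [
        {
            "snp_id": inst.snp_id,
            "bx": inst.bx,
            "sx": inst.sx,
            "by": inst.by,
            "sy": inst.sy,
            "eaf": "" if inst.eaf is None else inst.eaf,
            "mapped_phenotypes": ";".join(inst.mapped_phenotypes),
        }
        for inst in instruments
    ]
    df = pd.DataFrame(rows, columns=_INSTRUMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_instruments(path: str | Path) -> list[HarmonizedInstrument]:
    """Read a table written by :func:`write_instruments`."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "mapped_phenotypes": str})
    missing = [c for c in _INSTRUMENT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing instrument column(s) {missing}")
    out: list[HarmonizedInstrument] = []
    for r in df.itertuples(index=False):
        phen = getattr(r, "mapped_phenotypes", "")
        phen = () if (not isinstance(phen, str) or phen == "") else tuple(phen.split(";"))
        eaf = getattr(r, "eaf", None)
        out.append(
            HarmonizedInstrument(
                snp_id=str(r.snp_id),
                bx=float(r.bx),
                sx=float(r.sx),
                by=float(r.by),
                sy=float(r.sy),
                eaf=None if eaf is None or pd.isna(eaf) else float(eaf),
                mapped_phenotypes=phen,
            )
        )
    return out


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    """Write a SummaryStats as a tab-delimited table (readable back as-is)."""
    rows = [
        {
            "snp_id": r.snp_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": "" if r.eaf is None else r.eaf,
            "beta": r.beta,
            "se": r.se,
            "pvalue": r.pvalue,
        }
        for r in stats
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_DIALECT)).to_csv(path, sep="\t", index=False)


def write_exclusion_log(exclusions: Sequence[Mapping[str, str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(list(exclusions), indent=2) + "\n")
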