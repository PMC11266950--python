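"""GWAS summary statistics: data model, file I/O and preprocessing.

The atoms of two-sample Mendelian randomization are per-variant association
records — for each SNP, an effect size per copy of a designated effect allele,
its standard error, the effect-allele frequency and the sample size.  This
module defines that record (:class:`VariantAssociation`), reads and writes it
as tab-separated text, aligns exposure and outcome records to a common effect
allele (:func:`harmonize`), and converts linear-mixed-model effect estimates
for binary traits to the log-odds scale (:func:`linear_to_logor`).
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantAssociation",
    "InstrumentSet",
    "HarmonizedPair",
    "HarmonizationResult",
    "StudyMeta",
    "SumstatsReadResult",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "flip_record",
    "linear_to_logor",
    "se_from_ci",
    "CANONICAL_COLUMNS",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical TSV dialect: field name -> column header.
CANONICAL_COLUMNS: dict[str, str] = {
    "rsid": "rsid",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "p",
    "n": "n",
    "trait": "trait",
    "scale": "scale",
}

_MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se")
_SCALES = ("linear", "log_odds", "inverse_normal")


class SumstatsError(ValueError):
    """Malformed summary-statistics input."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary statistics for one trait.

    ``beta`` is the effect per copy of ``effect_allele`` on the scale named by
    ``scale`` (``linear`` for a continuous or linear-mixed-model fit,
    ``log_odds`` for logistic effects, ``inverse_normal`` for a rank-based
    inverse-normal-transformed trait).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pval: float | None = None
    n: int | None = None
    chrom: str | None = None
    pos: int | None = None
    trait: str | None = None
    scale: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise SumstatsError(
                f"{self.rsid}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.rsid}: effect and other allele are identical")
        if not (self.se > 0):
            raise SumstatsError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise SumstatsError(f"{self.rsid}: eaf must lie in (0, 1), got {self.eaf}")
        if self.pval is not None:
            if not (0.0 < self.pval <= 1.0):
                raise SumstatsError(f"{self.rsid}: p-value must lie in (0, 1], got {self.pval}")
            # Loose internal consistency: |beta/se| should imply a p-value within
            # a factor of ~2 of the reported one (rounding in published tables
            # easily produces that much slack).  A warning, never an error.
            implied = 2.0 * stats.norm.sf(abs(self.beta / self.se))
            if implied > 0 and not (implied / 2.5 <= self.pval <= min(1.0, implied * 2.5)):
                warnings.warn(
                    f"{self.rsid}: reported p={self.pval:.3g} inconsistent with "
                    f"|beta/se| (implies p={implied:.3g})",
                    stacklevel=2,
                )
        if self.n is not None and self.n <= 0:
            raise SumstatsError(f"{self.rsid}: n must be positive, got {self.n}")
        if self.scale is not None and self.scale not in _SCALES:
            raise SumstatsError(f"{self.rsid}: unknown scale {self.scale!r}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G variants, whose strand is ambiguous."""
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass(frozen=True)
class InstrumentSet:
    """The exposure instruments: variants plus the total variance explained."""

    variants: tuple[VariantAssociation, ...]
    r2_total: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(self.variants))
        if len(self.variants) < 1:
            raise SumstatsError("an instrument set needs at least one variant")
        if not (0.0 < self.r2_total < 1.0):
            raise SumstatsError(f"r2_total must lie in (0, 1), got {self.r2_total}")
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            raise SumstatsError("duplicate rsid in instrument set")

    @property
    def k(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class HarmonizedPair:
    """An exposure/outcome variant pair aligned to a common effect allele.

    ``action`` records what was done to the outcome record: ``none`` (alleles
    already aligned), ``flipped`` (outcome beta negated, eaf reflected),
    ``dropped_palindromic`` or ``dropped_mismatch``.
    """

    rsid: str
    exposure: VariantAssociation
    outcome: VariantAssociation | None
    action: str
    palindromic: bool

    @property
    def kept(self) -> bool:
        return self.action in ("none", "flipped")


class HarmonizationResult(Sequence):
    """Sequence of :class:`HarmonizedPair` plus the unmatched instruments."""

    def __init__(self, pairs: list[HarmonizedPair], unmatched: list[str]):
        self.pairs = list(pairs)
        self.unmatched = list(unmatched)

    def __getitem__(self, i):
        return self.pairs[i]

    def __len__(self) -> int:
        return len(self.pairs)

    def kept(self) -> list[HarmonizedPair]:
        return [p for p in self.pairs if p.kept]


@dataclass(frozen=True)
class StudyMeta:
    """Case/control bookkeeping for one binary-outcome GWAS."""

    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise SumstatsError("case and control counts must be positive")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


class SumstatsReadResult(Sequence):
    """Accepted records plus a per-row rejection report.

    Iterates as a sequence of :class:`VariantAssociation`; ``rejections`` is a
    DataFrame with columns ``row`` (1-based data-row number), ``rsid``,
    ``field`` and ``reason``.
    """

    def __init__(self, records: list[VariantAssociation], rejections: pd.DataFrame):
        self.records = list(records)
        self.rejections = rejections

    def __getitem__(self, i):
        return self.records[i]

    def __len__(self) -> int:
        return len(self.records)


def _parse_optional(value, cast):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() in ("", ".", "NA", "nan"):
        return None
    return cast(value)


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> SumstatsReadResult:
    """Read GWAS summary statistics from delimited text.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Mapping from field names (``rsid``, ``effect_allele`` …) to column
        headers.  Defaults to the canonical dialect
        (``rsid/chr/pos/ea/oa/eaf/beta/se/p/n``).
    sep
        Field delimiter.

    Rows violating type or range invariants are collected into the rejection
    report rather than aborting the read; a missing mandatory column or an
    empty file is an error.
    """
    colmap = dict(CANONICAL_COLUMNS)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[0] == 0:
        raise SumstatsError(f"{path}: no data rows")
    missing = [colmap[f] for f in _MANDATORY_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise SumstatsError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    records: list[VariantAssociation] = []
    rejected: list[dict] = []
    for idx, row in df.iterrows():
        def get(fieldname: str):
            col = colmap[fieldname]
            return row[col] if col in df.columns else None

        rsid = str(get("rsid"))
        try:
            rec = VariantAssociation(
                rsid=rsid,
                effect_allele=str(get("effect_allele")),
                other_allele=str(get("other_allele")),
                beta=float(get("beta")),
                se=float(get("se")),
                eaf=_parse_optional(get("eaf"), float),
                pval=_parse_optional(get("pval"), float),
                n=_parse_optional(get("n"), lambda v: int(float(v))),
                chrom=_parse_optional(get("chrom"), str),
                pos=_parse_optional(get("pos"), lambda v: int(float(v))),
                trait=_parse_optional(get("trait"), str),
                scale=_parse_optional(get("scale"), str),
            )
        except (SumstatsError, TypeError, ValueError) as exc:
            msg = str(exc)
            fieldname = next(
                (f for f in ("eaf", "se", "beta", "p-value", "allele", "n", "scale") if f in msg),
                "row",
            )
            rejected.append(
                {"row": int(idx) + 1, "rsid": rsid, "field": fieldname, "reason": msg}
            )
            continue
        records.append(rec)
    report = pd.DataFrame(rejected, columns=["row", "rsid", "field", "reason"])
    return SumstatsReadResult(records, report)


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_sumstats(
    records: Iterable[VariantAssociation],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write records as canonical TSV (floats in shortest round-trip form)."""
    colmap = dict(CANONICAL_COLUMNS)
    if dialect:
        colmap.update(dialect)
    fields = list(CANONICAL_COLUMNS)
    lines = ["\t".join(colmap[f] for f in fields)]
    for rec in records:
        lines.append("\t".join(_fmt(getattr(rec, f)) for f in fields))
    Path(path).write_text("\n".join(lines) + "\n")


def flip_record(rec: VariantAssociation) -> VariantAssociation:
    """Swap effect/other allele, negating beta and reflecting eaf.

    An involution: flipping twice restores the original record.
    """
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def _complement_record(rec: VariantAssociation) -> VariantAssociation:
    return replace(
        rec,
        effect_allele=_COMPLEMENT[rec.effect_allele],
        other_allele=_COMPLEMENT[rec.other_allele],
    )


def _check_unique(records: Iterable[VariantAssociation], label: str) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.rsid in seen:
            raise SumstatsError(f"duplicate rsid {rec.rsid} in {label} input")
        seen.add(rec.rsid)


def harmonize(
    exposure: InstrumentSet | Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_eaf_window: float = 0.08,
) -> HarmonizationResult:
    """Align outcome records to the exposure's effect alleles, by rsid.

    For each instrument found in the outcome set:

    * alleles already identical → action ``none``;
    * identical after swapping effect/other → ``flipped`` (outcome beta
      negated, eaf → 1 − eaf);
    * palindromic variant (A/T or C/G) whose strand cannot be resolved —
      either study's eaf within ``palindrome_eaf_window`` of 0.5, or an eaf
      missing → ``dropped_palindromic``; otherwise palindromic pairs are
      aligned by frequency (flip when the eafs sit on opposite sides of 0.5);
    * reconcilable only after strand complement → harmonized on the exposure
      strand (complement, then match as above);
    * irreconcilable alleles → ``dropped_mismatch``.

    Instruments absent from the outcome set are listed in ``unmatched``.
    """
    exp_variants = exposure.variants if isinstance(exposure, InstrumentSet) else tuple(exposure)
    _check_unique(exp_variants, "exposure")
    _check_unique(outcome, "outcome")
    out_by_rsid = {rec.rsid: rec for rec in outcome}

    pairs: list[HarmonizedPair] = []
    unmatched: list[str] = []
    for exp in exp_variants:
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            unmatched.append(exp.rsid)
            continue
        pairs.append(_harmonize_one(exp, out, palindrome_eaf_window))
    return HarmonizationResult(pairs, unmatched)


def _near_half(eaf: float | None, window: float) -> bool:
    return eaf is None or abs(eaf - 0.5) <= window


def _harmonize_one(
    exp: VariantAssociation, out: VariantAssociation, window: float
) -> HarmonizedPair:
    palindromic = exp.is_palindromic

    if palindromic:
        # Strand cannot be told from the alleles; use allele frequency, and
        # give up when either frequency is too close to 0.5 (or missing).
        alleles_match = {out.effect_allele, out.other_allele} == {
            exp.effect_allele,
            exp.other_allele,
        }
        if not alleles_match:
            return HarmonizedPair(exp.rsid, exp, None, "dropped_mismatch", True)
        if _near_half(exp.eaf, window) or _near_half(out.eaf, window):
            return HarmonizedPair(exp.rsid, exp, None, "dropped_palindromic", True)
        same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
        aligned_alleles = out.effect_allele == exp.effect_allele
        # Frequency decides orientation; the allele labels decide whether the
        # record as stored needs the textual swap as well.
        if same_side == aligned_alleles:
            action, rec = ("none", out) if aligned_alleles else ("flipped", flip_record(out))
        else:
            # Frequencies disagree with the labels: the outcome is reported on
            # the opposite strand. Complementing relabels without changing
            # beta/eaf; a label swap may then still be needed.
            rec = _complement_record(out)
            if rec.effect_allele == exp.effect_allele:
                action = "none"
            else:
                rec = flip_record(rec)
                action = "flipped"
        return HarmonizedPair(exp.rsid, exp, rec, action, True)

    for candidate in (out, _complement_record(out)):
        if (
            candidate.effect_allele == exp.effect_allele
            and candidate.other_allele == exp.other_allele
        ):
            return HarmonizedPair(exp.rsid, exp, candidate, "none", False)
        if (
            candidate.effect_allele == exp.other_allele
            and candidate.other_allele == exp.effect_allele
        ):
            return HarmonizedPair(exp.rsid, exp, flip_record(candidate), "flipped", False)
    return HarmonizedPair(exp.rsid, exp, None, "dropped_mismatch", False)


def linear_to_logor(beta: float, se: float, meta: StudyMeta) -> tuple[float, float]:
    """Convert a linear-scale effect on a binary trait to the log-odds scale.

    Linear mixed models (BOLT-LMM and kin) fit case/control status as if it
    were continuous; dividing the effect and its standard error by
    ``mu * (1 - mu)``, with ``mu`` the case fraction, recovers approximate log
    odds ratios.
    """
    mu = meta.case_fraction
    if not (0.0 < mu < 1.0):
        raise ValueError(f"case fraction must lie in (0, 1), got {mu}")
    factor = 1.0 / (mu * (1.0 - mu))
    return beta * factor, se * factor


def se_from_ci(or_lower: float, or_upper: float, level: float = 0.95) -> float:
    """Back-derive the log-scale SE from an odds ratio confidence interval.

    ``se = (ln U - ln L) / (2 z)`` with ``z`` the standard-normal quantile at
    ``(1 + level) / 2``.  Lets published per-SNP ORs and CIs be reused as
    inputs to meta-analysis.
    """
    if not (0.0 < or_lower < or_upper):
        raise ValueError(
            f"need 0 < lower < upper, got ({or_lower}, {or_upper})"
        )
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (math.log(or_upper) - math.log(or_lower)) / (2.0 * z)
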