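"""Allele designation: repeat-unit counting, CE-equivalent (pseudo-CE)
designations, isometric-allele detection and diversity summaries.

Sequence-based typing resolves alleles that length-based CE cannot: isometric
alleles (same length, different internal sequence) and flanking indels that
shift the CE-apparent size away from the repeat count.  Designations follow
the CE convention ``n`` for integer alleles and ``n.b`` for micro-variants
(``b`` leftover bases, 0 < b < period), e.g. 9.3 = nine full repeats plus
three bases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .catalog import Catalog, LocusDef, VariantCatalogEntry


@dataclass(frozen=True, order=True)
class Designation:
    """A length-based allele designation: full repeat units + leftover bases."""

    full_units: int
    partial: int = 0

    def __post_init__(self) -> None:
        if self.full_units < 0 or self.partial < 0:
            raise ValueError("designation components must be non-negative")

    def __str__(self) -> str:
        return f"{self.full_units}" if self.partial == 0 else f"{self.full_units}.{self.partial}"

    @classmethod
    def parse(cls, text: str) -> "Designation":
        """Parse ``"12"`` or ``"9.3"``.  The suffix is a base count, not a
        decimal fraction, so ``"9.30"`` is rejected."""
        text = text.strip()
        if "." in text:
            head, _, tail = text.partition(".")
            # partial is a single base-count digit (periods are at most 5)
            if not head.isdigit() or len(tail) != 1 or not tail.isdigit() or tail == "0":
                raise ValueError(f"malformed allele designation {text!r}")
            return cls(int(head), int(tail))
        if not text.isdigit():
            raise ValueError(f"malformed allele designation {text!r}")
        return cls(int(text), 0)

    def total_bases(self, period: int) -> int:
        return self.full_units * period + self.partial


@dataclass(frozen=True)
class RepeatRun:
    """A run of ``count`` copies of ``motif``; uncounted runs do not
    contribute to the designation."""

    motif: str
    count: int
    counted: bool = True


@dataclass(frozen=True)
class SequenceAllele:
    """A sequenced STR allele.

    ``sequence_id`` is a stable identifier unique within the locus; two
    alleles with equal designations but different ``sequence_id`` are
    isometric.  ``flanking_variants`` lists catalogued variant ids carried by
    the allele (anything outside counted blocks is treated as flanking).
    """

    locus: str
    repeat_blocks: tuple[RepeatRun, ...]
    partial_bases: int = 0
    flanking_variants: tuple[str, ...] = ()
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if self.partial_bases < 0:
            raise ValueError("partial_bases must be non-negative")
        if any(r.count < 0 for r in self.repeat_blocks):
            raise ValueError("repeat counts must be non-negative")


def allele_from_designation(
    locus: LocusDef,
    designation: str | Designation,
    seq_tag: str = "",
    variants: Sequence[str] = (),
) -> SequenceAllele:
    """Construct a canonical-structure allele for a locus from a designation.

    Used by the simulator and scenario builders; ``seq_tag`` distinguishes
    isometric variants sharing the designation.
    """
    des = Designation.parse(designation) if isinstance(designation, str) else designation
    blocks = (RepeatRun(motif=locus.motif or "N" * (locus.period or 4), count=des.full_units),)
    sid = f"{locus.name}:{des}"
    if seq_tag:
        sid += f"#{seq_tag}"
    if variants:
        sid += "+" + "+".join(variants)
    return SequenceAllele(
        locus=locus.name,
        repeat_blocks=blocks,
        partial_bases=des.partial,
        flanking_variants=tuple(variants),
        sequence_id=sid,
    )


def repeat_designation(allele: SequenceAllele, locus: LocusDef) -> Designation:
    """Designation by repeat-unit counting: sum of counted block repeats plus
    any leftover counted bases."""
    if allele.locus != locus.name:
        raise ValueError(f"allele belongs to {allele.locus}, not {locus.name}")
    period = locus.period
    if period is None:
        raise ValueError(f"{locus.name} is not an STR locus")
    if allele.partial_bases >= period:
        raise ValueError(f"partial_bases {allele.partial_bases} >= period {period}")
    full = sum(r.count for r in allele.repeat_blocks if r.counted)
    return Designation(full, allele.partial_bases)


def ce_equivalent_designation(
    repeat_des: Designation,
    locus: LocusDef,
    variants: Iterable[VariantCatalogEntry] = (),
) -> Designation:
    """CE-compatible (pseudo-CE) designation from a repeat-count designation.

    Flanking indels shorten or lengthen the CE-apparent amplicon without
    changing the repeat count, so the total base length
    ``L = full·period + partial + Σ shift`` is re-expressed in repeat units.
    A catalogued ``ce_designation_override`` supersedes the arithmetic
    (locus-specific conventions the arithmetic cannot express).  SNPs are
    identity.
    """
    period = locus.period
    if period is None:
        raise ValueError(f"{locus.name} is not an STR locus")
    variants = list(variants)
    for v in variants:
        if v.locus != locus.name:
            raise ValueError(f"variant {v.variant_id} belongs to {v.locus}, not {locus.name}")
        if v.ce_designation_override is not None:
            return Designation.parse(v.ce_designation_override)
    total = repeat_des.total_bases(period) + sum(v.effective_shift for v in variants)
    if total < 0:
        raise ValueError("net deletion exceeds allele length")
    return Designation(total // period, total % period)


def allele_ce_designation(
    allele: SequenceAllele, locus: LocusDef, catalog: Catalog
) -> Designation:
    """Pseudo-CE designation for a sequenced allele via its catalogued variants."""
    from .catalog import lookup_variant

    entries = [lookup_variant(vid, catalog) for vid in allele.flanking_variants]
    return ce_equivalent_designation(repeat_designation(allele, locus), locus, entries)


# --- isometric-allele detection ---------------------------------------------

LENGTH_HOM_SEQ_HOM = "length_hom_seq_hom"
LENGTH_HOM_SEQ_HET = "length_hom_seq_het"  # isometric heterozygote
LENGTH_HET = "length_het"


def classify_genotype(a: SequenceAllele, b: SequenceAllele, locus: LocusDef) -> str:
    da, db = repeat_designation(a, locus), repeat_designation(b, locus)
    if da != db:
        return LENGTH_HET
    return LENGTH_HOM_SEQ_HOM if a.sequence_id == b.sequence_id else LENGTH_HOM_SEQ_HET


def detect_isoalleles(
    genotypes: Iterable[tuple[str, str, SequenceAllele, SequenceAllele]],
    catalog: Catalog,
) -> pd.DataFrame:
    """Classify genotypes ``(sample_id, locus, allele_a, allele_b)`` into
    length-homozygous/sequence-homozygous, isometric heterozygote, or
    length-heterozygous; report per-locus counts and the percentage of
    length-homozygous genotypes reclassified by sequence.
    """
    rows: list[dict] = []
    for sample_id, locus_name, a, b in genotypes:
        locus = catalog.locus(locus_name)
        rows.append({"sample_id": sample_id, "locus": locus_name,
                     "status": classify_genotype(a, b, locus)})
    detail = pd.DataFrame(rows, columns=["sample_id", "locus", "status"])
    if detail.empty:
        return pd.DataFrame(columns=["locus", "length_hom", "isometric_het", "length_het", "pct_reclassified"])
    per = detail.groupby("locus")["status"].value_counts().unstack(fill_value=0)
    for col in (LENGTH_HOM_SEQ_HOM, LENGTH_HOM_SEQ_HET, LENGTH_HET):
        if col not in per:
            per[col] = 0
    out = pd.DataFrame({
        "locus": per.index,
        "length_hom": (per[LENGTH_HOM_SEQ_HOM] + per[LENGTH_HOM_SEQ_HET]).values,
        "isometric_het": per[LENGTH_HOM_SEQ_HET].values,
        "length_het": per[LENGTH_HET].values,
    }).reset_index(drop=True)
    out["pct_reclassified"] = [
        round_half_up(100.0 * i / h, 1) if h else 0.0
        for i, h in zip(out["isometric_het"], out["length_hom"])
    ]
    return out


def isoallele_reclassification_pct(report: pd.DataFrame) -> float:
    """Global percentage of length-homozygous genotypes unveiled as isometric
    heterozygotes, to one decimal."""
    hom = int(report["length_hom"].sum())
    iso = int(report["isometric_het"].sum())
    if hom == 0:
        return 0.0
    return round_half_up(100.0 * iso / hom, 1)


# --- diversity summaries ------------------------------------------------------


def round_half_up(x: float, ndigits: int) -> float:
    """Round-half-up (CE reporting convention), avoiding banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_allele_diversity(
    genotypes: Iterable[tuple[str, str, SequenceAllele, SequenceAllele]],
    catalog: Catalog,
) -> pd.DataFrame:
    """Per-locus length- vs sequence-level diversity.

    Columns: distinct length-based alleles, distinct sequence-based alleles,
    difference, fold increase (sequence/length, half-up to 1 decimal), and
    observed heterozygosity at both levels.
    """
    length_sets: dict[str, set] = {}
    seq_sets: dict[str, set] = {}
    het_len: Counter = Counter()
    het_seq: Counter = Counter()
    n_geno: Counter = Counter()
    for _sid, locus_name, a, b in genotypes:
        locus = catalog.locus(locus_name)
        da, db = repeat_designation(a, locus), repeat_designation(b, locus)
        length_sets.setdefault(locus_name, set()).update((da, db))
        seq_sets.setdefault(locus_name, set()).update((a.sequence_id, b.sequence_id))
        n_geno[locus_name] += 1
        if da != db:
            het_len[locus_name] += 1
        if a.sequence_id != b.sequence_id:
            het_seq[locus_name] += 1
    rows = []
    for locus_name in sorted(length_sets):
        nl, ns = len(length_sets[locus_name]), len(seq_sets[locus_name])
        n = n_geno[locus_name]
        rows.append({
            "locus": locus_name,
            "length_based_alleles": nl,
            "sequence_based_alleles": ns,
            "additional_alleles": ns - nl,
            "fold_increase": round_half_up(ns / nl, 1) if nl else float("nan"),
            "h_obs_length": round_half_up(het_len[locus_name] / n, 2) if n else float("nan"),
            "h_obs_sequence": round_half_up(het_seq[locus_name] / n, 2) if n else float("nan"),
        })
    return pd.DataFrame(rows)


def fold_increase(n_length: int, n_sequence: int) -> float:
    """Fold increase in distinguishable alleles from sequence-based typing."""
    if n_length <= 0:
        raise ValueError("need at least one length-based allele")
    return round_half_up(n_sequence / n_length, 1)
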