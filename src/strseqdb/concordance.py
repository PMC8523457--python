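"""CE/MPS concordance: compares length-based genotypes from capillary
electrophoresis with pseudo-CE designations recalculated from sequence calls,
and classifies every disagreement (drop-out by direction, drop-in, other)."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .calling import GenotypeCall
from .catalog import Catalog, lookup_variant
from .nomenclature import (
    Designation,
    allele_ce_designation,
    repeat_designation,
    round_half_up,
)

STATUS_CONCORDANT = "concordant"
STATUS_DROPOUT_SHORTER = "dropout_shorter"
STATUS_DROPOUT_LONGER = "dropout_longer"
STATUS_DROPIN = "dropin"
STATUS_DISCORDANT = "discordant"
STATUS_MISSING = "missing"


@dataclass(frozen=True)
class LocusComparison:
    sample_id: str
    locus: str
    ce_alleles: tuple[str, ...]
    mps_alleles: tuple[str, ...]
    status: str
    matched_allele_count: int


@dataclass
class ConcordanceReport:
    allele_concordance_pct: float
    locus_concordance_pct: float
    total_alleles: int
    total_loci: int
    matched_alleles: int
    concordant_loci: int
    events: list[LocusComparison] = field(default_factory=list)


def _sort_key(des: str) -> tuple[int, int]:
    d = Designation.parse(des)
    return (d.full_units, d.partial)


def compare_locus(
    ce: Iterable[str],
    mps: Iterable[str],
    sample_id: str = "",
    locus: str = "",
) -> LocusComparison:
    """Classify one sample × locus comparison of designation multisets.

    Both sides are expanded to two allele copies for matching (a homozygote
    contributes the same designation twice).  Drop-out requires the surviving
    sequence alleles to be a subset of the CE support with exactly one CE
    allele unmatched; direction follows the designation value of the missing
    allele (full units, then partial bases) rather than amplicon size.
    """
    ce_list = sorted((str(x) for x in ce), key=_sort_key)
    mps_list = sorted((str(x) for x in mps), key=_sort_key)
    ce_ms, mps_ms = Counter(ce_list), Counter(mps_list)
    matched = sum((ce_ms & mps_ms).values())

    if not ce_list:
        status = STATUS_DROPIN if mps_list else STATUS_MISSING
    elif ce_ms == mps_ms:
        status = STATUS_CONCORDANT
    elif not mps_list:
        status = STATUS_DISCORDANT
    elif matched == len(ce_list) - 1 and not (mps_ms - ce_ms) - (ce_ms & mps_ms):
        # one CE allele unmatched and every sequence designation is within the
        # CE support (a drop-out may surface as an apparent homozygote)
        missing = list((ce_ms - mps_ms).elements())[0]
        others = [a for a in ce_list if a != missing]
        ref = others[0] if others else missing
        if _sort_key(missing) > _sort_key(ref):
            status = STATUS_DROPOUT_LONGER
        else:
            status = STATUS_DROPOUT_SHORTER
    elif set(ce_list) < set(mps_list):
        status = STATUS_DROPIN
    else:
        status = STATUS_DISCORDANT
    return LocusComparison(
        sample_id=sample_id,
        locus=locus,
        ce_alleles=tuple(ce_list),
        mps_alleles=tuple(mps_list),
        status=status,
        matched_allele_count=min(matched, 2),
    )


def concordance_summary(comparisons: Iterable[LocusComparison]) -> ConcordanceReport:
    """Allele- and locus-level concordance percentages (two decimals).

    Allele concordance counts matched designations over two alleles per
    compared locus; locus concordance counts fully concordant loci.
    """
    comps = list(comparisons)
    if not comps:
        raise ValueError("no comparisons supplied")
    total_loci = len(comps)
    total_alleles = 2 * total_loci
    matched = sum(c.matched_allele_count for c in comps)
    concordant = sum(c.status == STATUS_CONCORDANT for c in comps)
    return ConcordanceReport(
        allele_concordance_pct=round_half_up(100.0 * matched / total_alleles, 2),
        locus_concordance_pct=round_half_up(100.0 * concordant / total_loci, 2),
        total_alleles=total_alleles,
        total_loci=total_loci,
        matched_alleles=matched,
        concordant_loci=concordant,
        events=[c for c in comps if c.status != STATUS_CONCORDANT],
    )


def pseudo_ce_profile(
    calls: Iterable[GenotypeCall],
    catalog: Catalog,
) -> pd.DataFrame:
    """Pseudo-CE designation multisets recalculated from sequence calls.

    Emits both the CE-equivalent designation (flanking-indel arithmetic
    applied) and the naive repeat-count designation per allele; rows where the
    two differ mark alleles that would cause false exclusions if naive repeat
    counting were used for database search.
    """
    rows = []
    for call in calls:
        locus = catalog.locus(call.locus)
        for allele in call.allele_multiset:
            naive = repeat_designation(allele, locus)
            pseudo = allele_ce_designation(allele, locus, catalog)
            rows.append({
                "sample_id": call.sample_id,
                "locus": call.locus,
                "sequence_id": allele.sequence_id,
                "pseudo_ce": str(pseudo),
                "naive_repeat_count": str(naive),
                "designation_mismatch": str(pseudo) != str(naive),
            })
    return pd.DataFrame(
        rows,
        columns=["sample_id", "locus", "sequence_id", "pseudo_ce",
                 "naive_repeat_count", "designation_mismatch"],
    )


def compare_datasets(
    ce_table: pd.DataFrame,
    mps_profiles: pd.DataFrame,
) -> list[LocusComparison]:
    """Compare a CE genotype table (sample_id, locus, allele1, allele2) with a
    pseudo-CE table from :func:`pseudo_ce_profile`, one comparison per CE row."""
    mps_sets: dict[tuple[str, str], list[str]] = {}
    for row in mps_profiles.itertuples():
        mps_sets.setdefault((row.sample_id, row.locus), []).append(row.pseudo_ce)
    comps = []
    for row in ce_table.itertuples():
        ce = [str(row.allele1), str(row.allele2)]
        mps = mps_sets.get((row.sample_id, row.locus), [])
        comps.append(compare_locus(ce, mps, sample_id=row.sample_id, locus=row.locus))
    return comps
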