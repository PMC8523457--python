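"""Profile-level QC: relative marker performance, heterozygote balance and
length-based (univariate) stutter ratios with read-depth categories."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .calling import GenotypeCall, SampleProfile
from .catalog import LocusDef
from .nomenclature import Designation, SequenceAllele, repeat_designation, round_half_up

#: Heterozygote-balance flag bound: calls with HB ≤ 0.30 are highly imbalanced.
HB_FLAG_THRESHOLD = 0.30
#: Stutter ratios strictly above 0.20 are counted as exceeding 20%.
STUTTER_HIGH_THRESHOLD = 0.20
#: Total-read categories: low-performing (category I) at or below this bound …
CATEGORY_I_MAX = 63_500
#: … and high-performing (category II) at or above this one.
CATEGORY_II_MIN = 199_000


def relative_marker_performance(profile: SampleProfile) -> dict[str, float]:
    """Per-marker fraction of the profile's total reads (all markers
    including amelogenin); fractions sum to 1."""
    total = profile.total_reads
    if total <= 0:
        raise ValueError(f"sample {profile.sample_id}: zero total reads")
    return {locus: profile.locus_reads(locus) / total for locus in profile.loci}


def expected_rmp(n_markers: int) -> float:
    """Expected relative marker performance (%) under equal marker output."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return round_half_up(100.0 / n_markers, 2)


def marker_performance_table(profiles: Iterable[SampleProfile]) -> pd.DataFrame:
    """Long table of per-sample relative marker performance fractions."""
    rows = []
    for p in profiles:
        for locus, frac in relative_marker_performance(p).items():
            rows.append({"sample_id": p.sample_id, "locus": locus, "fraction": frac})
    return pd.DataFrame(rows, columns=["sample_id", "locus", "fraction"])


def flag_unbalanced_markers(marker_means: Mapping[str, float]) -> list[str]:
    """Markers whose mean relative performance lies outside the well-balanced
    band: grand mean of marker means ± one SD of the marker means."""
    if len(marker_means) < 2:
        raise ValueError("need at least two markers")
    vals = np.array(list(marker_means.values()), dtype=float)
    grand, sd = vals.mean(), vals.std(ddof=1)
    lo, hi = grand - sd, grand + sd
    return sorted(m for m, v in marker_means.items() if v < lo or v > hi)


def heterozygote_balance(reads_a: int, reads_b: int) -> float:
    """Minor/major read ratio for a heterozygous call, in (0, 1]."""
    if reads_a <= 0 or reads_b <= 0:
        raise ValueError("heterozygote balance requires positive reads on both alleles")
    return min(reads_a, reads_b) / max(reads_a, reads_b)


def hb_flagged(reads_a: int, reads_b: int, threshold: float = HB_FLAG_THRESHOLD) -> bool:
    return heterozygote_balance(reads_a, reads_b) <= threshold


# --- stutter ------------------------------------------------------------------


@dataclass(frozen=True)
class StutterRecord:
    sample_id: str
    locus: str
    parent_designation: str
    parent_reads: int
    stutter_reads: int
    category: str  # "I" | "II" | "none"

    def __post_init__(self) -> None:
        if self.parent_reads <= 0:
            raise ValueError("parent reads must be positive")
        if self.stutter_reads < 0:
            raise ValueError("stutter reads must be non-negative")

    @property
    def ratio(self) -> float:
        return self.stutter_reads / self.parent_reads


def categorize_sample(total_reads: int, low: int = CATEGORY_I_MAX, high: int = CATEGORY_II_MIN) -> str:
    """Read-depth category: ``I`` at or below ``low``, ``II`` at or above
    ``high``, ``none`` in between (inclusive bounds)."""
    if low >= high:
        raise ValueError("category bounds must satisfy low < high")
    if total_reads <= low:
        return "I"
    if total_reads >= high:
        return "II"
    return "none"


def stutter_ratio(
    seqs: Mapping[SequenceAllele, int],
    parent: SequenceAllele,
    locus: LocusDef,
    sample_id: str,
    category: str = "none",
    other_allele: Optional[SequenceAllele] = None,
) -> Optional[StutterRecord]:
    """Stutter record for one parent allele, or ``None`` when not assessable.

    Length-defined (univariate): both the parent and the stutter position are
    read as length classes, summing reads over isometric sequences.  Skipped
    when the stutter position coincides with the genotype's other true allele
    — the artifact reads would be confounded with real allelic reads.
    """
    parent_des = repeat_designation(parent, locus)
    stutter_des = Designation(parent_des.full_units - 1, parent_des.partial)
    if other_allele is not None:
        other_des = repeat_designation(other_allele, locus)
        if other_des == stutter_des:
            return None
    parent_reads = sum(
        r for a, r in seqs.items() if repeat_designation(a, locus) == parent_des
    )
    if parent_reads <= 0:
        return None
    stutter_reads = sum(
        r for a, r in seqs.items() if repeat_designation(a, locus) == stutter_des
    )
    return StutterRecord(
        sample_id=sample_id,
        locus=locus.name,
        parent_designation=str(parent_des),
        parent_reads=parent_reads,
        stutter_reads=stutter_reads,
        category=category,
    )


def collect_stutter_records(
    profile: SampleProfile,
    calls: Iterable[GenotypeCall],
    catalog,
    category: Optional[str] = None,
) -> list[StutterRecord]:
    """Stutter records for every called parent allele of a profile."""
    cat = categorize_sample(profile.total_reads) if category is None else category
    records = []
    for call in calls:
        if not call.called_alleles:
            continue
        locus = catalog.locus(call.locus)
        seqs = profile.loci.get(call.locus, {})
        alleles = call.called_alleles
        seen: set[str] = set()  # isometric pair = one parent length class
        for i, parent in enumerate(alleles):
            des = str(repeat_designation(parent, locus))
            if des in seen:
                continue
            seen.add(des)
            other = alleles[1 - i] if len(alleles) == 2 else None
            rec = stutter_ratio(seqs, parent, locus, profile.sample_id, cat, other)
            if rec is not None:
                records.append(rec)
    return records


def summarize_stutter(records: Iterable[StutterRecord]) -> pd.DataFrame:
    """Per locus × category: n, mean, sample SD (empty when n = 1), median,
    min, max of stutter ratios, and the count of ratios exceeding 20%."""
    rows = [{"locus": r.locus, "category": r.category, "ratio": r.ratio} for r in records]
    df = pd.DataFrame(rows, columns=["locus", "category", "ratio"])
    if df.empty:
        return pd.DataFrame(
            columns=["locus", "category", "n", "mean", "sd", "median", "min", "max", "n_gt_20pct"]
        )
    out = []
    for (locus, cat), grp in df.groupby(["locus", "category"], sort=True):
        r = grp["ratio"].to_numpy()
        out.append({
            "locus": locus,
            "category": cat,
            "n": len(r),
            "mean": float(r.mean()),
            "sd": float(r.std(ddof=1)) if len(r) > 1 else np.nan,
            "median": float(np.median(r)),
            "min": float(r.min()),
            "max": float(r.max()),
            "n_gt_20pct": int((r > STUTTER_HIGH_THRESHOLD).sum()),
        })
    return pd.DataFrame(out)
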