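"""Read-count thresholding, genotype calling and sequencing-run QC.

Two thresholds govern interpretation: the analytical threshold (AT, default
50 reads) below which a sequence is disregarded entirely, and the
interpretation threshold (IT) above which alleles are called — 500 reads for
homozygous and 100 reads for heterozygous genotypes.  A single candidate
between the heterozygous and homozygous IT is deliberately *not* forced to a
homozygote: it is flagged as possible drop-out, so that allele loss surfaces
as a discordance instead of a silent genotype change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Iterable, Optional

from .catalog import Catalog, LocusDef
from .nomenclature import Designation, SequenceAllele, repeat_designation, round_half_up

logger = logging.getLogger(__name__)

DEFAULT_AT = 50
DEFAULT_IT_HOM = 500
DEFAULT_IT_HET = 100
#: A sequence one full repeat unit below a stronger sequence is treated as its
#: stutter product when the read ratio does not exceed this bound (above the
#: highest stutter ratios seen in practice, below plausible heterozygote balance).
DEFAULT_STUTTER_FILTER = 0.35

FLAG_BELOW_AT = "below_AT_removed"
FLAG_POSSIBLE_DROPOUT = "possible_dropout"
FLAG_NO_CALL = "no_call"
FLAG_IMBALANCED = "imbalanced"
FLAG_TRIALLELIC = "triallelic_pattern"


@dataclass
class SampleProfile:
    """Per-sample sequence read counts, keyed locus → sequence allele → reads."""

    sample_id: str
    loci: dict[str, dict[SequenceAllele, int]] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(r for m in self.loci.values() for r in m.values())

    def locus_reads(self, locus: str) -> int:
        return sum(self.loci.get(locus, {}).values())


@dataclass
class GenotypeCall:
    sample_id: str
    locus: str
    called_alleles: tuple[SequenceAllele, ...]  # 1 entry for homozygote
    homozygous: bool = False
    flags: frozenset[str] = frozenset()
    reads: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.called_alleles) > 2:
            raise ValueError("at most two called alleles")

    @property
    def allele_multiset(self) -> tuple[SequenceAllele, ...]:
        """Alleles expanded to two copies (homozygote duplicated)."""
        if self.homozygous and len(self.called_alleles) == 1:
            return self.called_alleles * 2
        return self.called_alleles


def apply_analytical_threshold(profile: SampleProfile, at: int = DEFAULT_AT) -> SampleProfile:
    """Drop sequences with fewer than ``at`` reads (inclusive retention:
    reads ≥ at survive).  Removals are logged."""
    if at < 0:
        raise ValueError("analytical threshold must be >= 0")
    kept: dict[str, dict[SequenceAllele, int]] = {}
    n_removed = 0
    for locus, seqs in profile.loci.items():
        m = {a: r for a, r in seqs.items() if r >= at}
        n_removed += len(seqs) - len(m)
        if m:
            kept[locus] = m
    if n_removed:
        logger.info("sample %s: %d sequences below AT=%d removed (%s)",
                    profile.sample_id, n_removed, at, FLAG_BELOW_AT)
    return SampleProfile(sample_id=profile.sample_id, loci=kept)


def resolve_candidates(
    seqs: dict[SequenceAllele, int],
    locus: LocusDef,
    stutter_filter: float = DEFAULT_STUTTER_FILTER,
) -> dict[SequenceAllele, int]:
    """Separate candidate alleles from stutter products at one locus.

    Length-based (univariate) rule: a sequence whose designation is exactly one
    full repeat unit below some other sequence, with a read ratio to that
    parent *length class* (summed over isometric sequences) of at most
    ``stutter_filter``, is classed as stutter and excluded from calling.
    """
    if not locus.is_str:
        return dict(seqs)
    des = {a: repeat_designation(a, locus) for a in seqs}
    by_length: dict[Designation, int] = {}
    for a, r in seqs.items():
        by_length[des[a]] = by_length.get(des[a], 0) + r
    out = {}
    for a, r in seqs.items():
        d = des[a]
        parent_reads = by_length.get(Designation(d.full_units + 1, d.partial), 0)
        if not (parent_reads > 0 and r <= parent_reads * stutter_filter):
            out[a] = r
    return out


def call_genotype(
    candidates: dict[SequenceAllele, int],
    sample_id: str,
    locus: str,
    it_hom: int = DEFAULT_IT_HOM,
    it_het: int = DEFAULT_IT_HET,
) -> GenotypeCall:
    """Call a genotype from candidate (non-stutter) sequences at one locus."""
    above = sorted(
        ((a, r) for a, r in candidates.items() if r >= it_het),
        key=lambda ar: (-ar[1], ar[0].sequence_id),
    )
    if len(above) > 2:
        return GenotypeCall(sample_id, locus, (), flags=frozenset({FLAG_TRIALLELIC, FLAG_NO_CALL}))
    if len(above) == 2:
        alleles = tuple(a for a, _ in above)
        return GenotypeCall(sample_id, locus, alleles, reads=tuple(r for _, r in above))
    if len(above) == 1:
        a, r = above[0]
        if r >= it_hom:
            return GenotypeCall(sample_id, locus, (a,), homozygous=True, reads=(r,))
        return GenotypeCall(sample_id, locus, (a,), reads=(r,),
                            flags=frozenset({FLAG_NO_CALL, FLAG_POSSIBLE_DROPOUT}))
    return GenotypeCall(sample_id, locus, (), flags=frozenset({FLAG_NO_CALL}))


def call_profile(
    profile: SampleProfile,
    catalog: Catalog,
    at: int = DEFAULT_AT,
    it_hom: int = DEFAULT_IT_HOM,
    it_het: int = DEFAULT_IT_HET,
    stutter_filter: float = DEFAULT_STUTTER_FILTER,
) -> list[GenotypeCall]:
    """AT filtering, stutter resolution and genotype calling for all STR loci
    present in a profile."""
    filtered = apply_analytical_threshold(profile, at)
    calls = []
    for locus_name, seqs in sorted(filtered.loci.items()):
        locus = catalog.locus(locus_name)
        if not locus.is_str:
            continue
        cands = resolve_candidates(seqs, locus, stutter_filter)
        calls.append(call_genotype(cands, profile.sample_id, locus_name, it_hom, it_het))
    return calls


# --- run-level QC -------------------------------------------------------------


@dataclass
class RunMetrics:
    """Sequencer run quality metrics (cluster density in K/mm², percentages 0–100)."""

    run_id: str
    cluster_density_mean: float
    cluster_density_sd: float
    pct_pf: float
    phasing: float
    prephasing: float
    total_reads: int
    reads_pf: int
    pct_q30: float

    def __post_init__(self) -> None:
        for name in ("pct_pf", "pct_q30"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100]")
        if self.reads_pf > self.total_reads:
            raise ValueError("reads passing filter cannot exceed total reads")
        if self.cluster_density_mean < 0:
            raise ValueError("cluster density must be non-negative")


DENSITY_OPTIMAL_LOW = 1000.0
DENSITY_OPTIMAL_HIGH = 1200.0
Q30_RECOMMENDED = 75.0


def classify_run(metrics: RunMetrics) -> dict:
    """Cluster-density class (under/optimal/over against the 1,000–1,200 K/mm²
    recommendation) and Q30 pass (> 75%)."""
    d = metrics.cluster_density_mean
    if d < DENSITY_OPTIMAL_LOW:
        density_class = "under"
    elif d <= DENSITY_OPTIMAL_HIGH:
        density_class = "optimal"
    else:
        density_class = "over"
    return {
        "run_id": metrics.run_id,
        "density_class": density_class,
        "q30_pass": metrics.pct_q30 > Q30_RECOMMENDED,
    }


def summarize_runs(runs: Iterable[RunMetrics]) -> tuple[float, float]:
    """Mean and n−1 sample SD of %≥Q30 across runs, half-up to one decimal."""
    vals = [r.pct_q30 for r in runs]
    if len(vals) < 2:
        raise ValueError("SD undefined for fewer than two runs")
    return round_half_up(mean(vals), 1), round_half_up(stdev(vals), 1)
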