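"""Synthetic paired MPS/CE cohort generator.

Emulates the statistical structure the analysis pipeline assumes for a
forensic reference-sample cohort: diploid genotypes drawn per locus from
allele-frequency spectra under Hardy–Weinberg proportions; per-sample total
read depth (log-normal); per-marker read shares around an equal-performance
expectation; heterozygote balance (Beta-distributed minor/major ratio);
one-repeat-shorter stutter whose mean ratio grows linearly with repeat count
(lower for micro-variant alleles); isometric sequence variants hidden inside
length classes; catalogued flanking indels; and explicitly injected
drop-out/drop-in events.

Deterministic scenario builders reproduce the worked-example cohort
structures used in the acceptance checks (exact drop-out, isoallele,
heterozygote-balance-flag and intermediate-allele counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .calling import SampleProfile
from .catalog import Catalog, default_catalog, lookup_variant
from .nomenclature import (
    Designation,
    SequenceAllele,
    allele_ce_designation,
    allele_from_designation,
    repeat_designation,
)

AMEL = "AMEL"


class AlleleSpec(BaseModel):
    """One allele of a locus spectrum; ``seq_tag`` separates isometric
    variants of the same designation, ``variants`` lists catalogued ids."""

    designation: str
    frequency: float = Field(gt=0)
    seq_tag: str = ""
    variants: list[str] = Field(default_factory=list)


class TotalReadsModel(BaseModel):
    """Log-normal per-sample total profile reads (log-space location/scale)."""

    log_mean: float
    log_sd: float = Field(ge=0)


class HBModel(BaseModel):
    """Beta parameters for the heterozygote-balance (minor/major) ratio;
    ``fixed`` pins the ratio to a constant (no noise) instead."""

    alpha: float = Field(default=25.0, gt=0)
    beta: float = Field(default=5.0, gt=0)
    fixed: Optional[float] = Field(default=None, gt=0, le=1)


class StutterModel(BaseModel):
    """Mean stutter ratio = intercept + slope · (full repeat units), Gaussian
    noise around it; micro-variant (partial-repeat) parents stutter lower by
    ``intermediate_factor``."""

    intercept: float
    slope: float
    sd: float = Field(ge=0)
    intermediate_factor: float = Field(default=0.75, gt=0, le=1)


class DropoutEvent(BaseModel):
    sample_id: str
    locus: str
    which: str  # "longer" | "shorter" | explicit designation string


class DropinEvent(BaseModel):
    sample_id: str
    locus: str
    designation: str
    reads: int = Field(gt=0)


class SimulationConfig(BaseModel):
    n_samples: int = Field(gt=0)
    freq_spectra: dict[str, list[AlleleSpec]]
    total_reads_model: TotalReadsModel
    marker_weights: dict[str, float]
    hb_model: dict[str, HBModel]
    stutter_model: dict[str, StutterModel]
    dropout_events: list[DropoutEvent] = Field(default_factory=list)
    dropin_events: list[DropinEvent] = Field(default_factory=list)
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for locus, spectrum in self.freq_spectra.items():
            if not spectrum:
                raise ValueError(f"{locus}: empty allele spectrum")
            s = sum(a.frequency for a in spectrum)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{locus}: spectrum sums to {s}, not 1")
        w = sum(self.marker_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"marker weights sum to {w}, not 1")
        return self


@dataclass(frozen=True)
class TrueGenotype:
    sample_id: str
    locus: str
    allele_a: SequenceAllele
    allele_b: SequenceAllele


def _spec_allele(catalog: Catalog, locus_name: str, spec: AlleleSpec) -> SequenceAllele:
    locus = catalog.locus(locus_name)
    return allele_from_designation(locus, spec.designation, seq_tag=spec.seq_tag,
                                   variants=spec.variants)


def _round_int(x: float) -> int:
    """Nearest integer, ties to even (exact integer read counts)."""
    return int(np.rint(x))


def generate_population(config: SimulationConfig, catalog: Optional[Catalog] = None) -> list[TrueGenotype]:
    """Draw diploid genotypes independently per locus under Hardy–Weinberg
    proportions from the configured spectra (P(aa)=p², P(ab)=2pq)."""
    catalog = catalog or default_catalog()
    rng = np.random.default_rng([config.seed, 0])
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    genotypes: list[TrueGenotype] = []
    for locus_name in sorted(config.freq_spectra):
        spectrum = config.freq_spectra[locus_name]
        alleles = [_spec_allele(catalog, locus_name, a) for a in spectrum]
        freqs = np.array([a.frequency for a in spectrum])
        freqs = freqs / freqs.sum()
        draws = rng.choice(len(alleles), size=(config.n_samples, 2), p=freqs)
        for sid, (ia, ib) in zip(sample_ids, draws):
            genotypes.append(TrueGenotype(sid, locus_name, alleles[ia], alleles[ib]))
    return genotypes


def simulate_reads(
    genotypes: list[TrueGenotype],
    config: SimulationConfig,
    catalog: Optional[Catalog] = None,
) -> list[SampleProfile]:
    """Turn true genotypes into per-sequence read counts.

    Per sample: total reads ~ log-normal; each marker receives its weight
    share; heterozygote reads split by a Beta-distributed balance ratio (which
    allele is minor is a fair coin); each parent sequence spawns an n−1
    stutter sequence; injected drop-outs zero an allele before stutter
    formation; drop-ins add a spurious sequence afterwards.
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng([config.seed, 1])
    by_sample: dict[str, list[TrueGenotype]] = {}
    for g in genotypes:
        by_sample.setdefault(g.sample_id, []).append(g)

    dropouts = {(e.sample_id, e.locus): e for e in config.dropout_events}
    dropins: dict[tuple[str, str], list[DropinEvent]] = {}
    for e in config.dropin_events:
        dropins.setdefault((e.sample_id, e.locus), []).append(e)

    profiles = []
    for sid in sorted(by_sample):
        trm = config.total_reads_model
        total = math.exp(rng.normal(trm.log_mean, trm.log_sd))
        loci: dict[str, dict[SequenceAllele, int]] = {}
        for g in sorted(by_sample[sid], key=lambda g: g.locus):
            locus = catalog.locus(g.locus)
            weight = config.marker_weights.get(g.locus, 0.0)
            marker_reads = weight * total
            seqs: dict[SequenceAllele, int] = {}
            a, b = g.allele_a, g.allele_b
            if a.sequence_id == b.sequence_id:
                alloc = {a: _round_int(marker_reads)}
            else:
                hbm = config.hb_model[g.locus]
                hb = hbm.fixed if hbm.fixed is not None else rng.beta(hbm.alpha, hbm.beta)
                minor_share = hb / (1.0 + hb)
                if rng.random() < 0.5:
                    a, b = b, a
                alloc = {a: _round_int(marker_reads * minor_share),
                         b: _round_int(marker_reads * (1.0 - minor_share))}
            # injected drop-out: zero the targeted allele before stutter forms
            ev = dropouts.get((sid, g.locus))
            if ev is not None:
                target = _dropout_target(ev, alloc, locus)
                if target is not None:
                    alloc.pop(target)
            for allele, reads in alloc.items():
                if reads > 0:
                    seqs[allele] = seqs.get(allele, 0) + reads
            _add_stutter(seqs, locus, config.stutter_model.get(g.locus), rng)
            for ev2 in dropins.get((sid, g.locus), []):
                spurious = allele_from_designation(locus, ev2.designation, seq_tag="dropin")
                seqs[spurious] = seqs.get(spurious, 0) + ev2.reads
            if seqs:
                loci[g.locus] = seqs
        amel_w = config.marker_weights.get(AMEL, 0.0)
        if amel_w > 0:
            amel_allele = SequenceAllele(locus=AMEL, repeat_blocks=(), sequence_id="AMEL:XY")
            loci[AMEL] = {amel_allele: _round_int(amel_w * total)}
        profiles.append(SampleProfile(sample_id=sid, loci=loci))
    return profiles


def _dropout_target(ev: DropoutEvent, alloc: dict[SequenceAllele, int], locus) -> Optional[SequenceAllele]:
    if not alloc:
        return None
    keyed = sorted(
        alloc, key=lambda al: (repeat_designation(al, locus).full_units,
                               repeat_designation(al, locus).partial)
    )
    if ev.which == "longer":
        return keyed[-1]
    if ev.which == "shorter":
        return keyed[0]
    want = Designation.parse(ev.which)
    for al in keyed:
        if repeat_designation(al, locus) == want:
            return al
    return None


def _add_stutter(
    seqs: dict[SequenceAllele, int],
    locus,
    model: Optional[StutterModel],
    rng: np.random.Generator,
) -> None:
    if model is None or not locus.is_str:
        return
    parents = list(seqs.items())
    for parent, reads in parents:
        des = repeat_designation(parent, locus)
        if des.full_units < 2 or reads <= 0:
            continue
        mean = model.intercept + model.slope * des.full_units
        if des.partial > 0:
            mean *= model.intermediate_factor
        if mean >= 1.0:
            raise ValueError(
                f"{locus.name}: stutter model yields mean ratio {mean:.2f} >= 1 "
                f"at {des} repeats (misconfiguration)"
            )
        ratio = max(0.0, rng.normal(mean, model.sd))
        if ratio >= 1.0:
            raise ValueError(f"{locus.name}: drawn stutter ratio {ratio:.2f} >= 1")
        st_reads = _round_int(reads * ratio)
        if st_reads <= 0:
            continue
        st_des = Designation(des.full_units - 1, des.partial)
        # length-defined placement: merge with an existing same-length sequence
        # (the other allele of an adjacent heterozygote), else a new sequence
        target = next(
            (al for al in seqs if repeat_designation(al, locus) == st_des), None
        )
        if target is None:
            target = allele_from_designation(locus, st_des, seq_tag=f"stut{des}")
        seqs[target] = seqs.get(target, 0) + st_reads


def derive_ce_dataset(genotypes: list[TrueGenotype], catalog: Optional[Catalog] = None) -> pd.DataFrame:
    """Ground-truth CE genotype table: the multiset of CE-equivalent
    designations of each true allele pair (isometric heterozygotes appear
    length-homozygous)."""
    catalog = catalog or default_catalog()
    rows = []
    for g in sorted(genotypes, key=lambda g: (g.sample_id, g.locus)):
        locus = catalog.locus(g.locus)
        da = allele_ce_designation(g.allele_a, locus, catalog)
        db = allele_ce_designation(g.allele_b, locus, catalog)
        lo, hi = sorted([da, db], key=lambda d: (d.full_units, d.partial))
        rows.append({"sample_id": g.sample_id, "locus": g.locus,
                     "allele1": str(lo), "allele2": str(hi)})
    return pd.DataFrame(rows, columns=["sample_id", "locus", "allele1", "allele2"])


# --- default study conditions -------------------------------------------------

# Plausible European-style allele spectra per panel locus.  Thirteen loci carry
# isometric splits (same designation, different sequence); TH01 and D1S1656
# carry common micro-variant alleles; D19S433 carries the catalogued
# repeat-boundary deletion.  Values are the generator's declared assumptions,
# not estimates from any particular dataset.
_DEFAULT_SPECTRA: dict[str, list[tuple]] = {
    # locus: [(designation, freq, seq_tag, variants), ...]
    "D1S1656": [("12", 0.12), ("13", 0.12), ("14", 0.14), ("15", 0.22, "a"), ("15", 0.08, "b"),
                ("16", 0.18), ("17.3", 0.14)],
    "TPOX": [("8", 0.45, "a"), ("8", 0.08, "b", ["rs149212737"]), ("9", 0.12), ("10", 0.08),
             ("11", 0.22), ("12", 0.05)],
    "D2S1338": [("17", 0.18), ("18", 0.10), ("19", 0.12), ("20", 0.14, "a"), ("20", 0.06, "b"),
                ("23", 0.14), ("24", 0.14), ("25", 0.12)],
    "D2S441": [("10", 0.26, "a"), ("10", 0.08, "b"), ("11", 0.30), ("11.3", 0.06),
               ("12", 0.06), ("14", 0.24)],
    "D3S1358": [("14", 0.12), ("15", 0.24, "a"), ("15", 0.08, "b"), ("16", 0.22, "a"),
                ("16", 0.06, "b"), ("17", 0.16), ("18", 0.12)],
    "FGA": [("19", 0.08), ("20", 0.12), ("21", 0.16), ("22", 0.18), ("23", 0.16),
            ("24", 0.14), ("25", 0.10), ("26", 0.06)],
    "D5S818": [("11", 0.26, "a"), ("11", 0.10, "b"), ("12", 0.30, "a"), ("12", 0.06, "b"),
               ("13", 0.20), ("10", 0.08)],
    "CSF1PO": [("10", 0.24), ("11", 0.30), ("12", 0.30), ("13", 0.10), ("9", 0.06)],
    "D7S820": [("8", 0.16), ("9", 0.14), ("10", 0.24, "a"), ("10", 0.06, "b"),
               ("11", 0.22), ("12", 0.18)],
    "D8S1179": [("12", 0.14), ("13", 0.28, "a"), ("13", 0.06, "b"), ("14", 0.22, "a"),
                ("14", 0.06, "b"), ("15", 0.14), ("16", 0.10)],
    "D10S1248": [("13", 0.28), ("14", 0.30), ("15", 0.20), ("16", 0.14), ("12", 0.08)],
    "TH01": [("6", 0.22), ("7", 0.16), ("8", 0.12), ("9", 0.16), ("9.3", 0.30), ("10", 0.04)],
    "vWA": [("16", 0.20), ("17", 0.26, "a"), ("17", 0.06, "b"), ("18", 0.22, "a"),
            ("18", 0.04, "b"), ("19", 0.14), ("15", 0.08)],
    "D12S391": [("18", 0.20, "a"), ("18", 0.04, "b"), ("19", 0.14), ("20", 0.14),
                ("21", 0.16), ("22", 0.14), ("23", 0.18)],
    "D13S317": [("11", 0.30, "a"), ("11", 0.06, "b"), ("12", 0.26, "a"), ("12", 0.06, "b"),
                ("13", 0.12), ("8", 0.12), ("9", 0.08)],
    "Penta E": [("7", 0.16), ("10", 0.12), ("11", 0.14), ("12", 0.22), ("13", 0.12),
                ("14", 0.12), ("15", 0.12)],
    "D16S539": [("9", 0.14), ("10", 0.08), ("11", 0.28, "a"), ("11", 0.06, "b"),
                ("12", 0.28), ("13", 0.16)],
    "D18S51": [("12", 0.14), ("13", 0.12), ("14", 0.16), ("15", 0.16), ("16", 0.14),
               ("17", 0.14), ("18", 0.14)],
    "D19S433": [("13", 0.28), ("14", 0.30), ("15", 0.16), ("15.2", 0.08),
                ("12.3", 0.06, "", ["rs147936416"]), ("16", 0.12)],
    "D21S11": [("28", 0.18), ("29", 0.22, "a"), ("29", 0.06, "b"), ("30", 0.24, "a"),
               ("30", 0.04, "b"), ("31.2", 0.12), ("32.2", 0.14)],
    "Penta D": [("9", 0.20), ("10", 0.16), ("11", 0.16), ("12", 0.18), ("13", 0.18), ("8", 0.12)],
    "D22S1045": [("11", 0.16), ("14", 0.08), ("15", 0.32), ("16", 0.30), ("17", 0.14)],
}


def _spectra() -> dict[str, list[AlleleSpec]]:
    out: dict[str, list[AlleleSpec]] = {}
    for locus, entries in _DEFAULT_SPECTRA.items():
        specs = []
        for e in entries:
            des, freq = e[0], e[1]
            tag = e[2] if len(e) > 2 else ""
            variants = list(e[3]) if len(e) > 3 else []
            specs.append(AlleleSpec(designation=des, frequency=freq, seq_tag=tag, variants=variants))
        out[locus] = specs
    return out


def default_config(n_samples: int, seed: int) -> SimulationConfig:
    """Default study conditions for a synthetic reference cohort.

    Equal expected marker shares (the equal-performance expectation), median
    total depth ~120k reads spanning both read-depth categories, heterozygote
    balance Beta(25, 5) (mean ≈ 0.83), and per-locus linear stutter means in
    the 10–15% range for typical repeat counts, with the trinucleotide locus
    D22S1045 highest.
    """
    spectra = _spectra()
    markers = sorted(spectra) + [AMEL]
    weights = {m: 1.0 / len(markers) for m in markers}
    # correct rounding drift so the shares sum to exactly 1
    weights[AMEL] = 1.0 - sum(v for m, v in weights.items() if m != AMEL)
    hb = {locus: HBModel(alpha=25.0, beta=5.0) for locus in spectra}
    stutter = {}
    for locus in spectra:
        if locus == "D22S1045":
            stutter[locus] = StutterModel(intercept=0.0, slope=0.0105, sd=0.02)
        elif locus in ("Penta D", "Penta E", "TH01"):
            stutter[locus] = StutterModel(intercept=-0.01, slope=0.006, sd=0.015)
        else:
            stutter[locus] = StutterModel(intercept=-0.03, slope=0.009, sd=0.02)
    return SimulationConfig(
        n_samples=n_samples,
        freq_spectra=spectra,
        total_reads_model=TotalReadsModel(log_mean=math.log(120_000.0), log_sd=0.5),
        marker_weights=weights,
        hb_model=hb,
        stutter_model=stutter,
        seed=seed,
    )


# --- deterministic worked-example scenarios ----------------------------------


@dataclass
class ScenarioBundle:
    name: str
    catalog: Catalog
    genotypes: list[TrueGenotype] = field(default_factory=list)
    profiles: list[SampleProfile] = field(default_factory=list)
    ce_table: Optional[pd.DataFrame] = None
    het_reads: Optional[pd.DataFrame] = None
    description: str = ""


SCENARIOS = ("concordance_247", "isoallele_1075", "hb_flags_5434", "d19_intermediate_494")

#: Isometric-heterozygote counts per locus among length-homozygous genotypes.
ISO_COUNTS = {
    "D5S818": 34, "D3S1358": 25, "D13S317": 23, "D21S11": 16, "D7S820": 15,
    "D8S1179": 14, "D16S539": 14, "vWA": 11, "D2S1338": 9, "D2S441": 8,
    "D12S391": 6, "D1S1656": 4, "TPOX": 2,
}


def build_scenario(name: str) -> ScenarioBundle:
    """Deterministic datasets whose aggregate counts match a documented
    worked-example scenario exactly; unknown names list the options."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; available: {', '.join(SCENARIOS)}")
    catalog = default_catalog()
    if name == "concordance_247":
        return _concordance_scenario(catalog)
    if name == "isoallele_1075":
        return _isoallele_scenario(catalog)
    if name == "hb_flags_5434":
        return _hb_scenario(catalog)
    return _d19_scenario(catalog)


def _concordance_scenario(catalog: Catalog) -> ScenarioBundle:
    """247 samples × 22 loci with exactly two injected single-allele
    drop-outs: the longer allele of a D2S1338 18/28 heterozygote and the
    shorter allele of a Penta E 8/11 heterozygote.  Depth is generous so no
    other calls fall below the interpretation thresholds."""
    cfg = default_config(n_samples=247, seed=20210826)
    cfg = cfg.model_copy(update={
        "total_reads_model": TotalReadsModel(log_mean=math.log(250_000.0), log_sd=0.2),
        "hb_model": {l: HBModel(alpha=40.0, beta=8.0) for l in cfg.freq_spectra},
        "stutter_model": {l: StutterModel(intercept=-0.03, slope=0.008, sd=0.01)
                          for l in cfg.freq_spectra},
    })
    genotypes = generate_population(cfg, catalog)
    s_drop_long, s_drop_short = "S0001", "S0002"
    d2 = catalog.locus("D2S1338")
    pe = catalog.locus("Penta E")
    forced = {
        (s_drop_long, "D2S1338"): (allele_from_designation(d2, "18"),
                                   allele_from_designation(d2, "28")),
        (s_drop_short, "Penta E"): (allele_from_designation(pe, "8"),
                                    allele_from_designation(pe, "11")),
    }
    genotypes = [
        TrueGenotype(g.sample_id, g.locus, *forced[(g.sample_id, g.locus)])
        if (g.sample_id, g.locus) in forced else g
        for g in genotypes
    ]
    cfg = cfg.model_copy(update={"dropout_events": [
        DropoutEvent(sample_id=s_drop_long, locus="D2S1338", which="longer"),
        DropoutEvent(sample_id=s_drop_short, locus="Penta E", which="shorter"),
    ]})
    profiles = simulate_reads(genotypes, cfg, catalog)
    ce = derive_ce_dataset(genotypes, catalog)
    return ScenarioBundle(
        name="concordance_247", catalog=catalog, genotypes=genotypes,
        profiles=profiles, ce_table=ce,
        description="247×22 cohort, two single-allele drop-outs (D2S1338 longer, Penta E shorter)",
    )


def _locus_allele(catalog: Catalog, locus_name: str, idx: int, tag: str = "") -> SequenceAllele:
    spec = _DEFAULT_SPECTRA[locus_name][idx]
    locus = catalog.locus(locus_name)
    return allele_from_designation(locus, spec[0], seq_tag=tag)


def _isoallele_scenario(catalog: Catalog) -> ScenarioBundle:
    """247 samples × 22 loci containing exactly 1,075 length-homozygous
    genotypes of which 181 are isometric heterozygotes, distributed across
    thirteen loci."""
    loci = sorted(_DEFAULT_SPECTRA)
    n_samples = 247
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    base, extra = divmod(1075, len(loci))  # 48 per locus + 19 remainders
    genotypes = []
    for li, locus_name in enumerate(loci):
        locus = catalog.locus(locus_name)
        n_hom = base + (1 if li < extra else 0)
        n_iso = ISO_COUNTS.get(locus_name, 0)
        hom_des = _DEFAULT_SPECTRA[locus_name][0][0]
        het_des = next(e[0] for e in _DEFAULT_SPECTRA[locus_name] if e[0] != hom_des)
        for si, sid in enumerate(sample_ids):
            if si < n_iso:
                a = allele_from_designation(locus, hom_des, seq_tag="a")
                b = allele_from_designation(locus, hom_des, seq_tag="b")
            elif si < n_hom:
                a = b = allele_from_designation(locus, hom_des, seq_tag="a")
            else:
                a = allele_from_designation(locus, hom_des, seq_tag="a")
                b = allele_from_designation(locus, het_des)
            genotypes.append(TrueGenotype(sid, locus_name, a, b))
    return ScenarioBundle(
        name="isoallele_1075", catalog=catalog, genotypes=genotypes,
        description="1,075 length-homozygous genotypes, 181 isometric heterozygotes at 13 loci",
    )


def _hb_scenario(catalog: Catalog) -> ScenarioBundle:
    """5,434 heterozygous genotype calls (247 samples × 22 loci) with exactly
    seven highly imbalanced calls (HB ≤ 0.30): five at D2S1338, one at
    D19S433, one at D21S11."""
    loci = sorted(_DEFAULT_SPECTRA)
    flagged = [("S0001", "D2S1338"), ("S0002", "D2S1338"), ("S0003", "D2S1338"),
               ("S0004", "D2S1338"), ("S0005", "D2S1338"),
               ("S0006", "D19S433"), ("S0007", "D21S11")]
    rows = []
    for si in range(247):
        sid = f"S{si + 1:04d}"
        for locus_name in loci:
            if (sid, locus_name) in flagged:
                ra, rb = 270, 1000  # HB 0.27
            else:
                ra, rb = 820, 1000  # HB 0.82
            rows.append({"sample_id": sid, "locus": locus_name,
                         "reads_a": ra, "reads_b": rb})
    return ScenarioBundle(
        name="hb_flags_5434", catalog=catalog,
        het_reads=pd.DataFrame(rows),
        description="5,434 heterozygous calls, 7 with HB <= 0.30",
    )


def _d19_scenario(catalog: Catalog) -> ScenarioBundle:
    """494 D19S433 alleles (247 genotypes) of which 55 carry the
    repeat-boundary [TC/-] deletion, i.e. intermediate alleles."""
    locus = catalog.locus("D19S433")
    carrier = allele_from_designation(locus, "12.3", variants=["rs147936416"])
    normal_a = allele_from_designation(locus, "13")
    normal_b = allele_from_designation(locus, "14")
    genotypes = []
    for si in range(247):
        sid = f"S{si + 1:04d}"
        if si < 55:
            genotypes.append(TrueGenotype(sid, "D19S433", carrier, normal_a))
        else:
            genotypes.append(TrueGenotype(sid, "D19S433", normal_a, normal_b))
    return ScenarioBundle(
        name="d19_intermediate_494", catalog=catalog, genotypes=genotypes,
        description="494 D19S433 alleles, 55 carrying rs147936416",
    )


def intermediate_allele_pct(genotypes: list[TrueGenotype], variant_id: str) -> float:
    """Percentage of alleles at the genotypes' locus carrying ``variant_id``
    (one decimal)."""
    from .nomenclature import round_half_up

    total = 0
    carriers = 0
    for g in genotypes:
        for al in (g.allele_a, g.allele_b):
            total += 1
            carriers += variant_id in al.flanking_variants
    if total == 0:
        raise ValueError("no genotypes")
    return round_half_up(100.0 * carriers / total, 1)
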