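import math

import numpy as np
import pytest
from pydantic import ValidationError

from strseqdb.nomenclature import repeat_designation
from strseqdb.simulate import (
    DropinEvent,
    DropoutEvent,
    HBModel,
    SCENARIOS,
    StutterModel,
    build_scenario,
    default_config,
    derive_ce_dataset,
    generate_population,
    intermediate_allele_pct,
    simulate_reads,
)

from conftest import small_config, spectrum


class TestGeneratePopulation:
    def test_degenerate_spectrum_all_homozygous(self, catalog):
        cfg = small_config({"TPOX": spectrum(("10", 1.0))}, n_samples=25, seed=1)
        genos = generate_population(cfg, catalog)
        assert len(genos) == 25
        assert all(g.allele_a.sequence_id == g.allele_b.sequence_id for g in genos)

    def test_heterozygote_fraction_near_binomial_expectation(self, catalog):
        """p = q = 0.5 gives P(het) = 0.5; the empirical fraction stays within
        three binomial standard errors at n = 10,000."""
        cfg = small_config({"TPOX": spectrum(("8", 0.5), ("11", 0.5))},
                           n_samples=10_000, seed=2)
        genos = generate_population(cfg, catalog)
        het = np.mean([g.allele_a.sequence_id != g.allele_b.sequence_id for g in genos])
        se = math.sqrt(0.25 / 10_000)
        assert abs(het - 0.5) <= 3 * se

    def test_seed_determinism(self, catalog):
        cfg = default_config(n_samples=15, seed=42)
        a = generate_population(cfg, catalog)
        b = generate_population(cfg, catalog)
        assert a == b

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValidationError):
            small_config({"TPOX": []}, n_samples=5, seed=1)

    def test_spectrum_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sums to"):
            small_config({"TPOX": spectrum(("8", 0.5), ("9", 0.4))}, n_samples=5, seed=1)


class TestSimulateReads:
    def test_fixed_balance_splits_heterozygotes_evenly(self, catalog):
        cfg = small_config(
            {"vWA": spectrum(("14", 0.5), ("18", 0.5))}, n_samples=40, seed=3,
            hb_model={"vWA": HBModel(fixed=1.0)},
            stutter_model={"vWA": StutterModel(intercept=0.0, slope=0.0, sd=0.0)},
        )
        genos = generate_population(cfg, catalog)
        profiles = simulate_reads(genos, cfg, catalog)
        for p in profiles:
            seqs = p.loci["vWA"]
            if len(seqs) == 2:
                a, b = seqs.values()
                assert abs(a - b) <= 1  # integer rounding only

    def test_read_conservation(self, catalog):
        cfg = default_config(n_samples=10, seed=5)
        profiles = simulate_reads(generate_population(cfg, catalog), cfg, catalog)
        for p in profiles:
            assert p.total_reads == sum(r for m in p.loci.values() for r in m.values())

    def test_stutter_grows_with_repeat_count(self, catalog):
        """Monte-Carlo: with positive slope, simulated long alleles carry a
        higher mean stutter ratio than short ones (n = 5,000 parents)."""
        cfg = small_config({"D18S51": spectrum(("10", 0.5), ("18", 0.5))},
                           n_samples=2500, seed=6)
        genos = generate_population(cfg, catalog)
        profiles = simulate_reads(genos, cfg, catalog)
        ratios = {10: [], 18: []}
        truth = {(g.sample_id): g for g in genos}
        for p in profiles:
            seqs = p.loci["D18S51"]
            locus = catalog.locus("D18S51")
            by_len = {}
            for a, r in seqs.items():
                d = repeat_designation(a, locus)
                by_len[d.full_units] = by_len.get(d.full_units, 0) + r
            for units in (10, 18):
                if units in by_len and (units - 1) in by_len and (units - 1) not in (10, 18):
                    ratios[units].append(by_len[units - 1] / by_len[units])
        assert np.mean(ratios[18]) > np.mean(ratios[10])

    def test_injected_dropout_removes_longer_allele(self, catalog):
        cfg = small_config(
            {"D2S1338": spectrum(("18", 0.5), ("28", 0.5))}, n_samples=5, seed=7,
            dropout_events=[DropoutEvent(sample_id="S0001", locus="D2S1338", which="longer")],
        )
        genos = generate_population(cfg, catalog)
        # force the target sample heterozygous
        from strseqdb.nomenclature import allele_from_designation
        from strseqdb.simulate import TrueGenotype

        l = catalog.locus("D2S1338")
        genos = [TrueGenotype("S0001", "D2S1338", allele_from_designation(l, "18"),
                              allele_from_designation(l, "28"))
                 if g.sample_id == "S0001" else g for g in genos]
        profiles = simulate_reads(genos, cfg, catalog)
        p = next(x for x in profiles if x.sample_id == "S0001")
        designs = {str(repeat_designation(a, l)) for a in p.loci["D2S1338"]}
        assert "28" not in designs and "18" in designs

    def test_injected_dropin_adds_spurious_sequence(self, catalog):
        cfg = small_config(
            {"TPOX": spectrum(("8", 1.0))}, n_samples=2, seed=8,
            dropin_events=[DropinEvent(sample_id="S0002", locus="TPOX",
                                       designation="11", reads=373)],
        )
        profiles = simulate_reads(generate_population(cfg, catalog), cfg, catalog)
        p = next(x for x in profiles if x.sample_id == "S0002")
        l = catalog.locus("TPOX")
        spurious = [r for a, r in p.loci["TPOX"].items()
                    if str(repeat_designation(a, l)) == "11"]
        assert spurious == [373]

    def test_misconfigured_stutter_model_rejected(self, catalog):
        cfg = small_config(
            {"D18S51": spectrum(("18", 1.0))}, n_samples=2, seed=9,
            stutter_model={"D18S51": StutterModel(intercept=0.9, slope=0.05, sd=0.0)},
        )
        with pytest.raises(ValueError, match=">= 1"):
            simulate_reads(generate_population(cfg, catalog), cfg, catalog)

    def test_bit_identical_rerun(self, catalog):
        cfg = default_config(n_samples=8, seed=10)
        genos = generate_population(cfg, catalog)
        p1 = simulate_reads(genos, cfg, catalog)
        p2 = simulate_reads(genos, cfg, catalog)
        assert [(p.sample_id, p.loci) for p in p1] == [(p.sample_id, p.loci) for p in p2]


class TestDeriveCE:
    def test_het_genotype_row(self, catalog):
        from strseqdb.nomenclature import allele_from_designation
        from strseqdb.simulate import TrueGenotype

        l = catalog.locus("D2S1338")
        g = TrueGenotype("s1", "D2S1338", allele_from_designation(l, "28"),
                         allele_from_designation(l, "18"))
        row = derive_ce_dataset([g], catalog).iloc[0]
        assert (row.allele1, row.allele2) == ("18", "28")

    def test_isometric_het_appears_length_homozygous(self, catalog):
        from strseqdb.nomenclature import allele_from_designation
        from strseqdb.simulate import TrueGenotype

        l = catalog.locus("TPOX")
        g = TrueGenotype("s1", "TPOX", allele_from_designation(l, "8", seq_tag="a"),
                         allele_from_designation(l, "8", seq_tag="b"))
        row = derive_ce_dataset([g], catalog).iloc[0]
        assert (row.allele1, row.allele2) == ("8", "8")

    def test_empty_cohort(self, catalog):
        assert derive_ce_dataset([], catalog).empty


class TestScenarios:
    def test_unknown_scenario_lists_options(self):
        with pytest.raises(ValueError) as exc:
            build_scenario("nope")
        for name in SCENARIOS:
            assert name in str(exc.value)

    def test_concordance_scenario_shape(self, concordance_scenario):
        b = concordance_scenario
        assert len(b.profiles) == 247
        assert len({g.locus for g in b.genotypes}) == 22
        assert len(b.ce_table) == 247 * 22

    def test_hb_scenario_counts(self):
        b = build_scenario("hb_flags_5434")
        df = b.het_reads
        assert len(df) == 5434
        hb = np.minimum(df.reads_a, df.reads_b) / np.maximum(df.reads_a, df.reads_b)
        assert int((hb <= 0.30).sum()) == 7
        flagged_loci = df.loc[hb <= 0.30, "locus"].value_counts().to_dict()
        assert flagged_loci == {"D2S1338": 5, "D19S433": 1, "D21S11": 1}

    def test_d19_scenario_counts(self):
        b = build_scenario("d19_intermediate_494")
        assert len(b.genotypes) == 247
        assert intermediate_allele_pct(b.genotypes, "rs147936416") == 11.1

    def test_scenarios_are_deterministic(self):
        a = build_scenario("d19_intermediate_494")
        b = build_scenario("d19_intermediate_494")
        assert a.genotypes == b.genotypes
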