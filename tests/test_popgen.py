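import itertools
import math
from collections import Counter

import numpy as np
import pytest

from strseqdb.nomenclature import allele_from_designation
from strseqdb.popgen import (
    _genotype_table,
    _log_table_prob,
    allele_frequencies,
    forensic_params,
    heterozygosities,
    heterozygosity_gain,
    hwe_exact_test,
    locus_stats,
)
from strseqdb.simulate import build_scenario, generate_population

from conftest import small_config, spectrum


class TestFrequencies:
    def test_monomorphic(self):
        assert allele_frequencies([("12", "12")] * 10) == {"12": 1.0}

    def test_counting_oracle(self):
        freqs = allele_frequencies([("a", "a"), ("a", "b")])
        assert freqs == {"a": 0.75, "b": 0.25}

    def test_incomplete_genotypes_excluded(self):
        freqs = allele_frequencies([("a", "a"), ("a", None)])
        assert freqs == {"a": 1.0}

    def test_sequence_level_splits_sum_to_length_class(self):
        genos_seq = [("12#a", "12#b"), ("12#a", "12#a"), ("12#b", "13"), ("13", "13")]
        genos_len = [tuple(g.split("#")[0] for g in pair) for pair in genos_seq]
        fs, fl = allele_frequencies(genos_seq), allele_frequencies(genos_len)
        assert fs["12#a"] + fs["12#b"] == pytest.approx(fl["12"])
        assert fs["13"] == pytest.approx(fl["13"])


class TestHeterozygosities:
    def test_monomorphic_is_zero(self):
        h_obs, h_exp = heterozygosities([("a", "a")] * 10)
        assert (h_obs, h_exp) == (0.0, 0.0)

    def test_balanced_biallelic_limit(self):
        genos = [("a", "b")] * 5000 + [("a", "a")] * 2500 + [("b", "b")] * 2500
        h_obs, h_exp = heterozygosities(genos)
        assert h_obs == 0.5
        assert h_exp == pytest.approx(0.5, abs=1e-3)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        alleles = ["a", "b", "c", "d"]
        genos = [tuple(rng.choice(alleles, 2)) for _ in range(60)]
        h_obs, h_exp = heterozygosities(genos)
        # independent recomputation from first principles
        n = len(genos)
        het = sum(a != b for a, b in genos) / n
        counts = Counter(itertools.chain.from_iterable(genos))
        ssq = sum((c / (2 * n)) ** 2 for c in counts.values())
        assert h_obs == pytest.approx(het)
        assert h_exp == pytest.approx((2 * n / (2 * n - 1)) * (1 - ssq))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            heterozygosities([("a", "b")])


class TestForensicParams:
    def test_monomorphic_extremes(self):
        fp = forensic_params([("a", "a")] * 10)
        assert (fp["mp"], fp["pd"], fp["pe"]) == (1.0, 0.0, 0.0)
        assert fp["tpi"] == pytest.approx(0.5)  # 1/(2H) with H = 1

    def test_all_heterozygous_tpi_infinite(self):
        assert math.isinf(forensic_params([("a", "b")] * 10)["tpi"])

    def test_tpi_at_half_heterozygosity(self):
        genos = [("a", "b")] * 5 + [("a", "a")] * 5
        assert forensic_params(genos)["tpi"] == pytest.approx(1.0)

    def test_mp_matches_class_count_oracle(self):
        genos = [("a", "a")] * 25 + [("a", "b")] * 50 + [("b", "b")] * 25
        fp = forensic_params(genos)
        assert fp["mp"] == pytest.approx(0.25**2 + 0.5**2 + 0.25**2)
        assert fp["pd"] == pytest.approx(1 - fp["mp"])

    def test_pd_plus_mp_is_exactly_one(self):
        rng = np.random.default_rng(8)
        genos = [tuple(rng.choice(["a", "b", "c"], 2)) for _ in range(80)]
        fp = forensic_params(genos)
        assert fp["pd"] + fp["mp"] == 1.0


def oracle_hwe_pvalue(genotypes):
    """Independent brute-force oracle: enumerate every arrangement of the
    allele vector into ordered pairs and accumulate exact table
    probabilities; p = mass of tables no more probable than the observed."""
    obs = Counter(tuple(sorted(g)) for g in genotypes)
    vector = list(itertools.chain.from_iterable(genotypes))
    tables = Counter()
    total = 0
    for perm in itertools.permutations(vector):
        table = tuple(sorted(tuple(sorted(perm[i:i + 2])) for i in range(0, len(perm), 2)))
        tables[table] += 1
        total += 1
    obs_key = tuple(sorted(obs.elements()))
    p_obs = tables[obs_key] / total
    return sum(c for t, c in tables.items() if c / total <= p_obs + 1e-12) / total


class TestHWE:
    def test_two_homozygotes_match_enumeration_oracle(self):
        genos = [("a", "a"), ("b", "b")]
        assert hwe_exact_test(genos, method="enumerate") == pytest.approx(
            oracle_hwe_pvalue(genos))

    @pytest.mark.parametrize("genos", [
        [("a", "a"), ("a", "b"), ("b", "b")],
        [("a", "b"), ("a", "b"), ("a", "a")],
        [("a", "a"), ("a", "c"), ("b", "c"), ("b", "b")],
    ])
    def test_small_cases_match_arrangement_oracle(self, genos):
        assert hwe_exact_test(genos, method="enumerate") == pytest.approx(
            oracle_hwe_pvalue(genos), abs=1e-12)

    def test_table_probability_matches_arrangement_frequency(self):
        # the conditional probability formula against direct arrangement counting
        genos = [("a", "b"), ("a", "a"), ("b", "b"), ("a", "b")]
        vector = list(itertools.chain.from_iterable(genos))
        tables = Counter()
        for perm in itertools.permutations(vector):
            t = tuple(sorted(tuple(sorted(perm[i:i + 2])) for i in range(0, len(perm), 2)))
            tables[t] += 1
        total = sum(tables.values())
        obs_key = tuple(sorted(Counter(tuple(sorted(g)) for g in genos).elements()))
        table = _genotype_table(genos)
        counts = Counter(itertools.chain.from_iterable(genos))
        assert math.exp(_log_table_prob(table, counts)) == pytest.approx(
            tables[obs_key] / total)

    def test_perfect_proportions_not_rejected(self):
        genos = [("a", "a")] * 25 + [("a", "b")] * 50 + [("b", "b")] * 25
        assert hwe_exact_test(genos, method="enumerate") > 0.05

    def test_monomorphic_convention(self):
        assert hwe_exact_test([("a", "a")] * 10) == 1.0

    def test_permutation_requires_seed(self):
        with pytest.raises(ValueError):
            hwe_exact_test([("a", "b")] * 4, method="permute")

    def test_permutation_converges_to_enumeration(self):
        """Three alleles, N=20: Monte-Carlo within 3·√(p(1−p)/n) of exact."""
        rng = np.random.default_rng(13)
        genos = [tuple(rng.choice(["a", "b", "c"], 2, p=[0.5, 0.3, 0.2]))
                 for _ in range(20)]
        exact = hwe_exact_test(genos, method="enumerate")
        n_perm = 20_000
        mc = hwe_exact_test(genos, method="permute", n_perm=n_perm, seed=99)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(mc - exact) <= max(3 * se, 1e-3)


class TestHeterozygosityGain:
    def test_locus_without_isoalleles_has_equal_columns(self, catalog):
        l = catalog.locus("FGA")
        genos = []
        for i in range(50):
            a = allele_from_designation(l, str(20 + i % 4))
            b = allele_from_designation(l, str(21 + i % 3))
            genos.append((f"s{i}", "FGA", a, b))
        table, total_iso, _ = heterozygosity_gain(genos, catalog)
        row = table.iloc[0]
        assert row["alleles_length"] == row["alleles_sequence"]
        assert row["h_obs_length"] == row["h_obs_sequence"]
        assert total_iso == 0

    def test_scenario_gain(self):
        b = build_scenario("isoallele_1075")
        genos = [(g.sample_id, g.locus, g.allele_a, g.allele_b) for g in b.genotypes]
        table, total_iso, pct = heterozygosity_gain(genos, b.catalog)
        assert total_iso == 181
        assert pct == 16.8
        # structural identity per locus
        assert (table["alleles_sequence"] ==
                table["alleles_length"] + table["isoalleles"]).all()
        assert (table["h_obs_sequence"] >= table["h_obs_length"]).all()


class TestParameterRecovery:
    def test_simulated_frequencies_converge_to_spectrum(self, catalog):
        """Estimated frequencies from a simulated cohort stay within three
        binomial standard errors of the configured spectrum."""
        spectra = {"CSF1PO": spectrum(("9", 0.1), ("10", 0.25), ("11", 0.3),
                                      ("12", 0.25), ("13", 0.1))}
        cfg = small_config(spectra, n_samples=4000, seed=31)
        genos = generate_population(cfg, catalog)
        pairs = [(str(g.allele_a.sequence_id), str(g.allele_b.sequence_id))
                 for g in genos]
        freqs = allele_frequencies(pairs)
        two_n = 2 * cfg.n_samples
        for spec_entry in spectra["CSF1PO"]:
            key = f"CSF1PO:{spec_entry.designation}"
            p = spec_entry.frequency
            se = math.sqrt(p * (1 - p) / two_n)
            assert abs(freqs[key] - p) <= 3 * se

    def test_locus_stats_bundle_consistency(self):
        rng = np.random.default_rng(3)
        genos = [tuple(rng.choice(["10", "11", "12"], 2)) for _ in range(40)]
        st = locus_stats("vWA", genos, hwe_method="enumerate")
        assert st.pd + st.mp == 1.0
        assert st.hom_exp == pytest.approx(1 - st.h_exp)
        assert 0 <= st.hwe_p <= 1
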