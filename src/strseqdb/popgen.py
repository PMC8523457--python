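"""Allele frequencies, forensic identity statistics and exact
Hardy–Weinberg testing.

Definitions (standard forensic usage):

* observed heterozygosity ``h_obs`` — heterozygote fraction of complete
  genotypes;
* expected heterozygosity ``h_exp = (2N/(2N−1)) · (1 − Σ p_i²)`` (unbiased
  Nei estimator);
* matching probability ``MP = Σ g_c²`` over observed genotype-class
  frequencies ``g_c``; power of discrimination ``PD = 1 − MP``;
* power of exclusion ``PE = h²·(1 − 2·h·H²)`` and typical paternity index
  ``TPI = 1/(2H)`` with ``h = h_obs`` and ``H = 1 − h_obs``;
* HWE exact test — probability mass of genotype tables, conditional on the
  observed allele counts, whose conditional probability does not exceed the
  observed table's (full enumeration, or Monte-Carlo permutation of the
  allele vector for large tables).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import round_half_up

Genotype = tuple[Hashable, Hashable]


def _norm(g: Genotype) -> Genotype:
    a, b = g
    return (a, b) if str(a) <= str(b) else (b, a)


def allele_frequencies(genotypes: Iterable[Genotype]) -> dict[Hashable, float]:
    """Allele relative frequencies from complete genotypes (homozygotes count
    two copies); incomplete genotypes (a ``None`` allele) are excluded."""
    counts: Counter = Counter()
    for g in genotypes:
        if g[0] is None or g[1] is None:
            continue
        counts[g[0]] += 1
        counts[g[1]] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no complete genotypes")
    return {a: c / total for a, c in sorted(counts.items(), key=lambda kv: str(kv[0]))}


def heterozygosities(genotypes: Sequence[Genotype]) -> tuple[float, float]:
    """Observed and unbiased expected heterozygosity."""
    complete = [g for g in genotypes if g[0] is not None and g[1] is not None]
    n = len(complete)
    if n < 2:
        raise ValueError("expected heterozygosity requires at least two genotypes")
    h_obs = sum(a != b for a, b in complete) / n
    freqs = allele_frequencies(complete)
    two_n = 2 * n
    h_exp = (two_n / (two_n - 1)) * (1.0 - sum(p * p for p in freqs.values()))
    return h_obs, h_exp


def forensic_params(genotypes: Sequence[Genotype]) -> dict[str, float]:
    """Matching probability, power of discrimination, power of exclusion and
    typical paternity index from observed genotype classes."""
    complete = [_norm(g) for g in genotypes if g[0] is not None and g[1] is not None]
    n = len(complete)
    if n < 2:
        raise ValueError("need at least two genotypes")
    class_counts = Counter(complete)
    mp = sum((c / n) ** 2 for c in class_counts.values())
    h = sum(a != b for a, b in complete) / n
    H = 1.0 - h
    pe = h * h * (1.0 - 2.0 * h * H * H)
    tpi = math.inf if H == 0 else 1.0 / (2.0 * H)
    return {"mp": mp, "pd": 1.0 - mp, "pe": pe, "tpi": tpi}


# --- exact Hardy–Weinberg test ------------------------------------------------


def _log_table_prob(table: Mapping[Genotype, int], allele_counts: Mapping[Hashable, int]) -> float:
    """log conditional probability of a genotype table given allele counts:
    N!·Π m_i!·2^h / ((2N)!·Π n_ij!)."""
    n = sum(table.values())
    two_n = 2 * n
    h = sum(c for (a, b), c in table.items() if a != b)
    lp = math.lgamma(n + 1) - math.lgamma(two_n + 1) + h * math.log(2.0)
    for m in allele_counts.values():
        lp += math.lgamma(m + 1)
    for c in table.values():
        lp -= math.lgamma(c + 1)
    return lp


def _genotype_table(genotypes: Iterable[Genotype]) -> Counter:
    return Counter(_norm(g) for g in genotypes)


def _allele_counts(table: Mapping[Genotype, int]) -> Counter:
    counts: Counter = Counter()
    for (a, b), c in table.items():
        counts[a] += c
        counts[b] += c
    return counts


class TableSpaceExceeded(RuntimeError):
    pass


def _enumerate_pvalue(
    allele_counts: Mapping[Hashable, int], lp_obs: float, max_tables: int
) -> float:
    """Full enumeration of genotype tables conditional on allele counts."""
    alleles = sorted(allele_counts, key=str)
    k = len(alleles)
    remaining = [allele_counts[a] for a in alleles]
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    table: dict[Genotype, int] = {}
    acc = {"p": 0.0, "count": 0}
    eps = 1e-9

    def rec(cell_idx: int) -> None:
        if cell_idx == len(cells):
            if all(r == 0 for r in remaining):
                acc["count"] += 1
                if acc["count"] > max_tables:
                    raise TableSpaceExceeded
                lp = _log_table_prob(table, allele_counts)
                if lp <= lp_obs + eps:
                    acc["p"] += math.exp(lp)
            return
        i, j = cells[cell_idx]
        if i == j:
            hi = remaining[i] // 2
        else:
            hi = min(remaining[i], remaining[j])
        # last cell touching allele i must absorb its remainder exactly
        for n_ij in range(hi + 1):
            take_i = 2 * n_ij if i == j else n_ij
            remaining[i] -= take_i
            if i != j:
                remaining[j] -= n_ij
            key = (alleles[i], alleles[j])
            table[key] = n_ij
            last_for_i = (j == k - 1)
            if not (last_for_i and remaining[i] != 0):
                rec(cell_idx + 1)
            del table[key]
            remaining[i] += take_i
            if i != j:
                remaining[j] += n_ij
        return

    rec(0)
    return min(acc["p"], 1.0)


def _permute_pvalue(
    allele_counts: Mapping[Hashable, int],
    lp_obs: float,
    n_perm: int,
    seed: int,
    chunk: int = 4096,
) -> float:
    """Monte-Carlo permutation: shuffle the allele vector, pair consecutive
    alleles into genotypes, and compare conditional table probabilities.

    The per-permutation log-probability shares the constant term
    ``log N! − log (2N)! + Σ log m_i!``; only the heterozygote count and the
    genotype-cell factorials vary, so permutations are scored vectorised.
    """
    from scipy.special import gammaln

    alleles = sorted(allele_counts, key=str)
    k = len(alleles)
    counts = np.array([allele_counts[a] for a in alleles], dtype=np.int64)
    pool = np.repeat(np.arange(k, dtype=np.int64), counts)
    n = pool.size // 2
    const = (
        math.lgamma(n + 1)
        - math.lgamma(2 * n + 1)
        + sum(math.lgamma(m + 1) for m in counts)
    )
    rng = np.random.default_rng(seed)
    eps = 1e-9
    hits = 0
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        mat = rng.permuted(np.broadcast_to(pool, (b, pool.size)).copy(), axis=1)
        x, y = mat[:, 0::2], mat[:, 1::2]
        i, j = np.minimum(x, y), np.maximum(x, y)
        cells = i * k + j
        flat = (np.arange(b)[:, None] * (k * k) + cells).ravel()
        tables = np.bincount(flat, minlength=b * k * k).reshape(b, k * k)
        het = (i != j).sum(axis=1)
        lp = const + het * math.log(2.0) - gammaln(tables + 1.0).sum(axis=1)
        hits += int((lp <= lp_obs + eps).sum())
        done += b
    return hits / n_perm


def hwe_exact_test(
    genotypes: Iterable[Genotype] | Mapping[Genotype, int],
    method: str = "auto",
    n_perm: int = 100_000,
    seed: Optional[int] = None,
    max_tables: int = 10_000_000,
) -> float:
    """Exact Hardy–Weinberg p-value conditional on allele counts.

    ``method`` is ``enumerate`` (full table enumeration), ``permute``
    (Monte-Carlo; ``seed`` mandatory), or ``auto`` (enumeration, falling back
    to permutation when the table space exceeds ``max_tables``).
    Monomorphic loci return 1.0 by convention.
    """
    table = Counter(genotypes) if isinstance(genotypes, Mapping) else _genotype_table(genotypes)
    table = Counter({_norm(g): c for g, c in table.items()})
    if not table:
        raise ValueError("no genotypes")
    allele_counts = _allele_counts(table)
    if len(allele_counts) < 2:
        return 1.0
    lp_obs = _log_table_prob(table, allele_counts)
    if method not in ("auto", "enumerate", "permute"):
        raise ValueError(f"unknown method {method!r}")
    n = sum(table.values())
    small_enough = len(allele_counts) <= 4 and n <= 50
    if method == "enumerate" or (method == "auto" and small_enough):
        try:
            return _enumerate_pvalue(allele_counts, lp_obs, max_tables)
        except TableSpaceExceeded:
            if method == "enumerate":
                raise
    if seed is None:
        raise ValueError("permutation method requires a seed")
    return _permute_pvalue(allele_counts, lp_obs, n_perm, seed)


# --- per-locus statistics bundle ---------------------------------------------


@dataclass
class LocusPopStats:
    locus: str
    n_samples: int
    allele_freqs: dict
    h_obs: float
    h_exp: float
    hom_exp: float
    mp: float
    pd: float
    pe: float
    tpi: float
    hwe_p: float


def locus_stats(
    locus: str,
    genotypes: Sequence[Genotype],
    hwe_method: str = "auto",
    n_perm: int = 100_000,
    seed: Optional[int] = None,
) -> LocusPopStats:
    complete = [g for g in genotypes if g[0] is not None and g[1] is not None]
    freqs = allele_frequencies(complete)
    h_obs, h_exp = heterozygosities(complete)
    fp = forensic_params(complete)
    p = hwe_exact_test(complete, method=hwe_method, n_perm=n_perm, seed=seed)
    return LocusPopStats(
        locus=locus,
        n_samples=len(complete),
        allele_freqs=freqs,
        h_obs=h_obs,
        h_exp=h_exp,
        hom_exp=1.0 - h_exp,
        mp=fp["mp"],
        pd=fp["pd"],
        pe=fp["pe"],
        tpi=fp["tpi"],
        hwe_p=p,
    )


def heterozygosity_gain(
    genotypes: Iterable[tuple[str, str, "SequenceAllele", "SequenceAllele"]],
    catalog,
) -> tuple[pd.DataFrame, int, float]:
    """Table-style summary of heterozygosity gained from sequence typing.

    Per locus: allele totals (distinct alleles summed over genotypes — a
    heterozygote contributes two, a homozygote one) at length and sequence
    level, isometric-heterozygote count and observed heterozygosity at both
    levels; plus the global reclassified count and its percentage of
    length-homozygous genotypes.
    """
    from .nomenclature import (
        LENGTH_HET,
        LENGTH_HOM_SEQ_HET,
        classify_genotype,
    )

    per: dict[str, Counter] = {}
    for _sid, locus_name, a, b in genotypes:
        locus = catalog.locus(locus_name)
        status = classify_genotype(a, b, locus)
        per.setdefault(locus_name, Counter())[status] += 1
    rows = []
    total_iso = 0
    total_hom = 0
    for locus_name in sorted(per):
        c = per[locus_name]
        n = sum(c.values())
        het_len = c[LENGTH_HET]
        iso = c[LENGTH_HOM_SEQ_HET]
        hom_len = n - het_len
        total_iso += iso
        total_hom += hom_len
        alleles_len = 2 * het_len + hom_len
        rows.append({
            "locus": locus_name,
            "alleles_length": alleles_len,
            "alleles_sequence": alleles_len + iso,
            "isoalleles": iso,
            "h_obs_length": round_half_up(het_len / n, 2),
            "h_obs_sequence": round_half_up((het_len + iso) / n, 2),
        })
    pct = round_half_up(100.0 * total_iso / total_hom, 1) if total_hom else 0.0
    return pd.DataFrame(rows), total_iso, pct
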