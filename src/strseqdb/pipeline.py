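"""End-to-end pipeline: call → designate → QC → concordance → popgen.

One configuration object carries every interpretation threshold; all
randomness (simulation, HWE permutation) flows from its single seed via
derived sub-seeds, so a fixed configuration reproduces a byte-identical
report bundle.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .calling import (
    DEFAULT_AT,
    DEFAULT_IT_HET,
    DEFAULT_IT_HOM,
    DEFAULT_STUTTER_FILTER,
    SampleProfile,
    call_profile,
)
from .catalog import Catalog, default_catalog, load_catalog
from .concordance import compare_datasets, concordance_summary, pseudo_ce_profile
from .io import read_ce_table, read_readcount_table, write_reports
from .nomenclature import round_half_up
from .popgen import locus_stats
from .qc import (
    CATEGORY_I_MAX,
    CATEGORY_II_MIN,
    HB_FLAG_THRESHOLD,
    collect_stutter_records,
    flag_unbalanced_markers,
    heterozygote_balance,
    marker_performance_table,
    summarize_stutter,
)

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    catalog_path: Optional[str] = None
    at: int = DEFAULT_AT
    it_hom: int = DEFAULT_IT_HOM
    it_het: int = DEFAULT_IT_HET
    stutter_filter: float = DEFAULT_STUTTER_FILTER
    category_low: int = CATEGORY_I_MAX
    category_high: int = CATEGORY_II_MIN
    hb_flag_threshold: float = HB_FLAG_THRESHOLD
    stutter_flag_threshold: float = 0.20
    hwe_method: str = "auto"
    n_perm: int = 10_000
    seed: int = 0
    out_dir: str = "strseqdb_out"


def run_pipeline(
    config: PipelineConfig,
    profiles: Optional[list[SampleProfile]] = None,
    ce_table: Optional[pd.DataFrame] = None,
    readcounts_path: Optional[str] = None,
    ce_path: Optional[str] = None,
    write: bool = True,
) -> dict:
    """Run every stage on a cohort and return the report bundle.

    Inputs are either in-memory (``profiles``/``ce_table``) or file paths.
    The bundle maps report names to DataFrames plus a ``summary`` dict; when
    ``write`` is true it is also materialised under ``config.out_dir``.
    """
    catalog = load_catalog(config.catalog_path) if config.catalog_path else default_catalog()
    if profiles is None:
        if readcounts_path is None:
            raise ValueError("no read-count input: pass profiles or readcounts_path")
        profiles = read_readcount_table(readcounts_path, catalog)
    if not profiles:
        raise ValueError("empty cohort: no sample profiles")
    if ce_table is None and ce_path is not None:
        ce_table = read_ce_table(ce_path)

    # stage 1: thresholded genotype calling
    calls_by_sample = {
        p.sample_id: call_profile(p, catalog, config.at, config.it_hom,
                                  config.it_het, config.stutter_filter)
        for p in profiles
    }
    all_calls = [c for calls in calls_by_sample.values() for c in calls]
    logger.info("stage call: %d profiles -> %d genotype calls (AT=%d, IT=%d/%d)",
                len(profiles), len(all_calls), config.at, config.it_hom, config.it_het)

    # stage 2: pseudo-CE designation
    designations = pseudo_ce_profile(all_calls, catalog)

    # stage 3: QC
    rmp = marker_performance_table(profiles)
    marker_means = rmp.groupby("locus")["fraction"].mean().to_dict()
    unbalanced = flag_unbalanced_markers(marker_means) if len(marker_means) > 1 else []
    hb_rows = []
    for call in all_calls:
        if len(call.called_alleles) == 2 and len(call.reads) == 2:
            hb = heterozygote_balance(*call.reads)
            hb_rows.append({"sample_id": call.sample_id, "locus": call.locus,
                            "hb": hb, "flagged": hb <= config.hb_flag_threshold})
    hb_table = pd.DataFrame(hb_rows, columns=["sample_id", "locus", "hb", "flagged"])
    stutter_records = []
    prof_by_id = {p.sample_id: p for p in profiles}
    for sid, calls in calls_by_sample.items():
        stutter_records.extend(collect_stutter_records(prof_by_id[sid], calls, catalog))
    stutter_table = summarize_stutter(stutter_records)

    # stage 4: concordance against CE, when a CE table is available
    conc_report = None
    if ce_table is not None:
        comps = compare_datasets(ce_table, designations)
        conc_report = concordance_summary(comps)

    # stage 5: population genetics on complete pseudo-CE genotypes
    geno_by_locus: dict[str, list] = {}
    for call in all_calls:
        ms = call.allele_multiset
        if len(ms) == 2 and not call.flags:
            locus = catalog.locus(call.locus)
            from .nomenclature import allele_ce_designation

            pair = tuple(str(allele_ce_designation(a, locus, catalog)) for a in ms)
            geno_by_locus.setdefault(call.locus, []).append(pair)
    pop_rows = []
    for locus_name in sorted(geno_by_locus):
        st = locus_stats(locus_name, geno_by_locus[locus_name],
                         hwe_method=config.hwe_method, n_perm=config.n_perm,
                         seed=config.seed + 17)
        pop_rows.append({
            "locus": st.locus, "n": st.n_samples,
            "h_obs": round_half_up(st.h_obs, 2), "h_exp": round_half_up(st.h_exp, 2),
            "mp": st.mp, "pd": st.pd, "pe": st.pe, "tpi": st.tpi, "hwe_p": st.hwe_p,
        })
    pop_table = pd.DataFrame(pop_rows)

    summary = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {"AT": config.at, "IT_hom": config.it_hom, "IT_het": config.it_het,
                       "hb_flag": config.hb_flag_threshold,
                       "stutter_flag": config.stutter_flag_threshold},
        "n_profiles": len(profiles),
        "n_calls": len(all_calls),
        "unbalanced_markers": unbalanced,
        "n_hb_flagged": int(hb_table["flagged"].sum()) if not hb_table.empty else 0,
    }
    if conc_report is not None:
        summary["allele_concordance_pct"] = conc_report.allele_concordance_pct
        summary["locus_concordance_pct"] = conc_report.locus_concordance_pct
        summary["discordant_events"] = [
            {"sample_id": e.sample_id, "locus": e.locus, "status": e.status,
             "ce": list(e.ce_alleles), "mps": list(e.mps_alleles)}
            for e in conc_report.events
        ]

    bundle = {
        "designations": designations,
        "marker_performance": rmp,
        "heterozygote_balance": hb_table,
        "stutter_summary": stutter_table,
        "popgen": pop_table,
        "summary": summary,
    }
    if write:
        write_reports(bundle, config.out_dir)
    return bundle
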