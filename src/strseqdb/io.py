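"""Tabular I/O: read-count tables, CE genotype tables and report bundles.

TSV is the canonical interchange format (CSV accepted on read); UTF-8, Unix
newlines, ``.`` decimal separator.  Allele designations travel as strings
(``"9.3"`` is nine repeats plus three bases, never a decimal fraction).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .calling import SampleProfile
from .catalog import Catalog
from .nomenclature import Designation, RepeatRun, SequenceAllele

READCOUNT_COLUMNS = ["sample_id", "locus", "sequence_id", "designation", "variants", "reads"]
CE_COLUMNS = ["sample_id", "locus", "allele1", "allele2"]


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_readcount_table(path: str | Path, catalog: Catalog) -> list[SampleProfile]:
    """Load per-sample sequence read counts.

    Expected columns: sample_id, locus, sequence_id, designation, variants
    (``+``-separated catalogue ids, may be empty), reads.  Errors carry the
    offending row number (1-based, excluding the header).
    """
    df = _read_table(path)
    missing = [c for c in READCOUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    known = {l.name for l in catalog.loci}
    profiles: dict[str, SampleProfile] = {}
    seen: set[tuple[str, str, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        if row.locus not in known:
            raise ValueError(f"{path} row {idx}: unknown locus {row.locus!r}")
        try:
            reads = int(row.reads)
        except ValueError:
            raise ValueError(f"{path} row {idx}: non-integer reads {row.reads!r}") from None
        if reads < 0:
            raise ValueError(f"{path} row {idx}: negative reads {reads}")
        key = (row.sample_id, row.locus, row.sequence_id)
        if key in seen:
            raise ValueError(f"{path} row {idx}: duplicate sequence {key}")
        seen.add(key)
        locus = catalog.locus(row.locus)
        variants = tuple(v for v in str(row.variants).split("+") if v)
        if locus.is_str:
            des = Designation.parse(str(row.designation))
            allele = SequenceAllele(
                locus=row.locus,
                repeat_blocks=(RepeatRun(motif=locus.motif, count=des.full_units),),
                partial_bases=des.partial,
                flanking_variants=variants,
                sequence_id=row.sequence_id,
            )
        else:
            allele = SequenceAllele(locus=row.locus, repeat_blocks=(), sequence_id=row.sequence_id)
        prof = profiles.setdefault(row.sample_id, SampleProfile(sample_id=row.sample_id))
        prof.loci.setdefault(row.locus, {})[allele] = reads
    return [profiles[s] for s in sorted(profiles)]


def write_readcount_table(profiles: Iterable[SampleProfile], catalog: Catalog, path: str | Path) -> None:
    from .nomenclature import repeat_designation

    rows = []
    for p in sorted(profiles, key=lambda p: p.sample_id):
        for locus_name in sorted(p.loci):
            locus = catalog.locus(locus_name)
            for allele, reads in sorted(p.loci[locus_name].items(), key=lambda ar: ar[0].sequence_id):
                des = str(repeat_designation(allele, locus)) if locus.is_str else ""
                rows.append({
                    "sample_id": p.sample_id,
                    "locus": locus_name,
                    "sequence_id": allele.sequence_id,
                    "designation": des,
                    "variants": "+".join(allele.flanking_variants),
                    "reads": reads,
                })
    pd.DataFrame(rows, columns=READCOUNT_COLUMNS).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ce_table(path: str | Path) -> pd.DataFrame:
    """Load a CE genotype table (sample_id, locus, allele1, allele2);
    designations are validated and normalized."""
    df = _read_table(path)
    missing = [c for c in CE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        for col in ("allele1", "allele2"):
            text = str(getattr(row, col))
            try:
                Designation.parse(text)
            except ValueError:
                raise ValueError(
                    f"{path} row {idx}, column {col}: malformed designation {text!r}"
                ) from None
    return df[CE_COLUMNS].copy()


def write_ce_table(table: pd.DataFrame, path: str | Path) -> None:
    table[CE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_reports(reports: Mapping[str, pd.DataFrame | dict], out_dir: str | Path) -> list[Path]:
    """Write a named bundle of DataFrames (TSV) and dicts (JSON) with stable
    ordering and fixed decimal formatting; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(reports):
        obj = reports[name]
        if isinstance(obj, pd.DataFrame):
            p = out / f"{name}.tsv"
            obj.to_csv(p, sep="\t", index=False, lineterminator="\n", float_format="%.6f")
        else:
            p = out / f"{name}.json"
            p.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str) + "\n",
                         encoding="utf-8")
        written.append(p)
    return written
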