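"""Locus definitions and the flanking/repeat variant catalogue.

The catalogue drives two things downstream: the micro-variant arithmetic that
maps repeat-count designations onto CE-compatible (length-based) designations,
and the injection of sequence variants into simulated cohorts.  Entries are
keyed by dbSNP identifier; each records where the variant sits relative to the
repeat region and how many bases it adds or removes from the amplicon.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

CATALOG_SCHEMA_VERSION = 1

#: Total markers in the sequencing panel: 22 autosomal STRs plus amelogenin.
PANEL_MARKER_COUNT = 23

VariantKind = Literal["SNP", "insertion", "deletion"]
VariantRegion = Literal["5'-flank", "3'-flank", "repeat", "repeat-boundary"]


class RepeatBlock(BaseModel):
    """One block of the repeat-region template.

    ``counted`` marks whether the block's repeat units contribute to the
    allele designation (interrupting blocks and anchors do not).
    Coordinates are implicit: blocks are ordered 5'→3' within the repeat
    region on the catalogue's reference strand.
    """

    motif: str
    counted: bool = True


class LocusDef(BaseModel):
    """A panel marker: an autosomal STR locus, or amelogenin (``is_str=False``)."""

    name: str
    is_str: bool = True
    period: Optional[int] = None
    motif: Optional[str] = None
    counted_template: list[RepeatBlock] = Field(default_factory=list)
    panel_marker_count: int = PANEL_MARKER_COUNT

    @model_validator(mode="after")
    def _check(self) -> "LocusDef":
        if self.panel_marker_count < 1:
            raise ValueError("panel_marker_count must be >= 1")
        if self.is_str:
            if self.period not in (3, 4, 5):
                raise ValueError(f"{self.name}: STR period must be 3, 4 or 5")
            if self.motif is None or len(self.motif) != self.period:
                raise ValueError(f"{self.name}: motif length must equal period")
            if not any(b.counted for b in self.counted_template):
                raise ValueError(f"{self.name}: at least one counted block required")
        return self


class VariantCatalogEntry(BaseModel):
    """A catalogued sequence variant at a panel STR locus.

    ``net_length_change`` is the signed base count of the bracketed
    insertion/deletion description (0 for SNPs).  ``designation_shift`` is the
    portion of that length change falling *outside* counted repeat sequence —
    the amount by which the CE-apparent length differs from what repeat-unit
    counting already accounts for.  It defaults to ``net_length_change``,
    which is correct for pure flanking indels; repeat-boundary indels can
    override it.  ``ce_designation_override``, when present, supersedes the
    arithmetic entirely.
    """

    locus: str
    variant_id: str
    kind: VariantKind
    region: VariantRegion
    net_length_change: int = 0
    designation_shift: Optional[int] = None
    ce_designation_override: Optional[str] = None
    note: str = ""

    @model_validator(mode="after")
    def _check(self) -> "VariantCatalogEntry":
        if self.kind == "SNP" and self.net_length_change != 0:
            raise ValueError(f"{self.variant_id}: SNP must have net_length_change 0")
        if self.kind == "deletion" and self.net_length_change >= 0:
            raise ValueError(f"{self.variant_id}: deletion must have net_length_change < 0")
        if self.kind == "insertion" and self.net_length_change <= 0:
            raise ValueError(f"{self.variant_id}: insertion must have net_length_change > 0")
        return self

    @property
    def effective_shift(self) -> int:
        """Base shift applied in CE-equivalent designation arithmetic."""
        return self.net_length_change if self.designation_shift is None else self.designation_shift


class Catalog(BaseModel):
    """Validated locus + variant catalogue."""

    schema_version: int = CATALOG_SCHEMA_VERSION
    loci: list[LocusDef]
    variants: list[VariantCatalogEntry]

    @model_validator(mode="after")
    def _check(self) -> "Catalog":
        names = [l.name for l in self.loci]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate locus definitions: {dup}")
        defined = set(names)
        for v in self.variants:
            if v.locus not in defined:
                raise ValueError(f"variant {v.variant_id} references undefined locus {v.locus!r}")
        vids = [v.variant_id for v in self.variants]
        if len(vids) != len(set(vids)):
            raise ValueError("duplicate variant_id in catalogue")
        return self

    def locus(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(f"locus {name!r} not in catalogue")

    @property
    def str_loci(self) -> list[LocusDef]:
        return [l for l in self.loci if l.is_str]


class VariantNotFoundError(KeyError):
    """Raised when a variant id is absent from the catalogue."""


def lookup_variant(variant_id: str, catalog: Catalog) -> VariantCatalogEntry:
    """Return the unique catalogue entry for ``variant_id`` or raise."""
    for v in catalog.variants:
        if v.variant_id == variant_id:
            return v
    raise VariantNotFoundError(f"variant {variant_id!r} not in catalogue")


def load_catalog(path: str | Path) -> Catalog:
    """Load and validate a JSON catalogue file."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return Catalog.model_validate(payload)


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalogue as versioned JSON (lossless round-trip)."""
    Path(path).write_text(
        json.dumps(catalog.model_dump(), indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def catalog_to_tsv(catalog: Catalog, path: str | Path) -> None:
    """Flat TSV export of the variant table for human review."""
    cols = ["locus", "variant_id", "kind", "region", "net_length_change", "ce_designation_override", "note"]
    lines = ["\t".join(cols)]
    for v in catalog.variants:
        lines.append(
            "\t".join(
                [v.locus, v.variant_id, v.kind, v.region, str(v.net_length_change),
                 v.ce_designation_override or "", v.note]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def default_catalog() -> Catalog:
    """The shipped panel catalogue: 22 autosomal STRs + amelogenin, with the
    named flanking/repeat variants that affect CE designation or QC."""
    data = resources.files("strseqdb").joinpath("data/default_catalog.json").read_text("utf-8")
    return Catalog.model_validate(json.loads(data))
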