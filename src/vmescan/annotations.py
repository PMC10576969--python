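"""Read, validate and write per-image benthic annotation tables.

One record per seafloor image: survey metadata (laboratory, site, depth,
imaged area, % hard substrate, camera), integer counts per VME indicator
taxon, an optional expert Yes/Maybe/No judgment of whether the image shows a
VME, and optional boolean evidence flags (reef present, chemosynthetic taxa,
large/old individual, visible nursery role, threatened taxon).

Missing depth or substrate is tolerated (the covariate regressions drop such
records); a missing or non-positive imaged area is fatal because densities
are undefined without it.  Counts are strict integers — percent-cover
annotation is out of scope.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

__all__ = [
    "EvidenceFlags",
    "ImageAnnotation",
    "AnnotationDataset",
    "SchemaConfig",
    "Violation",
    "AnnotationError",
    "read_annotations",
    "write_annotations",
    "validate",
    "normalize_label",
]

LABELS = ("Yes", "Maybe", "No")

_LABEL_ALIASES = {
    "y": "Yes", "yes": "Yes",
    "m": "Maybe", "maybe": "Maybe",
    "n": "No", "no": "No",
}

FLAG_FIELDS = (
    "reef_present",
    "chemo_present",
    "large_old_present",
    "functional_role_visible",
    "threatened_present",
)

#: Canonical metadata column order for files written by this package.
METADATA_COLUMNS = (
    "image_id",
    "laboratory",
    "site",
    "region",
    "depth_m",
    "area_m2",
    "pct_hard_substrate",
    "camera",
    "label",
) + FLAG_FIELDS


class AnnotationError(ValueError):
    """Raised on malformed annotation files; names the offending row/column."""


def normalize_label(token: Optional[str]) -> Optional[str]:
    """Map y/yes/m/maybe/n/no (any case) to Yes/Maybe/No; reject the rest."""
    if token is None:
        return None
    stripped = token.strip()
    if stripped == "":
        return None
    try:
        return _LABEL_ALIASES[stripped.lower()]
    except KeyError:
        raise AnnotationError(f"unknown label token {token!r}") from None


@dataclass(frozen=True)
class EvidenceFlags:
    """Annotator-supplied visual evidence used by the decision flow chart.

    These are expert judgments (reef — live or dead scleractinian or sponge
    reef; chemosynthetic community taxa; an individual large enough to likely
    be >100 years old; a visible nursery/spawning/egg-attachment role; a
    threatened species), not quantities computable from a count table.
    """

    reef_present: bool = False
    chemo_present: bool = False
    large_old_present: bool = False
    functional_role_visible: bool = False
    threatened_present: bool = False

    def any(self) -> bool:
        return any(getattr(self, f) for f in FLAG_FIELDS)


@dataclass(frozen=True)
class ImageAnnotation:
    image_id: str
    area_m2: float
    counts: dict[str, int] = field(default_factory=dict)
    laboratory: str = ""
    site: str = ""
    region: Optional[str] = None
    depth_m: Optional[float] = None
    pct_hard_substrate: Optional[float] = None
    camera: Optional[str] = None
    label: Optional[str] = None
    flags: EvidenceFlags = field(default_factory=EvidenceFlags)


@dataclass
class AnnotationDataset:
    """An ordered collection of image annotations sharing taxon columns."""

    records: list[ImageAnnotation]
    taxon_columns: list[str]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationDataset):
            return NotImplemented
        return (
            self.taxon_columns == other.taxon_columns
            and self.records == other.records
        )


@dataclass
class SchemaConfig:
    """Maps source-file columns onto canonical fields.

    ``columns`` maps canonical metadata field -> source column name (fields
    not mapped default to their canonical name).  ``taxon_columns``, when
    given, names the count columns explicitly; otherwise every column not
    claimed by the metadata mapping is treated as a taxon count column.
    """

    columns: dict[str, str] = field(default_factory=dict)
    taxon_columns: Optional[list[str]] = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SchemaConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        columns = dict(raw.get("columns", {}))
        unknown = set(columns) - set(METADATA_COLUMNS)
        if unknown:
            raise AnnotationError(f"schema maps unknown fields: {sorted(unknown)}")
        taxa = raw.get("taxon_columns")
        return cls(columns=columns, taxon_columns=list(taxa) if taxa else None)

    def source_name(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def _parse_float(text: str, *, row: str, col: str, required: bool) -> Optional[float]:
    text = text.strip()
    if text == "":
        if required:
            raise AnnotationError(f"row {row}: column {col!r} is required")
        return None
    try:
        value = float(text)
    except ValueError:
        raise AnnotationError(f"row {row}: non-numeric {col!r} value {text!r}") from None
    if math.isnan(value):
        return None if not required else _fail_nan(row, col)
    return value


def _fail_nan(row: str, col: str):
    raise AnnotationError(f"row {row}: column {col!r} is NaN")


def _parse_count(text: str, *, row: str, col: str) -> int:
    text = text.strip()
    if text == "":
        return 0
    try:
        value = float(text)
    except ValueError:
        raise AnnotationError(f"row {row}: non-numeric count in {col!r}: {text!r}") from None
    if value < 0 or value != int(value):
        raise AnnotationError(
            f"row {row}: count in {col!r} must be a non-negative integer, got {text!r}"
        )
    return int(value)


def _parse_bool(text: str, *, row: str, col: str) -> bool:
    text = text.strip().lower()
    if text in {"", "0", "false", "no", "f"}:
        return False
    if text in {"1", "true", "yes", "t"}:
        return True
    raise AnnotationError(f"row {row}: column {col!r} is not boolean: {text!r}")


def _sniff_delimiter(sample: str) -> str:
    # The deposited supplement's dialect is unknown a priori; auto-detect
    # between comma and tab from the header line.
    header = sample.splitlines()[0] if sample else ""
    return "\t" if header.count("\t") > header.count(",") else ","


def read_annotations(
    path: Union[str, Path],
    schema: Optional[SchemaConfig] = None,
) -> AnnotationDataset:
    """Read a delimited annotation table (CSV or TSV, auto-detected).

    Lines starting with ``#`` (provenance headers) are skipped.  Raises
    :class:`AnnotationError` naming the row and column for non-positive
    areas, fractional or negative counts, and unknown label tokens.
    """
    schema = schema or SchemaConfig()
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    if not lines:
        raise AnnotationError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter=delim)
    header = reader.fieldnames or []

    src = {f: schema.source_name(f) for f in METADATA_COLUMNS}
    id_col = src["image_id"]
    area_col = src["area_m2"]
    for needed in (id_col, area_col):
        if needed not in header:
            raise AnnotationError(f"{path}: missing required column {needed!r}")
    meta_cols = {c for c in src.values() if c in header}
    if schema.taxon_columns is not None:
        taxa = list(schema.taxon_columns)
        missing = [t for t in taxa if t not in header]
        if missing:
            raise AnnotationError(f"{path}: missing taxon columns {missing}")
    else:
        taxa = [c for c in header if c not in meta_cols]

    records: list[ImageAnnotation] = []
    for row in reader:
        rid = (row.get(id_col) or "").strip() or f"#{reader.line_num}"
        area = _parse_float(row.get(area_col, ""), row=rid, col=area_col, required=True)
        if area is None or area <= 0:
            raise AnnotationError(f"row {rid}: area_m2 must be > 0, got {row.get(area_col)!r}")
        counts = {t: _parse_count(row.get(t, ""), row=rid, col=t) for t in taxa}
        flags = EvidenceFlags(**{
            f: _parse_bool(row.get(src[f], ""), row=rid, col=src[f])
            if src[f] in header else False
            for f in FLAG_FIELDS
        })
        try:
            label = normalize_label(row.get(src["label"])) if src["label"] in header else None
        except AnnotationError as exc:
            raise AnnotationError(f"row {rid}: {exc}") from None
        records.append(ImageAnnotation(
            image_id=rid,
            laboratory=(row.get(src["laboratory"]) or "").strip(),
            site=(row.get(src["site"]) or "").strip(),
            region=(row.get(src["region"]) or "").strip() or None,
            depth_m=_parse_float(row.get(src["depth_m"], ""), row=rid,
                                 col=src["depth_m"], required=False),
            area_m2=area,
            pct_hard_substrate=_parse_float(
                row.get(src["pct_hard_substrate"], ""), row=rid,
                col=src["pct_hard_substrate"], required=False),
            camera=(row.get(src["camera"]) or "").strip() or None,
            counts=counts,
            label=label,
            flags=flags,
        ))
    return AnnotationDataset(records=records, taxon_columns=sorted(taxa))


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_annotations(dataset: AnnotationDataset, path: Union[str, Path]) -> None:
    """Write a dataset as CSV: metadata columns then taxa alphabetically.

    Output is deterministic — two writes of the same dataset are
    byte-identical, and ``read_annotations`` inverts it exactly.
    """
    taxa = sorted(dataset.taxon_columns)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(list(METADATA_COLUMNS) + taxa)
        for rec in dataset.records:
            writer.writerow(
                [_fmt(getattr(rec, f)) for f in METADATA_COLUMNS[:9]]
                + [_fmt(getattr(rec.flags, f)) for f in FLAG_FIELDS]
                + [_fmt(rec.counts.get(t, 0)) for t in taxa]
            )


@dataclass(frozen=True)
class Violation:
    image_id: str
    field: str
    rule: str

    def __str__(self) -> str:
        return f"[{self.image_id}] {self.field}: {self.rule}"


def validate(dataset: AnnotationDataset) -> list[Violation]:
    """Check dataset invariants; an empty list means all hold."""
    out: list[Violation] = []
    seen: set[str] = set()
    for rec in dataset.records:
        if rec.image_id in seen:
            out.append(Violation(rec.image_id, "image_id", "duplicate image_id"))
        seen.add(rec.image_id)
        if not rec.image_id:
            out.append(Violation(rec.image_id, "image_id", "empty image_id"))
        if not (rec.area_m2 > 0):
            out.append(Violation(rec.image_id, "area_m2", "must be > 0"))
        if rec.depth_m is not None and rec.depth_m < 0:
            out.append(Violation(rec.image_id, "depth_m", "must be >= 0"))
        if rec.pct_hard_substrate is not None and not (0 <= rec.pct_hard_substrate <= 100):
            out.append(Violation(rec.image_id, "pct_hard_substrate", "must be in [0, 100]"))
        if rec.label is not None and rec.label not in LABELS:
            out.append(Violation(rec.image_id, "label", f"unknown label {rec.label!r}"))
        for taxon, count in rec.counts.items():
            if not isinstance(count, int) or count < 0:
                out.append(Violation(rec.image_id, taxon,
                                     "count must be a non-negative integer"))
        extra = set(rec.counts) - set(dataset.taxon_columns)
        if extra:
            out.append(Violation(rec.image_id, "counts",
                                 f"taxa outside taxon_columns: {sorted(extra)}"))
    return out
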