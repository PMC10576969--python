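"""Counts to per-area densities and richness, with the small-image filter.

Analyses run on individuals per m² (count / imaged area) and on VME-taxon
richness per image.  Images smaller than the minimum area (default 1 m²) are
removed before any density work to avoid extrapolating densities from tiny
fields of view; the filter removes areas *strictly below* the threshold.

Only taxa that resolve to registry rows and are indicators under the chosen
body (or cross-region consensus) and policy contribute to the per-image
totals; unresolvable annotation labels are reported, not silently dropped.
Feature rows never carry counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd

from .annotations import AnnotationDataset, ImageAnnotation
from .registry import IndicatorRegistry, TaxonGroup

__all__ = [
    "DensityRecord",
    "DensityTable",
    "filter_by_area",
    "compute_densities",
    "group_density",
    "indicator_set",
]

#: Numerical tolerance for the invariant total == sum of per-taxon densities.
SUM_TOL = 1e-9

CONSENSUS_MODES = ("union", "intersection")


@dataclass(frozen=True)
class DensityRecord:
    image_id: str
    area_m2: float
    densities: dict[str, float]          # canonical taxon -> individuals / m²
    total_density: float                 # individuals / m², all indicator taxa
    richness: int                        # distinct indicator taxa present
    richness_density: float              # taxa / m²
    label: Optional[str] = None
    depth_m: Optional[float] = None
    pct_hard_substrate: Optional[float] = None
    site: str = ""


@dataclass
class DensityTable:
    records: list[DensityRecord]
    n_input: int
    n_removed: int
    min_area_m2: float
    body: str = "union"
    policy: str = "qualified_counts"
    unresolved_taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_input != len(self.records) + self.n_removed:
            raise ValueError("filter provenance counts do not sum")

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per image, one column per indicator-taxon density."""
        taxa = sorted({t for r in self.records for t in r.densities})
        rows = []
        for r in self.records:
            row = {
                "image_id": r.image_id,
                "site": r.site,
                "label": r.label,
                "area_m2": r.area_m2,
                "depth_m": r.depth_m,
                "pct_hard_substrate": r.pct_hard_substrate,
                "richness": r.richness,
                "richness_per_m2": r.richness_density,
                "total_density": r.total_density,
            }
            row.update({f"d_{t}": r.densities.get(t, 0.0) for t in taxa})
            rows.append(row)
        return pd.DataFrame(rows)


def filter_by_area(
    dataset: AnnotationDataset, min_area_m2: float = 1.0
) -> tuple[AnnotationDataset, int]:
    """Drop records with imaged area strictly below ``min_area_m2``."""
    if min_area_m2 < 0:
        raise ValueError(f"min_area_m2 must be >= 0, got {min_area_m2}")
    kept = [r for r in dataset.records if r.area_m2 >= min_area_m2]
    removed = len(dataset.records) - len(kept)
    return AnnotationDataset(records=kept, taxon_columns=list(dataset.taxon_columns)), removed


def indicator_set(
    registry: IndicatorRegistry, body: str = "union", policy: str = "qualified_counts"
) -> set[str]:
    """Canonical countable indicator taxa for a body or consensus mode."""
    if body in CONSENSUS_MODES:
        taxa = registry.consensus_list(mode=body, policy=policy)
    else:
        taxa = registry.indicator_taxa(body, policy)
    features = set(registry.group_members(TaxonGroup.FEATURE))
    return set(taxa) - features


def _image_densities(
    ann: ImageAnnotation,
    resolution: dict[str, Optional[str]],
    indicators: set[str],
) -> DensityRecord:
    dens: dict[str, float] = {}
    for taxon, count in ann.counts.items():
        canonical = resolution[taxon]
        if canonical is None or canonical not in indicators:
            continue
        dens[canonical] = dens.get(canonical, 0.0) + count / ann.area_m2
    total = sum(dens.values())
    richness = sum(1 for v in dens.values() if v > 0)
    return DensityRecord(
        image_id=ann.image_id,
        area_m2=ann.area_m2,
        densities=dens,
        total_density=total,
        richness=richness,
        richness_density=richness / ann.area_m2,
        label=ann.label,
        depth_m=ann.depth_m,
        pct_hard_substrate=ann.pct_hard_substrate,
        site=ann.site,
    )


def compute_densities(
    dataset: AnnotationDataset,
    registry: IndicatorRegistry,
    body: str = "union",
    policy: str = "qualified_counts",
    min_area_m2: float = 1.0,
    apply_area_filter: bool = True,
) -> DensityTable:
    """Per-image indicator densities and richness for a whole dataset.

    ``body`` is a management-body identifier or a consensus mode
    (``union`` — the default, counting taxa listed by any body — or
    ``intersection``).
    """
    n_input = len(dataset.records)
    if apply_area_filter:
        dataset, removed = filter_by_area(dataset, min_area_m2)
    else:
        removed = 0
    indicators = indicator_set(registry, body, policy)
    resolution = {t: registry.resolve(t) for t in dataset.taxon_columns}
    unresolved = tuple(sorted(t for t, c in resolution.items() if c is None))
    records = [_image_densities(a, resolution, indicators) for a in dataset.records]
    return DensityTable(
        records=records,
        n_input=n_input,
        n_removed=removed,
        min_area_m2=min_area_m2 if apply_area_filter else 0.0,
        body=body,
        policy=policy,
        unresolved_taxa=unresolved,
    )


def group_density(
    table: DensityTable,
    taxon_group: Union[str, TaxonGroup],
    registry: IndicatorRegistry,
) -> pd.DataFrame:
    """Per-image summed density over a registry group or a single taxon.

    Returns a frame with image_id, label and density (individuals / m²).
    Passing the pseudo-group ``"all"`` reproduces the overall density.
    """
    if taxon_group == "all":
        members = None
    elif isinstance(taxon_group, TaxonGroup) or taxon_group in {g.value for g in TaxonGroup}:
        members = set(registry.group_members(taxon_group))
    else:
        canonical = registry.resolve(str(taxon_group))
        if canonical is None:
            raise KeyError(f"unknown taxon or group {taxon_group!r}")
        members = {canonical}
    rows = []
    for r in table.records:
        if members is None:
            value = r.total_density
        else:
            value = sum(v for t, v in r.densities.items() if t in members)
        rows.append({"image_id": r.image_id, "label": r.label, "density": value})
    return pd.DataFrame(rows, columns=["image_id", "label", "density"])
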