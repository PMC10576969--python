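"""Single-image VME decision procedure as a short-circuiting rule engine.

The procedure asks an ordered sequence of questions about one image.  Step 0
checks for any evidence at all (an indicator taxon counted, or any annotator
evidence flag); merely detecting an element is not sufficient, so a positive
step 0 only allows the later steps to run.  Steps 1–5 are expert visual
judgments carried by evidence flags (reef — live or dead; chemosynthetic
community; large/old individual; visible functional role such as a nursery;
threatened taxon).  Steps 6–8 are quantitative: indicator-taxon richness,
the densest monotypic stand against its per-taxon threshold, and the
combined indicator density.  The first positive step wins and attaches the
FAO criteria it invokes; if no step fires the image is not, on its own,
evidence of a VME and more images from the site should be evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import yaml

from .annotations import AnnotationDataset, EvidenceFlags, ImageAnnotation
from .registry import IndicatorRegistry
from .densities import indicator_set

__all__ = [
    "Decision",
    "Step",
    "FaoCriterion",
    "ThresholdConfig",
    "FlowchartResult",
    "ClassificationSummary",
    "classify_image",
    "classify_dataset",
    "DEFAULT_THRESHOLDS",
]


class Decision(str, Enum):
    VME = "VME"
    NOT_VME_THIS_IMAGE = "NOT_VME_THIS_IMAGE"
    NO_EVIDENCE_EVALUATE_MORE = "NO_EVIDENCE_EVALUATE_MORE"


class Step(str, Enum):
    INDICATOR_CHECK = "indicator_check"
    REEF = "reef"
    CHEMOSYNTHETIC = "chemosynthetic"
    LARGE_OLD = "large_old"
    FUNCTIONAL_ROLE = "functional_role"
    THREATENED = "threatened"
    RICHNESS_THRESHOLD = "richness_threshold"
    MONOTYPIC_DENSITY = "monotypic_density"
    COMBINED_DENSITY = "combined_density"
    NONE = "none"


class FaoCriterion(str, Enum):
    UNIQUENESS_RARITY = "uniqueness_rarity"
    FUNCTIONAL_SIGNIFICANCE = "functional_significance"
    FRAGILITY = "fragility"
    LIFE_HISTORY = "life_history"
    STRUCTURAL_COMPLEXITY = "structural_complexity"


ALL_CRITERIA = frozenset(FaoCriterion)

#: FAO criteria attached to each positive step.
STEP_CRITERIA: dict[Step, frozenset[FaoCriterion]] = {
    Step.REEF: ALL_CRITERIA,
    Step.CHEMOSYNTHETIC: frozenset({
        FaoCriterion.UNIQUENESS_RARITY,
        FaoCriterion.FUNCTIONAL_SIGNIFICANCE,
        FaoCriterion.FRAGILITY,
        FaoCriterion.LIFE_HISTORY,
    }),
    Step.LARGE_OLD: frozenset({
        FaoCriterion.UNIQUENESS_RARITY,
        FaoCriterion.FUNCTIONAL_SIGNIFICANCE,
        FaoCriterion.FRAGILITY,
    }),
    Step.FUNCTIONAL_ROLE: frozenset({FaoCriterion.FUNCTIONAL_SIGNIFICANCE}),
    Step.THREATENED: frozenset({
        FaoCriterion.UNIQUENESS_RARITY,
        FaoCriterion.FUNCTIONAL_SIGNIFICANCE,
    }),
    Step.RICHNESS_THRESHOLD: frozenset({FaoCriterion.STRUCTURAL_COMPLEXITY}),
    Step.MONOTYPIC_DENSITY: frozenset({FaoCriterion.STRUCTURAL_COMPLEXITY}),
    Step.COMBINED_DENSITY: frozenset({FaoCriterion.STRUCTURAL_COMPLEXITY}),
}

_FLAG_STEPS: tuple[tuple[str, Step], ...] = (
    ("reef_present", Step.REEF),
    ("chemo_present", Step.CHEMOSYNTHETIC),
    ("large_old_present", Step.LARGE_OLD),
    ("functional_role_visible", Step.FUNCTIONAL_ROLE),
    ("threatened_present", Step.THREATENED),
)

GUIDANCE_NO_EVIDENCE = (
    "The image does not have evidence of a VME; more images from the site "
    "need to be evaluated."
)
GUIDANCE_NOT_VME = (
    "This single image does not depict a VME; to be certain about the "
    "implied absence of VMEs in the area, more images should be evaluated."
)


class ThresholdError(ValueError):
    """Raised on invalid or incomplete threshold configuration."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Quantitative thresholds for the last three steps.

    tau_S — distinct indicator taxa; tau_d — per-taxon density thresholds
    (individuals / m²) for monotypic stands; tau_D — combined indicator
    density (individuals / m²).  The packaged defaults are midpoints of the
    calibration study's Yes/No group means — placeholders derived from
    expert labels, meant to be overridden as better evidence accrues, not
    settled dogma.  ``richness_metric`` selects raw taxon count (default)
    or taxa per m² for step 6.
    """

    tau_S: float = 3
    tau_d: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_TAU_D))
    tau_D: float = 4.16
    richness_metric: str = "count"  # "count" or "per_area"

    def __post_init__(self) -> None:
        if not self.tau_S > 0:
            raise ThresholdError(f"tau_S must be > 0, got {self.tau_S}")
        if not self.tau_D > 0:
            raise ThresholdError(f"tau_D must be > 0, got {self.tau_D}")
        for taxon, value in self.tau_d.items():
            if not value > 0:
                raise ThresholdError(f"tau_d[{taxon}] must be > 0, got {value}")
        if self.richness_metric not in {"count", "per_area"}:
            raise ThresholdError(
                f"richness_metric must be 'count' or 'per_area', got {self.richness_metric!r}"
            )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ThresholdConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for required in ("tau_S", "tau_d", "tau_D"):
            if required not in raw:
                raise ThresholdError(f"thresholds file {path}: missing field {required!r}")
        return cls(
            tau_S=raw["tau_S"],
            tau_d=dict(raw["tau_d"]),
            tau_D=raw["tau_D"],
            richness_metric=raw.get("richness_metric", "count"),
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "tau_S": self.tau_S,
                    "tau_d": dict(sorted(self.tau_d.items())),
                    "tau_D": self.tau_D,
                    "richness_metric": self.richness_metric,
                },
                fh,
                sort_keys=False,
            )


_DEFAULT_TAU_D = {
    "Alcyonacea": 0.88,     # midpoint of Yes 1.47 / No 0.29 individuals/m²
    "Scleractinia": 2.035,  # midpoint of Yes 3.59 / No 0.48
    "Porifera": 0.935,      # midpoint of Yes 1.29 / No 0.58
}

DEFAULT_THRESHOLDS = ThresholdConfig()


@dataclass(frozen=True)
class FlowchartResult:
    image_id: str
    decision: Decision
    step_fired: Step
    fao_criteria: frozenset[FaoCriterion]
    richness: int
    combined_density: float
    max_density: float
    max_density_taxon: Optional[str]
    guidance: Optional[str] = None

    def __post_init__(self) -> None:
        is_vme = self.step_fired not in (Step.INDICATOR_CHECK, Step.NONE)
        assert (self.decision is Decision.VME) == is_vme
        assert (self.decision is Decision.VME) == bool(self.fao_criteria)


def classify_image(
    annotation: ImageAnnotation,
    registry: IndicatorRegistry,
    body: str = "union",
    policy: str = "qualified_counts",
    thresholds: ThresholdConfig = DEFAULT_THRESHOLDS,
    _indicators: Optional[set[str]] = None,
) -> FlowchartResult:
    """Run the decision procedure on one annotated image.

    Stateless and short-circuiting: the first positive step decides, and
    later inputs cannot change the outcome.  Raises :class:`ThresholdError`
    if a counted taxon carries a per-taxon threshold but cannot be resolved
    in the registry.
    """
    indicators = (
        _indicators if _indicators is not None
        else indicator_set(registry, body, policy)
    )

    densities: dict[str, float] = {}
    for taxon, count in annotation.counts.items():
        canonical = registry.resolve(taxon)
        if canonical is None:
            if taxon in thresholds.tau_d:
                raise ThresholdError(
                    f"taxon {taxon!r} has a tau_d threshold but is not "
                    "resolvable in the registry"
                )
            continue
        if canonical in indicators:
            densities[canonical] = densities.get(canonical, 0.0) + count / annotation.area_m2
    for taxon in thresholds.tau_d:
        if registry.resolve(taxon) is None:
            raise ThresholdError(
                f"tau_d key {taxon!r} is not resolvable in the registry"
            )

    richness = sum(1 for v in densities.values() if v > 0)
    combined = sum(densities.values())
    max_taxon, max_d = None, 0.0
    for taxon, d in sorted(densities.items()):
        if d > max_d:
            max_taxon, max_d = taxon, d

    def result(decision: Decision, step: Step, guidance: Optional[str] = None):
        return FlowchartResult(
            image_id=annotation.image_id,
            decision=decision,
            step_fired=step,
            fao_criteria=STEP_CRITERIA.get(step, frozenset()),
            richness=richness,
            combined_density=combined,
            max_density=max_d,
            max_density_taxon=max_taxon,
            guidance=guidance,
        )

    # Step 0 — element detection: any indicator counted or any flag raised.
    # A raised flag satisfies this even with zero counts (a reef image may
    # contain no countable colonies).
    if richness == 0 and not annotation.flags.any():
        return result(Decision.NO_EVIDENCE_EVALUATE_MORE, Step.INDICATOR_CHECK,
                      GUIDANCE_NO_EVIDENCE)

    # Steps 1–5 — annotator evidence flags, in fixed order.
    for flag_name, step in _FLAG_STEPS:
        if getattr(annotation.flags, flag_name):
            return result(Decision.VME, step)

    # Step 6 — threshold number of distinct indicator taxa.
    richness_value = (
        richness if thresholds.richness_metric == "count"
        else richness / annotation.area_m2
    )
    if richness_value >= thresholds.tau_S:
        return result(Decision.VME, Step.RICHNESS_THRESHOLD)

    # Step 7 — monotypic stand at or above its per-taxon density threshold.
    for taxon in sorted(thresholds.tau_d):
        canonical = registry.resolve(taxon)
        if densities.get(canonical, 0.0) >= thresholds.tau_d[taxon]:
            return result(Decision.VME, Step.MONOTYPIC_DENSITY)

    # Step 8 — combined density of all indicator taxa.
    if combined >= thresholds.tau_D:
        return result(Decision.VME, Step.COMBINED_DENSITY)

    return result(Decision.NOT_VME_THIS_IMAGE, Step.NONE, GUIDANCE_NOT_VME)


@dataclass
class ClassificationSummary:
    results: list[FlowchartResult]
    by_decision: dict[str, int]
    by_step: dict[str, int]

    def to_dataframe(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "image_id": r.image_id,
                "decision": r.decision.value,
                "step_fired": r.step_fired.value,
                "fao_criteria": ";".join(sorted(c.value for c in r.fao_criteria)),
                "richness": r.richness,
                "combined_density": r.combined_density,
                "max_density": r.max_density,
                "max_density_taxon": r.max_density_taxon,
            }
            for r in self.results
        )


def classify_dataset(
    dataset: AnnotationDataset,
    registry: IndicatorRegistry,
    body: str = "union",
    policy: str = "qualified_counts",
    thresholds: ThresholdConfig = DEFAULT_THRESHOLDS,
) -> ClassificationSummary:
    """Classify every image, order-preserving, with summary counts."""
    indicators = indicator_set(registry, body, policy)
    results = []
    for ann in dataset.records:
        try:
            results.append(
                classify_image(ann, registry, body, policy, thresholds,
                               _indicators=indicators)
            )
        except ThresholdError as exc:
            raise ThresholdError(f"image {ann.image_id}: {exc}") from exc
    by_decision: dict[str, int] = {}
    by_step: dict[str, int] = {}
    for r in results:
        by_decision[r.decision.value] = by_decision.get(r.decision.value, 0) + 1
        by_step[r.step_fired.value] = by_step.get(r.step_fired.value, 0) + 1
    return ClassificationSummary(results=results, by_decision=by_decision, by_step=by_step)
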