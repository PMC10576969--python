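"""Machine-readable registry of VME indicator taxa by management body.

Each Regional Fisheries Management Organization/Arrangement (RFMO/A) keeps
its own list of taxa whose presence flags a possible Vulnerable Marine
Ecosystem (VME).  The lists disagree: a taxon may be a full indicator in one
region, excluded in another, and a *qualified* indicator elsewhere (only a
restricted sub-taxon counts, e.g. "only Cerianthidae", or only stalked
crinoids).  This module encodes those per-body statuses, resolves free-text
annotation labels onto registry rows (synonyms, case folding, and an upward
walk of a small taxonomic hierarchy), and computes cross-region consensus
lists (union / intersection / at-least-k bodies).

Octocoral taxonomy predates the 2022 revision (Alcyonacea is kept as an
order, with Gorgonacea as a synonym) because the management bodies have not
adopted the revision; the synonym table is the extension point.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

__all__ = [
    "BODIES",
    "Rank",
    "TaxonGroup",
    "Status",
    "TaxonEntry",
    "IndicatorStatus",
    "IndicatorRegistry",
    "RegistryError",
    "load_registry",
]

#: Fixed management-body identifiers (stable keys for config files).
#: "NAFO ABNJ" is encoded as NAFO_ABNJ.
BODIES: tuple[str, ...] = (
    "NPFC",
    "SPRFMO",
    "NEAFC",
    "NAFO_ABNJ",
    "CCAMLR",
    "SEAFO",
    "GFCM",
    "SIOFA",
)


class Rank(str, Enum):
    PHYLUM = "phylum"
    CLASS = "class"
    SUBCLASS = "subclass"
    ORDER = "order"
    SUBORDER = "suborder"
    FAMILY = "family"
    GENUS = "genus"
    SPECIES = "species"


class TaxonGroup(str, Enum):
    CNIDARIA = "Cnidaria"
    ECHINODERMATA = "Echinodermata"
    OTHER_TAXA = "OtherTaxa"
    FEATURE = "Feature"


class Status(str, Enum):
    INDICATOR = "indicator"
    NOT_INDICATOR = "not_indicator"
    QUALIFIED = "qualified"


class RegistryError(ValueError):
    """Raised on malformed registry or synonym files."""


@dataclass(frozen=True)
class TaxonEntry:
    """One registry row: a qualifying taxon or feature.

    ``rank`` is None only for Feature rows ("Seamounts as a whole"), which
    have no taxonomic rank and never take part in count-based density
    operations.
    """

    name: str
    rank: Optional[Rank]
    group: TaxonGroup
    parent: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise RegistryError("taxon name must be non-empty")
        if self.rank is None and self.group is not TaxonGroup.FEATURE:
            raise RegistryError(f"taxon {self.name!r}: rank required for non-feature rows")


@dataclass(frozen=True)
class IndicatorStatus:
    """Indicator status of one (taxon, body) cell.

    ``subtaxa`` holds the machine-readable restricted sub-taxa of a qualified
    cell; ``note`` preserves verbatim restrictions that are ambiguous between
    restriction and synonymy (those are flagged, never silently interpreted).
    """

    status: Status
    subtaxa: tuple[str, ...] = ()
    note: Optional[str] = None

    def __post_init__(self) -> None:
        has_qualifier = bool(self.subtaxa) or self.note is not None
        if (self.status is Status.QUALIFIED) != has_qualifier:
            raise RegistryError(
                "qualifier present iff status is qualified "
                f"(status={self.status.value}, subtaxa={self.subtaxa}, note={self.note})"
            )


def _parse_status_token(token: str, *, taxon: str, body: str) -> IndicatorStatus:
    token = token.strip()
    low = token.lower()
    if low == "yes":
        return IndicatorStatus(Status.INDICATOR)
    if low == "no":
        return IndicatorStatus(Status.NOT_INDICATOR)
    if low.startswith("qualified:"):
        payload = token.split(":", 1)[1]
        if payload.startswith("note="):
            return IndicatorStatus(Status.QUALIFIED, note=payload[len("note="):].strip())
        subtaxa = tuple(s.strip() for s in payload.split(";") if s.strip())
        if not subtaxa:
            raise RegistryError(f"empty qualifier in cell ({taxon}, {body})")
        return IndicatorStatus(Status.QUALIFIED, subtaxa=subtaxa)
    raise RegistryError(f"unrecognized status token {token!r} in cell ({taxon}, {body})")


@dataclass
class IndicatorRegistry:
    """(taxon, body) -> indicator status, with rank-aware label resolution."""

    taxa: dict[str, TaxonEntry]
    entries: dict[tuple[str, str], IndicatorStatus]
    synonyms: dict[str, str] = field(default_factory=dict)
    hierarchy: dict[str, str] = field(default_factory=dict)
    bodies: tuple[str, ...] = BODIES

    def __post_init__(self) -> None:
        self._resolve_cache: dict[str, Optional[str]] = {}
        self._name_index = {name.casefold(): name for name in self.taxa}
        self._syn_index = {a.casefold(): c for a, c in self.synonyms.items()}
        self._hier_index = {c.casefold(): p for c, p in self.hierarchy.items()}

    # -- lookup ---------------------------------------------------------

    def lookup(self, taxon: str, body: str) -> IndicatorStatus:
        """Status of a registry taxon under one body; KeyError if absent."""
        self._check_body(body)
        canonical = self.resolve(taxon)
        if canonical is None:
            raise KeyError(f"unknown taxon {taxon!r}")
        return self.entries[(canonical, body)]

    def is_indicator(
        self, taxon: str, body: str, policy: str = "qualified_counts"
    ) -> Optional[bool]:
        """Whether ``taxon`` is a VME indicator for ``body``.

        Under ``strict`` only full indicators count; under
        ``qualified_counts`` (default) qualified entries count too, because
        the cross-region consensus statements treat "members ... considered
        VME indicators" as membership.  Returns None (not False) for taxa
        that cannot be resolved to a registry row.
        """
        self._check_policy(policy)
        self._check_body(body)
        canonical = self.resolve(taxon)
        if canonical is None:
            return None
        status = self.entries[(canonical, body)].status
        if status is Status.INDICATOR:
            return True
        if status is Status.QUALIFIED:
            return policy == "qualified_counts"
        return False

    def indicator_taxa(self, body: str, policy: str = "qualified_counts") -> list[str]:
        """Sorted taxa that are indicators for one body."""
        return sorted(
            name for name in self.taxa if self.is_indicator(name, body, policy)
        )

    def consensus_list(
        self,
        mode: str = "intersection",
        k: Optional[int] = None,
        policy: str = "qualified_counts",
    ) -> list[str]:
        """Taxa that are indicators across bodies.

        ``union``: indicator anywhere; ``intersection``: indicator in every
        body; ``at_least_k``: indicator in >= k bodies (k=1 equals union).
        """
        if mode not in {"union", "intersection", "at_least_k"}:
            raise ValueError(f"unknown consensus mode {mode!r}")
        if mode == "at_least_k":
            if k is None or not 1 <= k <= len(self.bodies):
                raise ValueError(f"k must be in [1, {len(self.bodies)}], got {k}")
            need = k
        elif mode == "union":
            need = 1
        else:
            need = len(self.bodies)
        out = []
        for name in self.taxa:
            n_yes = sum(
                1 for b in self.bodies if self.is_indicator(name, b, policy)
            )
            if n_yes >= need:
                out.append(name)
        return sorted(out)

    # -- label resolution ----------------------------------------------

    def resolve(self, label: str) -> Optional[str]:
        """Canonical registry taxon for a free-text annotation label.

        Case-insensitive, strips whitespace, applies the synonym table, then
        walks the taxonomic hierarchy upward until a registry row is hit.
        Unknown labels yield None (a value, not an exception); resolution is
        idempotent.
        """
        key = " ".join(label.split()).casefold()
        if key in self._resolve_cache:
            return self._resolve_cache[key]
        result = self._resolve_uncached(key)
        self._resolve_cache[key] = result
        return result

    def _resolve_uncached(self, key: str, _depth: int = 0) -> Optional[str]:
        if _depth > 32:  # defensive: cyclic synonym/hierarchy data
            return None
        if key in self._name_index:
            return self._name_index[key]
        if key in self._syn_index:
            return self._resolve_uncached(self._syn_index[key].casefold(), _depth + 1)
        if key in self._hier_index:
            return self._resolve_uncached(self._hier_index[key].casefold(), _depth + 1)
        return None

    def group_members(self, group: Union[str, TaxonGroup]) -> list[str]:
        group = TaxonGroup(group)
        return sorted(n for n, e in self.taxa.items() if e.group is group)

    def countable_taxa(self) -> list[str]:
        """Registry taxa that participate in count-based density operations
        (Feature rows are excluded)."""
        return sorted(
            n for n, e in self.taxa.items() if e.group is not TaxonGroup.FEATURE
        )

    # -- internal -------------------------------------------------------

    def _check_body(self, body: str) -> None:
        if body not in self.bodies:
            raise KeyError(f"unknown management body {body!r}; known: {self.bodies}")

    @staticmethod
    def _check_policy(policy: str) -> None:
        if policy not in {"strict", "qualified_counts"}:
            raise ValueError(f"unknown policy {policy!r}")


def _read_two_column_csv(path, col_a: str, col_b: str) -> dict[str, str]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != {col_a, col_b}:
            raise RegistryError(
                f"{path}: expected columns [{col_a},{col_b}], got {reader.fieldnames}"
            )
        return {row[col_a].strip(): row[col_b].strip() for row in reader}


def _default_data_path(name: str) -> Path:
    return Path(str(resources.files("vmescan").joinpath("data", name)))


def load_registry(
    source: Optional[Union[str, Path]] = None,
    synonyms: Optional[Union[str, Path]] = None,
    hierarchy: Optional[Union[str, Path]] = None,
) -> IndicatorRegistry:
    """Load an indicator registry from CSV (packaged default if no path).

    The registry file has columns ``taxon,rank,group,parent`` followed by one
    column per management body holding ``yes``, ``no`` or
    ``qualified:<subtaxa;...>`` / ``qualified:note=<verbatim>``.
    """
    if source is None:
        source = _default_data_path("vme_indicator_registry.csv")
        if synonyms is None:
            synonyms = _default_data_path("synonyms.csv")
        if hierarchy is None:
            hierarchy = _default_data_path("hierarchy.csv")

    with open(source, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [b for b in BODIES if b not in header]
        if missing:
            raise RegistryError(f"{source}: missing body columns {missing}")
        taxa: dict[str, TaxonEntry] = {}
        entries: dict[tuple[str, str], IndicatorStatus] = {}
        for row in reader:
            name = row["taxon"].strip()
            if name in taxa:
                raise RegistryError(f"{source}: duplicate taxon row {name!r}")
            rank = Rank(row["rank"].strip().lower()) if row.get("rank", "").strip() else None
            group = TaxonGroup(row["group"].strip())
            parent = row.get("parent", "").strip() or None
            taxa[name] = TaxonEntry(name=name, rank=rank, group=group, parent=parent)
            for body in BODIES:
                entries[(name, body)] = _parse_status_token(
                    row[body], taxon=name, body=body
                )

    syn = _read_two_column_csv(synonyms, "alias", "canonical") if synonyms else {}
    hier = _read_two_column_csv(hierarchy, "child", "parent") if hierarchy else {}
    # Registry rows with a parent column also feed the upward walk.
    for entry in taxa.values():
        if entry.parent:
            hier.setdefault(entry.name, entry.parent)
    return IndicatorRegistry(taxa=taxa, entries=entries, synonyms=syn, hierarchy=hier)
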