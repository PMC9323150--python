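"""Per-element mineral statistics.

For every chemical element present in a mineral table this module computes:

* ``n_minerals`` — the number of mineral species whose ideal formula
  contains the element;
* ``n_localities`` — the summed per-mineral locality counts over those
  species (locality identity is not tracked across minerals, so the sum is
  an upper bound on distinct localities);
* ``n_mineral_elements`` — the number of *other* elements co-occurring with
  the element across all of its minerals (the element's chemical breadth:
  the union of constituent elements of its minerals, minus itself);
* atomic number and, where available, crustal weight-percent abundance.

Short-lived radioactive elements and elements forming fewer than a minimum
number of minerals can be excluded before trend fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .formula import ATOMIC_NUMBERS, parse_formula

__all__ = [
    "MineralRecord",
    "DEFAULT_EXCLUDED_ELEMENTS",
    "DEFAULT_MIN_MINERALS",
    "ELEMENT_STATS_COLUMNS",
    "build_element_index",
    "mineral_elements",
    "compute_element_stats",
    "apply_exclusions",
]

#: short-lived radioactive elements excluded from all trend analyses
DEFAULT_EXCLUDED_ELEMENTS: frozenset[str] = frozenset({"Tc", "Po", "At", "Ra", "Pu"})

#: elements forming fewer than this many minerals are dropped ("fewer than five")
DEFAULT_MIN_MINERALS: int = 5

ELEMENT_STATS_COLUMNS = [
    "symbol",
    "atomic_number",
    "n_minerals",
    "n_localities",
    "n_mineral_elements",
    "crustal_wt_pct",
]


@dataclass(frozen=True)
class MineralRecord:
    """One IMA-approved mineral species admitted to the analysis."""

    name: str
    formula_text: str
    elements: frozenset[str]
    locality_count: int = 0
    max_age_ga: float | None = None

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError(f"mineral {self.name!r} has an empty element set")
        if self.locality_count < 0:
            raise ValueError(f"mineral {self.name!r} has negative locality_count")
        if self.max_age_ga is not None and not (0 <= self.max_age_ga <= 4.6):
            raise ValueError(
                f"mineral {self.name!r} max_age_ga={self.max_age_ga} outside [0, 4.6] Ga"
            )

    @classmethod
    def from_formula(
        cls,
        name: str,
        formula_text: str,
        locality_count: int = 0,
        max_age_ga: float | None = None,
    ) -> "MineralRecord":
        """Parse ``formula_text`` and build a record; ambiguous formulas raise."""
        parsed = parse_formula(formula_text)
        from .formula import extract_element_set

        return cls(name, formula_text, extract_element_set(parsed), locality_count, max_age_ga)


def build_element_index(minerals: Iterable[MineralRecord]) -> dict[str, set[str]]:
    """Map each element to the names of the minerals containing it."""
    index: dict[str, set[str]] = {}
    for m in minerals:
        for el in m.elements:
            index.setdefault(el, set()).add(m.name)
    return index


def mineral_elements(element: str, minerals: Iterable[MineralRecord]) -> frozenset[str]:
    """Elements co-occurring with ``element`` across all of its minerals.

    The union of constituent-element sets over every mineral containing
    ``element``, excluding ``element`` itself.  Its cardinality is the
    element's #-mineral-elements.
    """
    found = False
    union: set[str] = set()
    for m in minerals:
        if element in m.elements:
            found = True
            union.update(m.elements)
    if not found:
        raise KeyError(f"element {element!r} not present in any mineral")
    union.discard(element)
    return frozenset(union)


def compute_element_stats(
    minerals: list[MineralRecord],
    crustal: Mapping[str, float] | None = None,
    periodic: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Build the per-element summary table (one row per element present).

    ``crustal`` may be partial (the bulk continental-crust compilation has
    no entry for C, H, or N); missing entries become NaN.  An element with
    no periodic-table entry indicates corrupt input and raises.
    """
    periodic = ATOMIC_NUMBERS if periodic is None else periodic
    crustal = {} if crustal is None else crustal

    cooccur: dict[str, set[str]] = {}
    n_minerals: dict[str, int] = {}
    n_localities: dict[str, int] = {}
    for m in minerals:
        for el in m.elements:
            cooccur.setdefault(el, set()).update(m.elements)
            n_minerals[el] = n_minerals.get(el, 0) + 1
            n_localities[el] = n_localities.get(el, 0) + m.locality_count

    rows = []
    for el in sorted(cooccur):
        if el not in periodic:
            raise KeyError(f"element {el!r} has no periodic-table entry (corrupt input)")
        rows.append(
            {
                "symbol": el,
                "atomic_number": periodic[el],
                "n_minerals": n_minerals[el],
                "n_localities": n_localities[el],
                "n_mineral_elements": len(cooccur[el] - {el}),
                "crustal_wt_pct": crustal.get(el, float("nan")),
            }
        )
    return pd.DataFrame(rows, columns=ELEMENT_STATS_COLUMNS)


@dataclass
class ExclusionLog:
    """Which rows an exclusion pass removed, and why."""

    excluded_by_symbol: list[str] = field(default_factory=list)
    excluded_by_min_minerals: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.excluded_by_symbol) + len(self.excluded_by_min_minerals)


def apply_exclusions(
    records: pd.DataFrame,
    excluded_symbols: frozenset[str] | set[str] = DEFAULT_EXCLUDED_ELEMENTS,
    min_minerals: int = DEFAULT_MIN_MINERALS,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop excluded symbols and elements with ``n_minerals < min_minerals``.

    The threshold is strict ("fewer than"): an element with exactly
    ``min_minerals`` minerals is retained.
    """
    if min_minerals < 1:
        raise ValueError("min_minerals must be >= 1")
    log = ExclusionLog()
    by_symbol = records["symbol"].isin(excluded_symbols)
    log.excluded_by_symbol = sorted(records.loc[by_symbol, "symbol"])
    too_few = ~by_symbol & (records["n_minerals"] < min_minerals)
    log.excluded_by_min_minerals = sorted(records.loc[too_few, "symbol"])
    kept = records.loc[~by_symbol & ~too_few].reset_index(drop=True)
    return kept, log
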