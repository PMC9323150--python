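"""Shared fixtures: worked-example minerals and brute-force oracles.

The oracles here deliberately avoid the library's own code paths: element
indexing and co-occurrence are recomputed by exhaustive pairwise scans,
and OLS coefficients come from the closed-form normal equations.
"""

from __future__ import annotations

import re

import numpy as np
import pytest

from mineralnet.elements import MineralRecord
from mineralnet.formula import ELEMENT_SYMBOLS

# --- worked-example minerals --------------------------------------------


@pytest.fixture
def abellaite() -> MineralRecord:
    return MineralRecord.from_formula("abellaite", "NaPb2(CO3)2(OH)", locality_count=2)


@pytest.fixture
def siderite() -> MineralRecord:
    return MineralRecord.from_formula("siderite", "FeCO3", locality_count=3)


@pytest.fixture
def chalcopyrite() -> MineralRecord:
    return MineralRecord.from_formula("chalcopyrite", "CuFeS2", locality_count=1, max_age_ga=3.5)


# --- brute-force oracles -------------------------------------------------


def regex_element_scan(text: str) -> set[str]:
    """Independent element-set oracle: greedy longest-match symbol scan."""
    out: set[str] = set()
    i = 0
    while i < len(text):
        two = text[i : i + 2]
        if two in ELEMENT_SYMBOLS and re.fullmatch(r"[A-Z][a-z]", two):
            out.add(two)
            i += 2
        elif text[i] in ELEMENT_SYMBOLS:
            out.add(text[i])
            i += 1
        else:
            i += 1
    return out


def brute_element_index(minerals: list[MineralRecord]) -> dict[str, set[str]]:
    symbols = sorted({e for m in minerals for e in m.elements})
    return {s: {m.name for m in minerals if s in m.elements} for s in symbols}


def brute_mineral_elements(element: str, minerals: list[MineralRecord]) -> set[str]:
    out: set[str] = set()
    for m in minerals:
        if element in m.elements:
            for other in m.elements:
                if other != element:
                    out.add(other)
    return out


def brute_count_with(minerals: list[MineralRecord], required: set[str]) -> int:
    return sum(1 for m in minerals if all(r in m.elements for r in required))


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS: slope, intercept, R^2."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    yhat = intercept + slope * x
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)


def random_minerals(
    rng: np.random.Generator,
    n_minerals: int,
    pool: tuple[str, ...] = ("O", "H", "C", "Fe", "Si", "Na", "S", "Cu", "Ca", "Al"),
    with_ages: bool = False,
) -> list[MineralRecord]:
    """Small random instances for oracle-equivalence checks."""
    age_levels = (3.5, 2.3, 1.7, 0.6, 0.0)
    out = []
    for i in range(n_minerals):
        k = int(rng.integers(1, min(5, len(pool)) + 1))
        els = frozenset(rng.choice(pool, size=k, replace=False).tolist())
        age = float(rng.choice(age_levels)) if with_ages and rng.random() < 0.8 else None
        out.append(
            MineralRecord(
                name=f"m{i:03d}",
                formula_text="".join(sorted(els)),
                elements=els,
                locality_count=int(rng.integers(1, 50)),
                max_age_ga=age,
            )
        )
    return out
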