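"""Composition arithmetic: molecule counts vs water content vs mass fraction.

Water content R is expressed in gH2O/gdw (grams of water per gram of dry
weight), the dry weight being the sugar mass alone.  The trehalose mass
fraction is x_t = 1/(1+R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

M_TREHALOSE = 342.30  # g/mol, anhydrous
M_WATER = 18.015  # g/mol


@dataclass(frozen=True)
class MixtureSpec:
    """A trehalose/water mixture defined by molecule counts."""

    n_trehalose: int
    n_water: int
    m_trehalose: float = M_TREHALOSE
    m_water: float = M_WATER

    def __post_init__(self) -> None:
        if self.n_trehalose < 0 or self.n_water < 0:
            raise ValueError("molecule counts must be non-negative")

    @property
    def water_content(self) -> float:
        return content_from_counts(
            self.n_trehalose, self.n_water, self.m_trehalose, self.m_water
        )

    @property
    def x_t(self) -> float:
        return 1.0 / (1.0 + self.water_content)


def content_from_counts(
    n_trehalose: int,
    n_water: int,
    m_trehalose: float = M_TREHALOSE,
    m_water: float = M_WATER,
) -> float:
    """Water content (gH2O/gdw) of a mixture of counted molecules."""
    if n_trehalose < 1:
        raise ValueError("need at least one trehalose molecule (dry weight > 0)")
    return (n_water * m_water) / (n_trehalose * m_trehalose)


def waters_for_content(
    n_trehalose: int,
    target: float,
    m_trehalose: float = M_TREHALOSE,
    m_water: float = M_WATER,
) -> int:
    """Smallest water count whose content reaches ``target`` gH2O/gdw.

    Exact inverse bound of :func:`content_from_counts`:
    content(n−1) < target ≤ content(n) for any returned n > 0.
    """
    if target < 0:
        raise ValueError("target water content must be non-negative")
    if n_trehalose < 1:
        raise ValueError("need at least one trehalose molecule")
    exact = target * n_trehalose * m_trehalose / m_water
    n = max(0, math.ceil(exact - 1e-9))
    while content_from_counts(n_trehalose, n, m_trehalose, m_water) < target:
        n += 1
    while n > 0 and content_from_counts(n_trehalose, n - 1, m_trehalose, m_water) >= target:
        n -= 1
    return n
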