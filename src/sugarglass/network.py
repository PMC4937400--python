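"""Network-level statistics over detected hydrogen bonds.

Aggregates one frame's bond list into the quantities the glass analysis
reports: sugar–sugar bond stoichiometry (bonds per participating
molecule), participation percentages, n-body sugar clusters (connected
components over direct-or-indirect sugar–sugar bonds) and the bound/free
water partition.  Frame-to-frame averaging reports mean ± sample
standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .hbond import HBond
from .topology import Topology


@dataclass(frozen=True)
class HBondCensus:
    """Per-frame bond counts and stoichiometric ratios.

    Ratios are ``None`` (absent, not zero) when no molecule participates
    in the corresponding bond class.
    """

    n_tt: int
    n_tw: int
    n_wt: int
    n_ww: int
    n_treh_tt: int
    n_treh_tw: int
    n_treh_wt: int
    n_treh_total: int
    n_water_total: int
    ratio_tt: float | None
    ratio_tw: float | None
    ratio_wt: float | None
    pct_treh_tt: float
    pct_treh_w: float


@dataclass(frozen=True)
class ClusterDistribution:
    """Histogram of n-body sugar clusters; singletons count as size 1."""

    counts: dict[int, int]
    largest: int

    def binned(self) -> dict[str, int]:
        """The three-bin convenience view: giant (n>200), small (1<n<6), single."""
        return {
            "n>200": sum(c for n, c in self.counts.items() if n > 200),
            "1<n<6": sum(c for n, c in self.counts.items() if 1 < n < 6),
            "n=1": self.counts.get(1, 0),
        }


@dataclass(frozen=True)
class WaterPartition:
    """Bound water has ≥1 H-bond to sugar; w-w bonds confer nothing."""

    n_bound: int
    n_free: int
    frac_bound: float | None
    frac_free: float | None


def census(hbonds: Sequence[HBond], topology: Topology) -> HBondCensus:
    """Count one frame's bonds by class and form per-molecule ratios."""
    n_by_class = {"tt": 0, "tw": 0, "wt": 0, "ww": 0}
    treh_tt: set[int] = set()
    treh_tw: set[int] = set()
    treh_wt: set[int] = set()
    for b in hbonds:
        if b.bond_class in n_by_class:
            n_by_class[b.bond_class] += 1
        if b.bond_class == "tt":
            treh_tt.add(b.donor_molecule)
            treh_tt.add(b.acceptor_molecule)
        elif b.bond_class == "tw":
            treh_tw.add(b.donor_molecule)
        elif b.bond_class == "wt":
            treh_wt.add(b.acceptor_molecule)

    n_treh = topology.n_trehalose
    n_water = topology.n_water

    def ratio(num: int, denom: int) -> float | None:
        return num / denom if denom > 0 else None

    treh_w = treh_tw | treh_wt
    return HBondCensus(
        n_tt=n_by_class["tt"],
        n_tw=n_by_class["tw"],
        n_wt=n_by_class["wt"],
        n_ww=n_by_class["ww"],
        n_treh_tt=len(treh_tt),
        n_treh_tw=len(treh_tw),
        n_treh_wt=len(treh_wt),
        n_treh_total=n_treh,
        n_water_total=n_water,
        ratio_tt=ratio(n_by_class["tt"], len(treh_tt)),
        ratio_tw=ratio(n_by_class["tw"], len(treh_tw)),
        ratio_wt=ratio(n_by_class["wt"], len(treh_wt)),
        pct_treh_tt=100.0 * len(treh_tt) / n_treh if n_treh else 0.0,
        pct_treh_w=100.0 * len(treh_w) / n_treh if n_treh else 0.0,
    )


def trehalose_clusters(
    hbonds: Sequence[HBond], topology: Topology
) -> ClusterDistribution:
    """Connected components over sugar–sugar bonds (multiplicity ignored).

    Every sugar molecule is a vertex, so isolated molecules appear as
    1-body clusters and cluster sizes always sum to the sugar count.
    """
    g = nx.Graph()
    g.add_nodes_from(
        m for m, s in topology.molecule_species.items() if s == "trehalose"
    )
    g.add_edges_from(
        (b.donor_molecule, b.acceptor_molecule)
        for b in hbonds
        if b.bond_class == "tt"
    )
    counts: dict[int, int] = {}
    for comp in nx.connected_components(g):
        counts[len(comp)] = counts.get(len(comp), 0) + 1
    return ClusterDistribution(counts=counts, largest=max(counts) if counts else 0)


def water_partition(hbonds: Sequence[HBond], topology: Topology) -> WaterPartition:
    bound: set[int] = set()
    for b in hbonds:
        if b.bond_class == "tw":
            bound.add(b.acceptor_molecule)
        elif b.bond_class == "wt":
            bound.add(b.donor_molecule)
    n_water = topology.n_water
    n_bound = len(bound)
    n_free = n_water - n_bound
    if n_water == 0:
        return WaterPartition(0, 0, None, None)
    return WaterPartition(n_bound, n_free, n_bound / n_water, n_free / n_water)


def frame_average(values: Sequence[float]) -> tuple[float, float]:
    """Mean ± sample standard deviation (ddof=1; 0 when a single frame)."""
    arr = np.asarray([v for v in values], dtype=float)
    if arr.size == 0:
        raise ValueError("frame_average needs at least one value")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def average_census(census_list: Sequence[HBondCensus]) -> dict[str, tuple[float, float]]:
    """Field-wise mean ± sd over frames; fields absent on every frame are skipped."""
    if not census_list:
        raise ValueError("average_census needs at least one frame")
    out: dict[str, tuple[float, float]] = {}
    for f in fields(HBondCensus):
        vals = [getattr(c, f.name) for c in census_list]
        vals = [v for v in vals if v is not None]
        if vals:
            out[f.name] = frame_average(vals)
    return out
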