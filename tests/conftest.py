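"""Shared builders for synthetic test systems."""

from __future__ import annotations

import numpy as np
import pytest

from sugarglass.hbond import HBond
from sugarglass.synthetic import PlantedNetworkSpec
from sugarglass.topology import AtomRecord, Topology
from sugarglass.trajio import Box, Frame


def make_water_system(
    n_waters: int, box_edge: float, seed: int
) -> tuple[Topology, Frame]:
    """Random water-only frame: O at uniform positions, two H at 0.96 Å."""
    rng = np.random.default_rng(seed)
    records: list[AtomRecord] = []
    pos: list[np.ndarray] = []
    for m in range(n_waters):
        o = rng.uniform(0, box_edge, 3)
        records.append(AtomRecord(3 * m, m, "water", "acceptor_oxygen", "OW", None))
        pos.append(o)
        for k in range(2):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            records.append(
                AtomRecord(3 * m + 1 + k, m, "water", "donor_hydrogen", f"HW{k + 1}", 3 * m)
            )
            pos.append(o + 0.96 * v)
    return Topology(records), Frame(
        np.array(pos), Box(box_edge, box_edge, box_edge)
    )


def random_forest_spec(seed: int) -> PlantedNetworkSpec:
    """Random feasible planted-network spec: forest edges, capped degrees."""
    rng = np.random.default_rng(seed)
    nt = int(rng.integers(6, 25))
    nw = int(rng.integers(0, 12))
    p_edge = rng.uniform(0.2, 0.9)
    degree = np.zeros(nt + nw, dtype=int)
    donations = np.zeros(nt + nw, dtype=int)
    tt, tw, wt = [], [], []
    for i in range(1, nt + nw):
        if rng.uniform() > p_edge:
            continue
        candidates = [j for j in range(i) if degree[j] < 5]
        if not candidates:
            continue
        j = int(rng.choice(candidates))
        i_water = i >= nt
        j_water = j >= nt
        if i_water and j_water:
            continue  # water-water bonds are not plantable
        if not i_water and not j_water:
            tt.append((j, i))
            donations[j] += 1
        elif i_water != j_water:
            w, t = (i, j) if i_water else (j, i)
            if rng.uniform() < 0.5 and donations[w] < 2:
                wt.append((w, t))
                donations[w] += 1
            else:
                tw.append((t, w))
                donations[t] += 1
        degree[i] += 1
        degree[j] += 1
    # size the box from the component structure: the packer uses cubic
    # cells of (largest component extent + separation)
    union = [(d, a) for d, a in tt + tw + wt]
    comps = dfs_components(nt + nw, union)
    biggest = max(len(c) for c in comps)
    cell = biggest * 2.8 + 2 * 0.96 + 6.0
    per_axis = int(np.ceil(len(comps) ** (1 / 3)))
    edge = float(cell * per_axis + rng.uniform(1, 15))
    return PlantedNetworkSpec(
        n_trehalose=nt,
        n_water=nw,
        tt_edges=tuple(tt),
        tw_edges=tuple(tw),
        wt_edges=tuple(wt),
        box=Box(edge, edge, edge),
        seed=seed,
    )


def dfs_components(n_nodes: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    """Naive depth-first-search connected components (independent oracle)."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_nodes)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set[int] = set()
    comps: list[set[int]] = []
    for start in range(n_nodes):
        if start in seen:
            continue
        stack = [start]
        comp: set[int] = set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def bond_keys(bonds: list[HBond]) -> list[tuple[int, int, int]]:
    return [b.key() for b in bonds]
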