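"""Synthetic inputs with known ground truth.

Every analysis stage in this package can be exercised without MD output:

* :func:`generate_planted_network` builds coordinates + topology whose
  detected hydrogen-bond set *provably equals* a requested adjacency.
  Molecules are minimal stand-ins (one hub oxygen, one hydroxyl hydrogen
  per donated bond) — sufficient because the analyses consume only roles
  and positions.  Bonded molecules sit on adjacent sites of a cubic
  lattice with edge equal to the O–O bond distance (default 2.8 Å,
  comfortably inside the 3.5 Å / 150° criterion), hydrogens lie exactly
  on the bond axis (180°), and non-bonded neighbours are separated by
  ≥ √2 lattice edges (3.96 Å > 3.5 Å) or by ``min_separation`` between
  connected groups.  The construction is verified against the
  brute-force detector and re-seeded on the (rare) packing failure.

* :func:`generate_random_walk` draws i.i.d. Gaussian steps of variance
  2·D·Δt per axis, so the Einstein relation holds exactly in
  expectation; the wrapped and unwrapped trajectories are both returned.

* :func:`generate_ideal_gas` gives uniform positions (g(r) = 1).

* :func:`generate_curve_dataset` samples the Gordon–Taylor, H-bond
  stoichiometry and viability models with optional Gaussian noise.

All generators take an explicit integer seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import gaussian_predict, gt_predict, mgt_predict, x_t_from_content
from .hbond import HBond, HBondParams, detect_hbonds_bruteforce
from .topology import AtomRecord, Topology
from .trajio import Box, Frame, Trajectory

_AXES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=int,
)


class FeasibilityError(ValueError):
    """Requested planted network cannot be realized geometrically."""


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """A hydrogen-bond adjacency to realize as coordinates + topology.

    Molecule ids: trehalose occupy 0..n_trehalose-1, water the next
    n_water ids.  Edges are (donor_molecule, acceptor_molecule) pairs;
    the union bond graph must be a forest with ≤ 6 distinct neighbours
    per molecule, and a water may donate at most its two hydrogens.
    """

    n_trehalose: int
    n_water: int = 0
    tt_edges: tuple[tuple[int, int], ...] = ()
    tw_edges: tuple[tuple[int, int], ...] = ()
    wt_edges: tuple[tuple[int, int], ...] = ()
    box: Box = field(default_factory=lambda: Box(60.0, 60.0, 60.0))
    oo_distance: float = 2.8
    oh_distance: float = 0.96
    min_separation: float = 6.0
    seed: int = 0
    max_retries: int = 8


@dataclass(frozen=True)
class PlantedNetwork:
    frame: Frame
    topology: Topology
    bonds: tuple[HBond, ...]  # the planted ground truth, canonically sorted

    @property
    def bond_keys(self) -> set[tuple[int, int, int]]:
        return {b.key() for b in self.bonds}


def _validate_spec(spec: PlantedNetworkSpec) -> list[tuple[int, int, str]]:
    nt, nw = spec.n_trehalose, spec.n_water
    is_treh = lambda m: 0 <= m < nt
    is_water = lambda m: nt <= m < nt + nw
    edges: list[tuple[int, int, str]] = []
    for d, a in spec.tt_edges:
        if not (is_treh(d) and is_treh(a)):
            raise FeasibilityError(f"tt edge ({d},{a}) must join two trehalose ids")
        edges.append((d, a, "tt"))
    for d, a in spec.tw_edges:
        if not (is_treh(d) and is_water(a)):
            raise FeasibilityError(f"tw edge ({d},{a}) must be trehalose→water")
        edges.append((d, a, "tw"))
    for d, a in spec.wt_edges:
        if not (is_water(d) and is_treh(a)):
            raise FeasibilityError(f"wt edge ({d},{a}) must be water→trehalose")
        edges.append((d, a, "wt"))
    for cls, lst in (("tt", spec.tt_edges), ("tw", spec.tw_edges), ("wt", spec.wt_edges)):
        if len(set(lst)) != len(lst):
            raise FeasibilityError(f"duplicate {cls} edges: not a simple graph")
    for d, a, _ in edges:
        if d == a:
            raise FeasibilityError(f"self edge on molecule {d}")
    donations: dict[int, int] = {}
    for d, _, _ in edges:
        donations[d] = donations.get(d, 0) + 1
    for m, k in donations.items():
        if is_water(m) and k > 2:
            raise FeasibilityError(f"water {m} donates {k} bonds but has 2 hydrogens")

    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(nt + nw))
    g.add_edges_from((d, a) for d, a, _ in edges)
    if not nx.is_forest(g):
        raise FeasibilityError(
            "union bond graph contains a cycle; only forests are realizable "
            "on the bond lattice"
        )
    for m in g.nodes:
        if g.degree(m) > 6:
            raise FeasibilityError(
                f"molecule {m} has {g.degree(m)} bonded neighbours; "
                "at most 6 fit the direction set"
            )
    return edges


def _layout_components(
    n_mol: int,
    neighbor: dict[int, set[int]],
    rng: np.random.Generator,
) -> tuple[dict[int, np.ndarray], list[list[int]]]:
    """BFS each component onto integer lattice sites, collision-free."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n_mol))
    for u, vs in neighbor.items():
        for v in vs:
            g.add_edge(u, v)
    sites: dict[int, np.ndarray] = {}
    components: list[list[int]] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        root = comp[0]
        # DFS order; each node's parent precedes it
        order = [root]
        parent = {root: None}
        stack = [root]
        seen = {root}
        while stack:
            u = stack.pop()
            for v in sorted(neighbor.get(u, ()), reverse=True):
                if v not in seen:
                    seen.add(v)
                    parent[v] = u
                    order.append(v)
                    stack.append(v)

        # self-avoiding placement with chronological backtracking
        pos: dict[int, tuple[int, int, int]] = {root: (0, 0, 0)}
        occupied = {(0, 0, 0)}
        dirs: list[list[int] | None] = [None] * len(order)
        ptr = [0] * len(order)
        i = 1
        steps = 0
        limit = 200 * len(order) + 1000
        while 0 < i < len(order):
            steps += 1
            if steps > limit:
                raise FeasibilityError(
                    f"lattice placement exceeded {limit} backtracking steps"
                )
            node = order[i]
            if dirs[i] is None:
                dirs[i] = list(rng.permutation(6))
                ptr[i] = 0
            base = pos[parent[node]]
            placed = False
            while ptr[i] < 6:
                d = _AXES[dirs[i][ptr[i]]]
                ptr[i] += 1
                cand = (base[0] + d[0], base[1] + d[1], base[2] + d[2])
                if cand not in occupied:
                    pos[node] = cand
                    occupied.add(cand)
                    placed = True
                    break
            if placed:
                i += 1
            else:
                dirs[i] = None
                i -= 1
                if i > 0:
                    prev = order[i]
                    occupied.discard(pos.pop(prev))
        if i == 0:
            raise FeasibilityError(
                f"component rooted at molecule {root} cannot be embedded "
                "on the bond lattice"
            )
        for m in comp:
            sites[m] = np.array(pos[m], dtype=int)
        components.append(comp)
    return sites, components


def generate_planted_network(spec: PlantedNetworkSpec) -> PlantedNetwork:
    """Realize the requested adjacency; detection is guaranteed exact."""
    edges = _validate_spec(spec)
    nt, nw = spec.n_trehalose, spec.n_water
    n_mol = nt + nw
    neighbor: dict[int, set[int]] = {m: set() for m in range(n_mol)}
    for d, a, _ in edges:
        neighbor[d].add(a)
        neighbor[a].add(d)

    last_error: Exception | None = None
    for attempt in range(spec.max_retries):
        rng = np.random.default_rng([spec.seed, attempt])
        try:
            net = _build(spec, edges, neighbor, rng)
        except FeasibilityError as exc:
            last_error = exc
            continue
        detected = detect_hbonds_bruteforce(net.frame, net.topology, HBondParams())
        if [b.key() for b in detected] == [b.key() for b in net.bonds]:
            return net
        last_error = FeasibilityError("oracle verification found extra/missing bonds")
    raise FeasibilityError(
        f"could not realize the planted network in {spec.max_retries} attempts "
        f"({last_error}); try a larger box or sparser adjacency"
    )


def _build(
    spec: PlantedNetworkSpec,
    edges: list[tuple[int, int, str]],
    neighbor: dict[int, set[int]],
    rng: np.random.Generator,
) -> PlantedNetwork:
    nt, nw = spec.n_trehalose, spec.n_water
    n_mol = nt + nw
    a_oo = spec.oo_distance
    sites, components = _layout_components(n_mol, neighbor, rng)

    # pack the components into the box on a coarse grid, gap >= min_separation
    extents = []
    for comp in components:
        pts = np.array([sites[m] for m in comp]) * a_oo
        lo = pts.min(axis=0) - spec.oh_distance
        hi = pts.max(axis=0) + spec.oh_distance
        extents.append((lo, hi))
    cell = max(float(np.max(hi - lo)) for lo, hi in extents) + spec.min_separation
    L = spec.box.lengths
    ncells = np.floor(L / cell).astype(int)
    if np.prod(np.maximum(ncells, 0)) < len(components):
        need = cell * math.ceil(len(components) ** (1 / 3))
        raise FeasibilityError(
            f"box {spec.box} too small to pack {len(components)} groups with "
            f"{spec.min_separation} Å separation; need roughly {need:.0f} Å edges"
        )
    order = rng.permutation(int(np.prod(ncells)))[: len(components)]
    anchors: dict[int, np.ndarray] = {}
    for comp, (lo, hi), cidx in zip(components, extents, order):
        ci = np.array(np.unravel_index(cidx, ncells), dtype=float)
        origin = ci * cell - lo  # shift so the group's bbox starts at the cell corner
        for m in comp:
            anchors[m] = np.asarray(sites[m], dtype=float) * a_oo + origin

    # directions of planted bonds (unit lattice vectors donor -> acceptor)
    def edge_dir(d: int, a: int) -> np.ndarray:
        v = (sites[a] - sites[d]).astype(float)
        return v / np.linalg.norm(v)

    occ_by_comp: dict[int, set[tuple[int, int, int]]] = {}
    for comp in components:
        s = {tuple(sites[m]) for m in comp}
        for m in comp:
            occ_by_comp[m] = s

    records: list[AtomRecord] = []
    positions: list[np.ndarray] = []
    donated: dict[int, list[tuple[int, str]]] = {m: [] for m in range(n_mol)}
    for d, a, cls in edges:
        donated[d].append((a, cls))

    oxygen_of: dict[int, int] = {}
    hydrogen_for_edge: dict[tuple[int, int], int] = {}
    idx = 0
    for m in range(n_mol):
        species = "trehalose" if m < nt else "water"
        o_name = "O16" if species == "trehalose" else "OW"
        oxygen_of[m] = idx
        records.append(
            AtomRecord(idx, m, species, "acceptor_oxygen", o_name, None)
        )
        positions.append(anchors[m])
        o_idx = idx
        idx += 1
        used_dirs = [edge_dir(m, a) for a, _ in donated[m]]
        h_needed = 2 if species == "water" else len(donated[m])
        h_count = 0
        for a, cls in donated[m]:
            h_name = "HO16" if species == "trehalose" else f"HW{h_count + 1}"
            records.append(
                AtomRecord(idx, m, species, "donor_hydrogen", h_name, o_idx)
            )
            positions.append(anchors[m] + spec.oh_distance * edge_dir(m, a))
            hydrogen_for_edge[(m, a)] = idx
            idx += 1
            h_count += 1
        # spare water hydrogens: point at a free lattice direction
        while h_count < h_needed:
            free = None
            for di in rng.permutation(6):
                cand = tuple(sites[m] + _AXES[di])
                vec = _AXES[di].astype(float)
                if cand in occ_by_comp[m]:
                    continue
                if any(np.dot(vec, u) > 0.99 for u in used_dirs):
                    continue
                free = vec
                used_dirs.append(vec)
                break
            if free is None:
                raise FeasibilityError(
                    f"water {m}: no safe direction for a spare hydrogen"
                )
            records.append(
                AtomRecord(idx, m, "water", "donor_hydrogen", f"HW{h_count + 1}", o_idx)
            )
            positions.append(anchors[m] + spec.oh_distance * free)
            idx += 1
            h_count += 1

    pos = np.array(positions, dtype=float)
    pos -= L * np.floor(pos / L)  # wrap into [0, L)
    topology = Topology(records)
    frame = Frame(pos, spec.box, time=0.0)

    planted: list[HBond] = []
    for d, a, cls in edges:
        h = hydrogen_for_edge[(d, a)]
        planted.append(
            HBond(
                donor_oxygen=oxygen_of[d],
                hydrogen=h,
                acceptor_oxygen=oxygen_of[a],
                donor_molecule=d,
                acceptor_molecule=a,
                bond_class=cls,
                distance=spec.oo_distance,
                angle=180.0,
            )
        )
    planted.sort(key=HBond.key)
    return PlantedNetwork(frame=frame, topology=topology, bonds=tuple(planted))


# ------------------------------------------------------------ random walk

@dataclass(frozen=True)
class RandomWalkSpec:
    """Isotropic Brownian walkers of known diffusion coefficient."""

    n_atoms: int
    d_target: float  # m²/s
    dt: float  # ps
    n_frames: int
    box: Box = field(default_factory=lambda: Box(50.0, 50.0, 50.0))
    seed: int = 0


@dataclass(frozen=True)
class RandomWalkResult:
    wrapped: Trajectory
    unwrapped: Trajectory
    d_target: float  # m²/s
    step_sd: float  # Å per axis per step


def generate_random_walk(spec: RandomWalkSpec) -> RandomWalkResult:
    """Gaussian steps with per-axis variance 2·D·Δt; D given in m²/s."""
    d_aps = spec.d_target * 1e8  # Å²/ps
    step_sd = math.sqrt(2.0 * d_aps * spec.dt)
    L = spec.box.lengths
    if step_sd * 6 >= min(L) / 2:
        raise ValueError("step size too large for the box; wrapping is ambiguous")
    rng = np.random.default_rng(spec.seed)
    start = rng.uniform(0, 1, size=(spec.n_atoms, 3)) * L
    steps = rng.normal(0.0, step_sd, size=(spec.n_frames - 1, spec.n_atoms, 3))
    unwrapped = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    wrapped = unwrapped - L * np.floor(unwrapped / L)
    times = np.arange(spec.n_frames) * spec.dt
    mk = lambda arr: Trajectory(
        [Frame(arr[i], spec.box, time=float(times[i])) for i in range(spec.n_frames)]
    )
    return RandomWalkResult(
        wrapped=mk(wrapped),
        unwrapped=mk(unwrapped),
        d_target=spec.d_target,
        step_sd=step_sd,
    )


def generate_ideal_gas(n: int, box: Box, seed: int = 0) -> Frame:
    """Uniform independent positions — the g(r) = 1 reference state."""
    if n < 2:
        raise ValueError("need at least two atoms")
    rng = np.random.default_rng(seed)
    return Frame(rng.uniform(0, 1, size=(n, 3)) * box.lengths, box)


# ----------------------------------------------------------- curve models

_MODELS = ("gt", "mgt", "viability")


def generate_curve_dataset(
    model: str,
    params: dict,
    x: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    x_is_content: bool = False,
) -> pd.DataFrame:
    """Sample one of the three curve models, optionally with Gaussian noise.

    Returns columns ``x`` (as given), ``y_true`` and ``y``.  For the two
    Gordon–Taylor-form models, ``x`` is a mass fraction unless
    ``x_is_content`` is set, in which case it is water content in
    gH2O/gdw and converted internally.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    x = np.asarray(x, dtype=float)
    if model == "gt":
        xt = x_t_from_content(x) if x_is_content else x
        y_true = gt_predict(xt, params["tg_t"], params["tg_w"], params["k1"])
    elif model == "mgt":
        xt = x_t_from_content(x) if x_is_content else x
        y_true = mgt_predict(xt, params["n_pure"], params["n_inf"], params["k2"])
    else:
        y_true = gaussian_predict(
            x, params["y0"], params["a"], params["xc"], params["w"]
        )
    y_true = np.atleast_1d(np.asarray(y_true, dtype=float))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=y_true.shape) if noise_sd > 0 else 0.0
    return pd.DataFrame({"x": x, "y_true": y_true, "y": y_true + noise})
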