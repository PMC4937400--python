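"""Geometric hydrogen-bond detection under periodic boundary conditions.

A donor O–H ··· acceptor O contact counts as a hydrogen bond when the
donor-oxygen/acceptor-oxygen minimum-image distance does not exceed
``d_max`` (default 3.5 Å, the first minimum of the O–O radial
distribution function in trehalose–water glasses) and the O-H···O angle
at the hydrogen is strictly greater than ``theta_min`` (default 150°,
reflecting the preferential linearity of H-bonds).  Boundary semantics
are deliberately asymmetric: distance inclusive, angle exclusive.

Two detectors are provided: an O(n_H × n_O) brute-force reference and a
cell-list implementation that must produce an identical, identically
sorted bond list on every input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .topology import Topology
from .trajio import Box, Frame

BOND_CLASSES = ("tt", "tw", "wt", "ww")

_CLASS = {
    ("trehalose", "trehalose"): "tt",
    ("trehalose", "water"): "tw",
    ("water", "trehalose"): "wt",
    ("water", "water"): "ww",
}


@dataclass(frozen=True)
class HBondParams:
    """Geometric criterion: O–O cutoff (Å) and minimum O-H···O angle (deg)."""

    d_max: float = 3.5
    theta_min: float = 150.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0 < self.theta_min <= 180):
            raise ValueError("theta_min must be in (0, 180]")


@dataclass(frozen=True)
class HBond:
    donor_oxygen: int
    hydrogen: int
    acceptor_oxygen: int
    donor_molecule: int
    acceptor_molecule: int
    bond_class: str
    distance: float  # donor-O — acceptor-O, Å
    angle: float  # O-H···O at the hydrogen, degrees

    def key(self) -> tuple[int, int, int]:
        return (self.donor_oxygen, self.hydrogen, self.acceptor_oxygen)


def minimum_image_displacement(
    p: np.ndarray, q: np.ndarray, box: Box
) -> np.ndarray:
    """Displacement q − p wrapped into (−L/2, L/2] per component."""
    L = box.lengths
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return d - L * np.round(d / L)


def hbond_angle(
    donor_o: np.ndarray, h: np.ndarray, acceptor_o: np.ndarray, box: Box
) -> float:
    """O-H···O angle (degrees) at the hydrogen, minimum-image arms.

    180° is perfectly linear (hydrogen between the oxygens).
    """
    u = minimum_image_displacement(h, donor_o, box)
    v = minimum_image_displacement(h, acceptor_o, box)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("coincident atoms: zero-length O-H or H···O arm")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _check_box(frame: Frame, params: HBondParams) -> None:
    if np.any(frame.box.lengths < 2 * params.d_max):
        raise ValueError(
            f"box {frame.box} is smaller than twice the cutoff "
            f"({params.d_max} Å); minimum-image detection is ambiguous"
        )


def _emit(
    frame: Frame,
    topology: Topology,
    h_idx: np.ndarray,
    a_idx: np.ndarray,
    params: HBondParams,
) -> list[HBond]:
    """Evaluate the criterion on explicit (hydrogen, acceptor) candidates."""
    pos = frame.positions
    box = frame.box
    L = box.lengths
    parents = topology.parent_oxygen[h_idx]
    d = pos[a_idx] - pos[parents]
    d -= L * np.round(d / L)
    dist = np.linalg.norm(d, axis=1)
    ok = dist <= params.d_max
    bonds: list[HBond] = []
    if not np.any(ok):
        return bonds
    h_idx, a_idx, parents, dist = h_idx[ok], a_idx[ok], parents[ok], dist[ok]
    u = pos[parents] - pos[h_idx]
    u -= L * np.round(u / L)
    v = pos[a_idx] - pos[h_idx]
    v -= L * np.round(v / L)
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore"):
        cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    sel = ang > params.theta_min
    for hh, aa, pp, dd, an in zip(
        h_idx[sel], a_idx[sel], parents[sel], dist[sel], ang[sel]
    ):
        dm = int(topology.molecule_id[pp])
        am = int(topology.molecule_id[aa])
        cls = _CLASS.get(
            (topology.molecule_species[dm], topology.molecule_species[am]), "other"
        )
        bonds.append(
            HBond(int(pp), int(hh), int(aa), dm, am, cls, float(dd), float(an))
        )
    bonds.sort(key=HBond.key)
    return bonds


def detect_hbonds_bruteforce(
    frame: Frame,
    topology: Topology,
    params: HBondParams = HBondParams(),
    intermolecular_only: bool = True,
) -> list[HBond]:
    """All-pairs reference detector; the oracle for :func:`detect_hbonds`."""
    if frame.n_atoms != topology.n_atoms:
        raise ValueError(
            f"frame has {frame.n_atoms} atoms but topology has {topology.n_atoms}"
        )
    _check_box(frame, params)
    hs = topology.donor_hydrogens
    accs = topology.acceptor_oxygens
    if hs.size == 0 or accs.size == 0:
        return []
    H, A = np.meshgrid(hs, accs, indexing="ij")
    H, A = H.ravel(), A.ravel()
    keep = topology.parent_oxygen[H] != A  # parent oxygen never self-accepts
    if intermolecular_only:
        keep &= topology.molecule_id[H] != topology.molecule_id[A]
    return _emit(frame, topology, H[keep], A[keep], params)


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    params: HBondParams = HBondParams(),
    intermolecular_only: bool = True,
) -> list[HBond]:
    """Cell-list detector; output is element-for-element identical to
    :func:`detect_hbonds_bruteforce`.

    Falls back to brute force when the box is too small for a ≥3³ cell
    grid with cell edge ≥ d_max (where a cell walk would double-count
    periodic neighbours).
    """
    if frame.n_atoms != topology.n_atoms:
        raise ValueError(
            f"frame has {frame.n_atoms} atoms but topology has {topology.n_atoms}"
        )
    _check_box(frame, params)
    hs = topology.donor_hydrogens
    accs = topology.acceptor_oxygens
    if hs.size == 0 or accs.size == 0:
        return []

    L = frame.box.lengths
    ncell = np.floor(L / params.d_max).astype(int)
    if np.any(ncell < 3):
        return detect_hbonds_bruteforce(frame, topology, params, intermolecular_only)

    pos = frame.positions
    frac = pos[accs] / L
    cells = np.floor((frac - np.floor(frac)) * ncell).astype(int)
    cells = np.minimum(cells, ncell - 1)  # guard frac == 1.0 rounding
    flat = (cells[:, 0] * ncell[1] + cells[:, 1]) * ncell[2] + cells[:, 2]
    order = np.argsort(flat, kind="stable")
    sorted_accs = accs[order]
    sorted_flat = flat[order]
    starts = np.searchsorted(sorted_flat, np.arange(np.prod(ncell)))
    ends = np.searchsorted(sorted_flat, np.arange(np.prod(ncell)), side="right")

    # donor parents binned the same way
    parents = topology.parent_oxygen[hs]
    fracp = pos[parents] / L
    pcell = np.floor((fracp - np.floor(fracp)) * ncell).astype(int)
    pcell = np.minimum(pcell, ncell - 1)

    offsets = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    cand_h: list[np.ndarray] = []
    cand_a: list[np.ndarray] = []
    for hi, cc in zip(hs, pcell):
        neigh = (cc + offsets) % ncell
        fl = (neigh[:, 0] * ncell[1] + neigh[:, 1]) * ncell[2] + neigh[:, 2]
        pieces = [sorted_accs[starts[f]:ends[f]] for f in np.unique(fl)]
        if not pieces:
            continue
        aa = np.concatenate(pieces)
        if aa.size == 0:
            continue
        cand_h.append(np.full(aa.size, hi, dtype=np.int64))
        cand_a.append(aa)
    if not cand_h:
        return []
    H = np.concatenate(cand_h)
    A = np.concatenate(cand_a)
    keep = topology.parent_oxygen[H] != A
    if intermolecular_only:
        keep &= topology.molecule_id[H] != topology.molecule_id[A]
    return _emit(frame, topology, H[keep], A[keep], params)


def hbonds_per_frame(
    trajectory,
    topology: Topology,
    params: HBondParams = HBondParams(),
    intermolecular_only: bool = True,
) -> list[list[HBond]]:
    """Detect bonds independently on every frame of a trajectory."""
    return [
        detect_hbonds(f, topology, params, intermolecular_only) for f in trajectory
    ]
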