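"""Single-particle dynamics and pair structure: MSD, diffusion, RDF.

Diffusion coefficients come from the Einstein relation
``MSD(τ) = 6 D τ`` fitted over an intermediate lag window (default 10 %
to 50 % of the trajectory length: short lags are ballistic/rattling,
long lags are poorly averaged).  Unit chain: coordinates in Å, time in
ps, so the fitted slope is Å²/ps and ``D = slope / 6 × 1e-8 m²/s``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .topology import Topology
from .trajio import Box, Frame, Trajectory

A2_PER_PS_TO_M2_PER_S = 1e-8  # 1 Å²/ps = 1e-8 m²/s


@dataclass(frozen=True)
class MSDSeries:
    lag_times: np.ndarray  # ps
    msd: np.ndarray  # Å²
    selection: str

    def __post_init__(self) -> None:
        if self.msd[0] != 0:
            raise ValueError("msd at zero lag must be 0")
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag grid must be strictly increasing")


@dataclass(frozen=True)
class DiffusionEstimate:
    d: float  # m²/s
    fit_window: tuple[float, float]  # ps
    slope: float  # Å²/ps
    r2: float


@dataclass(frozen=True)
class RDF:
    r_centers: np.ndarray  # Å
    g: np.ndarray
    pair_spec: tuple[str, str]
    bin_width: float
    r_max: float


def select_atoms(topology: Topology, label: str) -> np.ndarray:
    """Indices of all atoms whose name equals ``label`` (pools symmetric copies)."""
    idx = np.flatnonzero(topology.atom_names == label)
    if idx.size == 0:
        available = sorted(set(topology.atom_names.tolist()))
        raise ValueError(
            f"no atoms named {label!r}; available names: {available}"
        )
    return idx


def unwrap(trajectory: Trajectory) -> Trajectory:
    """Undo periodic wrapping so displacements accumulate continuously.

    Valid only when every per-step displacement is below half a box edge;
    larger jumps are ambiguous and raise with advice to use finer frame
    spacing.
    """
    pos = trajectory.positions
    box = trajectory[0].box
    L = box.lengths
    steps = np.diff(pos, axis=0)
    steps -= L * np.round(steps / L)
    if np.any(np.abs(steps) >= L / 2 * (1 - 1e-12)):
        raise ValueError(
            "per-step displacement reaches half a box edge; unwrapping is "
            "ambiguous — extract frames at finer time spacing"
        )
    out = np.concatenate([pos[:1], pos[:1] + np.cumsum(steps, axis=0)])
    return Trajectory(
        [
            Frame(out[i], box, time=trajectory[i].time)
            for i in range(len(trajectory))
        ]
    )


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """All-origin MSD of each column of x (shape (T, C)) via autocorrelation."""
    T = x.shape[0]
    nfft = 1 << (2 * T - 1).bit_length()
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:T].real
    sq = x**2
    ssum = sq.sum(axis=0)
    msd = np.empty_like(acf)
    q = 2.0 * ssum
    for tau in range(T):
        if tau > 0:
            q = q - sq[tau - 1] - sq[T - tau]
        msd[tau] = q / (T - tau) - 2.0 * acf[tau] / (T - tau)
    return msd


def msd(
    trajectory: Trajectory,
    selection: str | np.ndarray,
    topology: Topology | None = None,
    max_lag_fraction: float = 0.5,
) -> MSDSeries:
    """Time-origin-averaged mean squared displacement of a selection.

    The trajectory must already be unwrapped.  All time origins are used
    (FFT algorithm, O(T log T)); lags run to ``max_lag_fraction`` of the
    trajectory length.
    """
    if len(trajectory) < 2:
        raise ValueError("MSD needs at least two frames")
    if isinstance(selection, str):
        if topology is None:
            raise ValueError("a topology is required to resolve a name selection")
        idx = select_atoms(topology, selection)
        label = selection
    else:
        idx = np.asarray(selection, dtype=np.int64)
        label = f"{idx.size} atoms"
        if idx.size == 0:
            raise ValueError("empty atom selection")
    dt = trajectory.uniform_dt()
    pos = trajectory.positions[:, idx, :]  # (T, n, 3)
    T, n, _ = pos.shape
    flat = pos.reshape(T, n * 3)
    per_coord = _msd_fft_1d(flat)  # (T, n*3)
    total = per_coord.reshape(T, n, 3).sum(axis=2).mean(axis=1)
    total[0] = 0.0
    n_lags = max(2, int(np.floor(max_lag_fraction * (T - 1))) + 1)
    n_lags = min(n_lags, T)
    lags = np.arange(n_lags) * dt
    return MSDSeries(lag_times=lags, msd=total[:n_lags], selection=label)


def diffusion_coefficient(
    series: MSDSeries,
    window: tuple[float, float] = (0.1, 0.5),
    slope_exponent_warn: float = 0.2,
) -> DiffusionEstimate:
    """Einstein-relation D from a linear fit of MSD over a lag window.

    ``window`` is given as fractions of the maximum available lag.  A
    warning is emitted when the log-log slope of the MSD in the window
    deviates from 1 by more than ``slope_exponent_warn`` (sub- or
    super-diffusive data).
    """
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    tmax = series.lag_times[-1]
    mask = (series.lag_times >= lo * tmax) & (series.lag_times <= hi * tmax)
    t = series.lag_times[mask]
    y = series.msd[mask]
    if t.size < 2:
        raise ValueError("fewer than 2 MSD points in the fit window")
    res = stats.linregress(t, y)
    slope = float(res.slope)
    r2 = float(res.rvalue**2) if np.std(y) > 0 else 1.0
    if np.all(y > 0) and np.all(t > 0):
        log_res = stats.linregress(np.log(t), np.log(y))
        if abs(log_res.slope - 1.0) > slope_exponent_warn:
            warnings.warn(
                f"MSD exponent {log_res.slope:.2f} deviates from diffusive "
                "scaling (1.0); the Einstein estimate may be unreliable",
                stacklevel=2,
            )
    return DiffusionEstimate(
        d=slope / 6.0 * A2_PER_PS_TO_M2_PER_S,
        fit_window=(float(t[0]), float(t[-1])),
        slope=slope,
        r2=r2,
    )


def rdf(
    frames: Sequence[Frame] | Trajectory,
    reference: np.ndarray,
    target: np.ndarray,
    r_max: float,
    bin_width: float = 0.05,
    pair_spec: tuple[str, str] = ("ref", "target"),
) -> RDF:
    """Radial distribution function g(r) between two selections.

    Normalization: pair count in shell k divided by
    ``n_ref × ρ_target × 4π r_k² Δr`` with the bin-centre radius,
    averaged over frames.  Self-pairs (identical atom index) are always
    excluded.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("rdf needs at least one frame")
    reference = np.asarray(reference, dtype=np.int64)
    target = np.asarray(target, dtype=np.int64)
    box = frames[0].box
    if r_max > min(box.lengths) / 2:
        raise ValueError(
            f"r_max {r_max} Å exceeds half the smallest box edge "
            f"({min(box.lengths) / 2:.3f} Å)"
        )
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(n_bins)
    L = box.lengths
    for frame in frames:
        p_ref = frame.positions[reference] % L
        p_tgt = frame.positions[target] % L
        tree_r = cKDTree(p_ref, boxsize=L)
        tree_t = cKDTree(p_tgt, boxsize=L)
        # cumulative pair counts at the bin edges; self-pairs (d = 0) sit
        # at the zero edge and cancel out of every bin difference
        cum = tree_r.count_neighbors(tree_t, edges)
        hist += np.diff(cum)
    rho = target.size / box.volume
    shell = 4.0 * np.pi * centers**2 * bin_width
    with np.errstate(divide="ignore", invalid="ignore"):
        g = hist / (len(frames) * reference.size * rho * shell)
    g[~np.isfinite(g)] = 0.0
    return RDF(
        r_centers=centers, g=g, pair_spec=pair_spec, bin_width=bin_width, r_max=r_max
    )


def first_minimum(curve: RDF, smooth: bool = True) -> float:
    """Bin centre of the first strict local minimum after the first maximum.

    Optionally applies a 3-bin moving average first (default on) to keep
    counting noise from producing spurious extrema.
    """
    g = np.asarray(curve.g, dtype=float)
    r = np.asarray(curve.r_centers, dtype=float)
    if smooth and g.size >= 3:
        g = np.convolve(g, np.ones(3) / 3.0, mode="same")
    imax = None
    for i in range(1, g.size - 1):
        if g[i] > g[i - 1] and g[i] >= g[i + 1]:
            imax = i
            break
    if imax is None:
        raise ValueError("no interior maximum: g(r) is monotone")
    for i in range(imax + 1, g.size - 1):
        if g[i] < g[i - 1] and g[i] < g[i + 1]:
            return float(r[i])
    raise ValueError("no interior minimum after the first maximum")
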