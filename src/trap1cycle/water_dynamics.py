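"""Pocket-water occupancy and residence-time analysis for MD trajectories.

Given frames of water-oxygen and ATP-pocket ("site") atom coordinates, this
module counts the waters within a cutoff (default 5 Å, strict ``<``) of each
pocket's β/γ-phosphate atoms per frame, histograms the per-frame counts per
protomer (buckled vs straight), and computes per-water fractional residence
and longest contiguous dwell times, optionally after rigid Kabsch alignment
of every frame on the ATP site atoms.  Waters are identified by their oxygen
only; hydrogens are ignored throughout.

Distances use a k-d tree; an optional orthorhombic box enables the periodic
minimum-image convention.  Counting itself is invariant under rigid motion —
alignment matters only for positional density maps.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

ROLE_WATER = "water_oxygen"
ROLE_SITE = "site_atom"


@dataclass
class TrajectoryFrames:
    """Per-frame coordinates with a fixed atom table and frame times (ns).

    ``atoms`` columns: ``id`` (unique), ``role`` (``water_oxygen`` |
    ``site_atom`` | ``other``) and ``site`` (site label for site atoms,
    e.g. ``"buckled"`` / ``"straight"``; empty otherwise).
    """

    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    atoms: pd.DataFrame
    times: np.ndarray  # ns, strictly increasing
    box: Optional[np.ndarray] = None  # (3,) orthorhombic box lengths, Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("one frame time per frame required")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom table must match the coordinate array")
        for col in ("id", "role"):
            if col not in self.atoms.columns:
                raise ValueError(f"atom table must have a {col!r} column")
        if "site" not in self.atoms.columns:
            self.atoms = self.atoms.assign(site="")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive orthorhombic lengths")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def water_indices(self) -> np.ndarray:
        return np.flatnonzero((self.atoms["role"] == ROLE_WATER).to_numpy())

    def site_indices(self, site: str) -> np.ndarray:
        mask = (self.atoms["role"] == ROLE_SITE) & (self.atoms["site"] == site)
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) == 0:
            raise ValueError(f"no site atoms labeled {site!r}")
        return idx

    def site_labels(self) -> list:
        mask = self.atoms["role"] == ROLE_SITE
        return sorted(self.atoms.loc[mask, "site"].unique())

    def frame_interval(self) -> float:
        dt = np.diff(self.times)
        if len(dt) == 0:
            raise ValueError("need >= 2 frames")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            warnings.warn("non-uniform frame spacing; dwell times use actual timestamps")
        return float(np.mean(dt))


@dataclass
class OccupancyHistogram:
    site: str
    counts: dict  # water count per frame -> number of frames
    n_frames: int
    cutoff: float

    @property
    def mean(self) -> float:
        total = sum(self.counts.values())
        return sum(k * v for k, v in self.counts.items()) / total


def kabsch_align(traj: TrajectoryFrames, reference_indices) -> tuple:
    """Rigid-body align every frame onto frame 0 using the given atom selection.

    Returns (aligned trajectory, per-frame RMSD of the selection).  The
    optimal rotation is proper (no reflection, no scaling); a degenerate
    (collinear) selection is rejected.
    """
    ref_idx = np.asarray(reference_indices, dtype=int)
    if len(ref_idx) < 3:
        raise ValueError("need at least 3 reference atoms for alignment")
    ref = traj.coords[0, ref_idx]
    ref_centroid = ref.mean(axis=0)
    ref_c = ref - ref_centroid
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("reference selection is collinear/degenerate")
    out = np.empty_like(traj.coords)
    rmsd = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.coords[f, ref_idx]
        mob_centroid = mob.mean(axis=0)
        rot, rssd = Rotation.align_vectors(ref_c, mob - mob_centroid)
        out[f] = rot.apply(traj.coords[f] - mob_centroid) + ref_centroid
        rmsd[f] = rssd / np.sqrt(len(ref_idx))
    aligned = TrajectoryFrames(out, traj.atoms.copy(), traj.times.copy(), box=None)
    return aligned, rmsd


def _min_distances(
    waters: np.ndarray, site_atoms: np.ndarray, box: Optional[np.ndarray]
) -> np.ndarray:
    """Minimum distance from each water oxygen to any site atom."""
    if len(waters) == 0:
        return np.empty(0)
    if box is not None:
        tree = cKDTree(np.mod(site_atoms, box), boxsize=box)
        d, _ = tree.query(np.mod(waters, box), k=1)
    else:
        tree = cKDTree(site_atoms)
        d, _ = tree.query(waters, k=1)
    return d


def count_waters_within(
    frame_coords: np.ndarray,
    water_indices,
    site_indices,
    cutoff: float = 5.0,
    box: Optional[np.ndarray] = None,
    boundary: str = "strict",
) -> int:
    """Count distinct water oxygens within ``cutoff`` of any site atom.

    ``boundary='strict'`` counts distances ``< cutoff`` (a water at exactly
    the cutoff is not counted); ``'inclusive'`` uses ``<=``.
    """
    if boundary not in ("strict", "inclusive"):
        raise ValueError("boundary must be 'strict' or 'inclusive'")
    wi = np.asarray(water_indices, dtype=int)
    si = np.asarray(site_indices, dtype=int)
    if len(si) == 0:
        raise ValueError("site atom selection is empty")
    d = _min_distances(frame_coords[wi], frame_coords[si], box)
    return int(np.sum(d < cutoff if boundary == "strict" else d <= cutoff))


def in_cutoff_mask(
    traj: TrajectoryFrames,
    site: str,
    cutoff: float = 5.0,
    boundary: str = "strict",
) -> np.ndarray:
    """Boolean (n_frames, n_waters) matrix: water within cutoff of the site."""
    wi = traj.water_indices()
    si = traj.site_indices(site)
    mask = np.zeros((traj.n_frames, len(wi)), dtype=bool)
    for f in range(traj.n_frames):
        d = _min_distances(traj.coords[f, wi], traj.coords[f, si], traj.box)
        mask[f] = d < cutoff if boundary == "strict" else d <= cutoff
    return mask


def occupancy_histogram(
    traj: TrajectoryFrames,
    site: str,
    cutoff: float = 5.0,
    boundary: str = "strict",
) -> OccupancyHistogram:
    """Histogram of per-frame water counts near one pocket."""
    mask = in_cutoff_mask(traj, site, cutoff, boundary)
    per_frame = mask.sum(axis=1)
    return OccupancyHistogram(site, dict(Counter(per_frame.tolist())), traj.n_frames, cutoff)


def compare_site_occupancy(
    traj: TrajectoryFrames,
    site_a: str,
    site_b: str,
    cutoff: float = 5.0,
    n_boot: int = 500,
    seed: int = 0,
    boundary: str = "strict",
) -> dict:
    """Difference of mean per-frame water counts between two pockets.

    Returns the two means, their difference (a - b) and a bootstrap
    percentile interval obtained by resampling frames.
    """
    counts_a = in_cutoff_mask(traj, site_a, cutoff, boundary).sum(axis=1)
    counts_b = in_cutoff_mask(traj, site_b, cutoff, boundary).sum(axis=1)
    rng = np.random.default_rng(seed)
    n = traj.n_frames
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[i] = counts_a[idx].mean() - counts_b[idx].mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "mean_a": float(counts_a.mean()),
        "mean_b": float(counts_b.mean()),
        "difference": float(counts_a.mean() - counts_b.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "site_a": site_a,
        "site_b": site_b,
    }


def _runs(in_site: np.ndarray, gap_tolerance: int):
    """Contiguous in-site runs as (start, stop) index pairs, merging runs
    separated by at most ``gap_tolerance`` out-of-site frames."""
    idx = np.flatnonzero(in_site)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 > gap_tolerance:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    return runs


def residence_profile(
    traj: TrajectoryFrames,
    site: str,
    cutoff: float = 5.0,
    gap_tolerance_frames: int = 0,
    class_thresholds: tuple = (0.1, 0.5),
    boundary: str = "strict",
) -> pd.DataFrame:
    """Per-water fractional residence and longest dwell near one pocket.

    Fractional residence is the fraction of frames the water spends within
    the cutoff.  The longest dwell is the maximal contiguous in-cutoff
    stretch (each frame counts one frame interval of time; runs may bridge
    up to ``gap_tolerance_frames`` out-of-cutoff frames), capped at the
    trajectory span.  ``class_thresholds`` split fractional residence into
    short/medium/long reporting classes.
    """
    if traj.n_frames < 2:
        raise ValueError("residence analysis needs >= 2 frames")
    mask = in_cutoff_mask(traj, site, cutoff, boundary)
    dt = traj.frame_interval()
    span = float(traj.times[-1] - traj.times[0])
    wi = traj.water_indices()
    ids = traj.atoms["id"].to_numpy()[wi]
    lo, hi = class_thresholds
    rows = []
    for w in range(mask.shape[1]):
        col = mask[:, w]
        frac = float(col.mean())
        runs = _runs(col, gap_tolerance_frames)
        if runs:
            longest = max(
                min(traj.times[b] - traj.times[a] + dt, span) for a, b in runs
            )
        else:
            longest = 0.0
        klass = "short" if frac < lo else ("medium" if frac < hi else "long")
        rows.append(
            {
                "water_id": ids[w],
                "fractional_residence": frac,
                "longest_dwell_ns": float(longest),
                "n_visits": len(runs),
                "residence_class": klass,
            }
        )
    return pd.DataFrame(rows)


def positional_density(
    traj: TrajectoryFrames,
    site: str,
    cutoff: float = 5.0,
    class_thresholds: tuple = (0.1, 0.5),
    boundary: str = "strict",
) -> pd.DataFrame:
    """Mean in-cutoff position and residence class per qualifying water.

    Meant to be run on an aligned trajectory: the rows are the dot cloud of
    pocket waters in the common (ATP-aligned) frame.
    """
    mask = in_cutoff_mask(traj, site, cutoff, boundary)
    wi = traj.water_indices()
    ids = traj.atoms["id"].to_numpy()[wi]
    lo, hi = class_thresholds
    rows = []
    for w in range(mask.shape[1]):
        sel = mask[:, w]
        if not sel.any():
            continue
        mean_pos = traj.coords[sel][:, wi[w], :].mean(axis=0)
        frac = float(sel.mean())
        klass = "short" if frac < lo else ("medium" if frac < hi else "long")
        rows.append(
            {
                "water_id": ids[w],
                "x": mean_pos[0],
                "y": mean_pos[1],
                "z": mean_pos[2],
                "fractional_residence": frac,
                "residence_class": klass,
            }
        )
    return pd.DataFrame(rows)
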