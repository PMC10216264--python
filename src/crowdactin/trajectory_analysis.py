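"""Monomer-near-filament trajectory analysis.

Implements the three observables used to characterise the dynamics of an
actin monomer (G-actin) diffusing near the barbed end of a short
filament:

* the mean square displacement (MSD) of a Cα selection, referenced to
  the first frame of the trajectory,
* the diffusion coefficient derived from the MSD through the
  Stokes–Einstein relation for three-dimensional diffusion,
  ``MSD(t) = 6 D t``,
* the filament–monomer inter-distance change ``ΔL(t) = l(t) − l(0)``,
  where ``l`` is the centroid-to-centroid distance between the filament
  barbed end and the monomer (negative values mean the monomer
  approached the filament).

Trajectories are short (nanoseconds) single realisations, so the default
MSD is the literal frame-0-referenced average over selected atoms; a
lag-averaged (time-origin averaged) variant is available for diffusion
estimation, where it is statistically much better behaved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .units import convert_diffusion_units

__all__ = [
    "Trajectory",
    "MSDSeries",
    "DiffusionEstimate",
    "InterDistanceSeries",
    "compute_msd",
    "estimate_diffusion",
    "compute_inter_distance",
    "convert_diffusion_units",
    "barbed_end_group",
]


@dataclass
class Trajectory:
    """Time-stamped coordinates for labeled atom groups.

    Parameters
    ----------
    frame_times:
        Frame times in ns, uniformly spaced, length ``F``.
    coords:
        Coordinates in Å, shape ``(F, N, 3)``.
    group_ids:
        Per-atom group label, length ``N`` (e.g. ``F1``..``F5`` for
        filament subunits and ``G`` for the monomer).
    atom_names:
        Per-atom name, length ``N`` (``CA`` for Cα records).
    """

    frame_times: np.ndarray
    coords: np.ndarray
    group_ids: np.ndarray
    atom_names: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.group_ids = np.asarray(self.group_ids, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        if self.frame_times.ndim != 1 or self.frame_times.size < 2:
            raise ValueError("trajectory needs at least 2 frames")
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != self.frame_times.size:
            raise ValueError(
                f"coords has {self.coords.shape[0]} frames but "
                f"frame_times has {self.frame_times.size}"
            )
        if self.coords.shape[1] != self.group_ids.size or self.coords.shape[1] != self.atom_names.size:
            raise ValueError("group_ids/atom_names length must match atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        dts = np.diff(self.frame_times)
        if np.any(dts <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
            raise ValueError("frame times must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def time_step(self) -> float:
        """Frame interval in ns."""
        return float(self.frame_times[1] - self.frame_times[0])

    @property
    def group_names(self) -> list[str]:
        """Group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.group_ids:
            seen.setdefault(str(g), None)
        return list(seen)

    def select(self, selection: str) -> np.ndarray:
        """Resolve an atom selection to an index array.

        Selection syntax: ``"G"`` (all atoms of group G),
        ``"G:CA"`` (Cα atoms of G), ``"F1,F2:CA"`` (Cα of F1 and F2).
        """
        sel = selection.strip()
        if not sel:
            raise ValueError("empty selection")
        if ":" in sel:
            group_part, name_part = sel.split(":", 1)
            name_filter = name_part.strip() or None
        else:
            group_part, name_filter = sel, None
        groups = [g.strip() for g in group_part.split(",") if g.strip()]
        if not groups:
            raise ValueError("empty selection")
        known = set(self.group_names)
        unknown = [g for g in groups if g not in known]
        if unknown:
            raise ValueError(
                f"unknown group(s) {unknown} in selection {selection!r}; "
                f"available: {sorted(known)}"
            )
        mask = np.isin(self.group_ids.astype(str), groups)
        if name_filter is not None:
            mask &= self.atom_names.astype(str) == name_filter
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"selection {selection!r} matches no atoms")
        return idx


@dataclass
class MSDSeries:
    """MSD curve in Å² against time (or lag time) in ns."""

    times: np.ndarray
    msd: np.ndarray
    atom_selection: str
    n_atoms_averaged: int
    lag_averaged: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if self.times.shape != self.msd.shape:
            raise ValueError("times and msd must have the same length")
        if self.msd.size and abs(self.msd[0]) > 1e-9:
            raise ValueError("msd must vanish at the reference time")
        if np.any(self.msd < -1e-12):
            raise ValueError("msd must be non-negative")


@dataclass
class DiffusionEstimate:
    """Diffusion coefficient in µm²/s with fit diagnostics."""

    D: float
    method: str
    fit_window: tuple[float, float]
    fit_r2: float
    per_time_D: np.ndarray | None = None
    clamped: bool = False
    stderr: float = float("nan")


@dataclass
class InterDistanceSeries:
    """Signed filament–monomer distance change ΔL(t) in Å."""

    times: np.ndarray
    delta_L: np.ndarray
    l0: float
    filament_selection: str
    monomer_selection: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta_L = np.asarray(self.delta_L, dtype=float)
        if self.times.shape != self.delta_L.shape:
            raise ValueError("times and delta_L must have the same length")
        if abs(self.delta_L[0]) > 1e-9:
            raise ValueError("delta_L must vanish at frame 0")
        if not self.l0 > 0:
            raise ValueError("initial separation l0 must be positive")


def compute_msd(
    traj: Trajectory,
    selection: str,
    *,
    lag_averaged: bool = False,
    max_lag: int | None = None,
) -> MSDSeries:
    """Mean square displacement of an atom selection.

    Default (``lag_averaged=False``): for each frame ``t``,
    ``msd(t) = mean_i |r_i(t) − r_i(0)|²`` over the selected atoms — the
    displacement from the *first frame*, with no averaging over time
    origins.  This is the estimator appropriate for asking "where did
    the monomer end up relative to where it started" on a single short
    trajectory.

    ``lag_averaged=True`` additionally averages over all time origins at
    each lag (up to ``max_lag`` frames, default a quarter of the
    trajectory); the returned ``times`` are then lag times.  Use this
    variant when feeding :func:`estimate_diffusion` — time-origin
    averaging is what makes a single-trajectory diffusion estimate
    statistically stable.
    """
    idx = traj.select(selection)
    sub = traj.coords[:, idx, :]  # (F, n, 3)
    if not lag_averaged:
        disp = sub - sub[0]
        msd = np.mean(np.sum(disp * disp, axis=2), axis=1)
        times = traj.frame_times - traj.frame_times[0]
    else:
        n_frames = traj.n_frames
        if max_lag is None:
            max_lag = max(1, n_frames // 4)
        if not 1 <= max_lag < n_frames:
            raise ValueError(f"max_lag must be in [1, {n_frames - 1}]")
        msd = np.zeros(max_lag + 1)
        for lag in range(1, max_lag + 1):
            d = sub[lag:] - sub[:-lag]
            msd[lag] = np.mean(np.sum(d * d, axis=2))
        times = np.arange(max_lag + 1) * traj.time_step
    return MSDSeries(
        times=times,
        msd=msd,
        atom_selection=selection,
        n_atoms_averaged=int(idx.size),
        lag_averaged=lag_averaged,
    )


def estimate_diffusion(
    msd: MSDSeries,
    method: str = "linear-fit",
    fit_window: tuple[float, float] | None = None,
) -> DiffusionEstimate:
    """Diffusion coefficient from an MSD curve via ``MSD = 6 D t``.

    ``method="pointwise"``: ``D(t) = msd(t) / (6 t)`` for every ``t > 0``;
    the headline ``D`` is the value at the final time.
    ``method="linear-fit"`` (default): ``D`` is the least-squares slope of
    msd versus time over ``fit_window`` divided by 6.  The default window
    is the final 50% of the series, skipping the initial regime.

    The result is converted from the trajectory's native Å²/ns to µm²/s.
    A negative fitted slope is clamped to ``D = 0`` with ``clamped=True``.
    """
    t = msd.times
    y = msd.msd
    if np.all(t == 0):
        raise ValueError("MSD series has all-zero times")
    if fit_window is None:
        fit_window = (float(t[0] + (t[-1] - t[0]) / 2.0), float(t[-1]))
    lo, hi = fit_window
    if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
        raise ValueError(f"fit_window {fit_window} outside series range ({t[0]}, {t[-1]})")

    if method == "pointwise":
        with np.errstate(divide="ignore", invalid="ignore"):
            per_time = np.where(t > 0, y / (6.0 * t), np.nan)
        per_time_um2s = convert_diffusion_units(1.0, "A2/ns", "um2/s") * per_time
        headline = float(per_time_um2s[-1])
        clamped = headline < 0
        return DiffusionEstimate(
            D=max(headline, 0.0),
            method="pointwise-at-final-time",
            fit_window=(float(t[0]), float(t[-1])),
            fit_r2=float("nan"),
            per_time_D=per_time_um2s,
            clamped=clamped,
        )
    if method != "linear-fit":
        raise ValueError(f"unknown method {method!r}")

    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    if int(mask.sum()) < 3:
        raise ValueError("need at least 3 MSD points inside fit_window")
    res = stats.linregress(t[mask], y[mask])
    d_ang2_ns = res.slope / 6.0
    d_um2_s = convert_diffusion_units(d_ang2_ns, "A2/ns", "um2/s")
    clamped = d_um2_s < 0
    return DiffusionEstimate(
        D=max(d_um2_s, 0.0),
        method="linear-fit",
        fit_window=(float(lo), float(hi)),
        fit_r2=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
        clamped=clamped,
        stderr=convert_diffusion_units(res.stderr / 6.0, "A2/ns", "um2/s"),
    )


def barbed_end_group(
    traj: Trajectory,
    monomer_sel: str = "G",
    n_subunits: int = 1,
) -> str:
    """Filament selection for the barbed end: the subunit group(s)
    whose frame-0 centroid lies nearest the monomer.

    ``n_subunits=2`` selects the two nearest terminal subunits instead
    of one; returns a selection string usable with :meth:`Trajectory.select`.
    """
    mono_idx = traj.select(monomer_sel)
    mono_groups = {str(g) for g in traj.group_ids[mono_idx]}
    candidates = [g for g in traj.group_names if g not in mono_groups]
    if not candidates:
        raise ValueError("no filament groups distinct from the monomer selection")
    mono_c = traj.coords[0, mono_idx].mean(axis=0)
    dists = []
    for g in candidates:
        gi = traj.select(g)
        dists.append(np.linalg.norm(traj.coords[0, gi].mean(axis=0) - mono_c))
    order = np.argsort(dists)
    chosen = [candidates[i] for i in order[:n_subunits]]
    return ",".join(chosen)


def compute_inter_distance(
    traj: Trajectory,
    filament_sel: str | None,
    monomer_sel: str = "G",
    *,
    mass_weighted: bool = False,
    masses: Sequence[float] | None = None,
) -> InterDistanceSeries:
    """Filament–monomer centroid distance change ΔL(t) = l(t) − l(0).

    ``l(t)`` is the Euclidean distance between the centroid of the
    filament barbed-end selection and the centroid of the monomer
    selection at frame ``t``.  If ``filament_sel`` is None the barbed
    end defaults to the terminal subunit group nearest the monomer.
    Centroids are unweighted by default (for Cα-only selections
    mass-weighting is nearly equivalent); pass per-atom ``masses`` with
    ``mass_weighted=True`` otherwise.
    """
    if filament_sel is None:
        filament_sel = barbed_end_group(traj, monomer_sel)
    fil_idx = traj.select(filament_sel)
    mono_idx = traj.select(monomer_sel)
    if np.intersect1d(fil_idx, mono_idx).size:
        raise ValueError("filament and monomer selections overlap")

    def centroid(frame_coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
        pts = frame_coords[idx]
        if mass_weighted:
            if masses is None:
                raise ValueError("mass_weighted=True requires masses")
            w = np.asarray(masses, dtype=float)[idx]
            return (pts * w[:, None]).sum(axis=0) / w.sum()
        return pts.mean(axis=0)

    ls = np.array(
        [
            np.linalg.norm(centroid(fr, fil_idx) - centroid(fr, mono_idx))
            for fr in traj.coords
        ]
    )
    l0 = float(ls[0])
    return InterDistanceSeries(
        times=traj.frame_times - traj.frame_times[0],
        delta_L=ls - l0,
        l0=l0,
        filament_selection=filament_sel,
        monomer_selection=monomer_sel,
    )
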