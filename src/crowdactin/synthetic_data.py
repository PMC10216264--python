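"""Seeded synthetic inputs for every analysis stage.

The experimental raw data behind the analyses — equilibrium molecular
trajectories of a monomer near a filament barbed end, TIRF timelapse
movies of single growing filaments, and plate-reader pyrene
fluorescence curves — are not deposited anywhere.  This module
generates statistically faithful stand-ins:

* :func:`simulate_monomer_trajectory` — a five-subunit filament held
  static plus a monomer undergoing rigid-body Brownian motion with
  optional drift, at MD-like scales (Å, ns; default 5 ns duration and
  a 15 Å axial offset of the monomer from the barbed end).
* :func:`simulate_filament_timelapse` — a filament growing at a
  constant nm/s rate, rendered frame by frame at TIRF-like scales
  (0.07 µm/pixel, 1 s frame interval) with a Gaussian PSF and additive
  Gaussian noise, returned together with the ground-truth length track.
* :func:`simulate_pyrene_timecourse` — a logistic (sigmoidal)
  polymerization curve sampled every 10 s over 2 h, preceded by a
  5 min pre-polymerization baseline.
* :func:`generate_point_charge_complex` — small point-charge systems
  (complex = exact union of filament part and monomer part) for
  exercising the solvation-energy combination.

Every generator is a pure function of its parameters including the
seed: identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .electrostatics import PointChargeSystem
from .trajectory_analysis import Trajectory
from .units import ANG2_PER_NS_TO_UM2_PER_S

__all__ = [
    "BrownianParams",
    "GrowthParams",
    "PyreneParams",
    "TimelapseStack",
    "FluorescenceTimeSeries",
    "simulate_monomer_trajectory",
    "simulate_filament_timelapse",
    "simulate_pyrene_timecourse",
    "generate_point_charge_complex",
]

#: Axial spacing between consecutive filament subunit centers, Å.
SUBUNIT_SPACING_ANG = 27.5


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class BrownianParams:
    """Parameters of the monomer-near-filament Brownian generator.

    ``diffusion_coefficient`` is in µm²/s (the unit diffusion tables are
    printed in; 1 Å²/ns = 10 µm²/s internally), ``time_step`` in ns,
    ``drift_velocity`` in Å/ns, ``initial_offset`` in Å along the
    filament axis beyond the barbed-end subunit.
    """

    diffusion_coefficient: float = 5.36
    time_step: float = 0.01
    n_steps: int = 500
    drift_velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)
    initial_offset: float = 15.0
    n_monomer_atoms: int = 8
    n_filament_subunits: int = 5
    atoms_per_subunit: int = 4
    filament_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        drift = np.asarray(self.drift_velocity, dtype=float)
        _require(drift.shape == (3,), "drift_velocity must be a 3-vector")
        _require(np.all(np.isfinite(drift)), "drift_velocity must be finite")
        for name in ("diffusion_coefficient", "time_step", "initial_offset", "filament_jitter_sd"):
            v = getattr(self, name)
            _require(np.isfinite(v), f"{name} must be finite")
        _require(self.time_step > 0, "time_step must be positive")
        _require(self.n_steps >= 1, "n_steps must be at least 1")
        _require(self.diffusion_coefficient >= 0, "diffusion_coefficient must be non-negative")
        _require(self.initial_offset >= 0, "initial_offset must be non-negative")
        _require(self.filament_jitter_sd >= 0, "filament_jitter_sd must be non-negative")
        _require(self.n_monomer_atoms >= 1, "n_monomer_atoms must be at least 1")
        _require(self.n_filament_subunits >= 1, "need at least one filament subunit")
        _require(self.atoms_per_subunit >= 1, "atoms_per_subunit must be at least 1")


@dataclass
class GrowthParams:
    """Parameters of the growing-filament timelapse generator.

    ``elongation_rate`` nm/s (may be 0), ``initial_length`` µm,
    ``pixel_size`` µm/pixel, ``psf_sigma`` pixels, ``noise_sd`` in
    units of the filament peak intensity (1.0).
    """

    elongation_rate: float = 35.9
    initial_length: float = 0.5
    frame_interval: float = 1.0
    duration: float = 120.0
    pixel_size: float = 0.07
    psf_sigma: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("elongation_rate", "initial_length", "frame_interval",
                     "duration", "pixel_size", "psf_sigma", "noise_sd"):
            _require(np.isfinite(getattr(self, name)), f"{name} must be finite")
        _require(self.frame_interval > 0, "frame_interval must be positive")
        _require(self.duration >= self.frame_interval,
                 "duration must cover at least one frame interval")
        _require(self.pixel_size > 0, "pixel_size must be positive")
        _require(self.initial_length >= 0, "initial_length must be non-negative")
        _require(self.psf_sigma >= 0, "psf_sigma must be non-negative")
        _require(self.noise_sd >= 0, "noise_sd must be non-negative")


@dataclass
class PyreneParams:
    """Parameters of the sigmoidal pyrene-fluorescence generator.

    The post-baseline signal is
    ``baseline_level + amplitude / (1 + exp(−rate_constant·(t − half_time)))``,
    a logistic whose maximum slope ``amplitude·rate_constant/4`` occurs
    at ``half_time``.
    """

    baseline_level: float = 100.0
    amplitude: float = 1000.0
    rate_constant: float = 0.005
    half_time: float = 2400.0
    noise_sd: float = 0.0
    baseline_duration: float = 300.0
    sampling_interval: float = 10.0
    total_duration: float = 7200.0
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("baseline_level", "amplitude", "rate_constant", "half_time",
                     "noise_sd", "baseline_duration", "sampling_interval", "total_duration"):
            _require(np.isfinite(getattr(self, name)), f"{name} must be finite")
        _require(self.sampling_interval > 0, "sampling_interval must be positive")
        _require(self.baseline_duration >= 0, "baseline_duration must be non-negative")
        _require(self.amplitude > 0, "amplitude must be positive")
        _require(self.total_duration > self.baseline_duration,
                 "total_duration must exceed baseline_duration")
        _require(self.noise_sd >= 0, "noise_sd must be non-negative")
        if self.half_time <= self.baseline_duration:
            raise ValueError(
                "half_time must exceed baseline_duration "
                "(the fluorescence rise cannot precede polymerization start)"
            )


@dataclass
class TimelapseStack:
    """Rendered timelapse: frames (T, H, W), µm/pixel, s/frame."""

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    line_row: int

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_frames, height, width)")
        if self.frames.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) * self.frame_interval


@dataclass
class FluorescenceTimeSeries:
    """Uniformly sampled fluorescence trace with a marked polymerization start."""

    times: np.ndarray
    intensities: np.ndarray
    polymerization_start: float
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have the same length")
        if self.times.size < 2:
            raise ValueError("series needs at least 2 samples")
        dts = np.diff(self.times)
        if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must be uniformly spaced and increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensities")

    @property
    def sampling_interval(self) -> float:
        return float(self.times[1] - self.times[0])


def _unit_sphere_points(n: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    if n == 1:
        return np.zeros((1, 3))
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts - pts.mean(axis=0)  # centered: group centroid = nominal center


def simulate_monomer_trajectory(params: BrownianParams) -> Trajectory:
    """Rigid-body Brownian monomer beside a static filament.

    The filament is ``n_filament_subunits`` groups (``F1``..``Fk``) of
    Cα-like atoms stacked along +z; the barbed end is the last subunit.
    The monomer (group ``G``) starts ``initial_offset`` Å beyond the
    barbed-end subunit center along the axis and receives one shared
    Gaussian displacement per step with per-axis variance ``2·D·Δt``
    (D converted to Å²/ns) plus ``drift·Δt`` — rigid-body motion, so
    the per-atom MSD average equals the center-of-mass MSD exactly.
    """
    rng = np.random.default_rng(params.seed)
    k = params.n_filament_subunits
    # Filament template: subunit centers on the z axis, barbed end on top.
    centers = np.arange(k)[:, None] * np.array([0.0, 0.0, SUBUNIT_SPACING_ANG])
    sub_cloud = _unit_sphere_points(params.atoms_per_subunit, radius=5.0)
    fil_coords = np.concatenate([c + sub_cloud for c in centers], axis=0)
    fil_groups = [f"F{i + 1}" for i in range(k) for _ in range(params.atoms_per_subunit)]

    barbed_center = centers[-1]
    mono0 = barbed_center + np.array([0.0, 0.0, params.initial_offset]) \
        + _unit_sphere_points(params.n_monomer_atoms, radius=2.5)

    n_steps = params.n_steps
    dt = params.time_step
    d_ang2_ns = params.diffusion_coefficient / ANG2_PER_NS_TO_UM2_PER_S
    sigma = math.sqrt(2.0 * d_ang2_ns * dt)
    steps = rng.normal(0.0, sigma, size=(n_steps, 3)) if sigma > 0 else np.zeros((n_steps, 3))
    steps = steps + np.asarray(params.drift_velocity, dtype=float) * dt
    disp = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])  # (n_steps+1, 3)

    n_frames = n_steps + 1
    n_fil = fil_coords.shape[0]
    coords = np.empty((n_frames, n_fil + params.n_monomer_atoms, 3))
    coords[:, :n_fil, :] = fil_coords[None, :, :]
    if params.filament_jitter_sd > 0:
        jitter = rng.normal(0.0, params.filament_jitter_sd, size=(n_frames, n_fil, 3))
        jitter[0] = 0.0
        coords[:, :n_fil, :] += jitter
    coords[:, n_fil:, :] = mono0[None, :, :] + disp[:, None, :]

    group_ids = np.array(fil_groups + ["G"] * params.n_monomer_atoms, dtype=object)
    atom_names = np.array(["CA"] * (n_fil + params.n_monomer_atoms), dtype=object)
    return Trajectory(
        frame_times=np.arange(n_frames) * dt,
        coords=coords,
        group_ids=group_ids,
        atom_names=atom_names,
    )


def simulate_filament_timelapse(params: GrowthParams):
    """Constant-rate filament growth rendered as a timelapse stack.

    True lengths follow ``L(t) = initial_length + rate·t`` (rate
    converted from nm/s to µm/s).  Each frame draws the filament as a
    one-pixel-wide horizontal segment from a fixed anchor column
    (mimicking a surface-anchored filament end) with sub-pixel endpoint
    coverage, convolves with a Gaussian PSF and adds Gaussian noise.

    Returns ``(track, stack)`` where ``track`` is the noiseless truth
    (a :class:`~crowdactin.elongation_analysis.FilamentTrack`) and
    ``stack`` the rendered :class:`TimelapseStack`.
    """
    from .elongation_analysis import FilamentTrack  # deferred: avoids import cycle

    rng = np.random.default_rng(params.seed)
    n_frames = int(math.floor(params.duration / params.frame_interval)) + 1
    times = np.arange(n_frames) * params.frame_interval
    lengths_um = params.initial_length + params.elongation_rate * 1e-3 * times

    anchor_px = 4
    margin_px = 6
    max_len_px = lengths_um[-1] / params.pixel_size
    width = int(math.ceil(anchor_px + max_len_px + margin_px + 4 * params.psf_sigma))
    height = 9
    row = height // 2

    frames = np.zeros((n_frames, height, width))
    cols = np.arange(width, dtype=float)
    for i, L in enumerate(lengths_um):
        end_px = anchor_px + L / params.pixel_size
        # coverage fraction of each pixel by the segment [anchor_px, end_px)
        coverage = np.clip(end_px - cols, 0.0, 1.0)
        coverage[cols < anchor_px] = 0.0
        frames[i, row, :] = coverage
    if params.psf_sigma > 0:
        frames = ndimage.gaussian_filter(frames, sigma=(0.0, params.psf_sigma, params.psf_sigma))
    # normalize so the blurred filament peak is 1: noise_sd is then a true
    # fraction of the signal amplitude
    peak = frames.max()
    if peak > 0:
        frames = frames / peak
    if params.noise_sd > 0:
        frames = frames + rng.normal(0.0, params.noise_sd, size=frames.shape)

    track = FilamentTrack(times=times, lengths=lengths_um, source="truth",
                          filament_id=f"synthetic-rate-{params.elongation_rate}")
    stack = TimelapseStack(frames=frames, pixel_size=params.pixel_size,
                           frame_interval=params.frame_interval, line_row=row)
    return track, stack


def simulate_pyrene_timecourse(params: PyreneParams) -> FluorescenceTimeSeries:
    """Sigmoidal pyrene polymerization curve with a flat pre-baseline.

    Samples ``floor(total_duration / sampling_interval) + 1`` points
    starting at t = 0.  Before ``baseline_duration`` the signal is
    ``baseline_level``; afterwards a logistic rise is superimposed.
    ``polymerization_start`` is recorded on the returned series.
    """
    n = int(math.floor(params.total_duration / params.sampling_interval)) + 1
    times = np.arange(n) * params.sampling_interval
    signal = np.full(n, params.baseline_level, dtype=float)
    post = times >= params.baseline_duration
    z = params.rate_constant * (times[post] - params.half_time)
    signal[post] += params.amplitude / (1.0 + np.exp(-z))
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        signal = signal + rng.normal(0.0, params.noise_sd, size=n)
    return FluorescenceTimeSeries(
        times=times,
        intensities=signal,
        polymerization_start=params.baseline_duration,
        label=params.label,
    )


def generate_point_charge_complex(
    n_filament_charges: int,
    n_monomer_charges: int,
    box: float,
    seed: int = 0,
    *,
    separation: float = 0.0,
    min_distance: float = 0.5,
) -> tuple[PointChargeSystem, PointChargeSystem, PointChargeSystem]:
    """Random point-charge complex plus its two isolated parts.

    Filament charges are drawn uniformly in a cubic box of edge ``box``
    Å centered at the origin; monomer charges in an identical box whose
    center is shifted by ``box + separation`` along +x (so the parts
    never interpenetrate and ``separation`` directly controls the gap).
    Charges are ±1 e at random.  The complex is the exact union of the
    parts — same positions, same charges — so its interaction energy
    reduces to the inter-part cross-term.

    Returns ``(complex, filament_alone, monomer_alone)``.
    """
    if n_filament_charges < 1 or n_monomer_charges < 1:
        raise ValueError("charge counts must be at least 1")
    if box <= 0:
        raise ValueError("box edge must be positive")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)

    def sample_cloud(n: int, center: np.ndarray) -> np.ndarray:
        pts = np.empty((0, 3))
        while pts.shape[0] < n:
            cand = rng.uniform(-box / 2, box / 2, size=(n, 3)) + center
            pts = np.vstack([pts, cand])
            # enforce the hard minimum pair distance by greedy rejection
            keep: list[np.ndarray] = []
            for p in pts:
                if all(np.linalg.norm(p - q) >= min_distance for q in keep):
                    keep.append(p)
            pts = np.array(keep)
        return pts[:n]

    fil_pos = sample_cloud(n_filament_charges, np.zeros(3))
    mono_center = np.array([box + separation, 0.0, 0.0])
    mono_pos = sample_cloud(n_monomer_charges, mono_center)
    fil_q = rng.choice([-1.0, 1.0], size=n_filament_charges)
    mono_q = rng.choice([-1.0, 1.0], size=n_monomer_charges)

    filament = PointChargeSystem(positions=fil_pos, charges=fil_q, label="filament")
    monomer = PointChargeSystem(positions=mono_pos, charges=mono_q, label="monomer")
    complex_sys = PointChargeSystem(
        positions=np.vstack([fil_pos, mono_pos]),
        charges=np.concatenate([fil_q, mono_q]),
        label="complex",
    )
    return complex_sys, filament, monomer
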