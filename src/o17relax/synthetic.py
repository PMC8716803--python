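"""Synthetic phantom and rat-brain generators with known ground truth.

The two study designs emulated here:

* a cylindrical phantom with 13 holes for 50-mL vials, filled across two
  layouts with 19 H₂¹⁷O concentrations from natural abundance (0.037%) to
  6.5%, plus three natural-abundance control vials per layout, imaged with
  variable-flip-angle T1, multi-echo gradient-echo T2*, and multi-echo
  turbo-spin-echo T2 protocols;
* a rat-brain dynamic series: one baseline multi-echo TSE acquisition
  followed by consecutive 3-minute series after a bolus of enriched water,
  with an immediate R2 elevation and slow mono-exponential washout.

Forward truth for the phantom is linear in concentration,
``R2(c) = a·c + b`` with a = 0.405 s⁻¹/% and b = 0.3215 s⁻¹, so every
downstream stage can be scored by parameter recovery.  T1 and T2* are
simulated concentration-independent (negative controls).  Noise is Rician —
the magnitude of a complex Gaussian perturbation — which is what magnitude
MR reconstruction produces.  All generators are reproducible given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    AcquisitionProtocol,
    FrameAxis,
    GroundTruthMaps,
    ImageSeries,
    ProtocolError,
    SequenceKind,
    ValidationError,
)

__all__ = [
    "CANONICAL_CONCENTRATIONS",
    "NATURAL_ABUNDANCE_PERCENT",
    "CALIBRATION_SLOPE",
    "CALIBRATION_INTERCEPT",
    "PhantomLayout",
    "NoiseModel",
    "RatDynamicsParams",
    "RatSimulation",
    "CapacityError",
    "tse_t2_protocol",
    "gre_t2star_protocol",
    "vfa_t1_protocol",
    "make_phantom_layout",
    "default_layout_pair",
    "true_relaxation_from_concentration",
    "phantom_ground_truth",
    "simulate_vfa_series",
    "simulate_multiecho_series",
    "add_rician_noise",
    "sigma_for_first_echo_snr",
    "simulate_rat_dynamics",
]

#: The 19 vial concentrations (% mole fraction of H₂¹⁷O), natural abundance first.
CANONICAL_CONCENTRATIONS: tuple[float, ...] = (
    0.037, 0.043, 0.045, 0.050, 0.074, 0.093, 0.145, 0.245, 0.491, 0.881,
    1.270, 1.603, 2.0, 2.5, 3.1, 3.8, 4.6, 5.5, 6.5,
)

#: Natural abundance of ¹⁷O in ordinary water (% of oxygen atoms).
NATURAL_ABUNDANCE_PERCENT = 0.037

#: Forward-truth calibration constants: R2 = slope·C + intercept (s⁻¹, C in %).
CALIBRATION_SLOPE = 0.405
CALIBRATION_INTERCEPT = 0.3215

#: Concentration-independent defaults for the non-T2 channels.
DEFAULT_T1_MS = 3000.0
DEFAULT_T2STAR_FRACTION = 0.8
DEFAULT_AMPLITUDE = 1000.0


class CapacityError(ValidationError):
    """More vials requested than the phantom has holes."""


# --------------------------------------------------------------------------
# Acquisition protocol factories (the three scanner sequences)
# --------------------------------------------------------------------------

def tse_t2_protocol(echo_spacing_ms: float = 20.0, n_echoes: int = 8,
                    matrix_shape=(96, 96, 1), series_duration_min: float | None = None,
                    ) -> AcquisitionProtocol:
    """Multi-echo turbo spin echo for T2: TR 800 ms, 8 echoes at a uniform
    spacing (default the 20-ms train: 20, 40, …, 160 ms), 1.67×1.67×5 mm."""
    echoes = tuple(echo_spacing_ms * (i + 1) for i in range(n_echoes))
    return AcquisitionProtocol(
        sequence_kind=SequenceKind.MULTIECHO_TSE,
        tr_ms=800.0,
        echo_times_ms=echoes,
        voxel_size_mm=(1.67, 1.67, 5.0),
        matrix_shape=matrix_shape,
        series_duration_min=series_duration_min,
    )


def gre_t2star_protocol(matrix_shape=(96, 96, 13)) -> AcquisitionProtocol:
    """Multi-echo gradient echo for T2*: 12 echoes at 1-ms spacing, TR 13 ms,
    10° excitation, 1.88×1.88×5 mm."""
    return AcquisitionProtocol(
        sequence_kind=SequenceKind.MULTIECHO_GRE,
        tr_ms=13.0,
        echo_times_ms=tuple(float(i) for i in range(1, 13)),
        voxel_size_mm=(1.88, 1.88, 5.0),
        matrix_shape=matrix_shape,
    )


def vfa_t1_protocol(matrix_shape=(192, 192, 15)) -> AcquisitionProtocol:
    """Variable-flip-angle spoiled gradient echo for T1: TR 14 ms, flip
    angles 5°, 10°, 15°, 20°, 45°, 1.88×1.88×5 mm."""
    return AcquisitionProtocol(
        sequence_kind=SequenceKind.VFA_SPGR,
        tr_ms=14.0,
        flip_angles_deg=(5.0, 10.0, 15.0, 20.0, 45.0),
        voxel_size_mm=(1.88, 1.88, 5.0),
        matrix_shape=matrix_shape,
    )


# --------------------------------------------------------------------------
# Phantom layout
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomLayout:
    """Hole geometry and vial→concentration assignment for one phantom.

    The hole template is one central hole plus a ring of 12, all inside the
    cylinder; three holes per layout hold natural-abundance controls.
    """

    cylinder_radius_mm: float
    hole_positions_mm: tuple[tuple[float, float], ...]
    vial_radius_mm: float
    vial_assignments: tuple[tuple[int, float], ...]  # (hole index, concentration %)
    concentration_set: tuple[float, ...] = CANONICAL_CONCENTRATIONS

    def __post_init__(self) -> None:
        if len(self.hole_positions_mm) > 13:
            raise CapacityError(f"at most 13 holes, got {len(self.hole_positions_mm)}")
        if len(self.vial_assignments) > len(self.hole_positions_mm):
            raise CapacityError("more vials assigned than holes available")
        pos = np.asarray(self.hole_positions_mm, dtype=float)
        if np.any(np.hypot(pos[:, 0], pos[:, 1]) + self.vial_radius_mm > self.cylinder_radius_mm):
            raise ValidationError("vials must lie fully inside the cylinder")
        d = np.hypot(pos[:, None, 0] - pos[None, :, 0], pos[:, None, 1] - pos[None, :, 1])
        np.fill_diagonal(d, np.inf)
        if np.any(d < 2 * self.vial_radius_mm):
            raise ValidationError("vials overlap")
        holes = [h for h, _ in self.vial_assignments]
        if len(set(holes)) != len(holes):
            raise ValidationError("a hole can only hold one vial")

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(c for _, c in self.vial_assignments)

    @property
    def n_controls(self) -> int:
        return sum(1 for _, c in self.vial_assignments if c == NATURAL_ABUNDANCE_PERCENT)


def _hole_template(cylinder_radius_mm: float, ring_radius_mm: float) -> tuple[tuple[float, float], ...]:
    holes = [(0.0, 0.0)]
    for k in range(12):
        ang = 2 * np.pi * k / 12
        holes.append((float(ring_radius_mm * np.cos(ang)),
                      float(ring_radius_mm * np.sin(ang))))
    return tuple(holes)


def make_phantom_layout(concentration_subset, *, cylinder_radius_mm: float = 70.0,
                        ring_radius_mm: float = 52.0, vial_radius_mm: float = 11.0,
                        ) -> PhantomLayout:
    """Build one deterministic phantom layout.

    Three control vials at natural abundance always occupy the first three
    holes; the experimental concentrations fill subsequent holes in the
    given order.  At most 10 experimental concentrations fit (13 holes minus
    3 controls).  Concentrations outside the canonical set are allowed but
    flagged with a warning.
    """
    subset = [float(c) for c in concentration_subset]
    if len(subset) > 10:
        raise CapacityError(
            f"{len(subset)} experimental concentrations exceed the 10 free holes "
            "(3 of 13 are reserved for controls)"
        )
    for c in subset:
        if not any(np.isclose(c, k) for k in CANONICAL_CONCENTRATIONS):
            warnings.warn(f"concentration {c}% is not in the canonical vial set", stacklevel=2)
    holes = _hole_template(cylinder_radius_mm, ring_radius_mm)
    assignments = [(i, NATURAL_ABUNDANCE_PERCENT) for i in range(3)]
    assignments += [(3 + j, c) for j, c in enumerate(subset)]
    return PhantomLayout(
        cylinder_radius_mm=cylinder_radius_mm,
        hole_positions_mm=holes,
        vial_radius_mm=vial_radius_mm,
        vial_assignments=tuple(assignments),
    )


def default_layout_pair(**kwargs) -> tuple[PhantomLayout, PhantomLayout]:
    """The two layouts that together cover all 19 canonical concentrations.

    Natural abundance (0.037%) appears as an experimental vial in the first
    layout; the remaining 18 concentrations are split 9/9 alternating low
    and high so both layouts span the calibration range.
    """
    rest = list(CANONICAL_CONCENTRATIONS[1:])
    a = [CANONICAL_CONCENTRATIONS[0]] + rest[0::2]   # 10 vials
    b = rest[1::2]                                   # 9 vials
    return make_phantom_layout(a, **kwargs), make_phantom_layout(b, **kwargs)


# --------------------------------------------------------------------------
# Forward truth
# --------------------------------------------------------------------------

def true_relaxation_from_concentration(
    c, *, slope: float = CALIBRATION_SLOPE, intercept: float = CALIBRATION_INTERCEPT,
    t1_ms: float = DEFAULT_T1_MS, t2star_fraction: float = DEFAULT_T2STAR_FRACTION,
    t2star_reference_percent: float = CANONICAL_CONCENTRATIONS[-1],
):
    """Ground-truth (T1, T2, T2*) in ms for a concentration ``c`` (%).

    T2 follows the linear rate model ``R2 = slope·c + intercept`` (s⁻¹),
    hence ``T2 = 1000/R2`` ms.  T1 and T2* are concentration-independent
    negative controls: T1 is saline-like (default 3000 ms) and T2* is a
    fixed fraction of the shortest in-design T2 (the T2 at
    ``t2star_reference_percent``), which keeps T2* ≤ T2 at every vial
    concentration while carrying no concentration signal of its own.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentration must be non-negative")
    r2 = slope * c + intercept
    t2 = 1000.0 / r2
    t1 = np.broadcast_to(np.asarray(t1_ms, dtype=float), t2.shape).copy()
    # keep the ordering T2 <= T1 without bending the linear R2(c) model:
    # below ~0.01% the intercept-only T2 slightly exceeds the saline T1 default
    t1 = np.maximum(t1, t2)
    t2star_const = t2star_fraction * 1000.0 / (slope * t2star_reference_percent + intercept)
    t2star = np.minimum(np.full_like(t2, t2star_const), t2)
    return t1, t2, t2star


def phantom_ground_truth(layout: PhantomLayout, protocol: AcquisitionProtocol,
                         amplitude: float = DEFAULT_AMPLITUDE) -> GroundTruthMaps:
    """Render a layout onto the protocol's voxel grid.

    Voxels whose centres fall inside a vial get that vial's concentration
    and the corresponding relaxation times; everything else (cylinder body
    and air) is signal-free.  Rendering is nearest-voxel: no partial-volume
    blending at vial edges.
    """
    nx, ny, nz = protocol.matrix_shape
    dx, dy, _ = protocol.voxel_size_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")

    conc = np.zeros((nx, ny, nz))
    amp = np.zeros((nx, ny, nz))
    t1 = np.full((nx, ny, nz), DEFAULT_T1_MS)
    t2 = np.full((nx, ny, nz), DEFAULT_T1_MS)  # placeholder outside objects
    t2s = t2 * DEFAULT_T2STAR_FRACTION

    for hole_idx, c in layout.vial_assignments:
        cx, cy = layout.hole_positions_mm[hole_idx]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= layout.vial_radius_mm ** 2
        v_t1, v_t2, v_t2s = true_relaxation_from_concentration(c)
        for z in range(nz):
            conc[:, :, z][inside] = c
            amp[:, :, z][inside] = amplitude
            t1[:, :, z][inside] = v_t1
            t2[:, :, z][inside] = v_t2
            t2s[:, :, z][inside] = v_t2s
    return GroundTruthMaps(
        true_t1=t1, true_t2=t2, true_t2star=t2s, true_amplitude=amp,
        concentration_map=conc, voxel_size_mm=protocol.voxel_size_mm,
    )


# --------------------------------------------------------------------------
# Signal models and noise
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Magnitude-image noise description.

    ``kind='rician'`` replaces each noiseless voxel value ``s`` by
    ``sqrt((s+g1)² + g2²)`` with independent zero-mean Gaussians of width
    ``sigma``; ``kind='none'`` leaves the data untouched.
    """

    kind: str = "none"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "rician"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")


def _spgr_signal(m0, t1_ms, tr_ms, flip_deg):
    """Spoiled gradient-echo steady state:
    ``M0·sinθ·(1−E1)/(1−cosθ·E1)`` with ``E1 = exp(−TR/T1)``."""
    theta = np.deg2rad(flip_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    sig = m0 * np.sin(theta) * (1.0 - e1) / (1.0 - np.cos(theta) * e1)
    return np.where(np.asarray(m0) > 0, sig, 0.0)


def _rician(values: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    g1 = rng.normal(0.0, sigma, size=values.shape)
    g2 = rng.normal(0.0, sigma, size=values.shape)
    return np.sqrt((values + g1) ** 2 + g2 ** 2)


def add_rician_noise(series: ImageSeries, sigma: float, seed: int) -> ImageSeries:
    """Return a new series with Rician noise of width ``sigma`` applied.

    ``sigma = 0`` returns the input unchanged (bit-identical data)."""
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    if sigma == 0:
        return series
    rng = np.random.default_rng(seed)
    noisy = _rician(series.data, sigma, rng)
    return ImageSeries(data=noisy, protocol=series.protocol,
                       frame_axis_meaning=series.frame_axis_meaning)


def sigma_for_first_echo_snr(truth: GroundTruthMaps, protocol: AcquisitionProtocol,
                             snr: float = 50.0, decay: str = "t2") -> float:
    """Noise width giving the requested SNR at the first echo, defined on
    the mean noiseless first-echo signal over object voxels."""
    obj = truth.true_amplitude > 0
    t = truth.true_t2 if decay == "t2" else truth.true_t2star
    te1 = protocol.echo_times_ms[0]
    s1 = truth.true_amplitude[obj] * np.exp(-te1 / t[obj])
    return float(s1.mean() / snr)


def _apply_noise(series: ImageSeries, noise: NoiseModel) -> ImageSeries:
    if noise.kind == "none" or noise.sigma == 0:
        return series
    return add_rician_noise(series, noise.sigma, noise.seed)


def simulate_vfa_series(truth: GroundTruthMaps, protocol: AcquisitionProtocol,
                        noise: NoiseModel = NoiseModel()) -> ImageSeries:
    """Render the variable-flip-angle T1 acquisition, one frame per angle."""
    if protocol.sequence_kind is not SequenceKind.VFA_SPGR:
        raise ProtocolError("simulate_vfa_series needs a vfa_spgr protocol")
    if len(protocol.flip_angles_deg) < 2:
        raise ProtocolError("VFA simulation needs at least 2 flip angles")
    frames = [
        _spgr_signal(truth.true_amplitude, truth.true_t1, protocol.tr_ms, a)
        for a in protocol.flip_angles_deg
    ]
    series = ImageSeries(data=np.stack(frames, axis=-1), protocol=protocol,
                         frame_axis_meaning=FrameAxis.FLIP_ANGLE)
    return _apply_noise(series, noise)


def simulate_multiecho_series(truth: GroundTruthMaps, protocol: AcquisitionProtocol,
                              noise: NoiseModel = NoiseModel(), decay: str = "t2",
                              ) -> ImageSeries:
    """Render a multi-echo acquisition, ``SI = k·exp(−TE/T)`` per echo,
    with ``T`` the voxel's T2 (``decay='t2'``) or T2* (``decay='t2star'``)."""
    if decay not in ("t2", "t2star"):
        raise ValidationError(f"decay must be 't2' or 't2star', got {decay!r}")
    if len(protocol.echo_times_ms) < 3:
        raise ProtocolError("multi-echo simulation needs at least 3 echo times")
    t = truth.true_t2 if decay == "t2" else truth.true_t2star
    te = np.asarray(protocol.echo_times_ms)
    with np.errstate(divide="ignore", invalid="ignore"):
        frames = truth.true_amplitude[..., None] * np.exp(-te / t[..., None])
    series = ImageSeries(data=frames, protocol=protocol,
                         frame_axis_meaning=FrameAxis.ECHO)
    return _apply_noise(series, noise)


# --------------------------------------------------------------------------
# Rat dynamic scenario
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RatDynamicsParams:
    """Shape of the bolus-induced R2 transient in the rat brain.

    The true brain R2 is ``baseline_r2`` before tracer arrival and
    ``baseline_r2·(1 + peak_relative_change·2^{−(t−t_arr)/halflife})``
    afterwards: an immediate relative elevation followed by mono-exponential
    washout toward baseline.  Defaults: baseline 13 s⁻¹ (typical 3-T brain
    tissue), 10% peak change, 60-min half-life, 82 post-injection series of
    3 min each with arrival at the first post series.
    """

    baseline_r2: float = 13.0
    peak_relative_change: float = 0.10
    washout_halflife_min: float = 60.0
    n_dynamic_series: int = 82
    series_duration_min: float = 3.0
    arrival_series_index: int = 0

    def __post_init__(self) -> None:
        if self.baseline_r2 <= 0:
            raise ValidationError("baseline_r2 must be positive")
        if not (0 <= self.peak_relative_change < 1):
            raise ValidationError("peak_relative_change must be in [0, 1)")
        if self.n_dynamic_series < 1:
            raise ValidationError("need at least one dynamic series")
        if not (0 <= self.arrival_series_index < self.n_dynamic_series):
            raise ValidationError(
                f"arrival_series_index {self.arrival_series_index} outside the "
                f"{self.n_dynamic_series} post series"
            )
        if self.washout_halflife_min <= 0:
            raise ValidationError("washout_halflife_min must be positive")

    def true_relative_change(self, t_min):
        """True (R2(t) − R2_pre)/R2_pre at post-injection time ``t_min``."""
        t = np.asarray(t_min, dtype=float)
        t_arr = (self.arrival_series_index + 1) * self.series_duration_min
        decay = np.power(0.5, (t - t_arr) / self.washout_halflife_min)
        return np.where(t >= t_arr, self.peak_relative_change * decay, 0.0)


@dataclass
class RatSimulation:
    """Baseline + post series with per-timepoint truth and the brain mask."""

    baseline: ImageSeries
    post_series: list[ImageSeries]
    truths: list[GroundTruthMaps]
    baseline_truth: GroundTruthMaps
    brain_mask: np.ndarray
    times_min: np.ndarray  # post-series timestamps, multiples of series duration


def _brain_truth(protocol: AcquisitionProtocol, r2_map: np.ndarray,
                 mask: np.ndarray, amplitude: float) -> GroundTruthMaps:
    t2 = np.where(mask, 1000.0 / np.where(r2_map > 0, r2_map, 1.0), DEFAULT_T1_MS)
    return GroundTruthMaps(
        true_t1=np.full(mask.shape, DEFAULT_T1_MS),
        true_t2=np.minimum(t2, DEFAULT_T1_MS),
        true_t2star=DEFAULT_T2STAR_FRACTION * np.minimum(t2, DEFAULT_T1_MS),
        true_amplitude=np.where(mask, amplitude, 0.0),
        concentration_map=np.zeros(mask.shape),
        voxel_size_mm=protocol.voxel_size_mm,
    )


def simulate_rat_dynamics(params: RatDynamicsParams = RatDynamicsParams(),
                          protocol: AcquisitionProtocol | None = None,
                          noise: NoiseModel = NoiseModel(),
                          amplitude: float = DEFAULT_AMPLITUDE) -> RatSimulation:
    """Simulate the baseline + dynamic multi-echo TSE experiment.

    An elliptical brain region on the central slice carries the transient
    R2 of :class:`RatDynamicsParams`; each timepoint is rendered with
    :func:`simulate_multiecho_series`.  Per-timepoint noise seeds are drawn
    deterministically from ``noise.seed`` so the whole experiment is
    reproducible.
    """
    if protocol is None:
        protocol = tse_t2_protocol(series_duration_min=params.series_duration_min)
    nx, ny, nz = protocol.matrix_shape
    dx, dy, _ = protocol.voxel_size_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    # rat brain approximated by a ~24 × 16 mm ellipse on every slice
    ellipse = (xx / 12.0) ** 2 + (yy / 8.0) ** 2 <= 1.0
    mask = np.repeat(ellipse[:, :, None], nz, axis=2)

    base_r2 = np.where(mask, params.baseline_r2, 0.0)
    baseline_truth = _brain_truth(protocol, base_r2, mask, amplitude)
    seeds = np.random.SeedSequence(noise.seed).generate_state(params.n_dynamic_series + 1)
    seeds = (seeds % np.uint32(2**31)).astype(np.int64)

    def render(truth: GroundTruthMaps, seed: int) -> ImageSeries:
        nm = NoiseModel(kind=noise.kind, sigma=noise.sigma, seed=int(seed))
        return simulate_multiecho_series(truth, protocol, nm, decay="t2")

    baseline = render(baseline_truth, seeds[0])
    times = params.series_duration_min * np.arange(1, params.n_dynamic_series + 1)
    post_series, truths = [], []
    for i, t in enumerate(times):
        rel = params.true_relative_change(t)
        r2_t = np.where(mask, params.baseline_r2 * (1.0 + rel), 0.0)
        truth_t = _brain_truth(protocol, r2_t, mask, amplitude)
        truths.append(truth_t)
        post_series.append(render(truth_t, seeds[i + 1]))
    return RatSimulation(
        baseline=baseline, post_series=post_series, truths=truths,
        baseline_truth=baseline_truth, brain_mask=mask, times_min=times,
    )
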