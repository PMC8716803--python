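"""Vial ROI extraction, per-vial statistics, and the R2↔concentration calibration.

The phantom workflow mirrors the acquisition design: circular regions of
interest of a fixed target area (default 118 mm²) are detected
automatically inside each vial on the centred five slices, relaxation-rate
samples are pooled over repeated acquisitions, and per-vial medians feed an
ordinary-least-squares calibration line ``R2 = slope·C + intercept``
restricted to the concentration range where the linear response holds
(default [0.245, 5.5]%).  The statistical battery — Shapiro–Wilk
normality, Spearman rank correlation against concentration, and
Games–Howell pairwise comparisons — matches what one would run on the
physical phantom data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .core_io import ImageSeries, ParametricMap, ValidationError
from .synthetic import PhantomLayout

__all__ = [
    "VialROI",
    "VialStats",
    "CalibrationModel",
    "DetectionError",
    "PairingError",
    "InsufficientDataError",
    "detect_vial_rois",
    "summarize_vials",
    "spearman_vs_concentration",
    "normality_test",
    "games_howell_pairwise",
    "fit_calibration",
    "estimate_concentration",
    "vial_stats_table",
]

DEFAULT_ROI_AREA_MM2 = 118.0
DEFAULT_FIT_RANGE = (0.245, 5.5)


class DetectionError(ValidationError):
    """No vial-like component was found in the image."""


class PairingError(ValidationError):
    """A detected ROI could not be matched to a layout hole."""


class InsufficientDataError(ValidationError):
    """Too few in-range vials for the requested fit."""


# --------------------------------------------------------------------------
# ROI detection
# --------------------------------------------------------------------------

@dataclass
class VialROI:
    """A circular region of interest inside one vial.

    The ROI is the set of voxels nearest the component centroid whose count
    matches the target area, replicated on each listed slice.
    """

    center_voxel: tuple[float, float]
    radius_voxels: float
    slice_indices: tuple[int, ...]
    area_mm2: float
    vial_id: int | None = None            # hole index in the matched layout
    concentration: float | None = None
    rows: np.ndarray | None = None        # in-plane voxel indices of the disc
    cols: np.ndarray | None = None


def _central_slices(nz: int, n: int = 5) -> tuple[int, ...]:
    if nz <= n:
        return tuple(range(nz))
    start = (nz - n) // 2
    return tuple(range(start, start + n))


def _disc_indices(shape2d, center, n_voxels: int):
    """The ``n_voxels`` in-plane voxels closest to ``center`` (deterministic
    tie-break by flat index), giving an ROI of exactly the target count."""
    nx, ny = shape2d
    rr, cc = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    order = np.argsort(d2.ravel(), kind="stable")[:n_voxels]
    return np.unravel_index(order, (nx, ny))


def detect_vial_rois(series: ImageSeries, layout: PhantomLayout | None = None,
                     target_area_mm2: float = DEFAULT_ROI_AREA_MM2,
                     n_slices: int = 5, circularity_min: float = 0.7,
                     ) -> list[VialROI]:
    """Automatically place one circular ROI per vial.

    The first frame (brightest echo / first flip angle) of the central
    slice is thresholded with Otsu's method, connected components are
    labelled, and components passing a circularity filter
    (4π·area/perimeter² > ``circularity_min``) become vial candidates.
    Each ROI is a disc of ``target_area_mm2`` centred on the component
    centroid and replicated on the centred ``n_slices`` slices.

    When a layout is given, ROIs are matched to its holes by nearest
    centre and a warning is raised if fewer components than assigned vials
    are found (a partial result is still returned).
    """
    nx, ny, nz = series.shape
    mid = nz // 2
    frame = series.data[:, :, mid, 0]
    if not np.any(frame > 0) or frame.max() == frame.min():
        raise DetectionError("image has no contrast; cannot detect vials")
    thr = threshold_otsu(frame)
    fgmask = frame > thr
    # Otsu always returns a split; require genuine object/background contrast
    bg_mean = frame[~fgmask].mean() if (~fgmask).any() else 0.0
    if fgmask.any() and frame[fgmask].mean() < 3.0 * max(bg_mean, 1e-12):
        raise DetectionError("image has no vial-like contrast above the noise floor")
    labels = label(fgmask)
    voxel_area = series.protocol.in_plane_voxel_area_mm2
    n_roi_vox = int(round(target_area_mm2 / voxel_area))
    candidates = []
    for prop in regionprops(labels):
        if prop.area < max(4, n_roi_vox // 4):
            continue
        perim = prop.perimeter
        if perim <= 0:
            continue
        circularity = 4 * np.pi * prop.area / perim**2
        if circularity < circularity_min:
            continue
        candidates.append(prop.centroid)
    if not candidates:
        raise DetectionError("no circular components found above threshold")

    slices = _central_slices(nz, n_slices)
    radius = np.sqrt(target_area_mm2 / np.pi) / np.sqrt(voxel_area)
    rois = []
    for cx, cy in candidates:
        rows, cols = _disc_indices((nx, ny), (cx, cy), n_roi_vox)
        rois.append(VialROI(
            center_voxel=(float(cx), float(cy)),
            radius_voxels=float(radius),
            slice_indices=slices,
            area_mm2=n_roi_vox * voxel_area,
            rows=np.asarray(rows),
            cols=np.asarray(cols),
        ))

    if layout is not None:
        _match_rois_to_layout(rois, layout, series)
        n_expected = len(layout.vial_assignments)
        if len(rois) < n_expected:
            warnings.warn(
                f"detected {len(rois)} vials but the layout assigns {n_expected}",
                stacklevel=2,
            )
    return rois


def _layout_centers_voxel(layout: PhantomLayout, series: ImageSeries) -> dict[int, tuple[float, float]]:
    nx, ny, _ = series.shape
    dx, dy, _ = series.protocol.voxel_size_mm
    out = {}
    for hole_idx, _ in layout.vial_assignments:
        mx, my = layout.hole_positions_mm[hole_idx]
        out[hole_idx] = (mx / dx + (nx - 1) / 2.0, my / dy + (ny - 1) / 2.0)
    return out

def _match_rois_to_layout(rois, layout: PhantomLayout, series: ImageSeries) -> None:
    centers = _layout_centers_voxel(layout, series)
    conc = dict(layout.vial_assignments)
    for roi in rois:
        best, best_d = None, np.inf
        for hole_idx, (vx, vy) in centers.items():
            d = np.hypot(roi.center_voxel[0] - vx, roi.center_voxel[1] - vy)
            if d < best_d:
                best, best_d = hole_idx, d
        max_d = 2 * layout.vial_radius_mm / min(series.protocol.voxel_size_mm[:2])
        if best is None or best_d > max_d:
            raise PairingError(
                f"ROI at {roi.center_voxel} is {best_d:.1f} voxels from the nearest hole"
            )
        roi.vial_id = best
        roi.concentration = conc[best]


# --------------------------------------------------------------------------
# Per-vial statistics
# --------------------------------------------------------------------------

@dataclass
class VialStats:
    """Median/IQR of the relaxation rate pooled over repeats for one vial."""

    vial_id: int
    concentration: float
    median_rate: float
    iqr_rate: float
    n_voxels: int
    n_repeats: int


def _roi_samples(pmap: ParametricMap, roi: VialROI) -> np.ndarray:
    vals = []
    for z in roi.slice_indices:
        if z >= pmap.shape[2]:
            continue
        v = pmap.rate_map[roi.rows, roi.cols, z]
        ok = pmap.converged_mask[roi.rows, roi.cols, z] & np.isfinite(v)
        vals.append(v[ok])
    return np.concatenate(vals) if vals else np.empty(0)


def summarize_vials(maps, rois: list[VialROI], layout: PhantomLayout) -> list[VialStats]:
    """Pool converged rate samples over repeats and summarise per vial.

    ``maps`` is one :class:`ParametricMap` or a list of repeats on the same
    grid.  Quartiles use linear interpolation; an unmatched ROI raises
    :class:`PairingError`.
    """
    if isinstance(maps, ParametricMap):
        maps = [maps]
    conc = dict(layout.vial_assignments)
    out = []
    for roi in sorted(rois, key=lambda r: (r.vial_id if r.vial_id is not None else -1)):
        if roi.vial_id is None or roi.vial_id not in conc:
            raise PairingError(f"ROI at {roi.center_voxel} has no layout assignment")
        pooled = np.concatenate([_roi_samples(m, roi) for m in maps])
        if pooled.size == 0:
            raise ValidationError(f"vial {roi.vial_id}: no converged voxels in ROI")
        q1, q2, q3 = np.percentile(pooled, [25, 50, 75], method="linear")
        out.append(VialStats(
            vial_id=roi.vial_id,
            concentration=float(conc[roi.vial_id]),
            median_rate=float(q2),
            iqr_rate=float(q3 - q1),
            n_voxels=int(pooled.size),
            n_repeats=len(maps),
        ))
    return out


def vial_stats_table(stats: list[VialStats]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])


# --------------------------------------------------------------------------
# Statistical battery
# --------------------------------------------------------------------------

def spearman_vs_concentration(vials: list[VialStats]) -> tuple[float, float]:
    """Spearman rank correlation of per-vial median rate vs concentration.

    Ties get average ranks and the p-value uses the standard
    t-approximation (as in :func:`scipy.stats.spearmanr`)."""
    if len(vials) < 4:
        raise InsufficientDataError("Spearman correlation needs at least 4 vials")
    c = np.array([s.concentration for s in vials])
    r = np.array([s.median_rate for s in vials])
    if np.ptp(c) == 0 or np.ptp(r) == 0:
        raise ValidationError("correlation undefined for a constant input vector")
    res = stats.spearmanr(c, r)
    return float(res.statistic), float(res.pvalue)


def normality_test(sample) -> tuple[float, float]:
    """Shapiro–Wilk W and p for a rate sample (3 ≤ n ≤ 5000)."""
    sample = np.asarray(sample, dtype=float)
    if not (3 <= sample.size <= 5000):
        raise ValidationError(f"Shapiro–Wilk requires 3 <= n <= 5000, got n={sample.size}")
    res = stats.shapiro(sample)
    return float(res.statistic), float(res.pvalue)


def games_howell_pairwise(groups) -> pd.DataFrame:
    """Games–Howell post hoc comparisons between concentration groups.

    ``groups`` is a list of ``(concentration, sample)`` pairs.  For each
    pair of groups the Welch standard error ``sqrt(s1²/n1 + s2²/n2)`` and
    Welch–Satterthwaite degrees of freedom are computed and the statistic
    ``q = |Δmean|·√2 / SE`` is referred to the studentized-range
    distribution with ``k`` groups.  Degenerate pairs with zero variance on
    both sides get p = 1 for equal means and p = 0 otherwise.

    Returns a table with columns ``group_a, group_b, mean_diff, se, df, q,
    p_adj``.
    """
    if len(groups) < 2:
        raise ValidationError("Games–Howell needs at least 2 groups")
    samples = [(float(c), np.asarray(x, dtype=float)) for c, x in groups]
    for c, x in samples:
        if x.size < 2:
            raise ValidationError(f"group {c}: need at least 2 observations")
    k = len(samples)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ca, xa = samples[i]
            cb, xb = samples[j]
            na, nb = xa.size, xb.size
            va, vb = xa.var(ddof=1), xb.var(ddof=1)
            diff = xa.mean() - xb.mean()
            se2 = va / na + vb / nb
            if se2 == 0:
                p = 1.0 if diff == 0 else 0.0
                rows.append((ca, cb, diff, 0.0, np.inf, np.inf if diff else 0.0, p))
                continue
            se = np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            q = np.abs(diff) * np.sqrt(2.0) / se
            p = float(stats.studentized_range.sf(q, k, df))
            rows.append((ca, cb, float(diff), float(se), float(df), float(q), min(max(p, 0.0), 1.0)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "se", "df", "q", "p_adj"])


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationModel:
    """The linear R2↔concentration calibration with its validity range."""

    slope: float          # s⁻¹ per %
    intercept: float      # s⁻¹
    fit_range: tuple[float, float]
    r_spearman: float
    n_points: int

    def __post_init__(self) -> None:
        lo, hi = self.fit_range
        if not lo < hi:
            raise ValidationError("fit_range must be ordered")
        if not np.isfinite(self.slope):
            raise ValidationError("slope must be finite")


def fit_calibration(stats_list: list[VialStats],
                    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
                    ) -> CalibrationModel:
    """Ordinary least squares of per-vial median R2 on concentration.

    Only vials with concentration inside ``fit_range`` (inclusive) enter
    the fit; the Spearman rho stored on the model is computed from the full
    vial set when at least 4 vials are available.
    """
    lo, hi = fit_range
    in_range = [s for s in stats_list if lo <= s.concentration <= hi]
    if len(in_range) < 2:
        raise InsufficientDataError(
            f"only {len(in_range)} vials inside [{lo}, {hi}]%; need at least 2"
        )
    c = np.array([s.concentration for s in in_range])
    r = np.array([s.median_rate for s in in_range])
    slope, intercept = np.polyfit(c, r, 1)
    try:
        rho, _ = spearman_vs_concentration(stats_list)
    except ValidationError:
        rho = float("nan")
    return CalibrationModel(
        slope=float(slope), intercept=float(intercept),
        fit_range=(float(lo), float(hi)), r_spearman=float(rho),
        n_points=len(in_range),
    )


def estimate_concentration(r2, model: CalibrationModel):
    """Invert the calibration line: ``C = (R2 − intercept)/slope``.

    Returns ``(concentration %, in_range flag)``; the flag is False where
    the estimate falls outside the model's fitted range, so extrapolation
    is never silent.  Accepts scalars or arrays.
    """
    if model.slope == 0:
        raise ValidationError("cannot invert a calibration with zero slope")
    r2 = np.asarray(r2, dtype=float)
    c = (r2 - model.intercept) / model.slope
    lo, hi = model.fit_range
    in_range = (c >= lo) & (c <= hi)
    if c.ndim == 0:
        return float(c), bool(in_range)
    return c, in_range
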