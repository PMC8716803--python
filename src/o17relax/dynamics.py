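"""Dynamic R2-change analysis of the injected-bolus series and dose planning.

After a bolus of enriched water, brain-tissue R2 rises and then washes out
slowly.  The tracer readout is the baseline-normalised voxel-wise change

    ΔR2_rel = (R2_POST − R2_PRE) / R2_PRE,

summarised over a brain mask per timepoint into a time curve.  The module
also implements the mixing arithmetic used to plan the injection: the
volume ``V`` of an ``E``-percent enriched solution that raises the
intravascular H₂¹⁷O mole fraction of a blood volume ``BV`` (weight ×
per-kg blood volume) from natural abundance ``c_nat`` to a target ``C``:

    (V·E + BV·c_nat) / (V + BV) = C   ⇒   V = BV·(C − c_nat)/(E − C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core_io import GridMismatchError, ParametricMap, ValidationError
from .synthetic import NATURAL_ABUNDANCE_PERCENT

__all__ = [
    "DynamicsResult",
    "DoseParams",
    "relative_r2_change",
    "change_time_curve",
    "fit_washout_curve",
    "dose_volume",
    "intravascular_concentration",
    "h217o_molality_umol_per_g",
]

#: baseline rates below this floor (s⁻¹) are excluded from the ratio
DEFAULT_R2PRE_FLOOR = 0.1


# --------------------------------------------------------------------------
# Relative change maps and curves
# --------------------------------------------------------------------------

def relative_r2_change(pre: ParametricMap, post: ParametricMap,
                       r2pre_floor: float = DEFAULT_R2PRE_FLOOR) -> np.ndarray:
    """Voxel-wise ``(R2_post − R2_pre)/R2_pre``.

    NaN where either input is non-converged/NaN or the baseline rate is
    below ``r2pre_floor`` (near-zero baselines make the ratio meaningless).
    """
    if pre.shape != post.shape:
        raise GridMismatchError(f"pre grid {pre.shape} != post grid {post.shape}")
    ok = (pre.converged_mask & post.converged_mask
          & np.isfinite(pre.rate_map) & np.isfinite(post.rate_map)
          & (pre.rate_map >= r2pre_floor))
    out = np.full(pre.shape, np.nan)
    out[ok] = (post.rate_map[ok] - pre.rate_map[ok]) / pre.rate_map[ok]
    return out


@dataclass
class DynamicsResult:
    """Baseline map, per-timepoint maps/changes, and the summary curve.

    ``curve`` rows are ``(time_min, mean_change, std_change)`` over the
    mask; ``flagged_timepoints`` lists indices where no valid voxel
    survived sentinel exclusion.
    """

    baseline_rate_map: ParametricMap
    post_rate_maps: list[ParametricMap]
    relative_change_maps: list[np.ndarray]
    curve: np.ndarray                       # (n_post, 3): time, mean, std
    flagged_timepoints: list[int] = field(default_factory=list)

    @property
    def times_min(self) -> np.ndarray:
        return self.curve[:, 0]

    @property
    def mean_changes(self) -> np.ndarray:
        return self.curve[:, 1]


def change_time_curve(baseline: ParametricMap, post_maps: list[ParametricMap],
                      mask: np.ndarray, series_duration_min: float,
                      statistic: str = "mean",
                      r2pre_floor: float = DEFAULT_R2PRE_FLOOR) -> DynamicsResult:
    """Summarise the relative R2 change over a mask at each timepoint.

    Timepoint ``i`` (1-based) is stamped ``i × series_duration_min``; the
    per-timepoint summary is the mean (default) or median of the voxel-wise
    relative change, with its standard deviation.  A timepoint whose mask
    is empty after excluding sentinels is flagged, not fatal.
    """
    if len(post_maps) < 1:
        raise ValidationError("need at least one post-injection map")
    if statistic not in ("mean", "median"):
        raise ValidationError("statistic must be 'mean' or 'median'")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != baseline.shape:
        raise GridMismatchError(f"mask grid {mask.shape} != map grid {baseline.shape}")
    if not mask.any():
        raise ValidationError("mask selects no voxels")
    center = np.mean if statistic == "mean" else np.median
    rows, changes, flagged = [], [], []
    for i, post in enumerate(post_maps):
        change = relative_r2_change(baseline, post, r2pre_floor=r2pre_floor)
        changes.append(change)
        t = (i + 1) * series_duration_min
        vals = change[mask & np.isfinite(change)]
        if vals.size == 0:
            flagged.append(i)
            rows.append((t, np.nan, np.nan))
        else:
            rows.append((t, float(center(vals)), float(vals.std())))
    return DynamicsResult(
        baseline_rate_map=baseline,
        post_rate_maps=list(post_maps),
        relative_change_maps=changes,
        curve=np.asarray(rows, dtype=float),
        flagged_timepoints=flagged,
    )


def fit_washout_curve(times_min, mean_changes, arrival_time_min: float | None = None,
                      ) -> tuple[float, float]:
    """Fit ``change(t) = peak·2^{−(t−t_arr)/halflife}`` to a summary curve.

    Returns ``(peak_relative_change, washout_halflife_min)``.  Used to
    recover the bolus parameters from a measured curve; ``arrival_time_min``
    defaults to the first timepoint.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(mean_changes, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 3:
        raise ValidationError("need at least 3 finite curve points")
    t_arr = float(t[0]) if arrival_time_min is None else float(arrival_time_min)

    def model(tt, peak, halflife):
        return peak * np.power(0.5, (tt - t_arr) / halflife)

    p0 = (max(float(y[0]), 1e-3), max((t[-1] - t[0]) / 2.0, 1.0))
    popt, _ = curve_fit(model, t, y, p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1])


# --------------------------------------------------------------------------
# Dose arithmetic
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseParams:
    """Inputs to the intravascular mixing model.

    ``enrichment`` and ``target_concentration`` are mole-percent H₂¹⁷O of
    the injectate and of the desired intravascular blood pool; the blood
    volume is ``subject_weight_kg × blood_volume_ml_per_kg``.
    """

    subject_weight_kg: float
    blood_volume_ml_per_kg: float = 65.0
    enrichment_percent: float = 70.0
    target_concentration_percent: float = 4.6
    natural_abundance_percent: float = NATURAL_ABUNDANCE_PERCENT

    def __post_init__(self) -> None:
        if self.subject_weight_kg <= 0:
            raise ValidationError("subject weight must be positive")
        if self.blood_volume_ml_per_kg <= 0:
            raise ValidationError("blood volume per kg must be positive")
        if not (0 < self.target_concentration_percent < self.enrichment_percent <= 100):
            raise ValidationError(
                "need 0 < target concentration < enrichment <= 100 (%)"
            )

    @property
    def blood_volume_ml(self) -> float:
        return self.subject_weight_kg * self.blood_volume_ml_per_kg


def dose_volume(params: DoseParams, include_background: bool = True) -> float:
    """Injection volume (mL) achieving the target intravascular concentration.

    With the natural-abundance background term (default),
    ``V = BV·(C − c_nat)/(E − C)``; with ``include_background=False`` the
    simpler ``V = BV·C/(E − C)`` is returned for comparison.
    """
    c_nat = params.natural_abundance_percent if include_background else 0.0
    if params.target_concentration_percent <= c_nat:
        raise ValidationError(
            f"target {params.target_concentration_percent}% does not exceed the "
            f"background {c_nat}%; nothing to inject"
        )
    bv = params.blood_volume_ml
    return bv * (params.target_concentration_percent - c_nat) / (
        params.enrichment_percent - params.target_concentration_percent
    )


def intravascular_concentration(volume_ml: float, params: DoseParams) -> float:
    """Resulting intravascular H₂¹⁷O concentration (%) after injecting
    ``volume_ml`` of the enriched solution: ``(V·E + BV·c_nat)/(V + BV)``."""
    if volume_ml < 0:
        raise ValidationError("volume must be non-negative")
    bv = params.blood_volume_ml
    return (volume_ml * params.enrichment_percent
            + bv * params.natural_abundance_percent) / (volume_ml + bv)


def h217o_molality_umol_per_g(concentration_percent: float = NATURAL_ABUNDANCE_PERCENT,
                              water_molar_mass_g_per_mol: float = 18.0) -> float:
    """μmol of H₂¹⁷O per gram of water at a given mole-percent concentration.

    One gram of water holds ``1/18`` mol of molecules, so natural abundance
    (0.037%) corresponds to ``0.00037/18 mol/g ≈ 20.56`` μmol/g.
    """
    if concentration_percent < 0:
        raise ValidationError("concentration must be non-negative")
    return concentration_percent / 100.0 / water_molar_mass_g_per_mol * 1e6
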