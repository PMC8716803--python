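"""Voxel-wise relaxation-time estimation and rate-map conversion.

Two signal models are fitted per voxel by damped (Levenberg–Marquardt)
least squares:

* variable-flip-angle spoiled gradient echo for T1,
  ``S(θ) = M0·sinθ·(1 − E1)/(1 − cosθ·E1)``, ``E1 = exp(−TR/T1)``;
* mono-exponential multi-echo decay for T2 or T2*,
  ``S(TE) = k·exp(−TE/T)``.

Starts are deterministic closed forms — the log-linear regression for the
exponential, and the DESPOT1-style linearisation (S/sinθ on S/tanθ) for
VFA — so repeated runs give identical maps.  The refinement is a small
Levenberg–Marquardt loop vectorised over all foreground voxels at once;
every echo (or angle) enters the unweighted residual, and no Rician bias
correction is applied.  Background voxels (maximum frame intensity below a
configurable fraction of the series maximum) are skipped and reported as
non-converged, as are voxels whose signal cannot be explained by the model
within bounds (e.g. echo trains that grow with TE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (
    ImageSeries,
    ParametricMap,
    ProtocolError,
    SequenceKind,
    ValidationError,
    time_to_rate,
)

__all__ = ["FitConfig", "fit_t1_vfa", "fit_monoexp", "to_rate_map", "fit_report"]


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings shared by the two fitters.

    ``time_bounds`` clip the relaxation time (ms); ``amplitude_bounds`` of
    ``None`` means (0, 10 × series maximum], resolved per series.  Voxels
    whose brightest frame is below ``min_signal_fraction`` of the series
    maximum are treated as background and not fitted.
    """

    max_iterations: int = 200
    convergence_tol: float = 1e-8
    time_bounds: tuple[float, float] = (1.0, 20000.0)
    amplitude_bounds: tuple[float, float] | None = None
    min_signal_fraction: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.time_bounds
        if not (0 < lo < hi):
            raise ValidationError(f"time_bounds must be positive and ordered, got {self.time_bounds}")
        if self.amplitude_bounds is not None:
            alo, ahi = self.amplitude_bounds
            if not (0 <= alo < ahi):
                raise ValidationError("amplitude_bounds must be ordered and non-negative")
        if not (0 <= self.min_signal_fraction < 1):
            raise ValidationError("min_signal_fraction must be in [0, 1)")
        if self.max_iterations < 1 or self.convergence_tol <= 0:
            raise ValidationError("max_iterations >= 1 and convergence_tol > 0 required")


# --------------------------------------------------------------------------
# Vectorised Levenberg–Marquardt over voxels (2 parameters per voxel)
# --------------------------------------------------------------------------

def _lm_refine(signal, amp0, t0, model_and_jac, config, amp_hi):
    """Damped least squares on (amplitude, time) for every voxel at once.

    ``signal`` is (n_vox, n_frames); ``model_and_jac(amp, t)`` returns the
    model prediction and its two Jacobian columns, each (n_vox, n_frames).
    Returns refined (amp, t, rss, converged, n_iter).
    """
    t_lo, t_hi = config.time_bounds
    amp = np.clip(np.asarray(amp0, dtype=float).copy(), 1e-12, amp_hi)
    t = np.clip(np.asarray(t0, dtype=float).copy(), t_lo, t_hi)
    lam = np.full(amp.shape, 1e-3)
    pred, ja, jt = model_and_jac(amp, t)
    resid = pred - signal
    rss = np.einsum("ij,ij->i", resid, resid)
    converged = np.zeros(amp.shape, dtype=bool)
    n_iter = np.zeros(amp.shape, dtype=int)

    for _ in range(config.max_iterations):
        active = ~converged
        if not active.any():
            break
        # normal equations J^T J + lam*diag, J^T r, per voxel (2x2 solve)
        a11 = np.einsum("ij,ij->i", ja, ja)
        a22 = np.einsum("ij,ij->i", jt, jt)
        a12 = np.einsum("ij,ij->i", ja, jt)
        g1 = np.einsum("ij,ij->i", ja, resid)
        g2 = np.einsum("ij,ij->i", jt, resid)
        d11 = a11 * (1.0 + lam) + 1e-30
        d22 = a22 * (1.0 + lam) + 1e-30
        det = d11 * d22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        da = -(d22 * g1 - a12 * g2) / det
        dt = -(d11 * g2 - a12 * g1) / det

        amp_new = np.clip(amp + da, 1e-12, amp_hi)
        t_new = np.clip(t + dt, t_lo, t_hi)
        pred_new, ja_new, jt_new = model_and_jac(amp_new, t_new)
        resid_new = pred_new - signal
        rss_new = np.einsum("ij,ij->i", resid_new, resid_new)

        improved = (rss_new <= rss) & active
        step_rel = np.maximum(
            np.abs(amp_new - amp) / np.maximum(np.abs(amp), 1e-12),
            np.abs(t_new - t) / np.maximum(np.abs(t), 1e-12),
        )
        amp = np.where(improved, amp_new, amp)
        t = np.where(improved, t_new, t)
        rss = np.where(improved, rss_new, rss)
        upd = improved[:, None]
        ja = np.where(upd, ja_new, ja)
        jt = np.where(upd, jt_new, jt)
        resid = np.where(upd, resid_new, resid)
        lam = np.where(improved, lam * 0.5, lam * 4.0)
        lam = np.clip(lam, 1e-12, 1e12)
        n_iter += active.astype(int)
        converged |= improved & (step_rel < config.convergence_tol)
        # a rejected step with a tiny predicted move also counts as done
        converged |= active & ~improved & (lam >= 1e10)
    return amp, t, rss, converged | (n_iter > 0), n_iter


def _assemble_map(shape, idx, amp, t, rss, good, voxel_size) -> ParametricMap:
    time_map = np.full(shape, np.nan)
    amp_map = np.full(shape, np.nan)
    rss_map = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    flat_idx = idx[good]
    time_map.flat[flat_idx] = t[good]
    amp_map.flat[flat_idx] = amp[good]
    rss_map.flat[flat_idx] = rss[good]
    mask.flat[flat_idx] = True
    return ParametricMap(
        time_map=time_map,
        rate_map=time_to_rate(time_map),
        amplitude_map=amp_map,
        converged_mask=mask,
        rss_map=rss_map,
        voxel_size_mm=voxel_size,
    )


# --------------------------------------------------------------------------
# Mono-exponential T2 / T2* fit
# --------------------------------------------------------------------------

def fit_monoexp(series: ImageSeries, config: FitConfig = FitConfig()) -> ParametricMap:
    """Fit ``S(TE) = k·exp(−TE/T)`` voxel-wise over all echoes.

    Initialisation is an ordinary least-squares line through
    ``log S`` vs TE using the voxel's positive intensities; the damped
    least-squares refinement then minimises the unweighted residual on the
    raw signal.  Voxels with fewer than two positive echoes, or whose
    best-fit decay is non-physical (signal growing with TE), are marked
    non-converged.
    """
    if len(series.protocol.echo_times_ms) < 3:
        raise ProtocolError("mono-exponential fitting needs at least 3 echoes")
    te = np.asarray(series.protocol.echo_times_ms)
    shape = series.shape
    sig = series.data.reshape(-1, len(te))

    peak = sig.max(axis=1)
    threshold = config.min_signal_fraction * peak.max() if peak.size else 0.0
    fg = peak >= max(threshold, 1e-12)
    idx = np.flatnonzero(fg)
    s = sig[idx]
    amp_hi = (config.amplitude_bounds[1] if config.amplitude_bounds
              else 10.0 * max(peak.max(), 1e-12))

    # log-linear start: log s = log k - TE/T, positive samples only
    pos = s > 0
    n_pos = pos.sum(axis=1)
    logs = np.where(pos, np.log(np.where(pos, s, 1.0)), 0.0)
    w = pos.astype(float)
    sw = n_pos.astype(float)
    safe = sw >= 2
    sw = np.where(safe, sw, 2.0)
    mx = (w * te).sum(axis=1) / sw
    my = logs.sum(axis=1) / sw
    sxx = (w * (te - mx[:, None]) ** 2).sum(axis=1)
    sxy = (w * (te - mx[:, None]) * (logs - my[:, None])).sum(axis=1)
    slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    decaying = safe & (slope < 0)
    t_lo, t_hi = config.time_bounds
    t0 = np.where(decaying, -1.0 / np.where(slope < 0, slope, -1.0), np.nan)
    t0 = np.clip(t0, t_lo, t_hi)
    k0 = np.exp(my - slope * mx)
    k0 = np.where(decaying, k0, np.nan)

    usable = decaying
    amp = np.where(usable, k0, 1.0)
    t = np.where(usable, t0, (t_lo + t_hi) / 2)

    def model_and_jac(a, tt):
        e = np.exp(-te[None, :] / tt[:, None])
        pred = a[:, None] * e
        ja = e
        jt = pred * te[None, :] / (tt[:, None] ** 2)
        return pred, ja, jt

    amp_f, t_f, rss, conv, _ = _lm_refine(s, amp, t, model_and_jac, config, amp_hi)
    interior = (t_f > t_lo * (1 + 1e-9)) & (t_f < t_hi * (1 - 1e-9))
    good = usable & conv & interior
    return _assemble_map(shape, idx, amp_f, t_f, rss, good,
                         series.protocol.voxel_size_mm)


# --------------------------------------------------------------------------
# Variable-flip-angle T1 fit
# --------------------------------------------------------------------------

def fit_t1_vfa(series: ImageSeries, config: FitConfig = FitConfig()) -> ParametricMap:
    """Fit the spoiled gradient-echo model voxel-wise for (M0, T1).

    Initialisation follows the standard linearisation: regressing
    ``S/sinθ`` on ``S/tanθ`` gives slope ``E1 = exp(−TR/T1)`` and intercept
    ``M0·(1 − E1)``.  Voxels whose linearised slope falls outside (0, 1) —
    including flat signal across angles, which no T1 within bounds can
    produce — are marked non-converged.
    """
    if series.protocol.sequence_kind is not SequenceKind.VFA_SPGR:
        raise ProtocolError("fit_t1_vfa needs a vfa_spgr series")
    angles = np.deg2rad(np.asarray(series.protocol.flip_angles_deg))
    if len(angles) < 2:
        raise ProtocolError("VFA fitting needs at least 2 flip angles")
    tr = series.protocol.tr_ms
    shape = series.shape
    sig = series.data.reshape(-1, len(angles))

    peak = sig.max(axis=1)
    threshold = config.min_signal_fraction * peak.max() if peak.size else 0.0
    fg = peak >= max(threshold, 1e-12)
    idx = np.flatnonzero(fg)
    s = sig[idx]
    # M0 far exceeds the measured SPGR signal when TR << T1 (the signal is
    # only a few percent of M0), so the VFA amplitude cap must be much
    # looser than the multi-echo one
    amp_hi = (config.amplitude_bounds[1] if config.amplitude_bounds
              else 1000.0 * max(peak.max(), 1e-12))

    ysin = s / np.sin(angles)[None, :]
    xtan = s / np.tan(angles)[None, :]
    mx = xtan.mean(axis=1)
    my = ysin.mean(axis=1)
    sxx = ((xtan - mx[:, None]) ** 2).sum(axis=1)
    sxy = ((xtan - mx[:, None]) * (ysin - my[:, None])).sum(axis=1)
    e1 = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    # flat signal across angles is incompatible with the SPGR model
    flat = (s.max(axis=1) - s.min(axis=1)) <= 1e-9 * np.maximum(s.max(axis=1), 1e-12)
    usable = np.isfinite(e1) & (e1 > 0) & (e1 < 1) & ~flat
    t_lo, t_hi = config.time_bounds
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = -tr / np.log(np.where(usable, e1, 0.5))
    t0 = np.clip(np.where(usable, t0, (t_lo + t_hi) / 2), t_lo, t_hi)
    m0 = np.where(usable, (my - e1 * mx) / np.maximum(1.0 - e1, 1e-12), 1.0)
    m0 = np.clip(m0, 1e-12, amp_hi)

    sin_a = np.sin(angles)[None, :]
    cos_a = np.cos(angles)[None, :]

    def model_and_jac(a, t1):
        e = np.exp(-tr / t1)[:, None]
        denom = 1.0 - cos_a * e
        frac = (1.0 - e) / denom
        pred = a[:, None] * sin_a * frac
        ja = sin_a * frac
        # d pred / d T1 through dE1/dT1 = E1 * TR / T1^2
        de = e * (tr / (t1 ** 2))[:, None]
        dfrac = (-de * denom + (1.0 - e) * cos_a * de) / denom**2
        jt = a[:, None] * sin_a * dfrac
        return pred, ja, jt

    amp_f, t_f, rss, conv, _ = _lm_refine(s, m0, t0, model_and_jac, config, amp_hi)
    interior = (t_f > t_lo * (1 + 1e-9)) & (t_f < t_hi * (1 - 1e-9))
    good = usable & conv & interior
    return _assemble_map(shape, idx, amp_f, t_f, rss, good,
                         series.protocol.voxel_size_mm)


# --------------------------------------------------------------------------
# Rates and reporting
# --------------------------------------------------------------------------

def to_rate_map(pmap: ParametricMap) -> ParametricMap:
    """Recompute ``rate_map = 1000/time_map`` (s⁻¹ from ms).

    Idempotent; NaN sentinels propagate unchanged."""
    return ParametricMap(
        time_map=pmap.time_map,
        rate_map=time_to_rate(pmap.time_map),
        amplitude_map=pmap.amplitude_map,
        converged_mask=pmap.converged_mask,
        rss_map=pmap.rss_map,
        voxel_size_mm=pmap.voxel_size_mm,
    )


def fit_report(pmap: ParametricMap) -> dict:
    """Summary counts for a fitted map (for logs and CLI reports)."""
    n_total = pmap.time_map.size
    n_conv = int(pmap.converged_mask.sum())
    ok = pmap.converged_mask
    return {
        "voxels_total": int(n_total),
        "voxels_converged": n_conv,
        "converged_fraction": n_conv / n_total if n_total else 0.0,
        "median_time_ms": float(np.median(pmap.time_map[ok])) if n_conv else float("nan"),
        "median_rate_per_s": float(np.median(pmap.rate_map[ok])) if n_conv else float("nan"),
        "mean_rss": float(np.mean(pmap.rss_map[ok])) if n_conv else float("nan"),
    }
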