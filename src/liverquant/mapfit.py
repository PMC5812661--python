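"""Voxel-wise quantification of the four MR contrasts.

T1 and T2 maps come from per-voxel nonlinear least squares
(Levenberg–Marquardt); ADC and MTR have closed forms.  Magnitude data are
fitted as such: the inversion-recovery model is evaluated through an absolute
value because exported magnitude images lose signal polarity, and the
background noise level estimated from an air ROI feeds a Rician bias
correction (squared subtraction) applied to low-SNR mean signals.

Plausibility gates (T1 in (1, 10000) ms, T2 in (1, 500) ms, ADC >= 0, MTR in
[-10, 100]%) sit an order of magnitude beyond physiological liver values and
reject only outright fit failures; gated or non-converged voxels are masked
in every derived map, never silently zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .signal_models import IR_TRUEFISP, MULTI_ECHO
from .phantom import AcquisitionSeries

__all__ = [
    "ParameterMap",
    "FitDiagnostics",
    "estimate_background_noise",
    "correct_rician_bias",
    "fit_t1_map",
    "fit_t2_map",
    "compute_adc_map",
    "compute_mtr_map",
    "RAYLEIGH_MEAN_FACTOR",
    "T1_RANGE_MS",
    "T2_RANGE_MS",
    "MTR_RANGE_PCT",
    "LM_MAX_ITER",
    "LM_XTOL",
]

# mean of |complex Gaussian noise| = sigma * sqrt(pi/2)
RAYLEIGH_MEAN_FACTOR = float(np.sqrt(np.pi / 2.0))

# plausibility gates, an order of magnitude beyond liver physiology
T1_RANGE_MS = (1.0, 10000.0)
T2_RANGE_MS = (1.0, 500.0)
MTR_RANGE_PCT = (-10.0, 100.0)

LM_MAX_ITER = 200
LM_XTOL = 1e-8


@dataclass
class ParameterMap:
    """Per-voxel map of one quantitative parameter with a validity mask.

    Invalid voxels hold NaN in ``values`` and False in ``mask``; exporters
    must replace the NaN sentinel (see io module) so no NaN leaks out.
    """

    name: str
    values: np.ndarray
    units: str
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("value grid and validity mask must share a shape")

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class FitDiagnostics:
    """Per-voxel residual sum of squares, iteration count, convergence flag."""

    rss: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray


def estimate_background_noise(series: AcquisitionSeries, background_roi, *, liver_mask=None) -> float:
    """Estimate the Gaussian noise level sigma from an air-background ROI.

    The ROI (polygon in voxel coordinates, or a boolean mask) is placed
    outside the body; there the magnitude signal is Rayleigh distributed with
    mean ``sigma * sqrt(pi/2)``, so the ROI mean divided by that factor
    recovers sigma.
    """
    if isinstance(background_roi, np.ndarray) and background_roi.dtype == bool:
        bg = background_roi
    else:
        from .roi_volumetry import rasterize_polygon

        bg = rasterize_polygon(background_roi, series.spatial_shape)
    if not bg.any():
        raise ValueError("background ROI rasterizes to zero voxels")
    if liver_mask is not None and (bg & np.asarray(liver_mask, dtype=bool)).any():
        warnings.warn("background ROI overlaps the liver mask; sigma may be biased high")
    vals = series.data[(slice(None),) + np.nonzero(bg)]
    return float(vals.mean() / RAYLEIGH_MEAN_FACTOR)


def correct_rician_bias(signal, noise):
    """Squared-subtraction noise correction: ``sqrt(max(S^2 - N^2, 0))``."""
    signal = np.asarray(signal, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if np.any(signal < 0) or np.any(noise < 0):
        raise ValueError("signal and noise level must be non-negative")
    out = np.sqrt(np.clip(signal**2 - noise**2, 0.0, None))
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Nonlinear voxel-wise fits
# ---------------------------------------------------------------------------

def _ir_residual(p, ti, y):
    s0, inv, t1s = p
    return np.abs(s0 * (1.0 - inv * np.exp(-ti / t1s))) - y


def _ir_jac(p, ti, y):
    s0, inv, t1s = p
    e = np.exp(-ti / t1s)
    model = s0 * (1.0 - inv * e)
    sign = np.where(model >= 0, 1.0, -1.0)
    j = np.empty((ti.size, 3))
    j[:, 0] = sign * (1.0 - inv * e)
    j[:, 1] = sign * (-s0 * e)
    j[:, 2] = sign * (-s0 * inv * e * ti / t1s**2)
    return j


def fit_t1_map(
    series: AcquisitionSeries,
    alpha_deg: Optional[float] = None,
    mask: Optional[np.ndarray] = None,
) -> Tuple[Dict[str, ParameterMap], FitDiagnostics]:
    """Fit the IR-trueFISP model per voxel and derive the corrected T1 map.

    The magnitude model ``|S0 (1 - INV exp(-TI/T1*))|`` is fitted by
    Levenberg–Marquardt; starting values are derived deterministically from
    the data: the TI of the minimum-magnitude sample approximates the
    zero-crossing ``TI0 = T1* ln(INV)`` (with INV0 = 2), and S0 starts at the
    longest-TI signal.  T1 follows from the apparent time via the flip-angle
    correction ``T1 = T1* cos(alpha/2)(INV - 1)``; voxels with INV <= 1,
    T1 outside (1, 10000) ms or a failed fit are masked.
    """
    if series.meta.contrast != IR_TRUEFISP:
        raise ValueError("fit_t1_map requires an ir_truefisp series")
    ti = series.meta.values
    if ti.size < 4:
        raise ValueError("at least 4 inversion times are required for a 3-parameter fit")
    alpha = series.meta.flip_angle_deg if alpha_deg is None else alpha_deg
    shape = series.spatial_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    data = series.data.reshape(ti.size, -1)
    flat_mask = mask.reshape(-1)
    n_vox = data.shape[1]

    out = {k: np.full(n_vox, np.nan) for k in ("S0", "INV", "T1_star", "T1")}
    rss = np.full(n_vox, np.nan)
    iters = np.zeros(n_vox, dtype=int)
    conv = np.zeros(n_vox, dtype=bool)

    cos_corr = np.cos(np.deg2rad(alpha) / 2.0)
    ln2 = np.log(2.0)
    for idx in np.flatnonzero(flat_mask):
        y = data[:, idx]
        s0_0 = y[-1]
        if s0_0 <= 0 or not np.all(np.isfinite(y)):
            continue
        t1s_0 = max(ti[int(np.argmin(y))] / ln2, ti[0] / ln2)
        p0 = np.array([s0_0, 2.0, t1s_0])
        try:
            res = least_squares(
                _ir_residual,
                p0,
                jac=_ir_jac,
                args=(ti, y),
                method="lm",
                xtol=LM_XTOL,
                max_nfev=LM_MAX_ITER * 4,
            )
        except Exception:
            continue
        s0, inv, t1s = res.x
        iters[idx] = res.nfev
        rss[idx] = 2.0 * res.cost
        if not res.success or t1s <= 0 or inv <= 1.0:
            continue
        t1 = t1s * cos_corr * (inv - 1.0)
        if not T1_RANGE_MS[0] < t1 < T1_RANGE_MS[1]:
            continue
        conv[idx] = True
        out["S0"][idx] = s0
        out["INV"][idx] = inv
        out["T1_star"][idx] = t1s
        out["T1"][idx] = t1

    valid = conv.reshape(shape)
    prov = {"contrast": IR_TRUEFISP, "n_ti": int(ti.size), "alpha_deg": float(alpha)}
    units = {"S0": "a.u.", "INV": "", "T1_star": "ms", "T1": "ms"}
    maps = {
        k: ParameterMap(k, v.reshape(shape), units[k], valid, dict(prov)) for k, v in out.items()
    }
    diags = FitDiagnostics(rss.reshape(shape), iters.reshape(shape), valid)
    return maps, diags


def _t2_residual(p, te, y):
    s0, t2, n = p
    return s0 * np.exp(-te / t2) + n - y


def _t2_jac(p, te, y):
    s0, t2, n = p
    e = np.exp(-te / t2)
    j = np.empty((te.size, 3))
    j[:, 0] = e
    j[:, 1] = s0 * e * te / t2**2
    j[:, 2] = 1.0
    return j


def _t2_init(te: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Log-linear start after subtracting the minimum signal as the floor."""
    n0 = float(y.min())
    z = y - n0
    use = z > max(1e-12, 1e-6 * y.max())
    if use.sum() >= 2:
        slope, icept = np.polyfit(te[use], np.log(z[use]), 1)
        if slope < 0:
            return np.array([np.exp(icept), -1.0 / slope, n0])
    return np.array([max(y[0] - n0, 1e-6), max(te[-1] / 3.0, 1.0), n0])


def fit_t2_map(
    series: AcquisitionSeries,
    mask: Optional[np.ndarray] = None,
    noise_sigma: Optional[float] = None,
) -> Tuple[Dict[str, ParameterMap], FitDiagnostics]:
    """Fit ``S(TE) = S0 exp(-TE/T2) + N`` per voxel.

    Uses the bounded trust-region variant of Levenberg–Marquardt with the
    physical constraint S0 >= 0; initialization is a log-linear regression on
    floor-subtracted signals.  When the background noise level
    ``noise_sigma`` is known, the magnitude signals are first corrected by
    squared subtraction and the residual floor N is then constrained to
    ``|N| <= noise_sigma`` — after the correction any genuine floor lies
    within the noise level, and the band breaks the strong N/T2
    anticorrelation that otherwise dominates the estimator variance at few
    echoes without the truncation bias an N >= 0 constraint would add.
    Voxels with T2 outside (1, 500) ms or a failed fit are masked.
    """
    if series.meta.contrast != MULTI_ECHO:
        raise ValueError("fit_t2_map requires a multi_echo series")
    te = series.meta.values
    if te.size < 4:
        raise ValueError("at least 4 echo times are required for a 3-parameter fit")
    shape = series.spatial_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    data = series.data.reshape(te.size, -1)
    if noise_sigma is not None and noise_sigma > 0:
        data = correct_rician_bias(data, noise_sigma)
        n_lo, n_hi = -noise_sigma, noise_sigma
    else:
        n_lo, n_hi = -np.inf, np.inf
    n_vox = data.shape[1]
    out = {k: np.full(n_vox, np.nan) for k in ("S0", "T2", "N")}
    rss = np.full(n_vox, np.nan)
    iters = np.zeros(n_vox, dtype=int)
    conv = np.zeros(n_vox, dtype=bool)

    for idx in np.flatnonzero(mask.reshape(-1)):
        y = data[:, idx]
        if y.max() <= 0 or not np.all(np.isfinite(y)):
            continue
        p0 = _t2_init(te, y)
        lo = [0.0, T2_RANGE_MS[0], n_lo]
        hi = [np.inf, T2_RANGE_MS[1], n_hi]
        p0 = np.clip(p0, [l if np.isfinite(l) else -1e300 for l in lo],
                     [h if np.isfinite(h) else 1e300 for h in hi])
        try:
            res = least_squares(
                _t2_residual,
                p0,
                jac=_t2_jac,
                args=(te, y),
                method="trf",
                bounds=(lo, hi),
                xtol=LM_XTOL,
                max_nfev=LM_MAX_ITER * 4,
            )
        except Exception:
            continue
        s0, t2, n = res.x
        iters[idx] = res.nfev
        rss[idx] = 2.0 * res.cost
        if not res.success or not T2_RANGE_MS[0] < t2 < T2_RANGE_MS[1]:
            continue
        conv[idx] = True
        out["S0"][idx] = s0
        out["T2"][idx] = t2
        out["N"][idx] = n

    valid = conv.reshape(shape)
    prov = {"contrast": MULTI_ECHO, "n_te": int(te.size)}
    units = {"S0": "a.u.", "T2": "ms", "N": "a.u."}
    maps = {
        k: ParameterMap(k, v.reshape(shape), units[k], valid, dict(prov)) for k, v in out.items()
    }
    diags = FitDiagnostics(rss.reshape(shape), iters.reshape(shape), valid)
    return maps, diags


# ---------------------------------------------------------------------------
# Closed-form maps
# ---------------------------------------------------------------------------

def compute_adc_map(
    s_b0: np.ndarray,
    s_b: np.ndarray,
    b: float,
    mask: Optional[np.ndarray] = None,
    noise_sigma: Optional[float] = None,
) -> ParameterMap:
    """Two-point ADC map: ``ADC = ln(S(b0)/S(b)) / b`` per voxel.

    When ``noise_sigma`` is given, both images are Rician-bias corrected by
    squared subtraction first (the high-b image sits at low SNR, where the
    magnitude bias materially inflates S(b) and deflates ADC).  Voxels with
    non-positive signals or attenuation reversal (S(b) > S(b0), which would
    give a negative ADC) are masked.
    """
    s_b0 = np.asarray(s_b0, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    if s_b0.shape != s_b.shape:
        raise ValueError("b=0 and high-b images must share a shape")
    if b <= 0:
        raise ValueError("b must be positive")
    if noise_sigma is not None and noise_sigma > 0:
        s_b0 = correct_rician_bias(s_b0, noise_sigma)
        s_b = correct_rician_bias(s_b, noise_sigma)
    if mask is None:
        mask = np.ones(s_b0.shape, dtype=bool)
    valid = np.asarray(mask, dtype=bool) & (s_b0 > 0) & (s_b > 0) & (s_b <= s_b0)
    adc = np.full(s_b0.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = np.log(s_b0[valid] / s_b[valid]) / b
    return ParameterMap("ADC", adc, "mm^2/s", valid, {"b": float(b), "bias_corrected": noise_sigma is not None})


def compute_mtr_map(m0_img: np.ndarray, msat_img: np.ndarray, mask: Optional[np.ndarray] = None) -> ParameterMap:
    """MTR map in percent: ``100 (M0 - Msat) / M0`` per voxel.

    Voxels with M0 <= 0 or MTR outside [-10, 100]% are masked.
    """
    m0 = np.asarray(m0_img, dtype=float)
    msat = np.asarray(msat_img, dtype=float)
    if m0.shape != msat.shape:
        raise ValueError("MT-off and MT-on images must share a shape")
    if mask is None:
        mask = np.ones(m0.shape, dtype=bool)
    valid = np.asarray(mask, dtype=bool) & (m0 > 0)
    mtr = np.full(m0.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr[valid] = 100.0 * (m0[valid] - msat[valid]) / m0[valid]
    in_range = np.zeros(m0.shape, dtype=bool)
    in_range[valid] = (mtr[valid] >= MTR_RANGE_PCT[0]) & (mtr[valid] <= MTR_RANGE_PCT[1])
    mtr[~in_range] = np.nan
    return ParameterMap("MTR", mtr, "%", in_range, {})
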