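"""Voxelwise BOLD-CVR mapping from a hypercapnia BOLD series.

The analysis chain is: (1) light preprocessing (optional Gaussian smoothing
within an intensity-derived brain mask; motion correction is an identity hook
because the synthetic data are motion-free), (2) a single global time-shift
aligning the end-tidal CO2 envelope with the mask-mean BOLD time course,
(3) a per-voxel ordinary-least-squares fit of

    BOLD(t) = b0 + b1 * etco2_centered(t - s) + b2 * l(t)

with ``l`` a zero-centered unit-step linear drift, and (4) conversion of the
coefficients to a CVR map referenced to the room-air state:

    CVR = b1 / (b0 - b1 * (mean(EtCO2) - baseline(EtCO2))) * 100   [%/mmHg]

where ``baseline(EtCO2)`` is the mean of the bottom 25% of the resampled
end-tidal samples. Referencing to the baseline rather than to the mean makes
the index the signal change per mmHg from the room-air state instead of from
a virtual zero-CO2 state. Voxels with a non-positive denominator are flagged
invalid and excluded from ROI summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .capno import EtCO2Curve, EtCO2Summary, summarize
from .errors import AlignmentError, ParameterError, ShapeError
from .protocol import Protocol

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BoldStudy:
    """4-D BOLD series with acquisition metadata.

    ``data`` has shape ``(nx, ny, nz, n_dynamics)``; ``mask`` is a 3-D brain
    mask; ``voxel_size`` the voxel edge lengths in mm.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray | None = None
    protocol: Protocol | None = None
    voxel_size: tuple[float, float, float] = (3.43, 3.43, 3.8)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, float)
        if d.ndim != 4:
            raise ShapeError("data must be 4-D (x, y, z, t)")
        if d.shape[-1] < 10:
            raise ParameterError("need at least 10 dynamics")
        if self.tr <= 0:
            raise ParameterError("tr must be > 0")
        if self.mask is not None:
            m = np.asarray(self.mask, bool)
            if m.shape != d.shape[:3]:
                raise ShapeError("mask shape must match spatial grid")
            if not m.any():
                raise ParameterError("mask is empty")
            object.__setattr__(self, "mask", m)
        object.__setattr__(self, "data", d)

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[-1]

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_dynamics) * self.tr

    def global_signal(self) -> np.ndarray:
        m = self.mask if self.mask is not None else np.ones(self.data.shape[:3], bool)
        return self.data[m].mean(axis=0)


@dataclass(frozen=True)
class GlmFitField:
    """Per-voxel GLM coefficients over the brain mask."""

    beta0: np.ndarray  # signal units
    beta1: np.ndarray  # signal units per mmHg
    beta2: np.ndarray  # signal units per dynamic
    residual_sd: np.ndarray
    mask: np.ndarray
    shift_s: float


@dataclass(frozen=True)
class CvrMap:
    """Voxelwise CVR in %/mmHg plus validity mask and provenance.

    ``valid`` marks in-mask voxels with a positive referencing denominator;
    ``n_excluded`` counts in-mask voxels flagged invalid (excluded from ROI
    means).
    """

    cvr: np.ndarray
    valid: np.ndarray
    shift_s: float
    summary: EtCO2Summary
    n_excluded: int = 0

    @property
    def n_invalid(self) -> int:
        return self.n_excluded


def motion_correct(study: BoldStudy) -> BoldStudy:
    """Identity hook: synthetic series are motion-free by construction."""
    return study


def preprocess(
    study: BoldStudy,
    fwhm: float = 0.0,
    mask_fraction: float = 0.2,
) -> BoldStudy:
    """Smooth spatially within the brain and derive an intensity mask.

    The brain mask keeps voxels whose temporal-mean intensity exceeds
    ``mask_fraction`` of the robust (98th percentile) maximum. Smoothing uses
    a Gaussian kernel of the given FWHM (mm) normalized within the mask, so a
    spatially uniform brain is left unchanged; ``fwhm = 0`` disables it.
    """
    if fwhm < 0:
        raise ParameterError("fwhm must be >= 0")
    study = motion_correct(study)
    mean_vol = study.data.mean(axis=-1)
    robust_max = np.percentile(mean_vol, 98.0)
    mask = mean_vol > mask_fraction * robust_max
    if not mask.any():
        raise ParameterError("empty brain mask after intensity threshold")
    if fwhm == 0:
        return replace(study, mask=mask)
    sigma_vox = tuple(
        fwhm * _FWHM_TO_SIGMA / vs for vs in study.voxel_size
    )
    norm = gaussian_filter(mask.astype(float), sigma_vox, mode="constant")
    data = np.empty_like(study.data)
    maskf = mask.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        for t in range(study.n_dynamics):
            sm = gaussian_filter(study.data[..., t] * maskf, sigma_vox, mode="constant")
            data[..., t] = np.where(mask, sm / norm, study.data[..., t])
    return replace(study, data=data, mask=mask)


def align_etco2(
    study: BoldStudy,
    curve: EtCO2Curve,
    search: tuple[float, float] = (-30.0, 30.0),
    step: float = 0.1,
    min_corr: float = 0.2,
    on_low_corr: str = "warn",
) -> EtCO2Curve:
    """Find the global shift maximizing EtCO2 / BOLD correlation.

    Returns the curve resampled onto the study's frame grid at the best
    shift ``s*`` (ties broken toward the smallest ``|s|``). When the maximum
    Pearson correlation falls below ``min_corr`` the alignment is considered
    unreliable: ``on_low_corr`` selects between raising
    :class:`AlignmentError` (``"error"``) and warning while falling back to
    ``s* = 0`` (``"warn"``).
    """
    lo, hi = search
    if hi - lo < 2 * study.tr:
        raise ParameterError("search range must cover at least one TR each side")
    g = study.global_signal()
    if np.std(g) == 0:
        raise AlignmentError("global BOLD signal is constant; shift undefined")
    t = study.frame_times()
    # project the constant and linear-drift components (which the GLM absorbs
    # anyway) out of BOTH sides: a one-sided detrend would leave the
    # envelope's own trend in the correlation denominator and bias the argmax
    Q, _ = np.linalg.qr(np.column_stack([np.ones(t.size), t]))
    g = g - Q @ (Q.T @ g)
    if np.std(g) == 0:
        raise AlignmentError("global BOLD signal is a pure trend; shift undefined")
    shifts = np.arange(lo, hi + step / 2, step)
    # one flattened interpolation for every candidate shift
    sample_times = (t[None, :] - shifts[:, None]).ravel()
    env = np.interp(sample_times, curve.breath_times, curve.breath_etco2)
    env = env.reshape(shifts.size, t.size)
    env_c = env - (env @ Q) @ Q.T
    denom = np.linalg.norm(env_c, axis=1) * np.linalg.norm(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = env_c @ g / denom
    corr = np.where(np.isfinite(corr), corr, -np.inf)
    best = corr.max()
    # tie-break toward the smallest |shift|
    candidates = np.flatnonzero(corr >= best - 1e-12)
    k = int(candidates[np.argmin(np.abs(shifts[candidates]))])
    s_star = float(shifts[k])
    # sub-step refinement: parabola through the peak and its neighbours
    if 0 < k < shifts.size - 1 and np.isfinite(corr[k - 1]) and np.isfinite(corr[k + 1]):
        c_prev, c_mid, c_next = corr[k - 1], corr[k], corr[k + 1]
        curvature = c_prev - 2.0 * c_mid + c_next
        if curvature < 0:
            offset = 0.5 * (c_prev - c_next) / curvature
            if abs(offset) <= 1.0:
                s_star += float(offset) * step
    if best < min_corr:
        msg = f"max EtCO2/BOLD correlation {best:.3f} < {min_corr}; shift unreliable"
        if on_low_corr == "error":
            raise AlignmentError(msg)
        warnings.warn(msg, stacklevel=2)
        s_star = 0.0
    return curve.resample(t, shift_s=s_star)


def fit_glm(study: BoldStudy, curve: EtCO2Curve) -> GlmFitField:
    """Per-voxel OLS on the design ``[1, etco2_centered, linear drift]``.

    The end-tidal regressor is the aligned curve resampled to the frame grid
    and centered; the drift covariate is the unit-step sequence
    ``-(N-1)/2, ..., (N-1)/2``.
    """
    if curve.resampled_etco2 is None:
        raise ParameterError("curve must be resampled to the frame grid first")
    x = np.asarray(curve.resampled_etco2, float)
    n = study.n_dynamics
    if x.size != n:
        raise ShapeError(f"regressor length {x.size} != n_dynamics {n}")
    if np.std(x) == 0:
        raise ParameterError("constant EtCO2 regressor: design is rank-deficient")
    mask = study.mask if study.mask is not None else np.ones(study.data.shape[:3], bool)
    drift = np.arange(n, dtype=float) - (n - 1) / 2.0
    design = np.column_stack([np.ones(n), x - x.mean(), drift])
    y = study.data[mask].T  # (n, n_voxels)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = max(n - 3, 1)
    rsd = np.sqrt((resid**2).sum(axis=0) / dof)

    def _field(v: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape, float)
        out[mask] = v
        return out

    return GlmFitField(
        beta0=_field(beta[0]),
        beta1=_field(beta[1]),
        beta2=_field(beta[2]),
        residual_sd=_field(rsd),
        mask=mask,
        shift_s=curve.shift_s,
    )


def compute_cvr_map(fits: GlmFitField, summary: EtCO2Summary) -> CvrMap:
    """Room-air-referenced CVR map from GLM coefficients (see module doc)."""
    denom = fits.beta0 - fits.beta1 * (summary.mean_etco2 - summary.baseline_etco2)
    valid = fits.mask & (denom > 0)
    cvr = np.zeros_like(fits.beta0)
    cvr[valid] = fits.beta1[valid] / denom[valid] * 100.0
    n_excluded = int((fits.mask & ~valid).sum())
    return CvrMap(cvr=cvr, valid=valid, shift_s=fits.shift_s, summary=summary,
                  n_excluded=n_excluded)


def adjust_cvr(
    cvr,
    b_etco2: float,
    d_etco2: float,
    ref_b: float = 38.1,
    ref_d: float = 8.0,
    coef_b: float = 2.0,
    coef_d: float = 4.0,
):
    """Normalize CVR for basal EtCO2 and EtCO2 rise.

    Individuals with higher resting EtCO2 show lower CVR (about 2% per mmHg),
    and larger hypercapnic EtCO2 rises likewise depress the index (about 4%
    per mmHg), so measured values are mapped to a common reference state
    (population mean basal EtCO2 38.1 mmHg; 8 mmHg rise) by the multiplicative
    linear correction

        cvr_adj = cvr * (1 + coef_b/100*(b - ref_b)) * (1 + coef_d/100*(d - ref_d))
    """
    factor = (1.0 + coef_b / 100.0 * (b_etco2 - ref_b)) * (
        1.0 + coef_d / 100.0 * (d_etco2 - ref_d)
    )
    if factor <= 0:
        raise ParameterError(f"adjustment factor {factor:.3g} <= 0")
    return cvr * factor


def roi_summary(cvr_map: CvrMap, rois: dict[str, np.ndarray]) -> pd.Series:
    """Mean CVR over valid voxels for each named ROI mask."""
    out: dict[str, float] = {}
    for name, mask in rois.items():
        m = np.asarray(mask, bool)
        if m.shape != cvr_map.cvr.shape:
            raise ShapeError(f"ROI {name!r} shape does not match map")
        sel = m & cvr_map.valid
        if not sel.any():
            warnings.warn(f"ROI {name!r} has no valid voxels; omitted", stacklevel=2)
            continue
        out[name] = float(cvr_map.cvr[sel].mean())
    return pd.Series(out, name="cvr_mmHg", dtype=float)


class BoldCvrModel:
    """BOLD-CVR mapping presented in the model/results idiom.

    ``BoldCvrModel(study, curve).fit()`` runs preprocessing, alignment, the
    per-voxel GLM and map conversion, returning a :class:`BoldCvrResults`.
    """

    def __init__(
        self,
        study: BoldStudy,
        curve: EtCO2Curve,
        fwhm: float = 0.0,
        search: tuple[float, float] = (-30.0, 30.0),
        step: float = 0.1,
        min_corr: float = 0.2,
        on_low_corr: str = "warn",
    ) -> None:
        self.study = study
        self.curve = curve
        self.fwhm = fwhm
        self.search = search
        self.step = step
        self.min_corr = min_corr
        self.on_low_corr = on_low_corr

    def fit(self) -> "BoldCvrResults":
        study = preprocess(self.study, fwhm=self.fwhm)
        aligned = align_etco2(
            study,
            self.curve,
            search=self.search,
            step=self.step,
            min_corr=self.min_corr,
            on_low_corr=self.on_low_corr,
        )
        fits = fit_glm(study, aligned)
        summary = summarize(aligned)
        cvr_map = compute_cvr_map(fits, summary)
        return BoldCvrResults(self, study, aligned, fits, summary, cvr_map)


class BoldCvrResults:
    """Fitted BOLD-CVR map with diagnostics."""

    def __init__(self, model, study, curve, glm, etco2_summary, cvr_map) -> None:
        self.model = model
        self.study = study
        self.curve = curve
        self.glm = glm
        self.etco2_summary = etco2_summary
        self.cvr_map = cvr_map

    @property
    def shift_s(self) -> float:
        return self.cvr_map.shift_s

    def whole_brain_cvr(self) -> float:
        sel = self.cvr_map.valid
        return float(self.cvr_map.cvr[sel].mean())

    def roi_table(self, rois: dict[str, np.ndarray]) -> pd.Series:
        return roi_summary(self.cvr_map, rois)

    def summary(self) -> str:
        s = self.etco2_summary
        lines = [
            "BOLD-CVR fit",
            "------------",
            f"dynamics            : {self.study.n_dynamics} (TR {self.study.tr} s)",
            f"brain voxels        : {int(self.glm.mask.sum())}",
            f"EtCO2 shift         : {self.shift_s:+.1f} s",
            f"EtCO2 mean/baseline : {s.mean_etco2:.2f} / {s.baseline_etco2:.2f} mmHg",
            f"EtCO2 delta         : {s.delta_etco2:.2f} mmHg",
            f"whole-brain CVR     : {self.whole_brain_cvr():.4f} %/mmHg",
            f"excluded voxels     : {self.cvr_map.n_excluded}",
        ]
        return "\n".join(lines)
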