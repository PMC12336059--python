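"""Venous oxygenation from TRUST (T2-relaxation-under-spin-tagging) MRI.

TRUST isolates pure venous blood in the superior sagittal sinus by
subtracting spin-labeled from control images — static tissue cancels while
labeled blood survives. Repeating the acquisition at several effective echo
times (eTEs) samples the T2 decay of the blood signal; a mono-exponential fit

    S(eTE) = S0 * exp(-eTE / T2)

to the spatially averaged signal of the brightest ROI voxels yields blood T2,
which a hematocrit-dependent calibration converts to venous oxygen saturation
Yv. Hematocrit is taken from literature sex-specific values (0.40 female,
0.42 male).

The shipped calibration is a strictly monotone quadratic in (1 - Yv) on the
transverse relaxation rate, R2 = A(Hct) + B(Hct)(1-Yv) + C(Hct)(1-Yv)^2 with
R2 in 1/s and T2 = 1000/R2 in ms. Its default coefficients are synthetic
placeholders with physiologically plausible output (venous T2 near 55 ms at
Yv = 0.6, Hct = 0.40); any alternative calibration can be supplied from YAML,
and the processing chain is calibration-agnostic (round-trip consistent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import curve_fit

from .errors import DomainError, FitError, ParameterError, ShapeError

#: Literature sex-specific hematocrit fractions.
SEX_HCT = {"F": 0.40, "M": 0.42}


@dataclass(frozen=True)
class CalibrationModel:
    """Monotone map between blood T2 (ms) and venous oxygenation Yv.

    ``a``, ``b``, ``c`` parameterize Hct-linear coefficients
    ``A = a0 + a1*Hct`` (and likewise B, C) of the rate model
    ``R2(1/s) = A + B*(1-Yv) + C*(1-Yv)^2``. ``yv_domain`` bounds the Yv
    range over which the map is used (and inverted).
    """

    a: tuple[float, float] = (3.0, 5.0)
    b: tuple[float, float] = (12.0, 20.0)
    c: tuple[float, float] = (20.0, 25.0)
    yv_domain: tuple[float, float] = (0.2, 0.98)

    def _coeffs(self, hct: float) -> tuple[float, float, float]:
        if not 0 < hct < 1:
            raise ParameterError("hct must be a fraction in (0, 1)")
        return (
            self.a[0] + self.a[1] * hct,
            self.b[0] + self.b[1] * hct,
            self.c[0] + self.c[1] * hct,
        )

    def yv_to_t2(self, yv: float, hct: float) -> float:
        """Forward map: oxygenation fraction -> blood T2 in ms."""
        lo, hi = self.yv_domain
        if not lo <= yv <= hi:
            raise DomainError(f"yv={yv} outside calibration domain [{lo}, {hi}]")
        A, B, C = self._coeffs(hct)
        u = 1.0 - yv
        r2 = A + B * u + C * u * u  # 1/s
        return 1000.0 / r2

    def t2_to_yv(self, t2: float, hct: float) -> float:
        """Inverse map: blood T2 in ms -> oxygenation fraction."""
        if t2 <= 0:
            raise DomainError("t2 must be > 0")
        A, B, C = self._coeffs(hct)
        r2 = 1000.0 / t2
        disc = B * B - 4.0 * C * (A - r2)
        lo, hi = self.yv_domain
        t2_lo = self.yv_to_t2(lo, hct)
        t2_hi = self.yv_to_t2(hi, hct)
        tol = 1e-9 * max(t2_lo, 1.0)
        if disc < 0 or not t2_lo - tol <= t2 <= t2_hi + tol:
            raise DomainError(
                f"t2={t2:.2f} ms outside admissible range "
                f"[{t2_lo:.2f}, {t2_hi:.2f}] ms at hct={hct}"
            )
        u = (-B + np.sqrt(disc)) / (2.0 * C)  # monotone branch, u = 1 - yv
        return float(np.clip(1.0 - u, lo, hi))

    def t2_domain(self, hct: float) -> tuple[float, float]:
        lo, hi = self.yv_domain
        return self.yv_to_t2(lo, hct), self.yv_to_t2(hi, hct)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            a=tuple(cfg["a"]),
            b=tuple(cfg["b"]),
            c=tuple(cfg["c"]),
            yv_domain=tuple(cfg.get("yv_domain", (0.2, 0.98))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "form": "r2_quadratic_in_1_minus_yv",
                    "a": list(self.a),
                    "b": list(self.b),
                    "c": list(self.c),
                    "yv_domain": list(self.yv_domain),
                },
                fh,
            )


@dataclass(frozen=True)
class TrustSeries:
    """Label/control image pairs across effective echo times.

    ``label`` and ``control`` have shape ``(n_ete, n_pairs, nx, ny)``;
    ``etes`` are the effective echo times in ms (>= 3, strictly increasing);
    ``roi`` is a boolean mask surrounding the sinus.
    """

    label: np.ndarray
    control: np.ndarray
    etes: np.ndarray
    roi: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.label, float)
        con = np.asarray(self.control, float)
        etes = np.asarray(self.etes, float)
        roi = np.asarray(self.roi, bool)
        if lab.ndim != 4 or lab.shape != con.shape:
            raise ShapeError("label/control must be 4-D with equal shapes")
        if etes.ndim != 1 or etes.size != lab.shape[0]:
            raise ShapeError("one eTE per volume group required")
        if etes.size < 3:
            raise ParameterError("need at least 3 distinct eTEs")
        if np.any(etes < 0) or np.any(np.diff(etes) <= 0):
            raise ParameterError("eTEs must be non-negative and strictly increasing")
        if roi.shape != lab.shape[2:]:
            raise ShapeError("roi shape must match image grid")
        object.__setattr__(self, "label", lab)
        object.__setattr__(self, "control", con)
        object.__setattr__(self, "etes", etes)
        object.__setattr__(self, "roi", roi)


@dataclass(frozen=True)
class T2Fit:
    """Mono-exponential decay fit across eTEs."""

    t2: float  # ms
    s0: float  # signal units
    rss: float  # residual sum of squares


@dataclass(frozen=True)
class OxygenationResult:
    yv: float  # fraction
    hct: float  # fraction
    t2: float  # ms
    fit: T2Fit | None = None


def subtract_pairs(series: TrustSeries) -> np.ndarray:
    """Mean control-minus-label difference image per eTE, shape (n_ete, nx, ny)."""
    return (series.control - series.label).mean(axis=1)


def select_voxels(diff_image: np.ndarray, roi: np.ndarray, k: int = 4) -> np.ndarray:
    """Flat indices of the k brightest ROI voxels (shortest-eTE image).

    Ties are broken deterministically toward the lower flat voxel index.
    """
    roi = np.asarray(roi, bool)
    n_roi = int(roi.sum())
    if n_roi < k:
        raise ParameterError(f"ROI has {n_roi} voxels; need at least k={k}")
    flat_idx = np.flatnonzero(roi.ravel())
    vals = np.asarray(diff_image, float).ravel()[flat_idx]
    order = np.argsort(-vals, kind="stable")  # stable => lower index wins ties
    return flat_idx[order[:k]]


def fit_t2(
    signals: np.ndarray,
    etes: np.ndarray,
    t2_start: float = 60.0,
    maxfev: int = 2000,
) -> T2Fit:
    """Nonlinear least-squares mono-exponential fit ``S0 * exp(-eTE/T2)``.

    Initialized from the log-linear regression of ``log S`` on eTE when all
    signals are positive; otherwise from ``(max signal, t2_start)``.
    """
    s = np.asarray(signals, float)
    e = np.asarray(etes, float)
    if s.size != e.size:
        raise ShapeError("signals and etes must have equal length")
    if s.size < 3:
        raise ParameterError("need at least 3 eTE points")
    if np.all(s > 0):
        slope, intercept = np.polyfit(e, np.log(s), 1)
        t2_init = -1.0 / slope if slope < 0 else t2_start
        s0_init = float(np.exp(intercept))
    else:
        t2_init, s0_init = t2_start, float(max(s.max(), 1e-6))
    t2_init = float(np.clip(t2_init, 1.0, 1000.0))

    def model(ete, s0, t2):
        return s0 * np.exp(-ete / t2)

    try:
        popt, _ = curve_fit(model, e, s, p0=(s0_init, t2_init), maxfev=maxfev)
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise FitError(f"mono-exponential fit did not converge: {exc}") from exc
    s0, t2 = float(popt[0]), float(popt[1])
    if t2 <= 0 or s0 <= 0:
        raise FitError(f"non-physical fit: s0={s0:.3g}, t2={t2:.3g}")
    rss = float(((s - model(e, s0, t2)) ** 2).sum())
    return T2Fit(t2=t2, s0=s0, rss=rss)


def t2_to_yv(t2: float, hct: float, calib: CalibrationModel) -> OxygenationResult:
    """Convert fitted blood T2 to venous oxygenation via the calibration."""
    yv = calib.t2_to_yv(t2, hct)
    return OxygenationResult(yv=yv, hct=hct, t2=t2)


def estimate_yv(
    series: TrustSeries,
    hct: float,
    calib: CalibrationModel | None = None,
    k: int = 4,
) -> OxygenationResult:
    """Full TRUST chain: subtraction, top-k selection, T2 fit, calibration."""
    calib = calib if calib is not None else CalibrationModel()
    diffs = subtract_pairs(series)
    idx = select_voxels(diffs[0], series.roi, k=k)
    signals = diffs.reshape(diffs.shape[0], -1)[:, idx].mean(axis=1)
    fit = fit_t2(signals, series.etes)
    yv = calib.t2_to_yv(fit.t2, hct)
    return OxygenationResult(yv=yv, hct=hct, t2=fit.t2, fit=fit)
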