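"""Phase-contrast flow quantification and flow-based CVR.

A single-slice phase-contrast scan through the superior sagittal sinus (SSS)
encodes through-plane blood velocity in the image phase, up to the encoding
velocity ``venc``: true velocities beyond ``venc`` wrap around (aliasing) and
must be unwrapped before integration. Summing velocity over a sinus ROI times
the voxel area gives the blood flux in ml/min; dividing by the SSS share of
total brain drainage (0.46), brain volume and tissue density converts flux to
unit-mass CBF in ml/100 g/min:

    CBF = BF * 100 / (0.46 * Bvol * 1.06)

Flow-based CVR is the percent CBF change between hypercapnia and room air per
mmHg of end-tidal CO2 rise:

    CVR = ((CBF_HC - CBF_RA) / CBF_RA * 100) / (EtCO2_HC - EtCO2_RA)

which is independent of brain volume because it is a CBF ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ShapeError

#: SSS drainage as a fraction of total brain blood flow.
SSS_FLOW_FRACTION = 0.46
#: Brain tissue mass density, g/ml.
BRAIN_DENSITY = 1.06


@dataclass(frozen=True)
class PcScan:
    """Single-slice phase-contrast acquisition.

    ``velocity`` is the through-plane velocity map in cm/s (phase image scaled
    by venc), ``cd_magnitude`` the complex-difference magnitude (bright over
    flowing blood), ``voxel_area`` the in-plane voxel area in mm^2 and
    ``acquisition_window`` the (start, end) time of the scan in seconds on
    the capnograph clock.
    """

    velocity: np.ndarray
    cd_magnitude: np.ndarray
    venc: float
    voxel_area: float
    acquisition_window: tuple[float, float] = (0.0, 0.0)
    unwrapped: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.velocity, float)
        m = np.asarray(self.cd_magnitude, float)
        if v.ndim != 2 or v.shape != m.shape:
            raise ShapeError("velocity and cd_magnitude must be equal-shape 2-D")
        if self.venc <= 0:
            raise ParameterError("venc must be > 0")
        if self.voxel_area <= 0:
            raise ParameterError("voxel_area must be > 0")
        object.__setattr__(self, "velocity", v)
        object.__setattr__(self, "cd_magnitude", m)


@dataclass(frozen=True)
class SinusRoi:
    """Boolean mask delineating the sinus on the PC slice."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, bool)
        if m.ndim != 2:
            raise ShapeError("mask must be 2-D")
        if not m.any():
            raise ParameterError("ROI is empty")
        _, n_comp = ndimage.label(m)
        if n_comp != 1:
            raise ParameterError(f"ROI must be connected (found {n_comp} components)")
        object.__setattr__(self, "mask", m)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class FlowResult:
    """Integrated flux and derived unit-mass CBF."""

    bf: float  # ml/min
    cbf: float  # ml/100 g/min
    bvol: float  # ml
    sinus_fraction: float = SSS_FLOW_FRACTION
    density: float = BRAIN_DENSITY
    etco2: float | None = None  # mmHg during the scan


@dataclass(frozen=True)
class CvrResult:
    """Flow-based CVR with the four quantities it was computed from."""

    cvr: float  # %/mmHg
    cbf_ra: float
    cbf_hc: float
    etco2_ra: float
    etco2_hc: float


def unwrap_velocity(
    scan: PcScan, roi: SinusRoi, near_frac: float = 0.5
) -> PcScan:
    """Correct venc aliasing inside the ROI.

    The dominant flow direction is the sign of the ROI-median velocity.
    Voxels opposing that direction whose value lies within
    ``near_frac * venc`` of the opposite encoding limit are assumed wrapped
    and corrected by ``2 * venc`` toward the dominant direction. Idempotent:
    corrected voxels exceed venc in magnitude and are never re-selected.
    """
    v = scan.velocity.copy()
    med = float(np.median(v[roi.mask]))
    s = 1.0 if med >= 0 else -1.0
    opposite_limit = -s * scan.venc
    wrapped = (
        roi.mask
        & (np.sign(v) == -s)
        & (np.abs(v - opposite_limit) < near_frac * scan.venc)
    )
    v[wrapped] += s * 2.0 * scan.venc
    return replace(scan, velocity=v, unwrapped=True)


def integrate_flux(scan: PcScan, roi: SinusRoi) -> float:
    """ROI-integrated blood flux in ml/min.

    ``sum(velocity [cm/s]) * voxel_area [mm^2] * 0.01 [cm^2/mm^2] * 60 [s/min]``
    with the sign convention that flow along the ROI-median direction is
    positive.
    """
    if roi.mask.shape != scan.velocity.shape:
        raise ShapeError("ROI shape does not match scan")
    vals = scan.velocity[roi.mask]
    med = float(np.median(vals))
    sgn = 1.0 if med >= 0 else -1.0
    return float(sgn * vals.sum() * scan.voxel_area * 0.01 * 60.0)


def compute_cbf(
    bf: float,
    bvol: float,
    sinus_fraction: float = SSS_FLOW_FRACTION,
    density: float = BRAIN_DENSITY,
) -> float:
    """Unit-mass CBF (ml/100 g/min) from sinus flux and brain volume."""
    if bvol <= 0:
        raise ParameterError("bvol must be > 0")
    return float(bf * 100.0 / (sinus_fraction * bvol * density))


def flow_result(
    scan: PcScan,
    roi: SinusRoi,
    bvol: float,
    etco2: float | None = None,
    sinus_fraction: float = SSS_FLOW_FRACTION,
    density: float = BRAIN_DENSITY,
) -> FlowResult:
    """Convenience: integrate flux and convert to CBF in one step."""
    bf = integrate_flux(scan, roi)
    cbf = compute_cbf(bf, bvol, sinus_fraction, density)
    return FlowResult(bf=bf, cbf=cbf, bvol=bvol, sinus_fraction=sinus_fraction,
                      density=density, etco2=etco2)


def compute_cbf_cvr(
    cbf_ra: float, cbf_hc: float, etco2_ra: float, etco2_hc: float
) -> CvrResult:
    """Flow-based CVR in %/mmHg from paired room-air/hypercapnia scans.

    Because the numerator is a relative CBF change, raw flux values may be
    passed instead of CBF — the brain-volume normalization cancels.
    """
    if etco2_hc == etco2_ra:
        raise ParameterError("EtCO2 values are equal; CVR undefined")
    if cbf_ra <= 0:
        raise ParameterError("baseline CBF must be > 0")
    cvr = ((cbf_hc - cbf_ra) / cbf_ra * 100.0) / (etco2_hc - etco2_ra)
    return CvrResult(cvr=float(cvr), cbf_ra=cbf_ra, cbf_hc=cbf_hc,
                     etco2_ra=etco2_ra, etco2_hc=etco2_hc)


def sinus_roi_from_magnitude(
    cd_magnitude: np.ndarray,
    percentile: float = 97.0,
    seed_box: tuple[slice, slice] | None = None,
) -> SinusRoi:
    """Threshold helper delineating a bright sinus on the magnitude image.

    Intended for synthetic tests only (the reference procedure draws the ROI
    manually): keeps the largest connected component above the given
    percentile of intensities, optionally restricted to a seed box.
    """
    img = np.asarray(cd_magnitude, float)
    region = img[seed_box] if seed_box is not None else img
    thr = np.percentile(region, percentile)
    mask = img > thr
    if seed_box is not None:
        box = np.zeros_like(mask)
        box[seed_box] = True
        mask &= box
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ParameterError("no suprathreshold voxels for ROI")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return SinusRoi(labels == keep)
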