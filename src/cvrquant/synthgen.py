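"""Synthetic raw-data generator with known ground truth.

Every input the quantification pipeline consumes can be rendered here from
explicit ground-truth parameters, so each downstream stage is testable by
recovery: capnograph traces whose breath maxima follow the gas-block
schedule, 4-D BOLD series driven linearly by the end-tidal envelope,
phase-contrast velocity/magnitude pairs whose ROI-integrated flux equals the
configured value exactly before noise (with optional venc aliasing), TRUST
label/control series with mono-exponential venous decay, and full two-group
pre/post cohorts drawn from configurable group means and SDs.

Modeling choices
----------------
* Breaths are raised cosines (trough near 2 mmHg); only the per-breath
  maxima matter downstream. Each breath's end-tidal level is the gas-block
  level at the moment of its peak, plus optional breath-to-breath
  physiological jitter (``envelope_sd``). That jittered envelope is the
  *true* arterial drive: the BOLD forward model consumes it, while the
  capnograph trace adds only a small instrument noise on top — measurement
  error is not physiology.
* The BOLD forward model is the regression model itself (linear in the
  delayed end-tidal curve, multiplicative in baseline signal) plus a linear
  drift and white Gaussian noise; no hemodynamic convolution.
* The sinus on the PC slice is an ellipse with a parabolic velocity
  profile, scaled so the discrete ROI integral matches the configured flux
  exactly. Velocities beyond venc are stored wrapped by 2*venc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .boldcvr import BoldStudy
from .capno import CapnoTrace, EtCO2Curve
from .errors import DomainError, ParameterError, ShapeError
from .pcflow import PcScan, SinusRoi
from .protocol import Protocol, bold_protocol, pc_protocol, PC_SCAN_WINDOWS
from .trustox import CalibrationModel, TrustSeries, SEX_HCT

DEFAULT_ETES = (0.0, 40.0, 80.0, 160.0)


@dataclass(frozen=True)
class GroundTruth:
    """True values of everything the pipeline estimates.

    ``cvr_map`` is the BOLD-CVR in %/mmHg, a scalar (uniform brain) or a 3-D
    array on the BOLD grid. Fluxes are sinus blood fluxes in ml/min for the
    room-air and hypercapnic PC scans. ``bold_delay`` is the lag of the BOLD
    response behind the end-tidal recording in seconds.
    """

    cvr_map: float | np.ndarray = 0.17
    etco2_ra: float = 38.1
    etco2_hc: float = 46.1
    flux_ra: float = 380.0
    flux_hc: float = 500.0
    t2_blood: float = 57.0  # ms
    yv_true: float = 0.61  # fraction
    drift_slope: float = 0.0  # signal units per dynamic
    noise_sd: float = 0.0  # signal units
    bold_delay: float = 6.0  # s

    def __post_init__(self) -> None:
        if self.etco2_hc <= self.etco2_ra:
            raise ParameterError("etco2_hc must exceed etco2_ra")
        if self.flux_ra <= 0 or self.flux_hc <= 0:
            raise ParameterError("flux values must be > 0")
        if not 0 < self.yv_true < 1:
            raise ParameterError("yv_true must be in (0, 1)")
        if self.t2_blood <= 0:
            raise ParameterError("t2_blood must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# capnograph


def generate_capno_trace(
    protocol: Protocol,
    truth: GroundTruth,
    breath_period: float = 4.0,
    seed=0,
    trough: float = 2.0,
    envelope_sd: float = 0.0,
    instrument_sd: float = 0.0,
) -> tuple[CapnoTrace, EtCO2Curve]:
    """Render a capnograph trace and return it with its true envelope.

    The trace is a sequence of raised-cosine breaths at ``breath_period``
    seconds each; the k-th breath peaks at ``(k + 1/2) * breath_period`` at
    the gas-block end-tidal level of that moment (plus physiological jitter
    ``envelope_sd``). The returned :class:`EtCO2Curve` holds the true
    per-breath envelope — the arterial drive a forward model should consume.
    """
    rng = _rng(seed)
    if breath_period <= 2.0 / protocol.capno_rate:
        raise ParameterError("breath_period must exceed two capnograph samples")
    total = protocol.total_duration
    n_breaths = int(np.floor(total / breath_period))
    if n_breaths < 1:
        raise ParameterError("protocol shorter than one breath")
    dt = 1.0 / protocol.capno_rate
    time = np.arange(0.0, n_breaths * breath_period - dt / 2, dt)
    peak_times = (np.arange(n_breaths) + 0.5) * breath_period
    hc = protocol.is_hypercapnic(peak_times)
    levels = np.where(hc, truth.etco2_hc, truth.etco2_ra).astype(float)
    if envelope_sd > 0:
        levels = levels + rng.normal(0.0, envelope_sd, n_breaths)
    breath_idx = np.minimum((time / breath_period).astype(int), n_breaths - 1)
    phase = 2.0 * np.pi * (time - breath_idx * breath_period) / breath_period
    shape = 0.5 * (1.0 - np.cos(phase))  # 0 at breath edges, 1 at the peak
    pco2 = trough + (levels[breath_idx] - trough) * shape
    if instrument_sd > 0:
        pco2 = pco2 + rng.normal(0.0, instrument_sd, pco2.size)
    pco2 = np.clip(pco2, 0.0, None)
    trace = CapnoTrace(time, pco2)
    envelope = EtCO2Curve(peak_times, levels)
    return trace, envelope


# ---------------------------------------------------------------------------
# BOLD


def ellipsoid_mask(grid: tuple[int, int, int], margin: float = 0.5) -> np.ndarray:
    """Brain-like ellipsoid mask inscribed in the grid."""
    nx, ny, nz = grid
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = nx / 2 - margin, ny / 2 - margin, nz / 2 - margin
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def generate_bold_series(
    protocol: Protocol,
    truth: GroundTruth,
    etco2: EtCO2Curve,
    seed=0,
    grid: tuple[int, int, int] = (16, 16, 8),
    beta0: float = 1000.0,
    voxel_size: tuple[float, float, float] = (3.43, 3.43, 3.8),
) -> BoldStudy:
    """Forward-model a 4-D BOLD series from the true end-tidal envelope.

    Inside the brain mask each voxel time series is

        beta0 * (1 + cvr/100 * (EtCO2(t - bold_delay) - etco2_ra))
        + drift_slope * l(t) + N(0, noise_sd)

    with ``l`` the zero-centered unit-step drift term. Outside the mask the
    signal is pure noise (air).
    """
    rng = _rng(seed)
    if protocol.tr is None or protocol.n_dynamics is None:
        raise ParameterError("protocol must carry MRI timing")
    n = protocol.n_dynamics
    t = protocol.frame_times()
    reg = etco2.value_at(t - truth.bold_delay, shift_s=0.0)
    if reg.size != n:
        raise ShapeError("regressor length does not match n_dynamics")
    mask = ellipsoid_mask(grid)
    cvr = np.asarray(truth.cvr_map, float)
    if cvr.ndim == 0:
        cvr = np.full(grid, float(cvr))
    elif cvr.shape != grid:
        raise ShapeError("cvr_map shape must match the BOLD grid")
    drift = np.arange(n, dtype=float) - (n - 1) / 2.0
    response = 1.0 + cvr[..., None] / 100.0 * (reg - truth.etco2_ra)[None, None, None, :]
    data = np.where(mask[..., None], beta0 * response, 0.0)
    data = data + truth.drift_slope * drift * mask[..., None]
    if truth.noise_sd > 0:
        data = data + rng.normal(0.0, truth.noise_sd, data.shape)
    return BoldStudy(
        data=data, tr=protocol.tr, mask=mask, protocol=protocol,
        voxel_size=voxel_size,
    )


# ---------------------------------------------------------------------------
# phase contrast


def _sinus_profile(
    grid: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Parabolic unit profile over an elliptical sinus; returns (profile, mask)."""
    nx, ny = grid
    x, y = np.ogrid[:nx, :ny]
    r2 = ((x - center[0]) / semi_axes[0]) ** 2 + ((y - center[1]) / semi_axes[1]) ** 2
    mask = r2 < 1.0
    profile = np.where(mask, 1.0 - r2, 0.0)
    return profile, mask


def wrap_velocity(v: np.ndarray, venc: float) -> np.ndarray:
    """Store velocities within [-venc, venc] by wrapping with multiples of 2*venc."""
    return v - 2.0 * venc * np.round(v / (2.0 * venc))


def generate_pc_scan(
    flux: float,
    venc: float,
    seed=0,
    grid: tuple[int, int] = (64, 64),
    voxel_size_mm: float = 0.4,
    center: tuple[float, float] | None = None,
    semi_axes: tuple[float, float] = (11.0, 9.0),
    noise_sd: float = 0.0,
    magnitude_background: float = 100.0,
    magnitude_amplitude: float = 900.0,
    acquisition_window: tuple[float, float] = (0.0, 60.0),
) -> tuple[PcScan, SinusRoi]:
    """Render one PC velocity/magnitude pair carrying the given flux.

    The velocity profile is parabolic over an elliptical sinus and scaled so
    that ``sum(v) * voxel_area * 0.01 * 60`` equals ``flux`` exactly before
    noise. Velocities beyond venc are stored aliased (wrapped by 2*venc).
    The generator refuses configurations whose ROI-mean velocity exceeds
    2*venc or whose peak reaches 3*venc: a single +-2*venc correction could
    not recover them.
    """
    rng = _rng(seed)
    if flux < 0:
        raise ParameterError("flux must be >= 0")
    if center is None:
        center = ((grid[0] - 1) / 2, (grid[1] - 1) / 2)
    profile, mask = _sinus_profile(grid, center, semi_axes)
    voxel_area = voxel_size_mm**2
    v = np.zeros(grid)
    if flux > 0:
        scale = flux / (profile.sum() * voxel_area * 0.01 * 60.0)
        v = profile * scale
        mean_v = float(v[mask].mean())
        peak_v = float(v.max())
        if mean_v > 2.0 * venc or peak_v >= 3.0 * venc:
            raise ParameterError(
                f"flux {flux} ml/min implies mean velocity {mean_v:.1f} cm/s "
                f"(peak {peak_v:.1f}) at venc {venc}: aliasing irrecoverable"
            )
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, v.shape)
    stored = wrap_velocity(v, venc)
    magnitude = magnitude_background + magnitude_amplitude * profile
    if noise_sd > 0:
        magnitude = magnitude + rng.normal(0.0, noise_sd * 10.0, magnitude.shape)
    scan = PcScan(
        velocity=stored,
        cd_magnitude=magnitude,
        venc=venc,
        voxel_area=voxel_area,
        acquisition_window=acquisition_window,
    )
    return scan, SinusRoi(mask)


def generate_pc_pair(
    truth: GroundTruth,
    venc_ra: float = 40.0,
    venc_hc: float = 60.0,
    seed=0,
    grid: tuple[int, int] = (64, 64),
    noise_sd: float = 0.0,
    **kwargs,
) -> tuple[PcScan, PcScan, SinusRoi]:
    """Room-air and hypercapnic PC scans sharing one sinus geometry.

    The room-air scan covers the first PC acquisition window and the
    hypercapnic scan the third (the second falls in the physiological
    transient and is not rendered).
    """
    rng = _rng(seed)
    ra, roi = generate_pc_scan(
        truth.flux_ra, venc_ra, seed=rng, grid=grid, noise_sd=noise_sd,
        acquisition_window=PC_SCAN_WINDOWS[0], **kwargs,
    )
    hc, _ = generate_pc_scan(
        truth.flux_hc, venc_hc, seed=rng, grid=grid, noise_sd=noise_sd,
        acquisition_window=PC_SCAN_WINDOWS[2], **kwargs,
    )
    return ra, hc, roi


# ---------------------------------------------------------------------------
# TRUST


def generate_trust_series(
    truth: GroundTruth,
    etes=DEFAULT_ETES,
    calib: CalibrationModel | None = None,
    hct: float = 0.40,
    noise_sd: float = 0.0,
    seed=0,
    grid: tuple[int, int] = (16, 16),
    n_pairs: int = 3,
    s0: float = 1000.0,
) -> TrustSeries:
    """Render a TRUST label/control series for the configured oxygenation.

    Blood T2 is obtained from ``calib`` at ``truth.yv_true`` and ``hct``.
    Control images carry static tissue plus sinus blood signal
    ``s0 * w * exp(-eTE / T2)`` (w = 1 in a 2x2 core, 0.6 in a partial-volume
    ring); label images carry the same static tissue, so subtraction cancels
    everything but blood. Independent Gaussian noise is added to label and
    control alike.
    """
    rng = _rng(seed)
    calib = calib if calib is not None else CalibrationModel()
    lo, hi = calib.yv_domain
    if not lo <= truth.yv_true <= hi:
        raise DomainError(f"yv_true={truth.yv_true} outside calibration domain")
    t2 = calib.yv_to_t2(truth.yv_true, hct)
    etes = np.asarray(etes, float)
    nx, ny = grid
    cx, cy = nx // 2, ny // 2
    weights = np.zeros(grid)
    weights[cx - 1 : cx + 1, cy - 1 : cy + 1] = 1.0  # bright 2x2 core
    ring = np.zeros(grid, bool)
    ring[cx - 2 : cx + 2, cy - 2 : cy + 2] = True
    ring &= weights == 0
    weights[ring] = 0.6
    static = 200.0 + 300.0 * rng.random(grid)
    decay = np.exp(-etes / t2)
    label = np.empty((etes.size, n_pairs, nx, ny))
    control = np.empty_like(label)
    for i in range(etes.size):
        blood = s0 * weights * decay[i]
        for p in range(n_pairs):
            label[i, p] = static
            control[i, p] = static + blood
    if noise_sd > 0:
        label = label + rng.normal(0.0, noise_sd, label.shape)
        control = control + rng.normal(0.0, noise_sd, control.shape)
    roi = np.zeros(grid, bool)
    roi[cx - 3 : cx + 3, cy - 3 : cy + 3] = True
    return TrustSeries(label=label, control=control, etes=etes, roi=roi)


# ---------------------------------------------------------------------------
# cohorts


#: Group-level (mean, SD) defaults per measure, group and state. CBF-CVR and
#: BOLD-CVR are %/mmHg, Yv is percent, basal CBF is ml/100 g/min. The CVR and
#: Yv entries follow the reported group summaries of the two-group caffeine
#: crossover design; the BOLD-CVR summary is only reported pooled and is used
#: for both groups. Basal-CBF means are unreported; values here are realistic
#: young-adult choices consistent with the reported percent reductions and
#: pre-caffeine SDs.
DEFAULT_MEASURES: dict = {
    "cbf": {
        "naive": {"pre": (62.0, 15.4), "post": (42.7, 10.6)},
        "habituated": {"pre": (55.0, 5.9), "post": (45.8, 4.9)},
    },
    "yv": {
        "naive": {"pre": (60.8, 9.2), "post": (46.9, 3.7)},
        "habituated": {"pre": (53.6, 3.9), "post": (49.6, 6.6)},
    },
    "cbf_cvr": {
        "naive": {"pre": (4.5, 0.9), "post": (3.0, 0.9)},
        "habituated": {"pre": (5.1, 1.5), "post": (3.7, 1.3)},
    },
    "bold_cvr": {
        "naive": {"pre": (0.17, 0.04), "post": (0.15, 0.05)},
        "habituated": {"pre": (0.17, 0.04), "post": (0.15, 0.05)},
    },
}

#: Sex composition per group (3M/5F naive, 5M/3F habituated) and age (mean, SD).
DEFAULT_SEXES = {
    "naive": ("M", "M", "M", "F", "F", "F", "F", "F"),
    "habituated": ("M", "M", "M", "M", "M", "F", "F", "F"),
}
DEFAULT_AGES = {"naive": (28.6, 5.2), "habituated": (29.1, 2.7)}

#: Rendering-validity bounds used to redraw degenerate samples. They are
#: deliberately loose — wide enough that redraws are vanishingly rare under
#: the default configuration (tight bounds would truncate the normals and
#: bias the realized group means) — and only exclude values the renderers
#: cannot represent: CBF must stay positive for a positive sinus flux, Yv
#: must stay inside the oximetry-calibration domain, and CBF-CVR must keep
#: the hypercapnic flux positive.
_MEASURE_BOUNDS = {
    "cbf": (5.0, 150.0),
    "yv": (25.0, 95.0),
    "cbf_cvr": (-5.0, 15.0),
    "bold_cvr": (-1.0, 1.5),
}


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a two-group pre/post cohort simulation."""

    measures: dict = field(default_factory=lambda: DEFAULT_MEASURES)
    n_per_group: int = 8
    correlation: float = 0.7  # within-subject pre/post correlation
    groups: tuple[str, ...] = ("naive", "habituated")
    etco2_ra_mean: float = 38.1
    etco2_ra_sd: float = 3.0
    delta_etco2_mean: float = 8.0
    delta_etco2_sd: float = 1.0
    bvol_mean: float = 1250.0
    bvol_sd: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if not -1.0 <= self.correlation <= 1.0:
            raise ParameterError("correlation must be in [-1, 1]")
        for measure, per_group in self.measures.items():
            for group, per_state in per_group.items():
                for state, (mean, sd) in per_state.items():
                    if sd < 0:
                        raise ParameterError(
                            f"SD < 0 for {measure}/{group}/{state}"
                        )

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if "measures" in cfg:
            cfg["measures"] = {
                m: {g: {s: tuple(v) for s, v in per_s.items()}
                    for g, per_s in per_g.items()}
                for m, per_g in cfg["measures"].items()
            }
        if "groups" in cfg:
            cfg["groups"] = tuple(cfg["groups"])
        return cls(**cfg)

    def to_yaml(self, path) -> None:
        cfg = {
            "measures": {
                m: {g: {s: list(v) for s, v in per_s.items()}
                    for g, per_s in per_g.items()}
                for m, per_g in self.measures.items()
            },
            "n_per_group": self.n_per_group,
            "correlation": self.correlation,
            "groups": list(self.groups),
            "etco2_ra_mean": self.etco2_ra_mean,
            "etco2_ra_sd": self.etco2_ra_sd,
            "delta_etco2_mean": self.delta_etco2_mean,
            "delta_etco2_sd": self.delta_etco2_sd,
            "bvol_mean": self.bvol_mean,
            "bvol_sd": self.bvol_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh)


def _draw_pair(
    rng: np.random.Generator,
    pre_ms: tuple[float, float],
    post_ms: tuple[float, float],
    corr: float,
    bounds: tuple[float, float],
    max_tries: int = 200,
) -> tuple[float, float]:
    """Bivariate-normal (pre, post) draw, redrawn until inside bounds."""
    m = np.array([pre_ms[0], post_ms[0]])
    cov = np.array(
        [
            [pre_ms[1] ** 2, corr * pre_ms[1] * post_ms[1]],
            [corr * pre_ms[1] * post_ms[1], post_ms[1] ** 2],
        ]
    )
    lo, hi = bounds
    for _ in range(max_tries):
        pre, post = rng.multivariate_normal(m, cov)
        if lo <= pre <= hi and lo <= post <= hi:
            return float(pre), float(post)
    raise ParameterError("could not draw in-bounds values; check spec means/SDs")


@dataclass
class RenderedSubjectState:
    """Raw inputs rendered for one subject in one caffeine state."""

    capno_pc: CapnoTrace | None = None
    pc_ra: PcScan | None = None
    pc_hc: PcScan | None = None
    pc_roi: SinusRoi | None = None
    capno_bold: CapnoTrace | None = None
    bold: BoldStudy | None = None
    trust: TrustSeries | None = None


@dataclass
class Cohort:
    """Simulated cohort: ground truth table plus rendered raw inputs.

    ``truth`` has one row per subject x state with the drawn true values;
    ``inputs[(subject_id, state)]`` holds the rendered raw data for the
    requested modalities.
    """

    spec: CohortSpec
    truth: pd.DataFrame
    inputs: dict[tuple[str, str], RenderedSubjectState]
    calib: CalibrationModel

    def subjects(self) -> pd.DataFrame:
        cols = ["subject_id", "group", "sex", "age", "bvol"]
        return self.truth[cols].drop_duplicates().reset_index(drop=True)


# Rendering noise defaults: modest, physiologically plausible levels.
RENDER_DEFAULTS = dict(
    breath_period=4.0,
    envelope_sd=0.5,  # mmHg breath-to-breath end-tidal jitter
    instrument_sd=0.1,  # mmHg capnograph noise
    bold_grid=(16, 16, 8),
    bold_beta0=1000.0,
    bold_noise_sd=10.0,  # 1% of baseline signal
    drift_slope_sd=0.05,  # signal units per dynamic
    pc_grid=(64, 64),
    pc_noise_sd=0.3,  # cm/s
    venc_ra=40.0,
    venc_hc=60.0,
    trust_noise_sd=15.0,
    trust_n_pairs=3,
)


def generate_cohort(
    spec: CohortSpec,
    render: tuple[str, ...] = (),
    seed=None,
    calib: CalibrationModel | None = None,
    render_params: dict | None = None,
) -> Cohort:
    """Draw a cohort and optionally render its raw inputs.

    ``render`` selects modalities to rasterize per subject x state:
    any of ``"pc"``, ``"bold"``, ``"trust"``. An empty tuple draws the
    ground-truth table only (fast path for statistics simulations).
    """
    rng = _rng(spec.seed if seed is None else seed)
    calib = calib if calib is not None else CalibrationModel()
    params = dict(RENDER_DEFAULTS)
    if render_params:
        params.update(render_params)
    unknown = set(render) - {"pc", "bold", "trust"}
    if unknown:
        raise ParameterError(f"unknown modalities: {sorted(unknown)}")

    rows = []
    inputs: dict[tuple[str, str], RenderedSubjectState] = {}
    for group in spec.groups:
        sexes = DEFAULT_SEXES.get(group)
        age_mean, age_sd = DEFAULT_AGES.get(group, (29.0, 4.0))
        for i in range(spec.n_per_group):
            sid = f"{group}_{i + 1:02d}"
            sex = sexes[i % len(sexes)] if sexes else ("F", "M")[i % 2]
            age = float(np.clip(rng.normal(age_mean, age_sd), 20.0, 45.0))
            bvol = float(np.clip(rng.normal(spec.bvol_mean, spec.bvol_sd),
                                 1000.0, 1550.0))
            etco2_ra = float(np.clip(rng.normal(spec.etco2_ra_mean,
                                                spec.etco2_ra_sd), 30.0, 48.0))
            delta = float(np.clip(rng.normal(spec.delta_etco2_mean,
                                             spec.delta_etco2_sd), 5.0, 12.0))
            drawn = {}
            for measure, per_group in spec.measures.items():
                per_state = per_group[group]
                drawn[measure] = _draw_pair(
                    rng, per_state["pre"], per_state["post"],
                    spec.correlation, _MEASURE_BOUNDS[measure],
                )
            for s_idx, state in enumerate(("pre", "post")):
                row = dict(
                    subject_id=sid, group=group, sex=sex, age=age, bvol=bvol,
                    state=state, etco2_ra=etco2_ra, delta_etco2=delta,
                )
                for measure, pair in drawn.items():
                    row[measure] = pair[s_idx]
                rows.append(row)
                if render:
                    inputs[(sid, state)] = _render_state(
                        row, rng, render, calib, params
                    )
    truth = pd.DataFrame(rows)
    return Cohort(spec=spec, truth=truth, inputs=inputs, calib=calib)


def _render_state(
    row: dict,
    rng: np.random.Generator,
    render: tuple[str, ...],
    calib: CalibrationModel,
    params: dict,
) -> RenderedSubjectState:
    """Rasterize the raw inputs for one subject-state row."""
    out = RenderedSubjectState()
    etco2_ra = row["etco2_ra"]
    etco2_hc = etco2_ra + row["delta_etco2"]
    hct = SEX_HCT[row["sex"]]

    if "pc" in render:
        cbf_ra = row["cbf"]
        cbf_hc = cbf_ra * (1.0 + row["cbf_cvr"] * row["delta_etco2"] / 100.0)
        to_flux = 0.46 * row["bvol"] * 1.06 / 100.0  # CBF -> sinus flux
        truth_pc = GroundTruth(
            etco2_ra=etco2_ra, etco2_hc=etco2_hc,
            flux_ra=cbf_ra * to_flux, flux_hc=cbf_hc * to_flux,
        )
        trace, _ = generate_capno_trace(
            pc_protocol(), truth_pc,
            breath_period=params["breath_period"], seed=rng,
            envelope_sd=params["envelope_sd"],
            instrument_sd=params["instrument_sd"],
        )
        ra, hc, roi = generate_pc_pair(
            truth_pc, venc_ra=params["venc_ra"], venc_hc=params["venc_hc"],
            seed=rng, grid=params["pc_grid"], noise_sd=params["pc_noise_sd"],
        )
        out.capno_pc, out.pc_ra, out.pc_hc, out.pc_roi = trace, ra, hc, roi

    if "bold" in render:
        protocol = bold_protocol()
        truth_bold = GroundTruth(
            cvr_map=row["bold_cvr"], etco2_ra=etco2_ra, etco2_hc=etco2_hc,
            drift_slope=float(rng.normal(0.0, params["drift_slope_sd"])),
            noise_sd=params["bold_noise_sd"],
            bold_delay=float(rng.uniform(4.0, 8.0)),
        )
        trace, envelope = generate_capno_trace(
            protocol, truth_bold,
            breath_period=params["breath_period"], seed=rng,
            envelope_sd=params["envelope_sd"],
            instrument_sd=params["instrument_sd"],
        )
        out.capno_bold = trace
        out.bold = generate_bold_series(
            protocol, truth_bold, envelope, seed=rng,
            grid=params["bold_grid"], beta0=params["bold_beta0"],
        )

    if "trust" in render:
        truth_trust = GroundTruth(yv_true=row["yv"] / 100.0)
        out.trust = generate_trust_series(
            truth_trust, calib=calib, hct=hct,
            noise_sd=params["trust_noise_sd"], seed=rng,
            n_pairs=params["trust_n_pairs"],
        )
    return out
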