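"""End-to-end per-subject analysis chains and cohort replicate runners.

These functions glue the stage modules into the three quantification chains
a study session produces — flow-based CVR from the phase-contrast session,
a whole-brain BOLD-CVR from the block-design BOLD scan, and venous
oxygenation from TRUST — starting from raw rendered inputs (capnograph
trace, images) exactly as the stage-wise tools would be run on acquired
data. The replicate runners repeat whole simulated cohorts to measure the
across-replicate grand mean of each estimate, the recovery surface used by
the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boldcvr import BoldCvrModel, BoldCvrResults
from .capno import CapnoTrace, detect_envelope, etco2_during_scan
from .pcflow import (
    CvrResult,
    PcScan,
    SinusRoi,
    compute_cbf,
    compute_cbf_cvr,
    integrate_flux,
    unwrap_velocity,
)
from .synthgen import Cohort, CohortSpec, generate_cohort
from .trustox import CalibrationModel, OxygenationResult, SEX_HCT, estimate_yv


@dataclass(frozen=True)
class PcAnalysis:
    """Flow-based CVR estimate with intermediate quantities."""

    cvr: CvrResult
    bf_ra: float
    bf_hc: float
    cbf_ra: float
    cbf_hc: float
    etco2_ra: float
    etco2_hc: float


def analyze_pc_subject(
    scan_ra: PcScan,
    scan_hc: PcScan,
    roi: SinusRoi,
    trace: CapnoTrace,
    bvol: float,
) -> PcAnalysis:
    """Quantify flow-based CVR from one phase-contrast session.

    Runs envelope detection on the capnograph, per-scan end-tidal means over
    the acquisition windows, venc unwrapping, flux integration and the CVR
    ratio.
    """
    curve = detect_envelope(trace)
    e_ra = etco2_during_scan(curve, scan_ra.acquisition_window)
    e_hc = etco2_during_scan(curve, scan_hc.acquisition_window)
    bf_ra = integrate_flux(unwrap_velocity(scan_ra, roi), roi)
    bf_hc = integrate_flux(unwrap_velocity(scan_hc, roi), roi)
    cbf_ra = compute_cbf(bf_ra, bvol)
    cbf_hc = compute_cbf(bf_hc, bvol)
    cvr = compute_cbf_cvr(cbf_ra, cbf_hc, e_ra, e_hc)
    return PcAnalysis(
        cvr=cvr, bf_ra=bf_ra, bf_hc=bf_hc, cbf_ra=cbf_ra, cbf_hc=cbf_hc,
        etco2_ra=e_ra, etco2_hc=e_hc,
    )


def analyze_bold_subject(
    study,
    trace: CapnoTrace,
    fwhm: float = 0.0,
    search: tuple[float, float] = (-30.0, 30.0),
    step: float = 0.1,
) -> BoldCvrResults:
    """Whole-brain BOLD-CVR from one BOLD scan plus its capnograph trace."""
    curve = detect_envelope(trace)
    return BoldCvrModel(study, curve, fwhm=fwhm, search=search, step=step).fit()


def analyze_trust_subject(
    series, sex: str, calib: CalibrationModel | None = None
) -> OxygenationResult:
    """Venous oxygenation from one TRUST series using sex-based hematocrit."""
    return estimate_yv(series, hct=SEX_HCT[sex], calib=calib)


# ---------------------------------------------------------------------------
# replicate runners


def _spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def run_pc_replicates(
    spec: CohortSpec,
    n_replicates: int,
    seed: int,
    group: str,
) -> dict[str, np.ndarray]:
    """Estimate flow-based CVR for replicate cohorts of one group.

    Returns per-replicate means of the estimated pre- and post-state CVR
    (keys ``"pre"`` and ``"post"``), each an array of length
    ``n_replicates``.
    """
    single = CohortSpec(
        measures=spec.measures, n_per_group=spec.n_per_group,
        correlation=spec.correlation, groups=(group,),
        etco2_ra_mean=spec.etco2_ra_mean, etco2_ra_sd=spec.etco2_ra_sd,
        delta_etco2_mean=spec.delta_etco2_mean,
        delta_etco2_sd=spec.delta_etco2_sd,
        bvol_mean=spec.bvol_mean, bvol_sd=spec.bvol_sd, seed=spec.seed,
    )
    out = {"pre": [], "post": []}
    for ss in _spawn_seeds(seed, n_replicates):
        cohort = generate_cohort(single, render=("pc",),
                                 seed=np.random.default_rng(ss))
        est = {"pre": [], "post": []}
        for (sid, state), rendered in cohort.inputs.items():
            bvol = float(
                cohort.truth.query("subject_id == @sid")["bvol"].iloc[0]
            )
            res = analyze_pc_subject(
                rendered.pc_ra, rendered.pc_hc, rendered.pc_roi,
                rendered.capno_pc, bvol,
            )
            est[state].append(res.cvr.cvr)
        out["pre"].append(float(np.mean(est["pre"])))
        out["post"].append(float(np.mean(est["post"])))
    return {k: np.asarray(v) for k, v in out.items()}


def run_bold_replicates(
    spec: CohortSpec,
    n_replicates: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Whole-brain BOLD-CVR for replicate cohorts pooling all groups."""
    out = {"pre": [], "post": []}
    for ss in _spawn_seeds(seed, n_replicates):
        cohort = generate_cohort(spec, render=("bold",),
                                 seed=np.random.default_rng(ss))
        est = {"pre": [], "post": []}
        for (sid, state), rendered in cohort.inputs.items():
            res = analyze_bold_subject(rendered.bold, rendered.capno_bold)
            est[state].append(res.whole_brain_cvr())
        out["pre"].append(float(np.mean(est["pre"])))
        out["post"].append(float(np.mean(est["post"])))
    return {k: np.asarray(v) for k, v in out.items()}


def run_trust_replicates(
    spec: CohortSpec,
    n_replicates: int,
    seed: int,
    group: str,
    states: tuple[str, ...] = ("pre", "post"),
) -> dict[str, np.ndarray]:
    """Estimated venous oxygenation (percent) for replicate cohorts."""
    single = CohortSpec(
        measures=spec.measures, n_per_group=spec.n_per_group,
        correlation=spec.correlation, groups=(group,),
        etco2_ra_mean=spec.etco2_ra_mean, etco2_ra_sd=spec.etco2_ra_sd,
        delta_etco2_mean=spec.delta_etco2_mean,
        delta_etco2_sd=spec.delta_etco2_sd,
        bvol_mean=spec.bvol_mean, bvol_sd=spec.bvol_sd, seed=spec.seed,
    )
    out: dict[str, list[float]] = {s: [] for s in states}
    for ss in _spawn_seeds(seed, n_replicates):
        cohort = generate_cohort(single, render=("trust",),
                                 seed=np.random.default_rng(ss))
        est: dict[str, list[float]] = {s: [] for s in states}
        subj = cohort.truth.set_index(["subject_id", "state"])
        for (sid, state), rendered in cohort.inputs.items():
            if state not in states:
                continue
            sex = str(subj.loc[(sid, state), "sex"])
            res = analyze_trust_subject(rendered.trust, sex, cohort.calib)
            est[state].append(res.yv * 100.0)
        for s in states:
            out[s].append(float(np.mean(est[s])))
    return {k: np.asarray(v) for k, v in out.items()}


def grand_mean_and_se(replicate_means: np.ndarray) -> tuple[float, float]:
    """Across-replicate grand mean and its Monte-Carlo standard error."""
    x = np.asarray(replicate_means, float)
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))
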