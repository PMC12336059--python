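"""Reading and writing the on-disk formats: NIfTI images, CSV tables, YAML.

NIfTI handling goes through nibabel; voxel sizes are carried in the header
zooms. BOLD series are stored as 3D+time volumes; phase-contrast scans as a
velocity image plus a complex-difference magnitude image with a small YAML
sidecar for venc and the acquisition window; TRUST series as one 4-D file
per eTE pair group with a manifest CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .boldcvr import BoldStudy, CvrMap
from .capno import CapnoTrace
from .pcflow import PcScan, SinusRoi
from .trustox import TrustSeries


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    for i, vs in enumerate(voxel_size[:3]):
        aff[i, i] = vs
    return aff


def save_bold(study: BoldStudy, path) -> None:
    img = nib.Nifti1Image(study.data.astype(np.float32), _affine(study.voxel_size))
    img.header.set_zooms((*study.voxel_size, study.tr))
    nib.save(img, str(path))


def load_bold(path, tr: float | None = None, protocol=None) -> BoldStudy:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    data = np.asarray(img.dataobj, dtype=float)
    if tr is None:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.5
    return BoldStudy(
        data=data, tr=tr, protocol=protocol,
        voxel_size=tuple(float(z) for z in zooms[:3]),
    )


def save_mask(mask: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(mask, np.uint8), _affine(voxel_size)), str(path)
    )


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_cvr_map(cvr_map: CvrMap, path, voxel_size=(3.43, 3.43, 3.8)) -> None:
    img = nib.Nifti1Image(cvr_map.cvr.astype(np.float32), _affine(voxel_size))
    img.header["descrip"] = b"CVR map, %/mmHg"
    nib.save(img, str(path))


def save_pc_scan(scan: PcScan, stem) -> None:
    """Write velocity + magnitude NIfTIs and a YAML sidecar next to ``stem``."""
    stem = Path(stem)
    vs = float(np.sqrt(scan.voxel_area))
    aff = _affine((vs, vs, 5.0))
    nib.save(nib.Nifti1Image(scan.velocity.astype(np.float32), aff),
             str(stem) + "_vel.nii")
    nib.save(nib.Nifti1Image(scan.cd_magnitude.astype(np.float32), aff),
             str(stem) + "_mag.nii")
    with open(str(stem) + ".yaml", "w") as fh:
        yaml.safe_dump(
            {
                "venc": scan.venc,
                "voxel_area": scan.voxel_area,
                "acquisition_window": list(scan.acquisition_window),
            },
            fh,
        )


def load_pc_scan(stem) -> PcScan:
    stem = Path(stem)
    vel = np.asarray(nib.load(str(stem) + "_vel.nii").dataobj, float)
    mag = np.asarray(nib.load(str(stem) + "_mag.nii").dataobj, float)
    with open(str(stem) + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    return PcScan(
        velocity=np.squeeze(vel),
        cd_magnitude=np.squeeze(mag),
        venc=float(meta["venc"]),
        voxel_area=float(meta["voxel_area"]),
        acquisition_window=tuple(meta["acquisition_window"]),
    )


def save_roi(roi: SinusRoi, path) -> None:
    nib.save(nib.Nifti1Image(roi.mask.astype(np.uint8), np.eye(4)), str(path))


def load_roi(path) -> SinusRoi:
    return SinusRoi(np.squeeze(np.asarray(nib.load(str(path)).dataobj)) > 0)


def save_trust(series: TrustSeries, directory) -> None:
    """Write one NIfTI per eTE (pairs x label/control stacked) + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ete in enumerate(series.etes):
        fname = f"trust_ete{int(round(ete)):03d}.nii"
        stack = np.stack([series.label[i], series.control[i]], axis=0)
        nib.save(nib.Nifti1Image(stack.astype(np.float32), np.eye(4)),
                 str(directory / fname))
        rows.append({"ete_ms": float(ete), "file": fname})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    save_mask(series.roi[..., None], directory / "roi.nii")


def load_trust(directory) -> TrustSeries:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv").sort_values("ete_ms")
    labels, controls = [], []
    for _, row in manifest.iterrows():
        stack = np.asarray(nib.load(str(directory / row["file"])).dataobj, float)
        labels.append(stack[0])
        controls.append(stack[1])
    roi = np.squeeze(load_mask(directory / "roi.nii"))
    return TrustSeries(
        label=np.stack(labels), control=np.stack(controls),
        etes=manifest["ete_ms"].to_numpy(float), roi=roi,
    )


def save_capno(trace: CapnoTrace, path) -> None:
    trace.to_csv(path)


def load_capno(path) -> CapnoTrace:
    return CapnoTrace.from_csv(path)


def write_cohort(cohort, out_dir, modalities=("pc", "bold", "trust")) -> None:
    """Write a simulated cohort: ground truth, manifest, per-subject inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort.truth.to_csv(out_dir / "ground_truth.csv", index=False)
    cohort.subjects().to_csv(out_dir / "subjects.csv", index=False)
    for (sid, state), rendered in cohort.inputs.items():
        sdir = out_dir / sid / state
        sdir.mkdir(parents=True, exist_ok=True)
        if rendered.capno_pc is not None and "pc" in modalities:
            save_capno(rendered.capno_pc, sdir / "capno_pc.csv")
            save_pc_scan(rendered.pc_ra, sdir / "pc_ra")
            save_pc_scan(rendered.pc_hc, sdir / "pc_hc")
            save_roi(rendered.pc_roi, sdir / "sss_roi.nii")
        if rendered.bold is not None and "bold" in modalities:
            save_capno(rendered.capno_bold, sdir / "capno_bold.csv")
            save_bold(rendered.bold, sdir / "bold.nii")
        if rendered.trust is not None and "trust" in modalities:
            save_trust(rendered.trust, sdir / "trust")
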