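"""Persistence: sinogram container (HDF5), NIfTI volumes, CSV exports."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import DynamicSinogram
from .geometry import ScannerGeometry
from .phantom import GridSpec, MotionWaveform
from .reconstruction import DerivativeImages, PhaseImage
from .weighting import WeightCurve, normalize_weights

__all__ = [
    "save_sinogram",
    "load_sinogram",
    "sinogram_metadata_table",
    "write_phase_images",
    "weight_curve_table",
]

_PHASE_FIELDS = ("phase_fraction", "phase_bin", "cycle_index", "peak_times")


def save_sinogram(sino: DynamicSinogram, path: str | Path) -> None:
    """Write a sinogram container: arrays + geometry/waveform metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=sino.data, compression="gzip")
        f.create_dataset("times", data=sino.times)
        f.create_dataset("angle_indices", data=sino.angle_indices)
        for name in _PHASE_FIELDS:
            arr = getattr(sino, name)
            if arr is not None:
                f.create_dataset(name, data=arr)
        wf = sino.waveform
        f.create_dataset("waveform/sample_times", data=wf.sample_times)
        f.create_dataset("waveform/surrogate", data=wf.surrogate)
        f.create_dataset("waveform/displacement", data=wf.displacement)
        f.attrs["geometry"] = json.dumps(asdict(sino.geometry))
        f.attrs["grid"] = json.dumps(asdict(sino.grid))
        f.attrs["waveform"] = json.dumps(
            {
                "kind": wf.kind,
                "breathing_period": wf.breathing_period,
                "amplitude": wf.amplitude,
                "seed": wf.seed,
                "irregularity": wf.irregularity,
            }
        )
        f.attrs["noise_sigma"] = sino.noise_sigma
        f.attrs["seed"] = sino.seed
        if sino.n_phases is not None:
            f.attrs["n_phases"] = sino.n_phases


def load_sinogram(path: str | Path) -> DynamicSinogram:
    with h5py.File(path, "r") as f:
        geom = ScannerGeometry(**json.loads(f.attrs["geometry"]))
        grid = GridSpec(**json.loads(f.attrs["grid"]))
        wf_meta = json.loads(f.attrs["waveform"])
        waveform = MotionWaveform(
            kind=wf_meta["kind"],
            breathing_period=wf_meta["breathing_period"],
            amplitude=wf_meta["amplitude"],
            sample_times=f["waveform/sample_times"][()],
            surrogate=f["waveform/surrogate"][()],
            displacement=f["waveform/displacement"][()],
            seed=wf_meta["seed"],
            irregularity=wf_meta["irregularity"],
        )
        extra = {
            name: (f[name][()] if name in f else None) for name in _PHASE_FIELDS
        }
        return DynamicSinogram(
            data=f["data"][()],
            times=f["times"][()],
            angle_indices=f["angle_indices"][()],
            geometry=geom,
            grid=grid,
            waveform=waveform,
            noise_sigma=float(f.attrs["noise_sigma"]),
            seed=int(f.attrs["seed"]),
            n_phases=int(f.attrs["n_phases"]) if "n_phases" in f.attrs else None,
            **extra,
        )


def sinogram_metadata_table(sino: DynamicSinogram) -> pd.DataFrame:
    """Per-projection metadata (angle, time, phase) as a tidy table."""
    d = {
        "index": np.arange(sino.n_projections),
        "time_s": sino.times,
        "angle_rad": sino.angles,
    }
    if sino.phase_fraction is not None:
        d["phase_fraction"] = sino.phase_fraction
        d["phase_bin"] = sino.phase_bin
        d["cycle_index"] = sino.cycle_index
    return pd.DataFrame(d)


def _nifti(img: np.ndarray, grid: GridSpec, slice_mm: float = 3.0) -> nib.Nifti1Image:
    affine = np.diag([grid.px, grid.px, slice_mm, 1.0])
    return nib.Nifti1Image(np.asarray(img, dtype=np.float32)[:, :, None], affine)


def write_phase_images(
    phases: list[PhaseImage],
    out_dir: str | Path,
    derivatives: DerivativeImages | None = None,
    to_hu_fn=None,
    sidecar: dict | None = None,
) -> list[Path]:
    """Write phase volumes (plus MIP/minIP/AVG) as NIfTI with a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conv = to_hu_fn if to_hu_fn is not None else (lambda a: a)
    written = []
    for ph in phases:
        path = out / f"phase_{ph.phase_bin:02d}.nii.gz"
        nib.save(_nifti(conv(ph.pixels), ph.grid), path)
        written.append(path)
    if derivatives is not None:
        grid = phases[0].grid
        for name, arr in (("mip", derivatives.mip), ("minip", derivatives.minip), ("avg", derivatives.avg)):
            path = out / f"{name}.nii.gz"
            nib.save(_nifti(conv(arr), grid), path)
            written.append(path)
    meta = {"scheme": phases[0].scheme, "n_phases": len(phases)}
    if sidecar:
        meta.update(sidecar)
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    return written


def weight_curve_table(curve: WeightCurve, group_labels=None) -> pd.DataFrame:
    """Weight curve as (index, raw, normalized) for CSV export / plotting."""
    d = {"index": np.arange(curve.total_projections), "raw_weight": curve.weights}
    if group_labels is not None:
        d["normalized_weight"] = normalize_weights(curve.weights, group_labels)
    return pd.DataFrame(d)
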