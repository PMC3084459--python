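"""File I/O: NIfTI volumes and masks, CSV ratings, YAML configs, NPZ arrays.

NIfTI-1 is used for all image data (via nibabel, affine diag(voxel sizes)),
CSV for ratings/predictions/score tables, YAML for configuration, and NPZ
with a JSON sidecar for matrices (time series, kernels, fitted models).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preprocess import MaskVolume, TimeSeriesMatrix
from .synth import SimulationConfig, SyntheticDataset

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_mask",
    "load_mask",
    "save_ratings_csv",
    "load_ratings_csv",
    "save_dataset",
    "load_dataset",
    "save_timeseries",
    "load_timeseries",
    "load_yaml",
    "save_yaml",
]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_nifti(path, data: np.ndarray, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(voxel_size_mm)), str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=float), vox


def save_mask(path, mask: MaskVolume) -> None:
    save_nifti(path, mask.data.astype(np.uint8), mask.voxel_size_mm)


def load_mask(path) -> MaskVolume:
    data, vox = load_nifti(path)
    return MaskVolume(data=(data > 0.5).astype(np.uint8), voxel_size_mm=vox)


def save_ratings_csv(path, ratings: list[np.ndarray], names: list[str],
                     run_boundaries: list[tuple[int, int]]) -> None:
    """One row per scan, one column per rating, plus a run-index column."""
    n = ratings[0].shape[0]
    run = np.empty(n, dtype=int)
    for r, (start, stop) in enumerate(run_boundaries):
        run[start:stop] = r
    df = pd.DataFrame({"run": run})
    for name, values in zip(names, ratings):
        df[name] = values
    df.to_csv(path, index=False)


def load_ratings_csv(path) -> tuple[list[np.ndarray], list[str], list[tuple[int, int]]]:
    df = pd.read_csv(path)
    if "run" not in df.columns:
        raise ValueError("ratings CSV must contain a 'run' column")
    runs = df["run"].to_numpy()
    boundaries = []
    for r in np.unique(runs):
        idx = np.flatnonzero(runs == r)
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise ValueError("scans of a run must be contiguous")
        boundaries.append((int(idx[0]), int(idx[-1] + 1)))
    names = [c for c in df.columns if c != "run"]
    return [df[c].to_numpy(dtype=float) for c in names], names, boundaries


def save_dataset(out_dir, ds: SyntheticDataset) -> None:
    """Persist a synthetic dataset: NIfTI volumes/masks/maps, CSV ratings, YAML config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = ds.config.voxel_size_mm
    save_nifti(out / "volumes.nii", ds.volumes, vox)
    save_mask(out / "gm_mask.nii", ds.gm_mask)
    for name, w in zip(ds.rating_names, ds.true_weight_maps):
        save_nifti(out / f"weights_{name}.nii", w, vox)
    save_ratings_csv(out / "ratings_raw.csv", ds.raw_ratings, ds.rating_names,
                     ds.run_boundaries)
    save_ratings_csv(out / "ratings_convolved.csv", ds.convolved_ratings,
                     ds.rating_names, ds.run_boundaries)
    save_yaml(out / "config.yaml", ds.config.to_dict())


def load_dataset(in_dir) -> SyntheticDataset:
    src = Path(in_dir)
    cfg = SimulationConfig.from_dict(load_yaml(src / "config.yaml"))
    volumes, _ = load_nifti(src / "volumes.nii")
    gm_mask = load_mask(src / "gm_mask.nii")
    raw, names, boundaries = load_ratings_csv(src / "ratings_raw.csv")
    conv, _, _ = load_ratings_csv(src / "ratings_convolved.csv")
    weights = []
    for name in names:
        path = src / f"weights_{name}.nii"
        weights.append(load_nifti(path)[0] if path.exists() else np.zeros(cfg.grid_dims))
    return SyntheticDataset(
        volumes=volumes,
        gm_mask=gm_mask,
        true_weight_maps=weights,
        raw_ratings=raw,
        convolved_ratings=conv,
        run_boundaries=boundaries,
        rating_names=names,
        config=cfg,
    )


def save_timeseries(path, tsm: TimeSeriesMatrix) -> None:
    """NPZ array container with a JSON sidecar for the voxel/run metadata."""
    path = Path(path)
    np.savez(path, X=tsm.X, voxel_index=tsm.voxel_index)
    sidecar = {
        "grid_dims": list(tsm.grid_dims),
        "run_boundaries": [list(b) for b in tsm.run_boundaries],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_timeseries(path) -> TimeSeriesMatrix:
    path = Path(path)
    arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return TimeSeriesMatrix(
        X=arrays["X"],
        voxel_index=arrays["voxel_index"],
        grid_dims=tuple(meta["grid_dims"]),
        run_boundaries=[tuple(b) for b in meta["run_boundaries"]],
    )


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
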