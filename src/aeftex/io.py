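"""NIfTI and cohort-manifest I/O.

Volumes are stored (plane, row, col) in memory; on disk the NIfTI affine is
diagonal in the voxel spacings so round-trips preserve both data and
geometry. A simulated cohort is laid out as one directory per subject
(ctu/cta/ctp/mask NIfTI files) plus a ``manifest.csv`` with subject ids,
labels and file paths.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .aef import AEFMap, MultiphaseVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_multiphase",
    "load_multiphase",
    "save_aef_map",
    "write_cohort",
    "read_manifest",
]


def save_volume(
    data: np.ndarray, voxel_size: tuple[float, float, float], path: str | Path
) -> Path:
    path = Path(path)
    affine = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(voxel_size)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), zooms


def save_multiphase(mv: MultiphaseVolume, directory: str | Path, stem: str = "") -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = f"{stem}_" if stem else ""
    paths = {}
    for name, grid in (("ctu", mv.ctu), ("cta", mv.cta), ("ctp", mv.ctp)):
        paths[name] = save_volume(grid, mv.voxel_size, directory / f"{prefix}{name}.nii.gz")
    return paths


def load_multiphase(
    ctu_path: str | Path, cta_path: str | Path, ctp_path: str | Path
) -> MultiphaseVolume:
    ctu, vs = load_volume(ctu_path)
    cta, _ = load_volume(cta_path)
    ctp, _ = load_volume(ctp_path)
    return MultiphaseVolume(ctu, cta, ctp, vs)


def save_aef_map(
    aef: AEFMap, voxel_size: tuple[float, float, float], path: str | Path
) -> tuple[Path, Path]:
    """Write the AEF values and the companion validity mask."""
    path = Path(path)
    values = np.where(aef.valid, aef.values, 0.0)
    vpath = save_volume(values, voxel_size, path)
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            name = name[: -len(suf)] + "_valid" + suf
            break
    else:
        name = name + "_valid.nii.gz"
    mpath = save_volume(aef.valid.astype(np.uint8), voxel_size, path.with_name(name))
    return vpath, mpath


def write_cohort(
    cohort: list[tuple[MultiphaseVolume, np.ndarray, str]], out_dir: str | Path
) -> Path:
    """Write per-subject NIfTI files and return the manifest CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (mv, mask, label) in enumerate(cohort):
        sid = f"subj{i:03d}"
        sdir = out_dir / sid
        paths = save_multiphase(mv, sdir)
        mask_path = save_volume(mask.astype(np.uint8), mv.voxel_size, sdir / "mask.nii.gz")
        rows.append(
            {
                "subject_id": sid,
                "label": label,
                "ctu": str(paths["ctu"]),
                "cta": str(paths["cta"]),
                "ctp": str(paths["ctp"]),
                "mask": str(mask_path),
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must carry columns {sorted(required)}")
    return df
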