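"""NIfTI-1 and sidecar IO for stacks, maps, and label masks.

Multi-echo stacks are stored as a single 3-D NIfTI volume with echo as the
third axis plus a JSON sidecar ``{"echo_times_ms": [...]}``; label masks as
integer NIfTI with a JSON label dictionary; fitted maps as one volume per
quantity with a JSON provenance record.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .relaxometry import FitSettings, MultiEchoStack, RelaxometryMaps
from .roi import LabelMask

__all__ = [
    "save_stack", "load_stack",
    "save_mask", "load_mask",
    "save_maps", "load_maps",
]

MAP_NAMES = ("s0", "t2star_ms", "r2star_s", "r_squared", "valid")


def _affine(voxel_size_mm: tuple[float, float]) -> np.ndarray:
    return np.diag([voxel_size_mm[0], voxel_size_mm[1], 1.0, 1.0])


def save_stack(stack: MultiEchoStack, path: str | Path) -> Path:
    """Write a stack to ``<path>.nii.gz`` (+ echo-time sidecar); returns the image path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img_path = path.with_suffix(".nii.gz") if path.suffix != ".gz" else path
    data = np.moveaxis(stack.signal, 0, -1)  # (rows, cols, echoes)
    nib.save(nib.Nifti1Image(data.astype(np.float64), _affine(stack.voxel_size_mm)),
             str(img_path))
    sidecar = img_path.with_name(img_path.name.replace(".nii.gz", "") + "_echoes.json")
    sidecar.write_text(json.dumps(
        {"echo_times_ms": [float(t) for t in stack.echo_times_ms]}, indent=2))
    return img_path


def load_stack(img_path: str | Path, sidecar: str | Path | None = None) -> MultiEchoStack:
    img_path = Path(img_path)
    if sidecar is None:
        sidecar = img_path.with_name(img_path.name.replace(".nii.gz", "") + "_echoes.json")
    meta = json.loads(Path(sidecar).read_text())
    img = nib.load(str(img_path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    zooms = img.header.get_zooms()
    return MultiEchoStack(echo_times_ms=np.asarray(meta["echo_times_ms"], float),
                          signal=data, voxel_size_mm=(float(zooms[0]), float(zooms[1])))


def save_mask(mask: LabelMask, path: str | Path,
              voxel_size_mm: tuple[float, float] = (1.0, 1.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img_path = path.with_suffix(".nii.gz") if path.suffix != ".gz" else path
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), _affine(voxel_size_mm)),
             str(img_path))
    labels_json = img_path.with_name(img_path.name.replace(".nii.gz", "") + "_labels.json")
    labels_json.write_text(json.dumps({str(k): v for k, v in mask.names.items()},
                                      indent=2))
    return img_path


def load_mask(img_path: str | Path, labels_json: str | Path | None = None) -> LabelMask:
    img_path = Path(img_path)
    if labels_json is None:
        labels_json = img_path.with_name(img_path.name.replace(".nii.gz", "") + "_labels.json")
    names = {int(k): v for k, v in json.loads(Path(labels_json).read_text()).items()}
    labels = np.asarray(nib.load(str(img_path)).dataobj).astype(np.int16)
    return LabelMask(labels=labels, names=names)


def save_maps(maps: RelaxometryMaps, out_dir: str | Path,
              voxel_size_mm: tuple[float, float] = (1.0, 1.0)) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {
        "s0": maps.s0, "t2star_ms": maps.t2star_ms, "r2star_s": maps.r2star_s,
        "r_squared": maps.r_squared, "valid": maps.valid.astype(np.uint8),
    }
    for name, arr in arrays.items():
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64),
                                 _affine(voxel_size_mm)),
                 str(out_dir / f"{name}.nii.gz"))
    (out_dir / "provenance.json").write_text(json.dumps(maps.provenance(), indent=2))
    return out_dir


def load_maps(out_dir: str | Path) -> RelaxometryMaps:
    out_dir = Path(out_dir)
    arrays = {name: np.asarray(nib.load(str(out_dir / f"{name}.nii.gz")).dataobj,
                               dtype=float)
              for name in MAP_NAMES}
    prov = json.loads((out_dir / "provenance.json").read_text())
    return RelaxometryMaps(
        s0=arrays["s0"], t2star_ms=arrays["t2star_ms"], r2star_s=arrays["r2star_s"],
        r_squared=arrays["r_squared"], valid=arrays["valid"] > 0.5,
        echo_times_ms=np.asarray(prov["echo_times_ms"], float),
        settings=FitSettings(
            rsq_threshold=prov["fit_settings"]["rsq_threshold"],
            t2_bounds_ms=tuple(prov["fit_settings"]["t2_bounds_ms"]),
            max_nfev=prov["fit_settings"]["max_nfev"],
        ),
    )
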