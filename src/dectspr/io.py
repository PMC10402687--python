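"""File I/O: NIfTI volumes, depth-dose CSVs, HLUT CSV+JSON, metadata JSON."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bragg import DepthDoseCurve
from .spr import HLUT, SPRMap
from .synthetic import SpectralImageSet

__all__ = [
    "save_imageset", "load_imageset", "save_labels",
    "save_sprmap", "load_sprmap",
    "save_curve", "load_curve",
    "save_hlut", "load_hlut",
]


def _affine(spacing) -> np.ndarray:
    return np.diag([*spacing, 1.0])


def save_sprmap(sprmap: SPRMap, path: str | Path) -> Path:
    """Write an SPR map as NIfTI (.nii.gz); provenance in the description."""
    path = Path(path)
    img = nib.Nifti1Image(sprmap.volume.astype(np.float32),
                          _affine(sprmap.spacing))
    img.header["descrip"] = sprmap.method.encode()[:79]
    nib.save(img, str(path))
    return path


def load_sprmap(path: str | Path) -> SPRMap:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    method = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="replace")
    return SPRMap(volume=np.asarray(img.dataobj, dtype=float),
                  spacing=spacing, method=method)


def save_imageset(imageset: SpectralImageSet, outdir: str | Path,
                  labels: np.ndarray | None = None) -> Path:
    """Write a spectral image set (+optional labels) as NIfTI + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(imageset.voxel_spacing)
    for kvp, vol in imageset.ctn_volumes.items():
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff),
                 str(outdir / f"ctn_{kvp}.nii.gz"))
    nib.save(nib.Nifti1Image(imageset.red_volume.astype(np.float32), aff),
             str(outdir / "red.nii.gz"))
    nib.save(nib.Nifti1Image(imageset.ean_volume.astype(np.float32), aff),
             str(outdir / "ean.nii.gz"))
    if labels is not None:
        save_labels(labels, imageset.voxel_spacing, outdir / "labels.nii.gz")
    meta = {
        "technique": imageset.technique,
        "kvp_labels": sorted(imageset.ctn_volumes),
        "voxel_spacing_mm": list(imageset.voxel_spacing),
        "shape": list(imageset.shape),
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_imageset(indir: str | Path) -> SpectralImageSet:
    indir = Path(indir)
    meta = json.loads((indir / "metadata.json").read_text())

    def _vol(name):
        return np.asarray(nib.load(str(indir / name)).dataobj, dtype=float)

    ctn = {kvp: _vol(f"ctn_{kvp}.nii.gz") for kvp in meta["kvp_labels"]}
    return SpectralImageSet(
        ctn_volumes=ctn, red_volume=_vol("red.nii.gz"),
        ean_volume=_vol("ean.nii.gz"), technique=meta["technique"],
        voxel_spacing=tuple(meta["voxel_spacing_mm"]),
    )


def save_labels(labels: np.ndarray, spacing, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(labels.astype(np.int16), _affine(spacing)),
             str(path))
    return path


def save_curve(curve: DepthDoseCurve, path: str | Path) -> Path:
    """Write a depth-dose curve as 2-column CSV (depth_mm, dose_arbitrary)."""
    path = Path(path)
    pd.DataFrame({"depth_mm": curve.depth,
                  "dose_arbitrary": curve.dose}).to_csv(path, index=False)
    return path


def load_curve(path: str | Path) -> DepthDoseCurve:
    df = pd.read_csv(path)
    return DepthDoseCurve(depth=df.iloc[:, 0].to_numpy(),
                          dose=df.iloc[:, 1].to_numpy())


def save_hlut(hlut: HLUT, path: str | Path) -> Path:
    """Write an HLUT as 2-column CSV with a JSON header sidecar (.json)."""
    path = Path(path)
    pd.DataFrame({"ctn_hu": hlut.nodes[:, 0],
                  "spr": hlut.nodes[:, 1]}).to_csv(path, index=False)
    header = {"max_spr": None if np.isinf(hlut.max_spr) else hlut.max_spr,
              "profile": hlut.profile}
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))
    return path


def load_hlut(path: str | Path) -> HLUT:
    path = Path(path)
    df = pd.read_csv(path)
    header = {"max_spr": None, "profile": ""}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        header.update(json.loads(sidecar.read_text()))
    max_spr = header["max_spr"] if header["max_spr"] is not None else np.inf
    return HLUT(nodes=df.to_numpy(), max_spr=max_spr,
                profile=header.get("profile") or "")
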