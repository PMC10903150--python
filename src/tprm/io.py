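"""NIfTI, CSV and JSON input/output plus run configuration."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .prm import CLASS_CODES, PairedCT
from .progression import DictionaryModel

__all__ = [
    "RunConfig",
    "read_paired_ct",
    "write_paired_ct",
    "write_labels",
    "read_labels",
    "write_tprm_maps",
    "save_model",
    "load_model",
]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (JSON round-trippable)."""

    out_dir: str = "tprm_run"
    n_subjects: int = 40
    effect_size: float = 1.0
    fast_fraction: float = 0.34
    window_vox: int = 21
    stride_vox: int = 5
    classes: tuple[str, ...] = ("Norm", "fSAD")
    # desk-scale ML profile; see docs/methods.md for the full-scale defaults
    patch_edge_vox: int = 7
    patches_per_case: int = 40
    n_atoms: int = 24
    sparsity: int = 3
    n_iter: int = 10
    train_fraction: float = 0.35
    aggregation_threshold: float = 0.5
    qc: bool = False
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        d = json.loads(s)
        d["classes"] = tuple(d["classes"])
        return cls(**d)


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def read_paired_ct(insp_path, exp_path, mask_path) -> PairedCT:
    """Load a co-registered inspiration/expiration pair and lung mask.

    The three images must share grid shape and affine; a mask voxel outside
    the volume extent is impossible by construction, but an intensity range
    that does not look like HU raises a warning.
    """
    imgs = [nib.load(str(p)) for p in (insp_path, exp_path, mask_path)]
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"grid shape mismatch across inputs: {shapes}")
    for im in imgs[1:]:
        if not np.allclose(im.affine, imgs[0].affine, atol=1e-4):
            raise ValueError("affine mismatch across inputs")
    insp = np.asarray(imgs[0].dataobj, dtype=float)
    exp = np.asarray(imgs[1].dataobj, dtype=float)
    mask = np.asarray(imgs[2].dataobj) > 0.5
    spacing = tuple(float(z) for z in imgs[0].header.get_zooms()[:3])
    for name, vol in (("inspiration", insp), ("expiration", exp)):
        inside = vol[mask]
        if inside.size and (inside.min() < -1100 or inside.max() > 200):
            warnings.warn(f"{name} intensities do not look like lung HU")
    return PairedCT(insp_hu=insp, exp_hu=exp, lung_mask=mask, spacing_mm=spacing)


def write_paired_ct(ct: PairedCT, insp_path, exp_path, mask_path) -> None:
    aff = _affine(ct.spacing_mm)
    nib.save(nib.Nifti1Image(ct.insp_hu.astype(np.float32), aff), str(insp_path))
    nib.save(nib.Nifti1Image(ct.exp_hu.astype(np.float32), aff), str(exp_path))
    nib.save(nib.Nifti1Image(ct.lung_mask.astype(np.uint8), aff), str(mask_path))


def write_labels(labels: np.ndarray, spacing_mm, path) -> None:
    """Write a PRM label volume with a JSON sidecar documenting the codes."""
    path = Path(path)
    nib.save(nib.Nifti1Image(labels.astype(np.uint8), _affine(spacing_mm)), str(path))
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"label_codes": CLASS_CODES, "background": 0}, indent=2))


def read_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.uint8)


def write_tprm_maps(tprm, spacing_mm, out_dir, prefix: str = "") -> list[Path]:
    """One NIfTI per (measure, class) plus a sidecar with the conventions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(spacing_mm)
    written = []
    for measure, fields in (("V", tprm.V), ("chi", tprm.chi)):
        for cls, vol in fields.items():
            p = out_dir / f"{prefix}{measure}_{cls}.nii"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), str(p))
            written.append(p)
    sidecar = out_dir / f"{prefix}tprm_meta.json"
    sidecar.write_text(json.dumps({
        "window_vox": tprm.window_vox,
        "stride_vox": tprm.stride_vox,
        "grid_origin": "volume index 0",
        "euler_convention": "closed voxels, 26-connected foreground",
        "V_normalization": "class voxel count / lung voxel count per window",
        "chi_normalization": "chi per lung voxel count per window",
    }, indent=2))
    written.append(sidecar)
    return written


def save_model(model: DictionaryModel, path_prefix) -> tuple[Path, Path]:
    """Persist a dictionary model as JSON metadata + an array container."""
    prefix = Path(path_prefix)
    meta = {
        "sparsity": model.sparsity,
        "channels": list(model.channels),
        "patch_edge_vox": model.patch_edge_vox,
        "aggregation_threshold": model.aggregation_threshold,
        "seed": model.seed,
        "n_train_fast": model.n_train_fast,
        "n_train_slow": model.n_train_slow,
        "objective_fast": model.objective_fast,
        "objective_slow": model.objective_slow,
    }
    jpath = prefix.with_suffix(".json")
    apath = prefix.with_suffix(".npz")
    jpath.write_text(json.dumps(meta, indent=2))
    np.savez(apath, dict_fast=model.dict_fast, dict_slow=model.dict_slow,
             channel_scales=model.channel_scales)
    return jpath, apath


def load_model(path_prefix) -> DictionaryModel:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    arrs = np.load(prefix.with_suffix(".npz"))
    return DictionaryModel(
        dict_fast=arrs["dict_fast"], dict_slow=arrs["dict_slow"],
        sparsity=meta["sparsity"], channel_scales=arrs["channel_scales"],
        channels=tuple(meta["channels"]), patch_edge_vox=meta["patch_edge_vox"],
        aggregation_threshold=meta["aggregation_threshold"], seed=meta["seed"],
        n_train_fast=meta["n_train_fast"], n_train_slow=meta["n_train_slow"],
        objective_fast=meta["objective_fast"], objective_slow=meta["objective_slow"],
    )
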