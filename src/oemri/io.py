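"""On-disk layout: NIfTI volumes with JSON sidecars, CSV tables.

Per animal directory:

* ``<state>.nii`` — magnitude images, inversion times along the third
  axis, in protocol order
* ``mask.nii`` — lung mask, integer 0/1 voxels
* ``series.json`` — protocol, group, animal_id
* ``ground_truth.nii`` + ``ground_truth.json`` — true parameter fields
  (synthetic studies only), layers s0_air / r1_air / delta_r1 / delta_r2star
* ``<state>_fit.nii`` (layers s0 / r1 / inv_eff / residual / fit_ok),
  ``delta_r1.nii``, ``delta_r2star.nii``, ``maps.json`` — fit outputs

Arrays round-trip bit-identically (float64 on disk).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .protocol import AcquisitionProtocol, GroundTruthMaps, ImageSeries, ParameterMaps

__all__ = [
    "save_image_series",
    "load_image_series",
    "save_ground_truth",
    "load_ground_truth",
    "save_parameter_maps",
    "load_parameter_maps",
]

_GT_LAYERS = ("s0_air", "r1_air", "delta_r1", "delta_r2star")
_FIT_LAYERS = ("s0", "r1", "inv_eff", "residual", "fit_ok")
_AFFINE = np.eye(4)


def _save_nii(path: Path, array: np.ndarray, dtype=np.float64) -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=dtype), _AFFINE)
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))


def _load_nii(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def _save_mask(dirpath: Path, mask: np.ndarray) -> None:
    _save_nii(dirpath / "mask.nii", mask.astype(np.uint8), dtype=np.uint8)


def _load_mask(dirpath: Path) -> np.ndarray:
    return _load_nii(dirpath / "mask.nii").astype(bool)


def save_image_series(series: ImageSeries, dirpath: str | Path) -> Path:
    """Write one animal's image series (one NIfTI per gas state)."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    for state, stack in series.images.items():
        _save_nii(d / f"{state}.nii", np.transpose(stack, (1, 2, 0)))
    _save_mask(d, series.mask)
    sidecar = {
        "protocol": series.protocol.to_dict(),
        "group": series.group,
        "animal_id": series.animal_id,
    }
    (d / "series.json").write_text(json.dumps(sidecar, indent=2))
    return d


def load_image_series(dirpath: str | Path) -> ImageSeries:
    d = Path(dirpath)
    meta = json.loads((d / "series.json").read_text())
    protocol = AcquisitionProtocol.from_dict(meta["protocol"])
    images = {
        state: np.transpose(_load_nii(d / f"{state}.nii"), (2, 0, 1))
        for state in protocol.gas_states
    }
    return ImageSeries(
        images=images,
        protocol=protocol,
        mask=_load_mask(d),
        group=meta["group"],
        animal_id=meta["animal_id"],
    )


def save_ground_truth(gt: GroundTruthMaps, dirpath: str | Path) -> Path:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    stack = np.stack([getattr(gt, name) for name in _GT_LAYERS], axis=-1)
    _save_nii(d / "ground_truth.nii", stack)
    _save_mask(d, gt.mask)
    meta = {"layers": list(_GT_LAYERS), "group": gt.group, "animal_id": gt.animal_id}
    (d / "ground_truth.json").write_text(json.dumps(meta, indent=2))
    return d


def load_ground_truth(dirpath: str | Path) -> GroundTruthMaps:
    d = Path(dirpath)
    meta = json.loads((d / "ground_truth.json").read_text())
    stack = _load_nii(d / "ground_truth.nii")
    fields = {name: stack[..., i] for i, name in enumerate(meta["layers"])}
    return GroundTruthMaps(
        mask=_load_mask(d), group=meta["group"], animal_id=meta["animal_id"], **fields
    )


def save_parameter_maps(maps: ParameterMaps, dirpath: str | Path) -> Path:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    for state in maps.gas_states:
        layers = [maps.s0[state], maps.r1[state], maps.inv_eff[state],
                  maps.residual[state], maps.fit_ok[state].astype(float)]
        _save_nii(d / f"{state}_fit.nii", np.stack(layers, axis=-1))
    _save_nii(d / "delta_r1.nii", maps.delta_r1)
    _save_nii(d / "delta_r2star.nii", maps.delta_r2star)
    _save_mask(d, maps.mask)
    meta = {
        "layers": list(_FIT_LAYERS),
        "gas_states": list(maps.gas_states),
        "group": maps.group,
        "animal_id": maps.animal_id,
    }
    (d / "maps.json").write_text(json.dumps(meta, indent=2))
    return d


def load_parameter_maps(dirpath: str | Path) -> ParameterMaps:
    d = Path(dirpath)
    meta = json.loads((d / "maps.json").read_text())
    s0, r1, inv_eff, residual, fit_ok = {}, {}, {}, {}, {}
    for state in meta["gas_states"]:
        stack = _load_nii(d / f"{state}_fit.nii")
        layers = {name: stack[..., i] for i, name in enumerate(meta["layers"])}
        s0[state] = layers["s0"]
        r1[state] = layers["r1"]
        inv_eff[state] = layers["inv_eff"]
        residual[state] = layers["residual"]
        fit_ok[state] = layers["fit_ok"].astype(bool)
    return ParameterMaps(
        s0=s0,
        r1=r1,
        inv_eff=inv_eff,
        residual=residual,
        fit_ok=fit_ok,
        delta_r1=_load_nii(d / "delta_r1.nii"),
        delta_r2star=_load_nii(d / "delta_r2star.nii"),
        mask=_load_mask(d),
        group=meta["group"],
        animal_id=meta["animal_id"],
    )
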