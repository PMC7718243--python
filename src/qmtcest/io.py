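"""On-disk layout for simulated studies and derived maps.

A study directory holds one NIfTI per B1 level (frames in acquisition order,
references interleaved), a frame table CSV (frame index, offset ppm, B1 µT,
is_reference), the IR series, ground-truth maps, the label image and the
generating spec as YAML.  Parameter maps are written as single-volume NIfTI.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import (CESTPool, PhantomSpec, Protocol, RegionSpec,
                      SyntheticStudy, ZStack, make_phantom)

_AFFINE = np.eye(4)


def _save_nii(path, array):
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float64), _AFFINE),
             str(path))


def _load_nii(path):
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def _b1_tag(b1: float) -> str:
    return f"{b1:g}".replace(".", "p")


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["regions"] = [dataclasses.asdict(r) for r in spec.regions]
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    regions = []
    for r in d["regions"]:
        pools = tuple(CESTPool(**p) for p in r.pop("cest_pools", ()))
        r = {k: tuple(v) if isinstance(v, list) else v for k, v in r.items()}
        regions.append(RegionSpec(cest_pools=pools, **r))
    spec = dict(d)
    spec["regions"] = tuple(regions)
    spec["grid_shape"] = tuple(spec["grid_shape"])
    return PhantomSpec(**spec)


def write_study(study: SyntheticStudy, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for b1, stack in sorted(study.zspec.items()):
        # NIfTI convention: spatial dims first, frames last
        _save_nii(out / f"zspec_b1_{_b1_tag(b1)}.nii",
                  np.moveaxis(stack.frames, 0, -1))
        for k in range(stack.frames.shape[0]):
            rows.append({"b1_ut": b1, "frame": k,
                         "offset_ppm": stack.offsets_ppm[k],
                         "is_reference": bool(stack.is_reference[k])})
    pd.DataFrame(rows).to_csv(out / "frames.csv", index=False)
    _save_nii(out / "ir.nii", np.moveaxis(study.ir_frames, 0, -1))
    pd.DataFrame({"ti_ms": study.protocol.tis_ms}).to_csv(
        out / "ir_tis.csv", index=False)
    geom = study.geometry
    _save_nii(out / "labels.nii", geom.label_image)
    _save_nii(out / "b0_truth.nii", geom.b0_map_ppm)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name, arr in geom.truth_maps.items():
        _save_nii(truth_dir / f"{name}.nii", arr)
    for off, (amp, wid) in geom.pool_maps.items():
        tag = f"{off:g}".replace(".", "p").replace("-", "m")
        _save_nii(truth_dir / f"pool_amp_{tag}ppm.nii", amp)
        _save_nii(truth_dir / f"pool_width_{tag}ppm.nii", wid)
    (out / "spec.yaml").write_text(
        yaml.safe_dump(spec_to_dict(geom.spec), sort_keys=False))
    proto = dataclasses.asdict(study.protocol)
    proto["offsets_ppm"] = {str(k): np.asarray(v).tolist()
                            for k, v in proto["offsets_ppm"].items()}
    (out / "protocol.json").write_text(json.dumps(proto, indent=2))
    (out / "meta.json").write_text(json.dumps({"seed": study.seed}))
    return out


def read_study(study_dir) -> SyntheticStudy:
    d = Path(study_dir)
    frames_tbl = pd.read_csv(d / "frames.csv")
    proto_d = json.loads((d / "protocol.json").read_text())
    proto_d["offsets_ppm"] = {float(k): np.asarray(v)
                              for k, v in proto_d["offsets_ppm"].items()}
    proto_d["b1_levels_ut"] = tuple(proto_d["b1_levels_ut"])
    proto_d["tis_ms"] = tuple(proto_d["tis_ms"])
    protocol = Protocol(**proto_d)
    spec = spec_from_dict(yaml.safe_load((d / "spec.yaml").read_text()))
    geometry = make_phantom(spec)
    # overwrite regenerated truth with the stored one (authoritative copy)
    geometry.label_image[:] = _load_nii(d / "labels.nii").astype(np.int16)
    geometry.b0_map_ppm[:] = _load_nii(d / "b0_truth.nii")
    for name in list(geometry.truth_maps):
        geometry.truth_maps[name][:] = _load_nii(d / "truth" / f"{name}.nii")
    zspec = {}
    for b1, grp in frames_tbl.groupby("b1_ut"):
        grp = grp.sort_values("frame")
        frames = np.moveaxis(_load_nii(d / f"zspec_b1_{_b1_tag(b1)}.nii"),
                             -1, 0)
        zspec[float(b1)] = ZStack(
            b1_ut=float(b1), frames=frames,
            offsets_ppm=grp["offset_ppm"].to_numpy(dtype=float),
            is_reference=grp["is_reference"].to_numpy(dtype=bool))
    ir = np.moveaxis(_load_nii(d / "ir.nii"), -1, 0)
    seed = json.loads((d / "meta.json").read_text())["seed"]
    return SyntheticStudy(geometry=geometry, protocol=protocol,
                          zspec=zspec, ir_frames=ir, seed=seed)


def write_map(path, array):
    """Write one 2-D parameter map as NIfTI."""
    _save_nii(path, array)


def read_map(path):
    return _load_nii(path)
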