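"""On-disk cohort layout: phenotype CSV, NIfTI tissue maps, sidecar JSON.

A cohort directory holds ``phenotypes.csv`` (UTF-8, header row, missing
values as empty cells), ``mask.nii.gz`` (0/1 volume), one
``<subject>_<TISSUE>.nii.gz`` per subject and tissue under ``maps/``, and
``ground_truth.json`` with the generating latents when the cohort is
synthetic.  Affines are RAS+ with the voxel spacing on the diagonal.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .morphometry import VoxelGrid

TISSUES = ("GM", "WM", "CSF")


def write_cohort(
    out_dir: str | Path,
    pheno: pd.DataFrame,
    maps: dict[str, dict[str, VoxelGrid]],
    ground_truth: dict | None = None,
) -> Path:
    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    pheno.to_csv(out / "phenotypes.csv", index=False)
    first = next(iter(maps.values()))["GM"]
    mask_img = nib.Nifti1Image(first.mask.astype(np.uint8), first.affine)
    nib.save(mask_img, out / "mask.nii.gz")
    for sid, tissues in maps.items():
        for t in TISSUES:
            nib.save(tissues[t].to_nifti(), out / "maps" / f"{sid}_{t}.nii.gz")
    if ground_truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
    return out


def read_cohort(
    in_dir: str | Path,
) -> tuple[pd.DataFrame, dict[str, dict[str, VoxelGrid]]]:
    src = Path(in_dir)
    pheno = pd.read_csv(src / "phenotypes.csv")
    mask_img = nib.load(src / "mask.nii.gz")
    mask = np.asanyarray(mask_img.dataobj) > 0
    maps: dict[str, dict[str, VoxelGrid]] = {}
    for sid in pheno["subject_id"]:
        maps[sid] = {}
        for t in TISSUES:
            path = src / "maps" / f"{sid}_{t}.nii.gz"
            if not path.exists():
                raise FileNotFoundError(f"missing tissue map: {path}")
            maps[sid][t] = VoxelGrid.from_nifti(nib.load(path), mask=mask, tissue=t)
    return pheno, maps
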