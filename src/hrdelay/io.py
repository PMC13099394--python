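"""On-disk formats: NIfTI run volumes, CSV voxel metadata, JSON sidecars.

A session directory contains one uncompressed 4D NIfTI per run
(``run-XX_bold.nii``, voxels stored along the first axis so arbitrary
voxel collections round-trip), a ``meta.csv`` voxel table, and a
``session.json`` sidecar with the design, the session id and the run
condition labels.  Ground truth, when present, is ``truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import StudyDesign
from .synth import GroundTruth, VoxelDataset

__all__ = ["save_dataset", "load_dataset", "save_study", "load_study"]


def save_dataset(dataset: VoxelDataset, directory: str | Path) -> Path:
    """Write one session to ``directory`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for r in range(dataset.n_runs):
        # (n_voxels, 1, 1, n_volumes): voxels x time
        vol = dataset.runs[r].T[:, None, None, :]
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine)
        img.header.set_zooms((1.0, 1.0, 1.0, dataset.design.tr_seconds))
        nib.save(img, directory / f"run-{r:02d}_bold.nii")
    dataset.meta.to_csv(directory / "meta.csv", index=False)
    sidecar = {
        "session_id": dataset.session_id,
        "conditions": list(dataset.conditions),
        "design": dataset.design.to_dict(),
    }
    (directory / "session.json").write_text(json.dumps(sidecar, indent=2))
    if dataset.truth is not None:
        (directory / "truth.json").write_text(dataset.truth.to_json())
    return directory


def load_dataset(directory: str | Path) -> VoxelDataset:
    """Read a session directory written by :func:`save_dataset`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "session.json").read_text())
    design = StudyDesign.from_dict(sidecar["design"])
    conditions = list(sidecar["conditions"])
    runs = []
    for r in range(len(conditions)):
        img = nib.load(directory / f"run-{r:02d}_bold.nii")
        runs.append(np.asarray(img.dataobj, dtype=float)[:, 0, 0, :].T)
    meta = pd.read_csv(directory / "meta.csv")
    truth = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        truth = GroundTruth.from_json(truth_path.read_text())
    return VoxelDataset(
        session_id=int(sidecar["session_id"]),
        runs=np.stack(runs),
        conditions=conditions,
        meta=meta,
        design=design,
        truth=truth,
    )


def save_study(
    sessions: list[VoxelDataset], directory: str | Path, participant: str = "sub-01"
) -> Path:
    """Write one participant's sessions under ``directory/participant``."""
    root = Path(directory) / participant
    for ds in sessions:
        save_dataset(ds, root / f"ses-{ds.session_id:02d}")
    return root


def load_study(participant_dir: str | Path) -> list[VoxelDataset]:
    """Read every ``ses-*`` session directory of one participant."""
    participant_dir = Path(participant_dir)
    ses_dirs = sorted(participant_dir.glob("ses-*"))
    if not ses_dirs:
        raise FileNotFoundError(f"no session directories under {participant_dir}")
    return [load_dataset(d) for d in ses_dirs]
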