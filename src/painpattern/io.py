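"""On-disk layout for synthetic cohorts: NIfTI volumes and masks,
tab-separated event and motion tables, and a JSON ground-truth manifest."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .images import VolumeSeries
from .masks import Mask
from .synth import GroundTruth, RunData, SubjectRecord

__all__ = ["write_dataset", "load_dataset"]

MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                  "rot_x_rad", "rot_y_rad", "rot_z_rad"]


def write_dataset(dataset: dict, outdir) -> Path:
    """Write a generated cohort under ``outdir``:

    - ``sub-XX/run-YY_bold.nii.gz``, ``..._events.tsv``, ``..._motion.tsv``
    - ``masks/roi.nii.gz``, ``masks/<subregion>.nii.gz``, ``masks/brain.nii.gz``
    - ``truth.json`` (pattern supports and ROI sizes)
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth: GroundTruth = dataset["truth"]
    masks_dir = out / "masks"
    masks_dir.mkdir(exist_ok=True)
    truth.roi_mask.save(masks_dir / "roi.nii.gz")
    truth.brain_mask.save(masks_dir / "brain.nii.gz")
    for name, m in truth.subregion_masks.items():
        m.save(masks_dir / f"{name}.nii.gz")
    (out / "truth.json").write_text(json.dumps(truth.to_manifest(), indent=2))
    for record in dataset["subjects"]:
        sdir = out / record.subject_id
        sdir.mkdir(exist_ok=True)
        for r, run in enumerate(record.runs):
            stem = sdir / f"run-{r:02d}"
            run.series.save(f"{stem}_bold.nii.gz")
            run.events.to_csv(f"{stem}_events.tsv", sep="\t", index=False)
            pd.DataFrame(run.motion, columns=MOTION_COLUMNS).to_csv(
                f"{stem}_motion.tsv", sep="\t", index=False)
    return out


def load_dataset(indir) -> dict:
    """Load a cohort written by :func:`write_dataset` (volumes, events,
    motion, ROI masks; injected patterns are not round-tripped)."""
    root = Path(indir)
    roi = Mask.from_nifti(root / "masks" / "roi.nii.gz")
    brain = Mask.from_nifti(root / "masks" / "brain.nii.gz")
    subregions = {p.name.removesuffix(".nii.gz"): Mask.from_nifti(p)
                  for p in sorted((root / "masks").glob("*.nii.gz"))
                  if p.name not in ("roi.nii.gz", "brain.nii.gz")}
    truth = GroundTruth(modality_patterns={}, shared_pattern=np.zeros(roi.grid_shape),
                        roi_mask=roi, subregion_masks=subregions,
                        brain_mask=brain)
    subjects = []
    for sdir in sorted(root.glob("sub-*")):
        runs = []
        for bold in sorted(sdir.glob("run-*_bold.nii.gz")):
            stem = str(bold).removesuffix("_bold.nii.gz")
            series = VolumeSeries.from_nifti(bold)
            events = pd.read_csv(f"{stem}_events.tsv", sep="\t")
            motion = pd.read_csv(f"{stem}_motion.tsv", sep="\t").to_numpy()
            runs.append(RunData(series=series, events=events, motion=motion))
        subjects.append(SubjectRecord(subject_id=sdir.name, runs=runs))
    return {"subjects": subjects, "truth": truth, "config": None}
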