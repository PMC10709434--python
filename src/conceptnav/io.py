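"""Loading a simulated (or equivalently structured) dataset from disk.

Layout per subject directory: ``run-XX_events.tsv``, ``run-XX_bold.npz``
(or ``.nii.gz`` with a ``run-XX_bold.json`` sidecar giving the TR),
``run-XX_gaze.tsv``, and ``manifest.json``.  Events and gaze are plain
TSV; BOLD arrays are voxel x time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .glm import DEFAULT_TR_S
from .synth import BoldRun, GazeTrace, SubjectData


def _load_bold(path: Path, run_index: int) -> BoldRun:
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return BoldRun(
                data=np.asarray(z["data"], dtype=float),
                tr_s=float(z["tr_s"]),
                run_index=run_index,
                context=str(z["context"]),
            )
    import nibabel as nib  # optional, only for NIfTI input

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = data.reshape(-1, data.shape[-1])
    sidecar = path.with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return BoldRun(
        data=data,
        tr_s=float(meta.get("tr_s", DEFAULT_TR_S)),
        run_index=run_index,
        context=str(meta.get("context", "")),
    )


def load_subject(sub_dir) -> SubjectData:
    """Reassemble a SubjectData from an on-disk subject directory."""
    sub_dir = Path(sub_dir)
    events, bold, gaze = [], [], []
    for i, ev_path in enumerate(sorted(sub_dir.glob("run-*_events.tsv"))):
        ev = pd.read_csv(ev_path, sep="\t")
        events.append(ev)
        stem = ev_path.name.replace("_events.tsv", "")
        for suffix in ("_bold.npz", "_bold.nii.gz"):
            bp = sub_dir / f"{stem}{suffix}"
            if bp.exists():
                run = _load_bold(bp, i)
                if not run.context:
                    run.context = str(ev["context"].iloc[0])
                bold.append(run)
                break
        gz = sub_dir / f"{stem}_gaze.tsv"
        if gz.exists():
            g = pd.read_csv(gz, sep="\t")
            tr = bold[-1].tr_s if bold else DEFAULT_TR_S
            gaze.append(
                GazeTrace(x=g["x"].to_numpy(), y=g["y"].to_numpy(), tr_s=tr)
            )
    pooled = pd.concat(events, ignore_index=True)
    tgt = pooled[(pooled["question"] == "target") & (pooled["expected_answer"] == "yes")]
    hit_rate = float((tgt["response"] == "yes").mean()) if len(tgt) else float("nan")
    return SubjectData(
        subject_id=sub_dir.name,
        session=None,
        events=events,
        bold=bold,
        gaze=gaze,
        realized=None,
        hit_rate=hit_rate,
    )


def load_cohort(root):
    root = Path(root)
    return [load_subject(d) for d in sorted(root.glob("sub-*")) if d.is_dir()]
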