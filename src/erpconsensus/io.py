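"""Study readers/writers and run manifests.

Matrices travel as plain TSV (one file per subject × condition, header row
of channel labels, one row per time-point, µV) next to a JSON study
manifest holding montage, sampling metadata, condition order, group labels
and — for synthetic studies — ground-truth windows.  Everything a run
reports is reconstructible from the manifest seeds and parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .sim import Montage, StudySet, SubjectRecord, TimeWindow

logger = logging.getLogger(__name__)

__all__ = ["write_study", "read_study", "write_outputs"]

MANIFEST_NAME = "study.json"


def _matrix_filename(subject_id: str, condition: str) -> str:
    return f"{subject_id}_{condition}.tsv"


def write_study(study: StudySet, out_dir: str | Path) -> Path:
    """Write a study as per-subject-condition TSVs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for subj in study.subjects:
        for cond in study.condition_order:
            df = pd.DataFrame(subj.conditions[cond], columns=list(study.montage.labels))
            df.to_csv(out / _matrix_filename(subj.subject_id, cond), sep="\t", index=False)
    manifest = {
        "sfreq_hz": study.sfreq_hz,
        "epoch_start_ms": study.epoch_start_ms,
        "condition_order": list(study.condition_order),
        "seed": study.seed,
        "montage": {
            "labels": list(study.montage.labels),
            "positions": study.montage.positions.tolist(),
        },
        "subjects": [
            {
                "id": s.subject_id,
                "group": s.group,
                "files": {c: _matrix_filename(s.subject_id, c) for c in study.condition_order},
                "ground_truth": {
                    cond: {comp: tw.to_dict() for comp, tw in comps.items()}
                    for cond, comps in s.ground_truth.items()
                },
            }
            for s in study.subjects
        ],
        "ground_truth": {
            cond: {comp: tw.to_dict() for comp, tw in comps.items()}
            for cond, comps in study.ground_truth.items()
        },
    }
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    return out / MANIFEST_NAME


def read_study(manifest_path: str | Path) -> StudySet:
    """Load a study written by :func:`write_study`.

    Validates that every matrix shares the manifest's channel header and
    that row counts agree across conditions and subjects; errors name the
    offending file.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    meta = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    labels = list(meta["montage"]["labels"])
    montage = Montage(labels=tuple(labels), positions=np.asarray(meta["montage"]["positions"]))
    order = tuple(meta["condition_order"])

    subjects = []
    n_rows: int | None = None
    for entry in meta["subjects"]:
        conds = {}
        for cond in order:
            path = root / entry["files"][cond]
            df = pd.read_csv(path, sep="\t")
            if list(df.columns) != labels:
                raise ValueError(f"{path}: channel header does not match the manifest")
            try:
                mat = df.to_numpy(dtype=float)
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell ({exc})") from None
            if n_rows is None:
                n_rows = mat.shape[0]
            elif mat.shape[0] != n_rows:
                raise ValueError(
                    f"{path}: {mat.shape[0]} rows, expected {n_rows} (row-count mismatch)"
                )
            conds[cond] = mat
        subj_truth = {
            cond: {
                comp: TimeWindow(start_ms=d["start_ms"], end_ms=d["end_ms"])
                for comp, d in comps.items()
            }
            for cond, comps in entry.get("ground_truth", {}).items()
        }
        subjects.append(
            SubjectRecord(
                subject_id=entry["id"],
                group=entry["group"],
                conditions=conds,
                ground_truth=subj_truth,
            )
        )

    truth = {
        cond: {
            comp: TimeWindow(start_ms=d["start_ms"], end_ms=d["end_ms"])
            for comp, d in comps.items()
        }
        for cond, comps in meta.get("ground_truth", {}).items()
    }
    return StudySet(
        montage=montage,
        sfreq_hz=float(meta["sfreq_hz"]),
        epoch_start_ms=float(meta["epoch_start_ms"]),
        condition_order=order,
        subjects=subjects,
        ground_truth=truth,
        seed=meta.get("seed"),
    )


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    return obj


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_outputs(objects: dict, out_dir: str | Path, parameters: dict | None = None) -> Path:
    """Write named artifacts and a manifest with checksums.

    ``objects`` maps artifact name → object; arrays with an integer dtype or
    2 columns are written as TSV, DataFrames as TSV, everything else as
    JSON.  The manifest lists every artifact with a SHA-256 prefix so a
    rerun with the same master seed can be verified byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, obj in objects.items():
        from .clusterers import Partition  # late import: io stays format-only

        if isinstance(obj, Partition):
            path = out / f"{name}.tsv"
            df = pd.DataFrame(
                {"time_point": np.arange(obj.n), "cluster": obj.labels}
            )
            df.to_csv(path, sep="\t", index=False)
            side = out / f"{name}.json"
            side.write_text(
                json.dumps({"method": obj.method, "k": obj.k, "seed": obj.seed}, indent=1)
            )
            entries[f"{name}.json"] = _checksum(side)
        elif isinstance(obj, pd.DataFrame):
            path = out / f"{name}.tsv"
            obj.to_csv(path, sep="\t")
        elif isinstance(obj, np.ndarray):
            path = out / f"{name}.tsv"
            pd.DataFrame(obj).to_csv(path, sep="\t", index=False, header=False)
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(_to_jsonable(obj), indent=1, default=str))
        entries[path.name] = _checksum(path)
    manifest = {"artifacts": entries, "parameters": _to_jsonable(parameters or {})}
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath
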