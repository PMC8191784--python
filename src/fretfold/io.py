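"""Reading and writing trace files and dataset manifests.

Trace files are plain tab-separated text with a mandatory header and the
columns ``frame_index  time_s  donor  acceptor``, one file per molecule,
written at %.6g precision.  A dataset directory carries a ``manifest.json``
recording the kinetic scheme, acquisition model, condition, master seed and
the file list; condition metadata lives in the manifest, not in per-file
headers, so trace files stay tool-agnostic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .scheme import AcquisitionModel, Condition, KineticScheme
from .simulate import SimulatedDataset
from .traces import IntensityTrace

__all__ = ["read_traces", "write_traces", "write_dataset", "read_manifest",
           "write_legacy_two_column"]

COLUMNS = ["frame_index", "time_s", "donor", "acceptor"]
MANIFEST_NAME = "manifest.json"
FLOAT_FORMAT = "%.6g"


class TraceParseError(ValueError):
    """A trace file failed to parse; the message names file (and line)."""


def _read_one(path: Path, frame_interval: Optional[float] = None,
              condition: Optional[Condition] = None) -> IntensityTrace:
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - passthrough
        raise TraceParseError(f"{path}: cannot parse TSV: {exc}") from exc
    if list(df.columns) != COLUMNS:
        raise TraceParseError(
            f"{path}: expected columns {COLUMNS}, got {list(df.columns)}"
        )
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + 2  # +header +1-based
        raise TraceParseError(f"{path}: missing/ragged value at line {line}")
    try:
        num = df.astype(float)
    except ValueError as exc:
        bad = df.apply(pd.to_numeric, errors="coerce")
        line = int(bad.isna().any(axis=1).idxmax()) + 2
        raise TraceParseError(
            f"{path}: non-numeric intensity at line {line}"
        ) from exc
    time_s = num["time_s"].to_numpy()
    if frame_interval is None:
        frame_interval = float(np.median(np.diff(time_s))) if len(time_s) > 1 else 1.0
    return IntensityTrace(
        time_s=time_s,
        donor=num["donor"].to_numpy(),
        acceptor=num["acceptor"].to_numpy(),
        frame_interval=frame_interval,
        trace_id=path.stem,
        condition=condition,
    )


def read_manifest(directory: Union[str, Path]) -> Optional[dict]:
    p = Path(directory) / MANIFEST_NAME
    if not p.exists():
        return None
    with open(p) as fh:
        return json.load(fh)


def read_traces(path: Union[str, Path]) -> List[IntensityTrace]:
    """Read all traces from a directory (or a single TSV file).

    Traces are returned in deterministic lexicographic trace-id order.  When
    a manifest is present its file list is authoritative: a listed file that
    is missing raises an error naming the id, and condition/frame-interval
    metadata are attached to every trace.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_file():
        return [_read_one(path)]

    manifest = read_manifest(path)
    frame_interval = None
    condition = None
    if manifest is not None:
        acq = manifest.get("acquisition")
        if acq:
            frame_interval = acq.get("frame_interval")
        cond = manifest.get("condition")
        if cond:
            condition = Condition.from_dict(cond)
        names = sorted(manifest.get("traces", []))
        files = []
        for trace_id in names:
            f = path / f"{trace_id}.tsv"
            if not f.exists():
                raise FileNotFoundError(
                    f"manifest lists trace id {trace_id!r} but {f} is missing"
                )
            files.append(f)
    else:
        files = sorted(p for p in path.glob("*.tsv"))
    return [_read_one(f, frame_interval, condition) for f in files]


def write_traces(
    traces: Sequence[IntensityTrace],
    path: Union[str, Path],
    overwrite: bool = False,
    manifest_extra: Optional[dict] = None,
) -> List[Path]:
    """Write traces as one TSV per molecule plus a manifest.

    Refuses to clobber an existing manifest unless ``overwrite`` is set.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mpath = path / MANIFEST_NAME
    if mpath.exists() and not overwrite:
        raise FileExistsError(
            f"{mpath} exists; pass overwrite=True to replace the dataset"
        )
    written = []
    ids = []
    for trace in traces:
        if not trace.trace_id:
            raise ValueError("every trace needs a trace_id before writing")
        df = pd.DataFrame(
            {
                "frame_index": np.arange(trace.n_frames),
                "time_s": trace.time_s,
                "donor": trace.donor,
                "acceptor": trace.acceptor,
            }
        )
        f = path / f"{trace.trace_id}.tsv"
        df.to_csv(f, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written.append(f)
        ids.append(trace.trace_id)
    manifest = {
        "scheme": None,
        "acquisition": None,
        "condition": traces[0].condition.to_dict()
        if traces and traces[0].condition is not None
        else None,
        "seed": None,
        "traces": ids,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return written


def write_dataset(
    dataset: SimulatedDataset, path: Union[str, Path], overwrite: bool = False
) -> List[Path]:
    """Write a simulated dataset with its full ground-truth manifest."""
    return write_traces(
        dataset.traces,
        path,
        overwrite=overwrite,
        manifest_extra=dataset.manifest(),
    )


def write_legacy_two_column(
    traces: Sequence[IntensityTrace], path: Union[str, Path]
) -> List[Path]:
    """Export headerless two-column (donor, acceptor) text files.

    Compatible with older trace-idealization tools that expect raw channel
    pairs without timestamps.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for trace in traces:
        f = path / f"{trace.trace_id}.dat"
        np.savetxt(
            f, np.column_stack([trace.donor, trace.acceptor]), fmt=FLOAT_FORMAT,
            delimiter="\t"
        )
        written.append(f)
    return written
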