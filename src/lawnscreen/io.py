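"""CSV/JSON readers and writers for all pipeline artifacts.

Everything is plain text: CSV for tables and time series, JSON for
reports.  Schemas:

* **event logs** — columns ``worm_id, line_id, condition, time_s, event``
  (required) plus ``duration_s`` and ``initial_state``; every worm also
  carries one bookkeeping row with ``event="end"`` at the assay end so
  that worms without behavioral events survive a round trip.
* **measurement matrix** — first column ``line_id``, remaining columns
  neuron labels, cells in [0, 1]; a sidecar CSV maps
  ``neuron_id -> class`` (interneuron/sensory/motor).
* **replicate table** — tidy columns
  ``line_id, metric, condition, replicate, value``.
* **calcium traces** — columns ``worm_id, neuron, condition, frame,
  intensity``; the sampling rate is carried in a ``# fps=...`` comment
  line at the top of the file.
* **expression table** — rows genes (first column ``gene_id``), columns
  neuron types.

Readers validate on load: schema violations name the offending row,
illegal event transitions name the worm and time (raised by the event-log
state machine).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import EVENT_KINDS, WormEventLog
from .calcium import CalciumTrace
from .expression import ExpressionMatrix
from .matrix import MeasurementMatrix
from .screen import PhenotypeVector

_EVENT_COLUMNS = ["worm_id", "line_id", "condition", "time_s", "event"]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


# ---------------------------------------------------------------- event logs

def write_event_logs(logs, path) -> None:
    rows = []
    for log in logs:
        for t, kind in log.events:
            rows.append((log.worm_id, log.line_id, log.condition, t, kind,
                         log.duration_s, log.initial_state))
        rows.append((log.worm_id, log.line_id, log.condition, log.duration_s,
                     "end", log.duration_s, log.initial_state))
    frame = pd.DataFrame(rows, columns=_EVENT_COLUMNS
                         + ["duration_s", "initial_state"])
    frame.to_csv(path, index=False)


def read_event_logs(path) -> list:
    """Load and validate event logs; returns a list of WormEventLog."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file with no header")
    missing = [c for c in _EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    legal = set(EVENT_KINDS) | {"end"}
    for i, ev in enumerate(frame["event"]):
        if ev not in legal:
            raise SchemaError(f"{path}: row {i + 2}: unknown event {ev!r}")
    logs = []
    for (worm, line, cond), grp in frame.groupby(
            ["worm_id", "line_id", "condition"], sort=False):
        events = [(float(t), str(e)) for t, e in zip(grp["time_s"], grp["event"])
                  if e != "end"]
        end_rows = grp[grp["event"] == "end"]
        if len(end_rows):
            duration = float(end_rows["time_s"].iloc[0])
        elif "duration_s" in grp.columns:
            duration = float(grp["duration_s"].iloc[0])
        else:
            duration = max(t for t, _ in events)
        initial = (str(grp["initial_state"].iloc[0])
                   if "initial_state" in grp.columns else "on_lawn")
        logs.append(WormEventLog(worm_id=str(worm), line_id=str(line),
                                 condition=str(cond), events=tuple(events),
                                 duration_s=duration, initial_state=initial))
    return logs


# -------------------------------------------------------------------- matrix

def write_matrix(M: MeasurementMatrix, path, annotation_path=None) -> None:
    M.to_frame().to_csv(path)
    if annotation_path is not None:
        with open(annotation_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["neuron_id", "class"])
            for n in M.neuron_ids:
                writer.writerow([n, M.class_annotation.get(n, "")])


def read_matrix(path, annotation_path=None) -> MeasurementMatrix:
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    annotation = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path)
        for col in ("neuron_id", "class"):
            if col not in ann.columns:
                raise SchemaError(f"{annotation_path}: missing column {col!r}")
        annotation = {str(r.neuron_id): str(r["class"])
                      for _, r in ann.iterrows() if str(r["class"])}
    return MeasurementMatrix.from_frame(frame, class_annotation=annotation)


# ----------------------------------------------------------- replicate table

_REPLICATE_COLUMNS = ["line_id", "metric", "condition", "replicate", "value"]


def write_replicates(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_replicates(path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REPLICATE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad = frame[~frame["condition"].isin(["plusATR", "minusATR"])]
    if len(bad):
        raise SchemaError(
            f"{path}: row {bad.index[0] + 2}: condition must be "
            f"plusATR/minusATR, got {bad['condition'].iloc[0]!r}")
    return frame


# ---------------------------------------------------------- phenotype vector

def write_phenotype_vector(P: PhenotypeVector, path) -> None:
    path = Path(path)
    P.to_frame().to_csv(path, index=False)
    payload = {"metric": P.metric, "alpha": P.alpha,
               "line_ids": list(P.line_ids), "values": P.values.tolist(),
               "pvalues": P.pvalues.tolist()}
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def read_phenotype_vector(path) -> PhenotypeVector:
    frame = pd.read_csv(path)
    for col in ("line_id", "metric", "value", "pvalue", "alpha"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return PhenotypeVector(
        metric=str(frame["metric"].iloc[0]),
        line_ids=tuple(str(x) for x in frame["line_id"]),
        values=frame["value"].to_numpy(float),
        pvalues=frame["pvalue"].to_numpy(float),
        alpha=float(frame["alpha"].iloc[0]))


# ------------------------------------------------------------ calcium traces

def write_traces(traces, path) -> None:
    traces = list(traces)
    fps = {t.fps for t in traces}
    if len(fps) != 1:
        raise ValueError("all traces in one file must share the frame rate")
    with open(path, "w", newline="") as fh:
        fh.write(f"# fps={fps.pop()}\n")
        writer = csv.writer(fh)
        writer.writerow(["worm_id", "neuron", "condition", "frame", "intensity"])
        for t in traces:
            for i, v in enumerate(t.values):
                writer.writerow([t.worm_id, t.neuron, t.condition, i, repr(float(v))])


def read_traces(path) -> list:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fps="):
            raise SchemaError(f"{path}: missing '# fps=' header comment")
        fps = float(first.split("=", 1)[1])
        frame = pd.read_csv(fh, float_precision="round_trip")
    for col in ("worm_id", "neuron", "condition", "frame", "intensity"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    traces = []
    for (worm, neuron, cond), grp in frame.groupby(
            ["worm_id", "neuron", "condition"], sort=False):
        grp = grp.sort_values("frame")
        traces.append(CalciumTrace(worm_id=str(worm), neuron=str(neuron),
                                   condition=str(cond), fps=fps,
                                   values=grp["intensity"].to_numpy(float)))
    return traces


# --------------------------------------------------------- expression table

def write_expression(E: ExpressionMatrix, path) -> None:
    E.to_frame().to_csv(path)


def read_expression(path) -> ExpressionMatrix:
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if frame.shape[1] == 0:
        raise SchemaError(f"{path}: no neuron columns")
    return ExpressionMatrix.from_frame(frame)


# ------------------------------------------------------------------- reports

def write_json_report(payload: dict, path) -> None:
    """JSON with numpy scalars/arrays coerced to plain Python types."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default,
                                     sort_keys=True))
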