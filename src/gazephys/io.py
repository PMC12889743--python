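"""Plain-text (CSV/JSON) and TIFF readers/writers for pipeline artifacts."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BasisParams,
    CosineComponent,
    GazeEvent,
    GazeTrace,
    GroundTruth,
    SceneFrameSet,
)

TRACE_COLUMNS = [
    "time_s",
    "eye_x_deg",
    "eye_y_deg",
    "head_x_deg",
    "head_y_deg",
    "body_x_cm",
    "body_y_cm",
    "head_height_cm",
]


def write_trace_csv(trace: GazeTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack(
            [
                trace.timestamps,
                trace.eye_pos,
                trace.head_pos,
                trace.body_pos,
                trace.head_height,
            ]
        ),
        columns=TRACE_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> GazeTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    return GazeTrace(
        timestamps=t,
        eye_pos=df[["eye_x_deg", "eye_y_deg"]].to_numpy(),
        head_pos=df[["head_x_deg", "head_y_deg"]].to_numpy(),
        body_pos=df[["body_x_cm", "body_y_cm"]].to_numpy(),
        head_height=df["head_height_cm"].to_numpy(),
        sample_rate=round(rate, 6),
    )


def write_spikes_csv(spike_trains: dict, path: str | Path) -> None:
    rows = [
        {"neuron_id": nid, "spike_time_s": t}
        for nid, spikes in spike_trains.items()
        for t in np.asarray(spikes)
    ]
    pd.DataFrame(rows, columns=["neuron_id", "spike_time_s"]).to_csv(path, index=False)


def read_spikes_csv(path: str | Path) -> dict:
    df = pd.read_csv(path)
    return {
        nid: np.sort(g["spike_time_s"].to_numpy())
        for nid, g in df.groupby("neuron_id")
    }


def write_events_csv(events: list[GazeEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "kind": e.kind,
                "onset_s": e.onset,
                "offset_s": e.offset,
                "duration_s": e.duration,
                "amplitude_deg": e.amplitude,
                "peak_speed_deg_per_ms": e.peak_speed,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[GazeEvent]:
    df = pd.read_csv(path)
    return [
        GazeEvent(
            kind=r.kind,
            onset=r.onset_s,
            offset=r.offset_s,
            peak_speed=r.peak_speed_deg_per_ms,
            amplitude=r.amplitude_deg,
        )
        for r in df.itertuples()
    ]


def _basis_to_dict(basis: BasisParams | None):
    if basis is None:
        return None
    return {
        "suppression": dataclasses.asdict(basis.suppression),
        "enhancement": dataclasses.asdict(basis.enhancement),
    }


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "session_length": truth.session_length,
        "true_model": truth.true_model,
        "baseline_rate": truth.baseline_rate,
        "true_basis": _basis_to_dict(truth.true_basis),
        "per_fixation_gain": (
            None
            if truth.per_fixation_gain is None
            else np.asarray(truth.per_fixation_gain).tolist()
        ),
        "locomotion_intervals": [list(iv) for iv in truth.locomotion_intervals],
        "events": [
            {
                "kind": e.kind,
                "onset": e.onset,
                "offset": e.offset,
                "peak_speed": None if np.isnan(e.peak_speed) else e.peak_speed,
                "amplitude": None if np.isnan(e.amplitude) else e.amplitude,
            }
            for e in truth.events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    basis = None
    if d.get("true_basis"):
        basis = BasisParams(
            suppression=CosineComponent(**d["true_basis"]["suppression"]),
            enhancement=CosineComponent(**d["true_basis"]["enhancement"]),
        )
    events = [
        GazeEvent(
            kind=e["kind"],
            onset=e["onset"],
            offset=e["offset"],
            peak_speed=np.nan if e["peak_speed"] is None else e["peak_speed"],
            amplitude=np.nan if e["amplitude"] is None else e["amplitude"],
        )
        for e in d["events"]
    ]
    return GroundTruth(
        events=events,
        seed=d["seed"],
        session_length=d["session_length"],
        true_model=d.get("true_model"),
        true_basis=basis,
        baseline_rate=d.get("baseline_rate", 0.0),
        per_fixation_gain=(
            None
            if d.get("per_fixation_gain") is None
            else np.asarray(d["per_fixation_gain"])
        ),
        locomotion_intervals=[tuple(iv) for iv in d.get("locomotion_intervals", [])],
    )


def write_frames_tiff(frameset: SceneFrameSet, path: str | Path) -> None:
    """Frames as multi-page TIFF plus a JSON sidecar with the metadata."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(frameset.frames, dtype=np.float32), photometric="minisblack"
    )
    sidecar = {
        "frame_times": frameset.frame_times.tolist(),
        "deg_per_px": frameset.deg_per_px,
        "gaze_center_px": np.asarray(frameset.gaze_center_px).tolist(),
        "validity": np.asarray(frameset.validity, dtype=bool).tolist(),
        "rf_offset_deg": list(frameset.rf_offset_deg),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_frames_tiff(path: str | Path) -> SceneFrameSet:
    import tifffile

    path = Path(path)
    frames = tifffile.imread(path)
    d = json.loads(path.with_suffix(".json").read_text())
    return SceneFrameSet(
        frames=frames,
        frame_times=np.asarray(d["frame_times"]),
        gaze_center_px=np.asarray(d["gaze_center_px"]),
        validity=np.asarray(d["validity"], dtype=bool),
        deg_per_px=d["deg_per_px"],
        rf_offset_deg=tuple(d["rf_offset_deg"]),
    )


def write_psth_csv(psth, path: str | Path) -> None:
    pd.DataFrame(
        {"time_ms": psth.time_bins, "mean": psth.mean, "se": psth.se}
    ).to_csv(path, index=False)


def metrics_frame(metrics_by_id: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "neuron_id": nid,
                "A_sup": m.a_sup,
                "A_enh": m.a_enh,
                "latency_ms": m.latency_ms,
                "z_sup": m.z_sup,
                "z_enh": m.z_enh,
                "significant_sup": m.significant_sup,
                "significant_enh": m.significant_enh,
                "latency_defined": m.latency_defined,
            }
            for nid, m in metrics_by_id.items()
        ]
    )


def fits_frame(comparisons_by_id: dict) -> pd.DataFrame:
    rows = []
    for nid, comp in comparisons_by_id.items():
        for fit in (comp.saccade_locked, comp.two_stage):
            p = fit.params
            rows.append(
                {
                    "neuron_id": nid,
                    "model_kind": fit.model_kind,
                    "a_sup": p.suppression.a,
                    "a_enh": p.enhancement.a,
                    "w_sup": p.suppression.w,
                    "w_enh": p.enhancement.w,
                    "l_sup": p.suppression.l,
                    "l_enh": p.enhancement.l,
                    "loss": fit.loss,
                    "model_error": fit.model_error,
                    "converged": fit.converged,
                    "winner": comp.winner,
                }
            )
    return pd.DataFrame(rows)
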