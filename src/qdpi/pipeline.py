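"""End-to-end orchestration: simulate -> demux -> quantify -> refine -> filter -> fit.

One seeded configuration drives the whole chain on synthetic data, producing
the session intensity summaries, refined keypoints, QC report and
sample-efficiency fit in a single deterministic pass.  This is the code path
behind ``qdpi simulate --preset full`` and the reproducibility checks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import fluor_quant, qc_filter, scaling_curves, spot_localization, synthetic
from .io_core import KeypointTable, demultiplex


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    recording: synthetic.RecordingConfig = field(default_factory=synthetic.RecordingConfig)
    scaling: synthetic.ScalingCurveConfig = field(default_factory=synthetic.ScalingCurveConfig)
    keypoint_jitter_sd: float = 1.0  # px, emulated tracker noise on spot centers
    refine_radius: int = 10
    background_window: int = 1500
    autocorr_stride: int = 200
    error_thresholds_px: tuple[float, float] = (4.9, 2.45)  # ~2 mm and ~1 mm

    def reseeded(self) -> "PipelineConfig":
        return replace(
            self,
            recording=replace(self.recording, seed=self.seed),
            scaling=replace(self.scaling, seed=self.seed + 1),
        )


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run the whole synthetic pipeline; returns a JSON-serializable summary."""
    config = config.reseeded()
    rng = np.random.default_rng(config.seed + 2)

    # simulate + demultiplex
    recording, truth = synthetic.simulate_recording(config.recording)
    demux = demultiplex(recording)
    channel_truth = truth["channels"]
    assigned = np.empty(recording.n_frames, dtype=object)
    assigned[demux.reflectance_indices] = "reflectance"
    assigned[demux.fluorescence_indices] = "fluorescence"
    n_assigned = len(demux.reflectance_indices) + len(demux.fluorescence_indices)
    demux_accuracy = float(
        np.mean(
            [
                assigned[i] == channel_truth[i]
                for i in np.concatenate([demux.reflectance_indices, demux.fluorescence_indices])
            ]
        )
    ) if n_assigned else float("nan")

    # quantify
    subtracted = fluor_quant.subtract_rolling_background(
        demux.fluorescence, window=config.background_window
    )
    trace = fluor_quant.frame_max_trace(subtracted, session=recording.session)
    summary = fluor_quant.summarize_session(trace)
    acmap = fluor_quant.estimate_spread(
        fluor_quant.spatial_autocorrelation(subtracted, frame_stride=config.autocorr_stride)
    )

    # emulated tracker predictions on the true spot centers, then refinement
    spots = truth["spots"]
    n = len(spots)
    jitter = rng.normal(0.0, config.keypoint_jitter_sd, size=(n, 2))
    records = pd.DataFrame(
        {
            "frame": np.arange(len(spots)) * 0 + spots["fluorescence_frame"].to_numpy(),
            "camera": recording.session.camera_id,
            "node": [f"spot{s}" for s in spots["spot"]],
            "x": spots["x"].to_numpy() + jitter[:, 0],
            "y": spots["y"].to_numpy() + jitter[:, 1],
            "score": np.clip(
                1.0 - np.linalg.norm(jitter, axis=1) / 10.0 + rng.normal(0, 0.02, n), 0, 1
            ),
        }
    )
    table = KeypointTable(records=records)
    refined = spot_localization.refine_keypoints(
        table, subtracted, radius=config.refine_radius
    )
    err_raw = np.linalg.norm(
        refined.records[["x", "y"]].to_numpy() - spots[["x", "y"]].to_numpy(), axis=1
    )
    err_refined = np.linalg.norm(
        refined.records[["refined_x", "refined_y"]].to_numpy() - spots[["x", "y"]].to_numpy(),
        axis=1,
    )

    # QC cascade (few-node table: pose-space stage disabled, as for knee data)
    report = qc_filter.run_cascade(refined, qc_filter.QCConfig(pca_enabled=False))

    # sample-efficiency fit on simulated scaling points
    points = synthetic.simulate_scaling_points(config.scaling)
    fit = scaling_curves.fit_power_law(
        points["n_frames"].to_numpy(), points["error_px"].to_numpy()
    )
    frames_needed = {
        f"{t}px": scaling_curves.frames_required(fit, t) for t in config.error_thresholds_px
    }

    return {
        "seed": config.seed,
        "demux": {
            "n_frames": recording.n_frames,
            "n_reflectance": int(len(demux.reflectance_indices)),
            "n_fluorescence": int(len(demux.fluorescence_indices)),
            "n_dropped": int(len(demux.dropped_indices)),
            "accuracy": demux_accuracy,
        },
        "quantify": {
            "mean_frame_max": summary.mean_value,
            "p95_frame_max": summary.p95_value,
            "spread_x_px": acmap.spread_x,
            "spread_y_px": acmap.spread_y,
        },
        "refine": {
            "median_error_raw_px": float(np.median(err_raw)),
            "median_error_refined_px": float(np.median(err_refined)),
            "n_refined": int(refined.records["refined_flag"].sum()),
        },
        "qc": dict(report.counts),
        "scaling": {
            "a": fit.a,
            "b": fit.b,
            "c": fit.c,
            "frames_required": frames_needed,
        },
    }


def run_and_save(config: PipelineConfig, out: str | Path) -> dict:
    result = run_full_pipeline(config)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(result, indent=1, sort_keys=True))
    return result
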