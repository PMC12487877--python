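"""Automated quality-control cascade for machine-labeled keypoint datasets.

Refined keypoint predictions are admitted to a training dataset only after
passing an ordered sequence of filters:

1. **jump** — a keypoint that jumps more than ``max_jump`` px (L2) between
   neighboring frames is an apparent tracking error and is excluded.
2. **PCA outlier** — pose vectors (x, y of the standard node set) are
   decomposed by PCA, keeping the smallest number of components that drops
   the cumulative mean squared reconstruction error by 90%; frames with an
   outlying reconstruction error are excluded.  Skipped for the two-node
   knee configuration.
3. **visibility** — a keypoint is visible only if its confidence exceeds 0.2.
4. **validity** — visible keypoints must show enough fluorescence close
   enough to the prediction; both thresholds scale linearly with confidence
   (less confident keypoints need more fluorescence, closer by).
5. **drop budget** — frames dropping more visible-but-invalid keypoints than
   a size-dependent budget (0 at <=3 visible, 3 at >=10) are excluded.
6. **pairwise distance** — frames where any keypoint pair is farther apart
   than ``max_pair_distance`` px are excluded.

Every exclusion carries a machine-readable reason in the report.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import KeypointTable

logger = logging.getLogger(__name__)

#: the ten standard body landmarks used for pose-space (PCA) filtering
STANDARD_NODES = (
    "back_bottom",
    "back_middle",
    "back_top",
    "tail_base",
    "tail_middle",
    "tail_tip",
    "forepaw_left",
    "forepaw_right",
    "hindpaw_left",
    "hindpaw_right",
)

RECORD_FLAGS = ("excluded_jump", "invisible", "invalid_fluor", "invalid_distance", "missing_evidence")
FRAME_FLAGS = ("excluded_pca", "excluded_drop_budget", "excluded_pairwise")


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the QC cascade (defaults: standard-keypoint settings)."""

    max_jump: float = 30.0  # px between neighboring frames
    jump_rule: str = "all_neighbors"  # or "any_neighbor"
    visibility_score: float = 0.2
    low_anchor_score: float = 0.7  # 0.5 for the knee-joint variant
    fluor_peak_at_low_anchor: float = 75.0  # a.u.
    fluor_peak_at_score1: float = 25.0
    max_dist_at_low_anchor: float = 5.0  # px
    max_dist_at_score1: float = 15.0
    budget_min_keypoints: int = 3
    budget_max_keypoints: int = 10
    budget_max_drops: int = 3
    max_pair_distance: float = 300.0  # px
    pca_mse_drop_fraction: float = 0.90
    pca_enabled: bool = True
    pca_outlier_nmad: float = 8.0  # flag err > median + nmad * 1.4826 * MAD
    pca_min_error: float = 1e-6  # absolute floor so exact low-rank data never flags

    def __post_init__(self) -> None:
        if not self.low_anchor_score < 1:
            raise ValueError("low_anchor_score must be < 1")
        if not (self.fluor_peak_at_low_anchor > self.fluor_peak_at_score1):
            raise ValueError("fluorescence threshold must decrease with confidence")
        if not (self.max_dist_at_low_anchor < self.max_dist_at_score1):
            raise ValueError("distance threshold must increase with confidence")
        if self.max_jump <= 0 or self.max_pair_distance <= 0:
            raise ValueError("max_jump and max_pair_distance must be positive")
        if self.jump_rule not in ("all_neighbors", "any_neighbor"):
            raise ValueError("jump_rule must be 'all_neighbors' or 'any_neighbor'")

    @classmethod
    def knee(cls) -> "QCConfig":
        """Knee-joint variant: lower confidence anchor, PCA stage skipped."""
        return cls(low_anchor_score=0.5, pca_enabled=False)


@dataclass
class QCReport:
    """Per-record and per-frame exclusion flags plus the surviving dataset."""

    records: pd.DataFrame  # input records + boolean flag columns
    frame_flags: pd.DataFrame  # (camera, frame) + frame-level flags
    counts: dict
    surviving: KeypointTable
    pca_k: int | None = None
    pca_skipped: bool = False


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------


def jump_filter(track: pd.DataFrame, max_jump: float = 30.0, rule: str = "all_neighbors") -> pd.Series:
    """Flag implausible jumps in one node's track (rows sorted by frame).

    A displacement counts against a keypoint when it *strictly* exceeds
    ``max_jump`` (a 30 px step is kept, 31 px is flagged).  Under the default
    ``all_neighbors`` rule a keypoint is flagged only when every displacement
    to its existing neighbors exceeds the limit (isolated-outlier semantics);
    ``any_neighbor`` flags on a single offending displacement.
    """
    track = track.sort_values("frame")
    xy = track[["x", "y"]].to_numpy(dtype=np.float64)
    present = np.isfinite(xy).all(axis=1)
    flags = np.zeros(len(track), dtype=bool)
    idx = np.nonzero(present)[0]
    if idx.size >= 2:
        disp = np.linalg.norm(np.diff(xy[idx], axis=0), axis=1)
        big = disp > max_jump
        for j in range(idx.size):
            before = big[j - 1] if j > 0 else None
            after = big[j] if j < idx.size - 1 else None
            sides = [s for s in (before, after) if s is not None]
            if rule == "any_neighbor":
                flags[idx[j]] = any(sides)
            else:
                flags[idx[j]] = bool(sides) and all(sides)
    return pd.Series(flags, index=track.index)


def validity_thresholds(score: float, config: QCConfig = QCConfig()) -> tuple[float, float]:
    """Confidence-scaled (min fluorescence peak, max center distance).

    Linear between the low anchor (default 0.7 -> 75 a.u., 5 px) and a score
    of 1.0 (-> 25 a.u., 15 px); scores below the anchor are clamped to the
    anchor values, since the scale is defined only between anchor and 1.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must be in [0, 1]")
    s = max(score, config.low_anchor_score)
    frac = (s - config.low_anchor_score) / (1.0 - config.low_anchor_score)
    min_peak = config.fluor_peak_at_low_anchor + frac * (
        config.fluor_peak_at_score1 - config.fluor_peak_at_low_anchor
    )
    max_dist = config.max_dist_at_low_anchor + frac * (
        config.max_dist_at_score1 - config.max_dist_at_low_anchor
    )
    return float(min_peak), float(max_dist)


def drop_budget(n_visible: int, config: QCConfig = QCConfig()) -> int:
    """Allowed visible-but-invalid keypoints for a frame with ``n_visible``.

    0 for frames with ``budget_min_keypoints`` (3) or fewer, up to
    ``budget_max_drops`` (3) at ``budget_max_keypoints`` (10), linear and
    floored to an integer in between.
    """
    if n_visible < 0:
        raise ValueError("n_visible must be >= 0")
    lo, hi = config.budget_min_keypoints, config.budget_max_keypoints
    if n_visible <= lo:
        return 0
    if n_visible >= hi:
        return config.budget_max_drops
    return math.floor(config.budget_max_drops * (n_visible - lo) / (hi - lo))


def pairwise_distance_flag(points: np.ndarray, max_pair_distance: float = 300.0) -> bool:
    """True when any pair of keypoints is strictly farther than the limit."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 2:
        return False
    diff = points[:, None, :] - points[None, :, :]
    dists = np.linalg.norm(diff, axis=-1)
    return bool(dists.max() > max_pair_distance)


def pca_outlier_filter(
    table: pd.DataFrame,
    config: QCConfig = QCConfig(),
    nodes: tuple[str, ...] = STANDARD_NODES,
) -> tuple[pd.DataFrame, int | None, bool]:
    """Flag frames whose pose does not fit the low-dimensional pose space.

    Only frames where every node in ``nodes`` has finite coordinates enter
    the analysis.  The component count ``k`` is the smallest number of
    principal components that reduces the cumulative mean squared
    reconstruction error by at least ``pca_mse_drop_fraction``.  A frame is
    an outlier when its reconstruction error exceeds
    ``median + pca_outlier_nmad * 1.4826 * MAD`` (and the absolute floor).

    Returns ``(frame_flags, k, skipped)`` where ``frame_flags`` has columns
    ``camera, frame, excluded_pca``.
    """
    poses = []
    keys = []
    for (cam, frame), sub in table.groupby(["camera", "frame"], sort=True):
        sub = sub.set_index("node")
        if not all(n in sub.index for n in nodes):
            continue
        xy = sub.loc[list(nodes), ["x", "y"]].to_numpy(dtype=np.float64).ravel()
        if not np.all(np.isfinite(xy)):
            continue
        poses.append(xy)
        keys.append((cam, frame))
    if len(poses) < 2:
        warnings.warn("PCA stage skipped: fewer than 2 complete frames", stacklevel=2)
        return pd.DataFrame(columns=["camera", "frame", "excluded_pca"]), None, True
    X = np.asarray(poses)

    def score(fit_mask: np.ndarray) -> tuple[np.ndarray, int] | None:
        mean = X[fit_mask].mean(axis=0)
        Xc_fit = X[fit_mask] - mean
        _, s, vt = np.linalg.svd(Xc_fit, full_matrices=False)
        var = s**2
        if var.sum() <= 0:
            return None
        frac = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(frac, config.pca_mse_drop_fraction - 1e-12) + 1)
        Xc = X - mean
        proj = Xc @ vt[:k].T @ vt[:k]
        return ((Xc - proj) ** 2).mean(axis=1), k

    scored = score(np.ones(len(X), dtype=bool))
    if scored is None:
        flags = pd.DataFrame(keys, columns=["camera", "frame"])
        flags["excluded_pca"] = False
        return flags, 0, False
    err, k = scored

    def cutoff(e: np.ndarray) -> float:
        med = np.median(e)
        mad = np.median(np.abs(e - med))
        return max(med + config.pca_outlier_nmad * 1.4826 * mad, config.pca_min_error)

    flagged = err > cutoff(err)
    # one robust refinement: outliers distort the basis itself, so refit the
    # component space on the unflagged frames and re-score everything
    if flagged.any() and (~flagged).sum() >= 2:
        rescored = score(~flagged)
        if rescored is not None:
            err, k = rescored
            flagged = err > cutoff(err)
    flags = pd.DataFrame(keys, columns=["camera", "frame"])
    flags["excluded_pca"] = flagged
    return flags, k, False


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------


def run_cascade(
    table: KeypointTable,
    config: QCConfig = QCConfig(),
    nodes: tuple[str, ...] | None = None,
) -> QCReport:
    """Apply the full QC cascade in its fixed stage order.

    ``table.records`` must carry fluorescence evidence columns
    ``peak_value`` (a.u.) and either ``center_distance`` or
    ``distance_moved`` (px to the nearest fluorescence center).  Records
    with missing evidence are invalid with reason ``missing_evidence``.
    """
    df = table.records.copy().reset_index(drop=True)
    if "center_distance" not in df.columns:
        if "distance_moved" in df.columns:
            df["center_distance"] = df["distance_moved"]
        else:
            df["center_distance"] = np.nan
    if "peak_value" not in df.columns:
        df["peak_value"] = np.nan
    for flag in RECORD_FLAGS:
        df[flag] = False

    # stage 1: jump
    for _, idx in df.groupby(["camera", "node"], sort=False).groups.items():
        sub = df.loc[idx]
        flags = jump_filter(sub, config.max_jump, config.jump_rule)
        df.loc[flags.index[flags], "excluded_jump"] = True
    alive = ~df["excluded_jump"]

    # stage 2: PCA outliers (frame-level); knee configs skip this stage
    pca_k: int | None = None
    pca_skipped = True
    pca_nodes = nodes if nodes is not None else STANDARD_NODES
    frame_keys = df[["camera", "frame"]].drop_duplicates().reset_index(drop=True)
    for flag in FRAME_FLAGS:
        frame_keys[flag] = False
    if config.pca_enabled:
        flags, pca_k, pca_skipped = pca_outlier_filter(df[alive], config, nodes=pca_nodes)
        if not pca_skipped and len(flags):
            bad = flags[flags["excluded_pca"]][["camera", "frame"]]
            merged = frame_keys.merge(bad.assign(_bad=True), on=["camera", "frame"], how="left")
            frame_keys["excluded_pca"] = merged["_bad"].notna().to_numpy()
    frame_alive = _frame_alive_mask(df, frame_keys)
    alive &= frame_alive

    # stage 3: visibility
    visible = df["score"] > config.visibility_score
    df.loc[alive & ~visible, "invisible"] = True

    # stage 4: confidence-scaled validity
    valid = np.zeros(len(df), dtype=bool)
    consider = alive & visible
    for i in np.nonzero(consider.to_numpy())[0]:
        peak = df.at[i, "peak_value"]
        dist = df.at[i, "center_distance"]
        if not (np.isfinite(peak) and np.isfinite(dist)):
            df.at[i, "missing_evidence"] = True
            continue
        min_peak, max_dist = validity_thresholds(float(df.at[i, "score"]), config)
        if peak < min_peak:
            df.at[i, "invalid_fluor"] = True
        if dist > max_dist:
            df.at[i, "invalid_distance"] = True
        valid[i] = peak >= min_peak and dist <= max_dist

    # stage 5: drop budget (frame-level)
    grouped = df.assign(_visible=consider.to_numpy() & alive.to_numpy(), _valid=valid)
    for j, row in frame_keys.iterrows():
        if row[list(FRAME_FLAGS)].any():
            continue
        sub = grouped[(grouped["camera"] == row["camera"]) & (grouped["frame"] == row["frame"])]
        n_vis = int(sub["_visible"].sum())
        n_val = int(sub["_valid"].sum())
        if n_vis - n_val > drop_budget(n_vis, config):
            frame_keys.at[j, "excluded_drop_budget"] = True

    # stage 6: pairwise distance (frame-level, on surviving valid keypoints)
    for j, row in frame_keys.iterrows():
        if row[list(FRAME_FLAGS)].any():
            continue
        sub = grouped[
            (grouped["camera"] == row["camera"]) & (grouped["frame"] == row["frame"]) & grouped["_valid"]
        ]
        if pairwise_distance_flag(sub[["x", "y"]].to_numpy(), config.max_pair_distance):
            frame_keys.at[j, "excluded_pairwise"] = True

    frame_alive = _frame_alive_mask(df, frame_keys)
    survive_mask = alive.to_numpy() & valid & frame_alive.to_numpy()
    surviving_df = df.loc[survive_mask, [c for c in df.columns if c not in RECORD_FLAGS]]
    surviving = KeypointTable(
        records=surviving_df[["frame", "camera", "node", "x", "y", "score"]],
        node_set=table.node_set,
    )
    surviving.records = surviving_df.reset_index(drop=True)

    counts = {flag: int(df[flag].sum()) for flag in RECORD_FLAGS}
    counts.update({flag: int(frame_keys[flag].sum()) for flag in FRAME_FLAGS})
    counts["n_input"] = len(df)
    counts["n_surviving"] = int(survive_mask.sum())
    if config.pca_enabled and pca_skipped:
        logger.warning("PCA stage requested but skipped (insufficient complete frames)")
    return QCReport(
        records=df,
        frame_flags=frame_keys,
        counts=counts,
        surviving=surviving,
        pca_k=pca_k,
        pca_skipped=pca_skipped or not config.pca_enabled,
    )


def _frame_alive_mask(df: pd.DataFrame, frame_keys: pd.DataFrame) -> pd.Series:
    bad = frame_keys[frame_keys[list(FRAME_FLAGS)].any(axis=1)][["camera", "frame"]]
    merged = df[["camera", "frame"]].merge(bad.assign(_bad=True), on=["camera", "frame"], how="left")
    return ~merged["_bad"].notna()
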