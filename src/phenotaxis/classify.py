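"""Run/tumble/intermediate classification from track kinematics.

Every frame of every track is described by three kinematic features —
speed, acceleration, and angular acceleration — computed from
frame-to-frame displacement at the acquisition frame rate.  The features
are standardized over the whole dataset (pooled across tracks, so clusters
are comparable between tracks) and clustered with a three-component
Gaussian mixture.  The cluster with low speed and high angular
acceleration is the tumble, the one with high speed and low angular
acceleration the run, and the remaining cluster the intermediate state
(entries/exits of tumbles and partial bundle disruptions).  Tumble bias is
the fraction of frames labeled tumble; intermediate frames count only in
the denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "RUN",
    "TUMBLE",
    "INTERMEDIATE",
    "kinematic_features",
    "classify_states",
    "classify_frames",
    "tumble_bias",
]

RUN, TUMBLE, INTERMEDIATE = 0, 1, 2

#: clusters whose mean speed exceeds this fraction of the run cluster's
#: mean speed are never labeled tumble (guards tumble-free data, where the
#: mixture would otherwise carve arbitrary clusters out of one blob)
_TUMBLE_SPEED_GUARD = 0.5


def kinematic_features(x: np.ndarray, y: np.ndarray, fps: float) -> np.ndarray:
    """Per-frame (speed, accel, ang_accel) for one track; shape (n, 3).

    Velocity is the forward difference of position times fps; acceleration
    the magnitude of the frame-to-frame velocity change times fps; angular
    acceleration the rate of change of the heading change.  Ends are
    handled by nearest-value extension.  Requires >= 3 frames.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"track too short for features: {n} < 3 frames")
    vx = np.diff(x) * fps  # n-1 values, frame i -> i+1
    vy = np.diff(y) * fps
    speed = np.hypot(vx, vy)
    accel = np.hypot(np.diff(vx), np.diff(vy)) * fps  # n-2 values
    heading = np.arctan2(vy, vx)
    dh = _wrap(np.diff(heading))  # n-2 per-frame heading changes
    # wrap the change-of-change too: a near-reversal is +/-pi ambiguously,
    # which must not leak a 2*pi jump into the feature
    ang_accel = np.abs(_wrap(np.diff(dh))) * fps * fps if n >= 4 else np.zeros(0)

    out = np.empty((n, 3))
    out[:, 0] = _extend(speed, n)
    out[:, 1] = _extend(accel, n)
    out[:, 2] = _extend(ang_accel, n) if ang_accel.size else 0.0
    return out


def _wrap(angle: np.ndarray) -> np.ndarray:
    return (angle + np.pi) % (2.0 * np.pi) - np.pi


def _extend(values: np.ndarray, n: int) -> np.ndarray:
    """Center ``values`` in a length-n vector, nearest-value extension."""
    pad_front = (n - len(values)) // 2
    pad_back = n - len(values) - pad_front
    return np.concatenate(
        [np.full(pad_front, values[0]), values, np.full(pad_back, values[-1])]
    )


def classify_states(
    features: np.ndarray,
    n_clusters: int = 3,
    seed: int = 0,
    max_fit_samples: int = 200_000,
) -> np.ndarray:
    """Cluster pooled standardized features into run/tumble/intermediate.

    features : (n_frames, 3) pooled over all tracks of a dataset.
    Returns integer labels (RUN/TUMBLE/INTERMEDIATE) per frame.  With
    degenerate features (no variance) every frame is labeled run.
    """
    features = np.asarray(features, dtype=float)
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    if np.all(sd < 1e-12):
        return np.full(len(features), RUN)
    sd = np.where(sd < 1e-12, 1.0, sd)
    z = (features - mu) / sd

    rng = np.random.default_rng(seed)
    fit_z = z
    if len(z) > max_fit_samples:
        fit_z = z[rng.choice(len(z), max_fit_samples, replace=False)]
    gmm = GaussianMixture(
        n_components=n_clusters,
        covariance_type="full",
        random_state=seed,
        reg_covar=1e-6,
        n_init=3,
    )
    gmm.fit(fit_z)
    comp = gmm.predict(z)

    # standardized space: columns (speed, accel, ang_accel).  Speed is the
    # primary discriminator: the stalled cluster is the tumble, the fast
    # cluster the run; the remaining cluster (tumble entries/exits: large
    # accelerations at intermediate speed) is the intermediate state.
    means = gmm.means_
    run_c = int(np.argmax(means[:, 0]))
    tumble_c = int(np.argmin(means[:, 0]))

    labels = np.full(len(z), INTERMEDIATE)
    labels[comp == run_c] = RUN
    labels[comp == tumble_c] = TUMBLE

    # guard: a "tumble" cluster moving at run-like speed is not a tumble
    run_speed = mu[0] + means[run_c, 0] * sd[0]
    tum_speed = mu[0] + means[tumble_c, 0] * sd[0]
    if run_speed > 0 and tum_speed > _TUMBLE_SPEED_GUARD * run_speed:
        labels[labels == TUMBLE] = INTERMEDIATE
    return labels


def classify_frames(
    frames: pd.DataFrame,
    fps: float = 8.78,
    seed: int = 0,
    min_frames: int = 3,
    stall_fraction: float = 0.5,
) -> np.ndarray:
    """Feature-extract every track in an observed frame table, pool,
    classify, and refine.  Returns per-frame labels aligned with
    ``frames`` rows; tracks shorter than ``min_frames`` are labeled
    intermediate.

    The mixture's tumble cluster captures fully stalled frames but leaves
    the first/last instants of each tumble — stalled frames carrying the
    large accelerations of the adjacent motion — in the intermediate
    cluster.  A second pass therefore promotes intermediate frames moving
    slower than ``stall_fraction`` of the track's own mean run speed to
    tumble, so the tumble count matches the instants the cell actually
    spent tumbling.  Set ``stall_fraction=0`` to disable.
    """
    labels = np.full(len(frames), INTERMEDIATE)
    feats = np.zeros((len(frames), 3))
    valid = np.zeros(len(frames), dtype=bool)
    groups = frames.groupby("track_id", sort=False).indices
    for _, idx in groups.items():
        if len(idx) < min_frames:
            continue
        g = frames.iloc[idx]
        feats[idx] = kinematic_features(g["x"].to_numpy(), g["y"].to_numpy(), fps)
        valid[idx] = True
    if valid.any():
        labels[valid] = classify_states(feats[valid], seed=seed)
    if stall_fraction > 0:
        for _, idx in groups.items():
            lab = labels[idx]
            run_speed = feats[idx][lab == RUN, 0]
            if run_speed.size == 0:
                continue
            stalled = (lab == INTERMEDIATE) & (
                feats[idx][:, 0] < stall_fraction * run_speed.mean()
            )
            labels[idx[stalled]] = TUMBLE
    return labels


def tumble_bias(states: np.ndarray) -> float:
    """Fraction of frames labeled tumble (granularity 1/n on an n-frame
    track; intermediate frames count in the denominator only)."""
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("empty state sequence")
    return float((states == TUMBLE).sum() / states.size)
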