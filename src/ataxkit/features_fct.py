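"""Finger-chase (FCT) features: DTW error, reaction time, kinematic delay,
acceleration alterations.

The trial shows a target that jumps to a random screen position 20 times
while the subject's finger marker chases it.  Per hand the test yields seven
features: DTW error and reaction time per axis (X, Y), acceleration
alterations per axis, and one Fitts'-law kinematic delay from the 2-D
geometry.
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit

from .core_io import AnalysisConfig, FctTrial

logger = logging.getLogger("ataxkit")


# --------------------------------------------------------------------------
# DTW error (accuracy / overshoot-undershoot surrogate)
# --------------------------------------------------------------------------

@njit(cache=True)
def _dtw_cost(a: np.ndarray, b: np.ndarray) -> float:
    n, m = a.shape[0], b.shape[0]
    big = 1e300
    prev = np.empty(m)
    cur = np.empty(m)
    for j in range(m):
        d = abs(a[0] - b[j])
        prev[j] = d if j == 0 else d + prev[j - 1]
    for i in range(1, n):
        for j in range(m):
            d = abs(a[i] - b[j])
            best = prev[j]
            if j > 0:
                if prev[j - 1] < best:
                    best = prev[j - 1]
                if cur[j - 1] < best:
                    best = cur[j - 1]
            cur[j] = d + best
        prev, cur = cur, prev
    return prev[m - 1]


def dtw_error(seq_a: np.ndarray, seq_b: np.ndarray) -> float:
    """Accumulated cost of the optimal warping path between two 1-D series.

    Dynamic-programming recursion
    ``DS(i,j) = |a_i - b_j| + min(DS(i-1,j), DS(i-1,j-1), DS(i,j-1))`` with
    ``DS(1,1) = |a_1 - b_1|``; the returned value is ``DS(n,m)``, the total
    misalignment between marker and target trajectories.
    """
    a = np.ascontiguousarray(seq_a, dtype=float)
    b = np.ascontiguousarray(seq_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw_error requires non-empty sequences")
    return float(_dtw_cost(a, b))


# --------------------------------------------------------------------------
# reaction time (cross-correlation lag)
# --------------------------------------------------------------------------

def reaction_time(marker: np.ndarray, target: np.ndarray,
                  sample_rate: float) -> float:
    """Reaction time in ms: the non-negative lag maximising the
    cross-correlation of the marker against the piecewise-constant target.
    """
    m = np.asarray(marker, dtype=float)
    t = np.asarray(target, dtype=float)
    if m.shape != t.shape:
        raise ValueError("marker and target must have equal length")
    m = m - m.mean()
    t = t - t.mean()
    if np.allclose(m, 0) or np.allclose(t, 0):
        raise ValueError("zero-variance input: correlation undefined")
    # full cross-correlation; keep lags 0 .. T-1 (marker trails target)
    xc = np.correlate(m, t, mode="full")[len(m) - 1:]
    lag = int(np.argmax(xc))
    return lag / sample_rate * 1000.0


# --------------------------------------------------------------------------
# kinematic delay (Fitts'-law index of performance)
# --------------------------------------------------------------------------

def kinematic_delay(trial: FctTrial) -> float:
    """Mean Fitts'-law throughput ID/MT over the trial's reaches, bits/s.

    Per reach, ID = log2(di/ra) with di the 2-D distance between consecutive
    target centres and ra the target radius; MT is the time from the target
    jump to the marker's first entry into the target disc.  The search for
    disc entry is capped by the next target jump; a reach whose marker never
    enters the disc inside that window is excluded (logged).
    """
    events = trial.target_events
    onsets = np.array([e[0] for e in events], dtype=int)
    centres = np.array([(e[1], e[2]) for e in events], dtype=float)
    bounds = np.append(onsets[1:], len(trial.marker_xy))
    rates = []
    excluded = 0
    for k in range(1, len(events)):
        di = float(np.linalg.norm(centres[k] - centres[k - 1]))
        if di <= trial.target_radius:
            rates.append(0.0)  # log2(di/ra) <= 0: no difficulty, no credit
            continue
        idx = np.log2(di / trial.target_radius)
        seg = trial.marker_xy[onsets[k]:bounds[k]]
        dist = np.linalg.norm(seg - centres[k], axis=1)
        hit = np.nonzero(dist <= trial.target_radius)[0]
        if hit.size == 0:
            excluded += 1
            continue
        mt = (hit[0] + 1) / trial.sample_rate
        rates.append(idx / mt)
    if excluded:
        logger.info("kinematic_delay: %d/%d reaches never entered the target "
                    "disc and were excluded", excluded, len(events) - 1)
    if not rates:
        raise ValueError("no reach entered the target disc")
    return float(np.mean(rates))


# --------------------------------------------------------------------------
# acceleration alterations (movement-efficiency surrogate)
# --------------------------------------------------------------------------

def accel_alterations(marker: np.ndarray, sample_rate: float,
                      onsets: np.ndarray | None = None,
                      smooth_window: int = 5) -> float:
    """Mean number of acceleration sign changes per reach along one axis.

    Position is smoothed with a short moving average before double
    differencing, because second differences of raw 30 Hz pixel data are
    noise-dominated.  Reaches are delimited by the target onsets; with no
    onsets the whole series counts as one reach.
    """
    x = np.asarray(marker, dtype=float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        xp = np.pad(x, pad, mode="edge")
        x = np.convolve(xp, kernel, mode="valid")[:len(marker)]
    if onsets is None:
        onsets = np.array([0])
    bounds = np.append(np.asarray(onsets, dtype=int), len(x))
    counts = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = x[a:b]
        if seg.size < 3:
            continue
        acc = np.diff(seg, n=2)
        # numerically-zero acceleration is not an alteration
        acc[np.abs(acc) < 1e-8 * max(1.0, np.max(np.abs(seg)))] = 0.0
        s = np.sign(acc)
        s = s[s != 0]
        counts.append(int(np.sum(s[1:] != s[:-1])))
    if not counts:
        raise ValueError("no reach segment with >= 3 samples")
    return float(np.mean(counts))


# --------------------------------------------------------------------------
# per-trial feature map
# --------------------------------------------------------------------------

def extract_fct_features(trial: FctTrial,
                         config: AnalysisConfig | None = None
                         ) -> dict[str, float]:
    """The seven FCT features for one hand, keyed by catalog name.

    DTW error and reaction time operate per axis on mean-subtracted position;
    AcAlt is reported as the per-trial total (per-reach mean times the number
    of reaches), the scaling on which group means are conventionally quoted.
    """
    cfg = config or AnalysisConfig()
    hand = trial.hand
    target = trial.target_xy
    onsets = np.array([e[0] for e in trial.target_events], dtype=int)
    n_reaches = len(trial.target_events)
    out: dict[str, float] = {}
    for ax, name in ((0, "X"), (1, "Y")):
        m = trial.marker_xy[:, ax] - trial.marker_xy[:, ax].mean()
        t = target[:, ax] - target[:, ax].mean()
        out[f"DTWEr_FCT_Pos{name}_{hand}"] = dtw_error(m, t)
        out[f"ReTi_FCT_Pos{name}_{hand}"] = reaction_time(
            m, t, trial.sample_rate)
        out[f"AcAlt_FCT_Pos{name}_{hand}"] = n_reaches * accel_alterations(
            trial.marker_xy[:, ax], trial.sample_rate, onsets=onsets,
            smooth_window=cfg.acalt_smooth_window)
    out[f"KiDe_FCT_Pos2D_{hand}"] = kinematic_delay(trial)
    return out
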