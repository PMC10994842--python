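"""Photobleaching/binding step detection in single-track intensity traces.

A labelled multimer shows its spot intensity drop to half when one of two
fluorophores bleaches, or jump to double when a second labelled subunit
binds.  Steps are found by recursive binary segmentation on the trace mean
(Welch-t criterion) and classified by the post/pre level ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: post/pre ratio windows counted as "half" and "twice" under shot noise
DROP_HALF_WINDOW = (0.35, 0.65)
JUMP_DOUBLE_WINDOW = (1.7, 2.3)


@dataclass
class StepEvent:
    frame: int
    kind: str          # drop_half | jump_double | other
    pre_level: float
    post_level: float

    @property
    def ratio(self) -> float:
        return self.post_level / self.pre_level


def _best_split(x: np.ndarray, min_len: int) -> tuple:
    """Most significant mean changepoint by Welch's t.

    Returns (index, p-value) with the p-value Bonferroni-corrected for the
    number of candidate split points tested.
    """
    n = len(x)
    ks = np.arange(min_len, n - min_len + 1)
    if len(ks) == 0:
        return None, 1.0
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    n1 = ks.astype(float)
    n2 = n - n1
    m1 = c1[ks] / n1
    m2 = (c1[n] - c1[ks]) / n2
    v1 = np.maximum((c2[ks] - n1 * m1 ** 2) / np.maximum(n1 - 1, 1), 1e-30)
    v2 = np.maximum((c2[n] - c2[ks] - n2 * m2 ** 2)
                    / np.maximum(n2 - 1, 1), 1e-30)
    se2 = v1 / n1 + v2 / n2
    t = np.abs(m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * np.maximum(n1 - 1, 1))
                     + v2 ** 2 / (n2 ** 2 * np.maximum(n2 - 1, 1)))
    p = 2 * stats.t.sf(t, df)
    i = int(np.argmin(p))
    return int(ks[i]), float(min(1.0, p[i] * len(ks)))


def _segment(x: np.ndarray, offset: int, min_len: int, alpha: float,
             breaks: list) -> None:
    if len(x) < 2 * min_len:
        return
    k, p = _best_split(x, min_len)
    if k is None or p >= alpha:
        return
    breaks.append(offset + k)
    _segment(x[:k], offset, min_len, alpha, breaks)
    _segment(x[k:], offset + k, min_len, alpha, breaks)


def detect_intensity_steps(trace: Sequence[float], min_level_frames: int = 5,
                           alpha: float = 0.001) -> list:
    """Detect discrete intensity steps in one background-corrected trace.

    Recursive binary segmentation keeps splitting while a Welch-t test on the
    candidate split is significant at ``alpha``; consecutive level means are
    then classified by their ratio: drop to ~half, jump to ~double, or other.
    """
    x = np.asarray(trace, dtype=float)
    if len(x) < 2 * min_level_frames:
        raise ValueError("trace too short for the requested level length")
    breaks: list[int] = []
    _segment(x, 0, min_level_frames, alpha, breaks)
    breaks = sorted(breaks)
    bounds = [0] + breaks + [len(x)]
    levels = [float(x[i:j].mean()) for i, j in zip(bounds[:-1], bounds[1:])]
    events = []
    for b, pre, post in zip(breaks, levels[:-1], levels[1:]):
        if pre <= 0:
            kind = "other"
        else:
            r = post / pre
            if DROP_HALF_WINDOW[0] <= r <= DROP_HALF_WINDOW[1]:
                kind = "drop_half"
            elif JUMP_DOUBLE_WINDOW[0] <= r <= JUMP_DOUBLE_WINDOW[1]:
                kind = "jump_double"
            else:
                kind = "other"
        events.append(StepEvent(frame=b, kind=kind, pre_level=pre,
                                post_level=post))
    return events


def step_fractions(traces: Sequence[Sequence[float]],
                   min_level_frames: int = 5,
                   alpha: float = 0.001) -> dict:
    """Per-track prevalence of halving drops and doubling jumps.

    Traces should come from full tracks (appearance and disappearance both
    inside the acquisition).  Returns fractions of tracks with at least one
    drop_half / jump_double event, their 95% Wilson CIs, and n.
    """
    n = len(traces)
    if n == 0:
        raise ValueError("no traces")
    with_drop = with_jump = 0
    for tr in traces:
        kinds = {e.kind for e in detect_intensity_steps(
            tr, min_level_frames, alpha)}
        with_drop += "drop_half" in kinds
        with_jump += "jump_double" in kinds
    out = {"n": n,
           "fraction_with_drop": with_drop / n,
           "fraction_with_jump": with_jump / n}
    for key, k in (("drop", with_drop), ("jump", with_jump)):
        lo, hi = _wilson_ci(k, n)
        out[f"ci_{key}"] = (lo, hi)
    return out


def _wilson_ci(k: int, n: int, z: float = 1.96) -> tuple:
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)
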