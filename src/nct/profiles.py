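"""Rank-index profiles of coverage tracks with run-window smoothing.

Features (typically genes or exons) are ranked ascending by an index track
(e.g. RNAPII ChIP-seq reads); companion tracks are reordered by the same
permutation and smoothed with a centered moving average.  The smoothing
width is chosen from the curve of the sum of absolute successive
differences (SAD) as a function of candidate window sizes: the smallest
window at which widening the window stops paying (relative SAD decrease
below a tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["IndexProfile", "rank_index", "run_window_average", "select_window", "sad"]


@dataclass
class IndexProfile:
    order: np.ndarray  # permutation sorting features by the index track
    index_values: np.ndarray  # sorted ascending
    tracks: dict[str, np.ndarray]  # reordered companion tracks
    window: int | None = None
    sad_curve: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"index": self.index_values, **self.tracks})
        df.insert(0, "original_position", self.order)
        return df


def rank_index(
    index_values: Sequence[float], other_tracks: dict[str, Sequence[float]]
) -> IndexProfile:
    """Sort features ascending by index value (stable; ties keep original
    order) and reorder every companion track by the same permutation."""
    idx = np.asarray(index_values, dtype=float)
    order = np.argsort(idx, kind="stable")
    tracks = {}
    for name, vals in other_tracks.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size != idx.size:
            raise ValueError(f"track {name!r} has {arr.size} values, index has {idx.size}")
        tracks[name] = arr[order]
    return IndexProfile(order=order, index_values=idx[order], tracks=tracks)


def run_window_average(values: Sequence[float], window: int) -> np.ndarray:
    """Centered moving mean with edge windows truncated to available
    neighbors; window must be odd (window 1 is the identity)."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(values, dtype=float)
    if window == 1 or x.size == 0:
        return x.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def sad(values: np.ndarray) -> float:
    """Sum of absolute successive differences (total variation)."""
    return float(np.abs(np.diff(np.asarray(values, dtype=float))).sum())


def select_window(
    values: Sequence[float],
    candidates: Sequence[int],
    rel_tolerance: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """Choose the smoothing window from the SAD-vs-window curve.

    The chosen window is the smallest candidate w where the relative SAD
    decrease to the next candidate, (SAD(w) - SAD(next)) / SAD(w), falls
    below ``rel_tolerance`` (an elbow rule); when the curve never flattens
    the largest candidate wins.  Returns (window, full curve).
    """
    cands = sorted(set(int(c) for c in candidates))
    if len(cands) < 2:
        raise ValueError("need at least 2 candidate windows")
    curve = [(w, sad(run_window_average(values, w))) for w in cands]
    chosen = cands[-1]
    for (w, s), (_, s_next) in zip(curve, curve[1:]):
        if s == 0 or (s - s_next) / s < rel_tolerance:
            chosen = w
            break
    df = pd.DataFrame(curve, columns=["window", "sad"])
    return chosen, df
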