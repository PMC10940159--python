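"""Whole-cell calcium trace processing and responder classification.

Traces from a genetically encoded calcium indicator are background-
subtracted and expressed relative to the first frame:
F(t) = (raw(t) - bg) / (raw(0) - bg). A cell is a positive responder to
the osmotic challenge when its peak ratio rises by strictly more than 70%
over baseline (max F - 1 > 0.70).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ResponderResult:
    is_responder: bool
    max_signal: float


def ratio_trace(
    raw: np.ndarray, background: "float | np.ndarray" = 0.0
) -> np.ndarray:
    """Background-subtracted trace normalized to the first frame.

    ``background`` may be a scalar (e.g. the mean of a background region
    of interest) or a per-frame series. The first element of the result is
    exactly 1. Raises when the background-subtracted baseline is not
    positive.
    """
    raw = np.asarray(raw, dtype=float)
    bg = np.asarray(background, dtype=float)
    if bg.ndim > 0 and bg.shape != raw.shape:
        raise ValueError("background series must match trace length")
    sub = raw - bg
    f0 = sub.flat[0]
    if f0 <= 0:
        raise ValueError(
            f"baseline after background subtraction must be positive, got {f0}"
        )
    out = sub / f0
    out.flat[0] = 1.0
    return out


def classify_responder(
    ratio: np.ndarray, threshold_increase: float = 0.70
) -> ResponderResult:
    """Classify a normalized trace as a positive responder.

    Positive iff the maximal ratio exceeds baseline by strictly more than
    ``threshold_increase`` (default: the over-70% rule). The maximal
    signal is returned for the responder-amplitude summary.
    """
    ratio = np.asarray(ratio, dtype=float)
    if len(ratio) < 2:
        raise ValueError("need at least 2 frames to classify")
    max_signal = float(np.max(ratio))
    return ResponderResult(
        is_responder=bool(max_signal - 1.0 > threshold_increase),
        max_signal=max_signal,
    )


def classify_traces(
    traces: pd.DataFrame,
    threshold_increase: float = 0.70,
    background_col: str | None = "background",
) -> pd.DataFrame:
    """Batch classification of a long-format trace table.

    ``traces`` columns: cell_id, frame, raw, and optionally a background
    column. Returns one row per cell: cell_id, max_signal, is_responder.
    """
    rows = []
    for cid, grp in traces.sort_values("frame").groupby("cell_id"):
        bg = (
            grp[background_col].to_numpy()
            if background_col and background_col in grp
            else 0.0
        )
        f = ratio_trace(grp["raw"].to_numpy(), bg)
        res = classify_responder(f, threshold_increase)
        rows.append(
            {
                "cell_id": cid,
                "max_signal": res.max_signal,
                "is_responder": res.is_responder,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "max_signal", "is_responder"])
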