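"""File I/O: multi-page TIFF stacks, label masks, sweep CSVs, protocol YAML."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from lysomech.ephys import PressureProtocol, SweepEnsemble


def write_movie(path: "str | Path", movie: np.ndarray) -> None:
    """Write a (T, 2, H, W) two-channel stack as multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32), photometric="minisblack")


def read_movie(path: "str | Path") -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 3:  # single frame (2, H, W)
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[1] != 2:
        raise ValueError(f"expected a (T, 2, H, W) stack, got shape {arr.shape}")
    return arr


def write_labels(path: "str | Path", labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint16), photometric="minisblack")


def read_labels(path: "str | Path") -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.int64)


def write_sweeps(path: "str | Path", ensemble: SweepEnsemble) -> None:
    """Long-format sweep CSV: sweep_id, time_s, current_pA."""
    t = ensemble.time_s
    frames = []
    for s in range(ensemble.n_sweeps):
        frames.append(
            pd.DataFrame(
                {"sweep_id": s, "time_s": t, "current_pA": ensemble.sweeps[s]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sweeps(
    path: "str | Path", protocol: PressureProtocol, sample_rate_hz: float
) -> SweepEnsemble:
    df = pd.read_csv(path)
    sweeps = [
        grp.sort_values("time_s")["current_pA"].to_numpy()
        for _, grp in df.groupby("sweep_id")
    ]
    return SweepEnsemble(
        sweeps=np.vstack(sweeps), sample_rate_hz=sample_rate_hz, protocol=protocol
    )


def write_protocol(path: "str | Path", protocol: PressureProtocol, sample_rate_hz: float | None = None) -> None:
    doc = {
        "steps_mmHg": [float(p) for p in protocol.steps_mmhg],
        "step_duration_s": protocol.step_duration_s,
        "baseline_s": protocol.baseline_duration_s,
    }
    if sample_rate_hz is not None:
        doc["sample_rate_Hz"] = float(sample_rate_hz)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_protocol(path: "str | Path") -> tuple[PressureProtocol, float | None]:
    doc = yaml.safe_load(Path(path).read_text())
    proto = PressureProtocol(
        steps_mmhg=list(doc["steps_mmHg"]),
        step_duration_s=float(doc.get("step_duration_s", 0.5)),
        baseline_duration_s=float(doc.get("baseline_s", 0.2)),
    )
    rate = doc.get("sample_rate_Hz")
    return proto, (float(rate) if rate is not None else None)
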