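"""Recording and report file plumbing (EDF / CSV in, JSON out)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .edfio import read_edf, write_edf
from .types import Recording


def read_recording(path: str | Path, fs: float | None = None) -> Recording:
    """Read an EDF or delimited-text recording.

    CSV layout: optional ``# fs=<Hz>`` comment line, a header row of channel
    labels, then one row per time sample.  ``fs`` overrides the comment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording: {path}")
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    header_fs = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "fs=" in first:
        header_fs = float(first.split("fs=")[1].split()[0])
    frame = pd.read_csv(path, comment="#")
    rate = fs or header_fs
    if rate is None:
        raise ValueError(f"{path}: sampling rate missing "
                         "(no '# fs=' line and no fs argument)")
    return Recording(samples=frame.to_numpy(dtype=np.float64).T, fs=rate,
                     channel_labels=[str(c) for c in frame.columns])


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        pd.DataFrame(rec.samples.T, columns=rec.channel_labels).to_csv(
            fh, index=False)
    return path


def write_recording(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return write_edf(path, rec)
    return write_recording_csv(rec, path)


def write_report(report, path: str | Path) -> Path:
    """Serialize a metrics report (dataclass or dict) as JSON."""
    path = Path(path)
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))
    return path
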