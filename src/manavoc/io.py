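"""WAV and metadata I/O.

Datasets are exchanged as one WAV file per call (float32 PCM) plus a
metadata CSV with header ``call_id,subject_id,sex,age_class,size_m,
call_type,path``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synth import Vocalization

__all__ = ["write_wav", "read_wav", "write_dataset", "read_dataset"]

META_COLUMNS = ["call_id", "subject_id", "sex", "age_class", "size_m", "call_type", "path"]


def write_wav(path, v: Vocalization) -> None:
    wavfile.write(path, v.sample_rate_hz, v.samples.astype(np.float32))


def read_wav(path, *, subject_id: str = "", call_id: str = "", call_type: str = "squeak") -> Vocalization:
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = data.astype(np.float64)
    if data.ndim > 1:
        data = data.mean(axis=1)
    return Vocalization(
        subject_id=subject_id,
        samples=data,
        sample_rate_hz=int(sr),
        call_type=call_type,
        call_id=call_id or Path(path).stem,
    )


def write_dataset(out_dir, vocs, metadata: pd.DataFrame) -> Path:
    """Write one WAV per call plus metadata.csv; returns the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for v in vocs:
        p = out / f"{v.call_id}.wav"
        write_wav(p, v)
        paths.append(str(p))
    meta = metadata.copy()
    meta["path"] = paths
    csv_path = out / "metadata.csv"
    meta[META_COLUMNS].to_csv(csv_path, index=False)
    return csv_path


def read_dataset(csv_path) -> tuple[list[Vocalization], pd.DataFrame]:
    meta = pd.read_csv(csv_path)
    vocs = [
        read_wav(
            row["path"],
            subject_id=row["subject_id"],
            call_id=row["call_id"],
            call_type=row.get("call_type", "squeak"),
        )
        for _, row in meta.iterrows()
    ]
    return vocs, meta.drop(columns=["path"])
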