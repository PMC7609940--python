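"""File I/O for recordings, TFR maps and cluster results.

Event tables and behavioral sessions serialize to TSV (see their
classes); recordings use a flat float32 binary with a JSON sidecar
header carrying rate, labels and electrode positions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clusterperm import ClusterResult
from .events import EventTable
from .montage import Montage
from .recording import Recording
from .tfr import TFRMap


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``<path>.dat`` (float32 channels x samples) + ``<path>.json``."""
    path = Path(path)
    rec.data.astype("<f4").tofile(path.with_suffix(".dat"))
    header = {
        "rate": rec.rate,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "labels": list(rec.montage.labels),
        "positions": rec.montage.positions.tolist(),
        "dtype": "<f4",
        "unit": "uV",
        "provenance": rec.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    rec.events.to_tsv(path.with_suffix(".events.tsv"))


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".dat"), dtype=header["dtype"])
    data = data.reshape(header["n_channels"], header["n_samples"])
    montage = Montage(labels=tuple(header["labels"]),
                      positions=np.asarray(header["positions"], float))
    events = EventTable.from_tsv(path.with_suffix(".events.tsv"))
    return Recording(data=data.astype(float), rate=header["rate"],
                     montage=montage, events=events,
                     provenance=header.get("provenance", []))


def tfr_to_long_tsv(tfr: TFRMap, path: str | Path) -> None:
    """Long-format export (freq_hz, time_s, value); per-trial maps averaged."""
    power = tfr.power.mean(axis=0) if tfr.per_trial else tfr.power
    f_idx, t_idx = np.meshgrid(np.arange(len(tfr.freqs)),
                               np.arange(len(tfr.times)), indexing="ij")
    df = pd.DataFrame({
        "freq_hz": tfr.freqs[f_idx.ravel()],
        "time_s": tfr.times[t_idx.ravel()],
        "value": power.ravel(),
        "valid": tfr.mask.ravel().astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def cluster_result_to_json(res: ClusterResult, path: str | Path,
                           save_null: bool = False) -> None:
    payload = {
        "df": res.df,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in res.params.items()},
        "clusters": [
            {"t_sum": c.t_sum, "size": c.size, "sign": c.sign,
             "p_fwe": c.p, "significant": c.significant,
             "coords": c.coords.tolist()}
            for c in res.clusters
        ],
    }
    if save_null:
        payload["null_max"] = res.null_max.tolist()
    Path(path).write_text(json.dumps(payload, indent=1))


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
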