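"""CSV/JSON persistence for series and run manifests.

Series CSVs round-trip exactly: floats are written with 17 significant
digits (lossless for float64) and integer columns are restored with
explicit dtypes on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .engine import SERIES_COLUMNS, ReplicateSeries

_INT_COLS = ["t", "N", "n_cooperators", "births", "deaths"]
_FLOAT_COLS = ["R0_t", "prop_coop", "mean_degree"]


def write_series(series, path) -> Path:
    """Write a per-step series (ReplicateSeries or DataFrame) as CSV."""
    frame = series.frame if isinstance(series, ReplicateSeries) else series
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")
    return path


def read_series(path) -> pd.DataFrame:
    """Read a series CSV back into the in-memory frame, dtypes restored."""
    dtype = {c: "int64" for c in _INT_COLS}
    dtype.update({c: "float64" for c in _FLOAT_COLS})
    frame = pd.read_csv(path, dtype=dtype, float_precision="round_trip")
    return frame[SERIES_COLUMNS]


def write_manifest(path, *, params, schedule, seeds, extra=None) -> Path:
    """Write a JSON run manifest: full parameter echo, seeds, version."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "coopdyn",
        "version": __version__,
        "params": dataclasses.asdict(params),
        "schedule": dataclasses.asdict(schedule) if schedule is not None else None,
        "seeds": list(int(s) for s in seeds),
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
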