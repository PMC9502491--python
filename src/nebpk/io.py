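"""Dataset and result I/O.

Two on-disk dialects are supported:

* ``nonmem`` — one CSV row per event with columns ID, TIME, AMT, DV, EVID,
  AGE, BMI, GENO (EVID 1 = dose, 0 = observation).  Lossless round trip.
* ``digitized`` — the two-column ``time,concentration`` CSV produced by
  plot digitisation, accompanied by a small YAML sidecar carrying what the
  plot cannot (subject id, dose schedule, covariates).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import COLUMNS, Dataset

__all__ = ["read_dataset", "write_dataset", "read_digitized", "write_results_json"]


def read_dataset(path, dialect: str = "nonmem", sidecar=None) -> Dataset:
    """Read a concentration-time dataset.

    For the ``digitized`` dialect, ``sidecar`` names the YAML metadata file
    (defaults to the CSV path with a ``.yaml`` suffix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "nonmem":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            warnings.warn(f"{path} is empty; returning an empty Dataset")
            return Dataset.empty()
        if df.empty and len(df.columns) <= 1:
            warnings.warn(f"{path} is empty; returning an empty Dataset")
            return Dataset.empty()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing mandatory column(s): {', '.join(missing)}"
            )
        return Dataset(df)
    if dialect == "digitized":
        return read_digitized(path, sidecar)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_digitized(path, sidecar=None) -> Dataset:
    """Read a digitized two-column profile plus its YAML sidecar.

    The sidecar must provide ``subject``, ``dose_mg`` and may provide
    ``dose_times_h`` (default single dose at 0), ``age``, ``bmi``, ``geno``.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"digitized dialect needs sidecar metadata: {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    prof = pd.read_csv(path)
    if prof.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns time,concentration")
    tcol, ccol = prof.columns[:2]
    dose_times = meta.get("dose_times_h", [0.0])
    rows = []
    base = {
        "ID": meta["subject"],
        "AGE": float(meta.get("age", np.nan)),
        "BMI": float(meta.get("bmi", np.nan)),
        "GENO": meta.get("geno", "EM"),
    }
    for td in dose_times:
        rows.append({**base, "TIME": float(td), "AMT": float(meta["dose_mg"]),
                     "DV": np.nan, "EVID": 1})
    for _, r in prof.iterrows():
        rows.append({**base, "TIME": float(r[tcol]), "AMT": 0.0,
                     "DV": float(r[ccol]), "EVID": 0})
    df = pd.DataFrame(rows).sort_values("TIME", kind="stable").reset_index(drop=True)
    return Dataset(df)


def write_dataset(dataset: Dataset, path) -> None:
    """Write the canonical CSV; ``read_dataset`` round-trips it losslessly."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.df.to_csv(path, index=False)


def write_results_json(obj: dict, path, seed=None) -> None:
    """Dump a result dict as JSON, stamping the seed used to produce it."""
    payload = dict(obj)
    if seed is not None:
        payload["seed"] = seed
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, default=_default) + "\n")
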