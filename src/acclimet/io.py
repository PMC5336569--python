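"""Plain-text serialization of spectra, metadata and run parameters.

Spectra travel as TSV (first column ``ppm``, descending; one column per
sample), metadata as CSV, and the processing log / generator parameters as
a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import META_COLUMNS, SpectrumSet
from .errors import ValidationError


def write_spectra(sset: SpectrumSet, directory, stem: str = "spectra") -> dict[str, Path]:
    """Write a spectrum set as ``<stem>.tsv`` + ``<stem>_meta.csv`` +
    ``<stem>_log.json``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tsv = directory / f"{stem}.tsv"
    meta_csv = directory / f"{stem}_meta.csv"
    log_json = directory / f"{stem}_log.json"
    df = pd.DataFrame(sset.intensities.T, columns=sset.meta["sample_id"])
    df.insert(0, "ppm", sset.ppm)
    df.to_csv(tsv, sep="\t", index=False)
    sset.meta[list(META_COLUMNS)].to_csv(meta_csv, index=False)
    log_json.write_text(json.dumps(sset.processing_log, indent=1) + "\n")
    return {"spectra": tsv, "meta": meta_csv, "log": log_json}


def read_spectra(tsv, meta_csv, log_json=None) -> SpectrumSet:
    """Read back a spectrum set written by :func:`write_spectra`."""
    df = pd.read_csv(tsv, sep="\t")
    if df.columns[0] != "ppm":
        raise ValidationError("first TSV column must be 'ppm'")
    meta = pd.read_csv(meta_csv)
    sample_ids = [str(c) for c in df.columns[1:]]
    meta = meta.set_index("sample_id").loc[sample_ids].reset_index()
    log = json.loads(Path(log_json).read_text()) if log_json else []
    return SpectrumSet(df["ppm"].to_numpy(), df.iloc[:, 1:].to_numpy().T,
                       meta, processing_log=log)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=default)
                    + "\n")
    return path
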