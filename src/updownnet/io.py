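"""On-disk formats: raster TSV, trace HDF5, YAML run configs.

Rasters are plain TSV (``time_ms  neuron_id  class_label``, sorted by time)
with a bit-exact float round trip (times printed with 17 significant
digits).  Traces go to HDF5 with datasets ``/v``, ``/u``, ``/Gex``,
``/Gin``, ``/t`` and the run config stored as a JSON attribute.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import yaml

from .raster import Raster

RASTER_COLUMNS = ("time_ms", "neuron_id", "class_label")


def write_raster_tsv(raster: Raster, path) -> None:
    path = Path(path)
    labels = raster.labels
    with path.open("w") as fh:
        fh.write("\t".join(RASTER_COLUMNS) + "\n")
        fh.write(
            f"# N={raster.N}\tt_start={float(raster.t_start)!r}"
            f"\tt_end={float(raster.t_end)!r}\n"
        )
        for t, j in zip(raster.times, raster.ids):
            lab = labels[j] if labels is not None else "NA"
            fh.write(f"{float(t)!r}\t{j}\t{lab}\n")


def read_raster_tsv(path) -> Raster:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if header.strip().split("\t") != list(RASTER_COLUMNS):
            raise ValueError(f"{path} is not a raster TSV (bad header)")
        meta = fh.readline().lstrip("# ").strip().split("\t")
        kv = dict(item.split("=", 1) for item in meta)
        times, ids, labs = [], [], []
        for line in fh:
            t, j, lab = line.rstrip("\n").split("\t")
            times.append(float(t))
            ids.append(int(j))
            labs.append(lab)
    N = int(kv["N"])
    labels = None
    if labs and labs[0] != "NA":
        labels = np.empty(N, dtype=object)
        labels[:] = ""
        for j, lab in zip(ids, labs):
            labels[j] = lab
    return Raster(
        times=np.array(times, dtype=np.float64),
        ids=np.array(ids, dtype=np.int64),
        N=N,
        t_start=float(kv["t_start"]),
        t_end=float(kv["t_end"]),
        labels=labels,
    )


def write_traces_h5(
    path,
    t: np.ndarray,
    v: np.ndarray,
    u: np.ndarray,
    Gex: np.ndarray,
    Gin: np.ndarray,
    config: Optional[dict] = None,
) -> None:
    """Write sampled traces; arrays are (n_samples,) or (n_samples, n_neurons)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=np.asarray(t))
        f.create_dataset("v", data=np.asarray(v))
        f.create_dataset("u", data=np.asarray(u))
        f.create_dataset("Gex", data=np.asarray(Gex))
        f.create_dataset("Gin", data=np.asarray(Gin))
        if config is not None:
            f.attrs["config"] = json.dumps(config, default=str)


def read_traces_h5(path) -> dict:
    with h5py.File(path, "r") as f:
        out = {k: f[k][...] for k in ("t", "v", "u", "Gex", "Gin")}
        if "config" in f.attrs:
            out["config"] = json.loads(f.attrs["config"])
    return out


def write_spectrum_csv(spectrum, path) -> None:
    """``f_hz,power`` CSV (units and record length in a comment header)."""
    with Path(path).open("w") as fh:
        fh.write(f"# units={spectrum.units_tag} T_s={spectrum.T!r}\n")
        fh.write("f_hz,power\n")
        for f, s in zip(spectrum.f, spectrum.S):
            fh.write(f"{float(f)!r},{float(s)!r}\n")


def read_spectrum_csv(path):
    from .measures import Spectrum

    with Path(path).open() as fh:
        meta = dict(kv.split("=", 1) for kv in fh.readline().lstrip("# ").split())
        header = fh.readline().strip()
        if header != "f_hz,power":
            raise ValueError(f"{path} is not a spectrum CSV")
        rows = [line.strip().split(",") for line in fh if line.strip()]
    return Spectrum(
        f=np.array([float(r[0]) for r in rows]),
        S=np.array([float(r[1]) for r in rows]),
        units_tag=meta["units"],
        T=float(meta["T_s"]),
    )


def write_rate_csv(rate, path) -> None:
    """``t_ms,rate_hz`` CSV for a population rate series."""
    with Path(path).open("w") as fh:
        fh.write(f"# delta_t_ms={float(rate.delta_t)!r}\n")
        fh.write("t_ms,rate_hz\n")
        for t, r in zip(rate.t, rate.r):
            fh.write(f"{float(t)!r},{float(r)!r}\n")


def read_rate_csv(path):
    from .measures import RateSeries

    with Path(path).open() as fh:
        meta = dict(kv.split("=", 1) for kv in fh.readline().lstrip("# ").split())
        if fh.readline().strip() != "t_ms,rate_hz":
            raise ValueError(f"{path} is not a rate-series CSV")
        rows = [line.strip().split(",") for line in fh if line.strip()]
    return RateSeries(
        t=np.array([float(r[0]) for r in rows]),
        r=np.array([float(r[1]) for r in rows]),
        delta_t=float(meta["delta_t_ms"]),
    )


def load_config(path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
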