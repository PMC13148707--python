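"""Signal input and result output.

Readers cover single-column delimited text (sample rate supplied by the
caller), two-column time/value text (rate inferred from the median time step)
and PCM/float WAV.  Results are written as one CSV of IMF columns, a JSON
diagnostics file and, optionally, PNG plots.
"""

from __future__ import annotations

import json
import os
import re

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = ["read_signal", "write_result"]

_WAV_SCALE = {np.dtype("int16"): 2.0**15, np.dtype("int32"): 2.0**31,
              np.dtype("uint8"): 2.0**7}


def _read_delimited(path: str, sample_rate: float | None):
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = re.split(r"[,\s;]+", line)
            if width is None:
                # tolerate a single header line of non-numeric labels
                try:
                    [float(f) for f in fields]
                except ValueError:
                    if lineno == 1:
                        continue
                    raise ValueError(f"non-numeric row at line {lineno} of {path}")
                width = len(fields)
            if len(fields) != width:
                raise ValueError(
                    f"ragged row at line {lineno} of {path}: expected {width} "
                    f"fields, found {len(fields)}")
            try:
                rows.append([float(f) for f in fields])
            except ValueError:
                raise ValueError(f"non-numeric row at line {lineno} of {path}")
    if not rows:
        raise ValueError(f"no numeric data found in {path}")
    data = np.asarray(rows)
    if data.shape[1] == 1:
        if sample_rate is None:
            raise ValueError("single-column input requires an explicit sample rate")
        return data[:, 0], float(sample_rate)
    if data.shape[1] == 2:
        t, v = data[:, 0], data[:, 1]
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise ValueError("time column must be strictly increasing")
        return v, float(1.0 / dt)
    raise ValueError(f"expected 1 or 2 columns, found {data.shape[1]} in {path}")


def _read_wav(path: str, channel: int):
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        if not (0 <= channel < data.shape[1]):
            raise ValueError(
                f"channel {channel} out of range for {data.shape[1]}-channel WAV")
        data = data[:, channel]
    scale = _WAV_SCALE.get(data.dtype)
    if scale is not None:
        offset = scale if data.dtype == np.dtype("uint8") else 0.0
        data = (data.astype(float) - offset) / scale
    else:
        data = data.astype(float)
    return data, float(rate)


def read_signal(path: str, fmt: str | None = None,
                sample_rate: float | None = None, channel: int = 0):
    """Read a 1-D signal; returns ``(samples, sample_rate)``."""
    if fmt is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        fmt = {"wav": "wav", "csv": "csv", "txt": "csv", "tsv": "csv"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer format from extension {ext!r}; pass fmt=")
    if fmt == "wav":
        x, rate = _read_wav(path, channel)
    elif fmt == "csv":
        x, rate = _read_delimited(path, sample_rate)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'csv' or 'wav')")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite samples in {path}")
    return x, rate


def write_result(result, out_dir: str, plots: bool = False) -> dict:
    """Write IMFs (CSV), diagnostics (JSON) and optional PNG plots.

    Returns a dict of written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    imf_path = os.path.join(out_dir, "imfs.csv")
    if result.imfs:
        frame = pd.DataFrame(
            {f"imf{i + 1}": imf.samples for i, imf in enumerate(result.imfs)})
    else:
        frame = pd.DataFrame()
    frame.to_csv(imf_path, index=False, float_format="%.12g")
    paths["imfs"] = imf_path

    diag_path = os.path.join(out_dir, "diagnostics.json")
    with open(diag_path, "w") as fh:
        json.dump(result.diagnostics, fh, indent=2, sort_keys=True)
    paths["diagnostics"] = diag_path

    if plots:
        paths.update(_write_plots(result, out_dir))
    return paths


def _write_plots(result, out_dir: str) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    n_imfs = len(result.imfs)
    if n_imfs:
        fig, axes = plt.subplots(n_imfs, 1, figsize=(9, 1.8 * n_imfs),
                                 sharex=True, squeeze=False)
        for i, imf in enumerate(result.imfs):
            axes[i, 0].plot(imf.samples, lw=0.7)
            axes[i, 0].set_ylabel(f"IMF {i + 1}")
        fig.tight_layout()
        p = os.path.join(out_dir, "imfs.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["imfs_plot"] = p

    bs = result.diagnostics.get("blaschke_spectrum")
    if bs:
        fig, ax = plt.subplots(figsize=(9, 3))
        ax.stem(np.arange(1, len(bs) + 1), bs, basefmt=" ")
        for seg in result.diagnostics.get("segments", []):
            a, b = seg["segment"]
            ax.axvspan(a - 0.5, b + 0.5, alpha=0.15)
        ax.set_xlabel("Blaschke order k")
        ax.set_ylabel("BS(k)")
        fig.tight_layout()
        p = os.path.join(out_dir, "blaschke_spectrum.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["spectrum_plot"] = p

    if n_imfs:
        fig, ax = plt.subplots(figsize=(9, 3))
        for i, imf in enumerate(result.imfs):
            sig = imf.signature
            if sig is not None and sig.valid:
                freqs = np.arange(sig.env_spectrum.size) * sig.bin_hz
                ax.plot(freqs, sig.env_spectrum, lw=0.8, label=f"IMF {i + 1}")
        ax.set_xlabel("envelope frequency [Hz]")
        ax.set_ylabel("|envelope spectrum|")
        ax.legend(loc="best", fontsize=7)
        fig.tight_layout()
        p = os.path.join(out_dir, "envelope_spectra.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["envelope_plot"] = p
    return paths
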