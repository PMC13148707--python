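"""Fusion of fundamental modes by periodic-pulse signature similarity.

Splitting a signal's spectrum into separated group-sparse bands routinely
over-decomposes a single pulse train: its carrier band and each sideband
cluster land in different fundamental modes.  All of those share the same
*envelope signature* -- the magnitude spectrum of the Hilbert envelope peaks
at the repetition rate and occupies the same low-frequency band -- so modes
whose envelope bands overlap strongly (Jaccard ratio above ``thr``) and whose
dominant envelope frequencies agree to within a spectral bin are summed into
one intrinsic mode function (IMF).  Fusion is conservative: the IMFs are an
exact partition of the input modes and their samples sum to the same total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "EnvelopeSignature",
    "IntrinsicModeFunction",
    "envelope_signature",
    "overlap_ratio",
    "fuse",
]


@dataclass(frozen=True)
class EnvelopeSignature:
    """Envelope-spectrum signature of one mode."""

    env_spectrum: np.ndarray  # magnitude spectrum of the mean-removed envelope
    bin_hz: float
    active_band: tuple  # inclusive (lo, hi) bin intervals where spectrum > mean
    dominant_bin: int | None  # None for a flat (constant-envelope) mode
    valid: bool

    @property
    def dominant_freq(self) -> float | None:
        if self.dominant_bin is None:
            return None
        return self.dominant_bin * self.bin_hz


@dataclass
class IntrinsicModeFunction:
    """A fused mode: exact sum of its member fundamental modes."""

    samples: np.ndarray
    members: list
    signature: EnvelopeSignature = field(repr=False, default=None)


def envelope_signature(mode, sample_rate: float,
                       flat_tol: float = 1e-10) -> EnvelopeSignature:
    """Envelope signature: Hilbert envelope -> mean-removed magnitude spectrum.

    The active band is the set of bins whose envelope-spectrum magnitude
    exceeds the spectrum mean; the dominant frequency is the argmax bin.  A
    mode whose envelope is (numerically) constant -- e.g. a pure tone -- has
    an empty active band and a flagged, undefined dominant frequency.
    """
    x = np.asarray(mode, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("mode must be a 1-D sequence of length >= 8")
    env = np.abs(hilbert(x))
    scale = float(np.max(env))
    if scale <= 0 or float(np.std(env)) <= flat_tol * scale:
        spec = np.zeros(x.size // 2 + 1)
        return EnvelopeSignature(
            env_spectrum=spec, bin_hz=sample_rate / x.size,
            active_band=(), dominant_bin=None, valid=False,
        )
    spec = np.abs(np.fft.rfft(env - env.mean()))
    mean = spec.mean()
    active = (spec > mean).astype(np.int8)
    idx = np.flatnonzero(active)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    band = tuple((int(b[0]), int(b[-1])) for b in np.split(idx, splits)) if idx.size else ()
    dominant = int(np.argmax(spec))
    return EnvelopeSignature(
        env_spectrum=spec, bin_hz=sample_rate / x.size,
        active_band=band, dominant_bin=dominant, valid=True,
    )


def _band_set(band) -> set:
    bins: set = set()
    for lo, hi in band:
        bins.update(range(lo, hi + 1))
    return bins


def overlap_ratio(band_i, band_j) -> float:
    """Jaccard ratio |L_i n L_j| / |L_i u L_j| of two unions of bin intervals."""
    si, sj = _band_set(band_i), _band_set(band_j)
    union = si | sj
    if not union:
        return 0.0
    return len(si & sj) / len(union)


def fuse(modes, sample_rate: float, thr: float = 0.5,
         freq_tol_bins: int = 1) -> list:
    """Fuse fundamental modes into intrinsic mode functions.

    Repeatedly takes the first unconsumed mode as a seed, sweeps the remaining
    modes in input order, and absorbs any mode whose envelope-band overlap
    ratio with the current seed exceeds ``thr`` while the dominant envelope
    bins agree within ``freq_tol_bins``; the seed's signature is recomputed
    after each absorption, and the sweep restarts until a full pass absorbs
    nothing.  Member lists partition the input indices and samples are summed
    exactly.
    """
    if not (0 < thr <= 1):
        raise ValueError("thr must lie in (0, 1]")
    modes = [np.asarray(m, dtype=float) for m in modes]
    if not modes:
        raise ValueError("at least one mode is required")
    signatures = [envelope_signature(m, sample_rate) for m in modes]
    consumed = [False] * len(modes)
    imfs: list[IntrinsicModeFunction] = []
    for i in range(len(modes)):
        if consumed[i]:
            continue
        consumed[i] = True
        current = modes[i].copy()
        members = [i]
        sig = signatures[i]
        changed = True
        while changed:
            changed = False
            for j in range(len(modes)):
                if consumed[j]:
                    continue
                sig_j = signatures[j]
                if not (sig.valid and sig_j.valid):
                    continue
                r = overlap_ratio(sig.active_band, sig_j.active_band)
                if r > thr and abs(sig.dominant_bin - sig_j.dominant_bin) <= freq_tol_bins:
                    current += modes[j]
                    members.append(j)
                    consumed[j] = True
                    sig = envelope_signature(current, sample_rate)
                    changed = True
        imfs.append(IntrinsicModeFunction(samples=current, members=members, signature=sig))
    return imfs
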