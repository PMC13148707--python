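"""Binary group-sparse frequency filters for periodic-pulse extraction.

A periodic pulse train concentrates its spectral energy in a few compact,
mutually separated bands (carrier plus repetition-rate sidebands).  The filter
is a binary mask over the non-negative frequency bins, obtained by energy
detection -- keep bin ``i`` iff ``|c_y[i]|^2 >= lambda * w_i`` -- which is the
separable minimiser of

    J(f) = || c_y - c_y o f ||_2^2 + lambda ||f||_{0,w},

followed by structural post-processing: gaps shorter than ``min_gap`` between
kept runs are filled, then runs shorter than ``min_group_len`` are dropped.
Masks live on the non-negative bins of an rfft and are implicitly mirrored to
negative bins, so filtered outputs are real.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroupSparseFilter",
    "SpectrumCoefficients",
    "pointwise_mask",
    "enforce_group_structure",
    "apply_filter",
    "choose_lambda",
    "objective",
]


@dataclass(frozen=True)
class SpectrumCoefficients:
    """One-sided (rfft) Fourier coefficients of a mono-component."""

    values: np.ndarray
    bin_hz: float
    n_samples: int

    @classmethod
    def from_signal(cls, x, sample_rate: float) -> "SpectrumCoefficients":
        x = np.asarray(x, dtype=float)
        return cls(values=np.fft.rfft(x), bin_hz=sample_rate / x.size, n_samples=x.size)


@dataclass(frozen=True)
class GroupSparseFilter:
    """Binary mask organised into compact, separated support groups."""

    mask: np.ndarray
    groups: tuple  # inclusive (lo, hi) bin intervals
    lam: float
    min_group_len: int
    min_gap: int
    weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        rebuilt = np.zeros_like(np.asarray(self.mask))
        for lo, hi in self.groups:
            rebuilt[lo : hi + 1] = 1
        if not np.array_equal(rebuilt, self.mask):
            raise ValueError("mask must equal the union of its groups")


def _runs_of_ones(mask: np.ndarray):
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return [(int(b[0]), int(b[-1])) for b in np.split(idx, splits)]


def pointwise_mask(c_y, lam: float, weights=None) -> np.ndarray:
    """Separable energy-detection mask: keep bin i iff ``|c_y[i]|^2 >= lam w_i``."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    c = np.asarray(c_y)
    energy = np.abs(c) ** 2
    w = np.ones_like(energy) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != energy.shape or np.any(w <= 0):
        raise ValueError("weights must be positive and match the spectrum length")
    return (energy >= lam * w).astype(np.int8)


def enforce_group_structure(mask, min_group_len: int = 3, min_gap: int = 2,
                            lam: float = 0.0, weights=None) -> GroupSparseFilter:
    """Impose compact-support / separation structure on a binary mask.

    Gaps of fewer than ``min_gap`` zero bins between runs of ones are filled
    first; remaining runs shorter than ``min_group_len`` are then dropped.
    """
    mask = np.asarray(mask).astype(np.int8).copy()
    if min_group_len < 1 or min_gap < 1:
        raise ValueError("min_group_len and min_gap must be positive")
    runs = _runs_of_ones(mask)
    for (lo1, hi1), (lo2, hi2) in zip(runs, runs[1:]):
        if lo2 - hi1 - 1 < min_gap:
            mask[hi1 : lo2 + 1] = 1
    runs = [(lo, hi) for lo, hi in _runs_of_ones(mask) if hi - lo + 1 >= min_group_len]
    final = np.zeros_like(mask)
    for lo, hi in runs:
        final[lo : hi + 1] = 1
    return GroupSparseFilter(
        mask=final, groups=tuple(runs), lam=float(lam),
        min_group_len=min_group_len, min_gap=min_gap, weights=weights,
    )


def apply_filter(c_y, filt, n_samples: int | None = None) -> np.ndarray:
    """Hadamard-filter one-sided coefficients and invert to a real signal."""
    if isinstance(c_y, SpectrumCoefficients):
        values, n = c_y.values, c_y.n_samples
    else:
        values = np.asarray(c_y)
        n = n_samples if n_samples is not None else 2 * (values.size - 1)
    mask = filt.mask if isinstance(filt, GroupSparseFilter) else np.asarray(filt)
    if mask.size != values.size:
        raise ValueError(
            f"mask length {mask.size} does not match spectrum length {values.size}"
        )
    return np.fft.irfft(values * mask, n=n)


def choose_lambda(c_y, strategy: str = "median", kappa: float = 10.0,
                  dust_rel: float = 1e-12) -> float:
    """Default threshold selection: ``lambda = kappa * median bin energy``.

    The median is taken over the occupied bins: bins whose energy is below
    ``dust_rel`` times the peak bin energy are numerically empty (a
    band-limited component leaves most of its transform length blank) and
    would drag the median to zero, so they are excluded.  On a spectrum with
    no empty bins this is the plain median.
    """
    values = c_y.values if isinstance(c_y, SpectrumCoefficients) else np.asarray(c_y)
    if values.size == 0:
        raise ValueError("empty spectrum")
    if strategy != "median":
        raise ValueError(f"unknown lambda strategy {strategy!r}")
    energy = np.abs(values) ** 2
    peak = float(energy.max())
    if peak <= 0:
        return 0.0
    occupied = energy[energy > dust_rel * peak]
    return float(kappa * np.median(occupied))


def objective(c_y, mask, lam: float, weights=None) -> float:
    """The weighted-l0 filtering objective J(f); used for optimality checks."""
    c = np.asarray(c_y)
    mask = np.asarray(mask)
    energy = np.abs(c) ** 2
    w = np.ones_like(energy) if weights is None else np.asarray(weights, dtype=float)
    return float(np.sum(energy * (1 - mask)) + lam * np.sum(w * mask))
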