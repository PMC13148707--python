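"""Unimodal pre-segmentation of a spectrum by a-contrario testing.

The Blaschke spectrum is smoothed into a *trend* (mean truncation followed by
a maximum filter), read as a histogram of ``N = sum z(i)`` samples over its
``L`` bins, and cut into intervals that are *statistically unimodal*: the
number of false alarms (NFA) of every sub-interval, measured against the
Grenander (nearest-monotone / nearest-unimodal) estimate of the interval, must
exceed a decision threshold ``delta``.  Strictly monotone runs are merged fine
to coarse, then an increasing run and the following decreasing run are paired
into one unimodal segment.

The amplitude-as-counts reading makes the test sensitive to the overall scale
of the spectrum, exactly as a histogram test is sensitive to its sample count;
this is inherent to the model and documented rather than normalised away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "SpectralTrend",
    "UnimodalSegment",
    "spectral_trend",
    "proportions",
    "binomial_tail",
    "nfa",
    "d_transform",
    "grenander_decreasing",
    "grenander_increasing",
    "unimodal_kl_estimate",
    "monotone_test",
    "presegment",
]


@dataclass(frozen=True)
class SpectralTrend:
    """Mean-truncated, max-filtered main trend of a spectrum."""

    values: np.ndarray  # z, non-negative
    window: int  # M, odd
    mean: float  # mu, mean of the raw spectrum
    total: float  # N = sum z

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class UnimodalSegment:
    """Inclusive index interval [a, b] of the trend with peak c (0-based)."""

    a: int
    b: int
    peak: int
    min_nfa: float

    def __post_init__(self) -> None:
        if not (self.a <= self.peak <= self.b):
            raise ValueError("peak must lie inside the segment interval")

    @property
    def interval(self):
        return (self.a, self.b)

    def as_one_based(self):
        """Interval reported 1-based, matching order indices k = 1..K."""
        return (self.a + 1, self.b + 1)


# ---------------------------------------------------------------------------
# trend and counts
# ---------------------------------------------------------------------------


def spectral_trend(s, window: int) -> SpectralTrend:
    """Main trend: values below the mean are zeroed, then a centred maximum
    filter of odd width ``window`` is applied (clipped at the boundaries)."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or s.size < 3:
        raise ValueError("spectrum must be 1-D with length >= 3")
    if np.any(s < 0):
        raise ValueError("spectrum must be non-negative")
    if window < 1 or window % 2 == 0:
        raise ValueError("window M must be a positive odd integer")
    mu = float(np.mean(s))
    thresholded = np.where(s >= mu, s, 0.0)
    half = window // 2
    n = s.size
    z = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        z[i] = thresholded[lo:hi].max()
    return SpectralTrend(values=z, window=window, mean=mu, total=float(z.sum()))


def proportions(trend, interval) -> float:
    """Q(a, b): fraction of trend mass inside the inclusive interval [a, b]."""
    z = trend.values if isinstance(trend, SpectralTrend) else np.asarray(trend, float)
    total = float(z.sum())
    if total <= 0:
        raise ValueError("degenerate trend: total mass is zero")
    a, b = interval
    if not (0 <= a <= b < z.size):
        raise IndexError(f"interval [{a}, {b}] out of range for length {z.size}")
    return float(z[a : b + 1].sum() / total)


# ---------------------------------------------------------------------------
# binomial tails and NFA
# ---------------------------------------------------------------------------


def binomial_tail(n: float, k: float, p: float) -> float:
    """Upper binomial tail ``B(n, k, p) = P(X >= k)``, X ~ Binomial(n, p).

    Extended to real-valued ``n`` and ``k`` through the regularized incomplete
    beta function ``I_p(k, n - k + 1)``, which coincides with the direct sum
    at integer arguments.
    """
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    if k < 0 or n < 0 or k > n:
        raise ValueError("require 0 <= k <= n")
    if k <= 0:
        return 1.0
    if p == 0:
        return 0.0
    if p == 1:
        return 1.0
    return float(special.betainc(k, n - k + 1.0, p))


def nfa(interval_length_total: int, total: float, q: float, p: float) -> float:
    """Number of false alarms of an interval against background proportion p.

    ``NFA = L(L+1)/2 * B(N, N q, p)`` when the interval is over-populated
    (``q >= p``) and the mirrored tail otherwise; values at or below the
    decision threshold mean the uniform-background hypothesis is rejected.
    """
    if not (0 <= q <= 1 and 0 <= p <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    L = interval_length_total
    n_tests = L * (L + 1) / 2.0
    if q >= p:
        tail = binomial_tail(total, total * q, p)
    else:
        tail = binomial_tail(total, total * (1.0 - q), 1.0 - p)
    return float(n_tests * tail)


# ---------------------------------------------------------------------------
# Grenander estimators (pool-adjacent-violators via the D-transformation)
# ---------------------------------------------------------------------------


def d_transform(r) -> np.ndarray:
    """One pass of the D-transformation for the non-increasing target.

    Every maximal non-decreasing run (a violation of monotone decrease) is
    replaced by its average.  Iterated to a fixed point this is exactly the
    pool-adjacent-violators algorithm.
    """
    r = np.asarray(r, dtype=float).copy()
    i = 0
    n = r.size
    while i < n - 1:
        if r[i] <= r[i + 1]:
            j = i + 1
            while j < n - 1 and r[j] <= r[j + 1]:
                j += 1
            r[i : j + 1] = r[i : j + 1].mean()
            i = j + 1
        else:
            i += 1
    return r


def grenander_decreasing(r) -> np.ndarray:
    """Nearest non-increasing sequence in least squares (Grenander estimate).

    Pool-adjacent-violators with uniform weights; preserves the total mass and
    equals the least-squares projection onto the non-increasing cone (and, for
    probability vectors, the minimum-KL monotone representative).
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 1:
        raise ValueError("input must be 1-D")
    if np.any(r < 0):
        raise ValueError("input must be non-negative")
    # stack-based PAVA: blocks of (sum, count) merged while out of order
    sums: list[float] = []
    counts: list[int] = []
    for v in r:
        cur_sum, cur_cnt = float(v), 1
        while sums and sums[-1] / counts[-1] <= cur_sum / cur_cnt:
            cur_sum += sums.pop()
            cur_cnt += counts.pop()
        sums.append(cur_sum)
        counts.append(cur_cnt)
    out = np.empty(r.size)
    pos = 0
    for s, c in zip(sums, counts):
        out[pos : pos + c] = s / c
        pos += c
    return out


def grenander_increasing(r) -> np.ndarray:
    """Nearest non-decreasing sequence (symmetry principle: reverse, pool, reverse)."""
    return grenander_decreasing(np.asarray(r, dtype=float)[::-1])[::-1]


def unimodal_kl_estimate(rt):
    """Minimum-KL unimodal representative of a probability vector.

    Scans every candidate mode position ``c``, fits the non-decreasing
    Grenander estimate on ``rt[:c+1]`` and the non-increasing one on
    ``rt[c+1:]`` (both mass-preserving, so the concatenation still sums to 1),
    and keeps the candidate minimising ``KL(rt || candidate)``.

    Returns ``(estimate, mode_index, kl)``.
    """
    rt = np.asarray(rt, dtype=float)
    if rt.ndim != 1 or rt.size == 0:
        raise ValueError("input must be a non-empty 1-D probability vector")
    if np.any(rt < 0):
        raise ValueError("probabilities must be non-negative")
    total = rt.sum()
    if total <= 0:
        raise ValueError("degenerate input: all mass is zero")
    rt = rt / total

    def kl(p, q):
        mask = p > 0
        if np.any(q[mask] <= 0):
            return np.inf
        return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))

    best = (np.inf, None, None)
    for c in range(rt.size):
        left = grenander_increasing(rt[: c + 1])
        right = grenander_decreasing(rt[c + 1 :]) if c + 1 < rt.size else np.empty(0)
        cand = np.concatenate([left, right])
        d = kl(rt, cand)
        if d < best[0]:
            best = (d, c, cand)
    d, c, cand = best
    return cand, c, d


# ---------------------------------------------------------------------------
# statistical monotonicity and segmentation
# ---------------------------------------------------------------------------


def _min_nfa_against(segment: np.ndarray, estimate: np.ndarray, total: float) -> float:
    """Smallest NFA over all sub-intervals of a segment vs a reference law.

    Vectorised form of the per-interval test: proportions are prefix-sum
    differences and the (real-argument) binomial tails are evaluated through
    the incomplete-beta ufunc on all L(L+1)/2 intervals at once.
    """
    L = segment.size
    seg_total = segment.sum()
    if seg_total <= 0:
        return np.inf
    q_prefix = np.concatenate([[0.0], np.cumsum(segment / seg_total)])
    p_prefix = np.concatenate([[0.0], np.cumsum(estimate)])
    a, b = np.triu_indices(L)
    q = np.clip(q_prefix[b + 1] - q_prefix[a], 0.0, 1.0)
    p = np.clip(p_prefix[b + 1] - p_prefix[a], 0.0, 1.0)
    if a.size > 50_000:
        # exact tails only where the minimum can occur: the binomial tail is
        # exp(-N KL(q||p)) to first order, so rank intervals by the Chernoff
        # exponent and evaluate the top slice exactly
        qm = np.where(q >= p, q, 1.0 - q)
        pm = np.where(q >= p, p, 1.0 - p)
        with np.errstate(divide="ignore", invalid="ignore"):
            kl = (np.where(qm > 0, qm * np.log(qm / np.maximum(pm, 1e-300)), 0.0)
                  + np.where(qm < 1, (1 - qm) * np.log((1 - qm) /
                                                       np.maximum(1 - pm, 1e-300)), 0.0))
        kl = np.where(np.isfinite(kl), kl, np.inf)
        keep = np.argsort(kl)[-2000:]
        a, b, q, p = a[keep], b[keep], q[keep], p[keep]
    over = q >= p
    k = np.where(over, total * q, total * (1.0 - q))
    pp = np.where(over, p, 1.0 - p)
    # betainc(k, n-k+1, p) = P(X >= k); k = 0 gives 1, p in {0, 1} handled apart
    with np.errstate(invalid="ignore"):
        tail = special.betainc(np.maximum(k, 1e-300), total - k + 1.0, pp)
    tail = np.where(k <= 0, 1.0, tail)
    tail = np.where(pp <= 0, np.where(k <= 0, 1.0, 0.0), tail)
    tail = np.where(pp >= 1, 1.0, tail)
    return float(L * (L + 1) / 2.0 * np.nanmin(tail))


def monotone_test(segment, direction: str, delta: float = 0.5,
                  return_nfa: bool = False):
    """Is a trend slice statistically monotone in the given direction?

    The slice is normalised, its Grenander estimate in ``direction``
    ('non-increasing' or 'non-decreasing') is taken as the background law, and
    the slice passes iff no sub-interval achieves ``NFA <= delta``.  Strictly
    monotone slices always pass (their estimate is themselves, so every
    sub-interval has Q = P).
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 1 or seg.size < 1:
        raise ValueError("segment must be a non-empty 1-D slice")
    if direction not in ("non-increasing", "non-decreasing"):
        raise ValueError("direction must be 'non-increasing' or 'non-decreasing'")
    total = float(seg.sum())
    if seg.size == 1 or total <= 0:
        return (True, np.inf) if return_nfa else True
    rt = seg / total
    est = (grenander_decreasing(rt) if direction == "non-increasing"
           else grenander_increasing(rt))
    min_nfa = _min_nfa_against(seg, est, total)
    ok = bool(min_nfa > delta)
    return (ok, min_nfa) if return_nfa else ok


def _strict_runs(z: np.ndarray, lo: int, hi: int):
    """Split z[lo..hi] (inclusive) into maximal monotone runs (as index pairs
    with a direction); plateaus extend the current run."""
    runs = []
    start = lo
    direction = 0  # 0 unknown, +1 increasing, -1 decreasing
    for i in range(lo, hi):
        d = np.sign(z[i + 1] - z[i])
        if d == 0:
            continue
        if direction == 0:
            direction = d
        elif d != direction:
            runs.append((start, i, direction))
            start = i
            direction = d
    runs.append((start, hi, direction if direction != 0 else 1))
    return runs


def _pair_merge_score(z: np.ndarray, left, right, delta: float):
    """Best (min-NFA, direction) of merging two adjacent runs, or None."""
    seg = z[left[0] : right[1] + 1]
    best = None
    for direction, sign in (("non-decreasing", 1), ("non-increasing", -1)):
        ok, mn = monotone_test(seg, direction, delta, return_nfa=True)
        if ok and (best is None or mn > best[0]):
            best = (mn, sign)
    return best


def _merge_runs_fine_to_coarse(z: np.ndarray, runs, delta: float):
    """Merge adjacent runs whose union is still statistically monotone.

    At each step the admissible merge with the largest min-NFA (the least
    meaningful rejection) is applied; deterministic for fixed input.  Pair
    scores are cached and only the pairs touching the last merge are
    re-evaluated.
    """
    runs = list(runs)
    scores = [_pair_merge_score(z, runs[i], runs[i + 1], delta)
              for i in range(len(runs) - 1)]
    while len(runs) > 1:
        best = None
        for i, sc in enumerate(scores):
            if sc is not None and (best is None or sc[0] > best[0]):
                best = (sc[0], i, sc[1])
        if best is None:
            break
        _, i, sign = best
        runs[i : i + 2] = [(runs[i][0], runs[i + 1][1], sign)]
        del scores[i]
        if i > 0:
            scores[i - 1] = _pair_merge_score(z, runs[i - 1], runs[i], delta)
        if i < len(runs) - 1:
            scores[i] = _pair_merge_score(z, runs[i], runs[i + 1], delta)
    return runs


def presegment(spectrum, window: int = 9, delta: float = 0.5):
    """Segment a spectrum into statistically unimodal intervals.

    Steps: build the trend, split its positive support into blocks, cut each
    block into strictly monotone runs, merge runs fine-to-coarse under the
    NFA-``delta`` monotonicity test, then pair each increasing run with the
    following decreasing run into one unimodal segment.  Returns a list of
    :class:`UnimodalSegment` (0-based inclusive trend indices).
    """
    trend = spectral_trend(spectrum, window)
    z = trend.values
    if trend.total <= 0:
        warnings.warn("degenerate all-zero trend; empty segmentation", stacklevel=2)
        return []

    segments = []
    # maximal blocks of strictly positive trend
    positive = z > 0
    idx = np.flatnonzero(positive)
    blocks = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for block in blocks:
        lo, hi = int(block[0]), int(block[-1])
        if hi == lo:
            segments.append(UnimodalSegment(lo, hi, lo, np.inf))
            continue
        runs = _strict_runs(z, lo, hi)
        runs = _merge_runs_fine_to_coarse(z, runs, delta)
        i = 0
        prev_end = lo - 1
        while i < len(runs):
            a, b, sign = runs[i]
            if sign > 0 and i + 1 < len(runs) and runs[i + 1][2] < 0:
                b = runs[i + 1][1]
                i += 2
            else:
                i += 1
            # adjacent runs share their extremum index; keep segments disjoint
            a = max(a, prev_end + 1)
            if a > b:
                continue
            prev_end = b
            seg_vals = z[a : b + 1]
            peak = a + int(np.argmax(seg_vals))
            est, _, _ = unimodal_kl_estimate(seg_vals / seg_vals.sum())
            min_nfa = _min_nfa_against(seg_vals, est, float(seg_vals.sum()))
            segments.append(UnimodalSegment(a, b, peak, float(min_nfa)))
    return segments
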