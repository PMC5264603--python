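"""Circular binary segmentation of the log2 channel.

The splitting statistic is the classic arc-vs-complement two-sample t in
its basic mean-shift form: for a candidate arc of k probes inside a
segment of n, with the segment-wide standard deviation held fixed,
maximising |t| is equivalent to maximising

    Z(i, k) = |S(i+k) - S(i) - k * mean| / sqrt(k * (n - k) / n)

over all contiguous arcs, where S is the cumulative sum.  Because the
statistic of an arc equals that of its circular complement, maximising
over linear intervals covers every circular arc.  A split is accepted only
if its permutation p-value is below ``alpha``; accepted splits are located
by exhaustive maximisation and the three resulting pieces are re-tested
recursively.  No segment-undo or smoothing refinements are applied.

Per-segment permutation streams are derived from (seed, chromosome,
segment bounds), so decisions do not depend on recursion order, and the
permutation schedule is identical for every ``alpha`` (lowering ``alpha``
can therefore only remove splits).  Long segments score arcs on a
geometric grid of lengths -- the same grid for the observed value and for
every permutation, which keeps the test exact as a test of the gridded
statistic -- while segments up to ``exact_max_probes`` use every length.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ArraySample,
    CGH,
    CnvCall,
    GAIN,
    LOSS,
    GenomicInterval,
    Segment,
)
from .params import CbsParams

_TIE_EPS = 1e-12


def segment_stats(values) -> tuple[float, float, float, float]:
    """(mean, median, MAD, |median|/MAD) of a segment's log2 ratios.

    The MAD is unscaled -- median(|x - median(x)|) with no 1.4826
    consistency factor -- because it only ever enters the unitless
    |median|/MAD ratio filter.  The ratio is +inf when the MAD is zero.
    """

    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("segment_stats requires at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment_stats requires finite values")
    mean = float(np.mean(x))
    median = float(np.median(x))
    mad = float(np.median(np.abs(x - median)))
    madr = float("inf") if mad == 0 else abs(median) / mad
    return mean, median, mad, madr


def _arc_lengths(n: int, params: CbsParams) -> np.ndarray:
    """Arc lengths scored: exhaustive for short segments, geometric beyond."""
    if n - 1 <= params.exact_max_probes:
        return np.arange(1, n)
    ks = []
    k = 1.0
    while k <= n - 1:
        ks.append(int(round(k)))
        k *= params.grid_ratio
    ks.append(n - 1)
    return np.unique(np.asarray(ks, dtype=int))


def _max_stat(x: np.ndarray, ks: np.ndarray) -> float:
    """Maximum arc statistic of one vector over the given arc lengths."""
    n = len(x)
    mu = x.mean()
    c = np.concatenate(([0.0], np.cumsum(x)))
    best = 0.0
    for k in ks:
        denom = np.sqrt(k * (n - k) / n)
        z = np.abs(c[k:] - c[:-k] - k * mu) / denom
        m = z.max()
        if m > best:
            best = m
    return float(best)


def best_split(x) -> tuple[float, int, int]:
    """Exhaustive arc maximisation: returns (Z, i, j) for the best arc
    x[i:j], ties broken toward the lexicographically smallest (i, j)."""

    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two probes to split")
    mu = x.mean()
    c = np.concatenate(([0.0], np.cumsum(x)))
    candidates = []  # (Z_max_at_k, i, k)
    best = 0.0
    for k in range(1, n):
        denom = np.sqrt(k * (n - k) / n)
        z = np.abs(c[k:] - c[:-k] - k * mu) / denom
        i = int(np.argmax(z))
        zk = float(z[i])
        candidates.append((zk, i, k))
        if zk > best:
            best = zk
    winners = [(i, i + k) for zk, i, k in candidates if zk >= best - _TIE_EPS]
    i, j = min(winners)
    return best, i, j


def _perm_rng(params: CbsParams, chrom_idx: int, a: int, b: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed), 17, chrom_idx, a, b])


def _split_is_significant(
    x: np.ndarray, ks: np.ndarray, u_obs: float, params: CbsParams, rng
) -> bool:
    """Permutation test with early stopping that is decision-equivalent to
    the full ``n_permutations`` draw (it stops only once the p-value is
    guaranteed to exceed alpha)."""

    n = len(x)
    nperm = params.n_permutations
    limit = params.alpha * (nperm + 1) - 1  # exceed > limit => p >= alpha
    exceed = 0
    done = 0
    while done < nperm:
        b = min(params.perm_block, nperm - done)
        perms = rng.permuted(np.tile(x, (b, 1)), axis=1)
        mu = x.mean()
        c = np.concatenate((np.zeros((b, 1)), np.cumsum(perms, axis=1)), axis=1)
        u = np.zeros(b)
        for k in ks:
            denom = np.sqrt(k * (n - k) / n)
            z = np.abs(c[:, k:] - c[:, :-k] - k * mu) / denom
            np.maximum(u, z.max(axis=1), out=u)
        exceed += int(np.sum(u >= u_obs - _TIE_EPS))
        done += b
        if exceed > limit:
            return False
    p = (exceed + 1) / (nperm + 1)
    return p < params.alpha


def _changepoints(x: np.ndarray, params: CbsParams, chrom_idx: int) -> list[int]:
    """Recursive CBS on one chromosome's log2 vector; returns sorted
    interior breakpoint indices (a breakpoint t separates x[:t] from x[t:])."""

    breaks: list[int] = []

    def recurse(a: int, b: int) -> None:
        n = b - a
        if n < 4:
            return
        sub = x[a:b]
        if np.ptp(sub) == 0.0:
            return
        ks = _arc_lengths(n, params)
        u_obs = _max_stat(sub, ks)
        if u_obs <= 0:
            return
        rng = _perm_rng(params, chrom_idx, a, b)
        if not _split_is_significant(sub, ks, u_obs, params, rng):
            return
        _, i, j = best_split(sub)
        for t in (i, j):
            if 0 < t < n:
                breaks.append(a + t)
        pieces = sorted({a, a + i, a + j, b})
        for lo, hi in zip(pieces[:-1], pieces[1:]):
            recurse(lo, hi)

    recurse(0, len(x))
    return sorted(set(breaks))


def cbs_segment(sample: ArraySample, params: CbsParams | None = None) -> list[Segment]:
    """Segment the CGH channel chromosome by chromosome.

    The returned segments partition each chromosome's probe sequence; the
    segment interval runs from its first to its last probe position.
    """

    if params is None:
        params = CbsParams()
    if sample.probes.n_cgh == 0:
        raise ValueError("sample has no CGH probes")
    if not np.all(np.isfinite(sample.log2)):
        raise ValueError("log2 channel contains missing/non-finite values")
    segments: list[Segment] = []
    for chrom_idx, (chrom, positions, idxs) in enumerate(
        sample.probes.chrom_slices(CGH)
    ):
        x = sample.log2[idxs]
        breaks = _changepoints(x, params, chrom_idx)
        bounds = [0] + breaks + [len(x)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            mean, median, mad, _ = segment_stats(x[a:b])
            segments.append(
                Segment(
                    chrom=chrom,
                    probe_start=a,
                    probe_end=b - 1,
                    interval=GenomicInterval(chrom, int(positions[a]), int(positions[b - 1])),
                    n_probes=b - a,
                    mean_log2=mean,
                    median_log2=median,
                    mad_log2=mad,
                )
            )
    return segments


def cbs_calls(
    segments,
    params: CbsParams | None = None,
    patient_id: str = "",
    tissue: str = "",
) -> list[CnvCall]:
    """Threshold segments into calls: segment mean at or beyond the +/-1.0
    cutoffs, at least ``min_probes`` probes, and |median|/MAD >= 2."""

    if params is None:
        params = CbsParams()
    calls = []
    for seg in segments:
        if seg.mean_log2 >= params.gain_cutoff:
            state = GAIN
        elif seg.mean_log2 <= params.loss_cutoff:
            state = LOSS
        else:
            continue
        if seg.n_probes < params.min_probes:
            continue
        if seg.madr < params.madr_min:
            continue
        calls.append(
            CnvCall(
                interval=seg.interval,
                state=state,
                n_probes=seg.n_probes,
                mean_log2=seg.mean_log2,
                provenance=frozenset({"CBS"}),
                patient_id=patient_id,
                tissues=frozenset({tissue}) if tissue else frozenset(),
            )
        )
    return calls
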