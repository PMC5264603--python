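"""Quality-weighted interval-score aberration detection.

A documented stand-in for the vendor's proprietary aberration method: the
score of a probe interval I is the error-weighted z-sum

    S(I) = | sum_{i in I} v_i / sigma_i | / sqrt(|I|),

so a constant shift of m over n probes with common error sigma scores
|m| * sqrt(n) / sigma.  Detection extracts maximal-scoring, non-overlapping
intervals greedily -- best interval first, its probes removed, the flanks
re-searched -- until no interval reaches the score threshold.  Reported
intervals must additionally pass the stated filters: |mean log2| >= 0.25,
at least 3 probes, and genomic span >= 1 kb.
"""

from __future__ import annotations

import numpy as np

from .core import ArraySample, CGH, CnvCall, GAIN, LOSS, GenomicInterval
from .params import AdmParams

_TIE_EPS = 1e-12


def interval_score(values, errors) -> float:
    """Score one probe interval; invariant under sign flip and under
    rescaling values and errors by the same positive constant."""

    v = np.asarray(values, dtype=float)
    s = np.asarray(errors, dtype=float)
    if v.shape != s.shape:
        raise ValueError("values and errors must have equal length")
    if v.size == 0:
        raise ValueError("empty interval")
    if np.any(s <= 0):
        raise ValueError("probe errors must be positive")
    return float(np.abs(np.sum(v / s)) / np.sqrt(v.size))


def global_error_estimate(log2: np.ndarray) -> float:
    """Robust per-probe sd from first differences: successive probes share
    the same copy state almost everywhere, so diff variance ~ 2 sigma^2."""
    d = np.diff(np.asarray(log2, dtype=float))
    if d.size == 0:
        return 1e-6
    sigma = 1.4826 * np.median(np.abs(d)) / np.sqrt(2.0)
    return float(max(sigma, 1e-6))


def best_interval(w: np.ndarray) -> tuple[float, int, int]:
    """Exhaustive search for the best-scoring interval of the weighted
    vector ``w`` (= values/errors): returns (score, i, j) for w[i:j], ties
    toward the lexicographically smallest (i, j)."""

    n = len(w)
    c = np.concatenate(([0.0], np.cumsum(w)))
    best = -1.0
    candidates = []
    for k in range(1, n + 1):
        z = np.abs(c[k:] - c[:-k]) / np.sqrt(k)
        i = int(np.argmax(z))
        zk = float(z[i])
        candidates.append((zk, i, k))
        if zk > best:
            best = zk
    winners = [(i, i + k) for zk, i, k in candidates if zk >= best - _TIE_EPS]
    i, j = min(winners)
    return best, i, j


def _extract(w: np.ndarray, offset: int, threshold: float, out: list) -> None:
    """Greedy peel-off of maximal-scoring intervals from one probe run."""
    if len(w) == 0:
        return
    score, i, j = best_interval(w)
    if score < threshold:
        return
    out.append((offset + i, offset + j, score))
    _extract(w[:i], offset, threshold, out)
    _extract(w[j:], offset + j, threshold, out)


def adm_detect(
    sample: ArraySample,
    params: AdmParams | None = None,
    patient_id: str = "",
    tissue: str = "",
) -> list[CnvCall]:
    """Detect aberrant intervals on each chromosome of the CGH channel."""

    if params is None:
        params = AdmParams()
    if sample.probes.n_cgh == 0:
        return []
    if params.probe_error is None:
        sigma = np.full(sample.probes.n_cgh, global_error_estimate(sample.log2))
    else:
        sigma = np.broadcast_to(
            np.asarray(params.probe_error, dtype=float), (sample.probes.n_cgh,)
        )
    if np.any(sigma <= 0):
        raise ValueError("probe errors must be positive")
    calls: list[CnvCall] = []
    for chrom, positions, idxs in sample.probes.chrom_slices(CGH):
        x = sample.log2[idxs]
        found: list[tuple[int, int, float]] = []
        _extract(x / sigma[idxs], 0, params.score_threshold, found)
        for i, j, score in sorted(found):
            seg = x[i:j]
            mean = float(seg.mean())
            if abs(mean) < params.min_abs_mean_log2:
                continue
            if j - i < params.min_probes:
                continue
            iv = GenomicInterval(chrom, int(positions[i]), int(positions[j - 1]))
            if iv.length < params.min_length_bp:
                continue
            calls.append(
                CnvCall(
                    interval=iv,
                    state=GAIN if mean > 0 else LOSS,
                    n_probes=j - i,
                    mean_log2=mean,
                    provenance=frozenset({"ADM"}),
                    patient_id=patient_id,
                    tissues=frozenset({tissue}) if tissue else frozenset(),
                    score=float(score),
                )
            )
    return calls
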