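"""Segmentation behaviour: hand-computed segment statistics, exhaustive
arc-statistic oracle, permutation-test calibration on pure noise, and the
call-level filters."""

import math

import numpy as np
import pytest

from cnvpipe.cbs import best_split, cbs_calls, cbs_segment, segment_stats
from cnvpipe.core import ArraySample, GenomicInterval, ProbeSet, Segment
from cnvpipe.params import CbsParams

import pandas as pd


def cgh_sample(values, chrom="chr1", spacing=10_000, patient="p", tissue="CAP"):
    """Wrap a log2 vector as an ArraySample with regular CGH probes."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    table = pd.DataFrame(
        {
            "probe_id": [f"P{i}" for i in range(n)],
            "chrom": chrom,
            "pos": spacing * (np.arange(n) + 1),
            "channel": "CGH",
        }
    )
    probes = ProbeSet(table)
    return ArraySample(probes, values, np.empty(0, dtype="U2"), patient, tissue)


def brute_force_best_split(x):
    """Independent exhaustive arc maximisation (same tie-break: smallest
    (i, j)), written as a plain double loop."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mu = x.mean()
    best = (-1.0, None, None)
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k == n:
                continue
            z = abs(x[i:j].sum() - k * mu) / math.sqrt(k * (n - k) / n)
            if z > best[0] + 1e-12:
                best = (z, i, j)
    return best


class TestSegmentStats:
    def test_hand_computed_positive_segment(self):
        mean, median, mad, madr = segment_stats([0.5, 0.6, 0.4, 0.5, 0.7])
        assert median == pytest.approx(0.5)
        assert mad == pytest.approx(0.1)
        assert madr == pytest.approx(5.0)

    def test_hand_computed_zero_median(self):
        _, median, _, madr = segment_stats([0.1, -0.1, 0.2, -0.2, 0.0])
        assert median == 0.0
        assert madr == 0.0

    def test_constant_segment_has_infinite_ratio(self):
        _, _, mad, madr = segment_stats([1.0, 1.0, 1.0])
        assert mad == 0.0
        assert madr == math.inf

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            segment_stats([])


class TestSplitOracle:
    def test_noiseless_step_found_exactly(self):
        x = np.zeros(100)
        x[50:] = 1.0
        _, i, j = best_split(x)
        assert (i, j) in [(0, 50), (50, 100)]
        assert {i, j} & {50}  # the boundary between probes 50 and 51

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_noiseless_instances(self, seed):
        """Split locations equal exhaustive maximisation for vectors of
        <= 30 probes with up to two change-points and zero noise."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        x = np.zeros(n)
        n_cp = int(rng.integers(1, 3))
        cps = np.sort(rng.choice(np.arange(1, n), size=n_cp, replace=False))
        levels = rng.choice([-1.5, -1.0, 0.5, 1.0, 2.0], size=n_cp)
        for cp, lev in zip(cps, levels):
            x[cp:] += lev
        if np.ptp(x) == 0:
            return
        z, i, j = best_split(x)
        zb, ib, jb = brute_force_best_split(x)
        assert (i, j) == (ib, jb)
        assert z == pytest.approx(zb)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_noisy_vectors(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=25)
        z, i, j = best_split(x)
        zb, ib, jb = brute_force_best_split(x)
        assert (i, j) == (ib, jb)
        assert z == pytest.approx(zb)


class TestSegmentation:
    def test_constant_vector_single_segment(self):
        sample = cgh_sample(np.full(200, 0.3))
        segs = cbs_segment(sample, CbsParams(seed=1))
        assert len(segs) == 1
        assert segs[0].n_probes == 200

    def test_noiseless_step_boundary_exact(self):
        x = np.zeros(100)
        x[50:] = 1.0
        segs = cbs_segment(cgh_sample(x), CbsParams(seed=1))
        assert [s.n_probes for s in segs] == [50, 50]
        assert segs[0].mean_log2 == pytest.approx(0.0)
        assert segs[1].mean_log2 == pytest.approx(1.0)

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.2, size=300)
        x[100:130] += 1.5
        segs = cbs_segment(cgh_sample(x), CbsParams(seed=2))
        assert sum(s.n_probes for s in segs) == 300
        bounds = [(s.probe_start, s.probe_end) for s in segs]
        assert bounds[0][0] == 0 and bounds[-1][1] == 299
        for (a, b), (c, d) in zip(bounds[:-1], bounds[1:]):
            assert c == b + 1

    def test_breakpoint_accuracy_under_noise(self):
        """A 0.585 shift over 20 probes at noise sd 0.2: both breakpoints
        within +/-2 probes in at least 95 of 100 seeded runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(0, 0.2, size=100)
            x[40:60] += 0.585
            segs = cbs_segment(cgh_sample(x), CbsParams(seed=seed))
            bounds = {s.probe_start for s in segs} | {s.probe_end + 1 for s in segs}
            if any(abs(b - 40) <= 2 for b in bounds) and any(
                abs(b - 60) <= 2 for b in bounds
            ):
                hits += 1
        assert hits >= 95

    def test_pure_noise_split_rate_controlled(self):
        """On pure noise the fraction of chromosomes split stays below
        2*alpha across 200 seeded replicates."""
        params = CbsParams(alpha=0.01, seed=0)
        splits = 0
        for seed in range(200):
            rng = np.random.default_rng(20_000 + seed)
            x = rng.normal(0, 0.2, size=100)
            segs = cbs_segment(cgh_sample(x), CbsParams(alpha=0.01, seed=seed))
            if len(segs) > 1:
                splits += 1
        assert splits / 200 <= 2 * params.alpha

    def test_lowering_alpha_never_adds_segments(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.2, size=150)
        x[60:80] += 1.2
        sample = cgh_sample(x)
        counts = [
            len(cbs_segment(sample, CbsParams(alpha=a, seed=9)))
            for a in (0.2, 0.05, 0.01, 0.001)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_missing_channel_rejected(self):
        sample = cgh_sample([0.0, np.nan, 0.1, 0.2])
        with pytest.raises(ValueError, match="non-finite"):
            cbs_segment(sample, CbsParams())


class TestCalls:
    def seg(self, mean, n, values=None, chrom="chr1"):
        values = np.full(n, mean) if values is None else np.asarray(values)
        _, median, mad, _ = (
            values.mean(),
            float(np.median(values)),
            float(np.median(np.abs(values - np.median(values)))),
            0,
        )
        return Segment(
            chrom=chrom,
            probe_start=0,
            probe_end=n - 1,
            interval=GenomicInterval(chrom, 1, 10_000 * n),
            n_probes=n,
            mean_log2=float(np.mean(values)),
            median_log2=median,
            mad_log2=mad,
        )

    def test_gain_call_passes_all_filters(self):
        rng = np.random.default_rng(0)
        seg = self.seg(1.2, 10, values=1.2 + rng.normal(0, 0.1, 10))
        calls = cbs_calls([seg], CbsParams(), patient_id="p", tissue="CAP")
        assert len(calls) == 1 and calls[0].state == "gain"
        assert calls[0].provenance == frozenset({"CBS"})

    def test_two_probe_segment_filtered(self):
        seg = self.seg(1.2, 2)
        assert cbs_calls([seg], CbsParams()) == []

    def test_low_madr_segment_filtered(self):
        # |median|/MAD = 1.5/1.0 = 1.5 < 2
        values = np.array([-1.5, -0.5, -2.5, -1.5, -0.5, -2.5, -1.5])
        seg = self.seg(-1.5, 7, values=values)
        assert seg.madr < 2
        assert cbs_calls([seg], CbsParams()) == []

    def test_sub_cutoff_mean_not_called(self):
        seg = self.seg(0.585, 20)
        assert cbs_calls([seg], CbsParams()) == []
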