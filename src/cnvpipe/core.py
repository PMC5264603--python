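"""Shared genomic containers used across the pipeline.

Coordinate convention: every interval in this package is 1-based and
inclusive on both ends, so ``length = end - start + 1``.  BED files use
0-based half-open coordinates; :mod:`cnvpipe.array_io` converts at that
boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CGH = "CGH"
SNP = "SNP"
CHANNELS = (CGH, SNP)

GENOTYPES = ("AA", "AB", "BB", "NC")

TISSUES = ("CAP", "IMA", "blood")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.start < 1:
            raise ValueError(f"1-based coordinate must be >= 1, got {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)


class ProbeSet:
    """The array design: ordered probes with coordinates and channel type.

    Backed by a DataFrame with columns ``probe_id, chrom, pos, channel``,
    sorted by (chrom, pos) in the chromosome order given at construction.
    Probe ids must be unique and positions strictly increasing within a
    chromosome.
    """

    COLUMNS = ("probe_id", "chrom", "pos", "channel")

    def __init__(self, table: pd.DataFrame, chrom_order: Sequence[str] | None = None):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"probe table missing columns: {sorted(missing)}")
        table = table.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if chrom_order is None:
            chrom_order = list(dict.fromkeys(table["chrom"]))
        self.chrom_order: list[str] = list(chrom_order)
        bad = set(table["chrom"]) - set(self.chrom_order)
        if bad:
            raise ValueError(f"probes on chromosomes outside the declared order: {sorted(bad)}")
        rank = {c: i for i, c in enumerate(self.chrom_order)}
        order = np.lexsort((table["pos"].to_numpy(), table["chrom"].map(rank).to_numpy()))
        table = table.iloc[order].reset_index(drop=True)
        if table["probe_id"].duplicated().any():
            dup = table.loc[table["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe id {dup!r}")
        bad_channel = set(table["channel"]) - set(CHANNELS)
        if bad_channel:
            raise ValueError(f"unknown channel labels: {sorted(bad_channel)}")
        for chrom, sub in table.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                i = int(np.argmax(np.diff(pos) <= 0))
                raise ValueError(
                    f"probe positions not strictly increasing on {chrom} "
                    f"near row {sub.index[i + 1]}"
                )
        self.table = table
        self._is_cgh = (table["channel"] == CGH).to_numpy()
        self._is_snp = ~self._is_cgh

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ProbeSet) and self.table.equals(other.table)

    @property
    def n_cgh(self) -> int:
        return int(self._is_cgh.sum())

    @property
    def n_snp(self) -> int:
        return int(self._is_snp.sum())

    def channel_table(self, channel: str) -> pd.DataFrame:
        """Rows of one channel, index preserved, in genomic order."""
        mask = self._is_cgh if channel == CGH else self._is_snp
        return self.table.loc[mask]

    def chrom_slices(self, channel: str) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """Per-chromosome (name, positions, indices-into-channel-vector)."""
        sub = self.channel_table(channel).reset_index(drop=True)
        out = []
        for chrom in self.chrom_order:
            m = sub["chrom"] == chrom
            if m.any():
                out.append(
                    (chrom, sub.loc[m, "pos"].to_numpy(), np.flatnonzero(m.to_numpy()))
                )
        return out


@dataclass
class ArraySample:
    """One hybridization: a log2-ratio channel plus a SNP genotype channel.

    ``log2`` aligns 1:1 with the CGH probes of ``probes`` (genomic order)
    and ``genotype`` with the SNP probes.
    """

    probes: ProbeSet
    log2: np.ndarray
    genotype: np.ndarray
    patient_id: str
    tissue: str

    def __post_init__(self) -> None:
        self.log2 = np.asarray(self.log2, dtype=float)
        self.genotype = np.asarray(self.genotype, dtype="U2")
        if len(self.log2) != self.probes.n_cgh:
            raise ValueError(
                f"log2 channel has {len(self.log2)} values for "
                f"{self.probes.n_cgh} CGH probes"
            )
        if len(self.genotype) != self.probes.n_snp:
            raise ValueError(
                f"genotype channel has {len(self.genotype)} values for "
                f"{self.probes.n_snp} SNP probes"
            )
        bad = set(np.unique(self.genotype)) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype tokens: {sorted(bad)}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ArraySample)
            and self.patient_id == other.patient_id
            and self.tissue == other.tissue
            and self.probes == other.probes
            and np.array_equal(self.log2, other.log2, equal_nan=True)
            and np.array_equal(self.genotype, other.genotype)
        )


@dataclass
class Segment:
    """A maximal run of CGH probes with a common copy-number level."""

    chrom: str
    probe_start: int  # index into the per-chromosome CGH probe vector
    probe_end: int  # inclusive
    interval: GenomicInterval
    n_probes: int
    mean_log2: float
    median_log2: float
    mad_log2: float

    @property
    def madr(self) -> float:
        if self.mad_log2 == 0:
            return float("inf")
        return abs(self.median_log2) / self.mad_log2


GAIN = "gain"
LOSS = "loss"


def copies_from_log2(mean_log2: float) -> int:
    """Integer copy estimate 2*2^log2 rounded, floored at 0 (never filtered on)."""
    return max(0, int(round(2.0 * 2.0 ** mean_log2)))


@dataclass
class CnvCall:
    """A copy-number call with provenance and tissue attribution."""

    interval: GenomicInterval
    state: str  # gain | loss
    n_probes: int
    mean_log2: float
    provenance: frozenset = frozenset()
    patient_id: str = ""
    tissues: frozenset = frozenset()
    copies: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.state not in (GAIN, LOSS):
            raise ValueError(f"state must be gain or loss, got {self.state!r}")
        if self.state == GAIN and self.mean_log2 < 0 or self.state == LOSS and self.mean_log2 > 0:
            raise ValueError("state inconsistent with sign of mean_log2")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        self.provenance = frozenset(self.provenance)
        self.tissues = frozenset(self.tissues)
        if self.copies is None:
            self.copies = copies_from_log2(self.mean_log2)


@dataclass
class RohRun:
    """A run of homozygosity in one sample's SNP channel."""

    interval: GenomicInterval
    n_snp: int
    n_het_inside: int
    patient_id: str = ""
    tissue: str = ""


@dataclass
class CnLohCall:
    """Copy-neutral LOH: homozygous in both tissues, diploid copy number."""

    interval: GenomicInterval
    n_snp: int
    patient_id: str = ""
    tissues: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.tissues = frozenset(self.tissues)


def match_calls(
    predicted: Iterable[GenomicInterval | CnvCall],
    truth: Iterable,
    min_reciprocal: float = 0.5,
    require_state: bool = True,
) -> tuple[int, int, int]:
    """Match predicted calls to truth intervals at a reciprocal-overlap cutoff.

    Returns (n_true_positive, n_false_positive, n_false_negative).  A truth
    event may absorb several predictions (fragmented detections are not
    penalised as false positives) but counts once toward recall.
    """

    preds = list(predicted)
    truths = list(truth)
    hit_truth = [False] * len(truths)
    n_tp_pred = 0
    for p in preds:
        p_iv = p.interval if hasattr(p, "interval") else p
        p_state = getattr(p, "state", None)
        matched = False
        for i, t in enumerate(truths):
            t_iv = t.interval if hasattr(t, "interval") else t
            t_state = getattr(t, "state", None)
            if require_state and p_state is not None and t_state is not None:
                if p_state != t_state:
                    continue
            ov = p_iv.overlap_bp(t_iv)
            if ov == 0:
                continue
            if ov / p_iv.length >= min_reciprocal and ov / t_iv.length >= min_reciprocal:
                hit_truth[i] = True
                matched = True
        if matched:
            n_tp_pred += 1
    fp = len(preds) - n_tp_pred
    fn = hit_truth.count(False)
    return n_tp_pred, fp, fn
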