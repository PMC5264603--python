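"""Copy-neutral LOH from the SNP genotype channel.

Detection is in two steps.  First, each tissue's genotype channel is
scanned for runs of homozygosity (ROH): maximal stretches of consecutive
SNP probes whose heterozygote fraction stays within ``het_tolerance``
(default 1%), carrying at least ``min_snp`` probes (default 25) and
reported from first to last homozygous probe.  Second, runs that overlap
between the two tissues of a patient are intersected -- homozygosity must
hold in both samples, so unlike CNV consensus the boundaries are the
intersection, not the envelope -- and kept only if they span strictly
more than 1.5 Mb and touch no CNV call of that patient (a deleted region
is LOH but not copy-neutral).
"""

from __future__ import annotations

import numpy as np

from .core import ArraySample, CnLohCall, GenomicInterval, RohRun, SNP
from .params import CnLohParams, RohParams


def _runs_from_het(het: np.ndarray, tol: float) -> list[tuple[int, int, int]]:
    """Maximal runs (start, end inclusive, n_het) with het fraction <= tol.

    Pure homozygous runs are grown by repeatedly absorbing a neighbouring
    run across a single heterozygous probe whenever the merged run still
    satisfies the tolerance; merging is attempted left to right until a
    fixed point, so every reported run has homozygous endpoints.
    """

    n = len(het)
    if n == 0:
        return []
    runs: list[tuple[int, int, int]] = []
    i = 0
    while i < n:
        if het[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not het[j + 1]:
            j += 1
        runs.append((i, j, 0))
        i = j + 1
    changed = True
    while changed:
        changed = False
        merged: list[tuple[int, int, int]] = []
        for run in runs:
            if merged:
                s0, e0, h0 = merged[-1]
                s1, e1, h1 = run
                if s1 - e0 == 2:  # exactly one het probe between the runs
                    htot = h0 + h1 + 1
                    if htot / (e1 - s0 + 1) <= tol:
                        merged[-1] = (s0, e1, htot)
                        changed = True
                        continue
            merged.append(run)
        runs = merged
    return runs


def detect_roh(sample: ArraySample, params: RohParams | None = None) -> list[RohRun]:
    """Runs of homozygosity per chromosome.

    Chromosomes carrying fewer than ``min_snp`` SNP probes are ineligible.
    'NC' no-calls count as probes but neither break nor extend a run as
    heterozygotes do; they are treated as uninformative homozygotes.
    """

    if params is None:
        params = RohParams()
    runs: list[RohRun] = []
    for chrom, positions, idxs in sample.probes.chrom_slices(SNP):
        if len(idxs) < params.min_snp:
            continue
        geno = sample.genotype[idxs]
        het = geno == "AB"
        for s, e, n_het in _runs_from_het(het, params.het_tolerance):
            n_snp = e - s + 1
            if n_snp < params.min_snp:
                continue
            runs.append(
                RohRun(
                    interval=GenomicInterval(chrom, int(positions[s]), int(positions[e])),
                    n_snp=n_snp,
                    n_het_inside=n_het,
                    patient_id=sample.patient_id,
                    tissue=sample.tissue,
                )
            )
    return runs


def cnloh_calls(
    roh_a,
    roh_b,
    cnvs,
    params: CnLohParams | None = None,
    snp_positions: dict | None = None,
) -> list[CnLohCall]:
    """Copy-neutral LOH calls shared by the two tissues of one patient.

    ``snp_positions`` may map chromosome name to the sorted SNP probe
    positions so the intersected run's probe count is exact; without it
    the smaller of the two runs' counts is used.  ``cnvs`` are that
    patient's CNV calls; any overlap disqualifies a run (not copy-neutral).
    """

    if params is None:
        params = CnLohParams()
    patients = {r.patient_id for r in list(roh_a) + list(roh_b) if r.patient_id}
    if len(patients) > 1:
        raise ValueError(f"ROH runs from different patients mixed: {sorted(patients)}")
    patient = patients.pop() if patients else ""
    calls: list[CnLohCall] = []
    for ra in roh_a:
        for rb in roh_b:
            if not ra.interval.overlaps(rb.interval):
                continue
            start = max(ra.interval.start, rb.interval.start)
            end = min(ra.interval.end, rb.interval.end)
            iv = GenomicInterval(ra.interval.chrom, start, end)
            if iv.length <= params.min_length_bp:
                continue
            if any(iv.overlaps(c.interval) for c in cnvs):
                continue
            if snp_positions is not None and iv.chrom in snp_positions:
                pos = np.asarray(snp_positions[iv.chrom])
                n_snp = int(np.searchsorted(pos, end, "right") - np.searchsorted(pos, start, "left"))
            else:
                n_snp = min(ra.n_snp, rb.n_snp)
            tissues = frozenset(t for t in (ra.tissue, rb.tissue) if t)
            calls.append(
                CnLohCall(interval=iv, n_snp=n_snp, patient_id=patient, tissues=tissues)
            )
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return calls
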