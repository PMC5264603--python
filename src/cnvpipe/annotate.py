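"""Novelty classification against a population-CNV catalogue, gene
overlap, cross-patient recurrence, cohort summary statistics, and a
generic hypergeometric gene-set enrichment with BH-FDR correction.

The novelty rule follows the strict "more than 50%" reading: a call is
novel unless some catalogued region covers MORE than half of the call, so
a best overlap of exactly 0.5 still counts as novel.  The overlap
fraction is asymmetric by default (fraction of the query call covered); a
reciprocal mode is available where a symmetric criterion is wanted, and
recurrence matching uses reciprocal overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import CnvCall, GenomicInterval, LOSS
from .array_io import RegionIndex


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval: end - start + 1."""
    return iv.length


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, reciprocal: bool = False
) -> float:
    """Fraction of ``a`` covered by ``b`` (0 for different chromosomes);
    with ``reciprocal`` the minimum of both directions."""

    ov = a.overlap_bp(b)
    if ov == 0:
        return 0.0
    if reciprocal:
        return min(ov / a.length, ov / b.length)
    return ov / a.length


def classify_novelty(call, db: RegionIndex, max_known_overlap: float = 0.5) -> str:
    """'novel' unless a database region covers more than half the call."""
    iv = call.interval if hasattr(call, "interval") else call
    best = 0.0
    for region in db.query(iv):
        best = max(best, overlap_fraction(iv, region.interval))
    return "known" if best > max_known_overlap else "novel"


def annotate_genes(call, genes: RegionIndex) -> list[str]:
    """Names of genes overlapping the call by >= 1 bp, sorted by start."""
    iv = call.interval if hasattr(call, "interval") else call
    return [r.name for r in genes.query(iv)]


def recurrence(calls_by_patient: dict, min_reciprocal: float = 0.5) -> pd.DataFrame:
    """Per-call patient counts at a reciprocal-overlap matching threshold.

    Two calls from different patients represent the same locus when they
    share the same state and overlap reciprocally by at least
    ``min_reciprocal``.  Loci are the transitive closure of that relation;
    the returned frame has one row per call with its locus id, the number
    of distinct patients at the locus, and a recurrence flag.
    """

    if not calls_by_patient:
        raise ValueError("at least one patient is required")
    flat: list[tuple[str, CnvCall]] = []
    for pid, calls in calls_by_patient.items():
        flat.extend((pid, c) for c in calls)
    n = len(flat)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = flat[i][1], flat[j][1]
            if ci.state != cj.state:
                continue
            if overlap_fraction(ci.interval, cj.interval, reciprocal=True) >= min_reciprocal:
                parent[find(i)] = find(j)
    locus_of = [find(i) for i in range(n)]
    locus_ids = {root: k for k, root in enumerate(dict.fromkeys(locus_of))}
    rows = []
    for (pid, call), root in zip(flat, locus_of):
        locus = locus_ids[root]
        rows.append((pid, call.interval.chrom, call.interval.start, call.interval.end,
                     call.state, locus))
    df = pd.DataFrame(rows, columns=["patient_id", "chrom", "start", "end", "state", "locus"])
    patients_per_locus = df.groupby("locus")["patient_id"].nunique()
    df["n_patients"] = df["locus"].map(patients_per_locus)
    df["recurrent"] = df["n_patients"] > 1
    return df


def recurrent_fraction_pct(n_recurrent: int, n_total: int) -> int:
    """Integer-rounded recurrence percentage (e.g. 55 of 90 -> 61)."""
    if n_total == 0:
        return 0
    return int(round(100.0 * n_recurrent / n_total))


@dataclass
class CohortSummary:
    """Cohort-level call statistics; percentages are fractions in [0, 1]."""

    total_cnvs: int
    per_patient_mean: float
    per_patient_min: int
    per_patient_max: int
    size_mean_bp: float
    size_min_bp: int
    size_max_bp: int
    loss_fraction: float
    recurrent_count: int
    recurrent_fraction: float
    genic_count: int | None = None
    genic_fraction: float | None = None
    empty: bool = False

    def round1(self, fraction: float) -> float:
        """Report a fraction as a percentage with one decimal."""
        return round(100.0 * fraction, 1)


def summarize_cohort(
    calls_by_patient: dict,
    genes: RegionIndex | None = None,
    min_reciprocal: float = 0.5,
) -> CohortSummary:
    """Compute the cohort summary over per-patient shared call sets."""

    all_calls = [c for calls in calls_by_patient.values() for c in calls]
    if not all_calls:
        return CohortSummary(0, 0.0, 0, 0, 0.0, 0, 0, 0.0, 0, 0.0, empty=True)
    per_patient = [len(calls) for calls in calls_by_patient.values()]
    sizes = [c.interval.length for c in all_calls]
    rec = recurrence(calls_by_patient, min_reciprocal=min_reciprocal)
    n_rec = int(rec["recurrent"].sum())
    genic_count = genic_fraction = None
    if genes is not None:
        genic_count = sum(1 for c in all_calls if annotate_genes(c, genes))
        genic_fraction = genic_count / len(all_calls)
    return CohortSummary(
        total_cnvs=len(all_calls),
        per_patient_mean=float(np.mean(per_patient)),
        per_patient_min=int(min(per_patient)),
        per_patient_max=int(max(per_patient)),
        size_mean_bp=float(np.mean(sizes)),
        size_min_bp=int(min(sizes)),
        size_max_bp=int(max(sizes)),
        loss_fraction=sum(c.state == LOSS for c in all_calls) / len(all_calls),
        recurrent_count=n_rec,
        recurrent_fraction=n_rec / len(all_calls),
        genic_count=genic_count,
        genic_fraction=genic_fraction,
    )


def hypergeom_enrich(hits, geneset, universe) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) for gene-set enrichment.

    With N = |universe| genes of which K belong to the set, drawing
    n = |hits| genes yields k = |hits ∩ set| set members.
    """

    universe = set(universe)
    hits = set(hits)
    geneset = set(geneset)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    if not geneset <= universe:
        raise ValueError("gene set must be a subset of the universe")
    N, K, n = len(universe), len(geneset), len(hits)
    k = len(hits & geneset)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(hit_genes, genesets: dict, universe) -> pd.DataFrame:
    """Hypergeometric enrichment of one gene list against many sets,
    BH-corrected across the sets (columns: set, k, K, n, N, p, q)."""

    universe = set(universe)
    hits = set(hit_genes) & universe
    rows = []
    for name, genes in genesets.items():
        genes = set(genes) & universe
        p = hypergeom_enrich(hits, genes, universe)
        rows.append((name, len(hits & genes), len(genes), len(hits), len(universe), p))
    df = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df.sort_values("p", kind="stable").reset_index(drop=True)
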