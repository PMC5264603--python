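"""Synthetic CGH+SNP cohorts and qPCR plates with known ground truth.

The generator emulates a two-channel oligonucleotide array design: a CGH
channel carrying per-probe log2 test/reference intensity ratios and a SNP
channel carrying genotype calls, hybridised for three tissues per patient
(diseased coronary artery wall, CAP; intact internal mammary artery, IMA;
and blood).  Copy-number events shift the expected log2 ratio to
log2(c/2) for c copies against a diploid reference; a mosaic event
carried by a cell fraction f shifts it to log2((f*c + (1-f)*2)/2).
Copy-neutral LOH events leave the log2 channel flat and force the SNP
channel homozygous.

Everything is deterministic for a fixed seed: identical specs and seed
produce bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .core import ArraySample, CGH, SNP, ProbeSet, TISSUES, GenomicInterval

GAIN = "gain"
LOSS = "loss"
CNLOH = "cnloh"

#: floor applied to the expected log2 ratio so a homozygous deletion
#: (0 copies) maps to -4 instead of -infinity in the noiseless limit
LOG2_FLOOR = -4.0

ALL_TISSUES = frozenset(TISSUES)


@dataclass(frozen=True)
class GenomeSpec:
    """A toy genome: chromosome sizes and total probe counts per channel."""

    chromosomes: tuple  # of (name, length_bp)
    cgh_probe_count: int
    snp_probe_count: int
    probe_spacing_model: str = "uniform"  # or "regular"

    def __post_init__(self) -> None:
        if self.cgh_probe_count < 0 or self.snp_probe_count < 0:
            raise ValueError("probe counts must be non-negative")
        if self.cgh_probe_count + self.snp_probe_count <= 0:
            raise ValueError("at least one probe is required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        if self.probe_spacing_model not in ("uniform", "regular"):
            raise ValueError(f"unknown spacing model {self.probe_spacing_model!r}")

    @property
    def chrom_names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return int(sum(c[1] for c in self.chromosomes))


@dataclass(frozen=True)
class EventSpec:
    """One injected genomic event (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    kind: str  # gain | loss | cnloh
    copies: int
    mosaic_fraction: float = 1.0
    tissues: frozenset = ALL_TISSUES

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("event start > end")
        if not 0 < self.mosaic_fraction <= 1:
            raise ValueError("mosaic_fraction must lie in (0, 1]")
        if self.kind == CNLOH and self.copies != 2:
            raise ValueError("cn-LOH events are copy-neutral: copies must be 2")
        if self.kind == GAIN and self.copies < 3:
            raise ValueError("a gain needs >= 3 copies")
        if self.kind == LOSS and self.copies > 1:
            raise ValueError("a loss needs <= 1 copy")
        if self.kind not in (GAIN, LOSS, CNLOH):
            raise ValueError(f"unknown event kind {self.kind!r}")
        object.__setattr__(self, "tissues", frozenset(self.tissues))
        bad = self.tissues - ALL_TISSUES
        if bad:
            raise ValueError(f"unknown tissues {sorted(bad)}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def expected_log2(self) -> float:
        """Expected CGH log2 ratio inside this event (0 for cn-LOH)."""
        if self.kind == CNLOH:
            return 0.0
        mix = self.mosaic_fraction * self.copies + (1 - self.mosaic_fraction) * 2.0
        if mix <= 0:
            return LOG2_FLOOR
        return max(math.log2(mix / 2.0), LOG2_FLOOR)


@dataclass(frozen=True)
class NoiseSpec:
    log2_sd: float = 0.2
    snp_genotype_error: float = 0.005
    het_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.log2_sd < 0:
            raise ValueError("log2_sd must be >= 0")
        for p in (self.snp_genotype_error, self.het_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PatientSpec:
    patient_id: str
    germline_events: tuple = ()
    somatic_events: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "germline_events", tuple(self.germline_events))
        object.__setattr__(self, "somatic_events", tuple(self.somatic_events))

    @property
    def all_events(self) -> tuple:
        return self.germline_events + self.somatic_events


# ---------------------------------------------------------------------------
# probe grid


def _uniform_positions(length: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct sorted 1-based positions drawn uniformly without replacement."""
    if n > length:
        raise ValueError(f"cannot place {n} distinct probes on {length} bp")
    chosen: np.ndarray = np.empty(0, dtype=np.int64)
    while len(chosen) < n:
        extra = rng.integers(1, length + 1, size=int((n - len(chosen)) * 1.2) + 16)
        chosen = np.unique(np.concatenate([chosen, extra]))
        if len(chosen) > n:  # drop a random surplus to stay uniform
            chosen = chosen[np.sort(rng.choice(len(chosen), n, replace=False))]
    return np.sort(chosen)


def _regular_positions(length: int, n: int) -> np.ndarray:
    if n > length:
        raise ValueError(f"cannot place {n} distinct probes on {length} bp")
    spacing = length / n
    pos = np.round(spacing * (np.arange(n) + 0.5)).astype(np.int64)
    return np.unique(np.clip(pos, 1, length))


def _allocate(counts_total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of a probe budget across chromosomes."""
    ideal = counts_total * weights / weights.sum()
    base = np.floor(ideal).astype(int)
    rem = counts_total - base.sum()
    order = np.argsort(-(ideal - base))
    base[order[:rem]] += 1
    return base


def make_probe_grid(genome: GenomeSpec, seed: int) -> ProbeSet:
    """Lay out the array design: CGH and SNP probes at distinct positions.

    Probe budgets are apportioned to chromosomes proportionally to length;
    positions are uniform-random without replacement (default) or on a
    regular grid, then channels are assigned so SNP probes interleave
    evenly (regular model) or at random (uniform model).
    """

    rng = np.random.default_rng([int(seed), 0x9E37])
    lengths = np.array([c[1] for c in genome.chromosomes], dtype=float)
    n_cgh = _allocate(genome.cgh_probe_count, lengths)
    n_snp = _allocate(genome.snp_probe_count, lengths)
    rows = []
    for (name, length), nc, ns in zip(genome.chromosomes, n_cgh, n_snp):
        total = int(nc + ns)
        if total == 0:
            continue
        if genome.probe_spacing_model == "uniform":
            pos = _uniform_positions(int(length), total, rng)
            snp_idx = np.sort(rng.choice(total, int(ns), replace=False))
        else:
            pos = _regular_positions(int(length), total)
            total = len(pos)
            ns_eff = min(int(ns), total)
            snp_idx = np.round(np.linspace(0, total - 1, ns_eff)).astype(int) if ns_eff else np.empty(0, int)
        channel = np.full(len(pos), CGH, dtype=object)
        channel[snp_idx] = SNP
        for p, ch in zip(pos, channel):
            rows.append((f"{ch}_{name}_{p}", name, int(p), ch))
    table = pd.DataFrame(rows, columns=list(ProbeSet.COLUMNS))
    return ProbeSet(table, chrom_order=genome.chrom_names)


# ---------------------------------------------------------------------------
# samples


def _events_for_tissue(events, tissue: str):
    return [e for e in events if tissue in e.tissues]


def simulate_sample(
    probes: ProbeSet,
    events,
    noise: NoiseSpec,
    tissue: str,
    patient_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> ArraySample:
    """Simulate one hybridization for the given tissue.

    Events whose ``tissues`` do not include ``tissue`` are ignored.  CGH
    probes inside a copy-number event take expected log2(mix/2) where mix
    is the mosaic-weighted copy number (floored at -4); SNP probes inside
    a cn-LOH event -- or a clonal loss, which is hemizygous -- are
    homozygous apart from genotype error.
    """

    if rng is None:
        rng = np.random.default_rng([noise.seed, TISSUES.index(tissue)])
    for e in events:
        if e.chrom not in probes.chrom_order:
            raise ValueError(f"event on unknown chromosome {e.chrom!r}")
    active = _events_for_tissue(events, tissue)

    cgh = probes.channel_table(CGH)
    log2 = np.zeros(len(cgh))
    chrom_arr = cgh["chrom"].to_numpy()
    pos_arr = cgh["pos"].to_numpy()
    for e in active:
        if e.kind == CNLOH:
            continue
        m = (chrom_arr == e.chrom) & (pos_arr >= e.start) & (pos_arr <= e.end)
        log2[m] = e.expected_log2()
    log2 = log2 + rng.normal(0.0, noise.log2_sd, size=len(log2))

    snp = probes.channel_table(SNP)
    n_snp = len(snp)
    het = rng.random(n_snp) < noise.het_rate
    allele = rng.random(n_snp) < 0.5
    geno = np.where(het, "AB", np.where(allele, "AA", "BB")).astype("U2")
    s_chrom = snp["chrom"].to_numpy()
    s_pos = snp["pos"].to_numpy()
    for e in active:
        hom_forcing = e.kind == CNLOH or (
            e.kind == LOSS and e.mosaic_fraction == 1.0 and e.copies <= 1
        )
        if not hom_forcing:
            continue
        m = (s_chrom == e.chrom) & (s_pos >= e.start) & (s_pos <= e.end)
        geno[m] = np.where(allele[m], "AA", "BB")
    if noise.snp_genotype_error > 0:
        err = rng.random(n_snp) < noise.snp_genotype_error
        if err.any():
            options = np.array(["AA", "AB", "BB"], dtype="U2")
            pick = rng.integers(0, 2, size=int(err.sum()))
            cur = geno[err]
            out = np.empty(len(cur), dtype="U2")
            for i, (g, k) in enumerate(zip(cur, pick)):
                others = options[options != g]
                out[i] = others[k]
            geno[err] = out
    return ArraySample(probes, log2, geno, patient_id=patient_id, tissue=tissue)


@dataclass
class Cohort:
    """Per-patient CAP / IMA / blood samples plus the injected-event truth."""

    probes: ProbeSet
    samples: dict  # (patient_id, tissue) -> ArraySample
    truth: list  # of (patient_id, EventSpec)
    patients: list  # of PatientSpec

    def sample(self, patient_id: str, tissue: str) -> ArraySample:
        return self.samples[(patient_id, tissue)]

    def truth_events(self, patient_id: str, kinds=(GAIN, LOSS)):
        return [e for pid, e in self.truth if pid == patient_id and e.kind in kinds]


def simulate_cohort(patients, genome: GenomeSpec, noise: NoiseSpec) -> Cohort:
    """Simulate the full paired-tissue cohort with a truth manifest."""

    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient id in cohort spec")
    bounds = dict(genome.chromosomes)
    for p in patients:
        for e in p.all_events:
            if e.chrom not in bounds:
                raise ValueError(f"event on unknown chromosome {e.chrom!r}")
            if e.end > bounds[e.chrom]:
                raise ValueError(
                    f"event {e.chrom}:{e.start}-{e.end} exceeds chromosome length"
                )
    probes = make_probe_grid(genome, noise.seed)
    samples = {}
    truth = []
    for p_idx, p in enumerate(patients):
        for t_idx, tissue in enumerate(TISSUES):
            rng = np.random.default_rng([noise.seed, 1, p_idx, t_idx])
            samples[(p.patient_id, tissue)] = simulate_sample(
                probes, list(p.all_events), noise, tissue, patient_id=p.patient_id, rng=rng
            )
        truth.extend((p.patient_id, e) for e in p.all_events)
    return Cohort(probes=probes, samples=samples, truth=truth, patients=list(patients))


# ---------------------------------------------------------------------------
# default desk-scale study design


def default_genome(
    n_chrom: int = 22, cgh: int = 40_000, snp: int = 15_000
) -> GenomeSpec:
    """22-chromosome toy genome, ~2.6 Gb, at roughly 1/10 real probe density."""
    lengths = np.linspace(200e6, 40e6, n_chrom).astype(np.int64)
    chroms = tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(lengths))
    return GenomeSpec(chroms, cgh, snp, "uniform")


def _draw_locus(
    rng: np.random.Generator,
    genome: GenomeSpec,
    size_range: tuple[float, float],
    occupied: list,
    margin: int,
    max_tries: int = 1000,
) -> GenomicInterval:
    lengths = np.array([c[1] for c in genome.chromosomes], dtype=float)
    w = lengths / lengths.sum()
    for _ in range(max_tries):
        ci = int(rng.choice(len(lengths), p=w))
        name, clen = genome.chromosomes[ci]
        size = int(np.exp(rng.uniform(np.log(size_range[0]), np.log(size_range[1]))))
        if size >= clen:
            continue
        start = int(rng.integers(1, clen - size + 1))
        iv = GenomicInterval(name, start, start + size - 1)
        pad = GenomicInterval(name, max(1, iv.start - margin), min(clen, iv.end + margin))
        if any(pad.overlaps(o) for o in occupied):
            continue
        occupied.append(iv)
        return iv
    raise RuntimeError("could not place a non-overlapping locus; genome too crowded")


def default_cohort_specs(
    seed: int,
    n_patients: int = 10,
    n_pool_loci: int = 80,
    events_per_patient: tuple[int, int] = (30, 45),
    loss_fraction: float = 0.62,
    loss_copies: int = 0,
    gain_copies: int = 5,
    cnv_size_range: tuple[float, float] = (6e5, 2.5e6),
    cnloh_size_range: tuple[float, float] = (8e6, 12e6),
    cnloh_per_patient: tuple[int, ...] = (3, 3, 1, 0, 0, 0, 1, 0, 0, 0),
    genome: GenomeSpec | None = None,
    noise: NoiseSpec | None = None,
):
    """Build the default study design: a germline CNV locus pool shared
    across patients (producing recurrence) plus cn-LOH regions in 4 of 10
    patients, mirroring the paired-artery study layout.

    Losses are homozygous deletions and gains five-copy amplifications:
    the segmentation arm's stated +/-1.0 log2 call cutoffs only admit
    events at least that extreme, so the default cohort probes the calling
    machinery rather than the threshold (see docs/methods.md).  Events are
    germline (present in all three tissues); somatic events are available
    through :class:`PatientSpec` but the default design injects none,
    matching a cohort with no artery-specific changes.
    """

    if genome is None:
        genome = default_genome()
    if noise is None:
        noise = NoiseSpec(seed=int(seed))
    rng = np.random.default_rng([int(seed), 2])
    occupied: list = []
    pool = []
    for _ in range(n_pool_loci):
        iv = _draw_locus(rng, genome, cnv_size_range, occupied, margin=5_000_000)
        if rng.random() < loss_fraction:
            kind, copies = LOSS, loss_copies
        else:
            kind, copies = GAIN, gain_copies
        pool.append(EventSpec(iv.chrom, iv.start, iv.end, kind, copies))
    cnloh_pool = []
    for _ in range(int(np.sum(cnloh_per_patient[:n_patients]))):
        iv = _draw_locus(rng, genome, cnloh_size_range, occupied, margin=5_000_000)
        cnloh_pool.append(EventSpec(iv.chrom, iv.start, iv.end, CNLOH, 2))
    patients = []
    loh_cursor = 0
    for i in range(n_patients):
        k = int(rng.integers(events_per_patient[0], events_per_patient[1] + 1))
        chosen = rng.choice(n_pool_loci, size=min(k, n_pool_loci), replace=False)
        events = [pool[j] for j in sorted(chosen)]
        n_loh = cnloh_per_patient[i] if i < len(cnloh_per_patient) else 0
        events += cnloh_pool[loh_cursor : loh_cursor + n_loh]
        loh_cursor += n_loh
        patients.append(PatientSpec(patient_id=f"patient{i + 1}", germline_events=tuple(events)))
    return patients, genome, noise


# ---------------------------------------------------------------------------
# qPCR plates


@dataclass(frozen=True)
class AssaySpec:
    """One target/reference qPCR assay pair with standard-curve efficiencies."""

    E_target: float = 2.0
    E_ref: float = 2.0
    base_ct_target: float = 28.0
    base_ct_ref: float = 27.0
    ct_sd: float = 0.0
    replicates: int = 3
    no_amplification_ct: float = 40.0

    def __post_init__(self) -> None:
        if self.E_target <= 1 or self.E_ref <= 1:
            raise ValueError("amplification efficiency must exceed 1")
        if self.replicates < 1:
            raise ValueError("at least one replicate is required")
        if self.ct_sd < 0:
            raise ValueError("ct_sd must be >= 0")


@dataclass
class QpcrPlate:
    """Simulated plate: replicate Cts per sample plus calibrator wells."""

    assay: AssaySpec
    target_ct: dict  # sample -> np.ndarray of replicate Cts
    ref_ct: dict
    calibrator_target_ct: np.ndarray
    calibrator_ref_ct: np.ndarray
    truth_copies: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sample in self.target_ct:
            for r, ct in enumerate(self.target_ct[sample]):
                rows.append((sample, "target", False, r + 1, float(ct)))
            for r, ct in enumerate(self.ref_ct[sample]):
                rows.append((sample, "reference", False, r + 1, float(ct)))
        for r, ct in enumerate(self.calibrator_target_ct):
            rows.append(("calibrator", "target", True, r + 1, float(ct)))
        for r, ct in enumerate(self.calibrator_ref_ct):
            rows.append(("calibrator", "reference", True, r + 1, float(ct)))
        return pd.DataFrame(
            rows, columns=["sample", "role", "is_calibrator", "replicate", "ct"]
        )


def simulate_qpcr_plate(copy_states: dict, assay: AssaySpec, seed: int) -> QpcrPlate:
    """Simulate replicate Cts so the efficiency-corrected ratio recovers c/2.

    The target Ct of a sample with c copies sits log_E(c/2) cycles below
    the 2-copy calibrator; the reference locus is copy-independent.
    """

    for s, c in copy_states.items():
        if c < 0:
            raise ValueError(f"negative copy number for sample {s!r}")
    rng = np.random.default_rng([int(seed), 3])
    n = assay.replicates

    def noisy(mean: float) -> np.ndarray:
        return mean + rng.normal(0.0, assay.ct_sd, size=n)

    target_ct, ref_ct = {}, {}
    for sample, c in copy_states.items():
        if c == 0:
            mean_t = assay.no_amplification_ct
        else:
            mean_t = assay.base_ct_target - math.log(c / 2.0, assay.E_target)
        target_ct[sample] = noisy(mean_t)
        ref_ct[sample] = noisy(assay.base_ct_ref)
    return QpcrPlate(
        assay=assay,
        target_ct=target_ct,
        ref_ct=ref_ct,
        calibrator_target_ct=noisy(assay.base_ct_target),
        calibrator_ref_ct=noisy(assay.base_ct_ref),
        truth_copies=dict(copy_states),
    )


# ---------------------------------------------------------------------------
# spec (de)serialisation for config files


def cohort_spec_to_yaml(patients, genome: GenomeSpec, noise: NoiseSpec) -> str:
    doc = {
        "genome": {
            "chromosomes": [[n, int(l)] for n, l in genome.chromosomes],
            "cgh_probe_count": genome.cgh_probe_count,
            "snp_probe_count": genome.snp_probe_count,
            "probe_spacing_model": genome.probe_spacing_model,
        },
        "noise": asdict(noise),
        "patients": [
            {
                "patient_id": p.patient_id,
                "germline_events": [_event_to_dict(e) for e in p.germline_events],
                "somatic_events": [_event_to_dict(e) for e in p.somatic_events],
            }
            for p in patients
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def _event_to_dict(e: EventSpec) -> dict:
    return {
        "chrom": e.chrom,
        "start": e.start,
        "end": e.end,
        "kind": e.kind,
        "copies": e.copies,
        "mosaic_fraction": e.mosaic_fraction,
        "tissues": sorted(e.tissues),
    }


def cohort_spec_from_yaml(text: str):
    doc = yaml.safe_load(text)
    g = doc["genome"]
    genome = GenomeSpec(
        tuple((n, int(l)) for n, l in g["chromosomes"]),
        int(g["cgh_probe_count"]),
        int(g["snp_probe_count"]),
        g.get("probe_spacing_model", "uniform"),
    )
    noise = NoiseSpec(**doc.get("noise", {}))
    patients = []
    for p in doc.get("patients", []):
        patients.append(
            PatientSpec(
                patient_id=p["patient_id"],
                germline_events=tuple(EventSpec(**e) for e in p.get("germline_events", [])),
                somatic_events=tuple(EventSpec(**e) for e in p.get("somatic_events", [])),
            )
        )
    return patients, genome, noise
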