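"""End-to-end orchestration: simulate (or load) -> segment with both arms
-> per-sample consensus -> paired-tissue intersection -> cn-LOH ->
summary -> truth comparison, with stable output filenames and a manifest
recording parameters, seed and per-stage counts.

Reproducibility: one global seed fans out to per-sample child seeds via a
fixed counter scheme (seed, patient index, tissue index), so a stage
re-run in isolation with the same child seed reproduces the full-run
result, and identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import adm, cbs, cnloh, consensus
from .annotate import CohortSummary, summarize_cohort
from .array_io import write_calls_bed, write_truth_bed
from .core import SNP, match_calls
from .params import PipelineParams
from .synthetic import CNLOH, Cohort, GAIN, LOSS

log = logging.getLogger("cnvpipe")

PAIR = ("CAP", "IMA")


def child_seed(seed: int, patient_idx: int, tissue_idx: int) -> int:
    """Deterministic per-sample seed below 2^31."""
    return (seed * 1_000_003 + patient_idx * 131 + tissue_idx) % (2**31)


@dataclass
class PatientResult:
    patient_id: str
    per_tissue_calls: dict  # tissue -> list[CnvCall] (high-confidence)
    shared: list
    differential: dict  # tissue -> tissue-specific calls
    cnloh: list
    stage_counts: dict


@dataclass
class RunReport:
    params: PipelineParams
    patients: list  # of PatientResult
    summary: CohortSummary
    truth_metrics: dict | None = None

    @property
    def shared_by_patient(self) -> dict:
        return {p.patient_id: p.shared for p in self.patients}


def _truth_metrics(cohort: Cohort, patients: list) -> dict:
    """Recall/precision of shared CNV calls and cn-LOH calls vs the truth
    manifest at 50% reciprocal overlap."""

    agg = {
        "cnv": {"matched": 0, "preds": 0, "hit": 0, "truths": 0},
        "cnloh": {"matched": 0, "preds": 0, "hit": 0, "truths": 0},
    }
    for res in patients:
        for key, preds, kinds, need_state in (
            ("cnv", res.shared, (GAIN, LOSS), True),
            ("cnloh", res.cnloh, (CNLOH,), False),
        ):
            truth = cohort.truth_events(res.patient_id, kinds=kinds)
            t, f, m = match_calls(
                preds, truth, min_reciprocal=0.5, require_state=need_state
            )
            agg[key]["matched"] += t
            agg[key]["preds"] += len(preds)
            agg[key]["hit"] += len(truth) - m
            agg[key]["truths"] += len(truth)

    def ratio(a, b):
        return a / b if b else float("nan")

    out = {}
    for key, d in agg.items():
        out[f"{key}_recall"] = ratio(d["hit"], d["truths"])
        out[f"{key}_precision"] = ratio(d["matched"], d["preds"])
        out[f"{key}_n_truth"] = d["truths"]
        out[f"{key}_n_called"] = d["preds"]
    return out


def run_pipeline(
    cohort: Cohort,
    params: PipelineParams | None = None,
    out_dir: str | Path | None = None,
    compare_truth: bool = True,
) -> RunReport:
    """Run the full calling chain on a cohort (simulated or loaded)."""

    if params is None:
        params = PipelineParams()
    snp_positions = {
        chrom: pos for chrom, pos, _ in cohort.probes.chrom_slices(SNP)
    }
    results: list[PatientResult] = []
    for p_idx, patient in enumerate(cohort.patients):
        pid = patient.patient_id
        per_tissue = {}
        roh_by_tissue = {}
        counts: dict = {}
        for t_idx, tissue in enumerate(PAIR):
            sample = cohort.sample(pid, tissue)
            cbs_params = dataclasses.replace(
                params.cbs, seed=child_seed(params.seed, p_idx, t_idx)
            )
            segments = cbs.cbs_segment(sample, cbs_params)
            calls_cbs = cbs.cbs_calls(segments, cbs_params, patient_id=pid, tissue=tissue)
            calls_adm = adm.adm_detect(sample, params.adm, patient_id=pid, tissue=tissue)
            hc = consensus.high_confidence(calls_adm, calls_cbs)
            roh_by_tissue[tissue] = cnloh.detect_roh(sample, params.roh)
            per_tissue[tissue] = hc
            counts[tissue] = {
                "segments": len(segments),
                "cbs_calls": len(calls_cbs),
                "adm_calls": len(calls_adm),
                "high_confidence": len(hc),
                "roh_runs": len(roh_by_tissue[tissue]),
            }
            log.info(
                "stage=consensus patient=%s tissue=%s adm=%d cbs=%d kept=%d "
                "dropped=%d filter=both-algorithms",
                pid, tissue, len(calls_adm), len(calls_cbs), len(hc),
                len(calls_adm) + len(calls_cbs) - len(hc),
            )
        shared = consensus.shared_in_pair(per_tissue["CAP"], per_tissue["IMA"])
        diff = {
            "CAP": consensus.differential(per_tissue["CAP"], per_tissue["IMA"]),
            "IMA": consensus.differential(per_tissue["IMA"], per_tissue["CAP"]),
        }
        loh = cnloh.cnloh_calls(
            roh_by_tissue["CAP"],
            roh_by_tissue["IMA"],
            shared,
            params.cnloh,
            snp_positions=snp_positions,
        )
        counts["pair"] = {
            "shared": len(shared),
            "cap_specific": len(diff["CAP"]),
            "ima_specific": len(diff["IMA"]),
            "cnloh": len(loh),
        }
        log.info(
            "stage=pair patient=%s shared=%d cap_only=%d ima_only=%d cnloh=%d",
            pid, len(shared), len(diff["CAP"]), len(diff["IMA"]), len(loh),
        )
        results.append(
            PatientResult(
                patient_id=pid,
                per_tissue_calls=per_tissue,
                shared=shared,
                differential=diff,
                cnloh=loh,
                stage_counts=counts,
            )
        )
    summary = summarize_cohort(
        {r.patient_id: r.shared for r in results},
        min_reciprocal=params.recurrence_overlap,
    )
    report = RunReport(
        params=params,
        patients=results,
        summary=summary,
        truth_metrics=_truth_metrics(cohort, results) if compare_truth and cohort.truth else None,
    )
    if out_dir is not None:
        _write_outputs(report, cohort, Path(out_dir))
    return report


def _write_outputs(report: RunReport, cohort: Cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for res in report.patients:
        pdir = out_dir / res.patient_id
        pdir.mkdir(exist_ok=True)
        write_calls_bed(res.shared, pdir / "shared_cnv.bed")
        write_calls_bed(res.differential["CAP"], pdir / "cap_specific.bed")
        write_calls_bed(res.differential["IMA"], pdir / "ima_specific.bed")
        write_calls_bed(res.cnloh, pdir / "cnloh.bed")
    if cohort.truth:
        write_truth_bed(cohort.truth, out_dir / "truth.bed")
    manifest = {
        "params": dataclasses.asdict(report.params),
        "stage_counts": {r.patient_id: r.stage_counts for r in report.patients},
        "summary": dataclasses.asdict(report.summary),
        "truth_metrics": report.truth_metrics,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
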