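"""High-confidence consensus between the two detection arms and the
paired-tissue shared/differential call logic.

A call is high-confidence when both algorithms detected it in the same
sample: calls of the same state on the same chromosome that overlap by at
least one base pair are grouped transitively and merged to the envelope of
the group (outer probe boundaries).  The same matching rule, applied
across the two tissues of one patient, yields the calls shared by both
tissues and, by complement, the tissue-specific (differential) calls.
"""

from __future__ import annotations

from .core import CnvCall, GenomicInterval, copies_from_log2


def _check_single_sample(calls_a, calls_b, same_tissue: bool) -> None:
    patients = {c.patient_id for c in calls_a} | {c.patient_id for c in calls_b}
    if len(patients) > 1:
        raise ValueError(f"calls from different patients mixed: {sorted(patients)}")
    if same_tissue:
        tissues = set()
        for c in list(calls_a) + list(calls_b):
            tissues |= set(c.tissues)
        if len(tissues) > 1:
            raise ValueError(
                f"consensus expects calls from one sample; saw tissues {sorted(tissues)}"
            )


def _merge_group(group: list[CnvCall]) -> CnvCall:
    """Envelope merge: outer boundaries, probe-weighted mean, unions."""
    iv = GenomicInterval(
        group[0].interval.chrom,
        min(c.interval.start for c in group),
        max(c.interval.end for c in group),
    )
    total_probes = sum(c.n_probes for c in group)
    mean = sum(c.mean_log2 * c.n_probes for c in group) / total_probes
    provenance = frozenset().union(*(c.provenance for c in group))
    tissues = frozenset().union(*(c.tissues for c in group))
    return CnvCall(
        interval=iv,
        state=group[0].state,
        n_probes=max(c.n_probes for c in group),
        mean_log2=mean,
        provenance=provenance,
        patient_id=group[0].patient_id,
        tissues=tissues,
        copies=copies_from_log2(mean),
    )


def _overlap_groups(calls: list[CnvCall]) -> list[list[CnvCall]]:
    """Transitive same-chromosome, same-state, >=1 bp overlap components.

    Overlap between genomic intervals is an interval graph, so a single
    sweep in start order finds the connected components.
    """

    groups: list[list[CnvCall]] = []
    by_key: dict[tuple[str, str], list[CnvCall]] = {}
    for c in calls:
        by_key.setdefault((c.interval.chrom, c.state), []).append(c)
    for members in by_key.values():
        members.sort(key=lambda c: (c.interval.start, c.interval.end))
        current: list[CnvCall] = []
        reach = -1
        for c in members:
            if current and c.interval.start <= reach:
                current.append(c)
                reach = max(reach, c.interval.end)
            else:
                if current:
                    groups.append(current)
                current = [c]
                reach = c.interval.end
        if current:
            groups.append(current)
    return groups


def _tag(call: CnvCall, tag: str) -> CnvCall:
    out = CnvCall(**{**call.__dict__})
    out._side = tag  # type: ignore[attr-defined]
    return out


def _consensus(calls_a, calls_b, require_both: bool) -> list[CnvCall]:
    tagged = [_tag(c, "a") for c in calls_a] + [_tag(c, "b") for c in calls_b]
    merged = []
    for group in _overlap_groups(tagged):
        sides = {getattr(c, "_side") for c in group}
        if require_both and sides != {"a", "b"}:
            continue
        merged.append(_merge_group(group))
    merged.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return merged


def high_confidence(calls_adm, calls_cbs) -> list[CnvCall]:
    """Calls detected by both algorithms in one sample, envelope-merged.

    Provenance of each emitted call is the union of the group members'
    (normally {ADM, CBS}).
    """

    _check_single_sample(calls_adm, calls_cbs, same_tissue=True)
    return _consensus(calls_adm, calls_cbs, require_both=True)


def shared_in_pair(calls_a, calls_b) -> list[CnvCall]:
    """Calls present in both tissues of one patient (outer-boundary merge);
    the result's ``tissues`` is the union of the members'."""

    _check_single_sample(calls_a, calls_b, same_tissue=False)
    return _consensus(calls_a, calls_b, require_both=True)


def differential(calls_a, calls_b) -> list[CnvCall]:
    """Calls in ``calls_a`` with no same-state overlap in ``calls_b``.

    An overlapping opposite-state call does not cancel: the state must
    match for a call to count as shared.
    """

    _check_single_sample(calls_a, calls_b, same_tissue=False)
    out = []
    for c in calls_a:
        shared = any(
            c.state == o.state and c.interval.overlaps(o.interval) for o in calls_b
        )
        if not shared:
            out.append(c)
    return out
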