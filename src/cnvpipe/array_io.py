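"""Readers and writers: probe tables, BED/TSV region files, UCSC cytoband
tables, GMT gene sets, and the ``arr[build]band(start-end)xN`` ISCN array
nomenclature used to report calls.

Internal coordinates are always 1-based inclusive.  BED input/output
(0-based, half-open) is converted exactly once, here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import (
    ArraySample,
    CGH,
    SNP,
    CHANNELS,
    GENOTYPES,
    CnLohCall,
    CnvCall,
    GenomicInterval,
    ProbeSet,
)

# ---------------------------------------------------------------------------
# probe tables

_PROBE_HEADER = ["probe_id", "chrom", "pos", "type", "value"]


def write_probe_table(sample: ArraySample, path) -> None:
    """Write one sample as a tab-separated probe table (round-trip exact)."""
    probes = sample.probes
    values = np.empty(len(probes), dtype=object)
    values[probes.table["channel"].to_numpy() == CGH] = [
        repr(float(v)) for v in sample.log2
    ]
    values[probes.table["channel"].to_numpy() == SNP] = list(sample.genotype)
    with open(path, "w") as fh:
        fh.write(f"#patient_id={sample.patient_id}\n")
        fh.write(f"#tissue={sample.tissue}\n")
        fh.write("#chrom_order=" + ",".join(probes.chrom_order) + "\n")
        fh.write("\t".join(_PROBE_HEADER) + "\n")
        for (pid, chrom, pos, ch), v in zip(
            probes.table.itertuples(index=False, name=None), values
        ):
            fh.write(f"{pid}\t{chrom}\t{pos}\t{ch}\t{v}\n")


def read_probe_table(path) -> ArraySample:
    """Read a probe table back into an :class:`ArraySample`.

    Raises on unsorted positions (naming the first offending row), unknown
    channel labels, genotype tokens in the log2 column or vice versa.
    """

    meta = {"patient_id": "", "tissue": "CAP"}
    chrom_order = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    if key == "chrom_order":
                        chrom_order = val.split(",")
                    else:
                        meta[key] = val
                continue
            if line.split("\t") == _PROBE_HEADER:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns")
            rows.append((lineno, *fields))

    log2, genotype = [], []
    table_rows = []
    prev = {}
    for lineno, pid, chrom, pos_s, channel, value in rows:
        pos = int(pos_s)
        if channel not in CHANNELS:
            raise ValueError(f"{path}: line {lineno}: unknown channel {channel!r}")
        if chrom in prev and pos <= prev[chrom]:
            raise ValueError(
                f"{path}: line {lineno}: position {pos} on {chrom} not strictly "
                f"increasing (previous {prev[chrom]})"
            )
        prev[chrom] = pos
        if channel == CGH:
            try:
                log2.append(float(value))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric log2 value {value!r} "
                    "on a CGH probe row"
                ) from None
        else:
            if value not in GENOTYPES:
                raise ValueError(
                    f"{path}: line {lineno}: invalid genotype token {value!r}"
                )
            genotype.append(value)
        table_rows.append((pid, chrom, pos, channel))
    table = pd.DataFrame(table_rows, columns=list(ProbeSet.COLUMNS))
    probes = ProbeSet(table, chrom_order=chrom_order)
    return ArraySample(
        probes,
        np.array(log2, dtype=float),
        np.array(genotype, dtype="U2"),
        patient_id=meta["patient_id"],
        tissue=meta["tissue"],
    )


# ---------------------------------------------------------------------------
# ISCN array nomenclature

_DASHES = "-–−"  # hyphen, en-dash, minus sign


class IscnParseError(ValueError):
    def __init__(self, text: str, pos: int, message: str):
        super().__init__(f"cannot parse ISCN string at position {pos}: {message} in {text!r}")
        self.pos = pos


@dataclass(frozen=True)
class IscnRecord:
    """One ``arr`` nomenclature record, e.g. arr[hg19]10q24.31(...)x3."""

    genome_build: str
    band: str
    interval: GenomicInterval
    copies: int
    hmz: bool = False

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        if self.hmz and self.copies != 2:
            raise ValueError("hmz records are copy-neutral (copies = 2)")

    @property
    def chrom(self) -> str:
        m = re.match(r"([0-9]{1,2}|[XY])", self.band)
        return m.group(1) if m else self.band


_BAND_RE = re.compile(
    r"(?P<chrom>[0-9]{1,2}|[XY])"
    r"(?P<first>[pq][0-9]+(?:\.[0-9]+)?)"
    r"(?:\s*[" + _DASHES + r"]\s*(?P<second>[pq][0-9]+(?:\.[0-9]+)?))?"
)


def parse_iscn(text: str) -> IscnRecord:
    """Parse an ISCN array-nomenclature string.

    Hyphen, en-dash and minus are accepted as separators, as are "x" and
    the multiplication sign; whitespace between tokens is tolerated.
    """

    s = text.strip()
    pos = 0

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos] in " \t\u00a0":
            pos += 1

    def expect(token: str) -> None:
        nonlocal pos
        if not s.startswith(token, pos):
            raise IscnParseError(text, pos, f"expected {token!r}")
        pos += len(token)

    def read_int() -> int:
        nonlocal pos
        m = re.compile(r"[0-9][0-9,]*").match(s, pos)
        if not m:
            raise IscnParseError(text, pos, "expected an integer")
        pos = m.end()
        return int(m.group(0).replace(",", ""))

    expect("arr")
    expect("[")
    close = s.find("]", pos)
    if close < 0:
        raise IscnParseError(text, pos, "unterminated genome build")
    build = s[pos:close]
    pos = close + 1
    skip_ws()
    m = _BAND_RE.match(s, pos)
    if not m:
        raise IscnParseError(text, pos, "expected a cytoband label")
    chrom = m.group("chrom")
    band = m.group(0).replace(" ", "")
    pos = m.end()
    skip_ws()
    expect("(")
    skip_ws()
    start = read_int()
    skip_ws()
    if pos >= len(s) or s[pos] not in _DASHES:
        raise IscnParseError(text, pos, "expected a dash between coordinates")
    pos += 1
    skip_ws()
    end = read_int()
    skip_ws()
    expect(")")
    skip_ws()
    if pos >= len(s) or s[pos] not in "x×":
        raise IscnParseError(text, pos, "expected x or the multiplication sign")
    pos += 1
    skip_ws()
    copies = read_int()
    skip_ws()
    hmz = False
    if s.startswith("hmz", pos):
        hmz = True
        pos += 3
    skip_ws()
    if pos != len(s):
        raise IscnParseError(text, pos, "trailing characters")
    return IscnRecord(build, band, GenomicInterval(chrom, start, end), copies, hmz)


def _strip_chr(name: str) -> str:
    return name[3:] if name.startswith("chr") else name


def format_iscn(call, cytobands: pd.DataFrame | None = None, build: str = "hg19") -> str:
    """Format a call as ISCN array nomenclature.

    For :class:`IscnRecord` inputs the stored band is reused; for CNV and
    cn-LOH calls the band label is looked up in a UCSC-style cytoband
    table, joining first-last with a hyphen when the interval spans
    several bands.
    """

    if isinstance(call, IscnRecord):
        iv = call.interval
        band = call.band
        copies = call.copies
        hmz = call.hmz
        build = call.genome_build
    else:
        iv = call.interval
        hmz = isinstance(call, CnLohCall)
        copies = 2 if hmz else call.copies
        if cytobands is None:
            raise ValueError("a cytoband table is required to format calls")
        sub = cytobands[cytobands["chrom"] == iv.chrom]
        if sub.empty:
            raise ValueError(f"chromosome {iv.chrom} absent from cytoband table")
        hit = sub[(sub["start"] <= iv.end) & (sub["end"] >= iv.start)]
        if hit.empty:
            raise ValueError(f"interval {iv} beyond cytoband coverage")
        names = hit.sort_values("start")["name"].tolist()
        chrom_label = _strip_chr(iv.chrom)
        band = (
            f"{chrom_label}{names[0]}"
            if names[0] == names[-1]
            else f"{chrom_label}{names[0]}-{names[-1]}"
        )
    suffix = " hmz" if hmz else ""
    return f"arr[{build}]{band}({iv.start}-{iv.end})x{copies}{suffix}"


def read_cytobands(path) -> pd.DataFrame:
    """UCSC cytoBand format (5 columns, 0-based half-open) -> 1-based table."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "stain"],
        comment="#",
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


# ---------------------------------------------------------------------------
# region databases


@dataclass(frozen=True)
class Region:
    interval: GenomicInterval
    name: str = ""


class RegionIndex:
    """Interval index over genomic regions supporting overlap queries."""

    def __init__(self, regions):
        self.regions: list[Region] = list(regions)
        self._trees: dict[str, IntervalTree] = {}
        for r in self.regions:
            iv = r.interval
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            # intervaltree is half-open; shift the inclusive end by one
            tree.addi(iv.start, iv.end + 1, r)

    def __len__(self) -> int:
        return len(self.regions)

    def query(self, interval: GenomicInterval) -> list[Region]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end + 1)
        return sorted((h.data for h in hits), key=lambda r: (r.interval.start, r.interval.end))


def _detect_convention(path) -> str:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#coords="):
        value = first.split("=", 1)[1].strip().lower()
        if value in ("bed", "0-based", "0-based-half-open"):
            return "bed"
        if value in ("1-based", "1-based-inclusive"):
            return "one"
        raise ValueError(f"{path}: undeclared/unknown coordinate convention {value!r}")
    if str(path).endswith(".bed"):
        return "bed"
    raise ValueError(
        f"{path}: coordinate convention undeclared (use a .bed extension or a "
        "#coords= header line)"
    )


def read_region_db(path, kind: str):
    """Load a region database (``dgv``/``genes``) or GMT ``genesets`` file.

    BED files (0-based half-open) are converted to the internal 1-based
    inclusive convention on read.
    """

    if kind == "genesets":
        return read_gmt(path)
    if kind not in ("dgv", "genes"):
        raise ValueError(f"unknown region database kind {kind!r}")
    convention = _detect_convention(path)
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\s+", line)
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            if convention == "bed":
                start += 1
            regions.append(Region(GenomicInterval(chrom, start, end), name))
    return RegionIndex(regions)


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "."] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# BED output

def _call_name(call) -> str:
    if isinstance(call, CnLohCall):
        return "hmz"
    return f"{call.state}:{call.copies}:{'+'.join(sorted(call.provenance)) or 'NA'}"


def write_calls_bed(calls, path) -> None:
    """Calls as BED (1-based inclusive -> 0-based half-open on write)."""
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            score = getattr(c, "score", None)
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{_call_name(c)}\t"
                f"{0 if score is None else round(score, 3)}\n"
            )


def write_truth_bed(truth, path) -> None:
    """Truth manifest: name column is kind:copies:tissues."""
    with open(path, "w") as fh:
        for patient_id, e in truth:
            name = f"{e.kind}:{e.copies}:{'+'.join(sorted(e.tissues))}"
            fh.write(
                f"{e.chrom}\t{e.start - 1}\t{e.end}\t{name}\t0\t{patient_id}\n"
            )
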