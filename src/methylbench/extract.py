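"""Methylation extraction: non-conversion filtering, deduplication, pileup,
weighted levels and organelle background estimation.

The extraction contract mirrors a BSMAP-style caller: a site's methylation
level is the number of methylated-C observations over the total C+T
observations, kept per cytosine (CG counts are never pooled across the
palindromic pair here; symmetric analyses pair strands downstream).

Reads carrying three or more consecutive methylated CHH calls are treated
as unconverted molecules and removed before anything else: plant CHH sites
are rarely methylated above ~10%, so under independent per-site methylation
at p = 0.1 a run of three methylated CHHs has probability p³ = 0.1%, and the
filter discards almost exclusively conversion failures.  "Consecutive" means
consecutive CHH sites along the read, regardless of interleaved CG/CHG sites
or non-cytosine bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError, MethylbenchError, ParseError
from .genome import (
    CONTEXTS,
    CTX_CHH,
    ContextMap,
    Genome,
    NAME_TO_CODE,
)
from .simulate import ReadCallRecord

_M, _U, _DOT = ord("M"), ord("U"), ord(".")


class SiteCounts:
    """Per-site (methylated, unmethylated) observation counts.

    ``meth[contig]`` and ``unmeth[contig]`` are ``(2, L)`` uint32 arrays
    (row 0 plus strand, row 1 minus strand) aligned to the context map that
    produced them.
    """

    def __init__(self, context_map: ContextMap):
        self.context_map = context_map
        self.meth: dict[str, np.ndarray] = {}
        self.unmeth: dict[str, np.ndarray] = {}
        for contig, codes in context_map.codes.items():
            self.meth[contig] = np.zeros(codes.shape, dtype=np.uint32)
            self.unmeth[contig] = np.zeros(codes.shape, dtype=np.uint32)
        self.n_undef_calls = 0  # M/U calls dropped at UNDEF-context sites

    @property
    def contigs(self) -> list[str]:
        return list(self.meth)

    def coverage(self, contig: str) -> np.ndarray:
        return self.meth[contig] + self.unmeth[contig]

    def total_calls(self) -> int:
        return int(sum(m.sum() + u.sum() for m, u in zip(self.meth.values(), self.unmeth.values())))

    def compatible_with(self, other: "SiteCounts") -> bool:
        if set(self.meth) != set(other.meth):
            return False
        return all(self.meth[c].shape == other.meth[c].shape for c in self.meth)


@dataclass
class QcSummary:
    """Read-accounting summary of one extraction run."""

    reads_in: int = 0
    reads_filtered_nonconversion: int = 0
    reads_deduplicated: int = 0  # removed as positional duplicates
    duplication_rate: float | None = None
    filter_rate: float | None = None
    n_undef_calls_dropped: int = 0
    background: dict[str, float | None] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "reads_filtered_nonconversion": self.reads_filtered_nonconversion,
            "reads_deduplicated": self.reads_deduplicated,
            "duplication_rate": self.duplication_rate,
            "filter_rate": self.filter_rate,
            "n_undef_calls_dropped": self.n_undef_calls_dropped,
            "background": dict(self.background),
        }


# ---------------------------------------------------------------------------
# Filtering and deduplication
# ---------------------------------------------------------------------------

def nonconversion_filter(
    record: ReadCallRecord, context_map: ContextMap, max_run: int = 2
) -> bool:
    """True to keep the read, False to discard it as unconverted.

    Discards when more than ``max_run`` consecutive CHH-context sites of the
    read (scanned in genomic order, skipping CG/CHG sites) are all called
    methylated; an unmethylated or uncalled CHH site breaks the run.
    """
    codes = context_map.contig_codes(record.contig, record.strand)
    span = codes[record.start : record.start + len(record.calls)]
    calls = np.frombuffer(record.calls.encode("ascii"), dtype=np.uint8)
    chh_calls = calls[span == CTX_CHH]
    run = 0
    for c in chh_calls:
        run = run + 1 if c == _M else 0
        if run > max_run:
            return False
    return True


def filter_nonconversion(
    records: Sequence[ReadCallRecord], context_map: ContextMap, max_run: int = 2
) -> tuple[list[ReadCallRecord], int]:
    kept = [r for r in records if nonconversion_filter(r, context_map, max_run)]
    return kept, len(records) - len(kept)


def expected_run_probability(p: float, k: int) -> float:
    """Probability that k consecutive CHH sites are all methylated under
    independent per-site methylation with probability p (the analytic bound
    behind the non-conversion filter)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p={p} outside [0,1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return p**k


@lru_cache(maxsize=4096)
def expected_discard_probability(p: float, n: int, k: int = 3) -> float:
    """Probability that n independent Bernoulli(p) CHH calls contain at least
    one run of k successes (the expected per-read discard rate of the
    non-conversion filter on converted reads covering n CHH sites).

    Standard run-probability recursion: q(n) = P(no run of k in n trials),
    q(n) = q(n-1) - p^k (1-p) q(n-1-k) for n > k, with q(n) = 1 for n < k
    and q(k) = 1 - p^k.
    """
    if n < k:
        return 0.0
    q = [1.0] * (n + 1)
    q[k] = 1.0 - p**k
    for m in range(k + 1, n + 1):
        q[m] = q[m - 1] - (p**k) * (1.0 - p) * q[m - 1 - k]
    return 1.0 - q[n]


def deduplicate(
    records: Sequence[ReadCallRecord],
) -> tuple[list[ReadCallRecord], float | None]:
    """Collapse positional duplicates, keeping the first record for each
    (contig, start, strand).  Returns the kept records and the duplication
    rate (removed / input), ``None`` when the input is empty."""
    if not records:
        return [], None
    seen: set[tuple[str, int, str]] = set()
    kept: list[ReadCallRecord] = []
    for rec in records:
        key = (rec.contig, rec.start, rec.strand)
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    return kept, (len(records) - len(kept)) / len(records)


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

def pileup_counts(
    records: Sequence[ReadCallRecord], context_map: ContextMap
) -> SiteCounts:
    """Accumulate per-site M/U counts from (already filtered, deduplicated)
    records.  Calls at UNDEF-context cytosines are dropped and tallied on
    ``SiteCounts.n_undef_calls``; a call at a non-cytosine position or a read
    hanging off the contig end violates the record contract and raises."""
    counts = SiteCounts(context_map)
    # group call positions per (contig, strand-row) for one add.at pass each
    pos_acc: dict[tuple[str, int], list[np.ndarray]] = {}
    m_acc: dict[tuple[str, int], list[np.ndarray]] = {}
    for rec in records:
        codes = context_map.contig_codes(rec.contig, rec.strand)
        if rec.start < 0 or rec.start + len(rec.calls) > codes.size:
            raise ContractError(
                f"read at {rec.contig}:{rec.start} extends past the contig end"
            )
        calls = np.frombuffer(rec.calls.encode("ascii"), dtype=np.uint8)
        called = calls != _DOT
        span = codes[rec.start : rec.start + calls.size]
        if (called & (span == 0)).any():
            raise ContractError(
                f"read {rec.molecule_id} at {rec.contig}:{rec.start} calls a "
                "non-cytosine position"
            )
        undef = called & (span == NAME_TO_CODE["UNDEF"])
        counts.n_undef_calls += int(undef.sum())
        use = called & ~undef
        if not use.any():
            continue
        key = (rec.contig, 0 if rec.strand == "+" else 1)
        pos_acc.setdefault(key, []).append(rec.start + np.flatnonzero(use))
        m_acc.setdefault(key, []).append(calls[use] == _M)
    for (contig, row), pos_lists in pos_acc.items():
        pos = np.concatenate(pos_lists)
        is_m = np.concatenate(m_acc[(contig, row)])
        np.add.at(counts.meth[contig][row], pos[is_m], 1)
        np.add.at(counts.unmeth[contig][row], pos[~is_m], 1)
    return counts


def process_reads(
    records: Sequence[ReadCallRecord],
    context_map: ContextMap,
    genome: Genome | None = None,
    max_run: int = 2,
) -> tuple[SiteCounts, QcSummary]:
    """Full extraction pipeline: non-conversion filter, then positional
    deduplication, then pileup; background is estimated when a genome with an
    organelle-control contig is supplied."""
    qc = QcSummary(reads_in=len(records))
    kept, n_filtered = filter_nonconversion(records, context_map, max_run)
    qc.reads_filtered_nonconversion = n_filtered
    qc.filter_rate = n_filtered / len(records) if records else None
    kept, dup_rate = deduplicate(kept)
    qc.reads_deduplicated = (qc.reads_in - n_filtered) - len(kept)
    qc.duplication_rate = dup_rate
    counts = pileup_counts(kept, context_map)
    qc.n_undef_calls_dropped = counts.n_undef_calls
    if genome is not None and genome.organelle_contigs:
        qc.background = background_level(counts, genome)
    return counts, qc


# ---------------------------------------------------------------------------
# Levels
# ---------------------------------------------------------------------------

def weighted_level(
    counts: SiteCounts,
    context: str,
    region: tuple[str, int, int] | None = None,
    min_coverage: int = 1,
    exclude_contigs: Iterable[str] = (),
) -> float | None:
    """Weighted methylation level: Σ n_meth / Σ (n_meth + n_unmeth) over the
    sites of ``context`` (both strands) in ``region`` (whole genome when
    None) with coverage ≥ ``min_coverage``.  ``None`` when no site qualifies.
    """
    code = NAME_TO_CODE[context]
    excl = set(exclude_contigs)
    num = den = 0
    if region is None:
        spans = [(c, 0, None) for c in counts.contigs if c not in excl]
    else:
        contig, start, end = region
        if contig not in counts.meth:
            raise ContractError(f"region names unknown contig {contig!r}")
        spans = [(contig, start, end)]
    for contig, start, end in spans:
        m = counts.meth[contig][:, start:end]
        u = counts.unmeth[contig][:, start:end]
        mask = counts.context_map.codes[contig][:, start:end] == code
        cov = m + u
        mask &= cov >= min_coverage
        num += int(m[mask].sum())
        den += int(cov[mask].sum())
    return num / den if den else None


def genome_wide_levels(
    counts: SiteCounts, genome: Genome, min_coverage: int = 1
) -> dict[str, float | None]:
    """Per-context weighted levels over nuclear contigs only (the organelle
    control is reserved for background estimation)."""
    excl = genome.organelle_contigs
    return {
        ctx: weighted_level(counts, ctx, min_coverage=min_coverage, exclude_contigs=excl)
        for ctx in CONTEXTS
    }


def background_level(counts: SiteCounts, genome: Genome) -> dict[str, float | None]:
    """Per-context weighted level on the organelle-control contig(s): the
    assay's false-positive methylation (non-conversion) rate, because the
    organelle is effectively unmethylated in vivo."""
    org = genome.organelle_contigs
    if not org:
        raise MethylbenchError(
            "background estimation needs a contig of class 'organelle_control'"
        )
    out: dict[str, float | None] = {}
    for ctx in CONTEXTS:
        num = den = 0
        for contig in org:
            m = counts.meth[contig]
            u = counts.unmeth[contig]
            mask = counts.context_map.codes[contig] == NAME_TO_CODE[ctx]
            num += int(m[mask].sum())
            den += int(m[mask].sum() + u[mask].sum())
        out[ctx] = num / den if den else None
    return out


# ---------------------------------------------------------------------------
# I/O: Bismark-style CX report and bedGraph
# ---------------------------------------------------------------------------

def write_cx_report(counts: SiteCounts, genome: Genome, path: str | Path) -> None:
    """Write per-site counts as a Bismark-style CX report: 1-based position,
    strand, methylated count, unmethylated count, context, trinucleotide.
    UNDEF-context cytosines are written with context ``Unknown`` and their
    (empty) counts, matching Bismark's handling of truncated triplets."""
    comp = str.maketrans("ACGTN", "TGCAN")
    with open(path, "w") as fh:
        for contig in counts.contigs:
            seq = genome.contigs[contig]
            codes = counts.context_map.codes[contig]
            for row, strand in ((0, "+"), (1, "-")):
                positions = np.flatnonzero(codes[row] > 0)
                for pos in positions:
                    p = int(pos)
                    code = int(codes[row][p])
                    name = {1: "CG", 2: "CHG", 3: "CHH", 4: "Unknown"}[code]
                    if strand == "+":
                        tri = seq[p : p + 3].ljust(3, "N")
                    else:
                        tri = seq[max(p - 2, 0) : p + 1][::-1].translate(comp).ljust(3, "N")
                    m = int(counts.meth[contig][row][p])
                    u = int(counts.unmeth[contig][row][p])
                    fh.write(f"{contig}\t{p + 1}\t{strand}\t{m}\t{u}\t{name}\t{tri}\n")


def read_cx_report(path: str | Path, context_map: ContextMap) -> SiteCounts:
    counts = SiteCounts(context_map)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError("CX report line has fewer than 6 columns", str(path), lineno)
            contig, pos1, strand, m, u = parts[0], parts[1], parts[2], parts[3], parts[4]
            try:
                p = int(pos1) - 1
                m_i, u_i = int(m), int(u)
            except ValueError as exc:
                raise ParseError(f"bad CX report field: {exc}", str(path), lineno)
            if contig not in context_map.codes:
                raise ParseError(f"unknown contig {contig!r}", str(path), lineno)
            row = 0 if strand == "+" else 1
            counts.meth[contig][row][p] = m_i
            counts.unmeth[contig][row][p] = u_i
    return counts


def write_bedgraph(
    counts: SiteCounts, path: str | Path, context: str, min_coverage: int = 1
) -> None:
    """Write per-site methylation percentages of one context as bedGraph
    (0-based half-open single-base intervals)."""
    code = NAME_TO_CODE[context]
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="methylation_{context}"\n')
        for contig in counts.contigs:
            codes = counts.context_map.codes[contig]
            m = counts.meth[contig]
            u = counts.unmeth[contig]
            cov = m + u
            sel = (codes == code) & (cov >= min_coverage)
            rows, positions = np.nonzero(sel)
            order = np.argsort(positions, kind="stable")
            for row, p in zip(rows[order], positions[order]):
                pct = 100.0 * m[row][p] / cov[row][p]
                fh.write(f"{contig}\t{p}\t{p + 1}\t{pct:.6g}\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    out: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError("bedGraph line has fewer than 4 columns", str(path), lineno)
            try:
                out.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ParseError(f"bad bedGraph field: {exc}", str(path), lineno)
    return out
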