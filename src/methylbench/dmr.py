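"""Differentially methylated region (DMR) calling and annotation enrichment.

Two samples are compared in sliding windows: counts of one context are
pooled per window and per sample into a 2×2 table (methylated / unmethylated
× sample), tested with a two-sided Fisher's exact test, and windows passing
a raw p-value cutoff together with a context-specific minimum methylation
difference are merged into DMRs.  The published cutoffs this reimplements
are P < 0.01 with minimum differences of 0.1 / 0.05 / 0.02 (CG / CHG / CHH)
for cross-protocol comparisons and 0.4 / 0.2 / 0.1 for cross-tissue
comparisons.  No multiple-testing correction is applied by default; a
Benjamini–Hochberg q-value option exists.

Enrichment of DMRs over annotation classes is measured against shuffled
controls: equal-length regions placed uniformly at random, the expected
overlap level being 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .errors import ConfigurationError, ContractError
from .extract import SiteCounts
from .genome import Feature, Genome, NAME_TO_CODE

#: published minimum-difference presets, per context
DIFF_PRESETS: dict[str, dict[str, float]] = {
    "protocol_compare": {"CG": 0.1, "CHG": 0.05, "CHH": 0.02},
    "tissue_compare": {"CG": 0.4, "CHG": 0.2, "CHH": 0.1},
}

DEFAULT_P_MAX = 0.01
DEFAULT_WINDOW = 100
DEFAULT_STEP = 50
DEFAULT_MIN_SITES = 4
DEFAULT_MIN_COV = 4


@dataclass(frozen=True)
class WindowStat:
    """One tested window (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    context: str
    n_sites: int
    meth_a: int
    unmeth_a: int
    meth_b: int
    unmeth_b: int
    level_a: float
    level_b: float
    p_value: float

    @property
    def diff(self) -> float:
        return self.level_a - self.level_b


@dataclass(frozen=True)
class DMR:
    """A merged run of significant same-direction windows."""

    contig: str
    start: int
    end: int
    context: str
    direction: str  # "hyper_in_a" | "hyper_in_b"
    level_a: float  # mean over merged windows
    level_b: float
    min_p: float
    n_windows: int

    @property
    def diff(self) -> float:
        return self.level_a - self.level_b

    @property
    def length(self) -> int:
        return self.end - self.start


def fisher_exact_two_sided(
    n_meth_a: int, n_unmeth_a: int, n_meth_b: int, n_unmeth_b: int
) -> float:
    """Two-sided Fisher's exact p for the 2×2 table [[a, b], [c, d]].

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities that do not exceed the observed table's probability
    (with a small relative tolerance against floating-point ties).
    An all-zero table has no information and returns 1 by convention.
    """
    a, b, c, d = n_meth_a, n_unmeth_a, n_meth_b, n_unmeth_b
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    total = a + b + c + d
    if total == 0:
        return 1.0
    row_a = a + b
    col_m = a + c
    k = np.arange(max(0, row_a - (total - col_m)), min(row_a, col_m) + 1)
    pmf = hypergeom.pmf(k, total, col_m, row_a)
    p_obs = hypergeom.pmf(a, total, col_m, row_a)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return min(p, 1.0)


def _context_site_arrays(
    counts: SiteCounts, contig: str, context: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted positions of one context on one contig (both strands pooled)
    with their meth/unmeth counts."""
    code = NAME_TO_CODE[context]
    codes = counts.context_map.codes[contig]
    rows, pos = np.nonzero(codes == code)
    order = np.argsort(pos, kind="stable")
    rows, pos = rows[order], pos[order]
    m = counts.meth[contig][rows, pos].astype(np.int64)
    u = counts.unmeth[contig][rows, pos].astype(np.int64)
    return pos, m, u


def scan_windows(
    counts_a: SiteCounts,
    counts_b: SiteCounts,
    context: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_sites: int = DEFAULT_MIN_SITES,
    min_cov: int = DEFAULT_MIN_COV,
    exclude_contigs: Iterable[str] = (),
    compute_p: bool = True,
) -> list[WindowStat]:
    """Slide windows over every contig, pool counts of ``context`` per window
    and per sample, and keep windows with at least ``min_sites`` context
    sites and pooled coverage ≥ ``min_cov`` in each sample."""
    if not counts_a.compatible_with(counts_b):
        raise ContractError("the two samples are not on the same genome")
    out: list[WindowStat] = []
    excl = set(exclude_contigs)
    for contig in counts_a.contigs:
        if contig in excl:
            continue
        L = counts_a.context_map.codes[contig].shape[1]
        pos, ma, ua = _context_site_arrays(counts_a, contig, context)
        _, mb, ub = _context_site_arrays(counts_b, contig, context)
        if pos.size == 0:
            continue
        cm_a = np.concatenate([[0], np.cumsum(ma)])
        cu_a = np.concatenate([[0], np.cumsum(ua)])
        cm_b = np.concatenate([[0], np.cumsum(mb)])
        cu_b = np.concatenate([[0], np.cumsum(ub)])
        starts = np.arange(0, max(L - window + step, 1), step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, np.minimum(starts + window, L), side="left")
        n_sites = hi - lo
        meth_a = cm_a[hi] - cm_a[lo]
        unmeth_a = cu_a[hi] - cu_a[lo]
        meth_b = cm_b[hi] - cm_b[lo]
        unmeth_b = cu_b[hi] - cu_b[lo]
        cov_a = meth_a + unmeth_a
        cov_b = meth_b + unmeth_b
        keep = (n_sites >= min_sites) & (cov_a >= min_cov) & (cov_b >= min_cov)
        for i in np.flatnonzero(keep):
            la = meth_a[i] / cov_a[i]
            lb = meth_b[i] / cov_b[i]
            p = (
                fisher_exact_two_sided(
                    int(meth_a[i]), int(unmeth_a[i]), int(meth_b[i]), int(unmeth_b[i])
                )
                if compute_p
                else float("nan")
            )
            out.append(
                WindowStat(
                    contig,
                    int(starts[i]),
                    int(min(starts[i] + window, L)),
                    context,
                    int(n_sites[i]),
                    int(meth_a[i]),
                    int(unmeth_a[i]),
                    int(meth_b[i]),
                    int(unmeth_b[i]),
                    la,
                    lb,
                    p,
                )
            )
    return out


def call_dmrs(
    counts_a: SiteCounts,
    counts_b: SiteCounts,
    context: str,
    p_max: float = DEFAULT_P_MAX,
    min_diff: float | None = None,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_sites: int = DEFAULT_MIN_SITES,
    min_cov: int = DEFAULT_MIN_COV,
    preset: str | None = None,
    exclude_contigs: Iterable[str] = (),
    fdr: float | None = None,
) -> list[DMR]:
    """Call DMRs between two samples for one context.

    Windows passing the coverage filters, ``|diff| >= min_diff`` and
    ``p < p_max`` are merged when overlapping or abutting with the same sign
    of difference; opposite directions never merge.  ``preset`` selects one
    of the published minimum-difference sets (``protocol_compare`` or
    ``tissue_compare``).  When ``fdr`` is set, Benjamini–Hochberg q-values
    over all scanned windows replace the raw p cutoff.
    """
    if preset is not None:
        if preset not in DIFF_PRESETS:
            raise ConfigurationError(f"unknown preset {preset!r}")
        min_diff = DIFF_PRESETS[preset][context]
    if min_diff is None:
        raise ConfigurationError("min_diff (or a preset) is required")
    # p-values are only needed for windows that survive the difference
    # filter, which keeps the Fisher evaluations to the candidate set
    wins = scan_windows(
        counts_a,
        counts_b,
        context,
        window,
        step,
        min_sites,
        min_cov,
        exclude_contigs,
        compute_p=False,
    )
    cands = [w for w in wins if abs(w.diff) >= min_diff]
    stats = [
        WindowStat(
            w.contig,
            w.start,
            w.end,
            w.context,
            w.n_sites,
            w.meth_a,
            w.unmeth_a,
            w.meth_b,
            w.unmeth_b,
            w.level_a,
            w.level_b,
            fisher_exact_two_sided(w.meth_a, w.unmeth_a, w.meth_b, w.unmeth_b),
        )
        for w in cands
    ]
    if fdr is not None:
        stats = _bh_filter(stats, fdr)
        sig = stats
    else:
        sig = [w for w in stats if w.p_value < p_max]
    sig.sort(key=lambda w: (w.contig, w.start))
    return _merge_windows(sig, context)


def _bh_filter(wins: list[WindowStat], fdr: float) -> list[WindowStat]:
    if not wins:
        return []
    p = np.array([w.p_value for w in wins])
    order = np.argsort(p)
    m = p.size
    thresh = fdr * (np.arange(1, m + 1) / m)
    passed = p[order] <= thresh
    k = np.max(np.flatnonzero(passed)) + 1 if passed.any() else 0
    keep_idx = set(order[:k].tolist())
    return [w for i, w in enumerate(wins) if i in keep_idx]


def _merge_windows(sig: list[WindowStat], context: str) -> list[DMR]:
    dmrs: list[DMR] = []
    cur: list[WindowStat] = []

    def flush():
        if not cur:
            return
        dmrs.append(
            DMR(
                contig=cur[0].contig,
                start=cur[0].start,
                end=max(w.end for w in cur),
                context=context,
                direction="hyper_in_a" if cur[0].diff > 0 else "hyper_in_b",
                level_a=float(np.mean([w.level_a for w in cur])),
                level_b=float(np.mean([w.level_b for w in cur])),
                min_p=min(w.p_value for w in cur),
                n_windows=len(cur),
            )
        )

    for w in sig:
        if cur and (
            w.contig == cur[0].contig
            and w.start <= max(x.end for x in cur)
            and (w.diff > 0) == (cur[0].diff > 0)
        ):
            cur.append(w)
        else:
            flush()
            cur = [w]
    flush()
    return dmrs


# ---------------------------------------------------------------------------
# Shuffled controls and enrichment
# ---------------------------------------------------------------------------

def shuffle_control(
    regions: Sequence[tuple[str, int, int]] | Sequence[DMR],
    genome: Genome,
    seed: int = 0,
    contigs: Sequence[str] | None = None,
) -> list[tuple[str, int, int]]:
    """Place regions of the same lengths uniformly at random in the genome
    (bedtools-shuffle style): a region of length ℓ lands on a contig with
    probability proportional to its number of valid starts, never crossing a
    contig end.  Overlap with the source regions is allowed."""
    lengths = [
        (r.end - r.start) if isinstance(r, DMR) else (r[2] - r[1]) for r in regions
    ]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5FF1E]))
    names = list(contigs) if contigs is not None else list(genome.contigs)
    sizes = np.array([genome.contig_length(c) for c in names], dtype=np.int64)
    out: list[tuple[str, int, int]] = []
    for ell in lengths:
        valid = sizes - ell + 1
        if (valid <= 0).all():
            raise ConfigurationError(f"region of length {ell} fits no contig")
        w = np.clip(valid, 0, None).astype(np.float64)
        ci = int(rng.choice(len(names), p=w / w.sum()))
        start = int(rng.integers(0, valid[ci]))
        out.append((names[ci], start, start + ell))
    return out


def _overlap_fraction(
    regions: Sequence[tuple[str, int, int]], features: Sequence[Feature]
) -> float:
    """Fraction of regions intersecting (≥1 bp) at least one feature."""
    if not regions:
        return float("nan")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append((f.start, f.end))
    idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, ivals in by_contig.items():
        ivals.sort()
        starts = np.array([s for s, _ in ivals])
        # running max of ends lets a single bisect answer "any interval
        # starting at or before x that still reaches past y?"
        ends = np.maximum.accumulate(np.array([e for _, e in ivals]))
        idx[contig] = (starts, ends)
    hits = 0
    for contig, start, end in regions:
        if contig not in idx:
            continue
        starts, ends = idx[contig]
        j = int(np.searchsorted(starts, end, side="left"))
        if j > 0 and ends[j - 1] > start:
            hits += 1
    return hits / len(regions)


def annotate_enrichment(
    dmrs: Sequence[DMR],
    features_by_class: dict[str, Sequence[Feature]],
    genome: Genome,
    n_shuffles: int = 20,
    seed: int = 0,
) -> dict[str, float]:
    """Per-class enrichment: observed fraction of DMRs touching the class
    divided by the mean fraction over ``n_shuffles`` shuffled controls
    (expected level 1 under a uniform null)."""
    if not dmrs:
        raise ConfigurationError("annotate_enrichment needs a non-empty DMR list")
    if n_shuffles < 1:
        raise ConfigurationError("n_shuffles must be >= 1")
    regions = [(d.contig, d.start, d.end) for d in dmrs]
    shuffled = [
        shuffle_control(regions, genome, seed=seed + 1000 * (i + 1))
        for i in range(n_shuffles)
    ]
    out: dict[str, float] = {}
    for cls, feats in features_by_class.items():
        obs = _overlap_fraction(regions, feats)
        exp = float(np.mean([_overlap_fraction(s, feats) for s in shuffled]))
        if exp == 0.0:
            out[cls] = float("inf") if obs > 0 else float("nan")
        else:
            out[cls] = obs / exp
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_dmrs_bed(dmrs: Sequence[DMR], path: str | Path) -> None:
    """BED6+ output: name = context:direction, score = -log10(min p), then
    level_a, level_b, diff and n_windows as extra columns."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = -np.log10(max(d.min_p, 1e-300))
            fh.write(
                f"{d.contig}\t{d.start}\t{d.end}\t{d.context}:{d.direction}\t"
                f"{score:.3f}\t.\t{d.level_a:.6g}\t{d.level_b:.6g}\t"
                f"{d.diff:.6g}\t{d.n_windows}\n"
            )


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int]]:
    from .genome import read_bed

    return [(f.contig, f.start, f.end) for f in read_bed(path)]


def write_regions_bed(regions: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end in regions:
            fh.write(f"{contig}\t{start}\t{end}\n")
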