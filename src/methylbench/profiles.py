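"""Metaplots, chromosomal profiles and coverage/composition bias diagnostics.

These are the comparison views used to contrast conversion protocols:

* gene/TE metaplots — 20 proportionally sized body bins plus fixed 50-bp
  bins over 1-kb flanks, pooled across features (minus-strand features are
  orientation-flipped);
* chromosomal methylation profiles in fixed 100-kb bins;
* normalized coverage by GC content of 400-bp bins and by reference
  dinucleotide (Picard CollectGcBiasMetrics / Bismark bam2nuc style),
  normalization being total read bases over genome length;
* methylation difference between two samples as a function of per-400-bp-bin
  methylated-cytosine density; for CG the analysis keeps only bins with an
  even number of CG sites, because CG methylation is strand-symmetric and an
  odd count means the bin splits a palindromic pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError
from .extract import SiteCounts
from .genome import Feature, Genome, NAME_TO_CODE, sequence_array
from .simulate import ReadCallRecord


@dataclass
class BinProfile:
    """An ordered sequence of bins with one value each.

    ``scheme`` names the binning (``metaplot``, ``genomic-fixed``,
    ``gc-class``, ``dinucleotide``); ``n`` carries the per-bin support
    (calls, bins or bases) behind each value.  Undefined bins hold NaN.
    """

    labels: list
    values: np.ndarray
    scheme: str
    n: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin": self.labels, "value": self.values})
        if self.n.size:
            df["n"] = self.n
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dense per-contig context sums (shared helpers)
# ---------------------------------------------------------------------------

def _context_call_arrays(
    counts: SiteCounts, contig: str, context: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position meth/unmeth call totals of one context, strands summed."""
    code = NAME_TO_CODE[context]
    mask = counts.context_map.codes[contig] == code
    m = np.where(mask, counts.meth[contig], 0).sum(axis=0).astype(np.int64)
    u = np.where(mask, counts.unmeth[contig], 0).sum(axis=0).astype(np.int64)
    return m, u


# ---------------------------------------------------------------------------
# Metaplot
# ---------------------------------------------------------------------------

def metaplot(
    counts: SiteCounts,
    features: Sequence[Feature],
    context: str,
    flank: int = 1000,
    body_bins: int = 20,
    flank_bin: int = 50,
) -> BinProfile:
    """Average methylation profile over features and their flanks.

    Bodies are split into ``body_bins`` proportional bins with floor-rounded
    boundaries (the rounding remainder accumulates over the later bins);
    each flank is split into ``flank // flank_bin`` fixed bins.  Counts are
    pooled across features per bin and converted to weighted levels.
    Minus-strand features are flipped so bin 0 is always the distal 5' flank.
    Features shorter than ``body_bins`` bp are skipped with a warning.
    """
    if not features:
        raise ConfigurationError("metaplot needs at least one feature")
    n_flank = flank // flank_bin
    total_bins = body_bins + 2 * n_flank
    meth = np.zeros(total_bins, dtype=np.int64)
    unmeth = np.zeros(total_bins, dtype=np.int64)
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for feat in features:
        if feat.length < body_bins:
            warnings.warn(
                f"feature {feat.id!r} shorter than {body_bins} bp skipped in metaplot"
            )
            continue
        if feat.contig not in cache:
            m, u = _context_call_arrays(counts, feat.contig, context)
            cache[feat.contig] = (np.concatenate([[0], np.cumsum(m)]),
                                  np.concatenate([[0], np.cumsum(u)]))
        cm, cu = cache[feat.contig]
        L = cm.size - 1

        def add(bin_index: int, s: int, e: int) -> None:
            s, e = max(s, 0), min(e, L)
            if s < e:
                meth[bin_index] += cm[e] - cm[s]
                unmeth[bin_index] += cu[e] - cu[s]

        flipped = feat.strand == "-"
        # 5' flank (upstream), body, 3' flank in feature orientation
        for j in range(n_flank):
            if not flipped:
                s = feat.start - flank + j * flank_bin
                add(j, s, s + flank_bin)
            else:
                s = feat.end + flank - (j + 1) * flank_bin
                add(j, s, s + flank_bin)
        bounds = [feat.start + (i * feat.length) // body_bins for i in range(body_bins + 1)]
        for i in range(body_bins):
            k = n_flank + (i if not flipped else body_bins - 1 - i)
            add(k, bounds[i], bounds[i + 1])
        for j in range(n_flank):
            if not flipped:
                s = feat.end + j * flank_bin
                add(n_flank + body_bins + j, s, s + flank_bin)
            else:
                s = feat.start - (j + 1) * flank_bin
                add(n_flank + body_bins + j, s, s + flank_bin)

    cov = meth + unmeth
    with np.errstate(invalid="ignore"):
        values = np.where(cov > 0, meth / np.maximum(cov, 1), np.nan)
    labels = (
        [f"up{(n_flank - j) * flank_bin}" for j in range(n_flank)]
        + [f"body{i + 1}" for i in range(body_bins)]
        + [f"down{(j + 1) * flank_bin}" for j in range(n_flank)]
    )
    return BinProfile(labels, values, "metaplot", cov.astype(float))


# ---------------------------------------------------------------------------
# Chromosomal profile
# ---------------------------------------------------------------------------

def chromosome_profile(
    counts: SiteCounts, context: str, bin_size: int = 100_000
) -> BinProfile:
    """Weighted methylation level in consecutive fixed genomic bins, per
    contig; the final partial bin is kept and labeled by its real interval.
    Zero-coverage bins are preserved as NaN."""
    labels: list[tuple[str, int, int]] = []
    values: list[float] = []
    support: list[float] = []
    for contig in counts.contigs:
        m, u = _context_call_arrays(counts, contig, context)
        L = m.size
        cm = np.concatenate([[0], np.cumsum(m)])
        cu = np.concatenate([[0], np.cumsum(u)])
        for s in range(0, L, bin_size):
            e = min(s + bin_size, L)
            mm = cm[e] - cm[s]
            uu = cu[e] - cu[s]
            labels.append((contig, s, e))
            values.append(mm / (mm + uu) if (mm + uu) > 0 else np.nan)
            support.append(float(mm + uu))
    return BinProfile(labels, np.array(values), "genomic-fixed", np.array(support))


# ---------------------------------------------------------------------------
# Coverage diagnostics
# ---------------------------------------------------------------------------

def _depth_array(records: Sequence[ReadCallRecord], genome: Genome) -> dict[str, np.ndarray]:
    """Per-base read depth from read footprints (difference-array trick)."""
    diffs = {c: np.zeros(len(genome.contigs[c]) + 1, dtype=np.int64) for c in genome.contigs}
    for rec in records:
        d = diffs.get(rec.contig)
        if d is None:
            raise ContractError(f"read names unknown contig {rec.contig!r}")
        end = rec.start + len(rec.calls)
        if rec.start < 0 or end > d.size - 1:
            raise ContractError(f"read at {rec.contig}:{rec.start} off contig end")
        d[rec.start] += 1
        d[end] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diffs.items()}


def coverage_by_gc(
    records: Sequence[ReadCallRecord],
    genome: Genome,
    bin_size: int = 400,
    min_bins: int = 5,
) -> BinProfile:
    """Normalized coverage of fixed-size genomic bins grouped by integer GC
    percentage.  Per bin: mean per-base depth and reference GC fraction
    (N bases excluded); per GC class: mean bin depth divided by the global
    expected depth (total read bases / genome length).  Classes supported by
    fewer than ``min_bins`` bins are suppressed."""
    if not records:
        raise ConfigurationError("coverage_by_gc needs a non-empty read list")
    depth = _depth_array(records, genome)
    gc_class: list[np.ndarray] = []
    bin_depth: list[np.ndarray] = []
    for contig in genome.contigs:
        seq = sequence_array(genome, contig)
        d = depth[contig]
        L = seq.size
        n_full = L // bin_size
        spans = [(i * bin_size, (i + 1) * bin_size) for i in range(n_full)]
        if L % bin_size:
            spans.append((n_full * bin_size, L))
        for s, e in spans:
            chunk = seq[s:e]
            known = chunk != ord("N")
            nk = int(known.sum())
            if nk == 0:
                continue
            gc = float(((chunk == ord("G")) | (chunk == ord("C"))).sum()) / nk
            gc_class.append(np.rint(gc * 100))
            bin_depth.append(d[s:e].mean())
    gc_arr = np.array(gc_class, dtype=int)
    dep_arr = np.array(bin_depth)
    expected = sum(len(r.calls) for r in records) / genome.total_length()
    labels, values, support = [], [], []
    for cls in np.unique(gc_arr):
        sel = gc_arr == cls
        if int(sel.sum()) < min_bins:
            continue
        labels.append(int(cls))
        values.append(float(dep_arr[sel].mean()) / expected)
        support.append(float(sel.sum()))
    return BinProfile(labels, np.array(values), "gc-class", np.array(support))


DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


def dinucleotide_coverage(
    records: Sequence[ReadCallRecord], genome: Genome
) -> dict[str, float]:
    """Observed frequency of each reference dinucleotide within read
    footprints divided by its genome-wide frequency (both on the reference
    top strand; pairs containing N are excluded)."""
    if not records:
        raise ConfigurationError("dinucleotide_coverage needs a non-empty read list")
    obs = np.zeros(16, dtype=np.float64)
    gen = np.zeros(16, dtype=np.float64)
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    # dinucleotide coverage per contig, again via a difference array: a read
    # spanning [s, e) covers dinucleotide start positions [s, e-1)
    diffs = {c: np.zeros(len(genome.contigs[c]), dtype=np.int64) for c in genome.contigs}
    for rec in records:
        e = rec.start + len(rec.calls) - 1
        diffs[rec.contig][rec.start] += 1
        if e < diffs[rec.contig].size:
            diffs[rec.contig][e] -= 1
        # else: footprint runs to the contig end; nothing to subtract
    for contig in genome.contigs:
        seq = sequence_array(genome, contig)
        if seq.size < 2:
            continue
        di = code[seq[:-1]] * 4 + code[seq[1:]]
        valid = (code[seq[:-1]] >= 0) & (code[seq[1:]] >= 0)
        cov = np.cumsum(diffs[contig])[: seq.size - 1]
        gen += np.bincount(di[valid], minlength=16)
        obs += np.bincount(di[valid], weights=cov[valid].astype(np.float64), minlength=16)
    if obs.sum() == 0:
        raise ConfigurationError("reads cover no dinucleotides")
    obs_freq = obs / obs.sum()
    gen_freq = gen / gen.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gen_freq > 0, obs_freq / gen_freq, np.nan)
    return {d: float(ratio[i]) for i, d in enumerate(DINUCLEOTIDES)}


# ---------------------------------------------------------------------------
# Methylation vs mC density
# ---------------------------------------------------------------------------

def mc_density_analysis(
    counts_a: SiteCounts,
    counts_b: SiteCounts,
    context: str,
    bin_size: int = 400,
    level_threshold: float = 0.5,
    min_site_coverage: int = 4,
    reference: str = "a",
    exclude_contigs: Sequence[str] = (),
) -> pd.DataFrame:
    """Methylation difference between two samples as a function of
    methylated-cytosine density.

    The genome is cut into fixed bins; in each bin the methylated Cs of the
    context are counted in the *reference* sample (a site counts as
    methylated when its level ≥ ``level_threshold`` at coverage ≥
    ``min_site_coverage``).  Bins are grouped by that count and each class
    reports the pooled weighted level in both samples and their difference
    (a − b).  For CG, bins with an odd number of CG sites are excluded
    (CG methylation is strand-symmetric, so a bin splitting a palindromic
    pair would distort the count).
    """
    if not counts_a.compatible_with(counts_b):
        raise ContractError("the two samples are not on the same genome")
    if reference not in ("a", "b"):
        raise ConfigurationError("reference must be 'a' or 'b'")
    code = NAME_TO_CODE[context]
    per_bin = []  # (mc_count, meth_a, cov_a, meth_b, cov_b)
    ref_counts = counts_a if reference == "a" else counts_b
    excl = set(exclude_contigs)
    for contig in counts_a.contigs:
        if contig in excl:
            continue
        codes = counts_a.context_map.codes[contig]
        mask = codes == code
        L = codes.shape[1]
        ma = np.where(mask, counts_a.meth[contig], 0).sum(axis=0)
        ua = np.where(mask, counts_a.unmeth[contig], 0).sum(axis=0)
        mb = np.where(mask, counts_b.meth[contig], 0).sum(axis=0)
        ub = np.where(mask, counts_b.unmeth[contig], 0).sum(axis=0)
        rm = np.where(mask, ref_counts.meth[contig], 0)
        ru = np.where(mask, ref_counts.unmeth[contig], 0)
        rcov = rm + ru
        with np.errstate(invalid="ignore", divide="ignore"):
            site_level = np.where(rcov > 0, rm / np.maximum(rcov, 1), 0.0)
        is_mc = mask & (rcov >= min_site_coverage) & (site_level >= level_threshold)
        n_sites_pos = mask.sum(axis=0)
        mc_pos = is_mc.sum(axis=0)
        for s in range(0, L, bin_size):
            e = min(s + bin_size, L)
            n_sites = int(n_sites_pos[s:e].sum())
            if n_sites == 0:
                continue
            if context == "CG" and n_sites % 2 == 1:
                continue
            per_bin.append(
                (
                    int(mc_pos[s:e].sum()),
                    int(ma[s:e].sum()),
                    int((ma[s:e] + ua[s:e]).sum()),
                    int(mb[s:e].sum()),
                    int((mb[s:e] + ub[s:e]).sum()),
                )
            )
    if not per_bin:
        return pd.DataFrame(
            columns=["mc_count", "n_bins", "level_a", "level_b", "difference"]
        )
    df = pd.DataFrame(per_bin, columns=["mc", "meth_a", "cov_a", "meth_b", "cov_b"])
    grouped = df.groupby("mc").agg(
        n_bins=("mc", "size"),
        meth_a=("meth_a", "sum"),
        cov_a=("cov_a", "sum"),
        meth_b=("meth_b", "sum"),
        cov_b=("cov_b", "sum"),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        level_a = grouped["meth_a"] / grouped["cov_a"]
        level_b = grouped["meth_b"] / grouped["cov_b"]
    out = pd.DataFrame(
        {
            "mc_count": grouped.index,
            "n_bins": grouped["n_bins"].to_numpy(),
            "level_a": level_a.to_numpy(),
            "level_b": level_b.to_numpy(),
            "difference": (level_a - level_b).to_numpy(),
        }
    ).reset_index(drop=True)
    return out
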