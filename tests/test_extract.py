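"""Non-conversion filtering, deduplication, pileup and level computation."""

import itertools

import numpy as np
import pytest

import methylbench as mb

from conftest import make_genome, make_record

# CHH sites on the + strand of this contig sit at fixed, known positions:
# every "CAT" triplet provides one CHH cytosine.
_CHH_SEQ = "ACATACATACATACATACATACAT"  # CHH (+) at 1, 5, 9, 13, 17, 21


@pytest.fixture(scope="module")
def chh_genome():
    g = make_genome({"c": _CHH_SEQ})
    return g, mb.build_context_map(g)


# ---------------------------------------------------------------------------
# non-conversion filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pattern,keep",
    [
        ("MMM...", False),  # three consecutive methylated CHHs → unconverted
        ("MMUMM.", True),  # longest run is 2
        ("UMMMU.", False),
        ("UUUUUU", True),
        ("......", True),  # no CHH call at all → vacuously kept
    ],
)
def test_nonconversion_filter_runs(chh_genome, pattern, keep):
    g, cmap = chh_genome
    chh_pos = [1, 5, 9, 13, 17, 21]
    calls_at = {p: c for p, c in zip(chh_pos, pattern) if c != "."}
    rec = make_record(cmap, "c", 0, "+", len(_CHH_SEQ), calls_at=calls_at)
    assert mb.nonconversion_filter(rec, cmap) is keep


def test_nonconversion_filter_ignores_interleaved_cg(chh_genome):
    """CG/CHG calls between CHH sites neither extend nor break a CHH run."""
    seq = "ACATACGACATACATA"  # CHH(+) at 1, 8, 12; CG(+) at 5
    g = make_genome({"c": seq})
    cmap = mb.build_context_map(g)
    rec = make_record(cmap, "c", 0, "+", len(seq),
                      calls_at={1: "M", 5: "U", 8: "M", 12: "M"})
    assert mb.nonconversion_filter(rec, cmap) is False  # run of 3 CHHs


def test_run_probability_examples():
    assert mb.expected_run_probability(0.10, 3) == pytest.approx(0.001)
    assert mb.expected_run_probability(0.0, 3) == 0.0
    assert mb.expected_run_probability(1.0, 3) == 1.0
    with pytest.raises(ValueError):
        mb.expected_run_probability(1.5, 3)


def test_discard_probability_matches_enumeration():
    """The run-probability recursion equals brute-force enumeration of all
    call patterns for small n."""
    p, k = 0.3, 3
    for n in range(0, 9):
        brute = 0.0
        for bits in itertools.product([0, 1], repeat=n):
            has_run = any(
                all(bits[i + j] for j in range(k)) for i in range(n - k + 1)
            )
            if has_run:
                prob = np.prod([p if b else 1 - p for b in bits])
                brute += float(prob)
        assert mb.expected_discard_probability(p, n, k) == pytest.approx(brute, abs=1e-12)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _rec(contig, start, strand, mol="m"):
    return mb.ReadCallRecord(contig, start, strand, "...", mol)


def test_deduplicate_examples():
    unique = [_rec("c", i, "+") for i in range(10)]
    kept, rate = mb.deduplicate(unique)
    assert kept == unique and rate == 0.0

    nine = [_rec("c", i, "+") for i in range(9)]
    dup = nine + [_rec("c", 0, "+", "other")]
    kept, rate = mb.deduplicate(dup)
    assert rate == pytest.approx(0.10)
    assert kept == nine  # first occurrence wins

    assert mb.deduplicate([]) == ([], None)


def test_deduplicate_idempotent():
    recs = [_rec("c", i % 3, s) for i, s in zip(range(8), "+-+-+-+-")]
    once, _ = mb.deduplicate(recs)
    twice, rate = mb.deduplicate(once)
    assert twice == once and rate == 0.0


def test_deduplicate_distinguishes_strand():
    kept, rate = mb.deduplicate([_rec("c", 5, "+"), _rec("c", 5, "-")])
    assert len(kept) == 2 and rate == 0.0


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def test_pileup_single_and_overlapping_reads(chh_genome):
    g, cmap = chh_genome
    r1 = make_record(cmap, "c", 0, "+", 8, calls_at={1: "M"})
    r2 = make_record(cmap, "c", 0, "+", 8, calls_at={1: "U", 5: "M"})
    counts = mb.pileup_counts([r1, r2], cmap)
    assert counts.meth["c"][0][1] == 1 and counts.unmeth["c"][0][1] == 1
    assert counts.meth["c"][0][5] == 1 and counts.unmeth["c"][0][5] == 0
    assert counts.total_calls() == 3


def test_pileup_conservation(clean_counts, sim_bundle):
    """Every retained defined-context call lands in exactly one site count."""
    genome, cmap, _ = sim_bundle
    records, counts, qc = clean_counts
    kept, _ = mb.filter_nonconversion(records, cmap)
    kept, _ = mb.deduplicate(kept)
    n_calls = sum(len(r.calls) - r.calls.count(".") for r in kept)
    assert counts.total_calls() + counts.n_undef_calls == n_calls


def test_pileup_rejects_off_contig_read(chh_genome):
    g, cmap = chh_genome
    rec = mb.ReadCallRecord("c", 20, "+", "......", "m0")
    with pytest.raises(mb.ContractError):
        mb.pileup_counts([rec], cmap)


def test_pileup_drops_and_counts_undef_calls():
    g = make_genome({"c": "AACGCA"})  # +4 C has one downstream base → UNDEF
    cmap = mb.build_context_map(g)
    assert cmap.context_at("c", 4, "+") == "UNDEF"
    rec = make_record(cmap, "c", 0, "+", 6, calls_at={2: "M", 4: "M"})
    counts = mb.pileup_counts([rec], cmap)
    assert counts.n_undef_calls == 1
    assert counts.total_calls() == 1


# ---------------------------------------------------------------------------
# levels and background
# ---------------------------------------------------------------------------

def _counts_with(cmap, contig, entries):
    """entries: {(pos, strand): (n_meth, n_unmeth)}"""
    counts = mb.SiteCounts(cmap)
    for (pos, strand), (m, u) in entries.items():
        row = 0 if strand == "+" else 1
        counts.meth[contig][row][pos] = m
        counts.unmeth[contig][row][pos] = u
    return counts


def test_weighted_level_arithmetic():
    g = make_genome({"c": "ACGACGACGACG"})
    cmap = mb.build_context_map(g)
    counts = _counts_with(cmap, "c", {(1, "+"): (3, 7)})
    assert mb.weighted_level(counts, "CG") == pytest.approx(0.30)
    counts = _counts_with(cmap, "c", {(1, "+"): (3, 7), (4, "+"): (1, 9)})
    # weighted pooling: 4/20, not the mean of 0.3 and 0.1
    assert mb.weighted_level(counts, "CG") == pytest.approx(0.20)
    assert mb.weighted_level(counts, "CG", region=("c", 6, 12)) is None
    assert mb.weighted_level(counts, "CG", min_coverage=11) is None


def test_weighted_level_union_bounds(clean_counts, sim_bundle):
    """The level of a union of disjoint regions lies between the parts."""
    genome, cmap, _ = sim_bundle
    _, counts, _ = clean_counts
    contig = genome.nuclear_contigs[0]
    a = mb.weighted_level(counts, "CG", region=(contig, 0, 40_000))
    b = mb.weighted_level(counts, "CG", region=(contig, 40_000, 120_000))
    whole = mb.weighted_level(counts, "CG", region=(contig, 0, 120_000))
    assert min(a, b) <= whole <= max(a, b)


def test_background_requires_control_contig(chh_genome):
    g, cmap = chh_genome  # nuclear-only genome
    counts = mb.SiteCounts(cmap)
    with pytest.raises(mb.MethylbenchError, match="organelle_control"):
        mb.background_level(counts, g)


def test_background_zero_without_errors(clean_counts, sim_bundle):
    genome, _, _ = sim_bundle
    _, counts, qc = clean_counts
    bg = mb.background_level(counts, genome)
    assert all(v == 0.0 for v in bg.values())


def test_genome_wide_levels_exclude_organelle(sim_bundle, clean_counts):
    """Organelle sites must not leak into genome-wide levels: planting heavy
    organelle counts leaves the nuclear level unchanged."""
    genome, cmap, _ = sim_bundle
    _, counts, _ = clean_counts
    before = mb.genome_wide_levels(counts, genome)
    org = genome.organelle_contigs[0]
    counts2 = mb.SiteCounts(cmap)
    for c in counts.contigs:
        counts2.meth[c][:] = counts.meth[c]
        counts2.unmeth[c][:] = counts.unmeth[c]
    counts2.meth[org][cmap.codes[org] > 0] += 1000
    after = mb.genome_wide_levels(counts2, genome)
    assert before == after


# ---------------------------------------------------------------------------
# CX report / bedGraph I/O
# ---------------------------------------------------------------------------

def test_cx_report_round_trip(tmp_path, sim_bundle, clean_counts):
    genome, cmap, _ = sim_bundle
    _, counts, _ = clean_counts
    path = tmp_path / "sample.CX_report.txt"
    mb.write_cx_report(counts, genome, path)
    back = mb.read_cx_report(path, cmap)
    for c in counts.contigs:
        assert np.array_equal(back.meth[c], counts.meth[c])
        assert np.array_equal(back.unmeth[c], counts.unmeth[c])


def test_cx_report_is_one_based_with_trinucleotide(tmp_path):
    g = make_genome({"c": "ACGTT"})
    cmap = mb.build_context_map(g)
    counts = _counts_with(cmap, "c", {(1, "+"): (2, 1)})
    path = tmp_path / "t.CX_report.txt"
    mb.write_cx_report(counts, g, path)
    rows = {tuple(l.split("\t")[:3]): l.split("\t") for l in path.read_text().splitlines()}
    row = rows[("c", "2", "+")]  # 0-based position 1 → 1-based 2
    assert row[3] == "2" and row[4] == "1" and row[5] == "CG" and row[6] == "CGT"
    row_minus = rows[("c", "3", "-")]
    assert row_minus[5] == "CG" and row_minus[6] == "CGT"


def test_bedgraph_round_trip(tmp_path):
    g = make_genome({"c": "ACGACGACG"})
    cmap = mb.build_context_map(g)
    counts = _counts_with(cmap, "c", {(1, "+"): (3, 1), (4, "+"): (0, 2)})
    path = tmp_path / "cg.bedGraph"
    mb.write_bedgraph(counts, path, "CG")
    rows = mb.read_bedgraph(path)
    assert ("c", 1, 2, 75.0) in rows and ("c", 4, 5, 0.0) in rows
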