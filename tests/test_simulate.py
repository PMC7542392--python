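"""Synthetic genome, truth methylome and read-simulation behaviour."""

import numpy as np
import pytest

import methylbench as mb
from methylbench.simulate import GENE_BODY, INTERGENIC, ORGANELLE, TE_PERICENTROMERE

from conftest import make_genome


# ---------------------------------------------------------------------------
# simulate_genome
# ---------------------------------------------------------------------------

def test_genome_layout_arithmetic():
    g = mb.simulate_genome(
        n_nuclear_contigs=1, contig_length=100_000, pericentromere_fraction=0.4,
        organelle_length=10_000, seed=3,
    )
    het = g.features(kind="heterochromatin")
    assert len(het) == 1
    assert het[0].length == 40_000
    assert het[0].start == (100_000 - 40_000) // 2
    assert g.contig_class["organelle"] == "organelle_control"


def test_genome_zero_densities_give_no_features():
    g = mb.simulate_genome(
        n_nuclear_contigs=1, contig_length=50_000, gene_density=0.0, te_density=0.0,
        organelle_length=5_000, seed=3,
    )
    assert g.features(kind="gene") == [] and g.features(kind="TE") == []
    assert {f.kind for f in g.annotations} <= {"heterochromatin", "arm"}


def test_genome_deterministic_outputs(tmp_path):
    kw = dict(n_nuclear_contigs=2, contig_length=30_000, organelle_length=8_000, seed=9)
    g1, g2 = mb.simulate_genome(**kw), mb.simulate_genome(**kw)
    mb.write_fasta(g1.contigs, tmp_path / "a.fa")
    mb.write_fasta(g2.contigs, tmp_path / "b.fa")
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    mb.write_bed(g1.annotations, tmp_path / "a.bed")
    mb.write_bed(g2.annotations, tmp_path / "b.bed")
    assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()


def test_genome_rejects_bad_config():
    with pytest.raises(mb.ConfigurationError):
        mb.simulate_genome(contig_length=0)
    with pytest.raises(mb.ConfigurationError):
        mb.simulate_genome(gene_density=0.95)


# ---------------------------------------------------------------------------
# assign_truth_methylome
# ---------------------------------------------------------------------------

def test_truth_organelle_is_zero(sim_bundle):
    genome, cmap, truth = sim_bundle
    for org in genome.organelle_contigs:
        assert not truth.probs[org].any()


def test_truth_point_rule_mean():
    """A point-probability rule assigns exactly that probability; over ≥10⁴
    pericentromeric CHH sites a 0.05 rule must average 0.05 exactly."""
    genome = mb.simulate_genome(
        n_nuclear_contigs=1, contig_length=200_000, pericentromere_fraction=0.6,
        te_density=0.7, organelle_length=5_000, seed=6,
    )
    cmap = mb.build_context_map(genome)
    params = mb.MethylationParams(
        rules={TE_PERICENTROMERE: {"CHH": mb.LevelRule.fixed(0.05)}}
    )
    truth = mb.assign_truth_methylome(genome, cmap, params, seed=4)
    from methylbench.simulate import compartment_codes, _COMP_CODE

    comp = compartment_codes(genome)
    vals = []
    for contig in genome.nuclear_contigs:
        mask = (comp[contig] == _COMP_CODE[TE_PERICENTROMERE])[None, :] & (
            cmap.codes[contig] == 3
        )
        vals.append(truth.probs[contig][mask])
    vals = np.concatenate(vals)
    assert vals.size >= 10_000
    assert np.allclose(vals, 0.05)


def test_truth_mixture_rule_fraction(sim_bundle):
    """Mixture rules hit level_high with the stated frequency (3σ binomial)."""
    genome, cmap, _ = sim_bundle
    params = mb.MethylationParams(
        rules={INTERGENIC: {"CHH": mb.LevelRule.bimodal(0.3, 0.8, 0.0)}}
    )
    truth = mb.assign_truth_methylome(genome, cmap, params, seed=4)
    from methylbench.simulate import compartment_codes, _COMP_CODE

    comp = compartment_codes(genome)
    vals = np.concatenate(
        [
            truth.probs[c][
                (comp[c] == _COMP_CODE[INTERGENIC])[None, :] & (cmap.codes[c] == 3)
            ]
            for c in genome.nuclear_contigs
        ]
    )
    frac = (vals == 0.8).mean()
    sigma = np.sqrt(0.3 * 0.7 / vals.size)
    assert abs(frac - 0.3) < 3 * sigma


def test_truth_all_zero_rules(sim_bundle):
    genome, cmap, _ = sim_bundle
    params = mb.MethylationParams(rules={})
    truth = mb.assign_truth_methylome(genome, cmap, params, seed=4)
    assert all(not truth.probs[c].any() for c in genome.contigs)


def test_truth_deterministic(sim_bundle):
    genome, cmap, _ = sim_bundle
    t1 = mb.assign_truth_methylome(genome, cmap, seed=5)
    t2 = mb.assign_truth_methylome(genome, cmap, seed=5)
    assert all(np.array_equal(t1.probs[c], t2.probs[c]) for c in genome.contigs)


def test_organelle_rule_must_be_zero():
    with pytest.raises(mb.ConfigurationError):
        mb.MethylationParams(rules={ORGANELLE: {"CG": mb.LevelRule.fixed(0.2)}})


# ---------------------------------------------------------------------------
# simulate_reads
# ---------------------------------------------------------------------------

def _flat_truth(cmap, value: float) -> mb.TruthMethylome:
    return mb.TruthMethylome(
        {c: np.where(codes > 0, np.float32(value), np.float32(0.0))
         for c, codes in cmap.codes.items()}
    )


def test_reads_all_biases_off_truth_zero(sim_bundle):
    """With truth 0 and no errors every cytosine call is U."""
    genome, cmap, _ = sim_bundle
    truth = _flat_truth(cmap, 0.0)
    p = mb.ProtocolParams(protocol="EMseq", n_input_molecules=2_000,
                          n_reads_out=1_000, seed=1)
    for rec in mb.simulate_reads(genome, cmap, truth, p):
        assert "M" not in rec.calls
        codes = cmap.contig_codes(rec.contig, rec.strand)
        span = codes[rec.start : rec.start + len(rec.calls)]
        calls = np.frombuffer(rec.calls.encode(), dtype=np.uint8)
        # U exactly at cytosines, '.' elsewhere
        assert np.array_equal(calls == ord("U"), span > 0)


def test_reads_forced_nonconversion(sim_bundle):
    """p_molecule_nc = 1 on an unmethylated genome reports M at every cytosine."""
    genome, cmap, _ = sim_bundle
    truth = _flat_truth(cmap, 0.0)
    p = mb.ProtocolParams(protocol="WGBS", p_molecule_nc=1.0,
                          n_input_molecules=2_000, n_reads_out=1_000, seed=1)
    for rec in mb.simulate_reads(genome, cmap, truth, p):
        assert "U" not in rec.calls and "M" in rec.calls


def test_reads_deterministic(sim_bundle):
    genome, cmap, truth = sim_bundle
    p = mb.ProtocolParams(protocol="WGBS", eps_fail=0.01, p_molecule_nc=0.05,
                          lambda_deg=0.02, gamma_gc=-0.1, pcr_cycles=6,
                          n_input_molecules=5_000, n_reads_out=2_000, seed=42)
    r1 = mb.simulate_reads(genome, cmap, truth, p)
    r2 = mb.simulate_reads(genome, cmap, truth, p)
    assert r1 == r2


def test_degradation_survival_matches_closed_form():
    """Unmethylated molecules survive at exp(-lambda * u); with truth 0 on one
    contig and 1 on another, the surviving-read ratio tracks the closed form.

    Reads are sampled uniformly from survivors (no PCR bias), so the share of
    output reads on the unmethylated contig estimates
    s/(s+1) with s = E[exp(-lambda*u)] ≈ exp(-lambda*E[u]) after averaging
    over per-molecule cytosine counts; the Monte-Carlo oracle below computes
    E[exp(-lambda*u)] exactly from the per-molecule u distribution.
    """
    rng = np.random.default_rng(0)
    seq_u = "".join(rng.choice(list("ACGT"), size=20_000))
    seq_m = "".join(rng.choice(list("ACGT"), size=20_000))
    genome = make_genome({"u": seq_u, "m": seq_m})
    cmap = mb.build_context_map(genome)
    probs = {c: np.where(codes > 0, np.float32(1.0 if c == "m" else 0.0), np.float32(0))
             for c, codes in cmap.codes.items()}
    truth = mb.TruthMethylome(probs)
    lam = 0.05
    p = mb.ProtocolParams(protocol="WGBS", lambda_deg=lam,
                          n_input_molecules=200_000, n_reads_out=50_000, seed=8)
    reads = mb.simulate_reads(genome, cmap, truth, p)
    frac_u = np.mean([r.contig == "u" for r in reads])

    # oracle: exact expected survival on the unmethylated contig, averaging
    # exp(-lam*u) over every possible read placement (u = cytosine count)
    R = p.read_length
    surv = []
    for strand in (0, 1):
        is_c = (cmap.codes["u"][strand] > 0).astype(float)
        csum = np.concatenate([[0.0], np.cumsum(is_c)])
        u_counts = csum[R:] - csum[: csum.size - R]
        surv.append(np.exp(-lam * u_counts))
    s = float(np.concatenate(surv).mean())
    expected = s / (s + 1.0)
    assert abs(frac_u - expected) < 0.01


def test_no_survivors_raises(sim_bundle):
    genome, cmap, truth = sim_bundle
    p = mb.ProtocolParams(protocol="WGBS", lambda_deg=50.0,
                          n_input_molecules=200, n_reads_out=100, seed=1)
    with pytest.raises(mb.SimulationError):
        mb.simulate_reads(genome, cmap, _flat_truth(cmap, 0.0), p)


def test_duplication_monotone_in_cycles_and_input(sim_bundle):
    """With a GC-dependent PCR weight, more cycles concentrate sampling on
    few molecules (duplication up); more input molecules dilute it."""
    genome, cmap, truth = sim_bundle

    def dup(cycles, n_mol):
        p = mb.ProtocolParams(protocol="WGBS", gamma_gc=-0.5, pcr_cycles=cycles,
                              n_input_molecules=n_mol, n_reads_out=20_000, seed=3)
        reads = mb.simulate_reads(genome, cmap, truth, p)
        _, rate = mb.deduplicate(reads)
        return rate

    assert dup(0, 40_000) <= dup(12, 40_000) <= dup(24, 40_000)
    assert dup(12, 200_000) <= dup(12, 40_000)


def test_emseq_preset_forbids_bias_parameters():
    with pytest.raises(mb.ConfigurationError):
        mb.ProtocolParams.emseq_preset(lambda_deg=0.1)
    with pytest.raises(mb.ConfigurationError):
        mb.ProtocolParams(protocol="EMseq", p_molecule_nc=0.5)


# ---------------------------------------------------------------------------
# read I/O
# ---------------------------------------------------------------------------

def test_reads_tsv_round_trip(tmp_path, sim_bundle):
    genome, cmap, truth = sim_bundle
    p = mb.ProtocolParams(protocol="EMseq", n_input_molecules=2_000,
                          n_reads_out=500, seed=2)
    records = mb.simulate_reads(genome, cmap, truth, p)
    path = tmp_path / "reads.tsv"
    mb.write_reads(records, path, cmap)
    assert mb.read_reads(path) == records


def test_reads_empty_round_trip(tmp_path):
    path = tmp_path / "empty.tsv"
    mb.write_reads([], path)
    assert path.read_text().startswith("contig\t")
    assert mb.read_reads(path) == []


def test_writer_refuses_call_at_non_cytosine(tmp_path):
    genome = make_genome({"c": "AAACGAAA"})
    cmap = mb.build_context_map(genome)
    bad = mb.ReadCallRecord("c", 0, "+", "M.......", "m0")
    with pytest.raises(mb.ContractError):
        mb.write_reads([bad], tmp_path / "x.tsv", cmap)


def test_reads_parse_error_carries_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("contig\tstart\tstrand\tcalls\tmolecule_id\nc\t0\t+\tMU\n")
    with pytest.raises(mb.ParseError, match="bad.tsv:2"):
        mb.read_reads(path)


def test_sam_emission(tmp_path, sim_bundle):
    genome, cmap, truth = sim_bundle
    p = mb.ProtocolParams(protocol="EMseq", n_input_molecules=500,
                          n_reads_out=100, seed=2)
    records = mb.simulate_reads(genome, cmap, truth, p)
    path = tmp_path / "reads.sam"
    mb.write_sam(records, genome, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("@HD")
    body = [l for l in lines if not l.startswith("@")]
    assert len(body) == len(records)
    first = body[0].split("\t")
    assert int(first[3]) == records[0].start + 1  # SAM is 1-based
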