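import numpy as np
import pytest

import methylbench as mb


def make_genome(contigs: dict[str, str], organelle: str | None = None,
                annotations=None) -> mb.Genome:
    """Hand-built genome helper for unit tests."""
    classes = {c: "nuclear" for c in contigs}
    if organelle is not None:
        classes[organelle] = "organelle_control"
    return mb.Genome(contigs=dict(contigs), contig_class=classes,
                     annotations=list(annotations or []))


def make_record(cmap: mb.ContextMap, contig: str, start: int, strand: str,
                length: int, calls_at: dict[int, str] | None = None,
                default_call: str | None = None, molecule_id: str = "m0"
                ) -> mb.ReadCallRecord:
    """Build a record whose cytosine offsets are called ``default_call``
    (or '.') except where ``calls_at`` (absolute positions) overrides."""
    codes = cmap.contig_codes(contig, strand)
    chars = []
    for off in range(length):
        pos = start + off
        if calls_at and pos in calls_at:
            chars.append(calls_at[pos])
        elif codes[pos] > 0 and default_call is not None:
            chars.append(default_call)
        else:
            chars.append(".")
    return mb.ReadCallRecord(contig, start, strand, "".join(chars), molecule_id)


@pytest.fixture(scope="session")
def sim_bundle():
    """One shared small simulation: genome, context map, truth methylome."""
    genome = mb.simulate_genome(
        n_nuclear_contigs=1, contig_length=120_000, organelle_length=30_000, seed=7
    )
    cmap = mb.build_context_map(genome)
    truth = mb.assign_truth_methylome(genome, cmap, seed=7)
    return genome, cmap, truth


@pytest.fixture(scope="session")
def clean_counts(sim_bundle):
    """Extraction output of a bias-free simulation over the shared genome."""
    genome, cmap, truth = sim_bundle
    params = mb.ProtocolParams(
        protocol="EMseq", eps_fail=0.0, eps_over=0.0,
        n_input_molecules=400_000, n_reads_out=50_000, seed=17,
    )
    records = mb.simulate_reads(genome, cmap, truth, params)
    counts, qc = mb.process_reads(records, cmap, genome)
    return records, counts, qc
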