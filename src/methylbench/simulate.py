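"""Synthetic genome, ground-truth methylome and converted-read simulation.

The simulator emulates the statistical structure of an Arabidopsis methylome
experiment run through either a bisulfite (WGBS-like) or an enzymatic
(EM-seq-like) conversion protocol:

* a nuclear chromosome layout with euchromatic arms flanking a TE-dense
  pericentromeric core, plus an unmethylated organelle control contig;
* bimodal CG methylation in gene bodies and TEs, CHG/CHH methylation
  concentrated on pericentromeric TEs;
* molecule-level non-conversion (strands that escape conversion entirely and
  read out as fully methylated);
* per-base conversion failure (false methylation) and inappropriate
  conversion of true methylcytosines;
* preferential loss of fragments rich in unmethylated cytosines
  (bisulfite depyrimidination damage), modelled as exponential survival;
* PCR amplification bias as a log-linear weight in the post-conversion G+C
  fraction of the fragment, scaling with cycle number.

The last three mechanisms are described only qualitatively in the bisulfite
literature; the quantitative forms here are the simplest monotone models that
expose each effect through a single parameter.  EM-seq presets switch all
three off: the enzymatic chemistry is non-destructive and its amplification
is close to unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, ContractError, ParseError, SimulationError
from .genome import (
    ContextMap,
    Feature,
    Genome,
    NUCLEAR,
    ORGANELLE_CONTROL,
    sequence_array,
)

# compartment labels used by the truth-methylome rules
GENE_BODY = "gene_body"
TE_ARM = "te_arm"
TE_PERICENTROMERE = "te_pericentromere"
INTERGENIC = "intergenic"
ORGANELLE = "organelle_control"
COMPARTMENTS = (GENE_BODY, TE_ARM, TE_PERICENTROMERE, INTERGENIC, ORGANELLE)

_COMP_CODE = {c: i for i, c in enumerate(COMPARTMENTS)}


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelRule:
    """Per-site methylation probability rule for one (compartment, context).

    Either a point probability (every site gets ``point``) or a
    two-component mixture: a site is drawn at ``level_high`` with probability
    ``frac_high`` and at ``level_low`` otherwise.  The mixture form
    reproduces the bimodal (all-or-nothing) character of plant CG
    methylation.
    """

    point: float | None = None
    frac_high: float | None = None
    level_high: float = 0.0
    level_low: float = 0.0

    def __post_init__(self):
        vals = [v for v in (self.point, self.frac_high, self.level_high, self.level_low) if v is not None]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ConfigurationError(f"methylation rule values must lie in [0,1]: {self}")
        if (self.point is None) == (self.frac_high is None):
            raise ConfigurationError("rule must set exactly one of point / frac_high")

    @staticmethod
    def fixed(p: float) -> "LevelRule":
        return LevelRule(point=p)

    @staticmethod
    def bimodal(frac_high: float, level_high: float, level_low: float) -> "LevelRule":
        return LevelRule(frac_high=frac_high, level_high=level_high, level_low=level_low)


@dataclass(frozen=True)
class MethylationParams:
    """Truth-methylome rules: compartment → context → :class:`LevelRule`."""

    rules: dict[str, dict[str, LevelRule]]

    def __post_init__(self):
        for comp, by_ctx in self.rules.items():
            if comp not in COMPARTMENTS:
                raise ConfigurationError(f"unknown compartment {comp!r}")
            for ctx in by_ctx:
                if ctx not in ("CG", "CHG", "CHH"):
                    raise ConfigurationError(f"unknown context {ctx!r}")
        org = self.rules.get(ORGANELLE, {})
        for ctx, rule in org.items():
            if (rule.point or 0) != 0 or rule.level_high != 0 or rule.level_low != 0:
                raise ConfigurationError("organelle-control methylation must be 0")

    def rule(self, compartment: str, context: str) -> LevelRule:
        by_ctx = self.rules.get(compartment, {})
        return by_ctx.get(context, LevelRule.fixed(0.0))

    @staticmethod
    def arabidopsis_like() -> "MethylationParams":
        """Default rules shaped on a flowering-plant methylome: bimodal
        gene-body CG, heavily methylated pericentromeric TEs, quiet
        intergenic space and an unmethylated organelle."""
        return MethylationParams(
            rules={
                GENE_BODY: {
                    "CG": LevelRule.bimodal(0.25, 0.90, 0.02),
                    "CHG": LevelRule.fixed(0.01),
                    "CHH": LevelRule.fixed(0.01),
                },
                TE_ARM: {
                    "CG": LevelRule.bimodal(0.80, 0.90, 0.05),
                    "CHG": LevelRule.fixed(0.35),
                    # per-site CHH methylation is heterogeneous in vivo: a
                    # minority of siRNA-targeted sites carries most of the
                    # signal, so a point probability would miss the high tail
                    "CHH": LevelRule.bimodal(0.06, 0.50, 0.03),
                },
                TE_PERICENTROMERE: {
                    "CG": LevelRule.bimodal(0.90, 0.95, 0.05),
                    "CHG": LevelRule.fixed(0.55),
                    "CHH": LevelRule.bimodal(0.12, 0.60, 0.05),
                },
                INTERGENIC: {
                    "CG": LevelRule.bimodal(0.10, 0.90, 0.02),
                    "CHG": LevelRule.fixed(0.02),
                    "CHH": LevelRule.fixed(0.015),
                },
                ORGANELLE: {
                    "CG": LevelRule.fixed(0.0),
                    "CHG": LevelRule.fixed(0.0),
                    "CHH": LevelRule.fixed(0.0),
                },
            }
        )


@dataclass(frozen=True)
class ProtocolParams:
    """Conversion-protocol and library-preparation parameters.

    eps_fail
        per-cytosine conversion-failure probability: an unmethylated C is
        reported methylated.  This is the background the organelle control
        estimates.
    eps_over
        per-methylcytosine inappropriate-conversion probability: a true mC
        is reported unmethylated.
    p_molecule_nc
        probability that a whole molecule escapes conversion (failed
        denaturation) and reads out methylated at every cytosine.
    lambda_deg
        degradation rate per unmethylated cytosine; a molecule with u
        unmethylated Cs survives conversion with probability exp(-lambda_deg*u).
    gamma_gc, pcr_cycles
        PCR weight per surviving molecule: exp(gamma_gc * pcr_cycles *
        (g - mean g)) with g its post-conversion G+C fraction.  A negative
        gamma_gc favours AT-rich (converted) templates, the direction seen
        in bisulfite libraries.
    """

    protocol: str  # "WGBS" | "EMseq"
    eps_fail: float = 0.0
    eps_over: float = 0.0
    p_molecule_nc: float = 0.0
    lambda_deg: float = 0.0
    gamma_gc: float = 0.0
    pcr_cycles: int = 0
    n_input_molecules: int = 100_000
    n_reads_out: int = 50_000
    read_length: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.protocol not in ("WGBS", "EMseq"):
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        for name in ("eps_fail", "eps_over", "p_molecule_nc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0,1]")
        if self.lambda_deg < 0:
            raise ConfigurationError("lambda_deg must be >= 0")
        if self.pcr_cycles < 0 or self.n_input_molecules <= 0 or self.n_reads_out <= 0:
            raise ConfigurationError("pcr_cycles >= 0; molecule and read counts > 0")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be > 0")
        if self.protocol == "EMseq" and (
            self.p_molecule_nc != 0 or self.lambda_deg != 0 or self.gamma_gc != 0
        ):
            raise ConfigurationError(
                "EMseq protocol forbids p_molecule_nc, lambda_deg and gamma_gc"
            )

    @staticmethod
    def emseq_preset(**overrides) -> "ProtocolParams":
        """Enzymatic conversion: tiny background, no destruction, no PCR bias."""
        base = dict(protocol="EMseq", eps_fail=0.001, eps_over=0.002)
        base.update(overrides)
        return ProtocolParams(**base)

    @staticmethod
    def wgbs_preset(**overrides) -> "ProtocolParams":
        """Bisulfite conversion: higher background, occasional whole-molecule
        non-conversion, degradation of unmethylated-C-rich fragments and a
        PCR preference for AT-rich templates that grows with cycle number."""
        base = dict(
            protocol="WGBS",
            eps_fail=0.005,
            eps_over=0.002,
            p_molecule_nc=0.02,
            lambda_deg=0.06,
            gamma_gc=-0.2,
            pcr_cycles=12,
        )
        base.update(overrides)
        return ProtocolParams(**base)


class TruthMethylome:
    """Per-site ground-truth methylation probability, aligned to a ContextMap.

    ``probs[contig]`` is a ``(2, L)`` float32 array; entries at non-cytosine
    positions are 0 and never read.
    """

    def __init__(self, probs: dict[str, np.ndarray]):
        self.probs = probs

    def contig_probs(self, contig: str, strand: str) -> np.ndarray:
        return self.probs[contig][0 if strand == "+" else 1]

    def mean_level(self, context_map: ContextMap, context: str, contigs: Iterable[str]) -> float:
        """Unweighted mean truth probability over all sites of one context."""
        from .genome import NAME_TO_CODE

        total, n = 0.0, 0
        code = NAME_TO_CODE[context]
        for c in contigs:
            mask = context_map.codes[c] == code
            total += float(self.probs[c][mask].sum())
            n += int(mask.sum())
        return total / n if n else float("nan")


@dataclass(frozen=True)
class ReadCallRecord:
    """One aligned, converted read.

    ``calls`` is aligned to reference offsets ``start .. start+len-1``:
    ``M`` = cytosine retained (methylated call), ``U`` = converted
    (unmethylated call), ``.`` = not a cytosine on the read's strand.
    ``molecule_id`` identifies the input molecule, so PCR duplicates created
    by resampling share it.
    """

    contig: str
    start: int
    strand: str
    calls: str
    molecule_id: str


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    n_nuclear_contigs: int = 2,
    contig_length: int = 150_000,
    pericentromere_fraction: float = 0.3,
    gene_density: float = 0.35,
    te_density: float = 0.5,
    gc_gradient: float = 0.07,
    organelle_length: int = 30_000,
    seed: int = 0,
    base_gc: float = 0.36,
    read_margin: int = 0,
) -> Genome:
    """Simulate a small plant-like genome.

    Each nuclear contig carries a central pericentromeric block (annotated
    ``heterochromatin``) flanked by two ``arm`` blocks; genes are placed in
    arms at ``gene_density`` (fraction of arm bp), TEs in the pericentromere
    at ``te_density`` and in arms at a quarter of it.  Local GC content
    follows a smooth gradient of amplitude ``gc_gradient`` around ``base_gc``
    so GC-bias diagnostics have signal.  One organelle-control contig is
    appended.  Deterministic given ``seed``.
    """
    if contig_length <= 0 or organelle_length <= 0:
        raise ConfigurationError("contig lengths must be positive")
    if not (0.0 <= pericentromere_fraction <= 1.0):
        raise ConfigurationError("pericentromere_fraction outside [0,1]")
    if not (0.0 <= gene_density <= 0.8) or not (0.0 <= te_density <= 0.9):
        raise ConfigurationError("infeasible gene/TE density")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    contigs: dict[str, str] = {}
    classes: dict[str, str] = {}
    annotations: list[Feature] = []

    for ci in range(n_nuclear_contigs):
        name = f"chr{ci + 1}"
        L = contig_length
        pos = np.arange(L)
        # smooth GC landscape: two full oscillations per contig, AT-shifted core
        gc = base_gc + gc_gradient * np.sin(2.0 * np.pi * 2.0 * pos / L + ci)
        peri_len = int(round(pericentromere_fraction * L))
        peri_start = (L - peri_len) // 2
        peri_end = peri_start + peri_len
        if peri_len:
            gc[peri_start:peri_end] -= 0.03  # pericentromeres run slightly AT-rich
        gc = np.clip(gc, 0.05, 0.95)
        p_gc = gc / 2.0
        p_at = (1.0 - gc) / 2.0
        u = rng.random(L)
        # cumulative thresholds A | C | G | T
        bases = np.full(L, ord("T"), dtype=np.uint8)
        bases[u < p_at] = ord("A")
        bases[(u >= p_at) & (u < p_at + p_gc)] = ord("C")
        bases[(u >= p_at + p_gc) & (u < p_at + 2 * p_gc)] = ord("G")
        contigs[name] = bases.tobytes().decode("ascii")
        classes[name] = NUCLEAR

        if peri_len:
            annotations.append(Feature(name, peri_start, peri_end, ".", "heterochromatin", f"{name}_het"))
        if peri_start > 0:
            annotations.append(Feature(name, 0, peri_start, ".", "arm", f"{name}_armL"))
        if peri_end < L:
            annotations.append(Feature(name, peri_end, L, ".", "arm", f"{name}_armR"))

        arm_spans = [(0, peri_start), (peri_end, L)]
        annotations.extend(
            _place_features(rng, name, arm_spans, gene_density, (1000, 3000), "gene", "g")
        )
        te_spans_peri = [(peri_start, peri_end)] if peri_len else []
        annotations.extend(
            _place_features(rng, name, te_spans_peri, te_density, (500, 4000), "TE", "te")
        )
        annotations.extend(
            _place_features(rng, name, arm_spans, te_density * 0.25, (300, 2000), "TE", "tea")
        )

    org = "organelle"
    u = rng.random(organelle_length)
    bases = np.full(organelle_length, ord("T"), dtype=np.uint8)
    p_at, p_gc = (1 - base_gc) / 2.0, base_gc / 2.0
    bases[u < p_at] = ord("A")
    bases[(u >= p_at) & (u < p_at + p_gc)] = ord("C")
    bases[(u >= p_at + p_gc) & (u < p_at + 2 * p_gc)] = ord("G")
    contigs[org] = bases.tobytes().decode("ascii")
    classes[org] = ORGANELLE_CONTROL

    return Genome(contigs=contigs, contig_class=classes, annotations=annotations)


def _place_features(
    rng: np.random.Generator,
    contig: str,
    spans: list[tuple[int, int]],
    density: float,
    length_range: tuple[int, int],
    kind: str,
    prefix: str,
) -> list[Feature]:
    """Place non-overlapping features left-to-right until the target density
    (fraction of span bp covered) is met; gaps drawn to match the density."""
    feats: list[Feature] = []
    if density <= 0:
        return feats
    lo, hi = length_range
    mean_len = (lo + hi) / 2.0
    mean_gap = max(mean_len * (1.0 - density) / density, 1.0)
    idx = 0
    for span_start, span_end in spans:
        cursor = span_start + int(rng.exponential(mean_gap / 2.0))
        while True:
            flen = int(rng.integers(lo, hi + 1))
            if cursor + flen > span_end:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            feats.append(Feature(contig, cursor, cursor + flen, strand, kind, f"{contig}_{prefix}{idx}"))
            idx += 1
            cursor += flen + max(int(rng.exponential(mean_gap)), 1)
    return feats


# ---------------------------------------------------------------------------
# Truth methylome
# ---------------------------------------------------------------------------

def compartment_codes(genome: Genome) -> dict[str, np.ndarray]:
    """Per-position compartment code for each contig.

    TE features dominate genes where they overlap; a TE inside an annotated
    heterochromatin block is pericentromeric, elsewhere an arm TE.  Positions
    outside any feature fall back to intergenic.
    """
    out: dict[str, np.ndarray] = {}
    for name, seq in genome.contigs.items():
        L = len(seq)
        if genome.contig_class[name] == ORGANELLE_CONTROL:
            out[name] = np.full(L, _COMP_CODE[ORGANELLE], dtype=np.int8)
            continue
        comp = np.full(L, _COMP_CODE[INTERGENIC], dtype=np.int8)
        in_het = np.zeros(L, dtype=bool)
        for f in genome.features(kind="heterochromatin", contig=name):
            in_het[f.start : f.end] = True
        for f in genome.features(kind="gene", contig=name):
            comp[f.start : f.end] = _COMP_CODE[GENE_BODY]
        for f in genome.features(kind="TE", contig=name):
            comp[f.start : f.end] = np.where(
                in_het[f.start : f.end], _COMP_CODE[TE_PERICENTROMERE], _COMP_CODE[TE_ARM]
            )
        out[name] = comp
    return out


def assign_truth_methylome(
    genome: Genome,
    context_map: ContextMap,
    params: MethylationParams | None = None,
    seed: int = 0,
) -> TruthMethylome:
    """Draw a per-site methylation probability for every cytosine.

    Each site's probability comes from the (compartment, context) rule; sites
    with UNDEF context and all organelle-control sites get probability 0.
    Deterministic given ``seed``.
    """
    if params is None:
        params = MethylationParams.arabidopsis_like()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA55160]))
    comp_by_contig = compartment_codes(genome)
    from .genome import NAME_TO_CODE

    probs: dict[str, np.ndarray] = {}
    for name in genome.contigs:
        codes = context_map.codes[name]  # (2, L)
        comp = comp_by_contig[name]  # (L,)
        m = np.zeros(codes.shape, dtype=np.float32)
        for comp_name, comp_code in _COMP_CODE.items():
            comp_mask = comp == comp_code
            if not comp_mask.any():
                continue
            for ctx in ("CG", "CHG", "CHH"):
                mask = comp_mask[None, :] & (codes == NAME_TO_CODE[ctx])
                n = int(mask.sum())
                if n == 0:
                    continue
                rule = params.rule(comp_name, ctx)
                if rule.point is not None:
                    m[mask] = rule.point
                else:
                    high = rng.random(n) < rule.frac_high
                    m[mask] = np.where(high, rule.level_high, rule.level_low)
        if genome.contig_class[name] == ORGANELLE_CONTROL:
            m[:] = 0.0
        probs[name] = m
    return TruthMethylome(probs)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: Genome,
    context_map: ContextMap,
    truth: TruthMethylome,
    protocol: ProtocolParams,
) -> list[ReadCallRecord]:
    """Simulate converted single-end reads under one protocol.

    Stages, each on its own deterministic sub-stream of ``protocol.seed``:

    1. fragmentation — molecule starts/strands uniform over positions where a
       full read fits, contigs weighted by their number of valid starts;
    2. methylation — each cytosine's state is Bernoulli(truth m);
    3. conversion — whole-molecule escape with ``p_molecule_nc`` (every
       cytosine reads M); otherwise per-base errors ``eps_fail``/``eps_over``;
    4. degradation — survival exp(-lambda_deg * #unmethylated C);
    5. PCR — weight exp(gamma_gc * pcr_cycles * (g - mean g)) over survivors,
       g = post-conversion G+C fraction;
    6. sequencing — ``n_reads_out`` draws with replacement, probability ∝
       weight; re-drawn molecules become duplicate records sharing a
       molecule id.
    """
    R = protocol.read_length
    ss = np.random.SeedSequence([protocol.seed, 0x5EED])
    rng_frag, rng_meth, rng_conv, rng_deg, rng_pcr = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    names = [c for c in genome.contigs if len(genome.contigs[c]) >= R]
    if not names:
        raise SimulationError(f"no contig can host a read of length {R}")
    valid = np.array([len(genome.contigs[c]) - R + 1 for c in names], dtype=np.float64)
    n_mol = protocol.n_input_molecules
    contig_idx = rng_frag.choice(len(names), size=n_mol, p=valid / valid.sum())
    start_u = rng_frag.random(n_mol)
    is_minus = rng_frag.random(n_mol) < 0.5

    surv_contig: list[np.ndarray] = []
    surv_start: list[np.ndarray] = []
    surv_minus: list[np.ndarray] = []
    surv_calls: list[np.ndarray] = []
    surv_gfrac: list[np.ndarray] = []
    surv_molid: list[np.ndarray] = []

    for ci, name in enumerate(names):
        sel = contig_idx == ci
        n = int(sel.sum())
        if n == 0:
            continue
        starts = (start_u[sel] * valid[ci]).astype(np.int64)
        minus = is_minus[sel]
        mol_ids = np.flatnonzero(sel)
        seq = sequence_array(genome, name)
        ctx = context_map.codes[name]
        pr = truth.probs[name]
        posm = starts[:, None] + np.arange(R)[None, :]
        base = seq[posm]
        strand_row = minus.astype(np.int8)
        ctx_codes = ctx[strand_row[:, None], posm]
        m_prob = pr[strand_row[:, None], posm]
        is_cyt = ctx_codes > 0

        meth = (rng_meth.random((n, R)) < m_prob) & is_cyt
        nc = rng_conv.random(n) < protocol.p_molecule_nc
        fail = rng_conv.random((n, R)) < protocol.eps_fail
        over = rng_conv.random((n, R)) < protocol.eps_over
        call_m = np.where(meth, ~over, fail)
        call_m |= nc[:, None]
        call_m &= is_cyt

        u_count = (is_cyt & ~meth).sum(axis=1)
        survive = rng_deg.random(n) < np.exp(-protocol.lambda_deg * u_count)
        if not survive.any():
            continue
        # post-conversion G+C on the molecule's strand: its G count is fixed
        # by the reference (G for plus molecules, C for minus), its retained
        # Cs are exactly the M calls.
        strand_g = np.where(minus[:, None], base == ord("C"), base == ord("G"))
        g_count = strand_g.sum(axis=1) + call_m.sum(axis=1)

        calls = np.full((n, R), ord("."), dtype=np.uint8)
        calls[is_cyt] = ord("U")
        calls[call_m] = ord("M")

        surv_contig.append(np.full(int(survive.sum()), ci, dtype=np.int32))
        surv_start.append(starts[survive])
        surv_minus.append(minus[survive])
        surv_calls.append(calls[survive])
        surv_gfrac.append(g_count[survive] / R)
        surv_molid.append(mol_ids[survive])

    if not surv_contig:
        raise SimulationError(
            "no molecules survived degradation "
            f"(lambda_deg={protocol.lambda_deg}, n_input_molecules={protocol.n_input_molecules})"
        )
    contig_all = np.concatenate(surv_contig)
    start_all = np.concatenate(surv_start)
    minus_all = np.concatenate(surv_minus)
    calls_all = np.concatenate(surv_calls)
    gfrac_all = np.concatenate(surv_gfrac)
    molid_all = np.concatenate(surv_molid)

    logw = protocol.gamma_gc * protocol.pcr_cycles * (gfrac_all - gfrac_all.mean())
    w = np.exp(logw - logw.max())
    picks = rng_pcr.choice(contig_all.size, size=protocol.n_reads_out, replace=True, p=w / w.sum())

    records: list[ReadCallRecord] = []
    for i in picks:
        records.append(
            ReadCallRecord(
                contig=names[contig_all[i]],
                start=int(start_all[i]),
                strand="-" if minus_all[i] else "+",
                calls=calls_all[i].tobytes().decode("ascii"),
                molecule_id=f"m{int(molid_all[i])}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Read I/O (TSV dialect; optional SAM emission)
# ---------------------------------------------------------------------------

READS_HEADER = "contig\tstart\tstrand\tcalls\tmolecule_id"


def write_reads(
    records: Iterable[ReadCallRecord],
    path: str | Path,
    context_map: ContextMap | None = None,
) -> None:
    """Write records as TSV.  When a context map is supplied, refuse records
    whose M/U calls sit at positions that are not cytosines on their strand."""
    with open(path, "w") as fh:
        fh.write(READS_HEADER + "\n")
        for rec in records:
            if context_map is not None:
                _validate_record(rec, context_map)
            fh.write(
                f"{rec.contig}\t{rec.start}\t{rec.strand}\t{rec.calls}\t{rec.molecule_id}\n"
            )


def _validate_record(rec: ReadCallRecord, context_map: ContextMap) -> None:
    codes = context_map.contig_codes(rec.contig, rec.strand)
    if rec.start < 0 or rec.start + len(rec.calls) > codes.size:
        raise ContractError(
            f"read at {rec.contig}:{rec.start} extends past the contig end"
        )
    span = codes[rec.start : rec.start + len(rec.calls)]
    called = np.frombuffer(rec.calls.encode("ascii"), dtype=np.uint8) != ord(".")
    if (called & (span == 0)).any():
        raise ContractError(
            f"read {rec.molecule_id} at {rec.contig}:{rec.start} has an M/U call "
            "at a non-cytosine position"
        )


def read_reads(path: str | Path) -> list[ReadCallRecord]:
    records: list[ReadCallRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != READS_HEADER:
            raise ParseError(f"unexpected header {header!r}", str(path), 1)
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError("expected 5 tab-separated fields", str(path), lineno)
            contig, start, strand, calls, mol = parts
            try:
                start_i = int(start)
            except ValueError:
                raise ParseError(f"bad start {start!r}", str(path), lineno)
            if strand not in "+-" or set(calls) - set("MU."):
                raise ParseError("bad strand or call symbols", str(path), lineno)
            records.append(ReadCallRecord(contig, start_i, strand, calls, mol))
    return records


def write_sam(
    records: Iterable[ReadCallRecord], genome: Genome, path: str | Path
) -> None:
    """Emit records as minimal text SAM for interoperability; calls are kept
    in the custom ``XC:Z`` tag since base sequences are not simulated."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in genome.contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for rec in records:
            flag = 16 if rec.strand == "-" else 0
            fh.write(
                f"{rec.molecule_id}\t{flag}\t{rec.contig}\t{rec.start + 1}\t255\t"
                f"{len(rec.calls)}M\t*\t0\t0\t*\t*\tXC:Z:{rec.calls}\n"
            )
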