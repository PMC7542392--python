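"""Genome representation, feature annotations and cytosine-context classification.

Cytosine methylation in plants is reported in three sequence contexts read
5'→3' on the strand carrying the cytosine: CG, CHG and CHH (H = A, T or C).
CG and CHG are palindromic between strands while CHH is asymmetric, so every
C on the plus strand and every G on the plus strand (a C on the minus strand)
carries its own context.  The :class:`ContextMap` built here is the coordinate
backbone for methylation extraction, DMR calling and all profile analyses.

Coordinates are 0-based half-open everywhere internally; 1-based coordinates
appear only in CX-report output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import ConfigurationError, ParseError

CONTEXTS = ("CG", "CHG", "CHH")

#: integer codes used in the dense context arrays
NOT_C, CTX_CG, CTX_CHG, CTX_CHH, CTX_UNDEF = 0, 1, 2, 3, 4
CODE_TO_NAME = {NOT_C: "NOT_C", CTX_CG: "CG", CTX_CHG: "CHG", CTX_CHH: "CHH", CTX_UNDEF: "UNDEF"}
NAME_TO_CODE = {v: k for k, v in CODE_TO_NAME.items()}

NUCLEAR = "nuclear"
ORGANELLE_CONTROL = "organelle_control"

FEATURE_KINDS = ("gene", "TE", "heterochromatin", "arm", "other")

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")


@dataclass(frozen=True)
class Feature:
    """An annotated genomic interval (0-based, half-open)."""

    contig: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"
    id: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ConfigurationError(
                f"feature {self.id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ConfigurationError(f"feature {self.id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A set of contigs with per-contig class labels and feature annotations.

    ``contig_class`` marks each contig as ``nuclear`` or ``organelle_control``;
    the organelle control (a chloroplast stand-in, effectively unmethylated
    in vivo) anchors background / false-positive estimation downstream.
    """

    contigs: dict[str, str]
    contig_class: dict[str, str] = field(default_factory=dict)
    annotations: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if not self.contigs:
            raise ConfigurationError("genome has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise ConfigurationError(f"contig {name!r} is empty")
            self.contig_class.setdefault(name, NUCLEAR)
        for name, cls in self.contig_class.items():
            if name not in self.contigs:
                raise ConfigurationError(f"contig_class names unknown contig {name!r}")
            if cls not in (NUCLEAR, ORGANELLE_CONTROL):
                raise ConfigurationError(f"unknown contig class {cls!r} for {name!r}")
        for feat in self.annotations:
            L = self.contig_length(feat.contig)
            if feat.end > L:
                raise ConfigurationError(
                    f"feature {feat.id!r} end {feat.end} exceeds contig "
                    f"{feat.contig!r} length {L}"
                )

    def contig_length(self, contig: str) -> int:
        if contig not in self.contigs:
            raise ConfigurationError(f"unknown contig {contig!r}")
        return len(self.contigs[contig])

    @property
    def organelle_contigs(self) -> list[str]:
        return [c for c, cls in self.contig_class.items() if cls == ORGANELLE_CONTROL]

    @property
    def nuclear_contigs(self) -> list[str]:
        return [c for c, cls in self.contig_class.items() if cls == NUCLEAR]

    def features(self, kind: str | None = None, contig: str | None = None) -> list[Feature]:
        out = self.annotations
        if kind is not None:
            out = [f for f in out if f.kind == kind]
        if contig is not None:
            out = [f for f in out if f.contig == contig]
        return out

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


class ContextMap:
    """Dense per-contig cytosine context arrays.

    For each contig a ``(2, L)`` int8 array holds one context code per
    position: row 0 for plus-strand cytosines (reference C), row 1 for
    minus-strand cytosines (reference G).  Code 0 marks positions that carry
    no cytosine on that strand.
    """

    def __init__(self, codes: dict[str, np.ndarray]):
        self.codes = codes

    def __contains__(self, contig: str) -> bool:
        return contig in self.codes

    def contig_codes(self, contig: str, strand: str) -> np.ndarray:
        """Context codes for one strand of one contig (1-D int8 view)."""
        return self.codes[contig][0 if strand == "+" else 1]

    def context_at(self, contig: str, pos: int, strand: str) -> str:
        return CODE_TO_NAME[int(self.contig_codes(contig, strand)[pos])]

    def sites(self, contig: str, strand: str, context: str | None = None) -> np.ndarray:
        """Positions carrying a cytosine on ``strand`` (optionally one context)."""
        row = self.contig_codes(contig, strand)
        if context is None:
            return np.flatnonzero(row > 0)
        return np.flatnonzero(row == NAME_TO_CODE[context])

    def n_sites(self, context: str | None = None) -> int:
        total = 0
        for arr in self.codes.values():
            if context is None:
                total += int((arr > 0).sum())
            else:
                total += int((arr == NAME_TO_CODE[context]).sum())
        return total

    def iter_entries(self, contig: str) -> Iterator[tuple[int, str, str]]:
        """Yield (pos, strand, context-name) for every entry on ``contig``."""
        for row, strand in ((0, "+"), (1, "-")):
            codes = self.codes[contig][row]
            for pos in np.flatnonzero(codes > 0):
                yield int(pos), strand, CODE_TO_NAME[int(codes[pos])]


def classify_context(sequence: str, pos: int, strand: str) -> str:
    """Classify the cytosine context at one position of a raw sequence.

    The context is the trinucleotide starting at the cytosine, read 5'→3' on
    the given strand (for the minus strand: the reverse complement, walking
    leftwards on the reference).  Returns ``NOT_C`` when the strand base is
    not a cytosine, and ``UNDEF`` when fewer than two downstream bases exist
    or an N interrupts the triplet.
    """
    n = len(sequence)
    if not (0 <= pos < n):
        raise IndexError(f"position {pos} out of range for sequence of length {n}")
    if strand not in ("+", "-"):
        raise ValueError(f"bad strand {strand!r}")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    if strand == "+":
        base = sequence[pos]
        down = [sequence[pos + i] for i in (1, 2) if pos + i < n]
    else:
        base = comp[sequence[pos]]
        down = [comp[sequence[pos - i]] for i in (1, 2) if pos - i >= 0]
    if base != "C":
        return "NOT_C"
    if len(down) < 2 or "N" in down:
        return "UNDEF"
    if down[0] == "G":
        return "CG"
    if down[1] == "G":
        return "CHG"
    return "CHH"


def _context_codes_plus(arr: np.ndarray) -> np.ndarray:
    """Vectorised plus-strand context codes for a uint8 sequence array."""
    L = arr.size
    n1 = np.zeros(L, dtype=np.uint8)
    n2 = np.zeros(L, dtype=np.uint8)
    n1[: L - 1] = arr[1:]
    n2[: L - 2] = arr[2:]
    return _codes_from_triplet(arr == _C, n1, n2)


def _context_codes_minus(arr: np.ndarray) -> np.ndarray:
    """Minus-strand codes: a reference G is a C on the minus strand whose
    downstream bases are the complements of the two reference bases to its left."""
    L = arr.size
    p1 = np.zeros(L, dtype=np.uint8)
    p2 = np.zeros(L, dtype=np.uint8)
    p1[1:] = arr[: L - 1]
    p2[2:] = arr[: L - 2]
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in ((_A, _T), (_T, _A), (_C, _G), (_G, _C), (_N, _N)):
        comp[a] = b
    return _codes_from_triplet(arr == _G, comp[p1], comp[p2])


def _codes_from_triplet(is_c: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    is_h1 = (n1 == _A) | (n1 == _T) | (n1 == _C)
    is_h2 = (n2 == _A) | (n2 == _T) | (n2 == _C)
    defined = ((n1 == _G) | is_h1) & ((n2 == _G) | is_h2)  # both downstream known, no N
    codes = np.zeros(is_c.size, dtype=np.int8)
    codes[is_c] = CTX_UNDEF
    codes[is_c & defined & (n1 == _G)] = CTX_CG
    codes[is_c & defined & is_h1 & (n2 == _G)] = CTX_CHG
    codes[is_c & defined & is_h1 & is_h2] = CTX_CHH
    return codes


def build_context_map(genome: Genome) -> ContextMap:
    """Classify every cytosine on both strands of every contig."""
    codes: dict[str, np.ndarray] = {}
    for name, seq in genome.contigs.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes[name] = np.stack([_context_codes_plus(arr), _context_codes_minus(arr)])
    return ContextMap(codes)


def sequence_array(genome: Genome, contig: str) -> np.ndarray:
    """Contig sequence as a uint8 array of ASCII codes (zero-copy view)."""
    return np.frombuffer(genome.contigs[contig].encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# I/O: FASTA, BED6, minimal GFF3
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly line-wrapped) multi-contig FASTA into a dict."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_genome(
    fasta_path: str | Path,
    annotations_path: str | Path | None = None,
    organelle_contigs: Iterable[str] = (),
) -> Genome:
    """Assemble a :class:`Genome` from a FASTA, optional BED/GFF annotations
    and an explicit list of organelle-control contig names (never inferred)."""
    contigs = read_fasta(fasta_path)
    classes = {c: NUCLEAR for c in contigs}
    for c in organelle_contigs:
        if c not in contigs:
            raise ConfigurationError(f"organelle contig {c!r} not present in FASTA")
        classes[c] = ORGANELLE_CONTROL
    annotations: list[Feature] = []
    if annotations_path is not None:
        p = str(annotations_path)
        if p.endswith((".gff", ".gff3")):
            annotations = read_gff3(p)
        else:
            annotations = read_bed(p)
    return Genome(contigs=contigs, contig_class=classes, annotations=annotations)


def read_bed(path: str | Path) -> list[Feature]:
    """Read BED6 (or BED4+) intervals; the name column encodes ``kind:id``
    when written by this package, otherwise kind defaults to ``other``."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line has fewer than 3 columns", str(path), lineno)
            try:
                contig, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"bad BED coordinates: {exc}", str(path), lineno)
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-." else "."
            kind, _, fid = name.partition(":")
            if kind not in FEATURE_KINDS:
                kind, fid = "other", name
            feats.append(Feature(contig, start, end, strand, kind, fid or name))
    return feats


def write_bed(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.kind}:{f.id}\t0\t{f.strand}\n")


_GFF_KIND = {
    "gene": "gene",
    "transposable_element": "TE",
    "transposable_element_gene": "TE",
    "heterochromatin": "heterochromatin",
    "chromosome_arm": "arm",
}


def read_gff3(path: str | Path) -> list[Feature]:
    """Minimal GFF3 reader: seqid, type, 1-based inclusive coords, strand, ID attr."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError("GFF3 line has fewer than 9 columns", str(path), lineno)
            contig, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise ParseError(f"bad GFF3 coordinates: {exc}", str(path), lineno)
            fid = ""
            for token in attrs.split(";"):
                if token.startswith("ID="):
                    fid = token[3:]
            feats.append(
                Feature(
                    contig,
                    start_i,
                    end_i,
                    strand if strand in "+-." else ".",
                    _GFF_KIND.get(ftype, "other"),
                    fid,
                )
            )
    return feats
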