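"""Core sequence types and substitution-tolerant motif matching.

Every stage of the pipeline is built on two primitives defined here: a
reverse-complement that is strict about its alphabet, and a fuzzy motif
matcher that scans a read for the best-placed window within a fixed
Hamming (substitution-only) budget.  Indel-tolerant matching is
deliberately not offered: keeping the mismatch model purely
substitutional is what makes the downstream CDR3 boundary arithmetic
(codon offsets relative to a motif hit) well defined.

Conventions
-----------
* Coordinates are 0-based, half-open throughout.
* ``N`` in a read always counts as a mismatch against any pattern base.
* A motif pattern is either a plain ``{A,C,G,T}`` literal or a literal
  with parenthesised alternation groups such as ``TGGGG(C|T)CAA``; a
  pattern expands to a finite set of literal alternatives and a window
  matches when *any* alternative matches within the budget.
* The leftmost qualifying window wins; at equal start the alternative
  with fewer substitutions (then the shorter one) wins.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class Orientation(str, Enum):
    """Whether a match was found in the read as given or after reverse-complementing."""

    AS_GIVEN = "as-given"
    REVERSE_COMPLEMENTED = "reverse-complemented"


class MotifRole(str, Enum):
    FORWARD_PRIMER = "forward-primer"
    ISOTYPE_MOTIF = "isotype-motif"
    REVERSE_PRIMER = "reverse-primer"
    PRE_CDR3 = "pre-CDR3"
    POST_CDR3 = "post-CDR3"


@dataclass(frozen=True)
class AmpliconRead:
    """One sequencing read with per-base Phred qualities and sample labels.

    Parameters
    ----------
    read_id:
        Unique identifier within a sample file.
    seq:
        Nucleotide string over ``{A,C,G,T,N}``.
    quals:
        Phred scores, one integer per base.
    cow_id, tissue, isotype:
        Sample labels; ``tissue`` is ``blood`` or ``colostrum`` and
        ``isotype`` is ``IgM`` or ``IgG``.
    """

    read_id: str
    seq: str
    quals: tuple[int, ...]
    cow_id: str = ""
    tissue: str = ""
    isotype: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quals)} "
                f"!= sequence length {len(self.seq)}"
            )
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(f"read {self.read_id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complemented(self) -> "AmpliconRead":
        """Return the read in the opposite orientation (qualities reversed too)."""
        return AmpliconRead(
            read_id=self.read_id,
            seq=reverse_complement(self.seq),
            quals=self.quals[::-1],
            cow_id=self.cow_id,
            tissue=self.tissue,
            isotype=self.isotype,
        )


@dataclass(frozen=True)
class MotifSpec:
    """A named nucleotide pattern with a substitution budget and boundary offsets.

    ``cdr3_boundary_offset`` locates the CDR3 edge relative to the match:
    for a pre-CDR3 motif it is the number of nt to skip after the match
    *end* before the CDR3 starts; for a post-CDR3 motif it is the signed
    offset from the match *start* to where the CDR3 ends.
    ``frame_offset`` is the number of nt from the match start to the
    first full codon boundary of the reading frame the motif anchors.
    """

    name: str
    pattern: str
    role: MotifRole
    max_subs: int = 0
    cdr3_boundary_offset: int = 0
    frame_offset: int = 0
    alternatives: tuple[str, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        alts = tuple(expand_pattern(self.pattern))
        object.__setattr__(self, "alternatives", alts)
        shortest = min(len(a) for a in alts)
        if self.max_subs < 0:
            raise ValueError(f"motif {self.name!r}: max_subs must be >= 0")
        if self.max_subs >= shortest:
            raise ValueError(
                f"motif {self.name!r}: max_subs {self.max_subs} >= shortest "
                f"literal length {shortest}"
            )


@dataclass(frozen=True)
class MatchResult:
    """A fuzzy motif hit: 0-based half-open window plus its substitution count."""

    start: int
    end: int
    substitutions: int
    orientation: Orientation = Orientation.AS_GIVEN

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid match window [{self.start}, {self.end})")


def reverse_complement(seq: str) -> str:
    """Reverse complement of ``seq``; ``N`` maps to ``N``.

    Raises
    ------
    ValueError
        If ``seq`` contains characters outside ``{A,C,G,T,N}``.
    """
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


_GROUP_RE = re.compile(r"\(([ACGT|]+)\)")


def expand_pattern(pattern: str) -> list[str]:
    """Expand a pattern with ``(X|Y|...)`` alternation groups into literals.

    A plain literal expands to itself.  Group contents are restricted to
    ``{A,C,G,T}`` segments separated by ``|``; whole-pattern top-level
    alternation may also be written ``LIT1|LIT2``.
    """
    if "|" in pattern and "(" not in pattern:
        branches = pattern.split("|")
    else:
        branches = [pattern]
    literals: list[str] = []
    for branch in branches:
        parts: list[Sequence[str]] = []
        pos = 0
        for m in _GROUP_RE.finditer(branch):
            if m.start() > pos:
                parts.append([branch[pos : m.start()]])
            parts.append(m.group(1).split("|"))
            pos = m.end()
        if pos < len(branch):
            parts.append([branch[pos:]])
        for combo in itertools.product(*parts):
            lit = "".join(combo)
            if not lit or set(lit) - set("ACGT"):
                raise ValueError(f"invalid motif pattern {pattern!r}")
            literals.append(lit)
    return literals


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_literal(seq_arr: np.ndarray, literal: str, max_subs: int) -> list[tuple[int, int, int]]:
    """All (start, end, substitutions) windows of ``literal`` within budget."""
    m = len(literal)
    if m > seq_arr.size:
        return []
    pat = _as_array(literal)
    windows = sliding_window_view(seq_arr, m)
    mismatches = (windows != pat).sum(axis=1)
    starts = np.flatnonzero(mismatches <= max_subs)
    return [(int(s), int(s) + m, int(mismatches[s])) for s in starts]


def find_fuzzy_all(seq: str, motif: MotifSpec) -> list[MatchResult]:
    """All windows matching any alternative of ``motif`` within its budget.

    Results are ordered left to right by start (then substitution count,
    then window length); overlapping hits are allowed.  An empty list
    means no match — patterns longer than the sequence simply never match.
    """
    arr = _as_array(seq)
    hits: list[tuple[int, int, int]] = []
    for literal in motif.alternatives:
        hits.extend(_scan_literal(arr, literal, motif.max_subs))
    hits.sort(key=lambda h: (h[0], h[2], h[1]))
    return [MatchResult(start=s, end=e, substitutions=d) for s, e, d in hits]


def find_fuzzy(seq: str, motif: MotifSpec) -> MatchResult | None:
    """Leftmost window matching ``motif`` within its substitution budget.

    Equivalent to the first element of :func:`find_fuzzy_all` (``None``
    when there is no hit at all).
    """
    hits = find_fuzzy_all(seq, motif)
    return hits[0] if hits else None


# --- translation ---------------------------------------------------------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def translate(nt: str) -> str:
    """Standard-code translation; codons containing ``N`` become ``X``.

    A trailing partial codon (length not divisible by 3) is dropped.
    Stop codons translate to ``*``.
    """
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        aa.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aa)


def iter_codons(nt: str) -> Iterator[str]:
    """Yield full codons of ``nt`` in frame 0 (trailing partial dropped)."""
    for i in range(0, len(nt) - len(nt) % 3, 3):
        yield nt[i : i + 3]
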