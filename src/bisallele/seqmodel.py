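"""Nucleotide sequence primitives shared by every pipeline stage.

Conventions used throughout the package:

* sequences are plain uppercase Python strings over ``A C G T N`` plus the
  IUPAC ambiguity codes (ambiguity codes are legal only in primers);
* coordinates are 0-based, half-open; any 1-based display is formatting only;
* the *assayed strand* is the strand the displayed reference and forward
  primer lie on — bisulfite conversion appears as C→T on this strand and as
  G→A on its reverse complement.

Primer degeneracy is written ``(A/G)`` in the wet-lab tables this package
mirrors; :func:`parse_primer` folds that notation into the single-letter
IUPAC code and :func:`to_slash_notation` re-emits it.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "InvalidSequenceError",
    "IUPAC_SETS",
    "COMPLEMENT",
    "ASSAYED",
    "OPPOSITE",
    "reverse_complement",
    "find_cpg_sites",
    "iupac_match",
    "parse_primer",
    "to_slash_notation",
    "is_concrete",
    "check_concrete",
    "read_fasta",
    "write_fasta",
]


class InvalidSequenceError(ValueError):
    """Raised for empty sequences, non-alphabet characters or ambiguity
    codes in a context that requires concrete bases."""


#: Strand tags. Exactly one must accompany every conversion/assayability call.
ASSAYED = "assayed"
OPPOSITE = "opposite"

#: IUPAC code -> set of concrete bases it stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}

#: Two-base IUPAC code -> display order used when re-emitting "(X/Y)"
#: notation.  The order matches the primer tables this package packages
#: ((A/G) for R, (T/G) for K, ...).
_SLASH_ORDER: dict[str, str] = {
    "R": "A/G", "Y": "C/T", "K": "T/G", "M": "A/C", "S": "C/G", "W": "A/T",
}
_SLASH_CODE: dict[frozenset[str], str] = {
    IUPAC_SETS[c]: c for c in _SLASH_ORDER
}

_CONCRETE = frozenset("ACGT")


def _check_alphabet(seq: str, what: str = "sequence") -> str:
    if not seq:
        raise InvalidSequenceError(f"empty {what}")
    up = seq.upper()
    bad = set(up) - set(IUPAC_SETS)
    if bad:
        raise InvalidSequenceError(
            f"non-alphabet character(s) {sorted(bad)!r} in {what}"
        )
    return up


def is_concrete(seq: str) -> bool:
    """True iff every base is one of A/C/G/T (N and ambiguity codes absent)."""
    return bool(seq) and set(seq.upper()) <= _CONCRETE


def check_concrete(seq: str, what: str = "sequence") -> str:
    """Uppercase ``seq`` and reject ambiguity codes (references and reads
    must be concrete; only primers may carry degenerate bases)."""
    up = _check_alphabet(seq, what)
    amb = set(up) - _CONCRETE - {"N"}
    if amb:
        raise InvalidSequenceError(
            f"ambiguity code(s) {sorted(amb)!r} not allowed in {what}"
        )
    return up


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    up = _check_alphabet(seq)
    return "".join(COMPLEMENT[b] for b in reversed(up))


def find_cpg_sites(seq: str) -> list[int]:
    """0-based positions of the C of every CpG dinucleotide.

    The input must be concrete (no ambiguity codes): CpG discovery on a
    degenerate sequence is ill-defined.  Positions are sorted and
    duplicate-free; overlap is impossible for a 2-mer but adjacent sites
    ("CGCG") are both reported.
    """
    up = _check_alphabet(seq)
    if set(up) - _CONCRETE:
        raise InvalidSequenceError(
            "find_cpg_sites requires a concrete A/C/G/T sequence"
        )
    return [i for i in range(len(up) - 1) if up[i] == "C" and up[i + 1] == "G"]


def iupac_match(pattern: str, target: str) -> list[int]:
    """All 0-based positions where ``pattern`` matches ``target`` exactly,
    expanding IUPAC codes in the pattern (the target must be concrete).

    A pattern longer than the target yields an empty list, not an error.
    With a concrete pattern this is plain substring search.
    """
    pat = _check_alphabet(pattern, "pattern")
    tgt = check_concrete(target, "target")
    m, n = len(pat), len(tgt)
    sets = [IUPAC_SETS[b] for b in pat]
    out = []
    for p in range(n - m + 1):
        if all(tgt[p + i] in sets[i] for i in range(m)):
            out.append(p)
    return out


_SLASH_RE = re.compile(r"\(([ACGT])/([ACGT])\)")


def parse_primer(text: str) -> str:
    """Fold ``(X/Y)`` degenerate-base notation into IUPAC codes.

    ``"CAG(A/G)"`` becomes ``"CAGR"``.  Case-insensitive; the result is the
    canonical uppercase form.  Raises :class:`InvalidSequenceError` if the
    two bases of a slash group are identical or the remainder is not
    alphabet.
    """
    up = text.upper().replace(" ", "")

    def sub(m: re.Match[str]) -> str:
        pair = frozenset((m.group(1), m.group(2)))
        if len(pair) != 2:
            raise InvalidSequenceError(f"degenerate base {m.group(0)} is not degenerate")
        return _SLASH_CODE[pair]

    folded = _SLASH_RE.sub(sub, up)
    return _check_alphabet(folded, "primer")


def to_slash_notation(seq: str) -> str:
    """Re-emit two-base IUPAC codes as ``(X/Y)`` groups (inverse of
    :func:`parse_primer` up to the fixed display order)."""
    out = []
    for b in seq.upper():
        if b in _SLASH_ORDER:
            out.append(f"({_SLASH_ORDER[b]})")
        else:
            out.append(b)
    return "".join(out)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record, wrapped or unwrapped) FASTA file into
    ``(name, uppercase sequence)`` tuples."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(name, sequence)`` tuples as FASTA."""
    seqrecs: Iterator[SeqRecord] = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    )
    SeqIO.write(seqrecs, str(path), "fasta")
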