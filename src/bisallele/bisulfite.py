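"""Deterministic in-silico bisulfite conversion.

Sodium bisulfite deaminates unmethylated cytosine to uracil (read as
thymine after PCR) while 5-methylcytosine is protected.  In the mammalian
context modelled here, methylation occurs only at CpG cytosines; every
other C therefore reads T after complete conversion.  On the assayed
strand the treatment appears as C→T; a reverse primer — being the reverse
complement of the converted assayed strand — shows the same chemistry as
G→A.

Conversion never inserts or deletes bases, so CpG and SNP coordinates on a
converted reference are identical to their genomic coordinates.

Stochastic conversion failure and over-conversion are modelled in
:mod:`bisallele.synthetic_data`, not here: these functions are pure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .seqmodel import (
    ASSAYED,
    InvalidSequenceError,
    check_concrete,
    find_cpg_sites,
    reverse_complement,
    _check_alphabet,
    _CONCRETE,
)

__all__ = [
    "METHYLATED",
    "UNMETHYLATED",
    "InvalidStateError",
    "ConvertedSeq",
    "convert_unmethylated",
    "convert_with_state",
    "convert_primer",
    "build_converted_reference",
]

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"


class InvalidStateError(ValueError):
    """A methylation state refers to a position that is not a CpG cytosine."""


@dataclass(frozen=True)
class ConvertedSeq:
    """A bisulfite-converted sequence that remembers where it came from.

    ``bases`` holds the converted string; at reference CpG cytosines the
    read-out depends on (unknown) methylation, so those positions are
    stored as the IUPAC wildcard ``Y`` (C or T) and listed in
    ``wildcard_positions``.  ``orientation`` records which conversion rule
    produced the sequence (``forward-like``: C→T; ``reverse-like``: G→A).
    """

    bases: str
    origin: str
    orientation: str = "forward-like"
    wildcard_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.origin):
            raise InvalidSequenceError("conversion must preserve length")


def convert_unmethylated(seq: str, strand: str = ASSAYED) -> ConvertedSeq:
    """Fully-unmethylated conversion of a concrete sequence: every C → T.

    Idempotent (the output is C-free, hence a fixed point).  ``strand``
    must be ``"assayed"``: to convert the opposite strand, reverse
    complement first so the C→T rule applies to the strand actually read.
    """
    if strand != ASSAYED:
        raise ValueError(
            "convert_unmethylated operates on the assayed strand; "
            "reverse-complement the input to convert the opposite strand"
        )
    up = check_concrete(seq)
    return ConvertedSeq(bases=up.replace("C", "T"), origin=up)


def convert_with_state(seq: str, state: Mapping[int, str]) -> ConvertedSeq:
    """Methylation-aware conversion.

    ``state`` maps CpG cytosine positions to ``"methylated"`` /
    ``"unmethylated"``; positions absent from the map are unmethylated.
    Non-CpG Cs always read T.  A key that is not a CpG cytosine of ``seq``
    raises :class:`InvalidStateError` — non-CpG methylation is out of
    model.
    """
    up = check_concrete(seq)
    cpg = set(find_cpg_sites(up))
    bad = [p for p in state if p not in cpg]
    if bad:
        raise InvalidStateError(
            f"state position(s) {sorted(bad)} are not CpG cytosines"
        )
    for p, v in state.items():
        if v not in (METHYLATED, UNMETHYLATED):
            raise InvalidStateError(f"unknown methylation value {v!r} at {p}")
    out = [
        "C" if (b == "C" and state.get(i) == METHYLATED) else
        ("T" if b == "C" else b)
        for i, b in enumerate(up)
    ]
    return ConvertedSeq(bases="".join(out), origin=up)


def convert_primer(primer: str, orientation: str) -> str:
    """Bisulfite-converted form of a PCR primer.

    ``forward`` primers lie on the assayed strand and convert C→T;
    ``reverse`` primers are reverse complements of the converted assayed
    strand, so the same chemistry manifests as G→A.  Degenerate IUPAC
    bases are preserved verbatim (they are printed unchanged in the primer
    tables this mirrors), even when an expansion contains C or G — the
    assay validator flags such positions instead.

    The strand-duality identity holds for concrete primers::

        convert_primer(p, "reverse")
            == reverse_complement(convert_unmethylated(reverse_complement(p)).bases)
    """
    up = _check_alphabet(primer, "primer")
    if orientation == "forward":
        return "".join("T" if b == "C" else b for b in up)
    if orientation == "reverse":
        return "".join("A" if b == "G" else b for b in up)
    raise ValueError(f"orientation must be 'forward' or 'reverse', got {orientation!r}")


def build_converted_reference(region: str) -> ConvertedSeq:
    """Conversion of a reference whose per-molecule methylation is unknown.

    Non-CpG Cs are forced to T; each CpG cytosine becomes the wildcard
    ``Y`` (matches C or T during alignment and primer matching) and is
    recorded in ``wildcard_positions``.
    """
    up = check_concrete(region)
    wild = find_cpg_sites(up)
    wildset = set(wild)
    out = [
        "Y" if i in wildset else ("T" if b == "C" else b)
        for i, b in enumerate(up)
    ]
    return ConvertedSeq(
        bases="".join(out),
        origin=up,
        wildcard_positions=tuple(wild),
    )
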