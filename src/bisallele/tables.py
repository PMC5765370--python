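"""Accessors for the packaged locus fixtures.

The package ships, as plain TSV data, the primer pairs (genomic and
printed bisulfite-converted forms) and the per-locus SNP screening
outcomes for ten mouse imprinting control regions assayed in a
C57BL/6J (B6) dam x CAST/EiJ sire hybrid background: Grb10, H19, Igf2r,
Impact, Lit1/Kcnq1ot1, Mest/Peg1, Peg3, Peg10, Snrpn and Zac1/Plagl1.

Two documented irregularities are preserved rather than corrected:

* the Igf2r reverse primer is listed with identical genomic and converted
  sequences even though it contains Gs — it violates the G→A rule every
  other reverse primer obeys (``expected_discrepancy`` below);
* the Impact reverse primer footprint contains a CpG, violating the
  CpG-free primer guideline; the assay validator flags it as a warning.

Unvalidated database records are carried as counts only (alleles and
identifiers were never transcribed); of the 75 failed records, 28 were
C/T polymorphisms that bisulfite sequencing cannot see, and exactly one
Sanger-database entry disagreed with resequencing — both figures are kept
here as metadata (:data:`CT_CONFOUNDED_AMONG_FAILED`,
:data:`SANGER_INCONSISTENT`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .snp_screen import GAP, SnpRecord

__all__ = [
    "PrimerRow",
    "EXPECTED_DISCREPANCIES",
    "CT_CONFOUNDED_AMONG_FAILED",
    "SANGER_INCONSISTENT",
    "table1_primers",
    "locus_info",
    "packaged_screening_records",
    "validated_snp_alleles",
]

#: (locus, orientation) pairs whose printed converted sequence is known
#: not to follow the conversion rule.
EXPECTED_DISCREPANCIES: frozenset[tuple[str, str]] = frozenset(
    {("Igf2r", "reverse")}
)

#: Among the 75 failed database records, how many were C/T (or opposite-
#: strand G/A) polymorphisms invisible to bisulfite sequencing.  Their
#: individual identities were never transcribed, so this count is
#: metadata, not derivable from the records.
CT_CONFOUNDED_AMONG_FAILED = 28

#: Number of records where the strain catalogue itself disagreed with
#: direct resequencing (reported G, observed C, on the B6 background).
SANGER_INCONSISTENT = 1


@dataclass(frozen=True)
class PrimerRow:
    """One locus's primer pair as printed: genomic and converted forms,
    in ``(X/Y)`` degenerate notation."""

    locus: str
    fwd_genomic: str
    fwd_converted: str
    rev_genomic: str
    rev_converted: str


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("bisallele.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def table1_primers() -> dict[str, PrimerRow]:
    """Primer pairs for all ten loci, keyed by locus name."""
    df = _read("table1_primers.tsv")
    return {
        row.locus: PrimerRow(
            locus=row.locus,
            fwd_genomic=row.fwd_genomic,
            fwd_converted=row.fwd_converted,
            rev_genomic=row.rev_genomic,
            rev_converted=row.rev_converted,
        )
        for row in df.itertuples()
    }


def locus_info() -> pd.DataFrame:
    """Per-locus assay metadata: imprint direction, strand note, amplicon
    length, CpG count and reported/validated SNP tallies (index: locus)."""
    df = _read("loci.tsv").set_index("locus")
    for col in ("amplicon_bp", "cpg_count", "reported_snps", "validated_snps"):
        df[col] = df[col].astype(int)
    return df


def _parse_allele(s: str) -> str | None:
    s = s.strip()
    if s == ".":
        return None
    return GAP if s in ("-", "−") else s


def packaged_screening_records() -> list[SnpRecord]:
    """All 94 screening records (93 database-reported + 1 novel), with
    alleles where transcribed and ``alleles=None`` placeholders for the
    records known only by count and outcome."""
    df = _read("screening_records.tsv")
    records = []
    for row in df.itertuples():
        a = _parse_allele(row.allele_b6)
        b = _parse_allele(row.allele_cast)
        alleles = None if a is None or b is None else (a, b)
        records.append(
            SnpRecord(
                locus=row.locus,
                position=None,
                alleles=alleles,
                source=frozenset(row.sources.split(",")),
                identifier=row.identifier,
                validation_status=row.validation_status,
                note=row.note,
            )
        )
    return records


def validated_snp_alleles() -> dict[str, list[tuple[str, str]]]:
    """Validated (B6, CAST) allele pairs per locus, in table order (the
    novel Snrpn call included)."""
    out: dict[str, list[tuple[str, str]]] = {}
    for rec in packaged_screening_records():
        if rec.validation_status == "validated":
            assert rec.alleles is not None
            out.setdefault(rec.locus, []).append(rec.alleles)
    return out
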