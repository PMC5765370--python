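"""SNP merging and bisulfite-assayability screening.

Candidate strain polymorphisms arrive from several databases (dbSNP, the
European Variation Archive, the Sanger strain catalogue) plus occasionally
a novel call made directly from sequencing.  Before an allele-specific
bisulfite assay can rely on a SNP, two questions must be answered:

1. is the record real (validation happens at the bench; this module just
   carries the status), and
2. can bisulfite sequencing *see* it?  Conversion collapses unmethylated C
   onto T, so a C/T polymorphism on the read strand (equivalently G/A when
   reading the opposite strand) becomes invisible, and a SNP that creates
   or destroys a CpG has a methylation-dependent read-out.

:func:`classify_assayability` encodes those rules; an exhaustive
conversion-simulation oracle in the test-suite checks them for every
ordered allele pair, strand and context.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from .seqmodel import (
    ASSAYED,
    OPPOSITE,
    COMPLEMENT,
    check_concrete,
)

__all__ = [
    "GAP",
    "ASSAYABLE",
    "CONVERSION_CONFOUNDED",
    "CPG_CONTEXT_UNRELIABLE",
    "INDEL_ASSAYABLE",
    "SnpRecord",
    "AssayabilityVerdict",
    "LoadResult",
    "ScreeningSummary",
    "load_snp_records",
    "classify_assayability",
    "summarize_screening",
]

#: Canonical gap symbol for the deleted side of an indel allele.
GAP = "-"

ASSAYABLE = "assayable"
CONVERSION_CONFOUNDED = "conversion_confounded"
CPG_CONTEXT_UNRELIABLE = "cpg_context_unreliable"
INDEL_ASSAYABLE = "indel_assayable"

VALIDATED = "validated"
FAILED = "failed"
UNTESTED = "untested"

_KNOWN_SOURCES = {"dbSNP", "EVA", "Sanger", "novel"}


@dataclass(frozen=True)
class SnpRecord:
    """One candidate polymorphism between the B6 (dam-side) and CAST
    (sire-side) genomes, expressed on the assayed strand.

    ``alleles`` is the ordered (B6, CAST) pair; ``"-"`` marks the deleted
    side of an indel.  ``alleles`` may be ``None`` for records whose
    identity was never transcribed (only their existence and validation
    outcome are known).  ``position`` is 0-based on the assayed strand of
    the assay region, or ``None`` when unknown.
    """

    locus: str
    position: int | None
    alleles: tuple[str, str] | None
    source: frozenset[str] = frozenset()
    identifier: str = ""
    validation_status: str = UNTESTED
    conflict: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = self.alleles
            if a == b:
                raise ValueError(f"{self.locus}: alleles must differ, got {a}/{b}")
            if a == GAP and b == GAP:
                raise ValueError(f"{self.locus}: gap on both sides")
        bad = self.source - _KNOWN_SOURCES
        if bad:
            raise ValueError(f"unknown source(s) {sorted(bad)}")
        if self.source == {"novel"} and self.identifier:
            raise ValueError("novel records carry no database identifier")

    @property
    def is_indel(self) -> bool:
        if self.alleles is None:
            return False
        a, b = self.alleles
        return GAP in (a, b) or len(a) != len(b)

    def footprint(self) -> int:
        """Number of reference (B6-allele) bases the SNP occupies."""
        if self.alleles is None:
            raise ValueError("footprint of a record with unknown alleles")
        a = self.alleles[0]
        return 0 if a == GAP else len(a)


@dataclass(frozen=True)
class AssayabilityVerdict:
    category: str
    strand_rescuable: bool
    rationale: str


@dataclass
class LoadResult:
    records: list[SnpRecord]
    parse_errors: list[str] = field(default_factory=list)


def _norm_allele(raw: object) -> str:
    s = str(raw).strip().upper().replace("−", GAP)
    if s in ("", ".", GAP, "DEL"):
        return GAP
    if not set(s) <= set("ACGT"):
        raise ValueError(f"malformed allele {raw!r}")
    return s


def _complement_allele(a: str) -> str:
    if a == GAP:
        return GAP
    return "".join(COMPLEMENT[b] for b in reversed(a))


def load_snp_records(
    tables: Mapping[str, "pd.DataFrame | str | Path"],
) -> LoadResult:
    """Merge per-source tabular SNP exports into deduplicated records.

    ``tables`` maps a source name (``dbSNP`` / ``EVA`` / ``Sanger``) to a
    DataFrame or a TSV path with columns ``locus, position, strand,
    allele_b6, allele_cast, identifier``.  Rows reported on the opposite
    strand are complemented onto the assayed strand at load time.  Records
    are deduplicated by ``(locus, position)``; sources are unioned and
    allele disagreements between sources are flagged on the record rather
    than dropped.  Malformed rows become entries in
    :attr:`LoadResult.parse_errors`, never a crash.
    """
    merged: dict[tuple[str, int], SnpRecord] = {}
    errors: list[str] = []
    for source, table in tables.items():
        if source not in _KNOWN_SOURCES:
            errors.append(f"{source}: unknown source name")
            continue
        df = (
            table
            if isinstance(table, pd.DataFrame)
            else pd.read_csv(table, sep="\t", dtype=str)
        )
        for i, row in df.iterrows():
            try:
                locus = str(row["locus"]).strip()
                position = int(row["position"])
                strand = str(row.get("strand", ASSAYED) or ASSAYED).strip()
                a = _norm_allele(row["allele_b6"])
                b = _norm_allele(row["allele_cast"])
                if strand == OPPOSITE:
                    a, b = _complement_allele(a), _complement_allele(b)
                elif strand != ASSAYED:
                    raise ValueError(f"unknown strand {strand!r}")
                ident = str(row.get("identifier", "") or "").strip()
                rec = SnpRecord(
                    locus=locus,
                    position=position,
                    alleles=(a, b),
                    source=frozenset({source}),
                    identifier=ident,
                )
            except (KeyError, ValueError) as exc:
                errors.append(f"{source} row {i}: {exc}")
                continue
            key = (rec.locus, rec.position)
            if key not in merged:
                merged[key] = rec
                continue
            prev = merged[key]
            conflict = prev.conflict or (prev.alleles != rec.alleles)
            note = prev.note
            if prev.alleles != rec.alleles and not prev.conflict:
                note = (
                    f"allele conflict: {prev.alleles} vs {rec.alleles} ({source})"
                )
            merged[key] = replace(
                prev,
                source=prev.source | rec.source,
                identifier=prev.identifier or rec.identifier,
                conflict=conflict,
                note=note,
            )
    records = [merged[k] for k in sorted(merged)]
    return LoadResult(records=records, parse_errors=errors)


def _classify_on_read_strand(
    b6: str, cast: str, left: str, right: str
) -> str:
    """Category for a single-base substitution read on the strand whose
    conversion rule is C→T, given the immediate neighbours on that strand.

    Rule order matters: the blanket C/T exclusion precedes the CpG-context
    rule (a C/T SNP next to a G is confounded, not merely unreliable).
    """
    pair = {b6, cast}
    if pair == {"C", "T"}:
        return CONVERSION_CONFOUNDED
    for allele in pair:
        if (allele == "C" and right == "G") or (allele == "G" and left == "C"):
            return CPG_CONTEXT_UNRELIABLE
    # {G, A} and every remaining substitution read out unchanged: G and A
    # are untouched by C→T conversion, and a lone C (paired with A or G)
    # deterministically reads T outside CpG context.
    return ASSAYABLE


def classify_assayability(
    snp: SnpRecord, context: str, strand: str = ASSAYED
) -> AssayabilityVerdict:
    """Decide whether bisulfite sequencing can genotype ``snp``.

    ``context`` is the assayed-strand sequence covering the SNP's
    B6-allele footprint plus exactly one base on each side (so a
    substitution SNP sits at ``context[1]``).  ``strand`` names the strand
    the assay actually reads.

    Categories, in rule order: length-changing alleles survive conversion
    as gaps (``indel_assayable``); C/T on the read strand is invisible
    (``conversion_confounded``, with ``strand_rescuable`` true iff the
    complementary G/A is cleanly assayable reading the other strand); an
    allele that creates a CpG with its neighbour has a
    methylation-dependent read-out (``cpg_context_unreliable``); everything
    else is ``assayable``.
    """
    if snp.alleles is None:
        raise ValueError("cannot classify a record with unknown alleles")
    ctx = check_concrete(context, "context")
    b6, cast = snp.alleles

    if snp.is_indel:
        return AssayabilityVerdict(
            category=INDEL_ASSAYABLE,
            strand_rescuable=False,
            rationale="length-changing alleles survive conversion as an alignment gap",
        )
    if len(b6) != 1:
        raise ValueError("multi-base equal-length substitutions are out of model")
    if len(ctx) < 3:
        raise IndexError("context must cover the SNP position plus one base each side")

    left, right = ctx[0], ctx[2]
    if strand == OPPOSITE:
        # Reading the opposite strand: complement the alleles and swap /
        # complement the neighbours, then apply the C→T rules there.
        b6, cast = COMPLEMENT[b6], COMPLEMENT[cast]
        left, right = COMPLEMENT[right], COMPLEMENT[left]
    elif strand != ASSAYED:
        raise ValueError(f"unknown strand {strand!r}")

    category = _classify_on_read_strand(b6, cast, left, right)
    rescuable = False
    if category == CONVERSION_CONFOUNDED:
        other = _classify_on_read_strand(
            COMPLEMENT[b6], COMPLEMENT[cast], COMPLEMENT[right], COMPLEMENT[left]
        )
        rescuable = other == ASSAYABLE
    rationale = {
        CONVERSION_CONFOUNDED: (
            "C/T on the read strand: unmethylated C reads T, alleles collapse"
        ),
        CPG_CONTEXT_UNRELIABLE: (
            "an allele forms a CpG with its neighbour; read-out depends on methylation"
        ),
        ASSAYABLE: "alleles remain distinguishable after conversion",
    }[category]
    return AssayabilityVerdict(
        category=category, strand_rescuable=rescuable, rationale=rationale
    )


@dataclass(frozen=True)
class ScreeningSummary:
    """Per-locus and overall screening tallies.

    ``reported`` counts database-reported records (novel calls are outside
    every database and tallied separately in ``validated_novel``).  The
    validation rate is an integer percent, rounded half-up, of
    database-validated over database-reported; ``None`` when nothing was
    reported.
    """

    per_locus: pd.DataFrame
    reported: int
    validated: int
    failed: int
    untested: int
    validated_novel: int
    confounded: int
    rate_percent: int | None


def _half_up_percent(num: int, den: int) -> int:
    return int(100 * num / den + 0.5)


def summarize_screening(records: list[SnpRecord]) -> ScreeningSummary:
    """Tally screening outcomes; totals are sums of per-locus counts and
    invariant under record order."""
    rows: dict[str, dict[str, int]] = {}
    cols = [
        "reported", "validated", "failed", "untested",
        "validated_novel", "validated_total", "confounded",
    ]
    for rec in records:
        row = rows.setdefault(rec.locus, {c: 0 for c in cols})
        is_novel_only = rec.source == {"novel"}
        if is_novel_only:
            if rec.validation_status == VALIDATED:
                row["validated_novel"] += 1
                row["validated_total"] += 1
            continue
        row["reported"] += 1
        if rec.validation_status == VALIDATED:
            row["validated"] += 1
            row["validated_total"] += 1
        elif rec.validation_status == FAILED:
            row["failed"] += 1
        else:
            row["untested"] += 1
        if rec.note == CONVERSION_CONFOUNDED or "C/T" in rec.note:
            row["confounded"] += 1
    per_locus = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    per_locus = per_locus.sort_index()
    totals = per_locus.sum() if len(per_locus) else pd.Series(0, index=cols)
    reported = int(totals.get("reported", 0))
    validated = int(totals.get("validated", 0))
    return ScreeningSummary(
        per_locus=per_locus,
        reported=reported,
        validated=validated,
        failed=int(totals.get("failed", 0)),
        untested=int(totals.get("untested", 0)),
        validated_novel=int(totals.get("validated_novel", 0)),
        confounded=int(totals.get("confounded", 0)),
        rate_percent=_half_up_percent(validated, reported) if reported else None,
    )
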