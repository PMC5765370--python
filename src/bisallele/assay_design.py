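"""Bisulfite primer-pair and assay validation, plus in-silico PCR.

Bisulfite PCR primers anneal to the *converted* template, so their design
is constrained: a CpG under a primer footprint has an unknown (methylation
dependent) template base, and any genomic C in a forward primer must be
written as T (G as A in a reverse primer).  This module checks a primer
pair against those constraints, locates its binding sites on a converted
reference, demands a unique product, and profiles the amplicon (length,
CpG content, SNP coverage).

The CpG-under-primer check is a high-severity warning rather than a
rejection: working assays exist whose primers break the guideline, and a
validator that refused them would be unable to describe the packaged
assay set (the Impact reverse primer covers a CpG).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from Bio.SeqUtils import MeltingTemp

from .bisulfite import ConvertedSeq, convert_primer
from .seqmodel import (
    IUPAC_SETS,
    check_concrete,
    find_cpg_sites,
    iupac_match,
    parse_primer,
    reverse_complement,
    _check_alphabet,
)
from .snp_screen import (
    ASSAYABLE,
    INDEL_ASSAYABLE,
    SnpRecord,
    classify_assayability,
)

__all__ = [
    "PcrProtocol",
    "PrimerPair",
    "AmpliconAssay",
    "Amplicon",
    "AmpliconStats",
    "Finding",
    "ValidationReport",
    "NoBindingSiteError",
    "NoProductError",
    "NonUniqueProductError",
    "InvalidGridError",
    "primer_tm",
    "validate_primer_pair",
    "in_silico_pcr",
    "amplicon_profile",
    "optimization_grid",
]


class NoBindingSiteError(ValueError):
    """A primer has no binding site on the region."""


class NoProductError(ValueError):
    """In-silico PCR found no viable product."""


class NonUniqueProductError(ValueError):
    """In-silico PCR found more than one viable product."""

    def __init__(self, products: list["Amplicon"]):
        self.products = products
        super().__init__(
            f"{len(products)} viable products: "
            + ", ".join(f"[{p.start},{p.end})" for p in products)
        )


class InvalidGridError(ValueError):
    """An optimisation-grid axis is empty or negative."""


@dataclass(frozen=True)
class PcrProtocol:
    """One PCR condition.  Pure metadata — never executed."""

    mgcl2_mM: float | None = None
    dmso_percent: float | None = None
    anneal_C: float | None = None
    cycles: int | None = None
    notes: str = ""


@dataclass(frozen=True)
class PrimerPair:
    """A bisulfite primer pair (IUPAC canonical strings; degenerate bases
    allowed) together with its stored converted forms.

    The stored converted forms may come from an external table and are
    checked against recomputation by :func:`validate_primer_pair` rather
    than silently replaced.
    """

    forward: str
    reverse: str
    converted_forward: str
    converted_reverse: str

    @classmethod
    def from_genomic(cls, forward: str, reverse: str) -> "PrimerPair":
        fwd = parse_primer(forward)
        rev = parse_primer(reverse)
        return cls(
            forward=fwd,
            reverse=rev,
            converted_forward=convert_primer(fwd, "forward"),
            converted_reverse=convert_primer(rev, "reverse"),
        )

    @classmethod
    def from_printed(
        cls, fwd_genomic: str, fwd_converted: str,
        rev_genomic: str, rev_converted: str,
    ) -> "PrimerPair":
        """Build from printed table strings in ``(X/Y)`` notation, keeping
        the printed converted forms verbatim."""
        return cls(
            forward=parse_primer(fwd_genomic),
            reverse=parse_primer(rev_genomic),
            converted_forward=parse_primer(fwd_converted),
            converted_reverse=parse_primer(rev_converted),
        )


@dataclass(frozen=True)
class AmpliconAssay:
    """A complete allele-specific methylation assay definition."""

    locus: str
    region: str
    pair: PrimerPair
    imprint_direction: str  # maternal_methylated | paternal_methylated
    validated_snps: tuple[SnpRecord, ...] = ()
    protocol: PcrProtocol | None = None
    strand_note: str = "as_assembly"  # or "reversed"

    def __post_init__(self) -> None:
        if self.imprint_direction not in (
            "maternal_methylated", "paternal_methylated"
        ):
            raise ValueError(f"bad imprint_direction {self.imprint_direction!r}")


@dataclass(frozen=True)
class Amplicon:
    """A unique in-silico PCR product, 0-based half-open on the region."""

    start: int
    end: int
    fwd_site: int
    rev_site: int
    converted_bases: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AmpliconStats:
    length_bp: int
    cpg_count: int
    snps_covered: int
    snps_assayable: int
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class Finding:
    code: str
    severity: str  # info | warning | error
    message: str


@dataclass
class ValidationReport:
    locus: str
    findings: list[Finding] = field(default_factory=list)
    fwd_length: int = 0
    rev_length: int = 0
    fwd_tm: float = 0.0
    rev_tm: float = 0.0
    tm_difference: float = 0.0
    cpgs_under_fwd: list[int] = field(default_factory=list)
    cpgs_under_rev: list[int] = field(default_factory=list)
    degenerate_positions: list[dict] = field(default_factory=list)
    conversion_consistent: dict[str, bool] = field(default_factory=dict)

    def has(self, code: str) -> bool:
        return any(f.code == code for f in self.findings)


def _expansions(seq: str) -> list[str]:
    pools = [sorted(IUPAC_SETS[b]) for b in seq]
    return ["".join(p) for p in itertools.product(*pools)]


def primer_tm(primer: str) -> float:
    """Nearest-neighbour melting temperature, 50 mM monovalent salt, to
    0.1 degC; degenerate primers report the mean over IUPAC expansions.
    Advisory only."""
    up = _check_alphabet(primer, "primer")
    tms = [MeltingTemp.Tm_NN(e, Na=50) for e in _expansions(up)]
    return round(sum(tms) / len(tms), 1)


def _wildcard_sites(pattern: str, text: str) -> list[int]:
    """Match with IUPAC sets on *both* sides (the converted reference uses
    Y at CpG cytosines): position p matches iff every pairwise base-set
    intersection is non-empty.  Full-length exact matching, no mismatches."""
    sets_p = [IUPAC_SETS[b] for b in pattern]
    sets_t = [IUPAC_SETS[b] for b in text]
    m, n = len(pattern), len(text)
    return [
        p
        for p in range(n - m + 1)
        if all(sets_p[i] & sets_t[p + i] for i in range(m))
    ]


def in_silico_pcr(converted_region: ConvertedSeq, pair: PrimerPair) -> Amplicon:
    """Locate the unique PCR product of ``pair`` on a converted reference.

    Both primers are matched in converted form, honouring the reference's
    CpG wildcards; the reverse primer binds where its reverse complement
    appears on the displayed strand.  Exactly one forward/reverse site
    combination with the forward 5' of the reverse is required: zero sites
    raise :class:`NoProductError`, several viable combinations raise
    :class:`NonUniqueProductError` listing all products.
    """
    text = converted_region.bases
    fwd = pair.converted_forward
    rev_rc = reverse_complement(pair.converted_reverse)
    fwd_sites = _wildcard_sites(fwd, text)
    rev_sites = _wildcard_sites(rev_rc, text)
    if not fwd_sites or not rev_sites:
        missing = "forward" if not fwd_sites else "reverse"
        raise NoProductError(f"no binding site for the {missing} primer")
    products = [
        Amplicon(
            start=f,
            end=r + len(rev_rc),
            fwd_site=f,
            rev_site=r,
            converted_bases=text[f : r + len(rev_rc)],
        )
        for f in fwd_sites
        for r in rev_sites
        if r >= f and r + len(rev_rc) >= f + len(fwd)
    ]
    if not products:
        raise NoProductError("primer sites are not in productive orientation")
    if len(products) > 1:
        raise NonUniqueProductError(products)
    return products[0]


def amplicon_profile(
    amplicon: Amplicon,
    genomic_region: str,
    snps: Sequence[SnpRecord] = (),
) -> AmpliconStats:
    """Profile a product on the *genomic* (unconverted) region: length,
    CpG count between the primers inclusive, and SNP coverage.  A SNP
    whose footprint touches the final base still counts as covered."""
    region = check_concrete(genomic_region, "region")
    sub = region[amplicon.start : amplicon.end]
    cpgs = find_cpg_sites(sub)
    covered = []
    for snp in snps:
        if snp.position is None:
            continue
        fp = max(snp.footprint(), 1)
        if amplicon.start <= snp.position and snp.position + fp <= amplicon.end:
            covered.append(snp)
    assayable = 0
    for snp in covered:
        assert snp.position is not None
        fp = max(snp.footprint(), 1)
        ctx = region[snp.position - 1 : snp.position + fp + 1]
        verdict = classify_assayability(snp, ctx)
        if verdict.category in (ASSAYABLE, INDEL_ASSAYABLE):
            assayable += 1
    warnings = []
    if not cpgs:
        warnings.append("assay-useless: product contains no CpG site")
    return AmpliconStats(
        length_bp=amplicon.length,
        cpg_count=len(cpgs),
        snps_covered=len(covered),
        snps_assayable=assayable,
        warnings=tuple(warnings),
    )


def validate_primer_pair(
    pair: PrimerPair,
    region: str,
    snps: Sequence[SnpRecord] = (),
    max_product_bp: int = 1000,
) -> ValidationReport:
    """Check a primer pair against the bisulfite design constraints.

    Reported findings: CpG dinucleotides under either primer footprint on
    the genomic region (high-severity warning, not an error); degenerate
    primer positions and whether each coincides with a known SNP; length
    and nearest-neighbour melting temperature of each primer and their
    difference; whether the stored converted forms match recomputation
    (``conversion-inconsistency`` finding when not); product length above
    ``max_product_bp``.  A primer with no binding site on the converted
    region raises :class:`NoBindingSiteError`.
    """
    reg = check_concrete(region, "region")
    from .bisulfite import build_converted_reference

    conv = build_converted_reference(reg)
    # binding is a property of the genomic primer under the conversion
    # rules; sites are found with the recomputed converted forms so a
    # mistranscribed stored form is reported, not fatal
    fwd_sites = _wildcard_sites(convert_primer(pair.forward, "forward"), conv.bases)
    rev_sites = _wildcard_sites(
        reverse_complement(convert_primer(pair.reverse, "reverse")), conv.bases
    )
    if not fwd_sites:
        raise NoBindingSiteError("forward primer not found on the region")
    if not rev_sites:
        raise NoBindingSiteError("reverse primer not found on the region")
    f0, r0 = fwd_sites[0], rev_sites[-1]
    rev_len = len(pair.reverse)
    fwd_len = len(pair.forward)

    report = ValidationReport(locus="", fwd_length=fwd_len, rev_length=rev_len)
    report.fwd_tm = primer_tm(pair.forward)
    report.rev_tm = primer_tm(pair.reverse)
    report.tm_difference = round(abs(report.fwd_tm - report.rev_tm), 1)

    region_cpgs = find_cpg_sites(reg)
    fwd_span = range(f0, f0 + fwd_len)
    rev_span = range(r0, r0 + rev_len)
    report.cpgs_under_fwd = [
        p for p in region_cpgs if p in fwd_span or p + 1 in fwd_span
    ]
    report.cpgs_under_rev = [
        p for p in region_cpgs if p in rev_span or p + 1 in rev_span
    ]
    for side, hits in (("forward", report.cpgs_under_fwd),
                       ("reverse", report.cpgs_under_rev)):
        if hits:
            report.findings.append(
                Finding(
                    code="cpg-under-primer",
                    severity="warning",
                    message=(
                        f"{side} primer footprint covers CpG(s) at "
                        f"region position(s) {hits}; template base there is "
                        "methylation-dependent"
                    ),
                )
            )

    snp_positions = {
        s.position for s in snps if s.position is not None
    }
    for side, primer, start in (("forward", pair.forward, f0),
                                ("reverse", pair.reverse, r0)):
        for i, b in enumerate(primer):
            if len(IUPAC_SETS[b]) > 1:
                pos = start + i
                entry = {
                    "orientation": side,
                    "primer_index": i,
                    "region_position": pos,
                    "snp_coincident": pos in snp_positions,
                }
                report.degenerate_positions.append(entry)
                report.findings.append(
                    Finding(
                        code="degenerate-base",
                        severity="info",
                        message=(
                            f"{side} primer degenerate base {b} at region "
                            f"position {pos}"
                            + (" coincides with a known SNP"
                               if entry["snp_coincident"] else "")
                        ),
                    )
                )

    for side, genomic, stored in (
        ("forward", pair.forward, pair.converted_forward),
        ("reverse", pair.reverse, pair.converted_reverse),
    ):
        recomputed = convert_primer(genomic, side)
        ok = recomputed == stored
        report.conversion_consistent[side] = ok
        if not ok:
            report.findings.append(
                Finding(
                    code="conversion-inconsistency",
                    severity="error",
                    message=(
                        f"{side} primer stored converted form {stored} does "
                        f"not match recomputed {recomputed}"
                    ),
                )
            )

    product_len = r0 + rev_len - f0
    if product_len > max_product_bp:
        report.findings.append(
            Finding(
                code="product-too-long",
                severity="warning",
                message=f"product length {product_len} bp exceeds {max_product_bp} bp",
            )
        )
    return report


def optimization_grid(
    mgcl2_levels: Sequence[float], dmso_levels: Sequence[float]
) -> list[PcrProtocol]:
    """Full-factorial MgCl2 x DMSO optimisation grid, MgCl2-major order.
    The canonical screen is four MgCl2 concentrations (1.5, 2.5, 3.5,
    4.5 mM) against three DMSO concentrations (0, 1.5, 5%): 12 conditions.
    """
    if not mgcl2_levels or not dmso_levels:
        raise InvalidGridError("both grid axes must be non-empty")
    if any(v < 0 for v in mgcl2_levels) or any(v < 0 for v in dmso_levels):
        raise InvalidGridError("grid levels must be non-negative")
    return [
        PcrProtocol(mgcl2_mM=m, dmso_percent=d)
        for m in mgcl2_levels
        for d in dmso_levels
    ]
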