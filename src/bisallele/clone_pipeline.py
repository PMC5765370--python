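"""Clone alignment, methylation calling, allele assignment and imprint
verification.

This is the computational equivalent of reading a panel of Sanger-cloned
bisulfite PCR products: each TA clone is one molecule, aligned globally to
the bisulfite-converted reference; per-CpG methylation is called from the
C/T read-out; strain SNPs genotype the molecule onto the maternal or
paternal allele of the hybrid cross; and the per-allele methylation means
are checked against the expected imprint direction.

Alignment uses an affine-gap global aligner over the alphabet
``A C G T N Y`` where ``Y`` marks reference CpG cytosines and scores as a
match against either C or T (methylation there is unknown until read).
Scoring: match +1, mismatch -1, gap open -4, gap extend -1 per base (a gap
of length L costs 4 + L).  ``N`` read bases score neutrally (0) and are
excluded from every statistic.

Because the reference is built from the dam-side (B6) haplotype, clones
from the sire-side allele legitimately mismatch it at every SNP; identity
and conversion-rate statistics therefore exclude known SNP footprint
columns as well as CpG columns, so a perfect read of either allele scores
identity 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .assay_design import AmpliconAssay
from .bisulfite import (
    METHYLATED,
    UNMETHYLATED,
    ConvertedSeq,
    build_converted_reference,
)
from .seqmodel import check_concrete, find_cpg_sites, reverse_complement
from .snp_screen import GAP, SnpRecord

__all__ = [
    "MISSING",
    "MATERNAL",
    "PATERNAL",
    "UNASSIGNED",
    "CloneRead",
    "AlignedClone",
    "Cross",
    "LollipopMatrix",
    "ImprintVerdict",
    "PipelineResult",
    "make_aligner",
    "align_clone",
    "qc_clone",
    "call_methylation",
    "genotype_and_assign",
    "aggregate_and_verify",
    "render_lollipop",
    "render_lollipop_svg",
    "analyze_clones",
]

MISSING = "missing"
MATERNAL = "maternal"
PATERNAL = "paternal"
UNASSIGNED = "unassigned"

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = 4.0   # charged once when a gap opens
GAP_EXTEND = 1.0  # charged per gapped base

_ALPHABET = "ACGTNY"


@dataclass(frozen=True)
class CloneRead:
    """One Sanger TA-clone consensus (base calls only, no qualities)."""

    id: str
    bases: str


@dataclass(frozen=True)
class Cross:
    """Which strain is the dam decides which haplotype is maternal.
    The canonical design is a B6 dam x CAST sire."""

    dam: str = "B6"
    sire: str = "CAST"


@dataclass
class AlignedClone:
    """A clone aligned to the converted reference, with fields filled in
    by successive pipeline stages (``align_clone`` -> ``qc_clone`` ->
    ``call_methylation`` -> ``genotype_and_assign``)."""

    read: CloneRead
    ref: ConvertedSeq
    orientation: str = "forward"
    score: float = 0.0
    ref_to_read: dict[int, str] = field(default_factory=dict)
    identity: float | None = None
    conversion_rate: float | None = None
    qc_pass: bool | None = None
    qc_reason: str = ""
    methylation_calls: dict[int, str] = field(default_factory=dict)
    snp_calls: dict[int, str] = field(default_factory=dict)
    informative_snps: int = 0
    allele: str = UNASSIGNED


def make_aligner() -> Align.PairwiseAligner:
    """Global affine-gap aligner with the package scoring scheme and the
    CpG ``Y`` wildcard (matches C or T)."""
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if "N" in (a, b):
                m[a, b] = 0.0
            elif a == b:
                m[a, b] = MATCH_SCORE
            else:
                m[a, b] = MISMATCH_SCORE
    for b in "CT":
        m["Y", b] = MATCH_SCORE
        m[b, "Y"] = MATCH_SCORE
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    # Biopython charges open_gap_score for the first gapped base and
    # extend_gap_score for each further one; open(4) + extend(1)/base
    # therefore maps to -5 / -1.
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = make_aligner()


def align_clone(read: CloneRead, ref: ConvertedSeq) -> AlignedClone:
    """Globally align a clone to the converted reference.

    Both read orientations are tried (TA cloning inserts either way); the
    higher-scoring one is kept, ties going to forward.  Poor alignments
    are a QC matter, never an error here.
    """
    bases = check_concrete(read.bases, "clone read")
    fwd = bases
    rev = reverse_complement(bases)
    aln_f = _ALIGNER.align(ref.bases, fwd)[0]
    aln_r = _ALIGNER.align(ref.bases, rev)[0]
    if aln_r.score > aln_f.score:
        aln, orientation = aln_r, "reverse"
    else:
        aln, orientation = aln_f, "forward"
    ref_row, read_row = str(aln[0]), str(aln[1])
    mapping: dict[int, str] = {}
    rp = 0
    for rc, qc in zip(ref_row, read_row):
        if rc != "-":
            mapping[rp] = qc  # '-' where the read has a deletion
            rp += 1
    return AlignedClone(
        read=read,
        ref=ref,
        orientation=orientation,
        score=float(aln.score),
        ref_to_read=mapping,
    )


def qc_clone(
    ac: AlignedClone,
    min_identity: float = 0.80,
    min_conversion: float = 0.95,
    exclude: Sequence[int] = (),
) -> AlignedClone:
    """Compute identity and bisulfite conversion rate, then gate the clone.

    * identity: matches / aligned columns, over reference positions that
      are not CpG wildcards and not in ``exclude`` (known SNP footprints),
      skipping read gaps and Ns;
    * conversion rate: fraction of non-CpG reference cytosines (again
      outside ``exclude``) read as T — the canonical check that bisulfite
      treatment went to completion.

    A clone with no assessable conversion column has an undefined rate and
    fails QC with the reason recorded.
    """
    wild = set(ac.ref.wildcard_positions)
    excl = set(exclude)
    id_n = id_hit = conv_n = conv_t = 0
    for p, base in ac.ref_to_read.items():
        if p in wild or p in excl or base in ("-", "N"):
            continue
        id_n += 1
        if base == ac.ref.bases[p]:
            id_hit += 1
        if ac.ref.origin[p] == "C":
            conv_n += 1
            if base == "T":
                conv_t += 1
    ac.identity = id_hit / id_n if id_n else None
    ac.conversion_rate = conv_t / conv_n if conv_n else None
    if ac.identity is None:
        ac.qc_pass = False
        ac.qc_reason = "no assessable aligned columns"
    elif ac.conversion_rate is None:
        ac.qc_pass = False
        ac.qc_reason = "no assessable non-CpG cytosine columns; conversion rate undefined"
    else:
        ac.qc_pass = (
            ac.identity >= min_identity and ac.conversion_rate >= min_conversion
        )
        if not ac.qc_pass:
            ac.qc_reason = (
                f"identity {ac.identity:.3f} (min {min_identity}) / "
                f"conversion {ac.conversion_rate:.3f} (min {min_conversion})"
            )
    return ac


def call_methylation(
    ac: AlignedClone, cpg_sites: Sequence[int]
) -> dict[int, str]:
    """Per-CpG methylation calls from the C/T read-out: C = methylated
    (protected), T = unmethylated (converted), anything else (gap, N,
    sequencing error) = missing.  Requires a QC-passing clone."""
    if ac.qc_pass is not True:
        raise ValueError("call_methylation requires a QC-passing clone")
    calls: dict[int, str] = {}
    for p in cpg_sites:
        base = ac.ref_to_read.get(p)
        if base == "C":
            calls[p] = METHYLATED
        elif base == "T":
            calls[p] = UNMETHYLATED
        else:
            calls[p] = MISSING
    ac.methylation_calls = calls
    return calls


def _expected_readout(
    allele: str, position: int, ref: ConvertedSeq
) -> list[set[str]] | None:
    """Per-position sets of read bases compatible with ``allele`` occupying
    the reference footprint starting at ``position``, after conversion on
    the assayed strand.  ``None`` marks an out-of-model allele."""
    if allele == GAP:
        return None  # handled by the caller with the partner footprint
    out: list[set[str]] = []
    for i, base in enumerate(allele):
        p = position + i
        if base == "C":
            nxt = allele[i + 1] if i + 1 < len(allele) else (
                ref.origin[p + 1] if p + 1 < len(ref.origin) else ""
            )
            out.append({"C", "T"} if nxt == "G" else {"T"})
        else:
            out.append({base})
    return out


def genotype_and_assign(
    ac: AlignedClone,
    snps: Sequence[SnpRecord],
    cross: Cross = Cross(),
) -> AlignedClone:
    """Genotype each SNP in converted space and vote the clone onto a
    parental allele.

    Every SNP's aligned read bases over its reference footprint are
    compared with each haplotype's expected post-conversion read-out
    (deletion alleles expect gaps).  A SNP is informative when the read
    matches exactly one haplotype; the clone takes the haplotype winning a
    strict majority of informative SNPs (a single-SNP assay assigns on
    that one call); ties or zero informative SNPs leave it unassigned.
    With a B6 dam, B6-haplotype clones are maternal.
    """
    votes = {"b6": 0, "cast": 0}
    snp_calls: dict[int, str] = {}
    for snp in snps:
        if snp.position is None or snp.alleles is None:
            continue
        b6, cast = snp.alleles
        fp = snp.footprint()
        if fp == 0:
            continue  # insertion relative to the reference: out of model
        chars = [ac.ref_to_read.get(snp.position + i) for i in range(fp)]
        if any(c is None or c == "N" for c in chars):
            snp_calls[snp.position] = "."
            continue
        observed = "".join(chars)  # may contain '-'
        snp_calls[snp.position] = observed
        exp_b6 = _expected_readout(b6, snp.position, ac.ref)
        if cast == GAP:
            exp_cast: list[set[str]] | None = [{"-"}] * fp
        else:
            exp_cast = _expected_readout(cast, snp.position, ac.ref)
        if exp_b6 is None or exp_cast is None or len(exp_cast) != fp:
            continue
        hit_b6 = all(c in s for c, s in zip(chars, exp_b6))
        hit_cast = all(c in s for c, s in zip(chars, exp_cast))
        if hit_b6 != hit_cast:
            votes["b6" if hit_b6 else "cast"] += 1
    ac.snp_calls = snp_calls
    ac.informative_snps = votes["b6"] + votes["cast"]
    if votes["b6"] > votes["cast"]:
        strain = "B6"
    elif votes["cast"] > votes["b6"]:
        strain = "CAST"
    else:
        ac.allele = UNASSIGNED
        return ac
    ac.allele = MATERNAL if strain == cross.dam else PATERNAL
    return ac


@dataclass
class LollipopMatrix:
    """Clones x CpG-sites call matrices, one per parental allele.

    Each DataFrame is indexed by clone id with one column per CpG
    position; values are ``methylated`` / ``unmethylated`` / ``missing``.
    Fractions are computed over non-missing calls only.
    """

    site_positions: tuple[int, ...]
    calls: dict[str, pd.DataFrame]

    def per_site_fraction(self, allele: str) -> pd.Series:
        df = self.calls[allele]
        meth = (df == METHYLATED).sum()
        known = df.isin([METHYLATED, UNMETHYLATED]).sum()
        return meth / known.where(known > 0)

    def mean_methylation(self, allele: str) -> float | None:
        df = self.calls[allele]
        meth = int((df == METHYLATED).sum().sum())
        known = int(df.isin([METHYLATED, UNMETHYLATED]).sum().sum())
        return meth / known if known else None

    def n_clones(self, allele: str) -> int:
        return len(self.calls[allele])


@dataclass(frozen=True)
class ImprintVerdict:
    """Did the expected parental allele carry the methylation?

    Passes iff the allele expected to be methylated has mean methylation
    >= ``upper`` and the other allele <= ``lower``.
    """

    expected: str  # imprint direction of the assay
    mean_methylation_maternal: float | None
    mean_methylation_paternal: float | None
    upper_threshold: float
    lower_threshold: float
    passed: bool
    reason: str = ""


def aggregate_and_verify(
    clones: Sequence[AlignedClone],
    assay: AmpliconAssay,
    upper_threshold: float = 0.70,
    lower_threshold: float = 0.30,
) -> tuple[LollipopMatrix, ImprintVerdict, dict[str, int]]:
    """Build the per-allele lollipop matrices and check the imprint.

    Only QC-passing, allele-assigned clones enter the matrix; the returned
    tally accounts for every input clone exactly once across
    ``qc_fail`` / ``unassigned`` / ``maternal`` / ``paternal``.
    """
    sites = tuple(find_cpg_sites(assay.region))
    tally = {"qc_fail": 0, "unassigned": 0, MATERNAL: 0, PATERNAL: 0}
    rows: dict[str, dict[str, dict[int, str]]] = {MATERNAL: {}, PATERNAL: {}}
    for ac in clones:
        if ac.qc_pass is not True:
            tally["qc_fail"] += 1
            continue
        if ac.allele not in (MATERNAL, PATERNAL):
            tally["unassigned"] += 1
            continue
        tally[ac.allele] += 1
        rows[ac.allele][ac.read.id] = {
            p: ac.methylation_calls.get(p, MISSING) for p in sites
        }
    calls = {
        allele: pd.DataFrame.from_dict(rows[allele], orient="index",
                                       columns=list(sites), dtype=object)
        for allele in (MATERNAL, PATERNAL)
    }
    matrix = LollipopMatrix(site_positions=sites, calls=calls)

    mat = matrix.mean_methylation(MATERNAL)
    pat = matrix.mean_methylation(PATERNAL)
    if mat is None or pat is None:
        verdict = ImprintVerdict(
            expected=assay.imprint_direction,
            mean_methylation_maternal=mat,
            mean_methylation_paternal=pat,
            upper_threshold=upper_threshold,
            lower_threshold=lower_threshold,
            passed=False,
            reason="insufficient-data: no assigned clones on at least one allele",
        )
        return matrix, verdict, tally
    if assay.imprint_direction == "maternal_methylated":
        hi, lo = mat, pat
    else:
        hi, lo = pat, mat
    passed = hi >= upper_threshold and lo <= lower_threshold
    verdict = ImprintVerdict(
        expected=assay.imprint_direction,
        mean_methylation_maternal=mat,
        mean_methylation_paternal=pat,
        upper_threshold=upper_threshold,
        lower_threshold=lower_threshold,
        passed=passed,
        reason="" if passed else (
            f"expected-methylated allele mean {hi:.3f} vs >= {upper_threshold}, "
            f"other allele mean {lo:.3f} vs <= {lower_threshold}"
        ),
    )
    return matrix, verdict, tally


_GLYPH = {METHYLATED: "●", UNMETHYLATED: "○", MISSING: "·"}


def render_lollipop(matrix: LollipopMatrix) -> str:
    """Text lollipop diagram: one row per clone, one circle per CpG
    (filled = methylated, open = unmethylated, middle dot = missing).
    Maternal block above paternal; rows sorted by clone id; deterministic
    byte-for-byte for a given matrix."""
    if all(matrix.calls[a].empty for a in (MATERNAL, PATERNAL)):
        return "(empty lollipop diagram: no assigned clones)\n"
    width = max((len(i) for a in (MATERNAL, PATERNAL)
                 for i in matrix.calls[a].index), default=0)
    lines = []
    for allele in (MATERNAL, PATERNAL):
        df = matrix.calls[allele]
        lines.append(f"[{allele}]")
        for cid in sorted(df.index):
            row = df.loc[cid]
            circles = "".join(_GLYPH[row[p]] for p in matrix.site_positions)
            lines.append(f"{cid:<{width}} {circles}")
    return "\n".join(lines) + "\n"


def render_lollipop_svg(matrix: LollipopMatrix, radius: int = 5,
                        spacing: int = 14) -> str:
    """Same diagram as vector graphics (SVG markup string): filled/open
    circles per call, a cross for missing."""
    rows: list[tuple[str, str, dict[int, str]]] = []
    for allele in (MATERNAL, PATERNAL):
        df = matrix.calls[allele]
        for cid in sorted(df.index):
            rows.append((allele, cid, dict(df.loc[cid])))
    ncol = len(matrix.site_positions)
    width = spacing * (ncol + 2) + 120
    height = spacing * (len(rows) + 2)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}">'
    ]
    for r, (allele, cid, calls) in enumerate(rows):
        cy = spacing * (r + 1)
        parts.append(
            f'<text x="4" y="{cy + 4}" font-size="9">{allele}:{cid}</text>'
        )
        for c, p in enumerate(matrix.site_positions):
            cx = 120 + spacing * c
            call = calls[p]
            if call == MISSING:
                d = radius - 1
                parts.append(
                    f'<path d="M{cx - d},{cy - d} L{cx + d},{cy + d} '
                    f'M{cx - d},{cy + d} L{cx + d},{cy - d}" '
                    'stroke="grey" fill="none"/>'
                )
            else:
                fill = "black" if call == METHYLATED else "white"
                parts.append(
                    f'<circle cx="{cx}" cy="{cy}" r="{radius}" '
                    f'fill="{fill}" stroke="black"/>'
                )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


@dataclass
class PipelineResult:
    clones: list[AlignedClone]
    matrix: LollipopMatrix
    verdict: ImprintVerdict
    tally: dict[str, int]


def analyze_clones(
    assay: AmpliconAssay,
    reads: Sequence[CloneRead],
    cross: Cross = Cross(),
    min_identity: float = 0.80,
    min_conversion: float = 0.95,
    upper_threshold: float = 0.70,
    lower_threshold: float = 0.30,
    remove_duplicates: bool = False,
) -> PipelineResult:
    """Run the full panel pipeline on a set of clone reads.

    Duplicate-sequence removal (first occurrence kept) is off by default:
    published panels display every clone.
    """
    if remove_duplicates:
        seen: set[str] = set()
        uniq = []
        for r in reads:
            if r.bases not in seen:
                seen.add(r.bases)
                uniq.append(r)
        reads = uniq
    ref = build_converted_reference(assay.region)
    sites = find_cpg_sites(assay.region)
    snp_columns = [
        s.position + i
        for s in assay.validated_snps
        if s.position is not None and s.alleles is not None
        for i in range(max(s.footprint(), 1))
    ]
    clones = []
    for read in reads:
        ac = align_clone(read, ref)
        qc_clone(ac, min_identity, min_conversion, exclude=snp_columns)
        if ac.qc_pass:
            call_methylation(ac, sites)
            genotype_and_assign(ac, assay.validated_snps, cross)
        clones.append(ac)
    matrix, verdict, tally = aggregate_and_verify(
        clones, assay, upper_threshold, lower_threshold
    )
    return PipelineResult(clones=clones, matrix=matrix, verdict=verdict, tally=tally)
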