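"""Synthetic hybrid regions and Sanger-style cloned bisulfite reads.

Every pipeline stage can be exercised without any download: this module
fabricates a two-haplotype region (B6-like dam x CAST-like sire) carrying
a known set of CpG sites and strain SNPs, then emits cloned bisulfite
reads with per-allele methylation probabilities, incomplete conversion,
over-conversion, sequencing error and random insert orientation — all
recorded in a truth table so recovery can be scored exactly.

A single pseudo-random stream (:func:`numpy.random.default_rng` seeded
once) drives a run; per-clone draws happen in a fixed order (allele,
methylation, chemistry, sequencing error, orientation), so a seed fully
determines the output.

:func:`build_paperlike` assembles the ten packaged locus assays: each
region is the locus's real primer pair flanking a synthetic insert sized
to the published amplicon length, with the published CpG count and the
validated SNP alleles planted at reproducible positions (no region
sequences are deposited anywhere, so the insert must be synthetic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assay_design import AmpliconAssay, PrimerPair
from .bisulfite import METHYLATED, UNMETHYLATED, convert_with_state
from .clone_pipeline import (
    MATERNAL,
    PATERNAL,
    AlignedClone,
    CloneRead,
)
from .seqmodel import (
    check_concrete,
    find_cpg_sites,
    parse_primer,
    reverse_complement,
)
from .snp_screen import GAP, SnpRecord
from .tables import locus_info, table1_primers, validated_snp_alleles

__all__ = [
    "InfeasibleSpecError",
    "ReconciliationError",
    "SimParams",
    "HybridRegion",
    "LocusSim",
    "RecoveryReport",
    "simulate_region",
    "simulate_clones",
    "truth_compare",
    "build_paperlike",
    "imprint_p_meth",
]

_BASES = np.array(list("ACGT"))


class InfeasibleSpecError(ValueError):
    """The requested CpG/SNP density cannot be placed in the region."""


class ReconciliationError(ValueError):
    """Pipeline output and truth table disagree on clone identities."""


@dataclass(frozen=True)
class SimParams:
    """Study conditions for a simulated locus.

    ``p_meth`` is the per-CpG methylation probability of the (maternal,
    paternal) allele.  ``conversion_failure`` is the probability an
    unmethylated C escapes conversion (reads C); ``over_conversion`` the
    probability a methylated C converts anyway (reads T); ``seq_error``
    the per-base substitution rate of the clone consensus.
    ``allele_ratio=None`` emits exactly ``n_clones`` per allele;
    a float draws each clone's allele Bernoulli(maternal=ratio) instead.
    """

    region_length: int = 400
    n_cpg: int = 20
    snp_spec: int | Sequence[tuple[int, tuple[str, str]]] = 3
    p_meth: tuple[float, float] = (0.9, 0.1)
    conversion_failure: float = 0.01
    over_conversion: float = 0.01
    seq_error: float = 0.005
    n_clones: int = 50
    allele_ratio: float | None = None
    random_orientation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            *self.p_meth, self.conversion_failure, self.over_conversion,
            self.seq_error,
        ]
        if self.allele_ratio is not None:
            probs.append(self.allele_ratio)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class HybridRegion:
    """A reference (dam/B6 haplotype) plus the SNPs that define the sire
    haplotype, with the region's CpG sites (reference coordinates)."""

    name: str
    reference: str
    cpg_sites: tuple[int, ...]
    snps: tuple[SnpRecord, ...]

    def sire_haplotype(self) -> tuple[str, dict[int, int]]:
        """Sire (CAST-like) sequence and the reference->sire coordinate
        map (deleted reference positions absent from the map)."""
        seq: list[str] = []
        ref2hap: dict[int, int] = {}
        by_pos = {s.position: s for s in self.snps if s.position is not None}
        p = 0
        n = len(self.reference)
        while p < n:
            snp = by_pos.get(p)
            if snp is None or snp.alleles is None:
                ref2hap[p] = len(seq)
                seq.append(self.reference[p])
                p += 1
                continue
            b6, cast = snp.alleles
            fp = snp.footprint()
            if cast == GAP:
                p += fp  # deleted in the sire; no coordinates map
                continue
            for i, b in enumerate(cast):
                ref2hap[p + i] = len(seq)
                seq.append(b)
            p += fp
        return "".join(seq), ref2hap


@dataclass(frozen=True)
class LocusSim:
    """One packaged locus ready to simulate: the assay definition plus
    the hybrid region behind it."""

    assay: AmpliconAssay
    region: HybridRegion


def imprint_p_meth(
    imprint_direction: str, p_hi: float = 0.9, p_lo: float = 0.1
) -> tuple[float, float]:
    """(maternal, paternal) methylation probabilities realising an
    imprint direction."""
    if imprint_direction == "maternal_methylated":
        return (p_hi, p_lo)
    if imprint_direction == "paternal_methylated":
        return (p_lo, p_hi)
    raise ValueError(f"bad imprint_direction {imprint_direction!r}")


# ---------------------------------------------------------------------------
# region construction


def _cg_free(rng: np.random.Generator, length: int) -> list[str]:
    """Random sequence with every CG dinucleotide broken."""
    seq = list(rng.choice(_BASES, size=length))
    for i in range(1, length):
        if seq[i - 1] == "C" and seq[i] == "G":
            seq[i] = str(rng.choice(np.array(["A", "T"])))
    return [str(b) for b in seq]


def _spaced_sample(
    rng: np.random.Generator, allowed: list[int], n: int, min_gap: int
) -> list[int]:
    """Greedy random subset of ``allowed`` with pairwise distance >=
    ``min_gap``; raises if it cannot reach ``n``."""
    if n == 0:
        return []
    order = list(rng.permutation(len(allowed)))
    chosen: list[int] = []
    for idx in order:
        pos = allowed[idx]
        if all(abs(pos - c) >= min_gap for c in chosen):
            chosen.append(pos)
            if len(chosen) == n:
                return sorted(chosen)
    raise InfeasibleSpecError(
        f"could not place {n} features (got {len(chosen)}) with gap {min_gap}"
    )


def _plant_segment(
    rng: np.random.Generator,
    length: int,
    n_cpg: int,
    snp_alleles: Sequence[tuple[str, str]],
    neutral_ends: bool = False,
) -> tuple[str, list[int], list[int]]:
    """Build a segment with exactly ``n_cpg`` CpGs and the given SNPs
    planted at reproducible positions.

    SNP neighbourhoods are neutralised (A/T flanks) so neither allele
    creates or destroys a CpG; returns (sequence, CpG positions, SNP
    positions) in segment coordinates.
    """
    if length < 4 * n_cpg:
        raise InfeasibleSpecError(
            f"length {length} too short for {n_cpg} CpGs"
        )
    seq = _cg_free(rng, length)
    if neutral_ends and length >= 2:
        seq[0] = "A" if seq[0] in "CG" else seq[0]
        seq[-1] = "T" if seq[-1] in "CG" else seq[-1]

    # one SNP per equal-width bin keeps neighbourhoods disjoint regardless
    # of the draws
    snp_positions: list[int] = []
    k = len(snp_alleles)
    if k:
        fps = [max(len(b6), 1) if b6 != GAP else 1 for b6, _ in snp_alleles]
        lo, hi = 2, length - 2
        span = hi - lo
        if span < k * (max(fps) + 5):
            raise InfeasibleSpecError("segment too short for requested SNPs")
        edges = [lo + span * i // k for i in range(k + 1)]
        for i, fp in enumerate(fps):
            pos = int(rng.integers(edges[i], edges[i + 1] - fp - 4))
            snp_positions.append(pos)
    # neutral flanks, then the B6 allele itself
    for pos, (b6, _cast) in zip(snp_positions, snp_alleles):
        fp = max(len(b6), 1) if b6 != GAP else 1
        seq[pos - 1] = "A"
        if b6 != GAP:
            seq[pos : pos + fp] = list(b6)
        if pos + fp < length:
            seq[pos + fp] = "T"

    blocked = set()
    for pos, (b6, _cast) in zip(snp_positions, snp_alleles):
        fp = max(len(b6), 1) if b6 != GAP else 1
        blocked.update(range(pos - 3, pos + fp + 3))
    start = 1 if neutral_ends else 0
    stop = length - (3 if neutral_ends else 2)
    allowed = [i for i in range(start, stop) if not (set(range(i - 1, i + 3)) & blocked)]
    cpg_positions = _spaced_sample(rng, allowed, n_cpg, min_gap=3)
    for i in cpg_positions:
        seq[i] = "C"
        seq[i + 1] = "G"

    out = "".join(seq)
    got = find_cpg_sites(out) if out else []
    if got != cpg_positions:
        raise InfeasibleSpecError(
            f"CpG planting produced {len(got)} sites, wanted {n_cpg}"
        )
    return out, cpg_positions, snp_positions


def _auto_alleles(
    rng: np.random.Generator, seq: str, positions: Sequence[int]
) -> list[tuple[str, str]]:
    """Pick a bisulfite-assayable CAST allele for each reference base."""
    pairs = []
    for pos in positions:
        b6 = seq[pos]
        forbidden = {b6}
        if b6 == "C":
            forbidden.add("T")  # C/T on the assayed strand is invisible
        if b6 == "T":
            forbidden.add("C")
        cast = str(rng.choice([b for b in "ACGT" if b not in forbidden]))
        pairs.append((b6, cast))
    return pairs


def simulate_region(params: SimParams, name: str = "sim") -> HybridRegion:
    """Fabricate a hybrid region: exactly ``n_cpg`` CpG sites, the
    requested SNPs, haplotypes differing only at SNPs.  Deterministic
    under ``params.seed``."""
    if params.region_length < 4 * params.n_cpg:
        raise InfeasibleSpecError(
            f"region_length {params.region_length} < 4 x n_cpg {params.n_cpg}"
        )
    rng = np.random.default_rng(params.seed)
    if isinstance(params.snp_spec, int):
        # place SNPs and CpGs together with neutralised SNP flanks; the
        # ("A", "G") pairs only size the slots, alleles are chosen after
        seq, cpgs, snp_pos = _plant_segment(
            rng, params.region_length, params.n_cpg,
            [("A", "G")] * params.snp_spec,
        )
        seq_l = list(seq)
        for p in snp_pos:
            seq_l[p] = str(rng.choice(_BASES))
        seq = "".join(seq_l)
        alleles = _auto_alleles(rng, seq, snp_pos)
        snps = tuple(
            SnpRecord(
                locus=name, position=p, alleles=pair,
                validation_status="validated",
            )
            for p, pair in zip(snp_pos, alleles)
        )
    else:
        seq_base, cpg_all, _ = _plant_segment(
            rng, params.region_length, params.n_cpg, [],
        )
        seq_l = list(seq_base)
        snps_l = []
        for pos, (b6, cast) in params.snp_spec:
            fp = len(b6) if b6 != GAP else 1
            if b6 != GAP:
                seq_l[pos : pos + fp] = list(b6)
            snps_l.append(
                SnpRecord(
                    locus=name, position=pos, alleles=(b6, cast),
                    validation_status="validated",
                )
            )
        seq = "".join(seq_l)
        snps = tuple(snps_l)
        cpgs = find_cpg_sites(seq)
        if len(cpgs) != params.n_cpg:
            raise InfeasibleSpecError(
                "explicit SNP placement changed the CpG count; adjust positions"
            )
    region = HybridRegion(
        name=name, reference=seq, cpg_sites=tuple(cpgs), snps=snps
    )
    # structural self-checks: haplotypes differ only at SNPs
    check_concrete(region.reference, "reference")
    return region


# ---------------------------------------------------------------------------
# clone simulation


def simulate_clones(
    region: HybridRegion, params: SimParams
) -> tuple[list[CloneRead], pd.DataFrame]:
    """Emit cloned bisulfite reads plus their truth table.

    Per clone, in fixed draw order: allele, per-CpG methylation
    Bernoulli(p_meth[allele]), methylation-aware conversion, chemistry
    flips (conversion failure / over-conversion) at genomic C sites,
    per-base sequencing error, then a fair coin for insert orientation.
    Sequencing errors never touch indel structure; indels exist only as
    haplotype SNPs.
    """
    rng = np.random.default_rng(params.seed)
    sire_seq, ref2sire = region.sire_haplotype()
    haps = {
        MATERNAL: (region.reference, {p: p for p in range(len(region.reference))}),
        PATERNAL: (sire_seq, ref2sire),
    }
    if params.allele_ratio is None:
        alleles = [MATERNAL] * params.n_clones + [PATERNAL] * params.n_clones
    else:
        draws = rng.random(2 * params.n_clones)
        alleles = [
            MATERNAL if d < params.allele_ratio else PATERNAL for d in draws
        ]
    p_by_allele = {MATERNAL: params.p_meth[0], PATERNAL: params.p_meth[1]}

    reads: list[CloneRead] = []
    truth_rows = []
    for idx, allele in enumerate(alleles):
        hap_seq, ref2hap = haps[allele]
        hap_cpgs = [ref2hap[p] for p in region.cpg_sites]
        meth = rng.random(len(hap_cpgs)) < p_by_allele[allele]
        state = {
            hp: (METHYLATED if m else UNMETHYLATED)
            for hp, m in zip(hap_cpgs, meth)
        }
        bases = list(convert_with_state(hap_seq, state).bases)
        n_fail = n_over = 0
        for i, b in enumerate(hap_seq):
            if b != "C":
                continue
            u = rng.random()
            if bases[i] == "C" and u < params.over_conversion:
                bases[i] = "T"
                n_over += 1
            elif bases[i] == "T" and u < params.conversion_failure:
                bases[i] = "C"
                n_fail += 1
        errs = rng.random(len(bases)) < params.seq_error
        n_err = 0
        for i in np.flatnonzero(errs):
            alts = [b for b in "ACGT" if b != bases[i]]
            bases[i] = str(rng.choice(alts))
            n_err += 1
        orientation = "forward"
        if params.random_orientation and rng.random() < 0.5:
            orientation = "reverse"
        seq = "".join(bases)
        if orientation == "reverse":
            seq = reverse_complement(seq)
        cid = f"{region.name}_clone{idx:04d}"
        reads.append(CloneRead(id=cid, bases=seq))
        truth_rows.append(
            {
                "clone_id": cid,
                "allele": allele,
                "meth_states": "".join("M" if m else "U" for m in meth),
                "orientation": orientation,
                "n_conversion_failures": n_fail,
                "n_over_conversions": n_over,
                "n_seq_errors": n_err,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("clone_id")
    truth.attrs["cpg_sites"] = list(region.cpg_sites)
    truth.attrs["conversion_failure"] = params.conversion_failure
    truth.attrs["region_name"] = region.name
    return reads, truth


@dataclass(frozen=True)
class RecoveryReport:
    """How well the pipeline recovered the simulation truth."""

    confusion: pd.DataFrame  # rows: true allele; cols: assigned outcome
    misassignment_rate: float | None  # among assigned, fraction wrong
    methylation_error_rate: float | None  # non-missing calls differing from truth
    conversion_rate_bias: float | None  # mean observed - (1 - conversion_failure)
    n_clones: int


def truth_compare(
    clones: Sequence[AlignedClone], truth: pd.DataFrame
) -> RecoveryReport:
    """Score pipeline output against the truth table (matched by clone
    id; any id mismatch raises :class:`ReconciliationError`)."""
    got = {c.read.id for c in clones}
    want = set(truth.index)
    if got != want:
        missing = sorted(want - got)
        extra = sorted(got - want)
        raise ReconciliationError(
            f"clone id mismatch: missing from output {missing}, unexpected {extra}"
        )
    cpg_sites = list(truth.attrs["cpg_sites"])
    conv_fail = truth.attrs.get("conversion_failure")

    rows = []
    meth_n = meth_bad = 0
    conv_rates = []
    for ac in clones:
        t = truth.loc[ac.read.id]
        outcome = (
            "qc_fail" if ac.qc_pass is not True else ac.allele
        )
        rows.append({"true_allele": t["allele"], "assigned": outcome})
        if ac.qc_pass is True:
            if ac.conversion_rate is not None:
                conv_rates.append(ac.conversion_rate)
            for p, true_char in zip(cpg_sites, t["meth_states"]):
                call = ac.methylation_calls.get(p, "missing")
                if call == "missing":
                    continue
                meth_n += 1
                truth_call = METHYLATED if true_char == "M" else UNMETHYLATED
                if call != truth_call:
                    meth_bad += 1
    df = pd.DataFrame(rows)
    confusion = pd.crosstab(df["true_allele"], df["assigned"], dropna=False)
    assigned = df[df["assigned"].isin([MATERNAL, PATERNAL])]
    mis = (
        float((assigned["assigned"] != assigned["true_allele"]).mean())
        if len(assigned)
        else None
    )
    bias = (
        float(np.mean(conv_rates)) - (1.0 - conv_fail)
        if conv_rates and conv_fail is not None
        else None
    )
    return RecoveryReport(
        confusion=confusion,
        misassignment_rate=mis,
        methylation_error_rate=(meth_bad / meth_n) if meth_n else None,
        conversion_rate_bias=bias,
        n_clones=len(clones),
    )


# ---------------------------------------------------------------------------
# the packaged ten-locus fixture


def build_paperlike(seed: int = 0) -> list[LocusSim]:
    """Assemble the ten packaged locus assays over synthetic inserts.

    Per locus: region = forward primer (degenerate base fixed to its B6
    allele) + synthetic insert + reverse-complemented reverse primer,
    sized to the published amplicon length with the published total CpG
    count; the validated SNP alleles are planted in the insert, except
    where a degenerate forward-primer 3' base covers the SNP
    (Grb10/Mest/Snrpn), which sits at the primer's last position.
    """
    primers = table1_primers()
    info = locus_info()
    alleles_by_locus = validated_snp_alleles()
    sims: list[LocusSim] = []
    for li, (locus, row) in enumerate(info.iterrows()):
        rng = np.random.default_rng((seed, li))
        prow = primers[locus]
        fwd = parse_primer(prow.fwd_genomic)
        rev = parse_primer(prow.rev_genomic)
        pairs = list(alleles_by_locus[locus])

        primer_snp: tuple[str, str] | None = None
        fwd_b6 = fwd
        if fwd[-1] not in "ACGT":
            # degenerate 3' base covers a validated SNP; the first listed
            # allele pair at these loci is that SNP
            primer_snp = pairs.pop(0)
            fwd_b6 = fwd[:-1] + primer_snp[0]
        rev_rc = reverse_complement(rev)

        insert_len = int(row["amplicon_bp"]) - len(fwd_b6) - len(rev_rc)
        n_cpg_insert = (
            int(row["cpg_count"])
            - len(find_cpg_sites(fwd_b6))
            - len(find_cpg_sites(rev_rc))
        )
        insert, _, snp_pos = _plant_segment(
            rng, insert_len, n_cpg_insert, pairs, neutral_ends=True
        )
        region_seq = fwd_b6 + insert + rev_rc
        cpgs = find_cpg_sites(region_seq)
        if len(cpgs) != int(row["cpg_count"]):
            raise InfeasibleSpecError(
                f"{locus}: built {len(cpgs)} CpGs, expected {row['cpg_count']}"
            )

        snps: list[SnpRecord] = []
        if primer_snp is not None:
            snps.append(
                SnpRecord(
                    locus=locus, position=len(fwd_b6) - 1, alleles=primer_snp,
                    validation_status="validated",
                    note="covered by the degenerate forward-primer 3' base",
                )
            )
        for pos, pair_alleles in zip(snp_pos, pairs):
            snps.append(
                SnpRecord(
                    locus=locus, position=len(fwd_b6) + pos,
                    alleles=pair_alleles, validation_status="validated",
                )
            )
        snps.sort(key=lambda s: s.position or 0)

        assay = AmpliconAssay(
            locus=locus,
            region=region_seq,
            pair=PrimerPair.from_genomic(prow.fwd_genomic, prow.rev_genomic),
            imprint_direction=row["imprint_direction"],
            validated_snps=tuple(snps),
            strand_note=row["strand_note"],
        )
        region = HybridRegion(
            name=locus, reference=region_seq,
            cpg_sites=tuple(cpgs), snps=tuple(snps),
        )
        sims.append(LocusSim(assay=assay, region=region))
    return sims
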