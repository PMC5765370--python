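"""Clone alignment, QC, methylation calling, allele assignment,
aggregation and lollipop rendering.

The alignment oracle is an independent hand-written Gotoh dynamic
program over the same scoring scheme (match +1, mismatch -1, gap of
length L costs 4 + L, CpG wildcard Y matches C or T, N neutral).
"""

import numpy as np
import pytest

from bisallele.bisulfite import (
    METHYLATED,
    UNMETHYLATED,
    build_converted_reference,
    convert_with_state,
)
from bisallele.clone_pipeline import (
    MATERNAL,
    MISSING,
    PATERNAL,
    UNASSIGNED,
    AlignedClone,
    CloneRead,
    Cross,
    aggregate_and_verify,
    align_clone,
    analyze_clones,
    call_methylation,
    genotype_and_assign,
    make_aligner,
    qc_clone,
    render_lollipop,
    render_lollipop_svg,
)
from bisallele.seqmodel import find_cpg_sites, reverse_complement
from bisallele.snp_screen import GAP, SnpRecord
from bisallele.synthetic_data import SimParams, imprint_p_meth, simulate_clones

NEG = -10**9


def gotoh_score(ref: str, read: str) -> float:
    """Independent affine-gap global alignment score (Gotoh recurrences)."""

    def sub(a: str, b: str) -> float:
        if "N" in (a, b):
            return 0.0
        if a == b or (a == "Y" and b in "CT") or (b == "Y" and a in "CT"):
            return 1.0
        return -1.0

    open_, ext = 5.0, 1.0  # first gapped base costs 5, each further 1
    n, m = len(ref), len(read)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -open_ - ext * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -open_ - ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(ref[i - 1], read[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - ext,
                          Y[i - 1][j] - open_)
            Y[i][j] = max(M[i][j - 1] - open_, Y[i][j - 1] - ext,
                          X[i][j - 1] - open_)
    return max(M[n][m], X[n][m], Y[n][m])


class TestAlignClone:
    def test_identical_read_aligns_gapless(self):
        region = "ATCAGGACGATTACGGATTA"
        ref = build_converted_reference(region)
        read = convert_with_state(region, {}).bases
        ac = align_clone(CloneRead("c", read), ref)
        ac = qc_clone(ac)
        assert ac.identity == 1.0
        assert "-" not in ac.ref_to_read.values()

    def test_fully_methylated_read_scores_as_match(self):
        region = "ATCAGGACGATTACGGATTA"
        ref = build_converted_reference(region)
        state = {p: METHYLATED for p in find_cpg_sites(region)}
        read = convert_with_state(region, state).bases
        ac = qc_clone(align_clone(CloneRead("c", read), ref))
        assert ac.identity == 1.0  # wildcard columns accept C

    def test_three_base_deletion_gives_one_gap(self):
        region = "ATTAGGATTAGATTAGGATTAATT"
        ref = build_converted_reference(region)
        read = region[:8] + region[11:]  # 3-base deletion
        ac = align_clone(CloneRead("c", read), ref)
        gaps = [p for p, b in ac.ref_to_read.items() if b == "-"]
        assert len(gaps) == 3
        assert gaps == list(range(gaps[0], gaps[0] + 3))  # one contiguous gap
        # score: (len-3) matches - (4 + 3) gap cost
        assert ac.score == (len(region) - 3) - 7

    def test_reverse_orientation_detected(self):
        region = "ATCAGGACGATTACGGATTAGGATCCATTAGG"
        ref = build_converted_reference(region)
        read = reverse_complement(convert_with_state(region, {}).bases)
        ac = align_clone(CloneRead("c", read), ref)
        assert ac.orientation == "reverse"
        assert qc_clone(ac).identity == 1.0

    def test_score_matches_exhaustive_dp_on_random_instances(self):
        rng = np.random.default_rng(42)
        aligner = make_aligner()
        for _ in range(200):
            n = int(rng.integers(5, 31))
            m = int(rng.integers(5, 31))
            region = "".join(rng.choice(list("ACGT"), size=n))
            ref = build_converted_reference(region)
            read = "".join(rng.choice(list("ACGTN"), size=m, p=[0.24] * 4 + [0.04]))
            assert aligner.align(ref.bases, read).score == pytest.approx(
                gotoh_score(ref.bases, read)
            )


class TestQcClone:
    def _aligned(self, region, read):
        return align_clone(CloneRead("c", read), build_converted_reference(region))

    def test_perfect_unmethylated_read_passes(self):
        region = "ATCAGGACGATTACGGATTA"
        ac = qc_clone(self._aligned(region, convert_with_state(region, {}).bases))
        assert ac.conversion_rate == 1.0 and ac.qc_pass

    def test_conversion_failures_counted_and_gated(self):
        # 10 non-CpG Cs; one left unconverted -> rate 0.9
        region = "AC" * 10 + "ATTA"
        converted = convert_with_state(region, {}).bases
        read = "AC" + converted[2:]  # first C escapes conversion
        ac = qc_clone(self._aligned(region, read), min_conversion=0.95)
        assert ac.conversion_rate == pytest.approx(0.9)
        assert not ac.qc_pass and "conversion" in ac.qc_reason

    def test_at_only_read_has_undefined_conversion_rate(self):
        region = "ATTAATTAATTA"
        ac = qc_clone(self._aligned(region, region))
        assert ac.conversion_rate is None
        assert ac.qc_pass is False and "undefined" in ac.qc_reason

    def test_snp_columns_are_excluded_from_identity(self):
        region = "ATTAGGATTAGATTAGGATT"
        read = region[:5] + "C" + region[6:]  # sire base at position 5
        ac = self._aligned(region, read)
        assert qc_clone(ac, exclude=[5]).identity == 1.0

    def test_raising_min_conversion_never_adds_passers(self):
        region = "ATCAGGACGATTACGGATTAGGATCC"
        rng = np.random.default_rng(0)
        reads = []
        for i in range(30):
            bases = list(convert_with_state(region, {}).bases)
            for j in rng.integers(0, len(bases), size=rng.integers(0, 4)):
                bases[j] = str(rng.choice(list("ACGT")))
            reads.append("".join(bases))
        passes = []
        for thr in [0.0, 0.5, 0.8, 0.95, 1.0]:
            n = sum(
                qc_clone(self._aligned(region, r), min_conversion=thr).qc_pass
                for r in reads
            )
            passes.append(n)
        assert passes == sorted(passes, reverse=True)


class TestCallMethylation:
    def test_direct_rule(self):
        region = "ACGACGACGATCA"  # trailing non-CpG C keeps QC defined
        sites = find_cpg_sites(region)
        state = {sites[0]: METHYLATED, sites[2]: METHYLATED}
        read = convert_with_state(region, state).bases
        ac = qc_clone(align_clone(CloneRead("c", read),
                                  build_converted_reference(region)))
        calls = call_methylation(ac, sites)
        assert [calls[p] for p in sites] == [METHYLATED, UNMETHYLATED, METHYLATED]

    def test_gap_over_cpg_is_missing(self):
        region = "ATTAGGACGTTAGGATTACATTAGAGT"
        sites = find_cpg_sites(region)
        read = convert_with_state(region, {}).bases
        read = read[: sites[0] - 1] + read[sites[0] + 2 :]  # delete the CpG
        ac = qc_clone(align_clone(CloneRead("c", read),
                                  build_converted_reference(region)))
        assert call_methylation(ac, sites)[sites[0]] == MISSING

    def test_requires_qc_pass(self):
        region = "ATTAATTAATTA"
        ac = qc_clone(align_clone(CloneRead("c", region),
                                  build_converted_reference(region)))
        with pytest.raises(ValueError):
            call_methylation(ac, [])


def _h19_like():
    """Region with a G/del, G/A and A/G SNP (CAST alleles del, A, G)."""
    region = "ATTA" + "G" + "TTAGATT" + "G" + "TATTAGA" + "A" + "TTAGGATTAG"
    snps = (
        SnpRecord("h", 4, ("G", GAP)),
        SnpRecord("h", 12, ("G", "A")),
        SnpRecord("h", 20, ("A", "G")),
    )
    for s in snps:
        assert region[s.position] == s.alleles[0]
    return region, snps


class TestGenotypeAndAssign:
    def _run(self, region, read, snps, cross=Cross()):
        ac = qc_clone(
            align_clone(CloneRead("c", read), build_converted_reference(region)),
            exclude=[s.position + i for s in snps for i in range(s.footprint())],
        )
        return genotype_and_assign(ac, snps, cross)

    def test_single_snp_b6_dam_gives_maternal(self):
        region = "ATTAGGATTAAGATTAGGATT"
        snp = SnpRecord("g", 10, ("A", "G"))
        ac = self._run(region, region, [snp])
        assert ac.allele == MATERNAL  # reads the B6 base, B6 is the dam

    def test_three_snp_cast_haplotype_is_paternal(self):
        region, snps = _h19_like()
        # CAST read: A at 12, G at 20, then the deletion at 4
        read = region[:12] + "A" + region[13:20] + "G" + region[21:]
        read = read[:4] + read[5:]
        ac = self._run(region, read, snps)
        assert ac.informative_snps == 3
        assert ac.allele == PATERNAL

    def test_split_votes_leave_clone_unassigned(self):
        region, snps = _h19_like()
        read = region[:12] + "A" + region[13:]  # CAST at one SNP, B6 elsewhere
        sub = [snps[1], snps[2]]  # two informative, one vote each way
        ac = self._run(region, read, sub)
        assert ac.allele == UNASSIGNED

    def test_dam_strain_flips_parental_labels(self):
        region = "ATTAGGATTAAGATTAGGATT"
        snp = SnpRecord("g", 10, ("A", "G"))
        ac = self._run(region, region, [snp], cross=Cross(dam="CAST", sire="B6"))
        assert ac.allele == PATERNAL


class TestAggregateAndRender:
    def _pipeline(self, sim, params):
        reads, truth = simulate_clones(sim.region, params)
        return analyze_clones(sim.assay, reads), truth

    def test_conservation_of_clones_across_tallies(self, paperlike_by_locus):
        sim = paperlike_by_locus["Snrpn"]
        params = SimParams(seed=13, n_clones=15,
                           p_meth=imprint_p_meth(sim.assay.imprint_direction))
        result, _ = self._pipeline(sim, params)
        assert sum(result.tally.values()) == 30

    def test_direction_flip_fails_verdict(self, paperlike_by_locus):
        from dataclasses import replace

        sim = paperlike_by_locus["Grb10"]  # maternal methylated
        params = SimParams(seed=13, n_clones=10, p_meth=(0.95, 0.05),
                           conversion_failure=0, over_conversion=0, seq_error=0)
        reads, _ = simulate_clones(sim.region, params)
        ok = analyze_clones(sim.assay, reads)
        assert ok.verdict.passed
        flipped = replace(sim.assay, imprint_direction="paternal_methylated")
        bad = analyze_clones(flipped, reads)
        assert not bad.verdict.passed

    def test_no_assigned_clones_is_insufficient_data(self, paperlike_by_locus):
        sim = paperlike_by_locus["Mest"]
        _, verdict, tally = aggregate_and_verify([], sim.assay)
        assert not verdict.passed
        assert "insufficient-data" in verdict.reason

    def test_text_lollipop_glyphs(self):
        region = "ACGACGA"
        sites = find_cpg_sites(region)
        ac = AlignedClone(
            read=CloneRead("c1", "x"),
            ref=build_converted_reference(region),
            qc_pass=True,
            allele=MATERNAL,
            methylation_calls={sites[0]: METHYLATED, sites[1]: UNMETHYLATED},
        )

        class _Assay:
            region_seq = region

        from bisallele.assay_design import AmpliconAssay, PrimerPair

        assay = AmpliconAssay(
            locus="toy", region=region,
            pair=PrimerPair.from_genomic("ACGA", "TCGT"),
            imprint_direction="maternal_methylated",
        )
        matrix, _, _ = aggregate_and_verify([ac], assay)
        text = render_lollipop(matrix)
        assert "●○" in text

    def test_renders_are_deterministic_and_sized(self, paperlike_by_locus):
        sim = paperlike_by_locus["Peg3"]
        params = SimParams(seed=17, n_clones=20,
                           p_meth=imprint_p_meth(sim.assay.imprint_direction))
        result, _ = self._pipeline(sim, params)
        t1, t2 = render_lollipop(result.matrix), render_lollipop(result.matrix)
        assert t1 == t2
        svg = render_lollipop_svg(result.matrix)
        assert svg == render_lollipop_svg(result.matrix)
        n_rows = result.matrix.n_clones(MATERNAL) + result.matrix.n_clones(PATERNAL)
        n_sites = len(result.matrix.site_positions)
        n_marks = svg.count("<circle") + svg.count("<path")
        assert n_marks == n_rows * n_sites

    def test_empty_matrix_renders_notice(self, paperlike_by_locus):
        sim = paperlike_by_locus["Mest"]
        matrix, _, _ = aggregate_and_verify([], sim.assay)
        assert "empty" in render_lollipop(matrix)

    def test_duplicate_filter_is_optional_and_off_by_default(
        self, paperlike_by_locus
    ):
        sim = paperlike_by_locus["Mest"]
        params = SimParams(seed=19, n_clones=4, p_meth=(1.0, 0.0),
                           conversion_failure=0, over_conversion=0, seq_error=0,
                           random_orientation=False)
        reads, _ = simulate_clones(sim.region, params)
        both = analyze_clones(sim.assay, reads)
        dedup = analyze_clones(sim.assay, reads, remove_duplicates=True)
        assert sum(both.tally.values()) == 8
        assert sum(dedup.tally.values()) == 2  # all-identical per allele
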