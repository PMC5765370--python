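# Methods

## Model and conventions

All coordinates are 0-based, half-open, on the *assayed strand* — the
strand the displayed reference and forward primer lie on. Bisulfite
chemistry is modelled as a deterministic substitution on that strand:
every cytosine reads thymine after PCR unless it is a 5-methyl-cytosine,
and methylation is modelled exclusively at CpG cytosines (the dominant
mammalian context; CHG/CHH methylation is out of model). A reverse
primer is the reverse complement of the converted assayed strand, so the
same chemistry appears there as G→A. Conversion never changes sequence
length, so CpG and SNP coordinates on a converted reference equal their
genomic coordinates.

A converted *reference* differs from a converted *read*: per-molecule
methylation is unknown until read, so reference CpG cytosines are stored
as the IUPAC wildcard `Y` and match either C or T during primer matching
and alignment. Degenerate primer bases (written `(X/Y)` in assay tables,
folded to one-letter IUPAC codes internally) are never converted, even
when an expansion contains C or G — the packaged primer tables print
them unchanged, and the validator flags such positions instead of
rewriting the resource.

## SNP assayability

A SNP survives bisulfite sequencing only if its two alleles remain
distinguishable after conversion on the strand actually read. The
classifier applies rules in a fixed order: (1) length-changing alleles
are `indel_assayable` (gaps survive conversion); (2) a C/T pair on the
read strand is `conversion_confounded` — this blanket exclusion
deliberately ignores CpG context, because even a methylated-CpG C that
would read C is unreliable when methylation varies per allele and per
cell; the verdict carries a `strand_rescuable` flag true when the
complementary G/A pair reads cleanly on the other strand; (3) an allele
that creates a CpG with its neighbour is `cpg_context_unreliable`
(methylation-dependent read-out); (4–5) everything else, including G/A
read on the assayed strand, is `assayable`. The test-suite checks these
rules against an independent oracle that enumerates every methylation
state of both alleles through the conversion function and compares the
resulting read-out sets: overlapping sets ⇒ confounded, multi-valued
sets ⇒ unreliable, otherwise assayable — for all 12 ordered base pairs ×
2 strands × CpG-adjacent and CpG-free contexts.

Screening tallies count database-reported records; a novel SNP (found by
sequencing, absent from every database) is tallied separately and
included in a locus's `validated_total`. Validation rates are integer
percents rounded half-up. Records whose identity was never transcribed
(only their count and outcome are known) carry `alleles=None` and a `.`
in the TSV fixture; the SnpRecord "alleles differ" invariant applies
only when alleles are known.

## Primer validation and in-silico PCR

Primer binding requires a full-length exact match (IUPAC set
intersection on both sides, honouring reference CpG wildcards) of the
*recomputed* converted primer on the converted reference; no mismatch
tolerance is allowed, since these are short Sanger amplicons and the
practical uniqueness concern is repetitive sequence, which exact search
detects. Binding sites are located with recomputed conversions so that a
mistranscribed stored converted form is *reported* (a
`conversion-inconsistency` finding) rather than fatal — the packaged
Igf2r reverse primer is exactly such a case and is preserved as printed.
A CpG under a primer footprint is a high-severity warning, not a
rejection: the packaged Impact reverse primer violates the CpG-free
guideline and demonstrably works. In-silico PCR demands exactly one
productive forward/reverse site combination; zero sites or multiple
viable products are distinct errors, the latter listing all products.
Products longer than 1000 bp draw a warning (these assays target sub-kb
regions). Melting temperatures are nearest-neighbour estimates at 50 mM
monovalent salt, averaged over degenerate expansions, reported to 0.1 °C,
and advisory only.

## Clone pipeline

Reads are aligned globally (affine gaps: match +1, mismatch −1, gap open
−4, extend −1 per gapped base, so a gap of length L costs 4 + L) against
the wildcard converted reference, via Biopython's `PairwiseAligner` over
the alphabet `ACGTNY`; `N` scores 0 everywhere and is excluded from all
statistics. Both insert orientations are tried (TA cloning is
undirected), ties going to forward. The test-suite cross-checks scores
against an independent Gotoh dynamic program on hundreds of random
instances.

QC follows bisulfite-analysis convention: *identity* (fraction of
matching aligned columns) gates gross misalignments and *conversion
rate* (fraction of non-CpG reference cytosines read as T) gates
incompletely converted molecules; defaults are 0.80 and 0.95, both
overridable. Both statistics exclude CpG wildcard columns, read gaps and
Ns — and also known SNP footprint columns, a deliberate choice: the
reference is built from the dam-side (B6) haplotype, so sire-derived
clones legitimately mismatch it at every SNP, and a perfect read of
either allele should score identity 1.0. A clone with no assessable
non-CpG C column has an undefined conversion rate and fails QC with the
reason recorded.

Methylation is called per CpG from the read base (C = methylated, T =
unmethylated, anything else missing). Allele assignment genotypes each
SNP in converted space — each haplotype's expected post-conversion
read-out over the SNP's reference footprint, deletion alleles expecting
gaps — and takes the haplotype winning a strict majority of informative
SNPs; single-SNP assays assign on that one call; ties and zero
informative SNPs leave the clone unassigned. With a B6 dam, B6-haplotype
clones are maternal. Every input clone lands in exactly one of
qc-fail / unassigned / maternal / paternal.

The imprint verdict passes when the allele expected to be methylated has
mean methylation ≥ 0.70 and the other allele ≤ 0.30 (defaults,
configurable; fractions over non-missing calls only). Zero assigned
clones on either allele yields an insufficient-data failure. Duplicate
clone removal exists but is off by default — published panels display
every clone.

## Synthetic data

The simulator is the package's stand-in for wet-lab clone panels, and
its defaults are the study conditions used throughout the tests: 50
clones per allele (balanced unless an `allele_ratio` is given), per-CpG
methylation probability 0.9 on the methylated and 0.1 on the
unmethylated allele, conversion failure 0.01 (unmethylated C reads C),
over-conversion 0.01 (methylated C reads T; a realistic rate, chosen
once), sequencing error 0.005 per base, random insert orientation on.
One seeded `numpy` generator drives a run, with per-clone draws in fixed
order (allele, methylation, chemistry, error, orientation), so a seed
fully determines the output, including FASTA bytes. Sequencing errors
are substitutions only; indels exist only as haplotype SNPs (Sanger
consensus indel noise is negligible at this scale).

`build_paperlike()` assembles the ten packaged loci: each region is the
locus's real primer pair flanking a synthetic insert sized to the
published amplicon length (e.g. Grb10: 390 bp, 31 CpGs) with the
validated SNP alleles planted at reproducible positions. No region
sequences are deposited anywhere, so the inserts are synthetic by
necessity; at Grb10, Mest and Snrpn the degenerate forward-primer
3′ base covers the locus's validated SNP, matching the primer-table
notation. Auto-placed SNPs are given assayable alleles with neutral
(A/T) flanks so neither allele perturbs the CpG set; explicit
`snp_spec` placement bypasses these guards for testing the confounded
categories.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: chromatogram-level base-calling error
structure, PCR amplification bias and clonal duplication, chimeric
molecules, strand-specific conversion artefacts, and cell-to-cell
methylation heterogeneity beyond independent per-CpG Bernoulli draws.
Real panels also exhibit correlated methylation along a molecule, which
the independence assumption understates.

## Numerical and design notes

- Alignment gap convention: the first gapped base costs open + extend
  (−5), each further base −1; the independent test oracle uses the same
  convention.
- Orientation ties (identical forward/reverse alignment scores) resolve
  to forward.
- Percentage rounding in screening summaries is half-up to integer.
- Stochastic acceptance checks compare estimates against the *realized*
  planted truth of the same clones (from the truth table) within 3
  binomial standard errors; with ~2700 calls per allele at a 54-CpG
  locus the 3-SE band is narrower than the deliberate 1% chemistry
  noise, so comparing against the nominal 0.9/0.1 rates would reject the
  generator's own conditions.
- Problem sizes in routine runs: 8 clones/allele for noise-free
  verification, 50/allele for stochastic recovery, 200 random instances
  ≤ 30 bp for the alignment oracle — small enough to re-run everywhere,
  large enough for the 3-SE bounds to bite.

## Known limitations

- Insertions relative to the reference (gap on the B6 side) are out of
  model for genotyping; all packaged indels are deletions in CAST.
- Equal-length multi-base substitutions are rejected by the assayability
  classifier rather than decomposed.
- In-silico PCR has no mismatch tolerance and no primer-dimer or
  secondary-structure screening; PCR protocol objects are metadata only.
- The 28 conversion-confounded records among the 75 failed database SNPs
  are carried as fixture metadata (their individual identities were
  never published in machine-readable form) and are not regenerated.
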