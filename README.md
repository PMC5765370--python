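# bisallele

Allele-specific DNA methylation analysis of mouse imprinting control
regions (ICRs) in a C57BL/6J (B6) × CAST/EiJ hybrid background.

Genomically imprinted genes are expressed from only one parental allele,
under the control of ICRs whose CpG-rich differentially methylated
regions carry parent-of-origin-specific DNA methylation. Reading that
methylation allele-specifically requires (i) bisulfite sequencing, which
converts unmethylated cytosine to thymine while 5-methyl-cytosine is
protected, and (ii) strain SNPs that tag each sequenced molecule as
maternal or paternal in a B6 dam × CAST sire cross. Both steps interact
badly: bisulfite conversion makes C/T polymorphisms invisible (and G/A
when the opposite strand is read), SNPs that create or destroy a CpG have
methylation-dependent read-outs, and bisulfite PCR primers should avoid
CpGs entirely. `bisallele` implements the full in-silico side of this
workflow, for anyone designing or analysing clone-based (Sanger)
bisulfite assays at imprinted loci:

- **`bisallele.bisulfite`** — deterministic in-silico conversion: C→T on
  the assayed strand, G→A for reverse primers, methylation-aware
  conversion, and a wildcard converted reference (CpG cytosines match C
  or T during alignment).
- **`bisallele.snp_screen`** — merges SNP database exports (dbSNP / EVA /
  Sanger style TSVs) and classifies every candidate as `assayable`,
  `conversion_confounded`, `cpg_context_unreliable` or `indel_assayable`,
  with per-locus validation tallies.
- **`bisallele.assay_design`** — primer-pair validation (CpG under
  primer, degenerate bases, nearest-neighbour Tm, conversion
  consistency), in-silico PCR with a uniqueness requirement, amplicon
  profiling and the 12-condition MgCl₂ × DMSO optimisation grid.
- **`bisallele.clone_pipeline`** — global affine-gap alignment of cloned
  reads to the converted reference (match +1, mismatch −1, gap open −4,
  extend −1; CpG wildcards), BiQ-style QC (sequence identity and
  bisulfite conversion rate), per-CpG methylation calls, SNP-based
  parental-allele assignment, lollipop diagrams (text and SVG) and an
  imprint verdict.
- **`bisallele.synthetic_data`** — a truth-tracked simulator of hybrid
  regions and cloned bisulfite reads (allele-specific methylation,
  incomplete/over-conversion, sequencing error, random insert
  orientation).
- **`bisallele.tables`** — packaged fixtures for ten mouse ICRs (Grb10,
  H19, Igf2r, Impact, Lit1/Kcnq1ot1, Mest/Peg1, Peg3, Peg10, Snrpn,
  Zac1/Plagl1): primer pairs with their printed bisulfite-converted
  forms, imprint directions, validated SNP alleles and screening
  outcomes (93 database SNPs screened, 18 validated — a 19% validation
  rate — plus one novel Snrpn SNP).

## Worked example

Simulate clone panels for the ten packaged loci, then analyse one:

```sh
bisallele simulate --seed 7 --n-clones 10 --out demo/
bisallele analyze-clones --assay Grb10 --reads demo/Grb10.reads.fasta
```

prints the lollipop diagram (● methylated, ○ unmethylated, · missing;
one row per clone, one circle per CpG) and the verdict:

```
[maternal]
Grb10_clone0000 ●●●●●●●●●●●●●●●●○●●○●●●●○●●○●●●
Grb10_clone0001 ●●●●●●●●●●●●○●●●●●●●●●●●●●●●○●●
...
[paternal]
Grb10_clone0010 ○○○○○○○○○●○○○●○○○○○○●○○○○○○○○○○
Grb10_clone0011 ○●○○○○○○○○○○○○○○○○○○●○○●○○○○○○○
...
{
  "locus": "Grb10",
  "expected": "maternal_methylated",
  "mean_methylation_maternal": 0.9032258064516129,
  "mean_methylation_paternal": 0.1262135922330097,
  "passed": true,
  "reason": "",
  "tally": { "qc_fail": 1, "unassigned": 0, "maternal": 9, "paternal": 10 }
}
```

The Grb10 ICR is maternally methylated; maternal (B6-haplotype) clones
read ~90% methylated and paternal (CAST-haplotype) clones ~13%, so the
assay verifies the imprint (`passed: true`). One of the 20 clones failed
the conversion-rate/identity QC gate and was excluded.

The same pipeline is available as a library:

```python
from bisallele.synthetic_data import build_paperlike, SimParams, simulate_clones, imprint_p_meth
from bisallele.clone_pipeline import analyze_clones

sim = {s.assay.locus: s for s in build_paperlike()}["H19"]
params = SimParams(seed=7, n_clones=10,
                   p_meth=imprint_p_meth(sim.assay.imprint_direction))
reads, truth = simulate_clones(sim.region, params)
result = analyze_clones(sim.assay, reads)
print(result.verdict)   # H19 is paternally methylated
```

`bisallele screen-snps` and `bisallele design-check` expose the SNP
screening and primer validation stages the same way.

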