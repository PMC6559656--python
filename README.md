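# promoterpop

Population-genetic analysis of a promoter-scale (~18 kb) regulatory region:

- **simulate** — built-in Hudson-style coalescent with a piecewise
  recombination map (hotspots), layered mutation classes (SNP, DNP, indel,
  VNTR, SSLP, poly-A; repeat loci evolve by a symmetric stepwise model on the
  marginal genealogy), diploid pairing and case/control labelling.
- **phase** — EM haplotype-frequency estimation with partition–ligation for
  long marker sets, maximum-posterior phase assignment.
- **ld** — pairwise D / D' / r², Hedrick's multiallelic D', region averages
  and Gabriel-style haplotype blocks from likelihood-grid D' confidence
  bounds.
- **recomb** — Hudson–Kaplan Rmin, a Monte-Carlo two-locus lookup table, a
  pairwise composite-likelihood sliding-window ρ profile and hotspot calling
  (a ready-made lookup for n = 60 chromosomes ships with the package).
- **selection** — Watterson θ, pairwise diversity π (with both the study's
  normalization and the textbook one), heterozygosity and Tajima's D,
  stratified by variant class.
- **phylo** — Kimura 2-parameter distances (optional Γ rate heterogeneity),
  neighbor joining, Newick output.
- **assoc** — carrier 2×2 tables, Fisher's exact test, Haldane–Anscombe
  odds ratios with Woolf confidence intervals, and detectable-allele-
  frequency design calculators.

## Command line

Every stage is a subcommand of `promoterpop` (exit codes: 0 ok, 2 config
error, 3 data error, 4 stage failure):

```sh
# simulate a 60-chromosome cohort with a 10x hotspot, write TSV + VCF + truth
promoterpop simulate -n 60 --theta 1.2 --length 18000 --rho 0.5 \
    --hotspots 15500:2000:10 --seed 1 --out cohort.tsv \
    --vcf cohort.vcf --truth truth.json

promoterpop phase cohort.tsv --out phased.tsv --freqs freqs.json
promoterpop ld phased.tsv --out ld_pairs.tsv --summary ld.json
promoterpop recomb phased.tsv --lookup lookup.json --out rho.tsv \
    --hotspot-json hotspots.json
promoterpop selection phased.tsv --length 18000 --out selection.json
promoterpop tree phased.tsv --out haplotypes.nwk
promoterpop assoc phased.tsv --pattern m1=A --out assoc.json
promoterpop design -n 60 --confidence 0.80   # -> 2.6%

# everything at once (see examples/demo.yaml; ~3 min)
promoterpop pipeline --config examples/demo.yaml --out-dir runs/demo --seed 1
```

The native variant table is a TSV with columns
`id  rsid  position  class  alleles  <subject...>`; positions are
TSS-relative signed integers with no zero (+1 = first base of the first
exon), calls are `a1/a2` (`a1|a2` when phased, `.` missing), and optional
`#phased` / `#phenotype` pragma lines carry phase and case/control labels.
VCF 4.2 import/export maps TSS coordinates through an explicit offset.

Note that ρ profiles computed on EM-phased genotypes (rather than known
haplotypes) absorb phase switch errors as apparent recombination; this is
inherent to any phase-then-estimate workflow and is why the hotspot caller
uses a conservative absolute floor and minimum run length.

## Layout

```
src/promoterpop/
  core.py        data model, variant classification, coordinates
  io.py          native TSV, VCF 4.2, Newick, JSON reports
  coalescent.py  ancestral-recombination-graph engine, marginal trees
  simulate.py    cohort simulation, diploidization, phenotype models
  phase.py       EM phasing, partition-ligation, haplotype counting
  ld.py          pairwise/multiallelic LD, blocks
  recomb.py      Rmin, two-locus lookup, composite-likelihood rho, hotspots
  selection.py   theta/pi/D/heterozygosity, per-class stratification
  phylo.py       K2P distances, neighbor joining
  assoc.py       Fisher/OR/CI, design calculators
  pipeline.py    stage orchestration and JSON report
  cli.py         click CLI
  data/two_locus_n60.json   pre-built lookup (n=60, 20k reps/grid point)
```
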