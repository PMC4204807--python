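# mosaicfam

Characterisation toolkit for hypervariable **185/333-type immune gene
families** — mosaic families of closely related sequences found in sea
urchins (e.g. *Heliocidaris erythrogramma* and *Strongylocentrotus
purpuratus* coelomocytes), whose diversity arises from the presence or
absence of short conserved sequence blocks ("elements"), SNPs, small
indels and amino-acid repeats.

Given a curated multiple alignment of family cDNAs, genes or deduced
polypeptides, the package answers the questions such a study asks:

* **Mosaic structure** — segment the alignment into elements wherever the
  set of sequences sharing a long gap block changes; assign each sequence
  its element pattern (`A, B, … Z, AA, …`); do the same for introns
  (patterns `α, β, γ, δ, …`) and combine exon and intron patterns into
  gene patterns such as `E-α`.
* **ORF integrity** — locate ORFs by Kozak context (`CAGACATGG`), call
  frameshifts (indel length ≢ 0 mod 3 against the alignment consensus)
  and premature stop codons, and classify each transcript as intact,
  missense or truncated.
* **Polypeptide features** — average-mass MW, isoelectric point (bisection
  on the Henderson–Hasselbalch net-charge function), glycine-/histidine-
  rich regions, poly-His runs, N-glycosylation sequons (`N-{P}-[S/T]`),
  RGD motifs, cysteine and arginine censuses.
* **Repeats** — de novo detection of tandem and interspersed amino-acid
  repeats by gapless self-comparison, typed by motif similarity, with a
  family-level copy-number census.
* **Phylogenetics** — Tamura–Nei (TN93) distances with optional Γ rate
  correction (default shape 0.8094), Saitou–Nei neighbor joining with
  deterministic tie-breaking, and bootstrap support by column resampling.
* **Per-codon selection** — SLAC-style counting (Fitch ancestors +
  Nei–Gojobori path counting, binomial test), FEL/IFEL-style per-site
  likelihood-ratio tests under an MG94×HKY codon model, and the
  subsample-consensus protocol: repeated random subsamples, an NJ tree
  per subsample, 2-of-3 method agreement within replicates and a strict
  replicate majority for the final per-codon verdict (α = 0.1).
* **Synthetic families** — a seeded generator that emulates the mosaic
  anatomy (elements 15–111 bp, 63-bp leader split 55/56 by an intron of
  457–1392 bp, planted defects and repeats, coalescent-shaped divergence)
  with full ground truth, so every stage is testable without external
  data.

## The core model in brief

An element map is a tiling of alignment columns into intervals
`[s_k, e_k)`; a boundary is placed wherever the set of sequences carrying
a gap run of length ≥ 15 changes. Sequence *i*'s pattern is the vector
`p_ik = 1{coverage_ik ≥ 0.5}`. TN93 distance uses the closed form with
the two transition classes `P₁ (A↔G)`, `P₂ (C↔T)` and transversions `Q`,
optionally Γ-corrected, `d = Σ kⱼ·a·(wⱼ^(−1/a) − 1)`. Per-site selection
compares the nonsynonymous rate β against the synonymous rate α: SLAC by
counting (binomial two-tailed test), FEL by a χ²(1) LRT of `β = α` on a
fixed tree; ω = β/α > 1 indicates diversifying, ω < 1 purifying
selection.

## Worked example

Simulate a 12-sequence family, segment it, assign patterns and annotate
defects:

```
$ mosaicfam simulate --seed 4 --n-sequences 12 --out sim
12 sequences -> sim
$ mosaicfam segment --aln sim/alignment.fasta --out elements.tsv
9 elements -> elements.tsv
$ mosaicfam patterns --aln sim/alignment.fasta --elements elements.tsv --out patterns.tsv
4 distinct patterns -> patterns.tsv
$ mosaicfam annotate --aln sim/alignment.fasta --elements elements.tsv \
      --out-orf orf.tsv --out-features features.tsv
1/12 sequences defective
$ mosaicfam dist --aln sim/alignment.fasta --model TN93+G --out dm.tsv
12x12 distance matrix -> dm.tsv
$ mosaicfam nj --dm dm.tsv --out tree.nwk
tree -> tree.nwk
```

The element table holds 1-based column intervals (`element_id 1: columns
1–147`, …); the pattern table is a 0/1 presence matrix whose first row is
the all-present consensus; `orf.tsv` classifies each sequence (here one
transcript carries a planted defect and is reported non-intact, matching
the generator's truth file `sim/truth.json`). The distance matrix and
Newick tree feed directly into the `selection` subcommand for the
per-codon consensus analysis.

The same operations are available as library functions
(`mosaicfam.segment_alignment`, `assign_patterns`, `find_orf`,
`find_repeats`, `tn93_distance`, `nj_tree`, `consensus_selection`,
`generate_family`, …).

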