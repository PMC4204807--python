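# Methods

## The mosaic model

185/333-type families are mosaics: each member is an ordered selection
from a shared library of conserved sequence blocks (elements), so that in
a multiple alignment a member lacking an element shows a long gap block
spanning exactly that element's columns. The package treats this as the
defining signal. Segmentation places a boundary wherever the set of
sequences carrying a gap run of length ≥ `min_gap` changes, yielding
maximal constant-membership column runs; runs shorter than
`min_element_len` are merged into the neighbour with which more sequences
share gap status (ties merge left, making the procedure deterministic).
Both thresholds default to 15 bp — the length of the family's shortest
element — on the rationale that any gap shorter than the smallest element
is an indel within an element, not a missing element.

Columns that are gap in every sequence carry no information and are
dropped (with a warning) before segmentation; the element map records the
retained columns so downstream annotation is invariant to all-gap
padding.

An element is called present in a sequence when non-gap characters cover
at least half of its columns (`presence_threshold = 0.5`); short in-frame
indels therefore never flip a presence call. Unique presence vectors are
named in order of first occurrence (`A…Z, AA, AB, …`; Greek letters for
introns), with the all-present consensus emitted first under the reserved
name `consensus` and excluded from naming. The published nomenclature of
real families is historical and not derivable, so no attempt is made to
reproduce specific letters. The leader (63 bp, encoding the signal
peptide, split 55/8 by the single intron) is annotated from a configured
length rather than inferred.

Segmentation can only recover boundaries at which the realised pattern
set actually changes: adjacent elements absent in exactly the same
sequences are indistinguishable from one block. The ground-truth
comparison in tests and the acceptance script therefore scores detected
boundaries against the *detectable* boundary set derived from the
generator's pattern assignment, not the raw element library. For the
same reason a family generated with a single all-present pattern
segments into one element (there are no gaps at all) — the element count
equals the library size only when every adjacent element pair is
distinguished by some realised pattern.

## ORF and defect annotation

ORFs are anchored on the family's Kozak context `CAGACATGG`: the first
ATG whose 9-nt context reaches 7/9 identities and that has a downstream
in-frame stop is chosen; if none qualifies, the best-scoring ATG wins
(ties to the 5'-most). Defects are measured against the alignment's
majority consensus: maximal runs of gap-state disagreement shorter than
`min_gap` are indels, and any such run with length ≢ 0 (mod 3) is a
frameshift. The running frame is then translated; a stop codon mapping
upstream of the sequence's final present element is premature. Status is
`truncated` with a premature stop, `missense` with a frameshift but no
premature stop, `intact` otherwise.

Polypeptide features: molecular weight is the sum of average residue
masses plus one water; the isoelectric point is found by bisection on the
Henderson–Hasselbalch net-charge function (tolerance 1e-4 pH), which is
strictly decreasing in pH so the root is unique. Two pKa sets ship
(EMBOSS default, Bjellqvist alternative); published pI ranges for real
families come from unstated tools, so exact reproduction is not promised.
Glycine-/histidine-rich regions are maximal runs of 30-aa windows in
which the residue's frequency is at least twice its whole-sequence
frequency — a deliberately simple operationalisation of regions the
literature describes qualitatively; it is undefined (returns none) when
the residue already dominates the global composition. Glycosylation
sequons are the `N-{P}-[S/T]` motif only; running external predictors is
out of scope.

## Repeat detection

Repeats are found by gapless self-comparison: exact 5-mer seeds define
diagonals, seeds are extended along their diagonal while the mismatch
fraction stays within `max_mismatch_frac` (default 0.2), and intervals
overlapping their own diagonal are tandem arrays with period equal to the
diagonal offset. Because extension can creep a few positions into
flanking sequence and shift the apparent phase, tandem arrays are re-cut
at the phase that admits the most copies consistent with the phase
consensus. Copies are clustered into types by motif similarity
(≥ 1 − `max_mismatch_frac` identity, computed cyclically since tandem
phase is arbitrary); a type is tandem iff every inter-copy gap is
≤ 2 aa. Sub-motif-length copies are kept only when ≥ 60% of the motif
and within the mismatch budget, flagged partial. Gapless extension is a
design choice: the family's repeats show substitutions but not internal
indels. The identity threshold for "same type" is not stated anywhere
for the real families; `1 − max_mismatch_frac` is the package's
convention. The fixture motif set shipped for the motif-scan mode is a
synthetic stand-in (the published motifs are not bundled).

## Distances, trees, support

TN93 distances use the closed form with pairwise-deleted sites and base
frequencies pooled from each pair (the convention of distance-matrix
software); IUPAC ambiguity codes count as missing. The Γ-corrected form
replaces each `−k·log w` term with `k·a·(w^(−1/a) − 1)`; the default
shape 0.8094 is the fitted value for this family class. Non-positive
logarithm arguments mark the pair saturated (distance ∞); NJ refuses
saturated matrices, while the consensus-selection driver caps them at
twice the largest finite distance with a warning (subsampled trees must
exist even for occasional deep pairs). Jukes–Cantor is available as the
degenerate model and equals TN93 exactly under equal frequencies and a
uniform substitution spectrum — a closed-form limit the tests exercise.

Neighbor joining is the Saitou–Nei algorithm with two pinned details: Q
ties break to the lowest index pair, and a negative branch length is
clamped to zero with the deficit moved to the sibling edge. On additive
matrices the generating tree is reproduced exactly (path lengths to
1e-9). Bootstrap support resamples columns with replacement, rebuilds
the NJ tree per replicate, and reports for each internal edge of the
full-data tree the fraction of replicates containing the same
bipartition; the replicate stream is a seeded `numpy` generator, so runs
are bit-reproducible.

## Per-codon selection

**SLAC.** Ancestral codons come from Fitch parsimony with seeded uniform
tie sampling, averaged over 20 draws — an openly stated approximation to
likelihood ancestors; the consensus rule downstream buffers method-level
differences. Per branch, codon changes are decomposed into synonymous
and nonsynonymous steps by averaging over all minimal substitution paths
that avoid stop codons (Nei–Gojobori convention; if every ordering passes
a stop, all orderings are averaged and stop-involving steps count as
nonsynonymous). The expected nonsynonymous fraction is the mean of
per-codon site counts over the site's observed codons, with stops
excluded from each position's denominator. The test is an equal-tail
two-sided binomial on integer-rounded counts. On a 2-taxon tree this
machinery reduces exactly to pairwise Nei–Gojobori counting, which the
tests assert against an independent implementation of the pairwise
formula.

**FEL / IFEL.** Per site, a synonymous rate α and nonsynonymous rate β
are fitted by maximum likelihood under an MG94×HKY rate matrix on the 61
sense codons (target-nucleotide parameterisation, reversible with
respect to F1×4 frequencies; stop codons unreachable). The global κ is
fitted once by 4-state HKY pruning on the whole alignment; codon
frequencies are F1×4. Branch lengths (nucleotide substitutions/site, as
produced by the TN93/NJ stack) are multiplied by 3 and the rate matrix is
normalised to one expected substitution per codon at α = β = 1.
Likelihoods use Felsenstein pruning through the symmetric
eigendecomposition (no full matrix exponentials), with per-node
rescaling. Rates are bounded in [1e-6, 100]; the null (β = α) is a
bounded 1-D fit at tolerance 1e-6, the alternative a 2-D L-BFGS-B fit in
log-space started from the null optimum. `p = χ²₁(LRT)`, with LRT
clamped at zero. IFEL is the same machinery with β freed only on
internal branches; external branches keep β = α in both models (the
method is defined only as "internal" in the source literature; this is
the package's realisation). A site that fails to fit is reported neutral
with a logged warning.

Per-site LRT p-values on finite trees have discrete atoms (invariant
sites give p = 1 exactly; single-substitution sites concentrate on a few
values), so the distribution under neutrality is super-uniform rather
than exactly uniform. Calibration is therefore asserted at the decision
thresholds: over 500 neutrally simulated sites the rejection rate at
p ≤ {0.01, 0.05, 0.1} must not exceed the nominal level beyond binomial
noise, and the type-I error at the analysis threshold 0.1 must lie in
[0.05, 0.15] over 200 sites.

**Consensus protocol.** The family-level analysis mirrors the published
procedure: draw `subsample_size = 100` sequences without replacement
(one replicate on all rows, with a warning, when the family is smaller),
build an NJ tree from TN93 distances, run SLAC, FEL and IFEL, call a site
within a replicate when a strict majority of methods (2 of 3) agree in
direction at p ≤ 0.1, and make the final call the direction held in a
strict majority of replicates (≥ 6 of 10). Neither voting rule is
specified in the source literature; both are configuration, and with one
replicate and one method the procedure reduces to that method's direct
calls (a tested invariant). All randomness derives from the run seed via
fixed sub-seed derivation, so replicates are individually reproducible.

**Simulator.** Codon alignments evolve by exact transition probabilities
of the per-site MG94×HKY matrix (eigendecomposition, root codons from
the stop-free equilibrium). At ω = 1 the empirical Nei–Gojobori dN/dS
over 2000 codons is 1 within sampling error — a law-of-large-numbers
check in the tests.

## Synthetic families

The generator's defaults are the study conditions of the family it
emulates: 12 elements of 15–111 bp (the printed extremes, both multiples
of 3 — element lengths are drawn as codon multiples so absent elements
never shift frame), a 63-bp leader opened by an ATG in a perfect Kozak
context, 6 patterns at 0.8 per-element occupancy with the first and last
elements always present, an intron of 457–1392 bp with 10 intron
elements and 4 patterns splitting the leader at 55/56 in gene mode, four
planted repeat types with copy numbers 2–4, and per-sequence defect
rates (frameshift 0.05, premature stop 0.05) that together approximate
the defective fraction observed in real libraries (≈ 10%).

Within-family divergence follows a random Kingman-coalescent-shaped tree
(root-to-tip divergence `snp_rate = 0.02` substitutions/site, inside the
distance range reported for such families) rather than i.i.d. noise, so
the phylogenetic modules see realistic correlation structure.
Substitutions inside the ORF never create stop codons, keeping defect
ground truth exact. Indels are realised as deletions only — background
deletions are in-frame (3–12 nt), element-interior with a 3-column
margin, and at most one event per element per sequence, so gap runs from
different causes never merge; this is what lets the generator emit the
gapped alignment directly with exact truth coordinates instead of
re-aligning. Planted frameshifts are 1–2 nt deletions; planted premature
stops are point mutations to TAA, placed only upstream of the last
detectable element boundary (a stop inside the terminal merged element is
by definition not premature under the final-element rule). What the
generator does not emulate: insertions relative to the family consensus,
alignment error (inputs are curated alignments by scope), gene
conversion/recombination, microsatellite dynamics, and UTR variation
beyond fixed flanks. Passing recovery tests therefore demonstrates
correctness of the algorithms on the mosaic model, not robustness to
alignment noise.

## Experiment sizes and numerical choices

The validation experiments use: 60-sequence families for mosaic/defect
recovery; an 8-taxon balanced tree (tip branches 0.1) with 500 neutral
sites for FEL calibration (200 for the headline type-I rate); a 24-taxon
balanced tree with 100 ω = 5 sites for power (> 0.5 asserted); and a
60-taxon balanced tree (branches 0.07, total length ≈ 5.9) with 5 ω = 5,
20 ω = 0.05 and 35 neutral codons for the consensus-recovery experiment.
The consensus experiment's tree is balanced rather than coalescent and
its depth chosen so that TN93 stays below saturation while each site
accumulates enough synonymous substitutions for purifying selection to
be detectable — the regime the subsample-consensus protocol presumes.
Thresholds asserted there (≥ 80% of planted negative sites, ≤ 2 false
positive sites at a fixed seed) were set from pilot simulation.

Numerical conventions: 0-based half-open coordinates internally, 1-based
closed in tables; gap character `-` ('.' normalised on input); sequences
upper-cased; optimizer bounds [1e-6, 100] and tolerance 1e-6 for
per-site rates; bisection tolerance 1e-4 pH for pI; LRT values below
1e-10 treated as zero; all stochastic stages seeded, with sub-seeds
derived deterministically from the run seed.

## Known limitations

* Segmentation assumes the input alignment is correct; it does not
  realign, and manual curation of real alignments is outside scope.
* The defect caller measures indels against the majority consensus; in a
  family where a defect allele is the majority at some column the call
  would invert.
* TN93 distances with pairwise deletion over sequences with disjoint
  element repertoires are not a metric (different pairs are compared on
  different sites); tree building on highly mosaic families inherits
  this.
* FEL/IFEL p-values are asymptotic; at few substitutions per site the
  χ²(1) reference is approximate (mildly anti-conservative in the
  mid-range of p, calibrated at the decision thresholds).
* IFEL's power is low on star-like or coalescent-shaped trees, where
  little length is internal.
* Exact numerical replication of HyPhy/Datamonkey output is a non-goal;
  the methods are reimplementations validated against their own oracles.
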