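# Methods

This note documents the models, defaults and design choices behind
`bemisia_delim`, and what the synthetic experiments do and do not
demonstrate.

## Barcode integrity screen

A NUMT (nuclear mitochondrial insertion) evolves without coding
constraint, so a barcode amplified from a NUMT tends to carry indels,
premature stop codons, and amino-acid replacements at residues conserved
across true mitochondrial sequences. The screen tests the three
signatures independently and flags a sequence when any fires:

* **Alignment.** Queries are aligned globally to a single designated
  reference with affine gaps (match +2, mismatch −1, gap open 5, gap
  extend 1). A full multiple alignment is unnecessary: the screen only
  needs reference coordinates. Pre-aligned input is accepted as-is.
  Queries shorter than 100 nt are refused — fragments produce unreliable
  placements. The first optimal alignment reported by the aligner is used,
  which is deterministic for a fixed library version.
* **Frameshift rule.** Insertions count +ℓ, deletions −ℓ; the query is
  frameshifted iff the running total is not ≡ 0 (mod 3) at some reference
  codon boundary (or at the end of the alignment). An in-frame 3 nt event
  therefore never flags, and a +1/−1 pair flags only because codons
  between the two events are out of frame.
* **Translation.** Genetic code defaults to NCBI table 5 (invertebrate
  mitochondrial); the underlying studies never state a table, so it is
  configuration, logged prominently. Codons containing N translate to X
  (never to a resolved residue, even where the ambiguity is synonymous);
  a stop at the terminal codon is legitimate (`terminal_window=1`).
  The reference itself must translate internally stop-free in the
  configured frame, otherwise the screen refuses to run.
* **Conserved-residue rule.** The conservation profile is built from the
  reference panel's aligned proteins; a column flags only when its
  conservation (max residue frequency) is ≥ 1.0 by default — i.e. only
  absolutely conserved columns — and the query holds a residue never
  observed there. This is the most conservative reading of "highly
  conserved regions"; the threshold and the minimum deviation count
  (default 1) are configuration. The profile reconstructs, rather than
  copies, any published site list.

Species diagnosis assigns the nearest reference by p-distance (gap/N
columns excluded from numerator and denominator) when that distance is
≤ 0.035, the conventional *B. tabaci* mtCOI species boundary — a
literature convention, not a value fitted here; ties across species give
"ambiguous". NUMT suspects are only diagnosed under an explicit override
and the call is marked unreliable. Haplotype collapsing is exact-match
grouping over the mutual overlap window; N is a mismatch by default, and
the optional N-as-wildcard mode groups greedily in input order (the
wildcard relation is not transitive — documented, deterministic).

## Genotype models

**Weir–Cockerham θ.** Per biallelic locus the 1984 variance components:
for diploids a (among populations), b (among individuals within
populations), c (within individuals, h̄/2); for haploids the two-level
form with c = 0. Multilocus θ is the ratio of sums Σa/Σ(a+b+c), never the
mean of per-locus ratios. Monomorphic loci have undefined θ and are
excluded from the sums; negative estimates are reported as computed, not
truncated. Missing data are handled per locus with pairwise-complete
individuals; a locus is skipped for a comparison when a population has no
calls there. Pairwise matrices recompute each pair on that pair's
individuals only.

**PCA.** Loci below 50 % call rate or without variance are removed;
missing dosages are mean-imputed; columns are centred and (by default)
scaled by √(p̄(1−p̄)·ploidy) — the Patterson convention. Eigendecomposition
is of the individual×individual covariance; coordinates are eigenvectors
scaled by √λ with a deterministic sign convention. All eigenvalues are
reported so their sum can be checked against the covariance trace.

**Ancestry.** The ADMIXTURE-style binomial mixture is maximised by plain
EM over Q (rows on the simplex) and P (entries clamped to
[10⁻⁶, 1−10⁻⁶] to avoid log 0). Both matrices update from the same E-step
responsibilities, so the likelihood trace is non-decreasing; convergence
is a relative gain below 10⁻⁶ (default) or 2000 iterations. Default 10
random restarts seeded from the run seed, best likelihood kept. (The
original analysis protocol repeated each K 100 times; 10 restarts is this
package's desk-scale default and the setting is exposed.) Label switching
is resolved, for any comparison against truth, by Hungarian assignment on
the Q columns.

**Choice of K.** Per fold, 10 % of non-missing entries are masked, the
model refitted, and the error is the mean squared difference between the
masked dosage and its expectation ploidy·qᵢᵀpₗ; the chosen K minimises the
mean across folds (ties to the smaller K). CV fits use lighter settings
(fewer restarts, looser tolerance) than the final fit, since ranking K
does not require deep convergence.

**Tree context.** An allele-sharing distance (mean |gᵢ−gⱼ|/ploidy over
co-called loci; population mode compares mean dosage profiles) feeds
Saitou–Nei neighbor joining. This is a qualitative stand-in for
likelihood phylogenetics, which is out of scope.

**Ploidy.** Whitefly males are haploid. Mixed-ploidy matrices are not
supported: callers must split by sex or declare a single ploidy; the
estimators take haploid or diploid mode explicitly.

## Integration rules

Clusters are anchored to species by majority vote of individuals whose
barcodes passed the screen; clusters sharing a species vote get
deterministic sub-labels (SSA1-1, SSA1-2). With τ = 0.10 (no numeric
threshold exists in the literature for the qualitative "hybrid" calls this
mirrors; τ is configuration and printed in every report): all minor
ancestry < τ ⇒ pure; any ≥ τ from another species ⇒ inter-specific
hybrid; otherwise within-species admixed. Verdict reconciliation:
agreement ⇒ concordant; NUMT-flagged barcode disagreeing ⇒ nuclear
species stands (resolved_numt); plausible barcode disagreeing ⇒
cytonuclear_discordant, nuclear species reported but the conflict is
flagged — a plausible barcode is never silently overwritten; no barcode ⇒
nuclear_only.

## Synthetic data: what it emulates, and what it does not

**Barcode panel.** A random 657 nt coding sequence (internally stop-free
under table 5) is the ancestor; species haplotypes accumulate uniform
(Jukes–Cantor-like) substitutions, rejection-sampled to remain stop-free,
at 8 % between species and 1 % within by default. NUMTs copy a random
haplotype, add 5 % substitutions with no constraint, and draw indels at
1 %/site with lengths 1/2/3 at probabilities 0.6/0.25/0.15 — mixing
frameshifting and in-frame events so both detector paths are exercised.
The generator records the planted alignment, so frameshift/stop truth is
exact, not re-detected. In the study mimic, within-species barcode
variation is synonymous-only, reflecting purifying selection on COI; the
indel length distribution is a free choice, flagged in configuration,
since the mutational spectrum of these NUMTs is not characterised beyond
"random indels".

**Genotypes.** Balding–Nichols: ancestral frequencies uniform on
[0.05, 0.95]; cluster frequencies Beta-distributed with per-cluster F;
binomial genotypes; admixed individuals draw from their Q-weighted
mixture frequency; missingness uniform at random. F = 1 is rejected
(degenerate Beta) and missing_rate = 1 leaves nothing callable.

**The study mimic** (62 individuals, 3,000 loci, seed-deterministic)
places 10 SSA2/SSA4, 34 SSA1-NW, 12 SSA1-SE and 6 contact-zone SSA-CA
individuals over three ancestral clusters at F = (0.40, 0.12, 0.15),
with five 50/50 NW/SE contact-zone individuals, one three-way hybrid and
two SSA2×SSA1-NW hybrids, and five SSA2 individuals carrying NUMT
barcodes descended from a divergent "SSA4" copy of the SSA2 barcode. The
real study's five populations keep WA and ECA separate (observed pairwise
Fst 0.171); here both are draws from the single NW cluster, so the mimic
uses four populations — splitting NW in two would create a near-zero
intra pair the observed data do not show. 3,000 loci stand in for the
study's 14,358: the package's chosen problem size, ample for every effect
simulated. The mimic has no linkage disequilibrium, no coalescent noise
shared between loci, no allele-frequency spectrum from real ascertainment,
and no sequencing error; passing tests show the estimators recover the
generating model, not that real nextRAD data are this clean.

## Numerical conventions

Reports use 1-based coordinates; internal indexing is 0-based half-open.
Missing dosage sentinel is −1 in memory, '.' in TSV, './.' in VCF. All
randomness descends from a single integer seed through
`numpy.random.default_rng`; identical configurations yield byte-identical
output files. p-distance ties in species assignment are resolved at
1 nt-per-site precision (abs 10⁻¹²); CV ties go to smaller K; NJ
tie-breaks are the library's, deterministic.

## Known limitations

* The screen depends on a trusted, stop-free reference in the correct
  frame; a contaminated reference invalidates every verdict (the tool
  refuses the obvious case of an in-frame stop).
* The conservation rule needs a reasonably diverse panel: with very few
  references almost every column looks absolutely conserved, inflating
  deviation calls on genuinely polymorphic residues.
* EM ancestry at large K on few individuals can converge to degenerate
  optima; restarts mitigate but do not eliminate this.
* Cross-validation selects predictive K, which may undercount clusters
  separated by very weak drift.
* The NJ tree and the admixture model ignore linkage; dense linked SNP
  panels should be thinned upstream.
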