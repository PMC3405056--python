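# Methods

This note documents the models, decision rules and numerical choices behind
`caviarid`, and what the synthetic benchmark does and does not demonstrate.

## Substitution model and likelihood

Nucleotide evolution follows the general time-reversible (GTR) model:
`q_ij = s_ij * pi_j` for `i != j`, six symmetric exchangeabilities `s`
(order AC, AG, AT, CG, CT, GT), stationary frequencies `pi` (A, C, G, T).
The rate matrix is normalised so `-sum_i pi_i q_ii = 1`; branch lengths are
therefore expected substitutions per site. Among-site rate variation uses
Yang's discrete gamma: K equal-probability categories (default K = 4), each
represented by its conditional mean, computed in closed form from the
regularised incomplete gamma function; category rates average exactly one,
so rate heterogeneity does not rescale branch lengths.

Likelihoods are computed by Felsenstein pruning over arrays of shape
(category, site, state). Partial likelihoods are rescaled per site at every
internal node, with the log scale accumulated separately, so alignments of
thousands of sites never underflow. Transition matrices come from the
symmetrised eigendecomposition of Q (exact for reversible models); rows are
clipped at zero and renormalised to absorb round-off. IUPAC ambiguity codes
and gaps are treated as missing data (partial likelihood 1 for every
compatible state). Reversibility makes the likelihood invariant to root
placement; the test suite checks this directly, along with exact agreement
(|Δ| < 1e-8) with exhaustive internal-state enumeration on small instances.

## Optimisation

* **Branch lengths** — coordinate-wise bounded Brent search per branch
  (bounds [0, 20] substitutions/site, `xatol` 1e-10), sweeping until a full
  sweep improves the log-likelihood by less than 1e-6. On two-taxon
  Jukes–Cantor data the optimum reproduces the closed form
  `-(3/4) ln(1 - 4p/3)` to better than 1e-4.
* **Gamma shape** — bounded Brent search on log(alpha), default bounds
  [0.02, 100]; a solution within 1% of either bound is flagged, which is the
  expected outcome on rate-homogeneous data.
* **Tree search** — multistart hill climbing: one neighbour-joining start
  (scikit-bio NJ on Jukes–Cantor distances) plus random-addition-order
  stepwise maximum-parsimony starts (Fitch scoring), refined by
  nearest-neighbour interchange with branch-length re-optimisation until no
  neighbour improves. Default 10 starts. This is a deliberately small,
  documented engine — no SPR, no partitioned or codon models — adequate for
  the reference-panel scale this package targets (tens of taxa), not for
  large phylogenomic searches.
* **Bootstrap support** — alignment columns are resampled, each replicate
  re-searched quickly (NJ start + NNI), and each internal edge of the best
  tree scored by the percentage of replicate trees containing its tip
  bipartition. Bipartitions are canonicalised by the side not containing the
  lexicographically smallest tip, making support invariant to rooting and
  tip order; 90% is the reporting threshold for "well supported".

## Query placement and species calling

A query is screened against every reference of its marker with
MegaBLAST-like local alignment scores (match +2, mismatch -3, gap open -5,
gap extend -2; biopython's PairwiseAligner). Queries already in reference
coordinates (the synthetic pipeline's case) are scored by direct column
comparison; others are mapped through their best-hit reference's alignment
coordinates, discarding query-only insertions. Identity is matches over
aligned columns of the best local alignment.

Placement precomputes, for every reference-tree edge, the conditional
likelihood of the reference alignment split at the edge midpoint
(inside x outside messages). Attaching a query then costs one contraction
per pendant-length value; the pendant length is optimised over a log-spaced
grid with two zoom rounds (final relative precision is ample for calling,
and the grid floor 1e-6 makes a tip-identical query report an effectively
zero pendant). Internal branch lengths stay fixed — placement is a
confirmation step, not a tree search. Likelihood-weight ratios (softmax of
per-edge maxima) are reported across all edges.

The caller is group-aware. Candidates are the species within 0.5 identity
points of the best hit plus the species of the placement edge's subtending
clade. One candidate gives a species call — unless that species belongs to
a group unresolvable at the marker, in which case the group is called (so
*A. persicus*, indistinguishable inside the *gueldenstaedtii* complex, is
never called at species level). Candidates spanning exactly one
unresolvable group give the group call; anything wider, or a best identity
below 98%, is unresolved. The 98% threshold anchors to the identity range
of solid barcode matches; both thresholds are configurable. When hits and
placement disagree, both are retained in the call's evidence and the
placement-derived clade drives the decision.

## Lot workflow

One egg per tin is identified first. cytb leads; D-loop is added when the
label is an osetra product or the cytb call lands in the *A. baerii* /
*A. gueldenstaedtii* / *A. naccarii* / *A. persicus* complex (where D-loop
adds resolution and separates *A. baerii* from *baerii*-like
*A. gueldenstaedtii*); a resolved D-loop call then overrides cytb within
that complex. cox1 is attempted only when neither cytb nor D-loop produced
a resolved call. Amplification failure is an input flag on the egg record,
never inferred from sequence content — wet-lab causes are outside scope.

A label-consistent call closes the lot on single-egg evidence. An
inconsistent call triggers confirmatory sequencing: nine further eggs by
default (all available eggs in the benchmark configuration), cytb-led with
the same escalation rules. The verdict is *mislabeled* only if every
resolvable confirmatory call is inconsistent with the label; tins containing
both consistent and inconsistent eggs are *mixed* — a case the original
survey design never encountered, which this package counts as mislabeled in
headline rates but reports separately. With fewer than nine confirmatory
eggs available the verdict stands but is flagged partially confirmed.
Haplotypes are counted at the deciding marker over all tested eggs, after
trimming to the commonly covered region and ignoring columns where any
sequence carries an ambiguity code. *Scaphirhynchus* calls are genus-level
and treated as consistent with hackleback labels.

Label consistency itself: an explicit species claim restricts the allowed
set to that species; otherwise the market-name policy applies (beluga →
*Huso huso*; sevruga → *A. stellatus*; osetra → *A. gueldenstaedtii*,
*A. persicus*, *A. baerii*; white → *A. transmontanus*; paddlefish →
*P. spathula*; hackleback → *S. platorynchus*; american → the three North
American species). Both sets are closed under marker-level
indistinguishability, so a group call inside the claim's group is
consistent. Labels that parse to no known market ("other") accept any
acipenseriform — such a tin is flagged only for a non-sturgeon substitute,
the most conservative reading of an uninformative label.

## Survey statistics

The rate denominator is lots with a usable extraction (verdicts other than
extraction-failed); unresolved lots stay in the denominator and are not
counted mislabeled. The 95% CI is exact binomial (Clopper–Pearson, via the
beta inversion); simulation confirms ≥93% empirical coverage at the study
conditions (p = 0.10, n = 90). Two surveys are compared by Fisher's exact
conditional test and a Newcombe score interval for the rate difference —
chosen because it respects the [−100, 100] range and behaves at zero
counts. The earlier pre-regulation survey enters only as its published
counts (18/95, ≈19%); nothing about it is recomputed.

## Synthetic data and the benchmark

`generate_references` simulates the three marker panels along a fixed
genus-level phylogeny (12 species, 2 sequences each). Interspecies
distances (≈2–10% divergence) and the gamma shapes (cytb 0.2237, D-loop
0.3453) follow values typical of sturgeon barcode alignments; D-loop evolves
1.4x faster than cytb. The *gueldenstaedtii* complex and the two
*Scaphirhynchus* species sit on branches of ~2e-4 substitutions/site, so
their non-identifiability is a property of the data, not a hard-coded rule.
Egg haplotypes are descendants of a species' reference haplotype along a
0.003 substitutions/site branch (≈99.5% identity to the panel).

`generate_survey` draws, per lot: a label from a market mix matching the
benchmark survey's composition; Bernoulli(p = 0.10) mislabeling with a
label-specific substitution table (premium Caspian labels replaced by the
complex species, *A. ruthenus*, *P. spathula* or Northern Pike); a
haplotype count (10% of tins pool 2–3 individuals); 14 available eggs; and
per-egg per-marker dropout (cytb 3%, D-loop 5%), matching the failure rates
a survey of this size encounters. Random streams split hierarchically
(survey → lot → egg), so one lot's draws never perturb another's, and
identical seeds give byte-identical surveys.

`encode_benchmark_survey` fixes one 92-tin survey — lot numbering, labels,
channels, years, the nine substitutions with their per-lot egg and
haplotype counts, the two no-DNA tins, the cox1-only pike tin, and the
D-loop amplification failures (lots 20, 44, 47, 94) that leave 32 lots
D-loop sequenced. Its sequences are synthetic, generated from the reference
panel under a fixed seed; the pipeline reproduces all headline figures
(90 testable, 9 mislabeled, 10.0%, all online, 32 D-loop lots) exactly.

**What passing these checks shows — and what it does not.** The synthetic
generator emulates survey *structure*: label mixes, substitution patterns,
pooling, dropout, group-level unresolvability. It does not emulate real
GenBank sequence content, alignment/trimming artefacts, chromatogram noise,
primer effects, heteroplasmy, or hybrid-origin caviar (mtDNA cannot detect
hybrids at all). Accuracy measured here is therefore a validation of the
decision logic and the inference engine under a realistic divergence
structure, not an accuracy claim for any particular wet-lab assay. Likewise
the engine's likelihood values on the benchmark panel are not comparable to
figures obtained from the authors' own alignments of real GenBank data,
which depend on unpublished alignment and trimming choices and on a
different (much larger) search heuristic.

## Problem sizes

Defaults were chosen so every routine study runs comfortably on a single
CPU: the reference panel is 24 sequences x 500–650 bp per marker; a 90-lot
survey identifies in about a second; the validation studies use 50 seeds x
50 lots (specificity), 20 seeds x 90 lots (sensitivity) and 200 replicate
surveys (rate recovery). Each knob is a `SimConfig` field and scales up
without code changes.

## Known limitations

* Placement keeps internal branch lengths fixed and evaluates midpoint
  attachment only; for queries far from every reference this can spread
  weight over adjacent edges (the group-aware caller absorbs most of this).
* The tree search is NNI-only and intended for small reference panels.
* No E-value statistics are attached to hits; identity and placement carry
  the evidential weight.
* Mixed-lot handling (both consistent and inconsistent eggs) is a design
  decision without an empirical precedent in the survey this benchmark
  encodes; the conservative choice (count as mislabeled, report separately)
  is documented above.
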