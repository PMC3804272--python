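# Methods

## Composition statistics

The unit of observation for the whole-sequence, shared-FSF, specific-FSF
and intervening contexts is one composition vector per sequence per
context: the relative abundance of each of the 20 standard amino acids in
that region (counts divided by the number of standard residues). Ambiguity
letters X/B/Z/U are excluded from numerator *and* denominator, so every
vector sums to 1, the property the downstream statistics assume; a region
left with zero standard residues contributes no observation.

Species are compared per amino acid with the two-sided Welch two-sample
*t*-test across the two sets of per-sequence abundances. No
multiple-testing correction is applied: the analysis reports raw *p*-values
under the star tiers \*<0.1, \*\*<0.01, \*\*\*<0.001, \*\*\*\*<0.0001 (the scheme has
no 0.05 tier, and we reproduce it exactly). The degenerate case of two
zero-variance samples returns *t* = 0, *p* = 1 when the means agree and is
an error otherwise; the df reported in that branch (nₓ+nᵧ−2) is a
convention, since Welch–Satterthwaite is undefined there. Report tables
carry both SD and SEM per group; plots draw SEM.

## Structural contexts

Assignments partition each sequence into three disjoint contexts —
shared-FSF domain regions, species-specific-FSF domain regions and
intervening regions — with a shared-over-specific precedence when
assignments overlap, so the three residue counts always sum to the
sequence length. Coordinates are 1-based inclusive in files (the
convention of structural-census region strings, including multi-segment
split domains) and 0-based half-open in memory. Sequences with an empty
relevant context are simply absent from that context's observation set;
no further filtering is applied.

## Homologous pairs and matched FSFs

Pairs are classified by comparing the FSF *multisets* of the two members
(categories: both empty / one empty / strict containment / incomparable /
identical). Multiset semantics mean an extra repeat of a shared FSF counts
as an extra assignment, and interval coordinates are deliberately ignored
— orthologs never align at the residue level. Only identical-architecture
pairs enter the matched analysis. Within a sequence, repeats of one FSF
are averaged, not pooled, so a short repeat weighs as much as a long one;
observations sharing an FSF are then averaged over pairs, and the per-FSF
species means are compared with the Welch two-sample test (the default
unit of inference is the FSF). A one-sample *t*-test on per-FSF paired
differences is available as a non-default alternative
(`matched_comparison(..., test="paired")`).

## Domain ages

Node distance is a topology-only statistic: internal nodes strictly
between the root and a leaf, normalized by the tree maximum. This is the
only reading under which a leaf attached directly to the root — the most
ancestral fold — gets nd = 0. Polytomous internal nodes count once each,
like binary ones. Normalization always uses the maximum over the provided
tree; restricting to a species subset does not re-normalize. The linear
clock *t* = −3.831·nd + 3.628 maps nd to Gy; values of nd above ≈0.947
yield negative ages, which are returned as-is with a warning rather than
clamped. Age strata are closed intervals: ancient nd ∈ [0, 0.2], recent
nd ∈ [0.6, 1.0]. A stratum holding fewer than two matched FSFs cannot be
tested; the library call raises, and the pipeline records the stratum as
unavailable and leaves its preference-grid column blank rather than
aborting the run.

## Preference grid and consistency

For each context a cell carries B (significant positive difference at
α = 0.1) or N (significant negative). An amino acid is flagged
*consistent* when at least 4 contexts carry the letter congruent with its
barophily class and no context carries an incongruent letter. This rule is
a design choice of the package (it reproduces the intended "consistent and
significant across structure and age" notion); indifferent amino acids
have no congruent letter and are never flagged.

## Synthetic generator

The generator emulates the statistical structure the pipeline is designed
to detect, not protein evolution. Residues are i.i.d. draws: domain
regions use class-tilted frequencies — in the barophile,
p(aa)·(1+δ_eff) for class-B and p(aa)·(1−δ_eff) for class-N amino acids
(renormalized), mirrored in the nonbarophile — and intervening regions use
the untilted background. δ_eff is the global δ times a per-stratum
multiplier of the domain FSF's age, which lets biases be confined to
ancient domains or erased in recent ones. The induced expected MAA
difference has the closed form

&nbsp;&nbsp;E[diff] = p·((1+δ_eff)/Z_A − (1−δ_eff)/Z_B),
&nbsp;&nbsp;Z_A = 1 + δ_eff·(P_B − P_N), Z_B = 1 − δ_eff·(P_B − P_N),

(P_B, P_N the background mass of the two biased classes), which the truth
record carries and tests verify both analytically and by Monte Carlo. For
uniform background and δ = 0.2 this is ≈ +0.02201 per barophilic amino
acid in domain regions.

Default study conditions: 300 homolog pairs plus 40 unpaired sequences per
species, 60 FSFs with 80% shared between species, domain lengths
N(200, 40²) truncated at 30 residues, intervening segments N(50, 20²)
truncated at 5, uniform background (p = 0.05), δ = 0.2, and 2% planting
rates for each of pair categories 1–4. These sizes give per-context
sample sizes (hundreds of sequences, ~48 matched FSFs) comparable to the
real *Pyrococcus* analyses while keeping a full run under a second.

The FSF tree is grown by sequential leaf splitting with probability 0.75
of splitting the most recently added leaf: real domain trees are highly
unbalanced, and this growth spreads leaf depths over the whole nd range
(uniform splitting concentrates depths mid-range and starves the ancient
stratum). One designated root-adjacent leaf is never split, so every tree
has a most-ancestral lineage with nd exactly 0.

What the generator does **not** emulate: positional composition structure,
phylogenetic autocorrelation among homologs, substitution processes, or
length/composition covariation. Passing recovery tests therefore
demonstrates correctness of the measurement and inference machinery under
the stated sampling model — not robustness to the dependence structure of
real proteomes.

## Numerical and calibration checks

* Welch *t* and df agree with a brute-force evaluation of the closed form
  to 1e−10 on random small samples.
* Node distances agree exactly with an independent root-down
  path-enumeration oracle on 200 random trees of up to 64 leaves.
* With δ = 0.2 at the default conditions (fixed seed), all 12 biased
  amino acids are recovered with the planted sign at *p* < 0.01 in domain
  contexts, while intervening regions stay null; with bias confined to
  the ancient stratum, the recent-stratum comparison shows no congruent
  letters for ≥10 of the 12.
* Under δ = 0 across 50 seeds (scaled-down bundles: 40 pairs, domain
  length 80, 30 FSFs), ~0.9% of amino-acid cells reach *p* < 0.01,
  confirming test calibration.
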