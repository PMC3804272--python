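# barocomp

Structure-resolved comparison of amino-acid usage between a barophilic
(piezophilic) proteome and a closely related nonbarophilic one — the
archetypal pair being the deep-sea archaeon *Pyrococcus abyssi* and its
low-pressure relative *P. furiosus*.

High hydrostatic pressure biases which amino acids proteins use. Five amino
acids (Arg, Ser, Val, Asp, Gly) are preferentially used by barophiles, seven
(Asn, Lys, Pro, Ile, Thr, Gln, Tyr) by nonbarophiles, and the remaining
eight are indifferent; each biased amino acid carries an integer barophily
rank BR (20 = most barophilic, 1 = least). `barocomp` asks *where in protein
structure* and *how far back in evolutionary time* these biases live, by
comparing mean relative amino-acid abundances (MAA) between the two species
across structural contexts:

* entire protein sequences,
* domain regions of fold superfamilies (FSFs, SCOP level) shared by the
  two species vs species-specific FSFs,
* intervening ("connecting") regions outside any domain,
* matched FSFs of homologous sequence pairs with identical domain
  architectures, optionally restricted to evolutionarily *ancient*
  (node distance nd ∈ [0, 0.2]) or *recent* (nd ∈ [0.6, 1]) domains.

## Model and statistics

For a region with residues drawn from the 20 standard amino acids, the
relative abundance of amino acid *i* is `n_i / Σ_j n_j` (ambiguity letters
X/B/Z/U are dropped from both counts). Per-sequence abundance vectors are
averaged within a species group to give MAA, and per amino acid the two
species are compared with the two-sided Welch two-sample *t*-test
(Welch–Satterthwaite degrees of freedom). Differences are reported as
MAA(barophile) − MAA(nonbarophile), so a positive difference means the
barophile uses the amino acid more. Significance tiers are
\**P* < 0.1, \*\**P* < 0.01, \*\*\**P* < 0.001, \*\*\*\**P* < 0.0001 (no 0.05 tier).

Domain age comes from a rooted phylogenomic tree of FSFs: the node distance
of a leaf is the number of internal nodes strictly between the root and the
leaf, normalized by the tree's maximum, and a linear molecular clock

&nbsp;&nbsp;&nbsp;&nbsp;*t* = −3.831 · nd + 3.628

converts nd to geological age in billions of years (Gy), placing the most
ancestral fold at 3.628 Gy.

For homologous pairs, only pairs whose two members carry identical FSF
multisets enter the matched analysis; within a sequence, repeats of an FSF
are averaged (not pooled), observations sharing an FSF are averaged over
pairs, and the per-FSF species means are compared by the same Welch test.

Because real structural-census inputs are large external resources, the
package ships a first-class synthetic generator that emits the exact input
formats with a planted, analytically tractable bias: domain-region residues
are sampled from class-tilted frequencies (`p·(1+δ)` for barophilic,
`p·(1−δ)` for nonbarophilic amino acids in the barophile, mirrored in the
nonbarophile; intervening regions untilted), with the tilt optionally
confined to an age stratum. Every pipeline stage is tested by recovering
those planted parameters.

## Worked example

```bash
barocomp simulate --out bundle --seed 42          # synthetic proteome pair, δ = 0.2
barocomp analyze --config run.yaml --out run      # run.yaml points at the bundle files
barocomp report --run run                         # renders the difference plots
```

The run on seed 42 analyzes 300 homolog pairs (276 of them with identical
domain architectures, spanning 48 matched FSFs). The shared-FSF comparison
table starts:

```
aa  class  rank  diff      p          stars
R   B      20    0.02052   1.4e-57    ****
S   B      19    0.02364   7.3e-70    ****
V   B      18    0.02357   1.5e-67    ****
D   B      17    0.02168   3.5e-58    ****
G   B      16    0.02090   2.4e-53    ****
```

All five barophilic amino acids are used significantly more by the
simulated barophile — each difference close to the analytic expectation
0.02201 for δ = 0.2 on a uniform background — all seven nonbarophilic ones
significantly less, and the preference grid
(`run/preference_summary.tsv`) flags exactly the 12 planted amino acids as
consistent. The intervening-region comparison shows no systematic bias, as
planted.

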