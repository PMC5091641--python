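# Methods

## The problem and the approach

A clan is a set of domain families that share a fold but cannot be linked by
sequence-only search. `clanseeker` links them with profile–profile
alignment: both query and target are summarized as profile HMMs — one
20-vector of pseudocounted amino-acid frequencies per match column, each
annotated with a predicted secondary-structure state (H/E/C) and a 0–9
confidence — and compared by local dynamic programming in which predicted
structure contributes a tunable fraction of the score. Around that engine
sits a calibrated, multi-stage search pipeline (chunked library → filter →
domain-only confirmation → transitive rescue) and a family-graph analysis.

## Profiles

Match columns come from the A3M case convention (lowercase and `.` are
inserts) or, for plain aligned FASTA, from a gap-majority rule (a column is
a match column when its gap fraction is < 0.5). Frequencies mix observed
counts with a background: `f_a = (n_a + α·bg_a) / (n_eff + α)`, uniform
sequence weights by default (Henikoff position-based weighting is an
option), α = 1 by default. The background is a Robinson–Robinson-style
composition table; tests use uniform 1/20. Insert/delete transition
probabilities are not modelled — gaps are handled by affine penalties in the
aligner, which keeps the engine small and the brute-force test oracle exact.

Proteins enter the search library as 200-residue windows stepped by 100; the
final window is anchored at the C-terminus rather than emitted short, so
every chunk presents a full-width profile and library statistics stay
uniform. Profiles round-trip through a TSV dialect (`#PHMM/1`) with
frequencies at 10 decimals (round-trip identity to 1e-9).

## Alignment engine

Per-cell score `S_aa + λ·S_ss`, where `S_aa = log2 Σ_a q_a t_a / bg_a` and
`S_ss = M(s_q, s_t) · (c_q/9)(c_t/9)` with `M(H,H) = M(E,E) = +1`,
`M(H,E) = −2`, and 0 for any pair involving a loop — confusing the two
regular structure classes is penalized harder than agreement is rewarded,
and loops are uninformative. λ defaults to 0.11 (sequence dominates);
0.30 is the "high structure weight" setting for diverged folds.

The DP is Gotoh-style local alignment with affine gaps (−3.0 bits to open,
−0.5 to extend; gap-to-gap transitions each open their own gap, matching the
enumeration oracle used in the tests). Alignment is local because genuine
remote hits can cover as few as a handful of columns. Traceback tie-breaking
is fixed (diagonal > up > left) and the best cell is the first maximal one in
row-major order, so results are deterministic; swapping query and target
mirrors the alignment (ties that would break the mirror have measure zero
for real-valued profiles). The inner loop is numba-jitted.

## Statistics and calibration

Decoy alignment scores follow an extreme-value law; a Gumbel is fit to the
benchmark's own decoy scores by method of moments (`β = sd·√6/π`,
`μ = mean − γ·β`) and gives each hit `Pval = 1 − exp(−exp(−(S−μ)/β))`
(floored at 1e-300) and `Evalue = N·Pval` for a library of N targets.

The ranking score is implemented exactly as printed in its source:

```
score_aass = base/0.45 − min(λ·score_ss, max(0, 0.2·(score−8)))/0.45 − 3.0
base       = logPval  if logPval < −10  else  ln(−ln(1−Pval))
```

together with the uncapped variant (`λ·score_ss/0.45` in place of the `min`
term), which removes the ceiling on the structural contribution; the capped
form is the default. Lower is stronger, and the uncapped value never exceeds
the capped one, with equality exactly when the cap does not bind.

prob[SS] — the probability that query and target share structure — is a
logistic in `−score_aass`, fit by Platt scaling (logistic maximum likelihood
with smoothed targets) on a labeled true/false hit set from the synthetic
benchmark: true examples are chunk-vs-own-family hits for chunks holding at
least 30 domain residues (so the weak end of the genuine range anchors the
transition), false examples are all decoy hits. Smoothed targets keep the
fit finite and deterministic when the classes are perfectly separated.
Because the calibration set is this package's own benchmark, absolute
prob[SS] values are meaningful only within it; they are intentionally
conservative in the score region between the decoy range and the weakest
labeled true hits.

## Pipeline

Fixed order: build → search → filter → confirm → (optional) transitive →
graph. The filter keeps hits with prob[SS] ≥ 85% — the threshold at which
the specificity curve shows essentially no decoys — and ≥ 20 aligned
columns, since shorter hits are typically to a single structural element.

**Domain-only confirmation.** For each passing hit, the query MSA is cut to
the hit window ± 4 columns (the midpoint of the 3–5 residue flank range),
rows with < 50% non-gap residues in the window are dropped, the profile is
rebuilt **without secondary-structure annotation** (states C, confidence 0 —
confirmation is a sequence-only re-alignment), and the window profile is
re-aligned pairwise against the reference domain. A hit is confirmed only if
the re-alignment again passes the policy. Confirmation can only reject,
never upgrade, and it runs only on hits that already passed the filter.
The row-coverage rule is what defeats contaminated MSAs: sequences that gave
a whole-region profile its domain-like character while only partially
overlapping the region fall out of the window sub-MSA.

**Bidirectional search** encodes the direction asymmetry of practical
searching: target libraries are built shallowly (here, single-sequence chunk
profiles), while a query centred on the region of interest carries its own
deep MSA. Forward search (reference family profile → chunk library) misses
diverged members that reverse search (region profile → reference library)
still finds; `agreed` records whether the reverse top hit names a family the
forward direction also found.

**Transitive search** takes every intermediate-library hit that passes the
policy, re-searches the reference library with the intermediate's profile,
and emits a link when both legs pass, deduplicated per (query, target) by
the maximal combined probability. Combined confidence is the minimum of the
two leg probabilities — deliberately conservative. The intermediate that
makes this work in the benchmark emulates a homolog of the query region in a
related proteome whose MSA spans the lineage (close relatives of the region
plus genuine family members), which is what lets it bridge a query too
diverged for direct detection.

## Family graph and curves

Families are nodes; a single hit at prob[SS] ≥ 85% makes a strong edge
(mutuality is not required; a `--mutual`-style strict mode would demand
both directions), and hits in the 50–85% band make weak edges provided no
known-negative hit ranks above them in their hit list (and the hit itself is
not a known negative). Clan groups are connected components over strong
(optionally plus weak) edges with deterministic ordering. Minimal seed sets
use greedy set cover (ties lexicographic) with an exhaustive exact mode for
≤ 20 seeds. The specificity curve bins hits by prob[SS] (width 5 over
[5, 100]) and compares observed false rates with the rate the metric itself
predicts; the COLs summary reports mean aligned length per prob[SS] centile
for true hits and individual points for false ones.

## Synthetic clans

The generator provides the statistical structure the analysis assumes. One
ancestral domain (length drawn from 100–120) is built on a fold template of
seven β-strands plus one C-terminal helix (strands ≈ 48% of length, helix ≈
12%, loops fill), with SS confidences 7–9 in structured elements and 0–4 in
loops. Family founders evolve from the ancestor at 1.6 substitutions/site;
members, reference sequences (8 per family) and "related-proteome"
intermediates (4 per family) evolve from each founder at 0.8, 0.8 and 0.4.
Substitution events arrive per site with Poisson counts (so divergence
compounds and composition equilibrates toward the background); each event
replaces the residue with a background draw excluding the current one. Loop
sites evolve 2× faster and are the only sites subject to indels (rate 0.02
per site; structured sites are never deleted), so fold outlasts sequence —
and loop columns of family MSAs have measurably higher entropy than
strand/helix columns, which is what makes SS weighting informative.

Members are embedded mid-host in 300-residue proteins (left flank ≥ 40
residues), which makes exactly two 200/100 chunks per host; with the default
6 families × 8 members and the 2:1 decoy ratio the benchmark presents 96
domain-bearing and 192 decoy chunk queries. Host MSAs carry the member's
family siblings aligned over the domain columns via the founder coordinate
system — emulating the MSA an iterative search would build — and decoys are
plain background sequence with single-row MSAs.

Contaminated constructs (the Age1p failure mode) are 180-residue background
regions whose MSAs carry two genuine donor-family sequences, alternating in
20-column blocks along the donor coordinate separated by 6 region-only
columns. Every contaminated column holds exactly one donor residue, so the
whole-region profile is half donor-derived and clears the raw filter, while
each donor row covers only ~43% of the hit window and is dropped by the
confirmation stage's coverage rule. Construct geometry was chosen so the
prescribed behaviour (pass raw, fail confirmation) holds across the 20
shipped construct seeds (7000–7019).

## What the benchmark shows — and does not

Passing the synthetic benchmark shows that the engine, statistics and
pipeline behave as designed under a known evolutionary model: i.i.d.
substitutions, indels confined to loops, exact SS templates with
well-calibrated confidences, and families of equal size and depth. Real
proteomes violate all of these — biased composition, rate heterogeneity,
repeats and low-complexity regions, secondary-structure prediction error,
wildly uneven family sizes — so the recovery and specificity rates here are
upper bounds on real-data behaviour, and absolute prob[SS] values do not
transfer outside the benchmark's own calibration. On this benchmark the
between-family divergence (1.6 subs/site per branch) leaves family-to-family
hits well above the decoy range but below the 85% confidence threshold, so
the family graph stays fully split at every SS weight; the SS-weight
comparison therefore appears as the invariant "raising λ never splits the
graph" rather than as observed merging.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere; converters live only at
  file boundaries.
* P-value floor 1e-300 keeps `logPval` finite; `Pval` is clamped just below
  1 before the second `score_aass` branch.
* The enumeration oracle and the DP agree to 1e-9 (floating-point addition
  order differs along a path); all other engine examples are exact.
* Degenerate inputs fail loudly: empty MSAs, constant conservation tracks
  (IQR 0), libraries without targets, uncalibrated hits reaching a filter.
* The `0.45` and `−3.0` constants in `score_aass` are inherited verbatim
  from the formula's source and are not reinterpreted here.
* Analysis scripts under `analysis/` are thin drivers over the library; the
  library functions (plus those scripts) are the interface — there is no
  separate CLI binary.

## Known limitations

* No maximum-accuracy (posterior) alignment variant; Viterbi-style DP only.
* No insert/delete transition modelling in profiles.
* prob[SS] is benchmark-calibrated (see above); cross-tool absolute values
  are out of reach by construction.
* The weak-edge curation rule needs truth labels; without them weak edges
  are band-only and flagged uncurated.
* `evolve_sequence`'s substitution model is i.i.d. across sites with a
  shared background — no rate matrix, no site-specific profiles.
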