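# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would want to know about.

## Paired differential expression

The design pairs each animal's operated (ipsilateral) and control
(contralateral) limb, so all inference runs on within-animal log2
differences; animal-level effects cancel by construction. Per probe the
statistic is the ordinary paired *t* on *n* differences (two-sided,
*t*(n−1)); at least three complete pairs are required. BH adjustment runs
across all tested probes of a timepoint, and probes collapse to genes by
the representative with minimal adjusted p — ties broken by larger
|log2FC|, then lexicographic probe id, making the result independent of
input order. A gene is significant iff any of its probes is (equivalent,
under a single threshold, to its representative being significant).

Degenerate probes: zero variance of differences with a zero mean is a
constant probe and is assigned p = 1 (logged); zero variance with a
non-zero mean is the noiseless limit of perfect separation and is
assigned p = 0. The second rule exists so that noise-free fixtures behave
as the limiting case of vanishing noise rather than inverting their
verdict at exactly zero.

Detection: a probe counts as confidently detected when its detection
p-value is below `alpha_det` (default 0.05) in at least `min_fraction`
(default 0.5) of the samples of at least one limb group — one group
suffices because a transcript switched fully off by the intervention is a
finding, not a detection failure. These defaults follow common BeadChip
practice. Without detection p-values all probes pass, with a logged
warning.

A moderated-*t* (empirical-Bayes variance shrinkage) option was
considered and left out: with eight pairs the ordinary paired *t* already
reaches the recovery levels reported by the acceptance checks, and one
reference method keeps the stage auditable.

## Hypergeometric overlap

`overlap_pmf_support` computes the overlap p.m.f. over its entire support
by anchoring the modal probability with exact integer binomial
coefficients (`math.comb`, converted through `fractions.Fraction` for a
correctly rounded float) and propagating outwards with the term ratio
pmf(k+1)/pmf(k) = (n₁−k)(n₂−k) / ((k+1)(U−n₁−n₂+k+1)). The cumulative
rounding of the ratio products grows only like the support length times
machine epsilon, so the support sums to 1 within ~1e−15 for U up to
20,000 — a log-gamma formulation drifts to ~1e−11 there, which is why it
is kept only as `overlap_log_pmf` for tails too deep to represent in
linear space. The scalar `hypergeom_overlap` reports both the point
p.m.f. (the quantity plotted when comparing a study against a reference
gene set) and the conventional upper tail P(X ≥ k), accumulated with
compensated summation.

The universe U for pairwise tests is an explicit, required parameter:
there is no universally correct choice, and making it implicit invites
silently incomparable p-values. The occurrence-pool default (10,000) is
used by the pipeline, with 15,000 as the documented alternative.

## Multi-study occurrence null

Observed histograms count membership only; direction of change is carried
as metadata but not required to agree, the more conservative reading when
source lists mix platforms and species. The Monte-Carlo null re-draws each
study list uniformly without replacement at its true size, independently
across studies, and tabulates genes by occupancy. Sampling uses the rank
trick — the nᵢ smallest of U iid uniforms per replicate form a uniform
without-replacement draw — which vectorises across a fixed internal batch
of 256 replicates; the batch size is fixed so results are bit-identical
regardless of how `n_sims` is chunked.

The closed form treats a single gene's occupancy as independent Bernoulli
across studies with pᵢ = nᵢ/U (the within-study dependence of a
without-replacement draw does not alter one gene's marginal), giving a
Poisson-binomial occurrence count evaluated by the standard O(S²)
convolution. Two identities hold exactly and are asserted in tests:
Σⱼ expected[j] = U and Σⱼ j·expected[j] = Σᵢ nᵢ.

Agreement between simulation and closed form is checked per level at
3 Monte-Carlo standard errors. Levels rare enough never to occur in a
finite simulation estimate their SD as zero, so the SE is floored by the
Poisson approximation √(μ/n_sims); without the floor the check is
ill-posed exactly where both numbers are indistinguishable from zero.

## Network stage

Edge tables follow the STRING export convention (`protein1, protein2,
combined_score`); the score scale (0–999 integer or 0–1 float) is
auto-detected from the maximum, and the default cut is the conventional
medium confidence (400 resp. 0.4). Both endpoints must be significant
genes; matching is case-insensitive; self-loops are dropped; parallel
edges collapse keeping the maximal score; nodes only enter through a kept
edge, so isolated genes are never represented. Hubs are nodes with at
least 10 partners — the criterion used for the network figures this
mirrors — ranked by degree then name, with the single top hub flagged.

## Enrichment

Over-representation uses the same hypergeometric upper tail with the
detected genes as background (standard ORA practice — testing against the
whole genome inflates enrichment of anything expressed in the tissue).
Pathways are intersected with the background before testing; BH runs
across tested pathways. For cross-study pathway comparisons the
significance call is raw p < 0.05, matching how such pathway lists are
usually reported; adjusted values are emitted alongside. The EASE-style
modification of the hypergeometric (subtracting one hit) is deliberately
not used; the plain tail is declared as the reference.

## Synthetic generators

`simulate_experiment` emulates the paired design: per probe p of gene g,
animal a, limb l,

    y = μ_g + δ_p + α_{a,g} + s_l·β_{g,t} + ε,

with gene baselines μ_g ~ N(8, 2) (typical log2 microarray intensities —
the value is irrelevant to paired statistics), fixed probe offsets
δ_p ~ N(0, 0.25), an animal-by-gene effect α ~ N(0, 0.5) shared by both
limbs (cancelling in the pairing, inflating any unpaired analysis),
planted effects β applied to ipsilateral samples only, and residual noise
ε ~ N(0, 0.5). Planted effect magnitudes are uniform on [0.585, 3.0]
(fold change 1.5–8), signed up with probability 0.6 — mirroring a
regulated-gene mixture dominated by up-regulation but with a substantial
down component. DE counts default to 1224/76/2 at 2/4/8 weeks, and
later-timepoint gene sets are nested inside earlier ones, reflecting the
persistence of a small gene core across the time course. Probes number
1.2 per gene (1425 probes for 1224 genes at the first timepoint is the
motivating ratio). One RNG stream per generator, seeded from the config;
identical configs give bit-identical matrices.

What this generator does *not* emulate: bead-level noise, background
correction, normalisation artefacts, batch effects, detection-call
structure, or correlated gene modules. Consequently, passing tests
demonstrate the statistical machinery is correct under its stated model,
not that the specific gene counts would reproduce on real arrays.

`simulate_study_collection` plants `planted_core` genes (default 22) into
exactly `m_core` (default 5) randomly chosen of 9 studies, then fills each
list to its exact size by sampling without replacement; background genes
can raise a core gene's occupancy by chance, so the planting contract is a
lower bound. Default list sizes (1224, 200, 300, …, 900) over U = 10,000
were chosen as a realistic spread for published OA arrays; under the
random null they give an analytic at-least-5 expectation of 0.74 genes,
so the planted core of 22 stands out by more than an order of magnitude.

Secondary generators produce STRING-style edge tables with planted hubs
(hub degrees are lower bounds; background edges can add partners) and toy
GMT catalogues with optionally planted pathways.

## Pipeline, seeding, reproducibility

All randomness derives from one root seed through named substreams
(`SeedSequence([seed, crc32(stage_name)])`), so stages are decorrelated
but individually reproducible, and re-running any stage from intermediates
is bit-exact. Every output table carries `# stage=<name>
config_hash=<hash>` in its first line; the hash covers analysis parameters
but not the output directory. Stage failures abort with the stage name
and a machine-readable code.

## Problem sizes used by tests and the acceptance script

Simulation-heavy checks use deliberately chosen sizes: FDR-control runs
200 null experiments of 500 genes; power uses 50 full-scale replicates
(10,000 genes, 8 pairs); the occurrence null is verified at 10,000
replicates on a grid of S ∈ {2, 5, 9} and U ∈ {100, 10,000}; exhaustive
p.m.f. enumeration covers every configuration with U ≤ 12. These sizes
give Monte-Carlo standard errors comfortably below the tolerances they
are tested at.

## Known limitations

* The DE reference method is a declared choice; the original analysis
  protocol behind the counts this emulates (normalisation, detection
  call, exact test) is not reproduced, and no claim is made that real
  deposited data would yield the same gene lists.
* Ortholog harmonization is translation through a supplied two-column
  map plus upper-casing; no orthology inference is attempted, and
  unmapped symbols pass through upper-cased.
* Venn region algebra covers 2–4 sets; higher arities are served by the
  occurrence histogram.
* The occurrence null assumes exchangeable genes within the pool; real
  arrays have platform-specific detectability, which the null ignores.
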