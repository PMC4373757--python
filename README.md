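# ptoa — paired DE and cross-study concordance for post-traumatic OA cartilage transcriptomics

`ptoa` re-implements, as a tested and reusable pipeline, the computational
analysis of a murine post-traumatic osteoarthritis (PTOA) cartilage
time-course study: articular cartilage of the medial tibial plateau is
profiled at 2, 4 and 8 weeks after destabilisation of the medial meniscus
(DMM), with each animal's operated (ipsilateral) knee compared against its
own unoperated (contralateral) control. It is aimed at researchers doing
transcriptomic meta-analysis of osteoarthritis models who want the
statistics behind such a study — not its wet-lab specifics — in library
form, runnable end to end on synthetic data.

## What it computes

**Paired differential expression.** For each probe at a timepoint, a
two-sided paired *t*-test on the within-animal log2 differences
d_a = y_a,ipsi − y_a,contra:

    t = mean(d) / (sd(d) / √n),   df = n − 1,

with Benjamini–Hochberg adjustment across all tested probes and
probe→gene collapsing by the minimal-adjusted-p representative. Genes with
adjusted p < 0.05 are significant; volcano classification highlights fold
changes beyond 2.8 / 0.35 (2 weeks) or 1.5 / 0.5 (later).

**Exact overlap statistics.** The overlap k between two gene lists of
sizes n₁, n₂ drawn from a universe of U genes follows a hypergeometric
law,

    P(X = k) = C(n₁, k) · C(U − n₁, n₂ − k) / C(U, n₂),

reported both as the point p.m.f. and as the upper tail P(X ≥ k). The
p.m.f. is computed over its whole support by anchoring the mode with exact
integer binomials and propagating term ratios, so it sums to one at
machine precision even for U in the tens of thousands.

**Multi-study occurrence null.** For S study lists over a common pool of
U genes, the observed histogram of genes present in exactly j lists is
contrasted with a Monte-Carlo null in which every list is re-drawn
uniformly without replacement at its true size. Its closed form — a gene
belongs to list i with probability nᵢ/U independently, so the occurrence
count is Poisson-binomial — serves as the analytic oracle:

    E[exactly j] = U · P( PB(n₁/U, …, n_S/U) = j ).

**Network and pathway layers.** A STRING-style edge table is filtered to
medium-confidence edges between significant genes; degrees, connected
components and hubs (≥ 10 partners) are reported. Over-representation of
the DE list in a GMT pathway catalogue uses the same hypergeometric upper
tail with the detected genes as background and BH across pathways.

**Synthetic data.** A generator emulates the study design: 8 animal pairs
per timepoint, ~1.2 probes per gene, and a planted DE signal decaying
1224 → 76 → 2 genes over the time course; a second generator builds
nine study gene lists with a planted core of 22 genes recurring in at
least five lists over a 10,000-gene pool — under the random-list null
only 0.74 such genes are expected.

## Worked example

The numbered drivers under `analysis/` run the study end to end on
synthetic data, writing tables under `results/analysis/`:

```bash
python analysis/01_simulate_experiment.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_cross_study_concordance.py --seed 1
python analysis/04_network_hubs.py --seed 1
python analysis/05_pathway_enrichment.py --seed 1
```

prints, among other lines:

```
2w: 1115 significant genes (8 pairs); planted 1224, recovered 86.8%, false positives 52
4w: 59 significant genes (8 pairs); planted 76, recovered 69.7%, false positives 6
8w: 0 significant genes (8 pairs); planted 2, recovered 0.0%, false positives 0
genes in >= 5 lists: observed 23, null expectation 0.75 (10000 simulations), closed form 0.74
network: 1190 edges between 984 nodes (30 components; 0 unknown-symbol edges skipped)
hubs (degree >= 10): 5; top hub g000335 with 18 edges
top pathway: PW_PLANTED (k=40/K=40, p_upper=4.14e-39, BH p=1.28e-37)
```

Reading this: the paired test recovers most of the planted 2-week signal
at a controlled false-positive cost and, as planted, the signal dissipates
by 8 weeks (two weak-effect genes among 10,000 are below the power of an
8-pair design). The concordance stage shows the planted recurrent core
standing far above the random-list expectation of under one gene — the
observed-versus-expected contrast that makes multi-study recurrence
meaningful. The network stage recovers exactly the five planted hubs, and
enrichment flags the pathway planted on truly regulated genes.

The same stages are available as subcommands of the `ptoa` CLI
(`ptoa run-all --config cfg.yaml`, or `simulate`/`de`/`overlap`/
`occurrence`/`network`/`enrich` individually), all driven by one YAML
config and one root seed; outputs carry their producing stage and config
hash in a header line and are byte-reproducible for a fixed seed.

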