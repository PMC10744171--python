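# Methods

This note documents the models, conventions and numerical choices behind
`viromix`, and what the synthetic-data tests do and do not establish about
real data.

## Dereplication: ANI, aligned fraction and greedy centroid clustering

Two genomes are compared by placing the shorter inside the longer with an
infix edit-distance alignment (edlib) and trimming that alignment to its
maximal-scoring contiguous block under match +1 / mismatch −1 / gap open −5 /
gap extend −1 (the scoring is configurable via `AlignScoring`). ANI is the
percent identity over the block's columns; AF is the block's span on the
shorter sequence divided by that sequence's length. For collinear genomes —
the dereplication use case — this equals the classical merged-block ANI; it
does not chain rearranged blocks, which is out of scope. The test suite
cross-checks ANI values against an independent exhaustive-DP global aligner
(Biopython) on small pairs.

Clustering is greedy centroid clustering: genomes are visited by decreasing
length (ties by ascending id) and join the first cluster whose
*representative* they match at ANI ≥ 95 and AF ≥ 85 (both inclusive — the
thresholds read as attainment). The founder, i.e. the longest member, is the
representative. Measuring AF on the shorter sequence makes containment
dereplicate into the longer genome. Whether AF should be measured on query
or target is not uniquely determined by convention; the shorter-sequence
rule is the package's documented choice and is boundary-tested.

Quality gate before clustering: length ≥ 1000 bp AND completeness determined
AND ≥ 50 %. Tier boundaries: 100 → complete, (90, 100) → high,
[50, 90] → medium (both ends inclusive, so exactly 90 is medium),
[0, 50) → low, undetermined stays undetermined.

## Presence calling

Average coverage is `read count × mean read length / vOTU length`. Presence
requires coverage **strictly over** the 10-fold threshold: the verbatim rule
is "over 10-fold", so exactly 10.0 is absent; the generator plants one such
boundary cell to keep the convention honest. A single qualifying sample
suffices for group presence (the Venn logic is existential). The VLP and WMS
datasets are classified independently and never pooled. A viral cluster is
case-unique only if it has ≥ 1 present member and every present member is
case-unique; any communal or opposite-group member makes it shared;
all-absent VCs are excluded from Venn counts.

## Cross-dataset identity cascade

Direction is fixed: WMS vOTUs are queries, VLP vOTUs subjects. Per query the
best hit is the maximal bitscore, ties broken by minimal e-value then
ascending subject id (tie-breaks are package inventions for determinism).
The filter requires all four of: e-value ≤ 1e−5, bitscore ≥ 1000,
pident ≥ 95, qcovs ≥ 85. The cascade consumes the standard 12-column tabular
alignment format plus a query-coverage column; for synthetic tests an
internal aligner emits the same dialect with blastn-style Karlin–Altschul
statistics (λ = 1.28, K = 0.46 for the +1/−2 scoring regime), under which a
≥ ~600 bp exact match clears bitscore 1000.

## Host association

Predictions below confidence 90 are dropped (inclusive cutoff). Host
identity is the verbatim genus string — GTDB-style suffixed genera such as
`Clostridium_J` are distinct taxa; no taxonomic normalisation is applied.
Links to absent viruses carry no evidence and are removed before labelling;
hosts left without present links are omitted. Labels are a pure function of
the multiset of linked presence classes (exclusively_case / case_associated
/ communal_only / mixed, and the control-side mirrors). The top-N
cross-reference ranks genera by **mean** relative abundance across case
samples (mean rather than median is the package's choice, configurable),
annotating each genus with its host class per dataset or "no prediction".

## Community statistics

* **CLR**: log(x / geometric mean) per sample after adding a pseudocount of
  1 to every cell (pseudocount 0 is allowed only for strictly positive
  tables). Natural logarithms throughout, for CLR and Shannon alike.
* **Chao1**: the bias-corrected form `S_obs + f1(f1−1)/(2(f2+1))`, defined
  even without doubletons. Coverage-valued tables must be rounded (half-up)
  to integers first; the functions refuse non-integer input rather than
  silently rounding.
* **Rarefaction**: multivariate hypergeometric subsampling (without
  replacement) to the minimum sample depth by default, seed-deterministic;
  the tests verify the mean rarefied richness against the closed form
  `E[S] = Σ_i (1 − C(N−N_i, d)/C(N, d))`.
* **Distances**: Bray–Curtis on counts, Jaccard on presence/absence, via
  scipy. Convention for degenerate samples: two empty samples are at
  distance 0, an empty vs a non-empty sample at 1.
* **PERMANOVA**: pseudo-F from the among/within decomposition of squared
  distances; p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm). With
  `restriction="within_household"` labels are permuted only inside each
  household block — the exchangeability structure of a matched design.
  `n_perm="exact"` enumerates all distinct labelings (small designs only);
  the 2+2 enumeration is tested against an independent brute force, and the
  unrestricted pseudo-F against scikit-bio.
* **ICC**: one-way ANOVA method of moments,
  `σ²_between/(σ²_between + σ²_within)`, truncated at 0, with the k0
  correction for unequal household sizes; singleton households are dropped.
  This replaces a full REML mixed model: with one case and one control
  member per household contributing one sample each, the random-intercept
  model reduces to the one-way decomposition at desk scale. The estimator
  matches pingouin's ICC(1,1) exactly in the tests.

## Household-matched power analysis

Model per genus: log10 abundance `y = μ_g + b_h + δ_g·I(case) + ε` with
`b_h ~ N(0, σ_h²)`, `ε ~ N(0, σ_e²)`, `δ_g = log10(fold change)` — so a
10-fold change is +1.0 and a two-fold change ≈ +0.301. The within-household
difference removes `b_h`; the per-genus test is a two-sided paired t-test on
n_pairs differences, which are `N(δ, 2σ_e²)`. Defaults: α = 0.001 and target
power 0.90 (the matched design's published decision thresholds);
σ_h = 0.8 and σ_e = 0.5 on the log10 scale. The variance components are free
parameters of the generator — the source cohort's estimates are not public —
chosen once as round values typical of gut genus abundances: a residual SD
of half a decade between cohabiting individuals, and a dominant household
share (ICC ≈ 0.72, consistent with the strong household clustering such
cohorts report). Under these defaults the simulated minimal sample sizes are
16 pairs for a 10-fold effect and ~122 pairs for a two-fold effect; only the
ordering (large effects need an order of magnitude fewer pairs), not the
exact counts, is asserted by the tests.

`simulate_power` simulates the generative model explicitly (household
intercept included, then differenced) rather than its reduced form;
`analytic_power` provides the noncentral-t closed form as a secondary
cross-check (the far-tail term is clamped where scipy's noncentral-t
underflows to NaN). `minimal_pairs` bisects on n using per-n seed-derived
streams, so probes agree with grid evaluations at the same seed. "Detect
90 % of genera" is operationalised as per-genus power ≥ target for ≥ 90 % of
the panel.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions all recovery tests run under:

* **Cohort**: 6 households, each contributing one case and one control
  member to both the VLP and WMS arms (12 samples per dataset) — a small
  household-matched design of the kind the analysis targets.
* **Contigs**: 4 parent genomes of 1.5–3 kb, each with a 2 %-substituted
  full-length copy and a 90 %-length contained fragment (also 2 % mutated),
  4 random decoys, 2 quality-gate decoys (sub-kilobase / undetermined /
  low-completeness, cycled), and 3 parents copied verbatim into the opposite
  dataset for the matching stage. Substitution-only mutation (no indels)
  keeps the DP oracle simple while exercising the ANI thresholds
  identically. At mutation rate ≤ 0.03 co-clustering with the parent is
  guaranteed (the parent is the representative by construction, so derived
  contigs face single-rate divergence); at ≥ 0.10 separation is guaranteed;
  the band between carries no guarantee and the default stays at 0.02.
* **Coverage**: 200 vOTUs per dataset; 30 case-unique, 30 control-unique,
  60 communal, 80 absent. Planted-present cells are log-normal draws
  truncated strictly above threshold + 2; background cells strictly below
  threshold − 0.5; one absent-vOTU cell sits at exactly 10.0 as a boundary
  probe. Margins make truth recovery exact, which is the point: these tests
  verify the logic, not robustness to borderline coverage.
* **Hosts**: one planted exclusive host (named for the disease-associated
  genus pattern it emulates) linked to three case-unique VLP vOTUs at high
  confidence; nine decoys cycling through the other association patterns in
  one or both datasets, including a near-miss whose only case-unique link
  sits below the confidence cutoff, plus sub-cutoff noise rows.
* **Abundances**: 30 genera with log10 baselines spanning 0–3.5 (so rare
  genera drop out of samples and richness varies), per-(genus, household)
  intercepts, and by default one 10-fold case effect in the first genus.
  Counts are rounded half-up for rarefaction compatibility.

Not emulated: read-level data (FASTQ), assembly artefacts, chimeras,
realistic phage genome content or length distributions (real gut phages run
to hundreds of kb; desk-scale lengths keep the exhaustive oracles fast),
indel divergence, compositional sequencing-depth effects, or
contamination. Passing recovery tests therefore demonstrates correctness of
the decision rules and statistics under their stated assumptions, not
robustness of upstream bioinformatics on real sequencing runs.

Determinism: each generator operation draws from its own stream derived from
the master seed by a fixed offset, so adding a generator never perturbs
another's output; identical configs give byte-identical files, and the
pipeline manifest records SHA-256 digests of every output.

## Problem sizes

Recovery and calibration checks run at: 100 seeds for dereplication
(≤ 25 contigs each), 5 seeds for presence matrices (200 × 24), 50 end-to-end
pipeline runs, 500 null PERMANOVA datasets at 99 permutations, 2000
simulations per power-grid cell (5000 in the acceptance script), and 10⁴
households for the ICC closed-form check. These sizes keep Monte-Carlo
standard errors small relative to the asserted tolerances (3 binomial SEs
for calibration checks, 4 SEs for rarefaction means).

## Known limitations

* The block aligner returns the single best local block; genomes related
  through rearrangement would under-report AF. Real-data runs at scale
  should delegate alignment to a dedicated search tool (the cascade consumes
  the standard tabular format either way).
* Greedy centroid clustering is order-dependent by design (longest-first);
  it matches the field's standard dereplication behaviour but is not a
  globally optimal partition.
* The internal aligner's e-values use an ungapped Karlin–Altschul
  approximation; they are meant for threshold logic on synthetic data, not
  for reporting.
* PERMANOVA p-values with sampled permutations are slightly conservative on
  very small designs where the distinct-permutation space is tiny; use
  `n_perm="exact"` there.
* The power model treats genera independently on the log scale and ignores
  compositionality; a CLR-level power model is out of scope.
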