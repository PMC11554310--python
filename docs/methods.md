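# Methods

## Measurement model

Each protein's soluble fraction after a brief heat challenge is a descending
two-state logistic in temperature,

    f(T) = plateau + (1 − plateau) / (1 + exp((T − Tm)/slope)),

with melting temperature `Tm` (°C), transition scale `slope` (°C, > 0), and a
non-denaturing `plateau` in [0, 0.3] — the fraction of the pool that stays
soluble at high temperature. A two-state logistic is standard CETSA/TPP
practice and is analytically tractable; no kinetic (non-equilibrium)
denaturation is modelled. f is strictly decreasing and f(Tm) = plateau +
(1 − plateau)/2 exactly.

A PISA sample pools equal volumes heated at `n_temperatures = 10` equally
spaced points spanning the window inclusive of both endpoints (matching a
ten-tube gradient), so the pooled soluble abundance is the arithmetic mean
S_M of f over that grid. A ligand-induced shift ΔTm reads out as

    log₂FC = log₂( S_M(Tm + ΔTm) / S_M(Tm) ),

whose sign matches ΔTm whenever the transition overlaps the window. The
default window is 48–58 °C; narrower windows amplify fold changes (the
48–58 °C window yields ~2.7× the mean |log₂FC| of 37–62 °C at ΔTm = +2 over
the default proteome), at the cost of leaving early- and late-melting
proteins uninformative.

## Synthetic screens

The generator exists so that every downstream statistic can be checked
against known ground truth. Defaults, chosen once:

* **Proteome** — Tm ~ Normal(50, 4) °C, slope ~ U(1, 3) °C, plateau ~
  U(0, 0.15). This puts the 48–58 °C window on the back half of most melting
  curves; ~97% of proteins are *window-informative* (S_M in (0.05, 0.95)),
  comfortably above the ≥ 80% design target.
* **Layout** — 16-channel plexes, duplicate treatments co-plexed, 4 vehicle
  channels per plex in cell mode (6 compounds × 2 + 4 = 16; 96 compounds →
  16 plexes, 256 channels) and 2 in lysate mode (7 × 2 + 2 = 16; 70
  compounds → 10 plexes, 160 channels). Partial final plexes are padded with
  extra vehicle channels and the padding is reported.
* **Effects** — one primary target per compound with signed ΔTm, magnitude
  U(1, 8) °C (saturating-dose shifts), stabilization twice as common as
  destabilization; 20% of compounds additionally perturb one unrelated
  protein (magnitude U(1, 4) °C) flagged `secondary`. Secondary effects act
  in cell mode only and are suppressed in lysate mode, mimicking indirect
  (e.g. phosphorylation-mediated) stability changes that vanish when
  signaling is disrupted — without modelling phosphorylation itself.
* **Noise** — per-measurement multiplicative log-normal noise with
  `measurement_cv = 0.05` (typical protein-level TMT precision after
  signal-to-noise filtering) and per-channel loading factors with
  `loading_cv = 0.10`. Both log-normals are median-one; zero CVs reproduce
  the noise-free expected matrix exactly. Abundance = loading × S_M(shifted
  curve) × exp(noise).
* **Randomness** — one seed spawns independent substreams for proteome,
  effect assignment, and noise, so any stage can be regenerated alone.

What the generator does **not** emulate: peptide/PSM-level effects (reporter
interference, isotopic impurity, missing-value structure from MS sampling),
protein-specific abundance scales, correlated co-regulation among
non-targets, and dose–response saturation. Passing tests therefore
demonstrate the correctness and calibration of the statistics under the
stated noise model, not robustness to every artifact of real LC-MS data.

## Normalization

Within each plex, channel sums are computed over the proteins quantified in
*all* channels of that plex (so missingness cannot bias scale factors) and
every channel is rescaled so those sums equal the plex-wide mean of the
original sums. The scale is applied to all rows, including incomplete ones.
Missing values propagate; nothing is imputed. The operation is idempotent
and preserves within-channel ratios.

## Hit calling

Replicate-level log₂ fold changes are taken against the arithmetic mean of
the vehicle channels of the same plex. Vehicle channels themselves re-enter
the analysis as one pseudo-treatment per plex (`DMSO::<plex>`), so vehicle
variability is represented in the per-protein spread estimate; they are
never eligible as compound hits.

Per protein, replicates are averaged per treatment first; the treatment-
level values across the whole screen (vehicle pseudo-treatments included)
are symmetric-trimmed by `trim_fraction = 0.1` per tail — floor(n × 0.1)
values removed from each end — and summarized by the mean and population SD
of the retained values. Population (ddof = 0) moments keep the invariant
trimmed SD ≤ untrimmed SD robust at small n. The z-score is

    nSD = (x̄_treatment − trimmed mean) / trimmed SD,

centered on the trimmed mean (the same retained set as the SD). Proteins
with fewer than 3 treatment-level values or trimmed SD = 0 get missing nSD
and can never be hits.

A (protein, treatment) is a hit iff **every** replicate has |log₂FC| ≥ 0.2
and |nSD| ≥ 3.5; cutoffs are inclusive and configurable. Treatments with a
missing replicate are ineligible (the both-replicate rule cannot be
certified). Direction follows the sign of the treatment mean. Raising either
cutoff can only remove hits, and nSD is invariant to rescaling a protein's
fold changes.

**False-hit calibration.** Within each plex, disjoint consecutive pairs of
vehicle channels are relabelled as duplicate pseudo-compounds — one pair per
plex per round, the remaining vehicles keeping the reference role (hence
≥ 4 vehicle channels per plex are required) — and scored through the
identical pipeline. The rate is pseudo-compound hits over fully measured
(protein, pseudo-compound) pairs, pooled over rounds, with a per-plex
breakdown. On a null 16-plex cell screen at default noise the rate is
~0.2%, well under the 3% design bound; it is conservative in that the
held-out pair is compared against only the two remaining vehicle channels.

Dose series need no bespoke statistic: each (compound, dose) is a distinct
treatment.

## Target assessment

A compound is *on-target* in a mode if any of its annotated targets is a hit
there (multi-target compounds count once); compounds with no quantified
target are excluded from denominators. The combined rate is computed over
compounds whose target is quantified in every mode present, with a hit in
any mode counting. Global target/non-target separation uses a two-sided
Wilcoxon rank-sum on |mean log₂FC| (exact enumeration below a combined n of
30, otherwise the normal approximation with continuity correction).

Ground-truth recovery on the default benchmark screen (50 compounds, 5,000
proteins, default noise): sensitivity ≥ 0.8 for primary effects with
|ΔTm| ≥ 2 °C on window-informative targets (measured ~0.89–0.98 across
seeds) at a non-target false-call rate ≤ 0.04%. The pair-level rank
correlation between measured log₂FC and injected ΔTm is ~0.87 (seed-median):
the ΔTm → ΔS_M map is protein-specific — the same shift yields a large fold
change mid-window and a small one near the solubility ceiling or plateau
floor — so cross-protein rank correlation is bounded below 1 by design, not
by noise.

## Correlation network

Solubility profiles are replicate-averaged log₂FCs per (protein, treatment),
vehicles excluded. Spearman's ρ (average-rank ties) is computed per
unordered protein pair over pairwise-complete treatments, requiring
`min_pairs = 10` shared observations. The all-by-all comparison count is
reported with the P² convention (self-pairs and both orders — 8,390 proteins
→ 70,392,100 comparisons) while the edge list stores each unordered pair
once. The default filter keeps |ρ| > 0.35 and reports the kept fraction; a
quantile mode (top fraction by |ρ|, deterministic tie-break) is provided for
exactness. Graphs are undirected, ρ-weighted, with kinome-group node labels
from the fixed vocabulary (AGC, Atypical, CAMK, CK1, CMGC, STE, TK, TKL,
Other, non-protein kinase; unannotated → "unknown") and induced-subgraph
extraction by node set or group. Edge p-values (t-approximation,
Benjamini–Hochberg) are not part of the default filter, which is magnitude-
based.

A planted complex — three proteins sharing six compounds' effects with
member-specific scaling among 200 background proteins — lands in one
connected component after default filtering in ≥ 95 of 100 seeds (measured
100/100).

## Pipeline and numerical choices

`run_pipeline` chains simulate-or-read → normalize → hit calling → target
assessment → network, writing per-stage TSVs, GraphML, a JSON summary, and a
run log with seed and cutoffs; outputs are byte-identical under a fixed
seed. Because pairwise-complete Spearman is quadratic in the protein count,
the pipeline's network stage keeps the `network_max_proteins = 500` most
variable profiles by default — the practice of restricting the network to an
annotated subset (e.g. the quantified kinome) — while the P² comparison
count still refers to the full matrix.

Degenerate inputs are handled explicitly: inverted windows, non-positive
slopes, infeasible plex geometries, all-zero channels, plexes with fewer
than two vehicle channels, trim fractions ≥ 0.5, and empty rank-sum groups
raise; constant proteins and missing replicates yield missing nSD/ineligible
hits rather than errors. Reported problem sizes (6,800 × 256 null screen,
5,000 × 50-compound benchmark, 100-seed network recovery) keep the full
suite and the acceptance script to a few minutes on one CPU.

## Known limitations

* The trim fraction, vehicle-pool construction, and nSD centering are
  reasonable conventions where the hit-calling framework is under-specified;
  hit counts are mildly sensitive to each (all are configurable).
* The generator's noise is homoscedastic on the log scale; real screens show
  intensity-dependent variance and structured missingness.
* On-target rates on synthetic screens are optimistic relative to published
  screens because every annotated target is quantified and every compound
  engages its target by construction.
* Lysate layouts (2 vehicle channels per plex) cannot support the held-out
  pseudo-compound false-hit estimate, which needs ≥ 4 vehicle channels.
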