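# Methods

This note documents the models and conventions implemented in `shapecov`,
the parameters that matter, and the design choices made where the published
conventions leave the details open.

## Pentamer shape model

DNA shape is predicted by a sliding-pentamer lookup: the structural
environment of a base pair is approximated by its two neighbours on each
side, so a table over the 512 pentanucleotides (unique up to reverse
complement) assigns to each pentamer a minor groove width (MGW, Å) and
propeller twist (ProT, °) for its central base pair, and Roll and helix
twist (HelT, °) for each of its two central base-pair steps.

Conventions, chosen here and applied uniformly:

* **Window arithmetic.** For a sequence of length *L* (0-based positions),
  MGW/ProT are defined at positions 2 … *L*−3; the outermost two positions
  on each side lack full context and are *missing* (NaN), never zero.
* **Step averaging.** The pentamer centred at *i* contributes its two
  central-step values to steps (*i*−1, *i*) and (*i*, *i*+1). Interior
  steps receive two contributions, which are averaged; the first and last
  *defined* steps receive one; the outermost step on each side receives
  none and is missing. The published pentamer model does not state how
  overlapping step contributions combine; averaging was chosen for
  continuity and because it makes the profile exactly reverse-complement
  consistent (verified by property test).
* **Strand symmetry.** The reverse complement of a pentamer carries the
  same MGW/ProT and the two step values in swapped order. Tables may be
  supplied in canonical-512 or raw-1024 form; the loader verifies
  completeness, positivity of MGW, and revcomp consistency, and
  mirror-fills an id-indexed array so prediction needs no run-time
  canonicalization.
* **Profiles.** A protein's shape profile is the unweighted per-position
  mean over its aligned sites, computed only over sites with a defined
  value at that position (site overhangs beyond the frame still provide
  pentamer context). Shape similarity between proteins is the negative
  absolute Euclidean distance between profile vectors, computed per
  parameter after dropping (pairwise, with a logged count) any position
  missing in at least one profile; missing flanks are never imputed in this
  comparison, to avoid fabricating structure.

## Motif frame

Bound 8-mers (E-score ≥ 0.45) are aligned to the degenerate core NNA(Y/K)N
(Y = C/T, K = G/T) scanning both strands; reverse-complement pairs collapse
to one lexicographic representative first, so the alignment is exactly
strand-symmetric. The frame is 8 columns wide with the consensus anchored
at columns 2–6 in the 1-based reporting convention (1–5 internally);
placements may overhang the frame, and overhanging bases are clipped for
PFM counting but retained as shape context.

When an 8-mer matches at several offsets/strands, disambiguation against a
previously published reference PFM (`reference_pfm=`) reproduces the
published behaviour. Without a reference, a self-contained two-pass scheme
is used *as a stand-in*: pass 1 places the unambiguous 8-mers and builds a
provisional PFM; pass 2 resolves ambiguous placements — and the Y-vs-K
variant, by placement count then mean per-column log-likelihood — against
it. Ties break deterministically toward the leftmost placement in the
canonical orientation. PFM log-likelihoods use a 0.01 pseudo-frequency and
are normalized per covered column so placements covering different numbers
of frame columns are comparable.

## Similarity and covariation statistics

* **Protein similarity** is the raw sum of BLOSUM45 scores over MSA
  columns, skipping columns where either row is gapped. No length
  normalization is applied: the downstream Pearson correlation is invariant
  to per-matrix scale, and raw sums are the most direct reading of a
  pairwise substitution-score comparison. Region windows (N-terminal tail
  = residues 1–9, recognition helix = 47–55, reference-row numbering)
  restrict the sum to the corresponding columns.
* **Matrix-level correlation** is the Pearson correlation of the strict
  upper triangles. Its significance is assessed two ways: a 1000-shuffle
  empirical null in which the label-to-sequence assignment is permuted
  (equivalently, the protein-similarity matrix is conjugated by the
  permutation — identical because BLOSUM pair scores depend only on the
  two sequences), reported as (r+1)/(n+1) to avoid zero p-values; and a
  binned control in which pairs are stratified by PFM-score bins
  (0–0.4, then 0.1-wide bins to 1.0) and an equal number sampled per bin.
  The published description of the binning is ambiguous about whether
  *sites* or *pairs* are subsampled; pairwise score entries are subsampled
  here, recorded as an interpretation.
* **Narrow minor groove calls** use a ≤ 5.12 Å threshold (inclusive) on
  each protein's *average* MGW profile — the same feature vector used for
  shape similarity — not on individual sites. 5.12 Å is a cohort-average
  convention; whether the underlying average is per-site or per-protein is
  not derivable, so the threshold is a free parameter with a 4.9–5.2 Å
  sensitivity list run by the pipeline.
* **Hypergeometric map.** For each (protein column, DNA position), the
  upper-tail cumulative hypergeometric P(K ≥ k) for the overlap between
  basic-residue carriers (R, K and H, which can be protonated) and
  narrow-groove proteins, over the proteins with a defined call at that
  position. Cells with no carrier or no narrow call are recorded as p = 1
  with a degenerate flag. Raw p-values are reported (as −log₁₀ p for
  heatmaps); a Benjamini–Hochberg overlay is available but off by default,
  matching the raw-heatmap convention of this analysis style.
* **MI map.** Mutual information (bits, plug-in frequencies, 0·log 0 ≡ 0)
  between the full residue alphabet (plus gap) at a column and the binary
  narrow/not-narrow call; an optional basic/non-basic binary mode exists
  for comparison. MI against a binary call is bounded by
  min(H(residue), 1) bit.
* **Residue-grouped MGW curves.** Proteins grouped by residue class (R, K,
  H, other) at a chosen column; per position, each basic class with ≥ 2
  members is compared to "other" by a two-sided Wilcoxon rank-sum test
  (exact for ≤ 10 per group without ties, normal approximation with tie
  correction otherwise), flagged at p < 5×10⁻⁵.

## Affinity regression

Each 8-mer is featurized on its placed frame: one-hot sequence indicators
per frame position, plus MGW/ProT per position and Roll/HelT per step
predicted on the placed, flank-extended sequence. Frame positions not
covered by the 8-mer are filled with a random nucleotide (sequence channel)
and the *table-average* value of the corresponding parameter (shape
channel), with extension flags recorded; the randomization happens once per
8-mer per run, so cross-validation variation comes from fold assignment
alone.

Models are ordinary least squares (minimum-norm solution; the one-hot block
plus intercept is singular by construction) with 10-fold cross-validation
repeated 50 times by default; every 8-mer is predicted exactly once per
repeat. **R² is the squared Pearson correlation between predicted and
observed E-scores**, not the regression coefficient of determination — the
two differ under cross-validation, and the squared-correlation convention
is the one this benchmark uses. Means and medians over repeats are both
reported (means are quoted by default). Variants: `seq`, `seq+shape`,
`seq+shuffled-shape` (shape rows permuted once per repeat; controls for the
added degrees of freedom), and per-parameter ablations `seq+mgw` etc.
Bound/unbound classification (E-score ≥ 0.45) is scored by midrank ROC AUC;
across-protein model comparisons use the two-sided Mann–Whitney U test.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
every random draw funnelled through one seed:

* **Shape table.** MGW = 5.8 − *a*·scale(p) + ε, where 5.8 Å is the B-DNA
  reference, *a* is the AT-narrowing coefficient (default 0.8 Å per unit
  scale), scale(p) = AT-fraction + 0.5·[all-AT], and ε ~ N(0, 0.1). The
  all-AT term gives A/T tracts the extra narrowing they show in real
  structural data; the closed-form mean (5.8 − 0.515625·*a*) is matched by
  the sampled table to < 0.01 Å. ProT trends more negative and Roll lower
  with AT content; HelT sits near 34–36°. Values are generated on
  canonical pentamers and mirrored, so revcomp consistency holds by
  construction.
* **Cohort.** A gapless 60-column MSA: a random consensus with 30%
  per-column background substitution, split half/half into carriers and
  non-carriers. Carriers carry the planted residue (arginine by default)
  at the tail column (residue 5); non-carriers never carry a basic residue
  there. "Subfamily signature" columns — the rest of the tail plus every
  fourth column across the domain — separate the groups imperfectly (85%
  fidelity) using non-basic residue pairs, mirroring how real TF
  subfamilies differ throughout the domain; these columns give the
  protein-similarity matrix the block structure that real homeodomain
  cohorts show (matrix-level correlations of ~0.3–0.6 against the
  DNA-channel similarities), while staying invisible to the
  basic-residue-specific hypergeometric statistic.
* **E-scores.** Every revcomp-unique 8-mer (32,896) receives a latent
  affinity: the best placement score over both strands and all offsets
  (strong A/Y core weights, weak protein-specific flank preferences) plus,
  for carriers, a shape term λ·(5.8 − mean MGW at the affected positions)
  with λ = shape_effect_weight·|mgw_shift|/0.5, minus half that weight
  applied to narrowing at the *other* positions (`shape_localization`) —
  a residue contacting the minor groove prefers narrow geometry at its
  contact positions specifically, not AT tracts everywhere — plus
  N(0, 0.25) noise. Latents are rank-transformed to the PBM scale
  via E = −0.5 + u⁵ (u = normalized rank): E-scores are rank statistics,
  and the convex transform concentrates ~1% of 8-mers above the 0.45
  threshold (≈336 per protein, within the realistic few-hundred range).
  The default shape_effect_weight (8.0) is set from the generative
  geometry: the reward per AT base (≈ λ·0.16 Å) must exceed the ±1 flank
  preference weights for carriers' selected sites to narrow coherently by
  ≈ |mgw_shift|. The shape effect flows only through the pentamer table —
  the table itself is never edited — keeping sequence and shape channels
  separable for ablations. With mgw_shift = 0 and shape_effect_weight = 0
  the cohort is an exact null.

**What the generator does not emulate:** probe-level PBM intensities and
their replicate structure, phylogenetic non-independence of the proteins,
residue–residue interdependencies within the domain, indels (the synthetic
MSA is gapless), and binding modes without a single degenerate core. A
passing recovery test therefore shows that the statistics detect the
modelled kind of covariation at realistic effect sizes and cohort sizes —
not that real cohorts are free of the confounders above.

## Problem sizes and runtime choices

The test suite and the acceptance script run the full 60-protein cohort for
recovery (1000-shuffle nulls), 20 null cohorts for type-I control, and the
regression comparison at a reduced scale — 1024 8-mers with 10 CV repeats —
which preserves the fold structure and the variant ordering while keeping a
single-CPU run in minutes. The pipeline's affinity stage likewise defaults
to a 2000-8-mer subsample (all bound 8-mers are always retained) and is
opt-in; `fit_cv` itself implements the full 50-repeat scheme.

## Known limitations

* The two-pass placement scheme is a deterministic stand-in for
  disambiguation against published PFMs; with multi-modal binding data the
  provisional PFM can lock in a suboptimal register.
* Plug-in MI is biased upward for small cohorts and large alphabets; maps
  are meant for ranking within a cohort, not as unbiased information
  estimates.
* Hypergeometric and MI maps treat protein columns independently;
  interdependent columns can both appear associated with the same DNA
  position.
* The narrow/not-narrow discretization discards within-class MGW variation;
  the 4.9–5.2 Å sensitivity list is the supported robustness check.
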