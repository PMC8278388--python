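# Methods

## The search problem and the two-step surrogate design

The target property is the aggregation propensity AP = SASA(t=0)/SASA(t=end),
a dimensionless surface-burial ratio measured from a coarse-grained MD
simulation of ~300 copies of one peptide in water. Labelling one peptide is
expensive; the space of candidates is 20^L. The package therefore separates
*coverage* from *resolution*: a descriptor set cheap enough to compute for
every sequence (pure table lookup, no molecular structures) feeds a first
surrogate that ranks the whole space, and a richer descriptor set is computed
only for that model's top N, where a second surrogate re-ranks before the
oracle labels the top batch. The pre-screen deliberately passes far more
candidates than will be labelled (default N(L) = min(20^L, 1000·L)) so that a
ranking error by the cheap model rarely costs a good candidate. Both
surrogates are retrained from scratch each iteration on the one shared label
set; retraining on ≤ a few hundred rows costs milliseconds, and from-scratch
fits keep runs exactly reproducible from (config, seed).

Both steps use the same learner: ε-SVR with an RBF kernel on standardised
features (scaler fitted on training rows only). Defaults C = 10,
gamma = "scale", ε = 0.01 — sensible SVR settings at AP scale (labels span
~0.9–2.6, so ε = 0.01 is well under label noise); `models.tune()` re-derives
hyperparameters by seeded 5-fold CV grid search (ties broken toward smaller
C, then larger ε, i.e. the flattest model) when a run wants its own. One
hyperparameter block serves both steps.

## Judred descriptors

All ten descriptors are per-residue table lookups aggregated over the chain;
the packaged `residue_properties.csv` carries the values and their
provenance. Conventions that the table (not the code) decides:

- **sp2 carbons** include one backbone carbonyl carbon per residue (the amide
  carbon is sp2 in every residue) plus side-chain sp2 carbons; **sp3
  carbons** include the backbone α-carbon, so the RotRatio denominator is
  ≥ 1 per residue and the ratio is finite even for polyglycine.
- **NH2** counts side-chain NH2/NH3: K = 1, R = 2 (guanidinium), N = Q = 1
  (amide); ring NH (W, H) is not an NH2.
- **Z** is side-chain charge at pH 7 (K/R = +1, D/E = −1, H = 0, pKa ≈ 6);
  peptides are zwitterions, the terminal charges cancel.
- **MW** uses average free-amino-acid masses minus 18.015 g/mol per peptide
  bond.
- **logP_WW** sums the Wimley–White water→octanol whole-residue transfer free
  energies, converted to log-units via −ΔG/(2.303 RT) at 298.15 K, so
  positive = hydrophobic and the solubility curation "remove log P > 0" reads
  naturally. Whether the original peptide log P normalises per residue is
  not determinable here; a plain sum is used — under any monotone
  transformation only filter thresholds would shift.
- **MaxASA** uses the theoretical maxima of Tien et al. (2013); **Bulkiness**
  the Zimmerman (1968) scale.

Restriction filters are conjunctions of strict/inclusive bounds on these ten
fields, applied while streaming the space; the first random batch is drawn
from the restricted space (the curation is defined as a property of the
data set, not of the model step).

## High-resolution step and feature elimination

The default second-step provider stays structure-free so the package runs
without a cheminformatics stack: 10 Judred values + 20 residue-composition
counts + 9 positional features (Wimley–White, bulkiness, max ASA and charge
of the first and of the last residue, plus the aromatic residue count).
Composition and terminal features resolve sequence permutations that
whole-chain sums cannot — which is the resolution the second step is for. An
external provider (e.g. a full molecular-descriptor calculator over
structures) plugs into the same `row()` contract; blocks refuse to mix
providers between train and predict.

Large external feature sets are pruned by cross-validated recursive feature
elimination: per round, a ridge surrogate is fitted per CV fold on the
standardised surviving features and features are ranked by mean |coefficient|
across folds; the lowest-ranked one (configurable block size) is dropped
until `n_target` remain. RBF machines expose no per-feature weights, so a
linear surrogate supplies the ranking — the standard RFE construction, and a
documented divergence risk if the original selection used something else.

## The synthetic oracle

The generator stands in for CGMD and is built to reproduce the *structure*
of real AP data, not its values:

- **Landscape.** Each residue has a propensity weight (F 1.05, W 1.00,
  Y 0.95, then branched hydrophobics ~0.5 down to D/E −0.5). The
  position-weighted mean s (terminal residues over-weighted: ×1.20 at the
  N-terminus, ×1.10 at the C-terminus, so permutations score differently, as
  they do in real screens where WFF/FWF/FFW are distinct top performers) is
  squashed through a logistic onto [0.9, ceiling(L)]. The midpoint (0.70)
  sits deep in the aromatic-rich region against a whole-space mean s ≈ 0.22,
  making the AP distribution strongly right-skewed: the bulk of the space
  rests near the floor and a sparse aromatic tail climbs to ~2.4 — the
  shape real tripeptide AP distributions show, and the reason an
  active-learning run can find peptides above the maximum of an 800-peptide
  random sample.
- **Range narrowing.** ceiling(3) = 2.6; for L > 3 the span contracts as
  (3/L)^0.8, so sampled AP ranges narrow from tri- to hexapeptides, as the
  elastic-network treatment of longer chains produces in real CGMD.
- **Replicate noise.** Gaussian with σ = min(0.10 · max(0, AP − 1), 0.119):
  zero for non-aggregators, growing with AP, capped strictly below 0.12.
  The cap bounds the *model* σ; a finite-sample standard deviation of
  replicates fluctuates around σ with sd ≈ σ/√(2(n−1)), so empirical checks
  compare sample stds to σ at that tolerance rather than asserting a hard
  ceiling on a random quantity. Only a distribution family had to be chosen;
  Gaussian is the least-structured choice given only a bound and a trend.
- **Determinism.** A measurement is a pure function of (sequence, config
  seed, replicate seed) via SHA-256-derived RNG streams; SASA endpoints are
  synthesised so AP·SASA_final = SASA_initial holds exactly.

What the generator does **not** emulate: real CGMD force-field artefacts,
concentration effects, the correlation structure of real descriptor sets,
or absolute AP values for specific sequences. Tests passing against it show
the *algorithm* behaves as designed (budget accounting, convergence,
efficiency over random screening on a landscape with realistic shape); they
are not evidence about any particular real peptide.

## Benchmark protocol and problem sizes

The discovery benchmark (`fixtures.al_screening_experiment`) pairs, per
seed: a 15-iteration × 10-label run (151 labels including the seed
homopolymer) against a one-shot screening baseline spending the same total
budget (141 random training labels + its predicted top 10), both on the full
8000-member tripeptide space. Honest accounting counts screening's training
labels — they are unavoidable oracle calls, and omitting them flatters
screening. Discovery curves measure the fraction of the brute-force true
top-20 (noise-free evaluation of all 8000) recovered per label spent,
against a uniformly random labelling order. 20 paired seeds; win counts are
reported rather than means because per-seed variation is large by design
(the first batch is random). These sizes — tripeptides, 20 seeds, 15
iterations — keep the full benchmark around a minute on one CPU while the
8000-member space is still ~50× the labelling budget, the regime the method
exists for; hexapeptide-scale runs use the seeded `subspace_sample` mode,
mirroring the use of random subsets to characterise large spaces.

A note on trend diagnostics at this scale: after the loop converges it
drains the sparse top of an 8000-member space (150–300 labels is 2–4% of
it), so late-iteration mean AP declines and a whole-run least-squares slope
is sign-ambiguous. Self-improvement is therefore checked over the climb
phase (slope over the first ~8 iterations, and model-driven iterations
beating the random first batch); upward trends over 30–100 iterations are a
large-space phenomenon where drain is negligible.

## Numerical and design choices

- Ranking ties (predicted AP) break lexicographically by sequence:
  deterministic and audit-friendly.
- The seed homopolymer's label is one oracle call outside the per-iteration
  budget; a restriction that excludes the seed simply starts the run with an
  empty label set and two random batches.
- Step-2 training uses the high-resolution block of labelled peptides only
  (it does not pool raw Judred rows); step-1 and step-2 models never share
  feature blocks, enforced by feature-name contracts.
- The exploration variant (`top1-plus-weighted-random`) keeps the argmax and
  samples the rest of the batch without replacement with probability
  proportional to predicted AP (clipped at zero).
- R², MCC and AUC are flagged `None` (never NaN) when undefined
  (zero-variance truth, one-class truth). AUC ranks raw predictions against
  the thresholded truth (standard ROC); only MCC thresholds predictions.
- Stopping criteria compose with OR semantics.
- Model archives are JSON (scaler parameters + support vectors + dual
  coefficients) with an archive version; loading a mismatched version is
  refused rather than guessed at.

## Known limitations

- No MD code ships; the external oracle is a file-exchange contract only.
- The built-in high-resolution provider, while strictly more resolving than
  the pre-screen set, is far poorer than a real 1000+-descriptor calculator;
  with it, step 2's advantage over step 1 is modest on the synthetic
  landscape.
- Chain lengths are capped at 8; non-canonical residues, cyclic peptides and
  capped termini are out of scope.
- `prescreen_size`'s default length-dependent policy is a documented
  package choice; runs record the policy used so results remain
  interpretable if it is swapped.
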