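# Methods

## Decision model

Each base classifier outputs a two-class softmax, stored as a single
probability-of-animal p (p_empty = 1 − p). A confidence threshold
δ ∈ [0.5, 1] converts p into a ternary decision: animal if p ≥ δ, empty if
1 − p ≥ δ, uncertain otherwise. Conventions:

- The comparison is inclusive: a probability exactly at δ is confident.
- δ < 0.5 is rejected — both classes could pass at once.
- At δ = 0.5 and p = 0.5 exactly, both class conditions hold; the animal
  branch wins. This is the conservative direction (an ambiguous image is
  kept, never auto-removed) and only matters on a measure-zero input.

The first-level ensemble is strict unanimity over the three models trained
on one training set: any internal disagreement, or any member abstention,
makes the ensemble abstain. The second level combines the two first-level
ensembles AIR_1 (imbalanced-trained trio) and AIR_2 (balanced-trained trio):

| AIR_1 | AIR_2 | enhanced ("and") | complementary ("or") |
|-------|-------|------------------|----------------------|
| 0     | 0     | 0                | 0                    |
| 0     | 1     | x                | 1                    |
| 0     | x     | x                | 0                    |
| 1     | 1     | 1                | 1                    |
| 1     | x     | x                | 1                    |
| x     | x     | x                | x                    |

(symmetric in its two arguments). A certain conflict (0 vs 1) resolving to
1 under the complementary rule is the defining conservative choice: a
contested image is never auto-removed.

Scheme IV resolves the complementary rule's residual by an unthresholded
majority vote of all six models (each votes by argmax). A 3–3 tie returns
animal, again the conservative direction; no tie rule is implied by the
two-level construction itself, so this is a package convention.

Which three probability columns form AIR_1 vs AIR_2 is explicit caller
input (default: manifest column order, first three = group 1). A manifest
cannot verify which training set produced a column, so the assignment is
the caller's statement of fact.

## Evaluation conventions

Confusion counts are tabulated over covered items only; abstentions are
tallied separately (`n_uncertain`). The exception is N_e in
R_re = TN / N_e: it counts every truly empty item in the evaluated set,
covered or not, because R_re measures saved manual-deletion workload over
the whole set. Any metric whose denominator is zero is reported as
undefined (None in memory, NA in CSV) — a scheme that covered nothing has
no error rate, and rendering it as 0 would fake perfection.

Event-level evaluation collapses each capture event before tabulation. An
event is truly empty iff all member images are empty. The decision rule
mirrors this: any animal-decided image makes the event animal; the event is
decided empty only when *every* image was decided empty; otherwise the
event is uncertain (some images undecided, none claiming an animal — the
event cannot be safely deleted). Event coverage counts non-uncertain event
decisions; an event whose images are partly certain but whose aggregate is
uncertain counts as not covered.

Threshold sweeps recompute decisions from the raw probabilities at every δ;
no thresholded intermediate is cached or reused across δ values.

A note on a tempting but false shortcut: at δ = 0.5 no base model abstains,
yet the complementary rule can still abstain — on images where both trios
disagree internally, both first-level ensembles emit x. Full coverage at
δ = 0.5 is guaranteed only for scheme IV.

## Data splitting

Train/test splitting samples capture events, not images, uniformly without
replacement from a seeded generator; the frames of one burst are
near-duplicates and must not straddle the split. Balanced-set construction
keeps every animal image and adds an equal-count seeded uniform sample of
empty images, at image level (not event level): the balanced set exists to
equalize class counts seen by a trainer, and image-level sampling
reproduces that arithmetic exactly. Both operations require explicit seeds;
reproducibility is a contract, not an option.

Manifests are plain CSV. Probabilities outside [0, 1], non-numeric cells,
duplicate image ids and species tags on empty images are hard validation
errors — silent imputation could corrupt a conservative decision chain.
Reading uses round-trip float parsing so write→read is bit-exact.

## Synthetic score generator

The generator emulates the *statistical shape* of classifier outputs on a
camera-trap test set, not any particular dataset:

- **Event structure.** Events are drawn first: empty with probability
  `empty_event_fraction` (default 0.76, matching the roughly
  three-quarters-empty composition typical of forest camera-trap surveys),
  holding `images_per_event` images (default a constant 3, the usual burst
  length; an integer distribution is accepted). Within an animal event each
  image is an animal image with probability 0.9 by default, with at least
  one forced — an animal event with no animal frame would contradict its
  definition.
- **Correctness.** Each image carries a latent difficulty u ~ Uniform(0, 1)
  shared by all models. A model with class-conditional accuracy `acc` is
  correct with probability `clip(1 − (1 − acc)·(1 + c·(2u − 1)), 0, 1)`,
  where c is the `correlation` weight. The multiplier has mean one, so the
  marginal accuracy equals `acc` for every c (exactly, absent clamping),
  c = 0 gives independent errors, and c = 1 doubles the error rate on the
  hardest images while zeroing it on the easiest. An earlier additive
  formulation (acc shifted by c·difficulty) was rejected because it made a
  perfect model err whenever c > 0; difficulty should scale error, not
  override competence.
- **Confidence.** The probability assigned to the *predicted* class is
  0.5 + 0.5·b with b ~ Beta(a, β), using the `confidence_when_correct`
  pair when the model is right and `confidence_when_wrong` otherwise. The
  affine map keeps argmax consistent with the drawn prediction. Defaults
  (18, 0.8) / (3, 1.5) emulate overconfident softmax outputs: a correct
  prediction clears δ = 0.95 about 89% of the time, a wrong one about 12%,
  so a 95% threshold retains a realistic share of images.
- **Preset.** `asymmetric_group_preset()` configures six models: group 1
  (A1/I1/R1) with higher accuracy on empty than on animal images —
  classifiers trained on empty-dominated data lean toward the majority
  class — and group 2 (A2/I2/R2) with the reverse profile, plus moderate
  correlation (0.4) and a small weighted species pool.

What the generator does **not** emulate: within-event correlation of
decisions (difficulty is per image, so near-duplicate frames of one burst
do not share errors as real frames do — synthetic event-level removal rates
run lower, relative to image-level ones, than on real bursts);
day/night or site heterogeneity; species-dependent difficulty; and any
distributional match to a specific dataset's score histograms. Passing
tests therefore demonstrate the correctness and the structural properties
of the decision rules and metrics (conservatism orderings, coverage
monotonicity, calibration), not field performance of any particular model
stack.

## Problem sizes and numerical choices

- Property tests run on manifests of roughly 300–1,000 images; the
  conservatism sweep uses 100 generator draws of ~1,000 images, and
  calibration checks use 10^4–3·10^4 images, where a 3-standard-error
  binomial band is tight enough to detect miscalibration while keeping the
  familywise false-alarm rate of twelve simultaneous checks small.
- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; identical config + seed is bit-identical output, including
  CSV bytes.
- Degenerate inputs: empty manifests round-trip as header-only CSV;
  coverage of zero decisions, events with zero images, and metrics with
  zero denominators raise or report undefined rather than guessing.

## Known limitations

- The package consumes probabilities as given; no calibration or
  temperature scaling is applied or estimated.
- Species tags are carried through manifests and decisions but no
  species-frequency analysis is provided; downstream tools can join the
  uncertain/removed lists back to species labels.
- Metrics come without confidence intervals; on small covered sets the
  error rates are coarse.
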