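# trapsift

Conservative ensemble filtering of empty camera-trap images.

Camera traps fire on any motion, so most frames contain no animal — in
typical forest surveys three quarters or more of all images are empty.
Classifiers can screen them out automatically, but a model trained on a
small labeled set will also mis-label some animal images as empty, and every
such *omission* is a lost species observation. `trapsift` implements a
filtering framework for exactly this regime: it trades coverage for safety,
auto-removing only images that several independently trained classifiers
confidently agree are empty, and routing everything else to manual review.

It is aimed at ecologists and ML practitioners who already have per-image
classifier scores (from any architectures) and want a principled, reproducible
way to turn them into keep / remove / review decisions and to quantify the
omission-error vs. workload trade-off.

## The method

Inputs are per-image probabilities of "animal" from six base classifiers:
three architectures trained on the raw, empty-dominated training set
(group 1) and the same three trained on a class-balanced set (group 2).

1. **Confidence threshold with abstention.** With threshold δ ∈ [0.5, 1],
   each model's output becomes ternary: animal (1) if p ≥ δ, empty (0) if
   1 − p ≥ δ, otherwise uncertain (x). δ = 0.5 never abstains.
2. **First-level unanimity ensemble.** Each trained trio is combined into
   an ensemble AIR_i that emits a certain label only when all three members
   agree on it; any disagreement or abstention yields x.
3. **Second-level combination.** The two first-level ensembles are combined
   by the *enhanced* rule (scheme I, "AIR_1 and AIR_2": both must agree —
   smallest omission error) or the *complementary* rule (scheme III,
   "AIR_1 or AIR_2": either may decide, certain conflicts resolve to
   animal — largest coverage). Scheme II uses AIR_2 alone. Scheme IV runs
   scheme III and then settles every remaining uncertain image by an
   unthresholded majority vote of all six models (ties go to animal), so
   nothing is left for manual review.

Decisions are scored with animal as the positive class, over the covered
(non-abstained) items:

- omission error of animal images `E_oa = FN / (FN + TP)` (= 1 − recall)
- commission error of empty images `E_ce = FN / (FN + TN)`
- removal rate of empty images `R_re = TN / N_e` (N_e = all empty items,
  abstentions included)
- overall error `E_ov = (FN + FP) / (TP + TN + FN + FP)`
- commission error of animal images `E_ca = FP / (TP + FP)` (= 1 − precision)

plus coverage, the share of items given a certain decision. Evaluation
works at image level or at capture-event level, where an event (the burst
of ~3 frames from one trigger) is truly empty only if all its images are,
and is decided empty only if every image was decided empty.

A synthetic score generator produces manifests with ground truth, realistic
class imbalance, event structure, per-model accuracy/confidence profiles and
correlated errors, so the whole pipeline is testable without trained
networks or image data. Train/test splitting is event-grouped (never
splitting a burst across sets), with balanced-set construction built in.

## Worked example

```python
from trapsift import (asymmetric_group_preset, generate, evaluate,
                      SchemeId, ThresholdPolicy)

manifest = generate(asymmetric_group_preset(n_events=2000, seed=7))
policy = ThresholdPolicy(0.95)
for s in SchemeId:
    r, c = evaluate(manifest, s, policy, level="image")
    print(s.value, f"coverage={100*r.coverage:.2f}%",
          f"E_oa={100*r.e_oa:.2f}%", f"R_re={100*r.r_re:.2f}%")
```

Output (6,000 images, 4,711 of them empty):

```
scheme  coverage   E_oa   E_ce   R_re
I          27.23   0.00   0.00  28.04
II         48.05   0.00   0.00  44.89
III        78.30   0.00   0.00  79.03
IV        100.00   0.31   0.09  99.00
```

Read this as the coverage/safety ladder: scheme I decides only 27% of the
images but removed 28% of the empty ones without a single animal image lost;
scheme III removes 79% of the empties, still error-free here; scheme IV
decides everything and removes 99% of the empties at the price of omitting
0.31% of the covered animal images (E_ce = 0.09% means roughly one in a
thousand auto-removed images actually contained an animal).

The same pipeline from the shell:

```bash
trapsift simulate --output manifest.csv --n-events 2000 --seed 7
trapsift run      --input manifest.csv --output decisions.csv --scheme III --delta 0.95
trapsift evaluate --input manifest.csv --output report.csv   --scheme III --level event
trapsift sweep    --input manifest.csv --output sweep.csv    --deltas 0.5,0.9,0.95,0.9725
```

`decisions.csv` encodes decisions as 0 (empty), 1 (animal), x (uncertain —
send to manual review); reports carry counts, proportions and two-decimal
percentage renderings.

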