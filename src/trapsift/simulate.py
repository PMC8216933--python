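"""Synthetic classifier-score generator.

Produces prediction manifests with ground truth and six correlated model
probability columns, so every decision rule and metric in the package can be
exercised without trained networks or camera-trap images.

The generative model, per image:

1. Capture events are drawn first.  Each event is empty with probability
   ``empty_event_fraction`` and holds ``images_per_event`` images (a constant
   or a small integer distribution).  Inside an animal event each image is an
   animal image with probability ``p_animal_image_within_animal_event``, with
   at least one animal image forced — an animal event with no animal frame
   would contradict its own definition.
2. Each image gets a latent difficulty u ~ Uniform(0, 1) shared by all
   models.  The difficulty scales each model's *error rate*: model m is
   correct on the image with probability

       clip(1 - (1 - acc_c) * (1 + correlation * (2u - 1)), 0, 1),

   where acc_c is the model's configured class-conditional accuracy for the
   image's true class.  The multiplier averages to 1 over u, so the marginal
   accuracy stays at acc_c for any correlation (exactly, absent clamping),
   and a model configured with accuracy 1.0 is correct on every image no
   matter how hard.  With correlation 0 the models err independently; with
   correlation near 1 hard images (large u) concentrate the errors of all
   models on the same frames, which is what makes unanimity ensembles
   behave non-trivially.
3. The model's confidence in its predicted class is 0.5 + 0.5 * b with
   b ~ Beta(shape pair), using the ``confidence_when_correct`` pair when the
   model is right and ``confidence_when_wrong`` pair when it is wrong.  The
   affine map keeps the reported probability consistent with the predicted
   class (argmax never contradicts the draw).  The probability-of-animal
   written to the manifest is the confidence when the predicted class is
   animal and 1 - confidence otherwise.
4. Animal images optionally receive a species tag sampled from a weighted
   pool.

Correctness and confidence are modeled separately (rather than through a
latent logit) so tests can dial error rates and coverage independently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .manifest import Label, PredictionManifest

__all__ = ["ModelProfile", "SyntheticConfig", "generate", "asymmetric_group_preset"]


class ModelProfile(BaseModel):
    """Error and confidence behaviour of one simulated classifier."""

    accuracy_on_empty: float = Field(ge=0.0, le=1.0)
    accuracy_on_animal: float = Field(ge=0.0, le=1.0)
    # Defaults emulate overconfident softmax outputs: a correct prediction
    # clears a 0.95 confidence bar ~89% of the time, a wrong one ~12%.
    confidence_when_correct: Tuple[float, float] = (18.0, 0.8)
    confidence_when_wrong: Tuple[float, float] = (3.0, 1.5)

    @field_validator("confidence_when_correct", "confidence_when_wrong")
    @classmethod
    def _positive_shapes(cls, v: Tuple[float, float]) -> Tuple[float, float]:
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError(f"Beta shape parameters must be positive, got {v}")
        return v


class SyntheticConfig(BaseModel):
    """All generator knobs; defaults echo a typical camera-trap dataset shape
    (about three quarters of events empty, three images per trigger)."""

    n_events: int = Field(default=1000, ge=1)
    images_per_event: Union[int, Dict[int, float]] = 3
    empty_event_fraction: float = Field(default=0.76, ge=0.0, le=1.0)
    p_animal_image_within_animal_event: float = Field(default=0.9, ge=0.0, le=1.0)
    model_profiles: Dict[str, ModelProfile]
    correlation: float = Field(default=0.4, ge=0.0, le=1.0)
    species_pool: Optional[Dict[str, float]] = None
    seed: int = 0

    @field_validator("images_per_event")
    @classmethod
    def _valid_counts(cls, v):
        if isinstance(v, int):
            if v < 1:
                raise ValueError("images_per_event must be >= 1")
            return v
        if not v:
            raise ValueError("images_per_event distribution is empty")
        if any(k < 1 for k in v) or any(w < 0 for w in v.values()):
            raise ValueError("images_per_event counts must be >= 1 with weights >= 0")
        if sum(v.values()) <= 0:
            raise ValueError("images_per_event weights must sum to > 0")
        return v

    @model_validator(mode="after")
    def _nonempty_models(self) -> "SyntheticConfig":
        if not self.model_profiles:
            raise ValueError("model_profiles must name at least one model")
        if self.species_pool is not None:
            if not self.species_pool or any(w < 0 for w in self.species_pool.values()):
                raise ValueError("species_pool weights must be non-negative, not all zero")
            if sum(self.species_pool.values()) <= 0:
                raise ValueError("species_pool weights must sum to > 0")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def _image_counts(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    ipe = config.images_per_event
    if isinstance(ipe, int):
        return np.full(config.n_events, ipe, dtype=int)
    counts = np.array(sorted(ipe), dtype=int)
    weights = np.array([ipe[int(k)] for k in counts], dtype=float)
    weights /= weights.sum()
    return rng.choice(counts, size=config.n_events, p=weights)


def generate(config: SyntheticConfig) -> PredictionManifest:
    """Draw one manifest from the generative model; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    model_ids = list(config.model_profiles)

    event_empty = rng.random(config.n_events) < config.empty_event_fraction
    counts = _image_counts(config, rng)
    n_images = int(counts.sum())
    event_index = np.repeat(np.arange(config.n_events), counts)
    image_in_animal_event = ~event_empty[event_index]

    # image truths: empty events are all empty; animal events draw per image
    # with >= 1 animal forced (uniformly chosen position when none drawn)
    truth_animal = np.zeros(n_images, dtype=bool)
    draw = rng.random(n_images) < config.p_animal_image_within_animal_event
    truth_animal[image_in_animal_event] = draw[image_in_animal_event]
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    for ev in np.flatnonzero(~event_empty):
        lo, hi = starts[ev], starts[ev] + counts[ev]
        if not truth_animal[lo:hi].any():
            truth_animal[rng.integers(lo, hi)] = True

    difficulty = rng.random(n_images)
    # mean-one multiplier on the error rate; see module docstring
    error_scale = 1.0 + config.correlation * (2.0 * difficulty - 1.0)

    data: dict[str, np.ndarray | list] = {
        "image_id": [f"img{i:07d}" for i in range(n_images)],
        "event_id": [f"ev{e:06d}" for e in event_index],
        "truth": np.where(truth_animal, Label.ANIMAL.value, Label.EMPTY.value),
    }

    if config.species_pool is not None:
        names = list(config.species_pool)
        weights = np.array([config.species_pool[n] for n in names], dtype=float)
        weights /= weights.sum()
        species = np.full(n_images, None, dtype=object)
        n_animal = int(truth_animal.sum())
        if n_animal:
            species[truth_animal] = rng.choice(
                np.array(names, dtype=object), size=n_animal, p=weights
            )
        data["species"] = species

    for model_id in model_ids:
        profile = config.model_profiles[model_id]
        acc = np.where(
            truth_animal, profile.accuracy_on_animal, profile.accuracy_on_empty
        )
        p_correct = np.clip(1.0 - (1.0 - acc) * error_scale, 0.0, 1.0)
        correct = rng.random(n_images) < p_correct
        pred_animal = np.where(correct, truth_animal, ~truth_animal)
        conf = np.where(
            correct,
            rng.beta(*profile.confidence_when_correct, size=n_images),
            rng.beta(*profile.confidence_when_wrong, size=n_images),
        )
        conf = 0.5 + 0.5 * conf
        data[model_id] = np.where(pred_animal, conf, 1.0 - conf)

    frame = pd.DataFrame(data)
    # column order: ids, truth, species, then models
    cols = ["image_id", "event_id", "truth"]
    if "species" in frame.columns:
        cols.append("species")
    return PredictionManifest(frame[cols + model_ids], model_ids)


def asymmetric_group_preset(n_events: int = 1000, seed: int = 0) -> SyntheticConfig:
    """Default six-model configuration with asymmetric group error profiles.

    Models A1/I1/R1 emulate classifiers trained on the raw, empty-dominated
    data: they lean toward the majority class, so their accuracy on empty
    images is high and their accuracy on animal images lower.  Models
    A2/I2/R2 emulate classifiers trained on a class-balanced set and show
    the reverse profile.  Moderate correlation (0.4) makes models share hard
    images, as real architectures trained on the same frames do.
    """
    group1 = {
        "A1": ModelProfile(accuracy_on_empty=0.96, accuracy_on_animal=0.82),
        "I1": ModelProfile(accuracy_on_empty=0.97, accuracy_on_animal=0.86),
        "R1": ModelProfile(accuracy_on_empty=0.94, accuracy_on_animal=0.80),
    }
    group2 = {
        "A2": ModelProfile(accuracy_on_empty=0.85, accuracy_on_animal=0.94),
        "I2": ModelProfile(accuracy_on_empty=0.88, accuracy_on_animal=0.96),
        "R2": ModelProfile(accuracy_on_empty=0.83, accuracy_on_animal=0.92),
    }
    return SyntheticConfig(
        n_events=n_events,
        images_per_event=3,
        empty_event_fraction=0.76,
        p_animal_image_within_animal_event=0.9,
        model_profiles={**group1, **group2},
        correlation=0.4,
        species_pool={"muntjac": 5.0, "macaque": 3.0, "pheasant": 1.5, "civet": 0.5},
        seed=seed,
    )
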