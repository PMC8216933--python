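"""Prediction manifests: the tabular contract between classifiers and the filter.

A manifest holds one row per camera-trap image with its capture-event
identifier, optional ground truth (empty/animal) and species tag, and one
probability-of-animal column per base classifier.  All downstream decision
rules and metrics consume this table; no image data is ever touched.

Capture events are the unit of data splitting: images from one trigger are
near-duplicates, so leaking an event across a train/test boundary inflates
test performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Label",
    "ImageRecord",
    "PredictionManifest",
    "ManifestValidationError",
    "read_manifest",
    "write_manifest",
    "split_by_events",
    "balance_training_set",
]

_ID_COLUMNS = ("image_id", "event_id", "site_id")
_TRUTH_ALIASES = {"empty": "empty", "animal": "animal", "0": "empty", "1": "animal"}


class ManifestValidationError(ValueError):
    """A manifest violates its contract (bad probability, duplicate id, ...)."""


class Label(str, Enum):
    """Binary ground-truth label of an image or capture event."""

    EMPTY = "empty"
    ANIMAL = "animal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ImageRecord:
    """One image row: identifiers, optional truth/species, per-model scores."""

    image_id: str
    event_id: str
    probs: Mapping[str, float]
    site_id: Optional[str] = None
    truth: Optional[Label] = None
    species: Optional[str] = None


@dataclass
class PredictionManifest:
    """Per-image classifier scores with capture-event grouping.

    Parameters
    ----------
    frame
        One row per image.  Required columns: ``image_id``, ``event_id`` and
        one float column per entry of `model_ids` holding the probability
        that the image contains an animal.  Optional columns: ``site_id``,
        ``truth`` (``empty``/``animal``), ``species``.
    model_ids
        Ordered classifier identifiers, e.g. ``["A1", "I1", "R1", "A2",
        "I2", "R2"]`` for three architectures trained on two training sets.
    """

    frame: pd.DataFrame
    model_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.model_ids = list(self.model_ids)
        self.frame = self.frame.reset_index(drop=True)
        self._validate()

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        df = self.frame
        for col in ("image_id", "event_id"):
            if col not in df.columns:
                raise ManifestValidationError(f"missing required column {col!r}")
            if df[col].isna().any():
                row = int(df.index[df[col].isna()][0])
                raise ManifestValidationError(f"missing {col} in row {row}")
        dup = df["image_id"].duplicated()
        if dup.any():
            raise ManifestValidationError(
                f"duplicate image_id {df['image_id'][dup].iloc[0]!r}"
            )
        for model in self.model_ids:
            if model not in df.columns:
                raise ManifestValidationError(f"missing probability column {model!r}")
            probs = pd.to_numeric(df[model], errors="coerce")
            bad = probs.isna() | (probs < 0.0) | (probs > 1.0)
            if bad.any():
                row = int(df.index[bad][0])
                raise ManifestValidationError(
                    f"malformed probability in column {model!r}, row {row}: "
                    f"{df[model].iloc[row]!r} (must be a number in [0, 1])"
                )
            self.frame[model] = probs.astype(float)
        if self.has_truth:
            truth = df["truth"].dropna()
            bad_vals = set(truth.unique()) - {Label.EMPTY.value, Label.ANIMAL.value}
            if bad_vals:
                raise ManifestValidationError(f"unrecognized truth labels {bad_vals}")
            if "species" in df.columns:
                on_empty = (df["truth"] == Label.EMPTY.value) & df["species"].notna()
                if on_empty.any():
                    row = int(df.index[on_empty][0])
                    raise ManifestValidationError(
                        f"species tag on an empty image in row {row}"
                    )

    # -- convenience ---------------------------------------------------

    @property
    def has_truth(self) -> bool:
        return "truth" in self.frame.columns

    @property
    def n_images(self) -> int:
        return len(self.frame)

    @property
    def event_ids(self) -> list[str]:
        """Distinct event identifiers in first-appearance order."""
        return list(pd.unique(self.frame["event_id"]))

    def truths(self) -> dict[str, Label]:
        """image_id -> truth label; raises if any truth is missing."""
        if "truth" not in self.frame.columns or self.frame["truth"].isna().any():
            raise ManifestValidationError("manifest has missing truth labels")
        return {
            img: Label(t)
            for img, t in zip(self.frame["image_id"], self.frame["truth"])
        }

    def class_counts(self) -> tuple[int, int, int]:
        """(total, empty, animal) image counts; requires truth labels."""
        truths = self.truths()
        n_empty = sum(1 for t in truths.values() if t is Label.EMPTY)
        return len(truths), n_empty, len(truths) - n_empty

    def records(self) -> Iterator[ImageRecord]:
        for _, row in self.frame.iterrows():
            truth = row.get("truth")
            species = row.get("species")
            site = row.get("site_id")
            yield ImageRecord(
                image_id=row["image_id"],
                event_id=row["event_id"],
                probs={m: float(row[m]) for m in self.model_ids},
                site_id=None if pd.isna(site) else site,
                truth=None if pd.isna(truth) else Label(truth),
                species=None if pd.isna(species) else species,
            )

    def subset(self, mask: Sequence[bool] | np.ndarray | pd.Series) -> "PredictionManifest":
        return PredictionManifest(self.frame[np.asarray(mask)], self.model_ids)


def read_manifest(path: str | Path, model_ids: Sequence[str]) -> PredictionManifest:
    """Read a manifest CSV, validating identifiers and probability bounds.

    Truth labels may be written as ``empty``/``animal`` or ``0``/``1``
    (0 = empty).  Optional columns that are absent from the file simply
    yield absent fields.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={c: "string" for c in (*_ID_COLUMNS, "truth", "species")},
        keep_default_na=True,
        float_precision="round_trip",  # write/read must be bit-exact
    )
    missing = [m for m in model_ids if m not in df.columns]
    if missing:
        raise ManifestValidationError(f"manifest lacks probability columns {missing}")
    df = df.astype({c: object for c in df.columns if c in (*_ID_COLUMNS, "truth", "species")})
    for col in (*_ID_COLUMNS, "truth", "species"):
        if col in df.columns:
            df[col] = df[col].where(df[col].notna(), None)
    if "truth" in df.columns:
        normalized = df["truth"].map(lambda t: _TRUTH_ALIASES.get(t, t) if t is not None else None)
        df["truth"] = normalized
    return PredictionManifest(df, list(model_ids))


def write_manifest(manifest: PredictionManifest, path: str | Path) -> None:
    """Write a manifest CSV with deterministic column order.

    Order: identifiers, truth, species, then model columns in manifest
    order.  Optional columns are included only when present.
    """
    df = manifest.frame
    cols = ["image_id", "event_id"]
    for opt in ("site_id", "truth", "species"):
        if opt in df.columns:
            cols.append(opt)
    cols.extend(manifest.model_ids)
    df[cols].to_csv(path, index=False)


def split_by_events(
    manifest: PredictionManifest, n_train_events: int, seed: int
) -> tuple[PredictionManifest, PredictionManifest]:
    """Event-grouped train/test split.

    All images of a capture event land on the same side, so near-duplicate
    frames from one trigger can never straddle the split.  Events are
    sampled uniformly without replacement with the given seed.
    """
    events = manifest.event_ids
    if n_train_events > len(events):
        raise ValueError(
            f"n_train_events={n_train_events} exceeds event count {len(events)}"
        )
    rng = np.random.default_rng(seed)
    train_events = set(rng.choice(np.array(events, dtype=object), size=n_train_events, replace=False)) \
        if n_train_events else set()
    in_train = manifest.frame["event_id"].isin(train_events).to_numpy()
    return manifest.subset(in_train), manifest.subset(~in_train)


def balance_training_set(train: PredictionManifest, seed: int) -> PredictionManifest:
    """Build a class-balanced training manifest.

    Keeps every animal image and pairs it with an equal-size uniform sample
    (seeded) of empty images, so the output is exactly 50% empty.  Sampling
    is at image level: the balanced set mirrors image counts, not event
    structure.
    """
    truths = train.frame.get("truth")
    if truths is None or truths.isna().any():
        raise ManifestValidationError("balance_training_set requires truth labels on every row")
    is_animal = (truths == Label.ANIMAL.value).to_numpy()
    n_animal = int(is_animal.sum())
    empty_idx = np.flatnonzero(~is_animal)
    if len(empty_idx) < n_animal:
        raise ValueError(
            f"cannot balance: {len(empty_idx)} empty images < {n_animal} animal images"
        )
    rng = np.random.default_rng(seed)
    chosen_empty = rng.choice(empty_idx, size=n_animal, replace=False)
    keep = np.zeros(len(train.frame), dtype=bool)
    keep[np.flatnonzero(is_animal)] = True
    keep[chosen_empty] = True
    return train.subset(keep)
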