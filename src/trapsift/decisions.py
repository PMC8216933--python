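"""Conservative decision rules: abstaining thresholds and two-level ensembles.

Every base classifier emits a probability-of-animal per image.  A confidence
threshold delta turns that probability into a ternary decision — empty (0),
animal (1), or uncertain (x) when neither class reaches delta.  Three models
trained on the same training set are combined by unanimity: they must all
agree on a certain label, otherwise the ensemble abstains.  Two such
first-level ensembles (one per training set) are then combined by either the
enhanced rule ("and": both must agree, smallest omission error) or the
complementary rule ("or": either may decide, conflicts resolve to animal,
larger coverage).  A final scheme adds an unthresholded six-model majority
vote on whatever the complementary rule left uncertain, so that nothing is
routed to manual review.

All rules are deliberately biased toward calling an image "animal": the cost
of auto-deleting an animal image (a lost species observation) is far higher
than the cost of keeping an empty one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .manifest import PredictionManifest

__all__ = [
    "TernaryDecision",
    "ThresholdPolicy",
    "SchemeId",
    "SchemeResult",
    "apply_threshold",
    "first_level_ensemble",
    "enhanced_combine",
    "complementary_combine",
    "majority_vote",
    "run_scheme",
]

# integer codes used by the vectorized kernels
_EMPTY, _ANIMAL, _UNCERTAIN = 0, 1, 2


class TernaryDecision(Enum):
    """Empty / animal / uncertain; serialized as 0 / 1 / x."""

    EMPTY = "0"
    ANIMAL = "1"
    UNCERTAIN = "x"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_CODE_TO_DECISION = {
    _EMPTY: TernaryDecision.EMPTY,
    _ANIMAL: TernaryDecision.ANIMAL,
    _UNCERTAIN: TernaryDecision.UNCERTAIN,
}
_DECISION_TO_CODE = {v: k for k, v in _CODE_TO_DECISION.items()}


@dataclass(frozen=True)
class ThresholdPolicy:
    """Confidence threshold delta in [0.5, 1].

    A prediction is accepted only if its class probability reaches delta;
    delta = 0.5 accepts everything (never abstains).  Values below 0.5 are
    rejected because both classes could then pass simultaneously.
    """

    delta: float = 0.95

    def __post_init__(self) -> None:
        if not 0.5 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0.5, 1.0], got {self.delta}")


class SchemeId(Enum):
    """The four named filtering schemes.

    I   enhanced ("and") — both first-level ensembles must agree
    II  second first-level ensemble alone (balanced-trained group)
    III complementary ("or") — either decides; certain conflicts -> animal
    IV  scheme III, then six-model majority vote on the residual
    """

    SCHEME_I = "I"
    SCHEME_II = "II"
    SCHEME_III = "III"
    SCHEME_IV = "IV"


@dataclass
class SchemeResult:
    """Per-image ternary decisions of one scheme at one threshold."""

    scheme: SchemeId
    delta: float
    image_ids: list[str]
    event_ids: list[str]
    codes: np.ndarray  # int8, values in {0, 1, 2}
    group1: list[str] = field(default_factory=list)
    group2: list[str] = field(default_factory=list)

    @property
    def decisions(self) -> dict[str, TernaryDecision]:
        return {
            img: _CODE_TO_DECISION[int(c)]
            for img, c in zip(self.image_ids, self.codes)
        }

    def to_frame(self) -> pd.DataFrame:
        """Decisions as a DataFrame with 0/1/x serialization."""
        symbol = np.array(["0", "1", "x"])
        return pd.DataFrame(
            {
                "image_id": self.image_ids,
                "event_id": self.event_ids,
                "decision": symbol[self.codes],
            }
        )


# ---------------------------------------------------------------------------
# scalar rules (the reference semantics; kernels below must match these)
# ---------------------------------------------------------------------------


def apply_threshold(p_animal: float, policy: ThresholdPolicy) -> TernaryDecision:
    """Threshold one probability-of-animal into a ternary decision.

    ANIMAL if p_animal >= delta, EMPTY if (1 - p_animal) >= delta, else
    UNCERTAIN.  The comparison is inclusive: a probability exactly at the
    threshold counts as confident.
    """
    if not 0.0 <= p_animal <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p_animal}")
    if p_animal >= policy.delta:
        return TernaryDecision.ANIMAL
    if 1.0 - p_animal >= policy.delta:
        return TernaryDecision.EMPTY
    return TernaryDecision.UNCERTAIN


def first_level_ensemble(
    a: TernaryDecision, i: TernaryDecision, r: TernaryDecision
) -> TernaryDecision:
    """Unanimity over three same-training-set models.

    A certain label is emitted only when all three models agree on it; any
    disagreement or abstention among the members yields UNCERTAIN.
    """
    if a is i is r and a is not TernaryDecision.UNCERTAIN:
        return a
    return TernaryDecision.UNCERTAIN


def enhanced_combine(d1: TernaryDecision, d2: TernaryDecision) -> TernaryDecision:
    """Second-level "and" rule: both ensembles must agree on a certain label."""
    if d1 is d2 and d1 is not TernaryDecision.UNCERTAIN:
        return d1
    return TernaryDecision.UNCERTAIN


def complementary_combine(d1: TernaryDecision, d2: TernaryDecision) -> TernaryDecision:
    """Second-level "or" rule: either ensemble may decide.

    Agreement keeps the shared label; one certain + one abstaining keeps the
    certain label; a certain conflict resolves to ANIMAL (never auto-remove
    a contested image); both abstaining stays UNCERTAIN.
    """
    if d1 is TernaryDecision.UNCERTAIN:
        return d2
    if d2 is TernaryDecision.UNCERTAIN:
        return d1
    if d1 is d2:
        return d1
    return TernaryDecision.ANIMAL


def majority_vote(p_animal_per_model: Sequence[float]) -> TernaryDecision:
    """Unthresholded majority over six models; a 3-3 tie returns ANIMAL.

    Each model votes by argmax (animal iff p_animal >= 0.5).  The tie-break
    to ANIMAL keeps the rule conservative: a contested image is retained.
    """
    probs = np.asarray(p_animal_per_model, dtype=float)
    if probs.shape != (6,):
        raise ValueError(f"majority_vote expects exactly 6 probabilities, got {probs.shape}")
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must be in [0, 1]")
    animal_votes = int((probs >= 0.5).sum())
    return TernaryDecision.ANIMAL if animal_votes >= 3 else TernaryDecision.EMPTY


# ---------------------------------------------------------------------------
# vectorized kernels
# ---------------------------------------------------------------------------


def threshold_codes(p_animal: np.ndarray, delta: float) -> np.ndarray:
    """Vectorized apply_threshold over an array of probabilities."""
    p = np.asarray(p_animal, dtype=float)
    codes = np.full(p.shape, _UNCERTAIN, dtype=np.int8)
    codes[1.0 - p >= delta] = _EMPTY
    codes[p >= delta] = _ANIMAL  # at delta=0.5, p=0.5 satisfies both; animal wins
    return codes


def _unanimity(codes: np.ndarray) -> np.ndarray:
    """Row-wise unanimity over the last axis of a code array."""
    first = codes[..., 0]
    agree = np.all(codes == first[..., None], axis=-1) & (first != _UNCERTAIN)
    return np.where(agree, first, _UNCERTAIN).astype(np.int8)


def _enhanced(air1: np.ndarray, air2: np.ndarray) -> np.ndarray:
    agree = (air1 == air2) & (air1 != _UNCERTAIN)
    return np.where(agree, air1, _UNCERTAIN).astype(np.int8)


def _complementary(air1: np.ndarray, air2: np.ndarray) -> np.ndarray:
    out = np.where(
        air1 == _UNCERTAIN,
        air2,
        np.where(air2 == _UNCERTAIN, air1, np.where(air1 == air2, air1, _ANIMAL)),
    )
    return out.astype(np.int8)


def _resolve_groups(
    manifest: PredictionManifest,
    group1: Optional[Sequence[str]],
    group2: Optional[Sequence[str]],
) -> tuple[list[str], list[str]]:
    models = manifest.model_ids
    if group1 is None and group2 is None:
        if len(models) < 6:
            raise ValueError(
                f"need six model columns (or explicit groups); manifest has {len(models)}"
            )
        group1, group2 = models[:3], models[3:6]
    if group1 is None or group2 is None:
        raise ValueError("provide both groups or neither")
    group1, group2 = list(group1), list(group2)
    if len(group1) != 3 or len(group2) != 3:
        raise ValueError("each model group must contain exactly three model ids")
    if set(group1) & set(group2):
        raise ValueError("model groups must be disjoint")
    missing = [m for m in (*group1, *group2) if m not in manifest.frame.columns]
    if missing:
        raise ValueError(f"manifest lacks model columns {missing}")
    return group1, group2


def run_scheme(
    manifest: PredictionManifest,
    scheme: SchemeId,
    policy: ThresholdPolicy = ThresholdPolicy(),
    group1: Optional[Sequence[str]] = None,
    group2: Optional[Sequence[str]] = None,
) -> SchemeResult:
    """Run one filtering scheme over every image of a manifest.

    Group 1 feeds the first unanimity ensemble (in the reference setup, the
    models trained on the imbalanced set) and group 2 the second (balanced
    set).  By default the first three manifest columns form group 1 and the
    next three group 2.
    """
    group1, group2 = _resolve_groups(manifest, group1, group2)
    p1 = manifest.frame[group1].to_numpy(dtype=float)
    p2 = manifest.frame[group2].to_numpy(dtype=float)
    air1 = _unanimity(threshold_codes(p1, policy.delta))
    air2 = _unanimity(threshold_codes(p2, policy.delta))

    if scheme is SchemeId.SCHEME_I:
        codes = _enhanced(air1, air2)
    elif scheme is SchemeId.SCHEME_II:
        codes = air2
    elif scheme is SchemeId.SCHEME_III:
        codes = _complementary(air1, air2)
    elif scheme is SchemeId.SCHEME_IV:
        codes = _complementary(air1, air2)
        residual = codes == _UNCERTAIN
        if residual.any():
            votes = (np.hstack([p1, p2])[residual] >= 0.5).sum(axis=1)
            codes = codes.copy()
            codes[residual] = np.where(votes >= 3, _ANIMAL, _EMPTY).astype(np.int8)
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown scheme {scheme}")

    return SchemeResult(
        scheme=scheme,
        delta=policy.delta,
        image_ids=list(manifest.frame["image_id"]),
        event_ids=list(manifest.frame["event_id"]),
        codes=codes,
        group1=group1,
        group2=group2,
    )
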