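"""Evaluation: confusion counts over covered items and the five error metrics.

Abstentions are routed to manual review, so they are excluded from the
confusion table: every rate conditions on the images (or events) the scheme
actually decided.  The one exception is the removal rate R_re = TN / N_e,
whose denominator N_e is the total number of empty items in the evaluated
set — it measures how much manual deletion work the scheme saves overall,
abstentions included.

Metrics (animal = positive class):

    E_oa = FN / (FN + TP)            omission error of animal images (1 - recall)
    E_ce = FN / (FN + TN)            commission error of empty images
                                     (animal images among the auto-removed)
    R_re = TN / N_e                  removal rate of empty images
    E_ov = (FN + FP) / (TP+TN+FN+FP) overall error on covered items
    E_ca = FP / (TP + FP)            commission error of animal images (1 - precision)

A metric whose denominator is zero is *undefined* (None / NA), never silently
zero.

Event-level evaluation first collapses each capture event: an event is truly
empty only if every image is empty; a predicted event is EMPTY only if every
image was decided EMPTY, ANIMAL if any image was decided ANIMAL, UNCERTAIN
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .decisions import (
    SchemeId,
    SchemeResult,
    TernaryDecision,
    ThresholdPolicy,
    run_scheme,
)
from .manifest import Label, PredictionManifest

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "coverage",
    "compute_confusion",
    "compute_metrics",
    "event_truth",
    "event_decision",
    "evaluate",
    "threshold_sweep",
    "write_report",
]

REPORT_COLUMNS = [
    "scheme",
    "level",
    "delta",
    "tp",
    "fp",
    "fn",
    "tn",
    "n_uncertain",
    "n_empty_total",
    "e_ov",
    "e_oa",
    "e_ca",
    "e_ce",
    "r_re",
    "coverage",
]

_PROPORTION_COLUMNS = ["e_ov", "e_oa", "e_ca", "e_ce", "r_re", "coverage"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts over covered (non-abstained) items, plus abstentions and N_e.

    ``n_empty_total`` is N_e: all truly empty items in the evaluated set,
    whether covered or not.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_uncertain: int
    n_empty_total: int

    @property
    def n_covered(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_total(self) -> int:
        return self.n_covered + self.n_uncertain


@dataclass(frozen=True)
class MetricsReport:
    """The five error metrics plus coverage; None marks an undefined value."""

    e_ov: Optional[float]
    e_oa: Optional[float]
    e_ca: Optional[float]
    e_ce: Optional[float]
    r_re: Optional[float]
    coverage: Optional[float]


def coverage(decisions: SchemeResult) -> float:
    """Share of items with an accepted (non-uncertain) decision."""
    n = len(decisions.codes)
    if n == 0:
        raise ValueError("coverage of an empty decision set is undefined")
    return float((decisions.codes != 2).sum() / n)


def compute_confusion(
    decisions: SchemeResult, truths: Mapping[str, Label]
) -> ConfusionCounts:
    """Tabulate TP/FP/FN/TN over covered items; abstentions counted apart."""
    missing = [img for img in decisions.image_ids if img not in truths]
    if missing:
        raise ValueError(f"missing truth for {len(missing)} images, e.g. {missing[0]!r}")
    truth_animal = np.array(
        [truths[img] is Label.ANIMAL for img in decisions.image_ids], dtype=bool
    )
    codes = decisions.codes
    pred_animal = codes == 1
    pred_empty = codes == 0
    return ConfusionCounts(
        tp=int((truth_animal & pred_animal).sum()),
        fp=int((~truth_animal & pred_animal).sum()),
        fn=int((truth_animal & pred_empty).sum()),
        tn=int((~truth_animal & pred_empty).sum()),
        n_uncertain=int((codes == 2).sum()),
        n_empty_total=int((~truth_animal).sum()),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Derive the error metrics from confusion counts.

    Any metric with a zero denominator is reported as None (undefined),
    never as zero: a scheme that covered nothing has no error rate.
    """
    return MetricsReport(
        e_ov=_ratio(c.fn + c.fp, c.n_covered),
        e_oa=_ratio(c.fn, c.fn + c.tp),
        e_ca=_ratio(c.fp, c.tp + c.fp),
        e_ce=_ratio(c.fn, c.fn + c.tn),
        r_re=_ratio(c.tn, c.n_empty_total),
        coverage=_ratio(c.n_covered, c.n_total),
    )


def event_truth(image_truths: Sequence[Label]) -> Label:
    """An event is ANIMAL if any member image is, EMPTY only if all are empty."""
    if len(image_truths) == 0:
        raise ValueError("event has no images")
    return Label.ANIMAL if any(t is Label.ANIMAL for t in image_truths) else Label.EMPTY


def event_decision(image_decisions: Sequence[TernaryDecision]) -> TernaryDecision:
    """Collapse image decisions to one event decision.

    Mirrors the truth definition conservatively: any ANIMAL decision makes
    the event ANIMAL; the event is EMPTY only when every image was decided
    EMPTY; anything else (some abstentions, no animal) stays UNCERTAIN.
    """
    if len(image_decisions) == 0:
        raise ValueError("event has no images")
    if any(d is TernaryDecision.ANIMAL for d in image_decisions):
        return TernaryDecision.ANIMAL
    if all(d is TernaryDecision.EMPTY for d in image_decisions):
        return TernaryDecision.EMPTY
    return TernaryDecision.UNCERTAIN


def _event_tables(
    manifest: PredictionManifest, result: SchemeResult
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Vectorized per-event truth (bool animal) and decision codes."""
    df = pd.DataFrame(
        {
            "event_id": result.event_ids,
            "animal": (manifest.frame["truth"] == Label.ANIMAL.value).to_numpy(),
            "pred_animal": result.codes == 1,
            "pred_empty": result.codes == 0,
        }
    )
    g = df.groupby("event_id", sort=False)
    agg = g.agg(
        truth_animal=("animal", "any"),
        any_animal=("pred_animal", "any"),
        all_empty=("pred_empty", "all"),
    )
    codes = np.full(len(agg), 2, dtype=np.int8)
    codes[agg["all_empty"].to_numpy()] = 0
    codes[agg["any_animal"].to_numpy()] = 1  # animal dominates
    return agg["truth_animal"].to_numpy(), codes, list(agg.index)


def evaluate(
    manifest: PredictionManifest,
    scheme: SchemeId,
    policy: ThresholdPolicy = ThresholdPolicy(),
    level: str = "image",
    group1: Optional[Sequence[str]] = None,
    group2: Optional[Sequence[str]] = None,
) -> tuple[MetricsReport, ConfusionCounts]:
    """Run a scheme and score it at image or capture-event level.

    At event level the per-image decisions are first collapsed per event
    (see `event_decision`), and N_e counts empty *events*.
    """
    if level not in ("image", "event"):
        raise ValueError(f"level must be 'image' or 'event', got {level!r}")
    truths = manifest.truths()
    result = run_scheme(manifest, scheme, policy, group1, group2)
    if level == "image":
        counts = compute_confusion(result, truths)
    else:
        truth_animal, codes, event_ids = _event_tables(manifest, result)
        ev_result = SchemeResult(
            scheme=scheme,
            delta=policy.delta,
            image_ids=event_ids,
            event_ids=event_ids,
            codes=codes,
            group1=result.group1,
            group2=result.group2,
        )
        ev_truths = {
            ev: (Label.ANIMAL if a else Label.EMPTY)
            for ev, a in zip(event_ids, truth_animal)
        }
        counts = compute_confusion(ev_result, ev_truths)
    return compute_metrics(counts), counts


def _report_row(
    scheme: SchemeId,
    level: str,
    delta: float,
    report: MetricsReport,
    counts: ConfusionCounts,
) -> dict:
    row = {
        "scheme": scheme.value,
        "level": level,
        "delta": delta,
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "tn": counts.tn,
        "n_uncertain": counts.n_uncertain,
        "n_empty_total": counts.n_empty_total,
    }
    for name in _PROPORTION_COLUMNS:
        row[name] = getattr(report, name)
    return row


def threshold_sweep(
    manifest: PredictionManifest,
    schemes: Sequence[SchemeId],
    deltas: Sequence[float],
    level: str = "image",
    group1: Optional[Sequence[str]] = None,
    group2: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Evaluate every scheme at every confidence threshold.

    Returns one row per (scheme, delta) with full confusion counts and
    metrics; decisions are recomputed from the raw probabilities at each
    delta.
    """
    for d in deltas:
        if not 0.5 <= d <= 1.0:
            raise ValueError(f"delta must be in [0.5, 1.0], got {d}")
    rows = []
    for scheme in schemes:
        for delta in deltas:
            report, counts = evaluate(
                manifest, scheme, ThresholdPolicy(delta), level, group1, group2
            )
            rows.append(_report_row(scheme, level, delta, report, counts))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def report_frame(
    scheme: SchemeId,
    level: str,
    delta: float,
    report: MetricsReport,
    counts: ConfusionCounts,
) -> pd.DataFrame:
    """One-row report DataFrame in the canonical column order."""
    return pd.DataFrame([_report_row(scheme, level, delta, report, counts)],
                        columns=REPORT_COLUMNS)


def write_report(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a report CSV, adding two-decimal percentage renderings.

    Each proportion column gains a ``*_pct`` companion formatted to two
    decimals; undefined values serialize as NA.
    """
    out = frame.copy()
    for col in _PROPORTION_COLUMNS:
        if col in out.columns:
            vals = pd.to_numeric(out[col], errors="coerce")
            out[col + "_pct"] = [
                "NA" if pd.isna(v) else f"{100 * v:.2f}" for v in vals
            ]
    out.to_csv(path, index=False, na_rep="NA")
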