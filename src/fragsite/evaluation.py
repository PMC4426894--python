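"""Evaluation: confusion metrics, operating points, leave-one-out driver,
balanced subsampling, adjacency-tolerant relabeling and per-type breakdown."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EvaluationError
from .scoring import ScoringParams, predictions_to_frame, score_query
from .structure_io import StructureModel
from .template_db import BindingAnnotation, TemplateDatabase

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    acc: float
    tpr: float
    fpr: float
    specificity: float
    mcc: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.acc,
            "sensitivity": self.tpr,
            "fpr": self.fpr,
            "specificity": self.specificity,
            "mcc": self.mcc,
        }


def counts_from_calls(labels, calls) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=bool)
    calls = np.asarray(calls, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(labels & calls)),
        tn=int(np.sum(~labels & ~calls)),
        fp=int(np.sum(~labels & calls)),
        fn=int(np.sum(labels & ~calls)),
    )


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """ACC, TPR, FPR, specificity and MCC from raw counts.

    MCC is 0 by convention whenever a denominator factor vanishes.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    if total == 0:
        raise EvaluationError("cannot compute metrics on zero residues")
    acc = (tp + tn) / total
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricSet(acc=acc, tpr=tpr, fpr=fpr, specificity=1.0 - fpr, mcc=mcc)


def _check_two_classes(labels):
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise EvaluationError("both classes must be present")
    return labels


def threshold_at_fpr(scores, labels, fpr_cap: float = 0.05) -> float:
    """Smallest observed-score threshold with pooled FPR <= cap.

    Calls are ``score >= t``. Lowering t only adds calls, so the smallest
    feasible t maximizes TPR; among equally sensitive optima the highest t
    is returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    candidates = np.unique(scores)  # ascending
    neg = scores[~labels]
    pos = scores[labels]
    n_neg, n_pos = len(neg), len(pos)
    best = None  # (tpr, t)
    for t in candidates:
        fpr = np.sum(neg >= t) / n_neg
        if fpr > fpr_cap:
            continue
        tpr = np.sum(pos >= t) / n_pos
        if best is None or tpr > best[0] or (tpr == best[0] and t > best[1]):
            best = (tpr, float(t))
    if best is None:
        # even the highest observed score exceeds the cap; call nothing
        return float(np.max(scores)) + 1.0
    return best[1]


def threshold_at_max_mcc(scores, labels) -> float:
    """Observed-score threshold maximizing MCC (ties -> higher threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    best = None  # (mcc, t)
    for t in np.unique(scores):
        counts = counts_from_calls(labels, scores >= t)
        mcc = confusion_metrics(counts).mcc
        if best is None or mcc > best[0] or (mcc == best[0] and t > best[1]):
            best = (mcc, float(t))
    if best[0] == 0.0:
        logger.warning("degenerate score distribution: best MCC is 0")
    return best[1]


# ---------------------------------------------------------------------------
# Leave-one-out driver
# ---------------------------------------------------------------------------

def _labels_for_model(model: StructureModel, annotations: list[BindingAnnotation]):
    """(chain, seq_pos) -> bool binding label from annotations of this model."""
    positive = set()
    for a in annotations:
        if a.pdb_id.lower() != model.pdb_id.lower():
            continue
        for p in a.binding_positions:
            positive.add((a.chain_id, p))
    return positive


def leave_one_out(
    dataset: list[tuple[StructureModel, list[BindingAnnotation]]],
    db: TemplateDatabase,
    params: ScoringParams | None = None,
    fpr_cap: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Score every protein excluding templates from its own PDB entry.

    Returns the pooled per-residue score table and operating-point metrics
    at the pooled FPR cap and at the pooled maximum-MCC threshold.
    """
    if len(dataset) < 2:
        raise EvaluationError("leave-one-out needs at least 2 proteins")
    params = params or ScoringParams()
    frames = []
    for model, annotations in dataset:
        predictions = score_query(
            model.chains, db, params, exclude_sources={model.pdb_id}
        )
        frame = predictions_to_frame(predictions)
        positive = _labels_for_model(model, annotations)
        frame.insert(0, "protein", model.pdb_id)
        frame["label"] = [
            (c, p) in positive for c, p in zip(frame["chain"], frame["seq_pos"])
        ]
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)

    z = table["Z"].to_numpy()
    labels = table["label"].to_numpy()
    results = {}
    for name, thr in (
        ("fpr_cap", threshold_at_fpr(z, labels, fpr_cap)),
        ("max_mcc", threshold_at_max_mcc(z, labels)),
    ):
        calls = z >= thr
        counts = counts_from_calls(labels, calls)
        results[name] = {
            "threshold": float(thr),
            "counts": counts,
            "metrics": confusion_metrics(counts),
        }
    table["call"] = z >= results["fpr_cap"]["threshold"]
    return table, results


# ---------------------------------------------------------------------------
# Balanced subsampling (comparison-protocol evaluation)
# ---------------------------------------------------------------------------

def balanced_subsample_eval(
    table: pd.DataFrame, n_repeats: int = 5, seed: int = 42
) -> pd.DataFrame:
    """Evaluate on per-protein balanced pools of binding vs nonbinding residues.

    For each repeat, every protein contributes all its binding residues plus
    an equal-size random sample of its nonbinding residues; the pooled
    balanced set is scored at its own maximum-MCC threshold. Returns one row
    per repeat plus an ``average`` row.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_repeats + 1):
        parts = []
        for protein, sub in table.groupby("protein", sort=True):
            pos = sub[sub["label"]]
            neg = sub[~sub["label"]]
            if len(pos) == 0 or len(neg) == 0:
                logger.warning("protein %s lacks one class; skipped", protein)
                continue
            if len(pos) > len(neg):
                logger.warning(
                    "protein %s has more binding than nonbinding residues; skipped",
                    protein,
                )
                continue
            pick = rng.choice(len(neg), size=len(pos), replace=False)
            parts.append(pd.concat([pos, neg.iloc[np.sort(pick)]]))
        if not parts:
            raise EvaluationError("no protein usable for balanced evaluation")
        pool = pd.concat(parts, ignore_index=True)
        z = pool["Z"].to_numpy()
        labels = pool["label"].to_numpy()
        thr = threshold_at_max_mcc(z, labels)
        m = confusion_metrics(counts_from_calls(labels, z >= thr))
        rows.append(
            {
                "repeat": str(rep),
                "accuracy": m.acc,
                "sensitivity": m.tpr,
                "specificity": m.specificity,
                "mcc": m.mcc,
                "threshold": thr,
            }
        )
    df = pd.DataFrame(rows)
    avg = df[["accuracy", "sensitivity", "specificity", "mcc"]].mean()
    df.loc[len(df)] = {
        "repeat": "average",
        "accuracy": avg["accuracy"],
        "sensitivity": avg["sensitivity"],
        "specificity": avg["specificity"],
        "mcc": avg["mcc"],
        "threshold": np.nan,
    }
    return df


# ---------------------------------------------------------------------------
# Adjacency-tolerant relabeling
# ---------------------------------------------------------------------------

def adjacency_relabel(table: pd.DataFrame) -> tuple[ConfusionCounts, ConfusionCounts]:
    """Reclassify false positives adjacent in sequence to true positives.

    An FP at position p becomes a TP when a TP sits at p-1 or p+1 in the
    same chain of the same protein. Returns (original, adjusted) counts.
    Only integer sequence positions take part in adjacency.
    """
    labels = table["label"].to_numpy(dtype=bool)
    calls = table["call"].to_numpy(dtype=bool)
    original = counts_from_calls(labels, calls)
    n_moved = 0
    for (_, _), sub in table.groupby(["protein", "chain"], sort=False):
        sub_labels = sub["label"].to_numpy(dtype=bool)
        sub_calls = sub["call"].to_numpy(dtype=bool)
        positions = sub["seq_pos"].tolist()
        tp_pos = {
            p
            for p, l, c in zip(positions, sub_labels, sub_calls)
            if l and c and isinstance(p, int)
        }
        for p, l, c in zip(positions, sub_labels, sub_calls):
            if c and not l and isinstance(p, int):
                if (p - 1) in tp_pos or (p + 1) in tp_pos:
                    n_moved += 1
    adjusted = ConfusionCounts(
        tp=original.tp + n_moved,
        tn=original.tn,
        fp=original.fp - n_moved,
        fn=original.fn,
    )
    return original, adjusted


def per_residue_breakdown(table: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity and specificity restricted to each amino-acid type."""
    rows = []
    for res_name, sub in table.groupby("res_name", sort=True):
        labels = sub["label"].to_numpy(dtype=bool)
        calls = sub["call"].to_numpy(dtype=bool)
        c = counts_from_calls(labels, calls)
        sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
        spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
        rows.append(
            {
                "res_name": res_name,
                "n": c.total,
                "n_binding": c.tp + c.fn,
                "sensitivity": sens,
                "specificity": spec,
            }
        )
    return pd.DataFrame(rows)
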