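"""Experimental protocol: stratified splits, metrics, cross-validation.

The data is first divided 90/10 into a cross-validation pool and a held-out
test set, then the pool undergoes k-fold cross-validation.  Five
stratification strategies control what the validation fold holds out:

* ``random``     — plain sample-level folds;
* ``cline``      — validation cell lines never appear in the fold's
  training set;
* ``drugcomb``   — unordered drug pairs are disjoint between training and
  validation (individual drugs may overlap);
* ``drugsingle`` — drugs are partitioned; a validation sample has exactly
  one held-out drug (samples with two held-out drugs are discarded, which
  shrinks the usable data);
* ``drugdouble`` — a validation sample has two held-out drugs; training
  samples have none.

The initial test split is drawn at the same grouping unit as the strategy,
so no held-out entity leaks into the test set.  Fold membership is decided
by hashing unit ids together with the seed, making assignments invariant
to sample order.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .data_io import Cohort, DataError, SynergySample

__all__ = ["STRATEGIES", "Fold", "SplitPlan", "MetricSet", "make_splits",
           "compute_metrics", "run_cv", "CvResult"]

STRATEGIES = ("random", "cline", "drugcomb", "drugsingle", "drugdouble")


@dataclass
class Fold:
    train_indices: list[int]
    val_indices: list[int]


@dataclass
class SplitPlan:
    strategy: str
    k: int
    folds: list[Fold]
    test_indices: list[int]
    seed: int

    def validate(self) -> None:
        test = set(self.test_indices)
        for f in self.folds:
            tr, va = set(f.train_indices), set(f.val_indices)
            if tr & va:
                raise DataError("train/validation overlap within a fold")
            if (tr | va) & test:
                raise DataError("test samples leak into a CV fold")


@dataclass
class MetricSet:
    auroc: float
    auprc: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"auroc": self.auroc, "auprc": self.auprc, "f1": self.f1}


def _unit_hash(seed: int, unit: str) -> int:
    h = hashlib.blake2b(f"{seed}:{unit}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "big")


def _hash_order(units: list[str], seed: int) -> list[str]:
    return sorted(units, key=lambda u: (_unit_hash(seed, u), u))


def _pair_key(s: SynergySample) -> str:
    return "||".join(sorted((s.drug_a, s.drug_b)))


def make_splits(samples: list[SynergySample], strategy: str, k: int = 5,
                test_fraction: float = 0.10, seed: int = 0) -> SplitPlan:
    """Build the test split and k cross-validation folds for a strategy."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; "
                         f"choose from {STRATEGIES}")
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    n = len(samples)

    if strategy == "random":
        units = [str(i) for i in range(n)]
        unit_of = {str(i): [i] for i in range(n)}
    elif strategy == "cline":
        unit_of = {}
        for i, s in enumerate(samples):
            unit_of.setdefault(s.cell_line, []).append(i)
        units = list(unit_of)
    elif strategy == "drugcomb":
        unit_of = {}
        for i, s in enumerate(samples):
            unit_of.setdefault(_pair_key(s), []).append(i)
        units = list(unit_of)
    else:  # drugsingle / drugdouble: unit = individual drug
        drugs = sorted({d for s in samples for d in (s.drug_a, s.drug_b)})
        units = drugs
        unit_of = None

    ordered = _hash_order(units, seed)
    n_test_units = math.ceil(test_fraction * len(ordered)) if test_fraction else 0
    test_units = set(ordered[:n_test_units])
    cv_units = ordered[n_test_units:]
    if len(cv_units) < k:
        raise DataError(
            f"strategy {strategy!r} needs at least {k} grouping units for "
            f"{k} folds; only {len(cv_units)} remain after the test split")
    group = {u: pos % k for pos, u in enumerate(cv_units)}

    if strategy in ("random", "cline", "drugcomb"):
        test_idx = sorted(i for u in test_units for i in unit_of[u])
        folds = []
        for f in range(k):
            val = sorted(i for u in cv_units if group[u] == f
                         for i in unit_of[u])
            tr = sorted(i for u in cv_units if group[u] != f
                        for i in unit_of[u])
            folds.append(Fold(tr, val))
        plan = SplitPlan(strategy, k, folds, test_idx, seed)
        plan.validate()
        return plan

    # drug-based strategies
    want_held = 1 if strategy == "drugsingle" else 2

    def n_in(s: SynergySample, drugset: set[str]) -> int:
        return int(s.drug_a in drugset) + int(s.drug_b in drugset)

    test_idx = sorted(i for i, s in enumerate(samples)
                      if n_in(s, test_units) == want_held
                      and n_in(s, test_units) + n_in(s, set(cv_units)) == 2)
    pool = [i for i, s in enumerate(samples) if n_in(s, test_units) == 0]
    folds = []
    for f in range(k):
        held = {u for u in cv_units if group[u] == f}
        val = [i for i in pool if n_in(samples[i], held) == want_held]
        tr = [i for i in pool if n_in(samples[i], held) == 0]
        folds.append(Fold(tr, val))
    plan = SplitPlan(strategy, k, folds, test_idx, seed)
    plan.validate()
    return plan


def compute_metrics(labels, scores, f1_threshold: float = 0.5) -> MetricSet:
    """AUROC (tied scores get half credit), step-interpolated AUPRC, and F1
    at the given probability threshold."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    if len(np.unique(y)) < 2:
        raise DataError("AUROC/AUPRC undefined: only one class present")
    return MetricSet(
        auroc=float(roc_auc_score(y, s)),
        auprc=float(average_precision_score(y, s)),
        f1=float(f1_score(y, (s >= f1_threshold).astype(int))),
    )


@dataclass
class CvResult:
    strategy: str
    fold_metrics: list[MetricSet]
    mean: MetricSet
    std: MetricSet
    test_metrics: MetricSet | None
    best_fold: int
    reports: list = field(default_factory=list)
    checkpoints: list = field(default_factory=list)
    plan: SplitPlan | None = None

    def summary(self) -> dict:
        out = {"strategy": self.strategy,
               "folds": [m.as_dict() for m in self.fold_metrics],
               "mean": self.mean.as_dict(), "std": self.std.as_dict(),
               "best_fold": self.best_fold}
        if self.test_metrics is not None:
            out["test"] = self.test_metrics.as_dict()
        return out


def run_cv(cohort: Cohort, strategy: str, config, k: int = 5,
           test_fraction: float = 0.10, evaluate_test: bool = True) -> CvResult:
    """Train one model per fold and summarize validation (and test) metrics.

    The held-out test set is scored with the model from the fold whose
    validation AUROC was highest.  Deterministic given ``config.seed``.
    """
    from .synergy_model import train  # local import avoids a cycle

    labeled = cohort.labeled_samples()
    plan = make_splits(labeled, strategy, k=k, test_fraction=test_fraction,
                       seed=config.seed)
    fold_metrics: list[MetricSet] = []
    reports = []
    checkpoints = []
    for fold in plan.folds:
        ckpt, report = train(cohort, (fold.train_indices, fold.val_indices),
                             config)
        val_samples = [labeled[i] for i in fold.val_indices]
        scores = ckpt.predict(val_samples)
        fold_metrics.append(compute_metrics([s.label for s in val_samples],
                                            scores))
        reports.append(report)
        checkpoints.append(ckpt)

    arr = np.array([[m.auroc, m.auprc, m.f1] for m in fold_metrics])
    mean = MetricSet(*arr.mean(axis=0))
    std = MetricSet(*arr.std(axis=0))
    best_fold = int(np.argmax([m.auroc for m in fold_metrics]))

    test_metrics = None
    if evaluate_test and plan.test_indices:
        test_samples = [labeled[i] for i in plan.test_indices]
        test_labels = [s.label for s in test_samples]
        if len(set(test_labels)) == 2:
            scores = checkpoints[best_fold].predict(test_samples)
            test_metrics = compute_metrics(test_labels, scores)

    return CvResult(strategy, fold_metrics, mean, std, test_metrics,
                    best_fold, reports, checkpoints, plan)
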