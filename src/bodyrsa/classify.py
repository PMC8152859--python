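"""Three-class decoding of body-part category from ROI betas.

A linear SVM (one-vs-one, cost 1) is trained on run-wise beta patterns
— one sample per condition per run — with leave-one-run-out
cross-validation. Because the three categories are unbalanced (4
effector, 2 noneffector, 2 face conditions), each training fold is
rebalanced by repeated subsampling down to the minority class count
(100 bootstrap draws); fold accuracy is the bootstrap mean. Category
assignment significance is assessed against the same complete
420-partition enumeration used by ANOSIM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .design import BODY_PART_CONDITIONS
from .partitions import Partition, enumerate_partitions, hypothesized_partition

__all__ = [
    "CHANCE_LEVEL",
    "loro_folds",
    "balanced_subsample",
    "CvResult",
    "decode",
    "ClassPermutationResult",
    "partition_permutation_test",
]

#: Chance accuracy for three classes.
CHANCE_LEVEL = 1.0 / 3.0


def loro_folds(n_runs: int) -> list[tuple[list[int], int]]:
    """Leave-one-run-out folds: (train run indices, test run index)."""
    if n_runs < 2:
        raise ValueError("need at least 2 runs for cross-validation")
    return [([r for r in range(n_runs) if r != t], t) for t in range(n_runs)]


def balanced_subsample(
    y: np.ndarray, n_bootstraps: int = 100, seed: int = 0
) -> list[np.ndarray]:
    """Index sets that balance class counts by subsampling.

    Each bootstrap draws, without replacement within class, the minority
    class count from every class. Returns ``n_bootstraps`` index arrays
    into the training samples.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts == 0):
        raise ValueError("empty class in training data")
    m = counts.min()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_bootstraps):
        idx = np.concatenate(
            [
                rng.choice(np.flatnonzero(y == c), size=m, replace=False)
                for c in classes
            ]
        )
        out.append(np.sort(idx))
    return out


@dataclass
class CvResult:
    fold_accuracies: np.ndarray  # one entry per fold (bootstrap-averaged)
    mean_accuracy: float
    accuracy_minus_chance: float
    n_bootstraps: int


def decode(
    run_betas: np.ndarray,
    partition: Partition | None = None,
    labels: Sequence[str] = BODY_PART_CONDITIONS,
    svm_cost: float = 1.0,
    n_bootstraps: int = 100,
    seed: int = 0,
) -> CvResult:
    """Leave-one-run-out linear-SVM decoding of the category labels.

    ``run_betas`` is runs x conditions x voxels. Features are
    standardized with training-fold statistics (zero-variance features
    dropped with a warning); each balanced bootstrap trains one
    classifier, evaluated on the full held-out run, and accuracies are
    averaged over bootstraps then folds.
    """
    run_betas = np.asarray(run_betas, dtype=float)
    if run_betas.ndim != 3:
        raise ValueError("run_betas must be runs x conditions x voxels")
    n_runs, n_cond, _ = run_betas.shape
    if partition is None:
        partition = hypothesized_partition()
    y_cond = partition.membership(tuple(labels))
    rng = np.random.default_rng(seed)
    fold_acc = []
    for train_runs, test_run in loro_folds(n_runs):
        Xtr = run_betas[train_runs].reshape(len(train_runs) * n_cond, -1)
        ytr = np.tile(y_cond, len(train_runs))
        Xte = run_betas[test_run]
        yte = y_cond
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance feature(s)",
                stacklevel=2,
            )
        if not keep.any():
            raise ValueError("all features are degenerate in a training fold")
        Xtr = (Xtr[:, keep] - mu[keep]) / sd[keep]
        Xte = (Xte[:, keep] - mu[keep]) / sd[keep]
        boots = balanced_subsample(
            ytr, n_bootstraps=n_bootstraps,
            seed=int(rng.integers(2**31)),
        )
        accs = []
        for idx in boots:
            clf = SVC(kernel="linear", C=svm_cost, decision_function_shape="ovo")
            clf.fit(Xtr[idx], ytr[idx])
            accs.append(np.mean(clf.predict(Xte) == yte))
        fold_acc.append(float(np.mean(accs)))
    fold_acc = np.array(fold_acc)
    mean_acc = float(fold_acc.mean())
    return CvResult(
        fold_accuracies=fold_acc,
        mean_accuracy=mean_acc,
        accuracy_minus_chance=mean_acc - CHANCE_LEVEL,
        n_bootstraps=n_bootstraps,
    )


@dataclass
class ClassPermutationResult:
    observed: float  # hypothesized accuracy minus chance
    null: np.ndarray  # accuracy-minus-chance for all enumerated partitions
    p: float
    rank: int


def partition_permutation_test(
    run_betas: np.ndarray,
    labels: Sequence[str] = BODY_PART_CONDITIONS,
    svm_cost: float = 1.0,
    n_bootstraps: int = 100,
    seed: int = 0,
) -> ClassPermutationResult:
    """Complete-permutation test of the three-category decodability.

    Decoding is repeated for every admissible (4, 2, 2) assignment of
    conditions to classes (420 in total, hypothesized included);
    P = (1 + #{alternatives strictly better than hypothesized}) / 420,
    the same strict-counting convention as the ANOSIM enumeration.
    """
    hyp = hypothesized_partition()
    parts = enumerate_partitions(tuple(labels), hyp.sizes)
    seeds = np.random.SeedSequence(seed).generate_state(len(parts)) % (2**31)
    null = np.empty(len(parts))
    hyp_classes = frozenset(frozenset(c) for c in hyp.classes)
    hyp_first = None
    for i, part in enumerate(parts):
        res = decode(
            run_betas,
            partition=part,
            labels=labels,
            svm_cost=svm_cost,
            n_bootstraps=n_bootstraps,
            seed=int(seeds[i]),
        )
        null[i] = res.accuracy_minus_chance
        if (
            hyp_first is None
            and frozenset(frozenset(c) for c in part.classes) == hyp_classes
        ):
            hyp_first = i
    obs = float(null[hyp_first])
    others = np.delete(null, hyp_first)
    p = (1 + int(np.sum(others > obs + 1e-12))) / len(parts)
    rank = 1 + int(np.sum(null > obs + 1e-12))
    return ClassPermutationResult(observed=obs, null=null, p=p, rank=rank)
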