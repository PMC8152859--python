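"""Split-half representational dissimilarity matrices and comparisons.

The dissimilarity between body parts i and j is 1 - r, with r the
Pearson correlation between the odd-run mean pattern of i and the
even-run mean pattern of j; the directed matrix is symmetrized by
averaging with its transpose. The split-half diagonal carries
1 - reliability and is excluded from all vectorized comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import MDS

from .design import BODY_PART_CONDITIONS

__all__ = [
    "RDM",
    "split_half_rdm",
    "mean_rdm",
    "rdm_vector",
    "MdsEmbedding",
    "mds_embed",
    "within_between_correlations",
]


@dataclass
class RDM:
    """Condition x condition dissimilarity matrix (1 - Pearson r)."""

    values: np.ndarray
    labels: tuple[str, ...] = BODY_PART_CONDITIONS
    symmetrized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"RDM shape {self.values.shape} does not match {n} labels"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RDM":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(), labels=tuple(df.columns))


def split_half_rdm(
    run_betas: Sequence[np.ndarray] | np.ndarray,
    labels: tuple[str, ...] = BODY_PART_CONDITIONS,
    symmetrize: bool = True,
) -> RDM:
    """Split-half RDM from per-run condition x voxel amplitude matrices.

    Odd runs (1st, 3rd, ...) and even runs (2nd, 4th, ...) are averaged
    separately per condition; entry (i, j) is 1 minus the Pearson
    correlation of odd pattern i with even pattern j.
    """
    runs = [np.asarray(r, dtype=float) for r in run_betas]
    if len(runs) < 2:
        raise ValueError("need at least one odd and one even run")
    if runs[0].shape[1] < 2:
        raise ValueError("need at least 2 voxels")
    odd = np.mean(runs[0::2], axis=0)
    even = np.mean(runs[1::2], axis=0)
    n = len(labels)
    if odd.shape[0] != n:
        raise ValueError(f"expected {n} conditions, got {odd.shape[0]}")
    for name, half in (("odd", odd), ("even", even)):
        sd = half.std(axis=1)
        if np.any(sd == 0):
            bad = labels[int(np.argmax(sd == 0))]
            raise ValueError(
                f"zero-variance {name}-half pattern for condition {bad!r}; "
                "correlation undefined"
            )
    oz = (odd - odd.mean(1, keepdims=True)) / odd.std(1, keepdims=True)
    ez = (even - even.mean(1, keepdims=True)) / even.std(1, keepdims=True)
    r = oz @ ez.T / odd.shape[1]
    D = 1.0 - r
    if symmetrize:
        D = (D + D.T) / 2.0
    return RDM(values=D, labels=labels, symmetrized=symmetrize)


def mean_rdm(rdms: Sequence[RDM], leave_out: int | None = None) -> RDM:
    """Entrywise mean RDM, optionally excluding one participant."""
    kept = [r for i, r in enumerate(rdms) if i != leave_out]
    if not kept:
        raise ValueError("no RDMs left after exclusion")
    labels = kept[0].labels
    if any(r.labels != labels for r in kept):
        raise ValueError("label mismatch across RDMs")
    return RDM(
        values=np.mean([r.values for r in kept], axis=0),
        labels=labels,
        symmetrized=all(r.symmetrized for r in kept),
    )


def rdm_vector(rdm: RDM, include_diagonal: bool = False) -> np.ndarray:
    """Lower-triangle entries in row-major order (28 values for 8x8)."""
    if not rdm.symmetrized:
        raise ValueError("vectorization requires a symmetrized RDM")
    k = 0 if include_diagonal else -1
    i, j = np.tril_indices(rdm.n, k=k)
    return rdm.values[i, j]


@dataclass
class MdsEmbedding:
    coordinates: np.ndarray  # conditions x k
    labels: tuple[str, ...]
    stress: float  # Kruskal stress-1
    seed: int

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.coordinates,
            index=self.labels,
            columns=[f"dim{d + 1}" for d in range(self.coordinates.shape[1])],
        )
        df["stress"] = self.stress
        df.to_csv(path)


def mds_embed(
    rdm: RDM, k: int = 2, n_restarts: int = 8, seed: int = 0
) -> MdsEmbedding:
    """Metric MDS of the RDM by least-squares stress minimization.

    Runs ``n_restarts`` seeded initializations and keeps the lowest
    stress; the reported value is Kruskal stress-1 (normalized).
    """
    if k >= rdm.n:
        raise ValueError("embedding dimension must be below the condition count")
    if not rdm.symmetrized:
        raise ValueError("MDS requires a symmetrized RDM")
    D = rdm.values.copy()
    np.fill_diagonal(D, 0.0)
    mds = MDS(
        n_components=k,
        metric="precomputed",
        n_init=n_restarts,
        init="random",
        random_state=seed,
        normalized_stress=False,
    )
    coords = mds.fit_transform(D)
    iu = np.triu_indices(rdm.n, 1)
    dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    denom = (D[iu] ** 2).sum()
    stress1 = float(np.sqrt(((dist[iu] - D[iu]) ** 2).sum() / denom)) if denom else 0.0
    return MdsEmbedding(coordinates=coords, labels=rdm.labels, stress=stress1, seed=seed)


def within_between_correlations(
    rdms: Sequence[RDM], groups: Sequence[str]
) -> pd.DataFrame:
    """Per-participant correlations with own- and other-group mean RDMs.

    The own-group mean excludes the participant (leave-one-out); both
    coefficients are Pearson correlations over the 28 unordered pairs.
    Returns a tidy frame with columns participant, group, within_r,
    between_r.
    """
    groups = list(groups)
    names = sorted(set(groups))
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    for g in names:
        if groups.count(g) < 2:
            raise ValueError(f"group {g!r} needs at least 2 participants")
    vecs = [rdm_vector(r) for r in rdms]
    rows = []
    for i, (v, g) in enumerate(zip(vecs, groups)):
        if np.std(v) == 0:
            raise ValueError(f"participant {i} has a constant RDM vector")
        own_idx = [j for j, gj in enumerate(groups) if gj == g and j != i]
        other_idx = [j for j, gj in enumerate(groups) if gj != g]
        own_mean = np.mean([vecs[j] for j in own_idx], axis=0)
        other_mean = np.mean([vecs[j] for j in other_idx], axis=0)
        rows.append(
            {
                "participant": i,
                "group": g,
                "within_r": float(np.corrcoef(v, own_mean)[0, 1]),
                "between_r": float(np.corrcoef(v, other_mean)[0, 1]),
            }
        )
    return pd.DataFrame(rows)
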