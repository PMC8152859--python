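"""ANOSIM and Mantel tests on body-part dissimilarity matrices.

ANOSIM (analysis of similarities) ranks the 28 pairwise dissimilarities
and compares mean between-category against mean within-category rank:

    R = (mean rank between - mean rank within) / (M / 2),  M = 28,

so R is in [-1, 1] with 1 indicating complete category separation. The
significance of the hypothesized three-category model (effectors |
noneffectors | face) is assessed by complete enumeration of all
8C4 x 4C2 = 420 assignments of the 8 conditions to classes of sizes
(4, 2, 2): P = (1 + #{alternatives with strictly greater R}) / 420.
Strict counting is used because swapping the two size-2 class labels
duplicates every R value exactly; counting ties would double the
minimum attainable P.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
from scipy.stats import rankdata

from .design import BODY_PART_CONDITIONS
from .rsa import RDM, rdm_vector

__all__ = [
    "Partition",
    "hypothesized_partition",
    "enumerate_partitions",
    "anosim_r",
    "AnosimResult",
    "anosim_permutation_test",
    "MantelResult",
    "mantel_test",
]


@dataclass(frozen=True)
class Partition:
    """Assignment of condition labels to ordered classes."""

    classes: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        flat = [c for cls in self.classes for c in cls]
        if len(set(flat)) != len(flat):
            raise ValueError("a condition appears in more than one class")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c for cls in self.classes for c in cls)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(cls) for cls in self.classes)

    def class_of(self, label: str) -> int:
        for k, cls in enumerate(self.classes):
            if label in cls:
                return k
        raise KeyError(label)

    def membership(self, labels: tuple[str, ...]) -> np.ndarray:
        return np.array([self.class_of(c) for c in labels])


def hypothesized_partition() -> Partition:
    """Action effectors | trunk noneffectors | face parts."""
    return Partition(
        classes=(
            ("hand", "arm", "leg", "foot"),
            ("chest", "waist"),
            ("upper_face", "lower_face"),
        )
    )


@lru_cache(maxsize=8)
def _enumerate_cached(
    labels: tuple[str, ...], sizes: tuple[int, ...]
) -> tuple[Partition, ...]:
    def recurse(remaining: tuple[str, ...], sizes_left: tuple[int, ...]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        first = remaining[0]
        # last class absorbs whatever remains (keeps order deterministic)
        if len(sizes_left) == 1:
            yield (remaining,)
            return
        for combo in combinations(remaining, k):
            rest = tuple(c for c in remaining if c not in combo)
            for tail in recurse(rest, sizes_left[1:]):
                yield (combo,) + tail

    return tuple(Partition(classes=c) for c in recurse(labels, sizes))


def enumerate_partitions(
    labels: tuple[str, ...] = BODY_PART_CONDITIONS,
    sizes: tuple[int, ...] = (4, 2, 2),
) -> list[Partition]:
    """All labeled partitions of ``labels`` into classes of ``sizes``.

    Deterministic lexicographic order over successive class choices;
    for the default 8 conditions and sizes (4, 2, 2) there are exactly
    8C4 x 4C2 = 420 partitions, each unlabeled grouping appearing twice
    (the two size-2 classes are interchangeable).
    """
    if sum(sizes) != len(labels):
        raise ValueError("class sizes must sum to the number of labels")
    return list(_enumerate_cached(tuple(labels), tuple(sizes)))


def _pair_within_mask(partition: Partition, labels: tuple[str, ...]) -> np.ndarray:
    """Boolean mask over the lower-triangle pair vector: within-class pairs."""
    m = partition.membership(labels)
    i, j = np.tril_indices(len(labels), k=-1)
    return m[i] == m[j]


def anosim_r(
    rdm: RDM | np.ndarray,
    partition: Partition,
    labels: tuple[str, ...] | None = None,
) -> float:
    """ANOSIM R for one categorization of the conditions.

    Ranks use the average-rank convention for ties; with every pair
    tied, R = 0. A bare array may be passed with ``labels`` naming its
    rows (defaults to the canonical body-part order).
    """
    if isinstance(rdm, np.ndarray):
        if labels is None:
            labels = BODY_PART_CONDITIONS[: rdm.shape[0]]
        rdm = RDM(values=rdm, labels=tuple(labels))
    vec = rdm_vector(rdm)
    ranks = rankdata(vec)
    within = _pair_within_mask(partition, rdm.labels)
    M = vec.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (M / 2.0))


@dataclass
class AnosimResult:
    r: float
    p: float
    rank: int  # 1 = hypothesized model has the largest R
    all_r: np.ndarray  # R for every enumerated partition, enumeration order
    partitions: list[Partition]
    hypothesized: Partition
    hypothesized_index: int  # scored occurrence within the enumeration


def anosim_permutation_test(
    rdm: RDM, hypothesized: Partition | None = None
) -> AnosimResult:
    """Complete-enumeration permutation test of the hypothesized model.

    R is computed for every admissible partition (420 for the default
    design); P = (1 + #{alternatives with R strictly greater than the
    hypothesized R}) / n_partitions. The hypothesized partition's rank
    (1 = best) among all partitions is also returned.
    """
    if hypothesized is None:
        hypothesized = hypothesized_partition()
    parts = enumerate_partitions(rdm.labels, hypothesized.sizes)
    vec = rdm_vector(rdm)
    ranks = rankdata(vec)
    masks = np.stack([_pair_within_mask(p, rdm.labels) for p in parts])
    M = vec.size
    n_within = masks[0].sum()
    sum_within = masks @ ranks
    total = ranks.sum()
    rw = sum_within / n_within
    rb = (total - sum_within) / (M - n_within)
    all_r = (rb - rw) / (M / 2.0)
    hyp_classes = frozenset(frozenset(c) for c in hypothesized.classes)
    hyp_idx = [
        i
        for i, p in enumerate(parts)
        if frozenset(frozenset(c) for c in p.classes) == hyp_classes
        and p.sizes == hypothesized.sizes
    ]
    # labeled enumeration contains the unlabeled hypothesized grouping
    # twice (2-class swap); score the first occurrence
    r_obs = float(all_r[hyp_idx[0]])
    others = np.delete(all_r, hyp_idx[0])
    p = (1 + int(np.sum(others > r_obs + 1e-12))) / len(parts)
    rank = 1 + int(np.sum(all_r > r_obs + 1e-12))
    return AnosimResult(
        r=r_obs, p=p, rank=rank, all_r=all_r, partitions=parts,
        hypothesized=hypothesized, hypothesized_index=hyp_idx[0],
    )


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int


def mantel_test(
    rdm_a: RDM,
    rdm_b: RDM,
    n_permutations: int = 9999,
    seed: int = 0,
    method: str = "permute",
) -> MantelResult:
    """Mantel test of the correlation between two RDMs.

    The statistic is the Pearson correlation over the 28 unordered
    pairs. The null relabels the conditions of the second matrix — a
    simultaneous row/column permutation — either randomly
    (``method='permute'``, ``n_permutations`` draws) or exhaustively
    over all 8! relabelings (``method='exact'``).
    P = (1 + #{null r >= observed}) / (n + 1).
    """
    if rdm_a.labels != rdm_b.labels:
        raise ValueError("RDMs must share condition labels")
    va = rdm_vector(rdm_a)
    vb = rdm_vector(rdm_b)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant RDM vector; correlation undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    n = rdm_a.n
    B = rdm_b.values
    i, j = np.tril_indices(n, k=-1)

    def stat(perm: np.ndarray) -> float:
        vp = B[np.ix_(perm, perm)][i, j]
        return float(np.corrcoef(va, vp)[0, 1])

    if method == "exact":
        null = np.array([stat(np.array(p)) for p in permutations(range(n))])
        n_perm = null.size - 1  # identity included in the enumeration
        p = np.sum(null >= r_obs - 1e-12) / null.size
        return MantelResult(r=r_obs, p=float(p), n_permutations=n_perm)
    if method != "permute":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if stat(rng.permutation(n)) >= r_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return MantelResult(r=r_obs, p=float(p), n_permutations=n_permutations)
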