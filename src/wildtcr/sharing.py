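"""Pairwise clonotype sharing, public clonotypes, ordination and clustering.

All sharing statistics are computed on repertoires down-sampled to the
smallest repertoire of the receptor type, then reduced to unique clonotype
sets; S[i, j] is the number of amino-acid clonotypes mice i and j share.
Dissimilarity is the re-scaled form d = S_max - S (the most similar pair has
dissimilarity exactly 0).  Ordination is classical (Gower) principal
coordinates with optional observation weights; clustering is average-linkage
(UPGMA) on the dissimilarity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diversity import downsample
from .repertoire_io import MouseMetadata, Repertoire
from .seeds import derive_seed

__all__ = [
    "SharingMatrix",
    "PCoAResult",
    "pairwise_shared",
    "public_clonotypes",
    "sharing_percentage",
    "sharing_to_dissimilarity",
    "dendrogram_order",
    "linkage_to_newick",
    "pcoa",
    "build_pair_table",
]


@dataclass
class SharingMatrix:
    """Symmetric pairwise shared-clonotype counts for one receptor type.

    The diagonal holds each mouse's down-sampled unique clonotype count.
    ``key_sets`` retains the down-sampled unique-clonotype sets for public-
    clonotype detection.
    """

    mouse_ids: List[str]
    receptor_type: str
    S: np.ndarray
    downsample_target: int
    seed: int
    key_sets: Optional[Dict[str, Set]] = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.mouse_ids, columns=self.mouse_ids)


def pairwise_shared(
    repertoires: Dict[Tuple[str, str], Repertoire],
    receptor_type: str,
    seed: int = 0,
) -> SharingMatrix:
    """Shared unique-clonotype counts between all mouse pairs.

    Each mouse's repertoire is down-sampled (without replacement, sub-seeded
    per mouse) to the smallest repertoire size of the receptor type, reduced
    to its set of unique clonotype keys, and intersected pairwise.
    """
    reps = {mid: rep for (mid, rt), rep in repertoires.items()
            if rt == receptor_type}
    if len(reps) < 2:
        raise ValueError(
            f"need >= 2 mice for receptor type {receptor_type}, got {len(reps)}"
        )
    mouse_ids = sorted(reps)
    target = min(reps[m].size for m in mouse_ids)
    key_sets: Dict[str, Set] = {}
    for mouse_id in mouse_ids:
        sub_seed = derive_seed(seed, mouse_id, receptor_type, "sharing")
        down = downsample(reps[mouse_id], target, seed=sub_seed)
        key_sets[mouse_id] = set(down.clones.keys())
    # incidence matrix over the union of keys -> S = A^T A
    all_keys = sorted(set().union(*key_sets.values()))
    key_index = {k: i for i, k in enumerate(all_keys)}
    A = np.zeros((len(all_keys), len(mouse_ids)), dtype=np.int32)
    for j, mouse_id in enumerate(mouse_ids):
        rows = [key_index[k] for k in key_sets[mouse_id]]
        A[rows, j] = 1
    S = A.T @ A
    return SharingMatrix(mouse_ids=mouse_ids, receptor_type=receptor_type,
                         S=S.astype(np.int64), downsample_target=target,
                         seed=seed, key_sets=key_sets)


def public_clonotypes(
    key_sets: Dict[str, Set], threshold: float = 0.75
) -> Tuple[pd.DataFrame, float]:
    """Clonotypes present in at least ``ceil(threshold * n_mice)`` mice.

    Returns (table of public keys with prevalence, public count as a fraction
    of the total number of distinct keys observed).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if len(key_sets) < 2:
        raise ValueError("need >= 2 mice")
    n_mice = len(key_sets)
    need = ceil(threshold * n_mice)
    prevalence: Dict = {}
    for keys in key_sets.values():
        for key in keys:
            prevalence[key] = prevalence.get(key, 0) + 1
    total_unique = len(prevalence)
    rows = [
        {"v_label": k[0], "cdr3_aa": k[1], "j_label": k[2],
         "prevalence": n, "n_mice": n_mice}
        for k, n in prevalence.items() if n >= need
    ]
    rows.sort(key=lambda r: (-r["prevalence"], r["v_label"], r["cdr3_aa"],
                             r["j_label"]))
    table = pd.DataFrame(
        rows, columns=["v_label", "cdr3_aa", "j_label", "prevalence", "n_mice"]
    )
    fraction = len(rows) / total_unique if total_unique else 0.0
    return table, fraction


def sharing_percentage(S: SharingMatrix) -> float:
    """Mean off-diagonal shared count as a percentage of the mean
    down-sampled unique-clonotype count."""
    n = S.S.shape[0]
    off = S.S[~np.eye(n, dtype=bool)]
    return 100.0 * float(off.mean()) / float(np.diag(S.S).mean())


def sharing_to_dissimilarity(S: SharingMatrix, form: str = "rescaled") -> np.ndarray:
    """Re-scaled dissimilarity d = S_max - S (``rescaled``, default) or the
    relative form 1 - S/S_max (``relative``); either way the most similar
    pair has dissimilarity exactly 0 and the diagonal is 0."""
    M = np.asarray(S.S, dtype=np.float64)
    n = M.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    s_max = M[off_mask].max()
    if np.all(M[off_mask] == M[off_mask][0]):
        warnings.warn("all off-diagonal sharing counts equal; "
                      "dissimilarity is identically zero")
    if form == "rescaled":
        d = s_max - M
    elif form == "relative":
        if s_max == 0:
            d = np.zeros_like(M)
        else:
            d = 1.0 - M / s_max
    else:
        raise ValueError(f"unknown dissimilarity form {form!r}")
    np.fill_diagonal(d, 0.0)
    return d


def _check_square_symmetric(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return d


def dendrogram_order(d: np.ndarray) -> Tuple[List[int], np.ndarray]:
    """Average-linkage (UPGMA) clustering of a dissimilarity matrix.

    Returns (leaf order, scipy linkage matrix).  Deterministic: scipy breaks
    ties by the lowest cluster index.
    """
    d = _check_square_symmetric(d)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    return [int(i) for i in leaves], Z


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node, branch: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{branch:.6g}"
        left = walk(node.get_left(), node.dist - node.get_left().dist)
        right = walk(node.get_right(), node.dist - node.get_right().dist)
        return f"({left},{right}):{branch:.6g}"

    left = walk(tree.get_left(), tree.dist - tree.get_left().dist)
    right = walk(tree.get_right(), tree.dist - tree.get_right().dist)
    return f"({left},{right});"


@dataclass
class PCoAResult:
    """Principal-coordinate ordination of a dissimilarity matrix.

    ``eigenvalues`` includes any negative eigenvalues (reported, not
    silently dropped); coordinates span the positive axes only, ordered by
    decreasing eigenvalue.  ``proportion_explained`` is relative to the sum
    of positive eigenvalues.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: np.ndarray, weights: Optional[Sequence[float]] = None) -> PCoAResult:
    """Classical (Gower) principal coordinates, optionally row-weighted.

    Double-centres -d^2/2 with the weighted centring operator
    (I - 1 w^T / sum w), eigendecomposes diag(sqrt(w)) B diag(sqrt(w)) and
    rescales eigenvectors by 1/sqrt(w) — with uniform weights this reduces
    exactly to unweighted classical PCoA.
    """
    d = _check_square_symmetric(d)
    n = d.shape[0]
    if weights is None:
        w = np.full(n, 1.0)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be n non-negative numbers with "
                             "positive sum")
    p = w / w.sum()
    A = -0.5 * d**2
    C = np.eye(n) - np.outer(np.ones(n), p)
    B = C @ A @ C.T
    sq = np.sqrt(p)
    M = (B * sq[:, None]) * sq[None, :]
    M = (M + M.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1]
    # eigenvalues on the total-weight scale: uniform weights then reproduce
    # unweighted classical PCoA exactly
    eigvals = eigvals[order] * w.sum()
    eigvecs = eigvecs[:, order]
    tol = max(1e-8 * max(abs(eigvals.max()), 1.0), 1e-12)
    pos = eigvals > tol
    with np.errstate(divide="ignore", invalid="ignore"):
        coords = (eigvecs[:, pos] * np.sqrt(eigvals[pos])) / np.sqrt(w)[:, None]
    coords = np.nan_to_num(coords)
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    return PCoAResult(coordinates=coords, eigenvalues=eigvals,
                      proportion_explained=prop)


def build_pair_table(
    S: SharingMatrix,
    metadata: Sequence[MouseMetadata],
    site_filter: Optional[str] = None,
) -> pd.DataFrame:
    """One row per unordered mouse pair: shared count, same_sex, age
    difference and age sum, optionally restricted to one sampling site."""
    meta = {m.mouse_id: m for m in metadata}
    unknown = [m for m in S.mouse_ids if m not in meta]
    if unknown:
        raise ValueError(f"mice missing from metadata: {unknown}")
    keep = [m for m in S.mouse_ids
            if site_filter is None or meta[m].site == site_filter]
    rows = []
    for i, a in enumerate(keep):
        for b in keep[i + 1:]:
            ia, ib = S.mouse_ids.index(a), S.mouse_ids.index(b)
            ma, mb = meta[a], meta[b]
            rows.append({
                "mouse_a": a,
                "mouse_b": b,
                "shared": int(S.S[ia, ib]),
                "same_sex": ma.sex == mb.sex,
                "age_diff": abs(ma.age - mb.age),
                "age_sum": ma.age + mb.age,
                "receptor_type": S.receptor_type,
            })
    return pd.DataFrame(
        rows, columns=["mouse_a", "mouse_b", "shared", "same_sex",
                       "age_diff", "age_sum", "receptor_type"]
    )
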