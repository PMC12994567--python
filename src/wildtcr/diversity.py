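"""Repertoire QC, richness, down-sampling and diversity indices.

Richness is the number of unique amino-acid clonotypes as a proportion of
repertoire size (already depth-normalised, so it is computed on the full
repertoire).  Shannon (H = -sum p_i ln p_i) and Simpson (lambda = sum p_i^2,
reported as ln(1/lambda)) are computed after down-sampling every mouse of a
receptor type, without replacement, to the smallest repertoire of that
receptor type; the down-sampling is repeated independently for each index.
Natural logarithms throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .repertoire_io import RECEPTOR_TYPES, MouseMetadata, Repertoire
from .seeds import derive_seed

__all__ = [
    "QCDecision",
    "qc_exclude",
    "qc_cohort",
    "repertoire_size",
    "unique_count",
    "richness",
    "downsample",
    "downsample_literal",
    "shannon_index",
    "simpson_index",
    "diversity_table",
]

QC_THRESHOLD_DEFAULT = 5000


@dataclass
class QCDecision:
    """Keep/drop decision for one (mouse, subset) chain pair."""

    mouse_id: str
    subset: str
    keep: bool
    alpha_size: int
    beta_size: int
    reason: str = ""


def repertoire_size(rep: Repertoire) -> int:
    """Total molecules: sum of clone counts."""
    if not rep.clones:
        raise ValueError("empty repertoire")
    return rep.size


def unique_count(rep: Repertoire) -> int:
    """Number of unique clone keys."""
    if not rep.clones:
        raise ValueError("empty repertoire")
    return rep.unique_count


def richness(rep: Repertoire) -> float:
    """Unique clonotypes as a proportion of repertoire size, in (0, 1]."""
    return unique_count(rep) / repertoire_size(rep)


def qc_exclude(
    alpha_rep: Optional[Repertoire],
    beta_rep: Optional[Repertoire],
    threshold: int = QC_THRESHOLD_DEFAULT,
) -> QCDecision:
    """Drop BOTH chains of a subset if either chain has fewer than
    ``threshold`` molecules (strict less-than: exactly ``threshold`` keeps)."""
    a_size = alpha_rep.size if alpha_rep is not None else 0
    b_size = beta_rep.size if beta_rep is not None else 0
    mouse_id = (alpha_rep or beta_rep).mouse_id if (alpha_rep or beta_rep) else ""
    subset = (alpha_rep or beta_rep).subset if (alpha_rep or beta_rep) else ""
    low = [name for name, size in (("alpha", a_size), ("beta", b_size))
           if size < threshold]
    keep = not low
    reason = "" if keep else (
        f"{' and '.join(low)} chain below {threshold} molecules "
        f"(alpha={a_size}, beta={b_size})"
    )
    return QCDecision(mouse_id=mouse_id, subset=subset, keep=keep,
                      alpha_size=a_size, beta_size=b_size, reason=reason)


def qc_cohort(
    repertoires: Dict[Tuple[str, str], Repertoire],
    threshold: int = QC_THRESHOLD_DEFAULT,
) -> Tuple[Dict[Tuple[str, str], Repertoire], List[QCDecision]]:
    """Apply :func:`qc_exclude` per (mouse, subset) over a whole cohort.

    ``repertoires`` is keyed by (mouse_id, receptor_type); both chains of a
    subset are dropped together when either is too small.
    """
    decisions: List[QCDecision] = []
    kept: Dict[Tuple[str, str], Repertoire] = {}
    pairs = sorted({(mid, rt.split("_")[0]) for (mid, rt) in repertoires})
    for mouse_id, subset in pairs:
        a = repertoires.get((mouse_id, f"{subset}_alpha"))
        b = repertoires.get((mouse_id, f"{subset}_beta"))
        decision = qc_exclude(a, b, threshold=threshold)
        decisions.append(decision)
        if decision.keep:
            for rep in (a, b):
                if rep is not None:
                    kept[(mouse_id, rep.receptor_type)] = rep
    return kept, decisions


def _counts_array(rep: Repertoire) -> Tuple[list, np.ndarray]:
    # canonical key order, so draws depend only on repertoire content,
    # not on dict insertion order
    keys = sorted(rep.clones.keys())
    counts = np.fromiter((rep.clones[k] for k in keys), dtype=np.int64,
                         count=len(keys))
    return keys, counts


def downsample(
    rep: Repertoire,
    target: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Repertoire:
    """Down-sample a repertoire to exactly ``target`` molecules without
    replacement.

    Distributionally identical to replicating every clonotype by its count,
    sampling ``target`` items from the list without replacement and
    re-tallying; implemented as a multivariate hypergeometric draw.
    """
    size = repertoire_size(rep)
    if not 1 <= target <= size:
        raise ValueError(f"target must be in [1, {size}], got {target}")
    if rng is None:
        rng = np.random.default_rng(seed)
    keys, counts = _counts_array(rep)
    sampled = rng.multivariate_hypergeometric(counts, target)
    clones = {k: int(c) for k, c in zip(keys, sampled) if c > 0}
    return Repertoire(mouse_id=rep.mouse_id, subset=rep.subset,
                      chain=rep.chain, clones=clones, level=rep.level)


def downsample_literal(
    rep: Repertoire, target: int, seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Repertoire:
    """Reference down-sampler: literally expand each clonotype by its count,
    shuffle, take ``target`` items and re-tally.  Kept as the independent
    oracle for the hypergeometric implementation."""
    size = repertoire_size(rep)
    if not 1 <= target <= size:
        raise ValueError(f"target must be in [1, {size}], got {target}")
    if rng is None:
        rng = np.random.default_rng(seed)
    keys, counts = _counts_array(rep)
    expanded = np.repeat(np.arange(len(keys)), counts)
    taken = rng.choice(expanded, size=target, replace=False)
    tallied = np.bincount(taken, minlength=len(keys))
    clones = {k: int(c) for k, c in zip(keys, tallied) if c > 0}
    return Repertoire(mouse_id=rep.mouse_id, subset=rep.subset,
                      chain=rep.chain, clones=clones, level=rep.level)


def _proportions(rep: Repertoire) -> np.ndarray:
    if not rep.clones:
        raise ValueError("empty repertoire")
    counts = np.fromiter(rep.clones.values(), dtype=np.float64,
                         count=len(rep.clones))
    return counts / counts.sum()


def shannon_index(rep: Repertoire) -> float:
    """Shannon diversity H = -sum_i p_i ln p_i (nats), summed over unique
    clonotypes; 0 <= H <= ln(unique_count)."""
    p = _proportions(rep)
    return float(-(p * np.log(p)).sum())


def simpson_index(rep: Repertoire) -> Tuple[float, float]:
    """Simpson's index lambda = sum_i p_i^2 and its log transform
    ln(1/lambda); larger log values mean higher diversity."""
    p = _proportions(rep)
    lam = float((p * p).sum())
    return lam, float(np.log(1.0 / lam))


def diversity_table(
    repertoires: Dict[Tuple[str, str], Repertoire],
    seed: int = 0,
    index: str = "both",
    richness_on_downsampled: bool = False,
) -> pd.DataFrame:
    """Per-mouse, per-receptor-type diversity table.

    For each receptor type the down-sampling target is the smallest
    repertoire size across included mice of that receptor type.  Each mouse
    is down-sampled to that target with an independent sub-seed derived from
    (seed, mouse_id, receptor_type, index name) — separately for Shannon and
    Simpson — and the index is computed on the down-sampled repertoire.
    Richness is computed on the full repertoire unless
    ``richness_on_downsampled`` is set.

    Returns a tidy frame with one row per mouse x receptor type x index.
    """
    if index not in ("shannon", "simpson", "both"):
        raise ValueError(f"unknown index {index!r}")
    indices = ("shannon", "simpson") if index == "both" else (index,)
    rows = []
    for rt in RECEPTOR_TYPES:
        reps = {mid: rep for (mid, rt_), rep in repertoires.items() if rt_ == rt}
        if not reps:
            continue
        if len(reps) < 2:
            warnings.warn(f"fewer than 2 mice for receptor type {rt}; "
                          "table emitted anyway")
        target = min(rep.size for rep in reps.values())
        for mouse_id in sorted(reps):
            rep = reps[mouse_id]
            rich_rep = rep
            for idx_name in indices:
                sub_seed = derive_seed(seed, mouse_id, rt, idx_name)
                down = downsample(rep, target, seed=sub_seed)
                if richness_on_downsampled:
                    rich_rep = down
                row = {
                    "mouse_id": mouse_id,
                    "receptor_type": rt,
                    "repertoire_size": rep.size,
                    "unique_count": rep.unique_count,
                    "richness": richness(rich_rep),
                    "downsample_target": target,
                    "index": idx_name,
                    "shannon": np.nan,
                    "simpson_lambda": np.nan,
                    "simpson_log": np.nan,
                    "seed": sub_seed,
                }
                if idx_name == "shannon":
                    row["shannon"] = shannon_index(down)
                else:
                    lam, slog = simpson_index(down)
                    row["simpson_lambda"] = lam
                    row["simpson_log"] = slog
                rows.append(row)
    return pd.DataFrame(rows)
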