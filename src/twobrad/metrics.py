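"""Benchmarking and ecology statistics for abundance profiles.

Profiles are plain ``{taxon: relative abundance}`` mappings.  Pairwise
metrics zero-fill both profiles over the union of their taxa before
comparing, so a taxon called by only one side contributes its full
abundance as disagreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PRPoint",
    "precision_recall_curve",
    "aupr",
    "l2_similarity",
    "pearson_union",
    "shannon",
    "bray_curtis",
    "rarefy",
    "rarefaction_similarity",
    "saturating_depth",
    "shannon_similarity",
]


@dataclass(frozen=True)
class PRPoint:
    """Precision/recall at one abundance threshold."""

    threshold: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int


def _union_vectors(p: Dict[str, float], q: Dict[str, float],
                   ) -> Tuple[np.ndarray, np.ndarray]:
    taxa = sorted(set(p) | set(q))
    pv = np.array([p.get(t, 0.0) for t in taxa], dtype=float)
    qv = np.array([q.get(t, 0.0) for t in taxa], dtype=float)
    if (pv < 0).any() or (qv < 0).any():
        raise ValueError("abundances must be non-negative")
    return pv, qv


def precision_recall_curve(pred: Dict[str, float],
                           truth: Set[str] | Iterable[str]) -> List[PRPoint]:
    """Precision/recall over descending abundance thresholds.

    At each distinct predicted abundance v (descending), a taxon is
    *called* iff its predicted abundance >= v.  Precision at a threshold
    where nothing is called is 1 by convention.  Recall is non-decreasing
    along the returned list.

    Raises
    ------
    ValueError
        If ``truth`` is empty (recall undefined).
    """
    truth = set(truth)
    if not truth:
        raise ValueError("truth set is empty; recall is undefined")
    thresholds = sorted({v for v in pred.values()}, reverse=True)
    points = []
    for thr in thresholds:
        called = {t for t, v in pred.items() if v >= thr}
        tp = len(called & truth)
        fp = len(called - truth)
        fn = len(truth - called)
        precision = tp / (tp + fp) if (tp + fp) else 1.0
        recall = tp / (tp + fn)
        points.append(PRPoint(thr, precision, recall, tp, fp, fn))
    return points


def aupr(pr_points: Sequence[PRPoint]) -> float:
    """Area under the precision-recall curve (average-precision form).

    Computed as Σ_k P_k × (R_k − R_{k−1}) over the descending-threshold
    point sequence with R_0 = 0 — the step-function integrator, which is
    deterministic and matches exhaustive threshold enumeration.
    """
    area = 0.0
    prev_recall = 0.0
    for pt in pr_points:
        area += pt.precision * (pt.recall - prev_recall)
        prev_recall = pt.recall
    return area


def l2_similarity(p: Dict[str, float], q: Dict[str, float]) -> float:
    """One minus the Euclidean (L2) distance between zero-filled profiles.

    Equals 1 iff the profiles are identical; for normalized profiles the
    minimum is 1 − √2 (disjoint supports).
    """
    pv, qv = _union_vectors(p, q)
    return 1.0 - float(np.linalg.norm(pv - qv))


def pearson_union(p: Dict[str, float], q: Dict[str, float]) -> float:
    """Pearson correlation over the taxon union, zero-filling taxa unique
    to one profile.  Returns NaN (with a warning) when either zero-filled
    vector is constant."""
    pv, qv = _union_vectors(p, q)
    if len(pv) < 2:
        raise ValueError("taxon union must contain at least 2 taxa")
    if np.ptp(pv) == 0 or np.ptp(qv) == 0:
        warnings.warn("constant abundance vector: Pearson r undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(pv, qv)[0, 1])


def shannon(profile: Dict[str, float], base: float = 2.0) -> float:
    """Shannon diversity index −Σ a_i log_base a_i (zero terms skipped)."""
    a = np.array([v for v in profile.values() if v > 0], dtype=float)
    if a.size == 0:
        return 0.0
    return float(-(a * (np.log(a) / np.log(base))).sum())


def bray_curtis(p: Dict[str, float], q: Dict[str, float]) -> float:
    """Bray-Curtis dissimilarity Σ|p_i−q_i| / Σ(p_i+q_i) on the union."""
    pv, qv = _union_vectors(p, q)
    denom = float((pv + qv).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return float(np.abs(pv - qv).sum() / denom)


def rarefy(read_counts: Dict[str, int], depth: int,
           seed: int | np.random.Generator) -> Dict[str, int]:
    """Subsample counts to ``depth`` reads without replacement
    (multivariate hypergeometric).  Reproducible under ``seed``."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    taxa = sorted(read_counts)
    counts = np.array([read_counts[t] for t in taxa], dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total reads {total}")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    sub = rng.multivariate_hypergeometric(counts, depth)
    return {t: int(c) for t, c in zip(taxa, sub)}


def shannon_similarity(h_sub: float, h_full: float) -> float:
    """Similarity of two Shannon indices as the ratio min/max (1 when
    equal, 0 when one is zero and the other is not)."""
    if h_sub == h_full:
        return 1.0
    hi = max(h_sub, h_full)
    lo = min(h_sub, h_full)
    if hi == 0:
        return 1.0
    return lo / hi


def rarefaction_similarity(
    profile_fn: Callable[[Sequence[str]], Dict[str, float]],
    reads: Sequence[str],
    depths: Sequence[int],
    reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Diversity saturation under subsampling.

    For each depth (ascending; depths exceeding the sample are omitted),
    draw ``reps`` random read subsamples without replacement, profile
    each, and compare to the full-depth profile: the Shannon-index
    similarity (min/max ratio) and 1 − Bray-Curtis dissimilarity, averaged
    over replicates.

    Returns a DataFrame with columns ``depth``, ``shannon_similarity``,
    ``bray_curtis_similarity``.
    """
    depths = sorted(depths)
    full_profile = profile_fn(reads)
    h_full = shannon(full_profile)
    rng = np.random.default_rng(seed)
    n = len(reads)
    rows = []
    for depth in depths:
        if depth > n:
            continue  # subsampling stops beyond the sample's data volume
        sh_sims, bc_sims = [], []
        for _ in range(reps):
            idx = rng.choice(n, size=depth, replace=False)
            sub_profile = profile_fn([reads[i] for i in idx])
            sh_sims.append(shannon_similarity(shannon(sub_profile), h_full))
            if sub_profile or full_profile:
                bc = bray_curtis(sub_profile, full_profile) if sub_profile \
                    else 1.0
            else:
                bc = 0.0
            bc_sims.append(1.0 - bc)
        rows.append({
            "depth": depth,
            "shannon_similarity": float(np.mean(sh_sims)),
            "bray_curtis_similarity": float(np.mean(bc_sims)),
        })
    return pd.DataFrame(rows)


def saturating_depth(table: pd.DataFrame, tol: float = 0.01) -> int:
    """Depth at which a rarefaction curve saturates.

    The curve is considered saturated once both diversity indices of the
    subsample are within ``tol`` (1% by default) of their full-depth
    values — i.e. Shannon- and Bray-Curtis-similarity ≥ 1 − tol.  Returns
    the smallest such depth from a :func:`rarefaction_similarity` table,
    or the largest available depth if the bound is never reached.
    """
    ok = ((table["shannon_similarity"] >= 1.0 - tol)
          & (table["bray_curtis_similarity"] >= 1.0 - tol))
    if ok.any():
        return int(table.loc[ok, "depth"].iloc[0])
    return int(table["depth"].iloc[-1])
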