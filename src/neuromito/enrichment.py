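"""Rank-based gene-set enrichment with a gene-label permutation null.

The statistic is the classic weighted Kolmogorov-Smirnov running sum: walk
the ranked list from top (highest score) to bottom; at an in-set gene the
sum rises by ``|score|^p`` normalised over the in-set total, at any other
gene it falls by ``1/(N - n)``.  The enrichment score (ES) is the signed
maximum deviation of this walk from zero.  Significance and the normalised
enrichment score (NES) come from a null of random same-size gene sets:
``NES = ES / mean(|null ES| of the same sign)`` and the permutation p-value
uses the add-one rule so it can never be exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass
class RankedList:
    """Protein ids ordered by a score, highest first (duplicate-free)."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in ranked list")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores")
        order = np.argsort(-self.scores, kind="mergesort")
        self.ids = [self.ids[i] for i in order]
        self.scores = self.scores[order]

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        return cls(list(map(str, s.index)), s.values)


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], *, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score of ``gene_set`` in ``ranked``.

    Returns ``(ES, running_sum)`` where the running sum has one entry per
    list position.  ES is the running-sum value of largest magnitude.
    """
    members = set(gene_set)
    hit = np.array([g in members for g in ranked.ids], dtype=bool)
    n_hit = int(hit.sum())
    N = len(ranked.ids)
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == N:
        # every gene is a hit: the miss penalty is undefined; the walk is
        # degenerate and carries no enrichment information
        return 0.0, np.zeros(N)
    w = np.abs(ranked.scores) ** weight
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all in-set scores are zero under positive weighting: fall back to
        # unweighted steps so the walk remains defined
        hit_w = hit.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit) / (N - n_hit)
    running = np.cumsum(steps)
    es_idx = int(np.argmax(np.abs(running)))
    return float(running[es_idx]), running


def permutation_nes(
    ranked: RankedList,
    gene_set: Iterable[str],
    *,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """ES, NES and permutation p-value for one gene set.

    The null is gene-label permutation: ``n_perm`` random same-size subsets
    of the ranked list.  NES divides ES by the mean magnitude of null ES of
    matching sign; the p-value is ``(1 + k) / (1 + m)`` where ``k`` counts
    same-sign null ES at least as extreme and ``m`` counts same-sign nulls.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    members = set(gene_set) & set(ranked.ids)
    es, _ = enrichment_score(ranked, members, weight=weight)
    size = len(members)
    N = len(ranked.ids)

    w = np.abs(ranked.scores) ** weight
    null = np.empty(n_perm)
    idx = np.arange(N)
    for i in range(n_perm):
        pick = rng.choice(idx, size=size, replace=False)
        hit = np.zeros(N, dtype=bool)
        hit[pick] = True
        hit_w = np.where(hit, w, 0.0)
        total = hit_w.sum()
        if total == 0:
            hit_w = hit.astype(float)
            total = hit_w.sum()
        steps = hit_w / total - (~hit) / (N - size)
        running = np.cumsum(steps)
        null[i] = running[np.argmax(np.abs(running))]

    if es == 0.0:
        return {"es": 0.0, "nes": 0.0, "p_perm": 1.0, "size": size}
    same_sign = null[np.sign(null) == np.sign(es)]
    if same_sign.size == 0:
        warnings.warn("all null enrichment scores have the opposite sign")
        nes = 0.0
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(same_sign))
        k = int(np.sum(np.abs(same_sign) >= abs(es)))
        p = (1 + k) / (1 + same_sign.size)
    return {"es": float(es), "nes": float(nes), "p_perm": float(p), "size": size}


def scaled_mean_expression(
    matrix,
    pathways: Mapping[str, Iterable[str]],
    *,
    group: str = "control",
) -> pd.Series:
    """Min-max scaled mean log2 expression per pathway, in [0, 1].

    Each pathway is summarised as the mean log2 LFQ of its measured member
    proteins over the samples of ``group`` (by default the healthy
    controls, so the value reflects baseline abundance); the summaries are
    then min-max scaled across the supplied pathway collection.
    """
    log2m = matrix.log2()
    samples = log2m.samples_of(group)
    if not samples:
        raise ValueError(f"no samples in group {group!r}")
    means = {}
    for name, proteins in pathways.items():
        present = [p for p in proteins if p in log2m.intensities.index]
        if not present:
            raise ValueError(f"pathway {name!r} has no measured proteins")
        means[name] = float(log2m.intensities.loc[present, samples].mean().mean())
    s = pd.Series(means)
    lo, hi = s.min(), s.max()
    if lo == hi:
        warnings.warn("degenerate min-max range; reporting 1.0 for all pathways")
        return pd.Series(1.0, index=s.index)
    return (s - lo) / (hi - lo)
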