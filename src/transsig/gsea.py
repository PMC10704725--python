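"""Self-contained gene set enrichment analysis.

Implements the weighted Kolmogorov-Smirnov-style running enrichment score:
walking a ranked gene list, members of the set ("hits") add
``|r_i|^p / sum_{g in S} |r_g|^p`` and non-members subtract ``1/(N - N_hit)``;
the enrichment score (ES) is the running-sum value of maximal absolute
deviation, signed.  The leading edge ("core enrichment") is the subset of
set members at or before the peak for positive ES (at or after it for
negative ES).  Significance comes from a permutation null — phenotype
relabelling when both groups have at least 7 samples, otherwise random gene
sets of equal size — with

    p_perm = (1 + #{same-sign null with |ES*| >= |ES|}) / (1 + #same-sign)
    NES    = ES / mean(|same-sign null ES|)

Ranking uses the signal-to-noise ratio with the customary variance floor,
or a mean log2 fold change for degenerate group sizes.  All tie-breaks are
deterministic (metric descending, then gene id ascending).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSet, ValidationError

log = logging.getLogger("transsig")

_PERM_CHUNK = 250  # permutations scored per vectorized block


@dataclass
class RankedList:
    """Genes ordered best-to-worst with their ranking metric."""

    genes: np.ndarray
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.metric = np.asarray(self.metric, dtype=float)
        if self.genes.size != self.metric.size:
            raise ValidationError("genes and metric lengths differ")
        if len(set(self.genes)) != self.genes.size:
            raise ValidationError("ranked list contains duplicate genes")
        if np.any(np.diff(self.metric) > 0):
            raise ValidationError("metric must be sorted descending")

    def __len__(self) -> int:
        return int(self.genes.size)


@dataclass
class EnrichmentResult:
    es: float
    running_sum: np.ndarray
    peak_index: int
    leading_edge: list[str]
    nes: float = float("nan")
    p_perm: float = float("nan")
    n_perm: int = 0
    perm_type: str = ""
    null_es: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "es": float(self.es),
            "nes": float(self.nes),
            "p": float(self.p_perm),
            "n_perm": int(self.n_perm),
            "perm_type": self.perm_type,
            "leading_edge": list(self.leading_edge),
            "peak_index": int(self.peak_index),
            "running_sum": [float(v) for v in self.running_sum],
        }


# ---------------------------------------------------------------------------
# ranking


def _group_arrays(expr: pd.DataFrame, labels, positive):
    labels = pd.Series(np.asarray(labels), index=expr.columns)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValidationError(f"need exactly two groups, got {uniq}")
    if positive is None:
        positive = uniq[1]
    if positive not in uniq:
        raise ValidationError(f"positive label {positive!r} not among {uniq}")
    mask1 = (labels == positive).to_numpy()
    return expr.to_numpy(dtype=float), mask1


def _s2n(values: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    """Signal-to-noise per gene with the variance floor
    sigma' = max(sigma, 0.2*|mu|, 0.2) applied per group."""
    x1, x0 = values[:, mask1], values[:, ~mask1]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    s1 = x1.std(axis=1, ddof=1)
    s0 = x0.std(axis=1, ddof=1)
    s1 = np.maximum(s1, np.maximum(0.2 * np.abs(m1), 0.2))
    s0 = np.maximum(s0, np.maximum(0.2 * np.abs(m0), 0.2))
    return (m1 - m0) / (s1 + s0)


def rank_genes(
    expr: pd.DataFrame,
    labels,
    metric: str = "s2n",
    positive=None,
) -> RankedList:
    """Rank genes by a two-group differential metric, best first.

    ``expr`` is genes x samples; ``labels`` aligns with its columns; the
    ``positive`` label names the group whose up-genes rank first (defaults
    to the lexicographically larger label).
    """
    values, mask1 = _group_arrays(expr, labels, positive)
    n1, n0 = int(mask1.sum()), int((~mask1).sum())
    if metric == "s2n":
        if n1 < 2 or n0 < 2:
            raise ValidationError(
                "signal-to-noise needs >=2 samples per group; use "
                "metric='log2fc_mean'"
            )
        scores = _s2n(values, mask1)
    elif metric == "log2fc_mean":
        if n1 < 1 or n0 < 1:
            raise ValidationError("both groups need >=1 sample")
        scores = np.log2(values[:, mask1].mean(axis=1) + 1.0) - np.log2(
            values[:, ~mask1].mean(axis=1) + 1.0
        )
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    genes = np.asarray(expr.index, dtype=object)
    order = np.lexsort((genes, -scores))
    return RankedList(genes=genes[order], metric=scores[order])


# ---------------------------------------------------------------------------
# the running enrichment score


def _running_sum(metric: np.ndarray, hit: np.ndarray, p_weight: float):
    """Running-sum profile for one ranked list and hit mask."""
    n = metric.size
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValidationError("gene set must be a proper nonempty subset")
    w = np.abs(metric) ** p_weight
    nr = w[hit].sum()
    if nr > 0:
        hit_inc = w / nr
    else:  # fully degenerate metric: fall back to equal hit weights
        hit_inc = np.full(n, 1.0 / n_hit)
    inc = np.where(hit, hit_inc, -1.0 / (n - n_hit))
    rs = np.cumsum(inc)
    peak = int(np.argmax(np.abs(rs)))
    return rs, peak


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, p_weight: float = 1.0
) -> EnrichmentResult:
    """ES, running-sum profile, peak position and leading edge for one set."""
    members = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    hit = np.fromiter((g in members for g in ranked.genes), bool, len(ranked))
    if not hit.any():
        raise ValidationError("gene set does not intersect the ranked universe")
    if hit.all():
        raise ValidationError("gene set equals the ranked universe")
    rs, peak = _running_sum(ranked.metric, hit, p_weight)
    es = float(rs[peak])
    if es >= 0:
        le_mask = hit & (np.arange(len(ranked)) <= peak)
    else:
        le_mask = hit & (np.arange(len(ranked)) >= peak)
    return EnrichmentResult(
        es=es,
        running_sum=rs,
        peak_index=peak,
        leading_edge=[str(g) for g in ranked.genes[le_mask]],
    )


def _es_batch(metric_cols: np.ndarray, hit_cols: np.ndarray, p_weight: float):
    """ES for many (metric, hit) columns at once.  Shapes (N, P)."""
    n, _ = metric_cols.shape
    w = np.abs(metric_cols) ** p_weight
    nr = np.sum(w * hit_cols, axis=0)
    n_hit = hit_cols.sum(axis=0)
    # degenerate all-zero-metric columns: equal hit weights
    bad = nr <= 0
    hit_inc = w / np.where(bad, 1.0, nr)[None, :]
    if bad.any():
        hit_inc[:, bad] = 1.0 / np.maximum(n_hit[bad], 1)[None, :]
    inc = np.where(hit_cols, hit_inc, -1.0 / (n - n_hit)[None, :])
    rs = np.cumsum(inc, axis=0)
    peaks = np.argmax(np.abs(rs), axis=0)
    return rs[peaks, np.arange(rs.shape[1])]


# ---------------------------------------------------------------------------
# permutation test


def gsea_test(
    expr: pd.DataFrame,
    labels,
    gene_set: GeneSet,
    n_perm: int = 1000,
    perm_type: str = "auto",
    seed=None,
    metric: str = "s2n",
    positive=None,
    p_weight: float = 1.0,
    min_phenotype_n: int = 7,
) -> EnrichmentResult:
    """Permutation GSEA of one gene set against a two-group comparison."""
    if n_perm < 10:
        raise ValidationError("n_perm must be at least 10")
    values, mask1 = _group_arrays(expr, labels, positive)
    n1, n0 = int(mask1.sum()), int((~mask1).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both groups must be nonempty")
    if perm_type == "auto":
        if n1 >= min_phenotype_n and n0 >= min_phenotype_n:
            perm_type = "phenotype"
        else:
            perm_type = "gene"
            log.info(
                "group sizes (%d, %d) below %d: switching to gene permutation",
                n1, n0, min_phenotype_n,
            )
    if perm_type not in ("phenotype", "gene"):
        raise ValidationError(f"unknown perm_type {perm_type!r}")

    ranked = rank_genes(expr, labels, metric=metric, positive=positive)
    obs = enrichment_score(ranked, gene_set, p_weight=p_weight)
    members = set(gene_set.genes if isinstance(gene_set, GeneSet) else gene_set)
    n_genes = len(ranked)
    n_hit = sum(1 for g in ranked.genes if g in members)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    genes = np.asarray(expr.index, dtype=object)
    member_mask_unsorted = np.fromiter((g in members for g in genes), bool, genes.size)

    done = 0
    while done < n_perm:
        block = min(_PERM_CHUNK, n_perm - done)
        if perm_type == "phenotype":
            perms = np.stack([rng.permutation(mask1) for _ in range(block)], axis=1)
            es = _phenotype_block_es(
                values, perms, member_mask_unsorted, metric, p_weight
            )
        else:
            hit_cols = np.zeros((n_genes, block), dtype=bool)
            for b in range(block):
                pick = rng.choice(n_genes, size=n_hit, replace=False)
                hit_cols[pick, b] = True
            metric_cols = np.repeat(ranked.metric[:, None], block, axis=1)
            es = _es_batch(metric_cols, hit_cols, p_weight)
        null[done : done + block] = es
        done += block

    same_sign = null >= 0 if obs.es >= 0 else null < 0
    n_same = int(same_sign.sum())
    n_extreme = int(np.sum(np.abs(null[same_sign]) >= abs(obs.es)))
    p = (1 + n_extreme) / (1 + n_same)
    denom = np.mean(np.abs(null[same_sign])) if n_same else np.nan
    nes = obs.es / denom if denom and denom > 0 else float("nan")
    obs.p_perm = float(p)
    obs.nes = float(nes)
    obs.n_perm = n_perm
    obs.perm_type = perm_type
    obs.null_es = null
    return obs


def _phenotype_block_es(values, perms, member_mask, metric, p_weight):
    """ES for a block of phenotype permutations (columns of ``perms``)."""
    n_samp, block = values.shape[1], perms.shape[1]
    P1 = perms.astype(float)
    P0 = 1.0 - P1
    n1 = P1.sum(axis=0)
    n0 = P0.sum(axis=0)
    if metric == "s2n":
        sum1 = values @ P1
        sum0 = values @ P0
        sq1 = (values**2) @ P1
        sq0 = (values**2) @ P0
        m1, m0 = sum1 / n1, sum0 / n0
        var1 = (sq1 / n1 - m1**2) * (n1 / (n1 - 1.0))
        var0 = (sq0 / n0 - m0**2) * (n0 / (n0 - 1.0))
        s1 = np.sqrt(np.maximum(var1, 0.0))
        s0 = np.sqrt(np.maximum(var0, 0.0))
        s1 = np.maximum(s1, np.maximum(0.2 * np.abs(m1), 0.2))
        s0 = np.maximum(s0, np.maximum(0.2 * np.abs(m0), 0.2))
        scores = (m1 - m0) / (s1 + s0)
    elif metric == "log2fc_mean":
        scores = np.log2(values @ P1 / n1 + 1.0) - np.log2(values @ P0 / n0 + 1.0)
    else:  # pragma: no cover - guarded upstream
        raise ValidationError(f"unknown metric {metric!r}")
    order = np.argsort(-scores, axis=0, kind="stable")
    metric_cols = np.take_along_axis(scores, order, axis=0)
    hit_cols = member_mask[order]
    return _es_batch(metric_cols, hit_cols, p_weight)
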