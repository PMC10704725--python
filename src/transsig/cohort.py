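"""Cohort-level application of the signature.

Two analyses mirror the clinical arm of the pipeline: a permutation GSEA of
the signature between disease and control transcriptomes (phenotype
permutation whenever both groups are large enough), and a comparison of
clinical phenotypes between the signature-high and signature-low score
quartiles using the Mann-Whitney U test.

The U statistic follows the convention U = #{(i,j): x_i > y_j} + ties/2.
Exact two-sided p-values (min(1, 2 x one-sided)) come from the full null
distribution of U — the rank-distribution recurrence without ties, literal
enumeration over group assignments with ties — switching to the normal
approximation with tie and continuity corrections for large samples.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .gsea import EnrichmentResult, gsea_test
from .io import GeneSet, ValidationError
from .signature import Signature
from .simulate import CohortTable

log = logging.getLogger("transsig")

EXACT_LIMIT = 400          # use the exact null when n_x * n_y <= this
_TIE_ENUM_LIMIT = 200_000  # cap on C(n+m, n) for literal tie enumeration


def cohort_enrichment(
    cohort: CohortTable,
    signature,
    gsea_params: dict | None = None,
    seed=None,
    transform: str = "log2p1",
) -> EnrichmentResult:
    """Permutation GSEA of the signature, disease vs control.

    Expression is log2(x+1)-transformed before ranking by default (matching
    the scoring convention); pass ``transform='none'`` for data already on a
    log scale.  The signal-to-noise ranking metric is poorly behaved on raw
    linear intensities, so the transform is applied up front rather than
    inside the GSEA machinery.
    """
    genes = signature.genes if isinstance(signature, Signature) else list(signature)
    if not set(genes) & set(cohort.expr.index):
        raise ValidationError("signature does not intersect the cohort genes")
    groups = set(cohort.labels)
    if len(groups) < 2:
        raise ValidationError("cohort labels are all identical")
    if transform == "log2p1":
        expr = np.log2(cohort.expr + 1.0)
    elif transform == "none":
        expr = cohort.expr
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    params = dict(gsea_params or {})
    params.setdefault("positive", "asthma" if "asthma" in groups else None)
    gene_set = GeneSet(name="signature", genes=list(genes))
    return gsea_test(expr, cohort.labels, gene_set, seed=seed, **params)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_null_pmf(n: int, m: int) -> np.ndarray:
    """Null pmf of U over {0, ..., n*m} for tie-free samples (DP recurrence)."""
    # DP over (i, j) remaining group sizes: peel off the largest pooled
    # value; if it is an x it contributes j to U, if a y it contributes 0.
    table = {(0, 0): np.array([1.0])}
    for i in range(n + 1):
        for j in range(m + 1):
            if (i, j) == (0, 0):
                continue
            size = i * j + 1
            acc = np.zeros(size)
            if i > 0:  # largest remaining value is an x: adds j to U
                prev = table[(i - 1, j)]
                acc[j : j + prev.size] += prev
            if j > 0:  # largest remaining value is a y: adds 0
                prev = table[(i, j - 1)]
                acc[: prev.size] += prev
            table[(i, j)] = acc
    pmf = table[(n, m)]
    return pmf / pmf.sum()


def _exact_p_no_ties(u: float, n: int, m: int) -> float:
    pmf = _exact_null_pmf(n, m)
    k = int(round(u))
    lower = pmf[: k + 1].sum()
    upper = pmf[k:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def _exact_p_with_ties(x: np.ndarray, y: np.ndarray, u_obs: float) -> float | None:
    """Enumerate all assignments of the pooled values to the x-group."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    if comb(n + m, n) > _TIE_ENUM_LIMIT:
        return None
    idx = range(n + m)
    lower = upper = total = 0
    for pick in combinations(idx, n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(pick)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if u <= u_obs + 1e-12:
            lower += 1
        if u >= u_obs - 1e-12:
            upper += 1
    return float(min(1.0, 2.0 * min(lower, upper) / total))


def _normal_p(x: np.ndarray, y: np.ndarray, u: float) -> float:
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    N = n + m
    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1.0)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1.0) - tie_term)
    if var <= 0:
        return 1.0
    from scipy.stats import norm

    z = (abs(u - mu) - 0.5) / np.sqrt(var)  # continuity-corrected
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))


def mann_whitney(x, y, mode: str = "auto", exact_limit: int = EXACT_LIMIT):
    """Mann-Whitney U with exact small-sample p-values.

    Returns ``(U, p)`` with U the statistic of ``x`` and p two-sided.
    ``mode`` is ``auto`` (exact when ``len(x)*len(y) <= exact_limit``),
    ``exact`` or ``normal``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown mode {mode!r}")
    u = _u_statistic(x, y)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    want_exact = mode == "exact" or (mode == "auto" and x.size * y.size <= exact_limit)
    if want_exact:
        if not has_ties:
            return u, _exact_p_no_ties(u, x.size, y.size)
        p = _exact_p_with_ties(x, y, u)
        if p is not None:
            log.info("ties present: exact p by enumeration over assignments")
            return u, p
        log.info("ties present and enumeration infeasible: normal approximation")
    return u, _normal_p(x, y, u)


# ---------------------------------------------------------------------------
# the Table-1-shaped comparison


def compare_phenotypes(
    cohort: CohortTable,
    scores: pd.DataFrame,
    strat: pd.DataFrame,
    mode: str = "auto",
) -> pd.DataFrame:
    """High-vs-low-quartile phenotype comparison.

    The first row compares the signature score itself; subsequent rows
    follow the phenotype-table column order.  Missing values are dropped
    per phenotype; a phenotype entirely missing in one group gets NaN for U
    and p.  Binary phenotypes ride the same U test on their 0/1 coding.
    """
    high = strat.index[strat["high"]]
    low = strat.index[strat["low"]]
    if set(high) & set(low):
        raise ValidationError("high and low masks overlap")
    if len(high) < 2 or len(low) < 2:
        raise ValidationError("each of high/low needs at least 2 samples")

    pheno = cohort.phenotypes
    rows = []

    def _row(name, hi_vals, lo_vals):
        hi = np.asarray(hi_vals, dtype=float)
        lo = np.asarray(lo_vals, dtype=float)
        hi = hi[~np.isnan(hi)]
        lo = lo[~np.isnan(lo)]
        rec = {
            "phenotype": name,
            "n_high": hi.size,
            "n_low": lo.size,
            "mean_high": hi.mean() if hi.size else np.nan,
            "sd_high": hi.std(ddof=1) if hi.size > 1 else np.nan,
            "mean_low": lo.mean() if lo.size else np.nan,
            "sd_low": lo.std(ddof=1) if lo.size > 1 else np.nan,
        }
        if hi.size and lo.size:
            u, p = mann_whitney(hi, lo, mode=mode)
            rec["U"], rec["p"] = u, p
        else:
            rec["U"], rec["p"] = np.nan, np.nan
            log.warning("phenotype %r entirely missing in one group", name)
        return rec

    s = scores["score"]
    rows.append(_row("signature_score", s.loc[high], s.loc[low]))
    hi_idx = [smp for smp in high if smp in pheno.index]
    lo_idx = [smp for smp in low if smp in pheno.index]
    for col in pheno.columns:
        if not pd.api.types.is_numeric_dtype(pheno[col]):
            coded = pheno[col].astype("category").cat.codes.replace(-1, np.nan)
            hi_vals, lo_vals = coded.loc[hi_idx], coded.loc[lo_idx]
        else:
            hi_vals, lo_vals = pheno.loc[hi_idx, col], pheno.loc[lo_idx, col]
        rows.append(_row(col, hi_vals, lo_vals))
    return pd.DataFrame(rows)
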