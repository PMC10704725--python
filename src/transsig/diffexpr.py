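"""Donor-adjusted negative-binomial differential expression.

The stage mirrors the standard bulk RNA-seq Wald workflow: median-of-ratios
size factors, a method-of-moments dispersion estimate shrunk toward a fitted
mean-dispersion trend, and a per-gene NB generalized linear model with log
link fitted by iteratively reweighted least squares.  The design is always
donor indicators plus the condition term(s) of interest, so the donor
pairing of the stimulation experiment (each donor contributes one sample per
condition) is absorbed as fixed effects.

Per contrast the model for gene g, sample j is

    K_gj ~ NB(mu_gj, alpha_g),   log mu_gj = log s_j + x_j' beta_g

with s_j the size factor.  The Wald statistic is the condition coefficient
over its asymptotic standard error; p-values are two-sided normal, and FDR
control is Benjamini-Hochberg across all tested genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountExperiment, ValidationError

log = logging.getLogger("transsig")

LN2 = np.log(2.0)

#: IRLS controls — deliberately conservative: non-convergence flags the gene
#: and forces p=1 rather than reporting an unstable estimate.
IRLS_MAX_ITER = 100
IRLS_TOL = 1e-8
_ETA_CLIP = 30.0


class SingularDesignError(ValidationError):
    """The requested design matrix is rank-deficient (confounded)."""


# ---------------------------------------------------------------------------
# normalization and dispersion


def size_factors(exp: CountExperiment) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with a nonzero count in every sample contribute (the usual
    reference-gene convention); if no such gene exists the input is too
    sparse for this estimator and an error is raised.
    """
    counts = exp.counts.astype(float)
    allpos = np.all(counts > 0, axis=1)
    if not allpos.any():
        raise ValidationError(
            "no gene has nonzero counts in all samples; a pseudo-reference "
            "fallback is not implemented"
        )
    ref = counts[allpos]
    log_geo = np.mean(np.log(ref), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geo, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def _design_matrix(design: pd.DataFrame, condition_terms: pd.DataFrame):
    """Intercept + donor indicators (reference donor dropped) + given terms."""
    donors = pd.get_dummies(design["donor"], prefix="donor", drop_first=True)
    X = pd.concat(
        [
            pd.Series(1.0, index=design.index, name="intercept"),
            donors.astype(float),
            condition_terms.astype(float),
        ],
        axis=1,
    )
    return X


def estimate_dispersion(
    exp: CountExperiment,
    factors: np.ndarray,
    trend_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-gene dispersion: method of moments shrunk toward a fitted trend.

    Normalized counts are projected onto the donor+condition design; the
    residual variance s^2 and the gene mean mu give the raw estimate
    ``alpha_mom = max(0, (s^2 - mu) / mu^2)``.  A hyperbolic trend
    ``alpha(mu) = a0/mu + a1`` is least-squares fitted across genes and the
    final value is ``(1-w) * alpha_mom + w * trend(mu)``.  All-zero genes get
    the trend value and are flagged.
    """
    counts = exp.counts.astype(float)
    y = counts / factors[None, :]
    cond = exp.condition_labels()
    groups = pd.get_dummies(cond, prefix="cond", drop_first=True)
    X = _design_matrix(exp.design, groups).to_numpy()
    n, p = X.shape
    if n <= p:
        raise ValidationError("not enough samples to estimate dispersion")
    # residuals from one shared projection
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    resid = y.T - X @ beta
    s2 = np.sum(resid**2, axis=0) / (n - p)
    mu = y.mean(axis=1)
    allzero = mu <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(allzero, 0.0, np.maximum(0.0, (s2 - mu) / mu**2))

    use = ~allzero & (mu > 1.0)
    if use.sum() >= 10:
        A = np.column_stack([1.0 / mu[use], np.ones(use.sum())])
        coef, *_ = np.linalg.lstsq(A, alpha_mom[use], rcond=None)
        a0, a1 = np.maximum(coef, 1e-8)
    else:  # too few informative genes: flat fallback trend
        a0, a1 = 1e-8, max(np.median(alpha_mom[~allzero], initial=0.01), 1e-8)
    with np.errstate(divide="ignore"):
        trend = np.where(allzero, a1, a0 / np.maximum(mu, 1e-8) + a1)
    alpha = np.where(
        allzero, trend, (1 - trend_weight) * alpha_mom + trend_weight * trend
    )
    alpha = np.maximum(alpha, 1e-8)
    out = pd.DataFrame(
        {
            "alpha": alpha,
            "alpha_mom": alpha_mom,
            "trend": trend,
            "mean": mu,
            "from_trend_only": allzero,
        },
        index=pd.Index(exp.genes, name="gene"),
    )
    out.attrs["trend_coef"] = (float(a0), float(a1))
    return out


# ---------------------------------------------------------------------------
# the NB GLM


def _irls_batch(counts, X, offset, alpha):
    """Batched IRLS for NB log-link GLMs sharing one design matrix.

    counts: (G, n); X: (n, p); offset: (n,); alpha: (G,).
    Returns (beta (G,p), se (G,p), converged (G,)).
    """
    G, n = counts.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(np.maximum(counts.mean(axis=1), 0.1)) - offset.mean()
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    for _ in range(IRLS_MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        b = beta[idx]
        eta = np.clip(b @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[idx, None] * mu)
        z = (eta - offset[None, :]) + (counts[idx] - mu) / mu
        A = np.einsum("gn,ni,nj->gij", w, X, X)
        A[:, np.arange(p), np.arange(p)] += 1e-10
        rhs = np.einsum("gn,ni->gi", w * z, X)
        try:
            b_new = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            b_new = np.stack(
                [np.linalg.lstsq(Ai, ri, rcond=None)[0] for Ai, ri in zip(A, rhs)]
            )
        delta = np.max(np.abs(b_new - b), axis=1)
        beta[idx] = b_new
        done = delta < IRLS_TOL
        converged[idx[done]] = True
        active[idx[done]] = False
    # covariance at the final estimate
    eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("gn,ni,nj->gij", w, X, X)
    A[:, np.arange(p), np.arange(p)] += 1e-10
    cov = np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return beta, se, converged


def _check_design(X: pd.DataFrame) -> None:
    M = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise SingularDesignError(
            f"design matrix is singular (columns: {list(X.columns)}); "
            "a condition is confounded with donor or duplicated"
        )


def _wald_table(genes, base_mean, beta_coef, se_coef, converged, contrast):
    log2fc = beta_coef / LN2
    se = se_coef / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_coef > 0, beta_coef / se_coef, 0.0)
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    wald_p = np.where(converged, wald_p, 1.0)
    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_p": wald_p,
            "q": bh_adjust(wald_p),
            "converged": converged,
        },
        index=pd.Index(genes, name="gene"),
    )
    res.attrs["contrast"] = contrast
    return res


def fit_de(
    exp: CountExperiment,
    contrast: tuple[str, str],
    alpha,
    factors: np.ndarray,
) -> pd.DataFrame:
    """Wald test of ``contrast = (numerator, denominator)`` condition labels.

    Genes with zero counts in every sample of both conditions are dropped
    (and logged).  Returns a gene-indexed frame with columns base_mean,
    log2fc, se, wald_p, q, converged; ``attrs['contrast']`` holds the label.
    """
    num, den = contrast
    if num == den:
        raise SingularDesignError(f"contrast of {num!r} against itself is singular")
    cond = exp.condition_labels()
    for c in (num, den):
        if not (cond == c).any():
            raise ValidationError(f"condition {c!r} has no samples")
    keep = cond.isin([num, den]).to_numpy()
    sub = exp.subset_samples(keep)
    sub_cond = cond[keep]
    tab = pd.crosstab(sub.design["donor"], sub_cond)
    if (tab.to_numpy() > 1).any():
        bad = list(tab.index[(tab > 1).any(axis=1)])
        raise ValidationError(
            f"donor(s) {bad} contribute more than one sample to a contrast condition"
        )
    sf = np.asarray(factors)[keep]
    alpha_vec = np.asarray(alpha["alpha"] if isinstance(alpha, pd.DataFrame) else alpha)

    term = pd.DataFrame({f"cond_{num}": (sub_cond == num).astype(float)})
    term.index = sub.design.index
    X = _design_matrix(sub.design, term)
    _check_design(X)

    nonzero = sub.counts.sum(axis=1) > 0
    if (~nonzero).any():
        log.info(
            "dropping %d gene(s) with all-zero counts in contrast %s vs %s",
            int((~nonzero).sum()), num, den,
        )
    counts = sub.counts[nonzero].astype(float)
    genes = [g for g, k in zip(exp.genes, nonzero) if k]
    beta, se, convg = _irls_batch(
        counts, X.to_numpy(dtype=float), np.log(sf), alpha_vec[nonzero]
    )
    j = X.columns.get_loc(f"cond_{num}")
    base_mean = (counts / sf[None, :]).mean(axis=1)
    res = _wald_table(genes, base_mean, beta[:, j], se[:, j], convg, f"{num}:{den}")
    res.attrs["n_dropped_allzero"] = int((~nonzero).sum())
    return res


def interaction_test(
    exp: CountExperiment, alpha, factors: np.ndarray
) -> pd.DataFrame:
    """Wald test of the IL-6 x sIL-6Ra interaction over the 2x2 factorial.

    Uses only inhibitor-free samples; all four cells (+/-IL-6 x +/-sIL-6Ra)
    must be present.  Design: donor + il6 + sil6r + il6:sil6r.
    """
    keep = (exp.design["inhibitor"] == "none").to_numpy()
    sub = exp.subset_samples(keep)
    cells = set(zip(sub.design["il6"], sub.design["sil6r"]))
    missing = [
        f"il6={a}, sil6r={b}"
        for a, b in [(False, False), (True, False), (False, True), (True, True)]
        if (a, b) not in cells
    ]
    if missing:
        raise ValidationError(f"missing factorial cell(s): {missing}")
    term = pd.DataFrame(
        {
            "il6": sub.design["il6"].astype(float),
            "sil6r": sub.design["sil6r"].astype(float),
            "il6:sil6r": (sub.design["il6"] & sub.design["sil6r"]).astype(float),
        },
        index=sub.design.index,
    )
    X = _design_matrix(sub.design, term)
    _check_design(X)
    sf = np.asarray(factors)[keep]
    alpha_vec = np.asarray(alpha["alpha"] if isinstance(alpha, pd.DataFrame) else alpha)
    nonzero = sub.counts.sum(axis=1) > 0
    counts = sub.counts[nonzero].astype(float)
    genes = [g for g, k in zip(exp.genes, nonzero) if k]
    beta, se, convg = _irls_batch(
        counts, X.to_numpy(dtype=float), np.log(sf), alpha_vec[nonzero]
    )
    j = X.columns.get_loc("il6:sil6r")
    base_mean = (counts / sf[None, :]).mean(axis=1)
    return _wald_table(genes, base_mean, beta[:, j], se[:, j], convg, "il6:sil6r")


# ---------------------------------------------------------------------------
# multiple testing and the amplification regression


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped
    at 1, returned in the original order (stable under ties)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class AmplificationFit:
    """OLS of trans log2FC on classic log2FC over the significant-gene mask."""

    slope: float
    intercept: float
    n_genes: int
    gene_mask: pd.Series

    def predict(self, x):
        return self.slope * np.asarray(x) + self.intercept


def amplification_fit(
    de_classic: pd.DataFrame,
    de_trans: pd.DataFrame,
    q_threshold: float = 0.05,
    mask: str = "union",
) -> AmplificationFit:
    """Fit the classic-to-trans amplification line.

    ``mask`` selects which genes enter the regression: ``union`` (significant
    in either contrast; default), ``intersection``, ``trans`` or ``classic``.
    """
    common = de_classic.index.intersection(de_trans.index)
    if len(common) == 0:
        raise ValidationError("no common genes between the two results")
    c = de_classic.loc[common]
    t = de_trans.loc[common]
    sig_c = c["q"] < q_threshold
    sig_t = t["q"] < q_threshold
    if mask == "union":
        m = sig_c | sig_t
    elif mask == "intersection":
        m = sig_c & sig_t
    elif mask == "classic":
        m = sig_c
    elif mask == "trans":
        m = sig_t
    else:
        raise ValidationError(f"unknown mask {mask!r}")
    if int(m.sum()) < 2:
        raise ValidationError(
            f"only {int(m.sum())} gene(s) pass the {mask} mask at "
            f"q<{q_threshold}; need at least 2"
        )
    x = c.loc[m, "log2fc"].to_numpy()
    y = t.loc[m, "log2fc"].to_numpy()
    fit = stats.linregress(x, y)
    return AmplificationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_genes=int(m.sum()),
        gene_mask=m,
    )
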