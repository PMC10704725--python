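"""Three-filter signature derivation, signature scoring, and stratification.

The derivation distills the significantly up-regulated genes of the
IL-6 + sIL-6Ra (trans-signaling) contrast into a compact signature via three
successive filters:

1. **Baseline quartile + top 5%** — significant genes are binned into
   quartiles of baseline (unstimulated) expression; within each quartile the
   top 5% by fold change become candidates.  Only candidates from the
   highest-baseline quartile (Q4) go forward, which avoids signature genes
   that are too lowly expressed to assay reliably.
2. **Core enrichment** — the Q4 candidate set must be in the GSEA leading
   edge ("core enrichment") of every provided validation dataset.
3. **Th2 exclusion** — genes known to respond to the type-2 cytokines IL-4
   and IL-13 are removed so the signature does not double as a Th2 readout.

Scoring a cohort sample is the unweighted mean of per-gene z-scores of
log2(x+1) expression (population standard deviation across the cohort);
patients are then stratified into rank-based score quartiles, the extreme
quartiles forming the signature-high and signature-low groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import size_factors
from .gsea import RankedList, enrichment_score, gsea_test
from .io import CountExperiment, GeneSet, ValidationError

log = logging.getLogger("transsig")


@dataclass
class Signature:
    """Ordered signature genes plus per-candidate provenance.

    ``provenance`` is indexed by candidate gene with columns ``quartile``,
    ``log2fc``, ``passed_top5``, ``core_in`` (comma-joined dataset names),
    ``th2_flag`` and ``final``.
    """

    genes: list[str]
    provenance: pd.DataFrame
    filters_applied: list[str] = field(
        default_factory=lambda: ["quartile_top5", "core_enrichment", "th2_exclusion"]
    )


def assign_quartiles(
    de_trans: pd.DataFrame,
    baseline: pd.Series | None = None,
    q_threshold: float = 0.05,
    direction: str = "up",
) -> pd.DataFrame:
    """Bin significant genes into baseline-expression quartiles.

    Restricts to genes with ``q < q_threshold`` (and ``log2fc > 0`` when
    ``direction='up'``), ranks them by baseline ascending (gene-id
    tie-break), and splits into four rank bins; when the count is not
    divisible by 4 the remainder goes to the higher quartiles.  Quartile 4
    holds the highest-baseline genes.
    """
    if direction not in ("up", "abs"):
        raise ValidationError(f"unknown direction {direction!r}")
    sig = de_trans["q"] < q_threshold
    if direction == "up":
        sig &= de_trans["log2fc"] > 0
    table = de_trans.loc[sig, ["base_mean", "log2fc"]].copy()
    base = baseline.loc[table.index] if baseline is not None else table["base_mean"]
    table["baseline"] = base
    n = len(table)
    if n < 4:
        raise ValidationError(
            f"only {n} gene(s) qualify at q<{q_threshold}; need at least 4"
        )
    order = sorted(table.index, key=lambda g: (table.at[g, "baseline"], g))
    base_size, r = divmod(n, 4)
    sizes = [base_size + (1 if q > 4 - r else 0) for q in (1, 2, 3, 4)]
    quart = np.repeat([1, 2, 3, 4], sizes)
    table = table.loc[order]
    table["quartile"] = quart
    log.info("quartile assignment: %d significant genes, sizes %s", n, sizes)
    return table[["baseline", "quartile", "log2fc"]]


def select_candidates(
    assignment: pd.DataFrame, top_frac: float = 0.05
) -> dict[int, list[str]]:
    """Top fraction of each quartile by fold change (ceiling count)."""
    if not 0.0 < top_frac <= 1.0:
        raise ValidationError("top_frac must lie in (0, 1]")
    out: dict[int, list[str]] = {}
    for q in (1, 2, 3, 4):
        block = assignment[assignment["quartile"] == q]
        k = math.ceil(top_frac * len(block))
        ranked = sorted(block.index, key=lambda g: (-block.at[g, "log2fc"], g))
        out[q] = ranked[:k]
    return out


def core_enrichment_filter(
    candidates: list[str],
    datasets: list,
    gsea_params: dict | None = None,
    seed=None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Keep candidates core-enriched (leading edge) in every dataset.

    Each dataset is either a ``RankedList`` or an ``(expr, labels[, positive])``
    tuple; in the latter case a permutation GSEA of the candidate set is run
    and its leading edge used.  Returns the surviving candidates (input
    order) and a per-gene map of the dataset names where it was core.
    """
    if not candidates:
        raise ValidationError("candidate list is empty")
    if not datasets:
        raise ValidationError("at least one validation dataset is required")
    params = dict(gsea_params or {})
    cand_set = GeneSet(name="candidates", genes=list(candidates))
    core_in: dict[str, list[str]] = {g: [] for g in candidates}
    names = []
    for i, ds in enumerate(datasets):
        name = f"dataset{i + 1}"
        names.append(name)
        if isinstance(ds, RankedList):
            universe = set(ds.genes)
            missing = [g for g in candidates if g not in universe]
            if missing:
                raise ValidationError(f"{name} lacks candidate gene(s): {missing}")
            res = enrichment_score(ds, cand_set,
                                   p_weight=params.get("p_weight", 1.0))
        else:
            expr, labels, *rest = ds
            universe = set(expr.index)
            missing = [g for g in candidates if g not in universe]
            if missing:
                raise ValidationError(f"{name} lacks candidate gene(s): {missing}")
            res = gsea_test(
                expr, labels, cand_set,
                positive=rest[0] if rest else None,
                seed=seed,
                **params,
            )
        # core enrichment means positive enrichment: a negative ES has no
        # leading edge in the enrichment sense, so nothing survives it
        if res.es < 0:
            log.warning("%s: negative enrichment (es=%.3f); no candidate is "
                        "core-enriched there", name, res.es)
            le = set()
        else:
            le = set(res.leading_edge)
        for g in candidates:
            if g in le:
                core_in[g].append(name)
    survivors = [g for g in candidates if len(core_in[g]) == len(datasets)]
    if not survivors:
        log.warning("no candidate is core-enriched in all %d dataset(s)",
                    len(datasets))
    return survivors, core_in


def exclude_th2(genes: list[str], th2: GeneSet) -> tuple[list[str], list[str]]:
    """Order-preserving removal of Th2-sensitive genes."""
    th2_set = set(th2.genes if isinstance(th2, GeneSet) else th2)
    kept = [g for g in genes if g not in th2_set]
    flagged = [g for g in genes if g in th2_set]
    if flagged:
        log.info("Th2 exclusion removed %d gene(s): %s", len(flagged), flagged)
    if not kept:
        log.warning("Th2 exclusion removed every candidate")
    return kept, flagged


def derive_signature(
    de_trans: pd.DataFrame,
    counts: CountExperiment | None = None,
    datasets: list | None = None,
    th2: GeneSet | None = None,
    baseline: pd.Series | None = None,
    q_threshold: float = 0.05,
    direction: str = "up",
    top_frac: float = 0.05,
    gsea_params: dict | None = None,
    seed=None,
) -> Signature:
    """Run the full three-filter derivation and emit provenance.

    Baseline expression is the mean size-factor-normalized count over
    control samples when ``counts`` is given, else an explicit ``baseline``
    series, else the contrast's ``base_mean``.
    """
    if baseline is None and counts is not None:
        factors = size_factors(counts)
        ctrl = (counts.condition_labels() == "control").to_numpy()
        norm = counts.counts[:, ctrl].astype(float) / factors[ctrl][None, :]
        baseline = pd.Series(norm.mean(axis=1), index=counts.genes)
    assignment = assign_quartiles(
        de_trans, baseline=baseline, q_threshold=q_threshold, direction=direction
    )
    candidates = select_candidates(assignment, top_frac=top_frac)
    q4 = candidates[4]
    if datasets:
        survivors, core_in = core_enrichment_filter(
            q4, datasets, gsea_params=gsea_params, seed=seed
        )
        n_datasets = len(datasets)
    else:
        survivors, core_in = list(q4), {g: [] for g in q4}
        n_datasets = 0
    final, flagged = exclude_th2(survivors, th2) if th2 is not None else (survivors, [])
    final = sorted(final, key=lambda g: (-assignment.at[g, "log2fc"], g))

    all_cands = [g for q in (4, 3, 2, 1) for g in candidates[q]]
    prov = pd.DataFrame(
        {
            "quartile": [assignment.at[g, "quartile"] for g in all_cands],
            "log2fc": [assignment.at[g, "log2fc"] for g in all_cands],
            "passed_top5": True,
            "core_in": [",".join(core_in.get(g, [])) for g in all_cands],
            "th2_flag": [g in set(flagged) for g in all_cands],
            "final": [g in set(final) for g in all_cands],
        },
        index=pd.Index(all_cands, name="gene"),
    )
    log.info(
        "signature derivation: %d Q4 candidates -> %d core-enriched -> %d final",
        len(q4), len(survivors), len(final),
    )
    sig = Signature(genes=final, provenance=prov)
    sig.provenance.attrs["n_datasets"] = n_datasets
    return sig


# ---------------------------------------------------------------------------
# scoring and stratification


def score_samples(
    expr: pd.DataFrame,
    signature,
    transform: str = "log2p1",
) -> pd.DataFrame:
    """Per-sample signature Z-score over a cohort expression matrix.

    Each available signature gene is z-scored across all cohort samples
    (population standard deviation); a sample's score is the mean z over
    those genes.  Zero-variance genes are dropped with a warning.
    """
    genes = signature.genes if isinstance(signature, Signature) else list(signature)
    if expr.shape[1] < 2:
        raise ValidationError("scoring needs at least 2 samples")
    present = [g for g in genes if g in expr.index]
    if not present:
        raise ValidationError("no signature gene present in the expression matrix")
    x = expr.loc[present].to_numpy(dtype=float)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform != "none":
        raise ValidationError(f"unknown transform {transform!r}")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        dropped = [g for g, k in zip(present, keep) if not k]
        log.warning("dropping zero-variance signature gene(s): %s", dropped)
    if not keep.any():
        raise ValidationError("all signature genes have zero variance")
    z = (x[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(
        {"score": z.mean(axis=0), "genes_used": int(keep.sum())},
        index=pd.Index(expr.columns, name="sample"),
    )


def stratify_quartiles(
    scores: pd.DataFrame | pd.Series,
    restrict_to=None,
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Rank-based score quartiles with high/low masks.

    When the sample count is not divisible by 4 the remainder is absorbed by
    the inner quartiles, so the extreme (high/low) quartiles are the smaller
    ones.  Ties are broken by sample id.  ``restrict_to`` limits the
    stratification to one disease label (requires ``labels``).
    """
    s = scores["score"] if isinstance(scores, pd.DataFrame) else scores
    if restrict_to is not None:
        if labels is None:
            raise ValidationError("restrict_to requires labels")
        s = s[labels.loc[s.index] == restrict_to]
    n = len(s)
    if n < 4:
        raise ValidationError(f"need at least 4 samples to stratify, got {n}")
    order = sorted(s.index, key=lambda smp: (s.loc[smp], smp))
    base, r = divmod(n, 4)
    sizes = [base, base + (r + 1) // 2, base + r // 2, base]
    quart = np.repeat([1, 2, 3, 4], sizes)
    out = pd.DataFrame({"score": s.loc[order], "quartile": quart},
                       index=pd.Index(order, name="sample"))
    out["high"] = out["quartile"] == 4
    out["low"] = out["quartile"] == 1
    return out.loc[sorted(out.index)]
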