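"""Synthetic stimulation experiments and patient cohorts with ground truth.

The stimulation simulator emulates the study design the pipeline targets:
six donors of differentiated airway epithelial cells, each measured under
control, IL-6, sIL-6Ra, IL-6 + sIL-6Ra, and the combination under two
IL-6-pathway inhibitors.  Counts are negative binomial with a per-gene
log-normal baseline, log-additive donor offsets, and a hyperbolic
mean-dispersion trend alpha(mu) = a0/mu + a1.  Condition effects encode the
trans-amplification model: a set of classic IL-6-responsive genes whose
log2 fold change under IL-6 + sIL-6Ra is the classic effect times a single
amplification multiplier (default 1.2); an optional extra set responds only
to the combination; sIL-6Ra alone is exactly null; inhibitors scale the
whole combination effect by (1 - blockade).

The cohort simulator produces a normalized (log-normal) expression matrix
for an asthma group and a control group in which a configurable fraction of
asthma patients carries an elevated planted signature, plus a clinical
phenotype table where sputum eosinophils decrease log-linearly with the
planted signature elevation and the remaining phenotypes are independent
noise.  Both simulators return the generating truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CONDITIONS,
    CountExperiment,
    GeneSet,
    ValidationError,
)

DEFAULT_SIGNATURE = ["S100A9", "SERPINB1", "LRG1", "IFITM3", "CLCA2"]

#: condition label -> (il6, sil6r, inhibitor) design flags
_CONDITION_FLAGS = {
    "control": (False, False, "none"),
    "il6": (True, False, "none"),
    "sil6r": (False, True, "none"),
    "il6_sil6r": (True, True, "none"),
    "il6_sil6r_olamkicept": (True, True, "olamkicept"),
    "il6_sil6r_tocilizumab": (True, True, "tocilizumab"),
}

LN2 = np.log(2.0)


@dataclass
class ExperimentSimConfig:
    """Generating parameters of the stimulation experiment."""

    n_genes: int = 10000
    n_donors: int = 6
    conditions: tuple = CONDITIONS
    baseline_logmean: float = 3.0       # natural log of expected counts
    baseline_logsd: float = 2.0
    donor_sd: float = 0.3
    dispersion_a0: float = 3.0          # alpha(mu) = a0/mu + a1
    dispersion_a1: float = 0.05
    n_responsive: int = 300
    lfc_shape: float = 2.0              # classic |log2FC| ~ lfc_min + Gamma
    lfc_scale: float = 0.75
    lfc_min: float = 0.0
    amplification: float = 1.2
    n_trans_only: int = 150
    blockade_olamkicept: float = 1.0
    blockade_tocilizumab: float = 0.98
    th2_fraction: float = 0.1
    min_responsive_mean: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.amplification <= 0:
            raise ValidationError("amplification must be positive")
        for name in ("blockade_olamkicept", "blockade_tocilizumab"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_responsive + self.n_trans_only > self.n_genes:
            raise ValidationError("n_responsive + n_trans_only exceeds n_genes")
        if self.n_genes <= 0 or self.n_donors <= 0:
            raise ValidationError("n_genes and n_donors must be positive")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValidationError(f"unknown condition(s): {sorted(unknown)}")
        if "control" not in self.conditions:
            raise ValidationError("conditions must include control")


@dataclass
class CohortSimConfig:
    """Generating parameters of the asthma/control cohort."""

    n_asthma: int = 77
    n_control: int = 66
    n_genes: int = 5000
    signature_genes: list[str] = field(default_factory=lambda: list(DEFAULT_SIGNATURE))
    high_fraction: float = 0.25
    signature_shift: float = 1.0        # mean log2 shift in the high subgroup
    eos_slope: float = -1.5             # log-linear score -> eosinophil link
    eos_noise_sd: float = 0.8
    eos_base: float = 0.2               # median eosinophil level at zero elevation
    null_phenotypes: tuple = ("age", "bmi", "blood_neutrophils_pct")
    phenotype_missing_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.high_fraction < 1.0:
            raise ValidationError("high_fraction must lie in (0, 1)")
        if self.n_asthma <= 0 or self.n_control <= 0:
            raise ValidationError("cohort sizes must be positive")
        if len(self.signature_genes) > self.n_genes:
            raise ValidationError("more signature genes than genes")
        if not 0.0 <= self.phenotype_missing_rate < 1.0:
            raise ValidationError("phenotype_missing_rate must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    classic_lfc: pd.Series = None        # per responsive gene, log2
    trans_lfc: pd.Series = None          # per responsive+trans-only gene, log2
    trans_only_genes: list[str] = field(default_factory=list)
    th2_genes: list[str] = field(default_factory=list)
    signature_plant: list[str] = field(default_factory=list)
    high_members: list[str] = field(default_factory=list)
    score_eos_link: dict = field(default_factory=dict)

    @property
    def responsive_genes(self) -> list[str]:
        return [] if self.classic_lfc is None else list(self.classic_lfc.index)


@dataclass
class CohortTable:
    """Normalized cohort expression with labels and clinical phenotypes."""

    expr: pd.DataFrame            # genes x samples, linear scale
    labels: pd.Series             # per sample: asthma | control
    phenotypes: pd.DataFrame      # per sample clinical variables (NaN allowed)

    def __post_init__(self) -> None:
        if not self.labels.index.equals(pd.Index(self.expr.columns)):
            raise ValidationError("labels do not align with expression columns")
        if not set(self.phenotypes.index) <= set(self.expr.columns):
            raise ValidationError("phenotype samples absent from expression")


# ---------------------------------------------------------------------------


def simulate_experiment(cfg: ExperimentSimConfig):
    """Draw a stimulation experiment; returns (CountExperiment, SimTruth)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = [f"G{i:05d}" for i in range(1, n + 1)]

    baseline = rng.normal(cfg.baseline_logmean, cfg.baseline_logsd, size=n)
    base_mu = np.exp(baseline)

    # choose which genes respond (gene order randomized once, then fixed)
    eligible = np.arange(n)
    if cfg.min_responsive_mean is not None:
        eligible = np.flatnonzero(base_mu >= cfg.min_responsive_mean)
        if eligible.size < cfg.n_responsive + cfg.n_trans_only:
            raise ValidationError(
                "too few genes satisfy min_responsive_mean for the requested "
                "responsive/trans-only counts"
            )
    picks = rng.permutation(eligible)
    resp = np.sort(picks[: cfg.n_responsive])
    trans_only = np.sort(picks[cfg.n_responsive : cfg.n_responsive + cfg.n_trans_only])

    signs = rng.choice([-1.0, 1.0], size=cfg.n_responsive)
    classic = signs * (cfg.lfc_min + rng.gamma(cfg.lfc_shape, cfg.lfc_scale,
                                               size=cfg.n_responsive))
    to_signs = rng.choice([-1.0, 1.0], size=cfg.n_trans_only)
    to_lfc = to_signs * (cfg.lfc_min + rng.gamma(cfg.lfc_shape, cfg.lfc_scale,
                                                 size=cfg.n_trans_only))

    # log2 effect per condition
    classic_vec = np.zeros(n)
    classic_vec[resp] = classic
    combo_vec = np.zeros(n)
    combo_vec[resp] = cfg.amplification * classic
    combo_vec[trans_only] = to_lfc
    effects = {
        "control": np.zeros(n),
        "il6": classic_vec,
        "sil6r": np.zeros(n),                     # sIL-6Ra alone is exactly null
        "il6_sil6r": combo_vec,
        "il6_sil6r_olamkicept": (1.0 - cfg.blockade_olamkicept) * combo_vec,
        "il6_sil6r_tocilizumab": (1.0 - cfg.blockade_tocilizumab) * combo_vec,
    }

    donors = [f"D{d+1}" for d in range(cfg.n_donors)]
    donor_off = rng.normal(0.0, cfg.donor_sd, size=cfg.n_donors)
    alpha = cfg.dispersion_a0 / np.maximum(base_mu, 1e-8) + cfg.dispersion_a1

    samples, cols, meta_rows = [], [], []
    for d, donor in enumerate(donors):
        for cond in cfg.conditions:
            mu = np.exp(baseline + donor_off[d] + effects[cond] * LN2)
            r = 1.0 / alpha
            p = r / (r + mu)
            cols.append(rng.negative_binomial(r, p))
            sid = f"{donor}_{cond}"
            samples.append(sid)
            il6_flag, sil6r_flag, inhibitor = _CONDITION_FLAGS[cond]
            meta_rows.append(
                {
                    "sample": sid,
                    "donor": donor,
                    "il6": il6_flag,
                    "sil6r": sil6r_flag,
                    "inhibitor": inhibitor,
                }
            )
    counts = np.column_stack(cols).astype(np.int64)
    design = pd.DataFrame(meta_rows).set_index("sample")
    exp = CountExperiment(genes=genes, samples=samples, counts=counts, design=design)

    gene_arr = np.asarray(genes, dtype=object)
    responsive = gene_arr[resp]
    n_th2 = int(round(cfg.th2_fraction * cfg.n_responsive))
    th2 = list(rng.choice(responsive, size=n_th2, replace=False)) if n_th2 else []
    truth = SimTruth(
        classic_lfc=pd.Series(classic, index=responsive, name="classic_log2fc"),
        trans_lfc=pd.Series(
            np.concatenate([cfg.amplification * classic, to_lfc]),
            index=np.concatenate([responsive, gene_arr[trans_only]]),
            name="trans_log2fc",
        ),
        trans_only_genes=list(gene_arr[trans_only]),
        th2_genes=[str(g) for g in th2],
    )
    return exp, truth


# ---------------------------------------------------------------------------


def simulate_cohort(cfg: CohortSimConfig):
    """Draw an asthma/control cohort; returns (CohortTable, SimTruth)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_filler = cfg.n_genes - len(cfg.signature_genes)
    genes = list(cfg.signature_genes) + [f"C{i:05d}" for i in range(1, n_filler + 1)]
    if len(set(genes)) != len(genes):
        raise ValidationError("signature gene collides with filler gene id")

    samples = [f"A{i:03d}" for i in range(1, cfg.n_asthma + 1)] + [
        f"N{i:03d}" for i in range(1, cfg.n_control + 1)
    ]
    labels = pd.Series(
        ["asthma"] * cfg.n_asthma + ["control"] * cfg.n_control,
        index=samples, name="group",
    )

    n_high = int(round(cfg.high_fraction * cfg.n_asthma))
    high_idx = np.sort(rng.choice(cfg.n_asthma, size=n_high, replace=False))
    elevation = np.zeros(len(samples))
    elevation[high_idx] = cfg.signature_shift

    gene_mu = rng.normal(6.0, 1.5, size=len(genes))      # per-gene log2 mean
    log2x = rng.normal(0.0, 1.0, size=(len(genes), len(samples))) + gene_mu[:, None]
    sig_rows = np.arange(len(cfg.signature_genes))
    log2x[sig_rows, :] += elevation[None, :]
    expr = pd.DataFrame(np.power(2.0, log2x), index=genes, columns=samples)

    # phenotypes: eosinophils follow the negative log-linear link to the
    # planted elevation; the rest are independent noise
    eos = np.exp(
        np.log(cfg.eos_base)
        + cfg.eos_slope * elevation
        + rng.normal(0.0, cfg.eos_noise_sd, size=len(samples))
    )
    pheno = pd.DataFrame(index=pd.Index(samples, name="sample"))
    pheno["sputum_eosinophils_1e6"] = eos
    pheno["sputum_eosinophils_pct"] = np.minimum(
        100.0,
        100.0 * eos / (eos + np.exp(rng.normal(1.5, 0.5, size=len(samples)))),
    )
    for name in cfg.null_phenotypes:
        pheno[name] = rng.normal(50.0, 10.0, size=len(samples))
    if cfg.phenotype_missing_rate > 0:
        miss = rng.random(pheno.shape) < cfg.phenotype_missing_rate
        pheno = pheno.mask(miss)

    table = CohortTable(expr=expr, labels=labels, phenotypes=pheno)
    truth = SimTruth(
        signature_plant=list(cfg.signature_genes),
        high_members=[samples[i] for i in high_idx],
        score_eos_link={
            "slope": cfg.eos_slope,
            "noise_sd": cfg.eos_noise_sd,
            "base": cfg.eos_base,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# packaged derivation fixture


def make_signature_fixture(seed: int = 0):
    """A compact, fully controlled input for the three-filter derivation.

    Plants exactly five qualifying genes (the pipeline's default signature
    names) among 560 significant up-regulated genes, plus decoys that each
    violate exactly one filter:

    * ``DECOY_LOWBASE`` — top fold change but bottom-quartile baseline;
    * ``DECOY_SUBTOP`` — 4th-quartile baseline, fold change just below the
      top-5% cut;
    * ``DECOY_NOCORE`` — passes quartile and top-5% but is not core-enriched
      in the second validation dataset;
    * ``DECOY_TH2`` — passes everything but is on the Th2-exclusion list.

    Returns ``(de_table, baseline, datasets, th2, expected)`` where
    ``datasets`` is a list of ``(expr, labels, positive)`` tuples and
    ``expected`` is the planted 5-gene signature in descending fold-change
    order.
    """
    rng = np.random.default_rng(seed)
    planted = list(DEFAULT_SIGNATURE)
    decoys = ["DECOY_LOWBASE", "DECOY_SUBTOP", "DECOY_NOCORE", "DECOY_TH2"]
    n_filler = 560 - len(planted) - len(decoys)
    filler = [f"F{i:04d}" for i in range(1, n_filler + 1)]
    genes = planted + decoys + filler

    # baselines: quartiles are rank-based, 140 genes each.  Planted genes,
    # DECOY_SUBTOP, DECOY_NOCORE and DECOY_TH2 sit in Q4; DECOY_LOWBASE in Q1.
    baseline = pd.Series(0.0, index=pd.Index(genes, name="gene"))
    q4_pool = planted + ["DECOY_SUBTOP", "DECOY_NOCORE", "DECOY_TH2"] + filler[:132]
    q123_pool = ["DECOY_LOWBASE"] + filler[132:]
    baseline[q4_pool] = 1000.0 + rng.random(len(q4_pool)) * 500.0
    baseline[q123_pool] = 1.0 + rng.random(len(q123_pool)) * 500.0
    baseline["DECOY_LOWBASE"] = 0.5  # strictly the lowest baseline -> Q1

    # fold changes: Q4's top-5% cut is ceil(0.05*140)=7 candidates — the five
    # planted genes plus DECOY_NOCORE and DECOY_TH2.  DECOY_SUBTOP is 8th.
    lfc = pd.Series(0.5 + rng.random(len(genes)), index=baseline.index)
    lfc[planted] = np.linspace(4.0, 3.2, len(planted))
    lfc["DECOY_NOCORE"] = 3.1
    lfc["DECOY_TH2"] = 3.05
    lfc["DECOY_SUBTOP"] = 2.9
    lfc["DECOY_LOWBASE"] = 5.0
    de = pd.DataFrame(
        {
            "base_mean": baseline,
            "log2fc": lfc,
            "se": 0.1,
            "wald_p": 1e-6,
            "q": 1e-4,
            "converged": True,
        }
    )
    de.attrs["contrast"] = "il6_sil6r:control"

    candidates = planted + ["DECOY_NOCORE", "DECOY_TH2"]

    def _dataset(up_genes, down_genes=()):
        cols = [f"S{j}" for j in range(1, 13)]
        lab = ["stim"] * 6 + ["ctrl"] * 6
        x = rng.normal(5.0, 0.3, size=(len(genes), 12))
        up = [genes.index(g) for g in up_genes]
        x[np.ix_(up, range(6))] += 4.0
        if down_genes:
            dn = [genes.index(g) for g in down_genes]
            x[np.ix_(dn, range(6))] -= 4.0
        expr = pd.DataFrame(x, index=genes, columns=cols)
        return expr, pd.Series(lab, index=cols), "stim"

    ds1 = _dataset(candidates)                       # all candidates core
    # DECOY_NOCORE is suppressed in the second dataset, so it ranks far
    # below the enrichment peak there and fails the core filter
    ds2 = _dataset([g for g in candidates if g != "DECOY_NOCORE"],
                   down_genes=["DECOY_NOCORE"])
    th2 = GeneSet(name="TH2_SENSITIVE", description="IL-4/IL-13-responsive",
                  genes=["DECOY_TH2", "IL4", "IL13"])
    return de, baseline, [ds1, ds2], th2, planted
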