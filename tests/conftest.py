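import numpy as np
import pytest

import transsig as ts


@pytest.fixture(scope="session")
def small_experiment():
    """A compact full-factorial stimulation experiment with ground truth."""
    cfg = ts.ExperimentSimConfig(
        n_genes=600, n_responsive=60, n_trans_only=20, seed=11
    )
    exp, truth = ts.simulate_experiment(cfg)
    return exp, truth, cfg


@pytest.fixture(scope="session")
def small_de(small_experiment):
    """Size factors, dispersions and both contrasts for the small experiment."""
    exp, truth, cfg = small_experiment
    factors = ts.size_factors(exp)
    disp = ts.estimate_dispersion(exp, factors)
    de_classic = ts.fit_de(exp, ("il6", "control"), disp, factors)
    de_trans = ts.fit_de(exp, ("il6_sil6r", "control"), disp, factors)
    return dict(
        exp=exp, truth=truth, factors=factors, disp=disp,
        de_classic=de_classic, de_trans=de_trans,
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = ts.CohortSimConfig(n_genes=1000, seed=7)
    table, truth = ts.simulate_cohort(cfg)
    return table, truth, cfg


def brute_running_es(metric, hit, p_weight=1.0):
    """Independent O(N*|S|) enumeration of the running enrichment score."""
    metric = np.asarray(metric, dtype=float)
    hit = np.asarray(hit, dtype=bool)
    n = len(metric)
    n_hit = int(hit.sum())
    w = np.abs(metric) ** p_weight
    nr = float(w[hit].sum())
    cur, profile = 0.0, []
    for i in range(n):
        if hit[i]:
            cur += (w[i] / nr) if nr > 0 else 1.0 / n_hit
        else:
            cur -= 1.0 / (n - n_hit)
        profile.append(cur)
    best_i = max(range(n), key=lambda i: (abs(profile[i]), -i))  # first max
    return profile[best_i], np.asarray(profile), best_i
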