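import numpy as np
import pandas as pd
import pytest

from photoadapt.synthdata import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def two_pop_panel():
    """Two well-separated subpopulations plus a handful of admixed lines."""
    cfg = SimConfig(seed=7, n_subpops=2, accessions_per_subpop=(50, 50),
                    n_admixed=10, n_snps=2000, fst=0.2)
    gm, truth = simulate_genotypes(cfg)
    return cfg, gm, truth


@pytest.fixture(scope="session")
def eight_pop_panel():
    """The default study-scale panel: 8 subpopulations at FST = 0.15."""
    cfg = SimConfig(seed=11)
    gm, truth = simulate_genotypes(cfg)
    return cfg, gm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def label_match_accuracy():
    """Permutation-matched assignment accuracy (Hungarian matching of
    estimated cluster labels onto true subpopulation labels)."""
    from scipy.optimize import linear_sum_assignment

    def _acc(true_labels: pd.Series, est_labels: pd.Series) -> float:
        true_labels = pd.Series(true_labels)
        est_labels = pd.Series(est_labels).reindex(true_labels.index)
        t_levels = sorted(true_labels.unique())
        e_levels = sorted(est_labels.unique())
        conf = np.zeros((len(t_levels), len(e_levels)))
        for i, t in enumerate(t_levels):
            for j, e in enumerate(e_levels):
                conf[i, j] = ((true_labels == t) & (est_labels == e)).sum()
        ri, ci = linear_sum_assignment(-conf)
        return conf[ri, ci].sum() / len(true_labels)

    return _acc
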