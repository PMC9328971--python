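import numpy as np
import pandas as pd
import pytest

import ferropair as fp


@pytest.fixture(scope="session")
def toy():
    """The fixed 8-gene x 10-sample worked cohort."""
    return fp.worked_toy()


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap simulated cohort with one planted pair, for unit tests."""
    cfg = fp.SimulationConfig(
        n_tumor=120, n_normal=20, n_lnc=60, n_mrna=40, n_frg=15,
        planted_pairs=[("LNC0001", "LNC0002", 1.0)], seed=42,
    )
    return fp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_cohort():
    """One cohort at the default recovery conditions (3 planted pairs)."""
    return fp.simulate_cohort(fp.default_recovery_config(seed=3))


def random_survival(rng, n, frac_censored=0.3):
    """Exponential survival with independent exponential censoring."""
    T = rng.exponential(100.0, n)
    C = rng.exponential(100.0 * (1 - frac_censored) / max(frac_censored, 1e-9), n)
    return np.minimum(T, C), (T <= C).astype(int)


def expression_from_array(arr, gene_ids, sample_ids, n_tumor):
    values = pd.DataFrame(
        np.asarray(arr, dtype=float),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=pd.Index(sample_ids, name="sample_id"),
    )
    condition = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * (len(sample_ids) - n_tumor),
        index=values.columns,
    )
    return fp.ExpressionMatrix(values, condition)
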