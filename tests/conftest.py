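"""Shared fixtures: one full-scale synthetic study, generated once."""

import numpy as np
import pytest

import connectotype as ct


@pytest.fixture(scope="session")
def default_cohort() -> ct.SyntheticCohort:
    """Full study-scale cohort (34/67/33 subjects, 379 regions)."""
    return ct.make_cohort(ct.GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort() -> ct.SyntheticCohort:
    """Reduced-resolution cohort for cheap structural checks."""
    return ct.make_cohort(ct.GeneratorConfig(n_regions_per_hemisphere=40, seed=3))


@pytest.fixture(scope="session")
def loss_map(default_cohort):
    return ct.regional_loss_map(
        default_cohort.connectomes, default_cohort.parcellation, "interhemispheric"
    )


@pytest.fixture(scope="session")
def synth_expr(default_cohort, loss_map) -> ct.SyntheticExpression:
    return ct.make_expression(
        default_cohort.config, loss_map, default_cohort.parcellation
    )


@pytest.fixture(scope="session")
def null_expr(default_cohort, loss_map) -> ct.SyntheticExpression:
    """Expression with no planted signal genes (null calibration data)."""
    import dataclasses
    cfg = dataclasses.replace(default_cohort.config, n_signal_genes=0, seed=99)
    return ct.make_expression(cfg, loss_map, default_cohort.parcellation)


@pytest.fixture(scope="session")
def pls(synth_expr, loss_map) -> ct.PLSFit:
    return ct.pls_fit(synth_expr.expression, loss_map)


@pytest.fixture(scope="session")
def left_centroids(default_cohort) -> np.ndarray:
    return default_cohort.parcellation.cortical_centroids("left").to_numpy()


@pytest.fixture(scope="session")
def spin_set(left_centroids) -> ct.SpinSet:
    return ct.make_spins(left_centroids, 500, seed=7)


@pytest.fixture(scope="session")
def pls_spin_null(synth_expr, loss_map, spin_set) -> ct.SpinNull:
    return ct.spin_null(synth_expr.expression, loss_map, spin_set)


@pytest.fixture(scope="session")
def boot_weights(synth_expr, loss_map, pls):
    return ct.bootstrap_weights(synth_expr.expression, loss_map, pls,
                                n_boot=200, seed=11)


@pytest.fixture(scope="session")
def gene_ranking(pls, boot_weights, pls_spin_null):
    return ct.rank_genes(pls, boot_weights, pls_spin_null)
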