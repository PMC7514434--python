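import numpy as np
import pytest

from phylodca import evaluation, msa_builder, site_pruning
from phylodca.potts_core import PottsModel, ToyModelParams, generate_toy_model


@pytest.fixture(scope="session")
def toy_model():
    """The frozen default toy model plus its true contact edges."""
    return generate_toy_model(ToyModelParams(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_model(L, q, rng, coupling_scale=0.5, field_scale=0.5) -> PottsModel:
    model = PottsModel(L, q,
                       h=field_scale * rng.normal(size=(L, q)))
    for i in range(L):
        for j in range(i + 1, L):
            model.set_J(i, j, coupling_scale * rng.normal(size=(q, q)))
    return model


@pytest.fixture(scope="session")
def desk_report():
    """Scaled repetition harness shared by the acceptance ordering tests.

    K=9 (512 leaves), 10 repetitions, per-branch mutation load 3, with
    reduced optimizer/annealer budgets so the whole run stays within the
    test-suite time budget.
    """
    config = evaluation.ExperimentConfig(
        toy=ToyModelParams(seed=7),
        K=9,
        mu_l_dt=3.0,
        reps=10,
        seed=11,
        arms=("tree", "site", "pair", "iid"),
        site_schedule=site_pruning.OptimizerSchedule(iters=1500),
        pair_schedule=site_pruning.OptimizerSchedule(iters=800),
        anneal=msa_builder.AnnealSchedule(moves=1_500_000),
        kl_samples=4000,
        n_wt=30,
    )
    return config, evaluation.run_experiment(config)
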