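"""Shared fixtures: small synthetic scenarios and hand-built model objects."""



import numpy as np
import pandas as pd
import pytest

import multinmix.model_core as mc
import multinmix.synthetic_data as sd
from multinmix.sampler import PosteriorSamples, SamplerConfig


def small_scenario(**overrides) -> sd.ScenarioConfig:
    """A scaled-down shared-population scenario for fast unit tests."""
    base = dict(
        n_sites=50, n_abundance_covariates=4, beta=(0.8, 0.0),
        detection_p=(0.25, 0.3), covariate_rho=0.2,
        frac_missing_method2=0.0, seed=7,
    )
    base.update(overrides)
    return sd.ScenarioConfig(**base)


def fast_config(**overrides) -> SamplerConfig:
    base = dict(n_iter=3000, burn_in=1000, thin=2, n_chains=2, seed=3)
    base.update(overrides)
    return SamplerConfig(**base)


@pytest.fixture(scope="session")
def small_dataset() -> sd.SimulatedDataset:
    return sd.make_dataset(small_scenario())


@pytest.fixture
def tiny_counts() -> mc.CountData:
    """3 sites, 2 methods (2 + 2 occasions), with one masked entry."""
    counts = np.array([[1, 0, 1, 2],
                       [2, 1, 0, 1],
                       [3, 2, 4, 0]])
    mask = np.ones_like(counts, dtype=bool)
    mask[2, 3] = False
    return mc.CountData(counts, mask, site_ids=["c1", "c2", "c3"],
                        method_names=["hair_trap", "bear_rub"],
                        occasions_per_method=[2, 2])


@pytest.fixture
def tiny_designs(tiny_counts):
    abund = mc.AbundanceDesign(np.array([[-1.0], [0.0], [1.0]]), ["x1"])
    det = mc.DetectionDesign(
        {m: np.zeros((3, 2, 0)) for m in tiny_counts.method_names},
        {m: [] for m in tiny_counts.method_names},
    )
    return abund, det


@pytest.fixture
def tiny_params():
    return mc.ModelParams(
        beta0=0.7, beta=[0.8], w=[1],
        alpha0={"hair_trap": -0.4, "bear_rub": -0.2},
        alpha={"hair_trap": np.zeros(0), "bear_rub": np.zeros(0)},
    )


def indicator_samples(w, names) -> PosteriorSamples:
    """Minimal PosteriorSamples wrapping given indicator draws (C, S, J)."""
    w = np.asarray(w, dtype=np.int8)
    C, S, J = w.shape
    return PosteriorSamples(
        beta0=np.zeros((C, S)), beta=np.zeros((C, S, J)), w=w,
        alpha0=np.zeros((C, S, 0)), alpha={}, N=None,
        covariate_names=list(names), method_names=[], det_cov_names={},
        site_ids=[], acceptance=pd.DataFrame(), attempts=pd.DataFrame(),
        chain_seeds=[], config=None,
    )
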