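import numpy as np
import pandas as pd
import pytest

import omsm
from omsm.core import ModelConfig, SourceDataset


@pytest.fixture(scope="session")
def tdf():
    return omsm.default_tdf_table()


@pytest.fixture(scope="session")
def source_panel():
    """Three-group synthetic particle panel (surface/large/small), 5 reps."""
    return omsm.default_source_panel(seed=3)


@pytest.fixture(scope="session")
def two_source_toy(tdf):
    """A 2-source, 4-tracer dataset with one simulated consumer, plus the
    model built with fixed source parameters (for grid-oracle comparison)."""
    rng = np.random.default_rng(7)
    names = ["Phe", "Lys", "Pro", "Glx"]
    means = {"A": [1.0, 2.0, 4.0, 5.0], "B": [7.0, 8.0, 10.0, 11.0]}
    sources = SourceDataset({
        g: pd.DataFrame(rng.normal([m], 0.8, (6, 4)), columns=names)
        for g, m in means.items()
    })
    config = ModelConfig(roles={
        "Phe": "mixing", "Lys": "mixing",
        "Pro": "trophic_fwl", "Glx": "trophic_mts",
    })
    consumers, truth = omsm.simulate_consumers(
        sources, n=1, tdf=tdf, seed=5, tracers=names
    )
    model = omsm.build_model(
        sources, consumers, tdf, config=config, fix_source_params=True
    )
    return sources, consumers, truth, model


def grid_posterior_mean_f(model, n_f=241, n_fwl=161, n_mts=161):
    """Dense-grid numerical posterior over (f_A, FWL, MTS) for a 2-source
    model with fixed source parameters.  Independent of the MCMC code path:
    evaluates the joint density on a lattice and integrates by quadrature.
    """
    mu = model.source_means
    fa = np.linspace(1e-4, 1 - 1e-4, n_f)
    FW = np.linspace(-1.0, 5.0, n_fwl)
    MT = np.linspace(-1.0, 4.0, n_mts)
    FA, FWg, MTg = np.meshgrid(fa, FW, MT, indexing="ij")
    jF, jM = model.jF, model.jM
    Y, A = model.Y[0], model.A[0]

    base = FA[..., None] * mu[:, 0] + (1 - FA[..., None]) * mu[:, 1]
    mF = (Y[jF] - base[..., jF]) / model.dm[jF]
    sF = np.maximum(
        np.abs(mF) * np.hypot(A[jF] / Y[jF], model.sdm[jF] / model.dm[jF]), 1e-9
    )
    mM = (Y[jM] - base[..., jM]) / model.dm[jM]
    sM = np.maximum(
        np.abs(mM) * np.hypot(A[jM] / Y[jM], model.sdm[jM] / model.dm[jM]), 1e-9
    )
    lp = (
        -np.log(sF) - 0.5 * ((FWg - mF) / sF) ** 2
        - np.log(sM) - 0.5 * ((MTg - mM) / sM) ** 2
    )
    PT = FWg - MTg
    for j in model.mix_idx:
        mean = base[..., j] + PT * model.dp[j] + MTg * model.dm[j]
        if model.cls[j] == 1:
            sd = np.sqrt(A[j] ** 2 + (FWg * model.sdm[j]) ** 2)
        elif model.cls[j] == 0:
            sd = np.full_like(FWg, A[j])
        else:
            sd = np.sqrt(
                A[j] ** 2 + (PT * model.sdp[j]) ** 2 + (MTg * model.sdm[j]) ** 2
            )
        lp += -np.log(sd) - 0.5 * ((Y[j] - mean) / sd) ** 2
    w = np.exp(lp - lp.max())
    w /= w.sum()
    return {
        "f_A": float((w * FA).sum()),
        "FWL": float((w * FWg).sum()),
        "MTS": float((w * MTg).sum()),
    }
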