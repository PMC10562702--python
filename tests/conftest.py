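"""Shared fixtures: programmatically built studies, no stored data files."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wavewire.io import TIME_POINTS, ExpressionStudy
from wavewire.pipeline import RunConfig, run_all
from wavewire.simulate import SimulationConfig, generate


def build_study(feature_means: dict[str, dict[str, list[float]]],
                n_replicates: int = 3, noise_sd: float = 0.0,
                seed: int = 0) -> ExpressionStudy:
    """Construct a study from exact per-genotype time-point means.

    ``feature_means[genotype][feature]`` is the 6-vector of log2 time-point
    means; replicates are identical (plus optional noise), so the study's
    replicate means reproduce the requested values exactly at zero noise.
    """
    rng = np.random.default_rng(seed)
    genotypes = list(feature_means)
    features = list(next(iter(feature_means.values())))
    samples, rows, cols = [], [], []
    for g in genotypes:
        for tp_idx, tp in enumerate(TIME_POINTS):
            for rep in range(1, n_replicates + 1):
                name = f"{g}_{tp:g}_r{rep}"
                samples.append(name)
                rows.append({"sample": name, "genotype": g,
                             "time_months": tp, "replicate": rep})
                col = np.array([feature_means[g][f][tp_idx] for f in features],
                               dtype=float)
                if noise_sd:
                    col = col + rng.normal(0, noise_sd, size=len(col))
                cols.append(col)
    values = np.column_stack(cols)
    return ExpressionStudy(features=features, samples=samples, values=values,
                           design=pd.DataFrame(rows))


@pytest.fixture(scope="session")
def zero_noise_data():
    """Default-size planted study with no noise: every call is recoverable."""
    return generate(SimulationConfig(noise_sd=0.0), seed=11)


@pytest.fixture(scope="session")
def noisy_data():
    """Planted study at the default noise level (0.25 log2 units)."""
    return generate(SimulationConfig(), seed=7)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A fast end-to-end pipeline run on a scaled-down planted study."""
    out = tmp_path_factory.mktemp("run")
    sim = SimulationConfig(n_features=700, wt_wave_size=60,
                           onc_only_per_wave=40, n_type1_signatures=2,
                           type1_signature_size=10)
    cfg = RunConfig(out_dir=str(out), seed=5, n_waves=6, simulation=sim)
    with pytest.warns(UserWarning):
        results = run_all(cfg)
    return cfg, results
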