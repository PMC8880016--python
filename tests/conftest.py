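import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tensorspec as ts
from tensorspec.io import SpectrumSet, WavenumberGrid
from tensorspec.pipeline import PipelineConfig, preprocess_band, run_pipeline

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_set() -> SpectrumSet:
    """3 samples x 5 points on a descending grid."""
    grid = WavenumberGrid(nu_max=5000.0, resolution=10.0, n_points=5)
    absorb = np.array(
        [[0.1, 0.2, 0.3, 0.4, 0.5],
         [1.0, 0.9, 0.8, 0.7, 0.6],
         [0.5, 0.5, 0.5, 0.5, 0.5]]
    )
    return SpectrumSet(grid=grid, absorbance=absorb,
                       labels=np.array(["I", "II", "I"], dtype=object),
                       sample_ids=["a", "b", "c"])


def small_synth_cfg(seed: int = 0, **overrides) -> ts.SynthConfig:
    """Scaled-down generator: 3 classes x 30 samples, 300-point grid."""
    cfg = ts.SynthConfig(
        n_classes=3, samples_per_class=30,
        nu_max=6800.0, nu_min=4400.0, resolution=8.0, seed=seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def small_pipeline_cfg(**overrides) -> PipelineConfig:
    """Pipeline settings matched to the scaled-down generator grid."""
    cfg = PipelineConfig(
        ndf=ts.NDFConfig(window_N=5),
        band=(5800.0, 4600.0),
        svm=ts.SVMConfig(C=10.0),
        seed=0,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


@pytest.fixture(scope="session")
def default_synth():
    """The full-size synthetic preset (5 x 150 x 2125, seed 42)."""
    return ts.generate(ts.SynthConfig(seed=42))


@pytest.fixture(scope="session")
def default_run(default_synth):
    """Full paper-mode pipeline run on the default preset.

    Returns (spectrum set, truth, report, post-preprocessing grid).
    """
    sset, truth = default_synth
    cfg = PipelineConfig()
    report = run_pipeline(sset, cfg)
    processed = preprocess_band(sset, cfg.ndf, cfg.band)
    return sset, truth, report, processed.grid
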