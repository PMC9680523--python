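import warnings

import numpy as np
import pytest

from octlayers.phantom import PhantomSpec, ShadowSector, generate_phantom
from octlayers.pipeline import RunConfig, run_pipeline

warnings.filterwarnings("ignore", category=FutureWarning)


def _scale_drift(spec: PhantomSpec) -> PhantomSpec:
    """Scale the per-pullback drift to the shorter slice count so the
    slice-to-slice boundary drift rate matches the default 60-slice suite."""
    for model in spec.boundary_models.values():
        model.drift_amp *= spec.n_slices / 60.0
    return spec


def small_spec(**overrides) -> PhantomSpec:
    """A compact pullback for unit tests: 12 slices, full angular grid."""
    kw = dict(
        n_slices=12,
        shadow_sectors=[ShadowSector((3, 8), (40.0, 130.0), 1.20, 0.02)],
        rng_seed=7,
    )
    kw.update(overrides)
    return _scale_drift(PhantomSpec(**kw))


def noise_free_spec(**overrides) -> PhantomSpec:
    """Small phantom without speckle, shadows or guidewire."""
    kw = dict(n_slices=6, speckle_sigma=0.0, shadow_sectors=[],
              guidewire_sector=None, rng_seed=3)
    kw.update(overrides)
    return _scale_drift(PhantomSpec(**kw))


@pytest.fixture(scope="session")
def small_phantom():
    spec = small_spec()
    stack, truth = generate_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noise_free_phantom():
    spec = noise_free_spec()
    stack, truth = generate_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default 60-slice phantom (speckle, two lipid
    shadows, guidewire), seed 1 — shared by the end-to-end checks."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(out_dir=str(out), seed=1)
    report = run_pipeline(cfg)
    spec = PhantomSpec(rng_seed=1)
    _, truth = generate_phantom(spec)
    return {"report": report, "out_dir": out, "spec": spec, "truth": truth,
            "cfg": cfg}
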