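"""Shared fixtures: small study configurations and generated datasets."""

import pytest

from ratgait.config import RunConfig


@pytest.fixture
def small_config() -> RunConfig:
    """A fast 2/2/2-animal study with two timepoints and tiny videos."""
    return RunConfig(
        seed=7,
        n_per_group={"naive": 2, "sham": 2, "operated": 2},
        days=[9, 23],
        gait_trials_per_session=2,
        grf_trials_per_session=1,
        incapacitance_trials=3,
        video_frames=12,
        simulate_video=True,
    ).validate()


@pytest.fixture(scope="module")
def analyzed_study(tmp_path_factory):
    """One simulated + analyzed + tested study shared across a module."""
    from ratgait import pipeline

    cfg = RunConfig(
        seed=11,
        n_per_group={"naive": 2, "sham": 2, "operated": 2},
        days=[9, 23],
        gait_trials_per_session=2,
        grf_trials_per_session=2,
        incapacitance_trials=3,
        simulate_video=False,
        timing_noise_sd_s=0.0,
        grf_noise_sd_N=0.0,
    ).validate()
    root = tmp_path_factory.mktemp("study")
    manifest = pipeline.simulate_study(cfg, root / "data")
    errors = pipeline.analyze_study(root / "data", cfg, root / "results")
    assert errors == []
    pipeline.run_stats(root / "results", cfg, root / "stats")
    return {"cfg": cfg, "root": root, "manifest": manifest}
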