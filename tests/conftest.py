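import pytest

from msrefcurve import default_config, generate_cohort, generate_followup


def scaled_config(seed: int = 0, scale: float = 1.0, fu_n: int | None = None):
    """Default config with group sizes scaled down for cheap tests."""
    cfg = default_config(seed=seed)
    if scale != 1.0:
        for g in cfg.groups.values():
            g.n = max(int(round(g.n * scale)), 8)
        cfg.followup.n = fu_n if fu_n is not None else max(
            int(round(cfg.followup.n * scale)), 8)
        cfg.followup.n_rrms_to_spms = min(
            cfg.followup.n_rrms_to_spms, cfg.followup.n // 4)
    elif fu_n is not None:
        cfg.followup.n = fu_n
    return cfg


@pytest.fixture(scope="session")
def default_cfg():
    return default_config(seed=7)


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    """One full-size cohort with follow-up, shared across the session."""
    return generate_followup(generate_cohort(default_cfg), default_cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A ~1/6-size cohort for expensive per-test refits."""
    cfg = scaled_config(seed=11, scale=0.16)
    return generate_followup(generate_cohort(cfg), cfg), cfg
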