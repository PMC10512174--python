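"""Shared fixtures: cohort tables and small phantom renders."""

from __future__ import annotations

import pytest

from adrenotelo.cohort import load_cohort_tables
from adrenotelo.phantom import SlidePhantomConfig, simulate_slide_pair
from adrenotelo.pipeline import quantify_pair
from adrenotelo.zones import ZoneLayout


@pytest.fixture(scope="session")
def cohort():
    """The packaged cohort fixtures (printed patient tables)."""
    return load_cohort_tables()


@pytest.fixture(scope="session")
def noise_free_config():
    return SlidePhantomConfig(poisson_noise=False, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def default_layout():
    cfg = SlidePhantomConfig()
    return ZoneLayout.from_fractions(
        cfg.shape[0], cfg.bands.capsule, cfg.bands.zg, cfg.bands.zf, cfg.bands.zr
    )


@pytest.fixture(scope="session")
def quantified_slide(default_layout):
    """One default (noisy) phantom slide pushed through the full chain."""
    cfg = SlidePhantomConfig()
    sim = simulate_slide_pair(cfg, 42, slide_id="fixture-slide")
    df, reference, qc = quantify_pair(sim.tissue, sim.cellblock, layout=default_layout)
    return sim, df, reference, qc
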