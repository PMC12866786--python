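"""Shared fixtures: one moderately sized simulated section reused across
modules (session scope) plus small cheap panels."""

import numpy as np
import pytest

import spatialmargin as sm


@pytest.fixture(scope="session")
def panel_small():
    return sm.make_signature_panel(
        n_genes=200, n_types=5, n_chroms=4, mito_fraction=0.02, seed=11
    )


@pytest.fixture(scope="session")
def scene_disk():
    """5 mm section, centered 1000-µm disk tumor, tumor-side fibroblast
    gradient (peak 0.4, decay 400 µm)."""
    return sm.Scene(
        width_um=5000.0,
        height_um=5000.0,
        tumor_region=sm.disk(2500.0, 2500.0, 1000.0),
        gradient_specs=(
            sm.GradientSpec("Fibroblast", "tumor", 400.0, 0.4),
            sm.GradientSpec("Macrophage", "normal", 300.0, 0.2),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def section_disk(scene_disk, panel_small):
    return sm.simulate_section(scene_disk, panel_small)


@pytest.fixture(scope="session")
def margin_fit(section_disk):
    return sm.TumorMarginDetector().fit(section_disk)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
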