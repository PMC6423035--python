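"""Shared fixtures.

The desk-preset phantom pipeline (generation at 0.4 mm, segmentation to
0.8 mm, FE solves) is expensive enough that the solved scenarios are cached
at session scope and shared across test modules.
"""

import numpy as np
import pytest

from nestmech import phantom, segmentation, scenarios
from nestmech.voxfem import MaterialModel


@pytest.fixture(scope="session")
def desk_bundle():
    """Default synthetic nest (seed 42, 0.4 mm desk preset)."""
    return phantom.generate_phantom()


@pytest.fixture(scope="session")
def desk_seg(desk_bundle):
    """Default segmentation of the desk phantom (0.8 mm mask)."""
    mask, pores, prov = segmentation.segment(desk_bundle.image)
    return mask, pores, prov


@pytest.fixture(scope="session")
def desk_gray(desk_bundle):
    return segmentation.downsample(desk_bundle.image, 2)


class _ScenarioCache:
    """Build-and-solve cache keyed by (scenario name, gravity flag)."""

    def __init__(self, mask, gray):
        self.mask = mask
        self.gray = gray
        self._models = {}
        self._solved = {}

    def model(self, name):
        if name not in self._models:
            self._models[name] = scenarios.make_scenario(
                name, self.mask, self.gray, MaterialModel(total_mass_g=5.93))
        return self._models[name]

    def solved(self, name, gravity=True):
        key = (name, gravity)
        if key not in self._solved:
            model, placement = self.model(name)
            report, field = scenarios.run_scenario(
                model, placement, name, gravity=gravity)
            self._solved[key] = (model, placement, report, field)
        return self._solved[key]


@pytest.fixture(scope="session")
def desk_scenarios(desk_seg, desk_gray):
    mask, _pores, _prov = desk_seg
    return _ScenarioCache(mask, desk_gray)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
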