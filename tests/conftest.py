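"""Shared fixtures: simulated scenes reused across the suite.

Session scope keeps the expensive end-to-end runs to one apiece; every
test treats the fixtures as read-only.
"""

from __future__ import annotations

import pytest

from ivprofiler.pipeline import profile_reads
from ivprofiler.synthetic_data import SimulationConfig, simulate_scene

#: compact scene: two scaffolds, one conserved + one random circle — enough
#: structure for junction/break-mode behaviour at a few seconds per run
SMALL_SCENE_KWARGS = dict(
    host_scaffold_lengths=(15_000, 15_000),
    circle_count=2,
    circle_size_range=(1_200, 1_800),
    him_circle_count=1,
    conserved_circle_count=1,
    random_circle_count=1,
    events_per_circle=5,
    episomal_coverage=20.0,
    host_coverage=12.0,
)


@pytest.fixture(scope="session")
def small_scene():
    return simulate_scene(SimulationConfig(seed=7, **SMALL_SCENE_KWARGS))


@pytest.fixture(scope="session")
def small_result(small_scene):
    return profile_reads(
        small_scene.circles, small_scene.host_scaffolds, small_scene.reads
    )


@pytest.fixture(scope="session")
def default_scene():
    """The standard scene: 5 × 50 kb host, 8 circles (3 HIM), 25 events."""
    return simulate_scene(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_result(default_scene):
    return profile_reads(
        default_scene.circles,
        default_scene.host_scaffolds,
        default_scene.reads,
    )
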