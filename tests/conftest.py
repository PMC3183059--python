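from dataclasses import replace

import pytest

from fluxdeconv import ChamberPhysics, default_stage_table, simulate_plate


@pytest.fixture(scope="session")
def noiseless_physics() -> ChamberPhysics:
    return ChamberPhysics().noiseless()


@pytest.fixture(scope="session")
def simulate_noiseless(noiseless_physics):
    """Factory: noiseless plate run + truth for a stage, optional param overrides."""

    cache: dict = {}

    def make(hpf: int, seed: int = 0, layout=None, **overrides):
        key = (hpf, seed, id(layout), tuple(sorted(overrides.items())))
        if key not in cache:
            params = default_stage_table()[hpf].noiseless()
            if overrides:
                params = replace(params, **overrides)
            cache[key] = simulate_plate(
                hpf, layout=layout, physics=noiseless_physics, seed=seed, stage_params=params
            )
        return cache[key]

    return make
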