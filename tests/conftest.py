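import pytest

import viaquant as vq

#: Panel conditions used by the recovery/robustness checks: planted live/dead
#: ratios spanning 0.25–4, three replicates, 256×256 frames, 400 cells per pair.
PANEL_RATIOS = [0.25, 0.5, 1.0, 2.0, 4.0]
PANEL_REPLICATES = 3
PANEL_SEED = 11


@pytest.fixture(scope="session")
def panel(tmp_path_factory):
    """Seeded synthetic Live/Dead panel shared across recovery tests."""
    out = tmp_path_factory.mktemp("panel")
    base = vq.SyntheticSpec(n_live=200, n_dead=200, width=256, height=256)
    manifest, truth = vq.simulate_panel(
        base, PANEL_RATIOS, [24.0], PANEL_REPLICATES, seed=PANEL_SEED, out_dir=out
    )
    return manifest, truth, out
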