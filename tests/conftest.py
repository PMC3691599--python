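import numpy as np
import pytest

from remethyl import synthetic

# canonical delayed-tanh run used across fitting tests:
# climbs from ~10.7% to 50% with rate 0.2/day and onset delay 10 days
CANON = dict(y0=30.0, y1=20.0, m=0.2, b=2.0)
CANON_DAYS = np.linspace(0.0, 50.0, 11)


def canonical_levels(days=CANON_DAYS):
    return CANON["y0"] + CANON["y1"] * np.tanh(CANON["m"] * days - CANON["b"])


def make_series(days, levels, baseline=50.0, cimp=False):
    return synthetic.MethylationTimeSeries(
        cell_line="CL1", locus="locus1", days=np.asarray(days, float),
        level_pct=np.asarray(levels, float), baseline_pct=baseline, cimp=cimp,
    )


@pytest.fixture
def canonical_series():
    return make_series(CANON_DAYS, canonical_levels())


@pytest.fixture
def default_panel():
    return synthetic.generate_methylation_panel(synthetic.PanelConfig(seed=42))
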