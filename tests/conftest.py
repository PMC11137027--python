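import numpy as np
import pandas as pd
import pytest

import nucshift as ns


def make_fragments(lengths, start=1000, chrom="chr1"):
    """One fragment per length, all starting at `start`."""
    lengths = list(lengths)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [start] * len(lengths),
            "end": [start + L for L in lengths],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort():
    """A 12-anchor cohort (3 per pattern group) with its fragment libraries."""
    cfg = ns.SimulationConfig(n_anchors=3, seed=42)
    archs, anchors = ns.default_cohort(cfg)
    frags = {
        cond: ns.simulate_fragments(archs, cfg, cond) for cond in ("control", "depleted")
    }
    return cfg, archs, anchors, frags
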