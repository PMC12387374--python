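import numpy as np
import pytest

from infoseason import SyntheticSpec, generate_series, monthly_climatology


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def make_climatology(seed=0, **spec_kwargs):
    """12-point climatology of a synthetic series on the latent (unscaled) scale."""
    defaults = dict(rescale_0_100=False, integer_round=False, seed=seed)
    defaults.update(spec_kwargs)
    series = generate_series(SyntheticSpec(**defaults))
    return monthly_climatology(series)


@pytest.fixture
def export_text():
    """A well-formed 132-month multiTimeline export."""
    rng = np.random.default_rng(7)
    values = rng.integers(0, 101, size=132)
    values[rng.integers(0, 132)] = 100  # exports are max-anchored
    lines = ["Category: All categories", "", "Month,gout: (United States)"]
    months = []
    for i in range(132):
        year, month = 2014 + i // 12, i % 12 + 1
        months.append(f"{year}-{month:02d}")
        lines.append(f"{months[-1]},{values[i]}")
    return "\n".join(lines) + "\n", values, months
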