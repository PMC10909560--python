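import numpy as np
import pytest

import migtraj as m


@pytest.fixture(scope="session")
def three_group_sim():
    """Well-separated three-group panel under the census availability pattern."""
    return m.generate_panel(m.three_group_spec(n_areas=500, seed=7))


@pytest.fixture(scope="session")
def fitted_three(three_group_sim):
    return m.fit(
        three_group_sim.panel,
        m.ModelSpec(n_groups=3, orders=3, seed=0, n_starts=2),
    )


def random_small_panel(rng, n=4, k=2, t=3, with_missing=True):
    """Tiny unstructured panel for oracle and property checks."""
    values = rng.uniform(5, 95, size=(n, k, t))
    mask = np.ones((n, k, t), dtype=bool)
    if with_missing:
        mask &= rng.random((n, k, t)) > 0.2
        # every indicator must keep at least one observed time somewhere
        for kk in range(k):
            if not mask[:, kk, :].any():
                mask[0, kk, 0] = True
    return m.IndicatorPanel(
        values=np.where(mask, values, np.nan),
        mask=mask,
        area_ids=np.array([f"A{i}" for i in range(n)]),
        years=2001 + np.arange(t),
        indicators=tuple(f"indicator_{j + 1}" for j in range(k)),
    )
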