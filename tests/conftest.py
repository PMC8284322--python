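import numpy as np
import pandas as pd
import pytest

import steroidokin as sk


@pytest.fixture(scope="session")
def small_sim():
    """A 150-gene simulated experiment shared across read-only tests."""
    return sk.simulate_course(sk.CourseConfig(n_genes=150), seed=11)


def make_matrix(expected, grid, n_reps, dispersion, seed, layer="mature"):
    """Sample a TimeCourseMatrix around a genes x times expectation."""
    rng = np.random.default_rng(seed)
    cols, times, reps, blocks = [], [], [], []
    for r in range(n_reps):
        blocks.append(sk.sample_counts(expected, 1.0, dispersion, rng))
        for t in grid:
            cols.append(f"{layer}_t{t:g}_r{r + 1}")
            times.append(t)
            reps.append(r + 1)
    counts = pd.DataFrame(
        np.hstack(blocks),
        index=[f"G{i:04d}" for i in range(expected.shape[0])],
        columns=cols,
    )
    meta = pd.DataFrame(
        {
            "time": times,
            "replicate": reps,
            "condition": ["stimulated" if t > 0 else "unstimulated" for t in times],
            "layer": layer,
        },
        index=cols,
    )
    return sk.TimeCourseMatrix(counts, meta, pd.Series(1.0, index=cols))
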