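import numpy as np
import pytest

import scanrel as sr


def make_matrix(values) -> sr.RatingsMatrix:
    """Wrap a plain array as a RatingsMatrix for direct statistic tests."""
    x = np.asarray(values, dtype=float)
    return sr.RatingsMatrix(
        values=x,
        subjects=tuple(f"s{i}" for i in range(x.shape[0])),
        raters=tuple(f"r{j}" for j in range(x.shape[1])),
        rater_kind="runs_within_scanner",
    )


@pytest.fixture(scope="session")
def preset_cohort() -> sr.CohortTable:
    """The default 21 x 3 x 2 design with one missing GE rescan."""
    return sr.generate_cohort(sr.preset_study_design(seed=42))


@pytest.fixture(scope="session")
def normalized_preset(preset_cohort) -> sr.CohortTable:
    return sr.normalize_by_tiv(preset_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)
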