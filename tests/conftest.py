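import numpy as np
import pytest

from reefsync import AbundanceTimeSeries, SiteYearMatrix


@pytest.fixture
def toy_series() -> AbundanceTimeSeries:
    """2 sites x 3 years x 2 taxa with simple hand-checkable values."""
    cover = np.array(
        [
            [[10.0, 30.0], [20.0, 20.0], [30.0, 10.0]],
            [[20.0, 10.0], [40.0, 20.0], [60.0, 30.0]],
        ]
    )
    return AbundanceTimeSeries(
        sites=["FR1", "FR2"], years=[2013, 2014, 2015], taxa=["a", "b"], cover=cover
    )


@pytest.fixture
def anti_matrix() -> SiteYearMatrix:
    """Two taxa whose covers sum to the same constant in every year."""
    return SiteYearMatrix(
        years=(2013, 2014, 2015),
        taxa=("A", "B"),
        values=np.array([[10.0, 30.0], [20.0, 20.0], [30.0, 10.0]]),
    )


@pytest.fixture
def sync_matrix() -> SiteYearMatrix:
    """Two identical population trajectories (perfect synchrony)."""
    return SiteYearMatrix(
        years=(2013, 2014, 2015),
        taxa=("A", "B"),
        values=np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]),
    )


def random_matrix(rng: np.random.Generator, n_years: int = 5, n_taxa: int = 4) -> SiteYearMatrix:
    values = rng.lognormal(mean=1.0, sigma=0.5, size=(n_years, n_taxa))
    return SiteYearMatrix(
        years=tuple(range(2000, 2000 + n_years)),
        taxa=tuple(f"t{i}" for i in range(n_taxa)),
        values=values,
    )
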