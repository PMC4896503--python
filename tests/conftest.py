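import numpy as np
import pytest

from densimm.experiment_io import RemovalEvent, SiteSeries, StudyDataset


@pytest.fixture
def simple_site() -> SiteSeries:
    """A small hand-built site: 60 fish, constant removals of 9, some immigration."""
    events = [
        RemovalEvent(0, 0, 60, 0),
        RemovalEvent(0, 0, 60, 0),
        RemovalEvent(1, 9, 51, 2),
        RemovalEvent(2, 9, 44, 0),
        RemovalEvent(3, 9, 35, 3),
        RemovalEvent(4, 9, 29, 4),
        RemovalEvent(5, 9, 24, 1),
        RemovalEvent(6, 9, 16, 2),
        RemovalEvent(7, 9, 9, 1),
        RemovalEvent(8, 9, 1, 0),
        RemovalEvent(9, 1, 0, 0),
        RemovalEvent(10, 0, 0, 0),
    ]
    return SiteSeries(site_id="A", n_initial=60, events=events)


@pytest.fixture
def simple_dataset(simple_site) -> StudyDataset:
    other = SiteSeries(
        site_id="B",
        n_initial=10,
        events=[
            RemovalEvent(1, 2, 8, 1),
            RemovalEvent(2, 2, 7, 0),
            RemovalEvent(3, 2, 5, 0),
            RemovalEvent(4, 2, 3, 0),
            RemovalEvent(5, 2, 1, 0),
            RemovalEvent(6, 1, 0, 0),
        ],
    )
    return StudyDataset(sites=[simple_site, other])


def random_valid_site(rng: np.random.Generator, site_id: str = "R") -> SiteSeries:
    """Build a random site that satisfies the bookkeeping identity by construction."""
    n_initial = int(rng.integers(5, 80))
    r = max(1, int(round(float(rng.uniform(0.1, 0.3)) * n_initial)))
    events = [RemovalEvent(0, 0, n_initial, 0) for _ in range(int(rng.integers(0, 4)))]
    present, t = n_initial, 0
    while True:
        t += 1
        removed = min(r, present)
        present -= removed
        immigrants = int(rng.poisson(1.0)) if present > 0 else int(rng.poisson(0.2))
        events.append(RemovalEvent(t, removed, present, immigrants))
        present += immigrants
        if t > 3 and present == 0 and immigrants == 0:
            break
        if t > 200:
            events.append(RemovalEvent(t + 1, present, 0, 0))
            break
    return SiteSeries(site_id=site_id, n_initial=n_initial, events=events)
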