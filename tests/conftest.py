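import numpy as np
import pytest

from segmap import datasets
from segmap.sssl_core import SSSLLine


@pytest.fixture(scope="session")
def gmap():
    return datasets.load_genetic_map()


@pytest.fixture(scope="session")
def detections():
    return datasets.load_detections()


@pytest.fixture(scope="session")
def detection_segments(gmap):
    return datasets.load_detection_segments(gmap)


@pytest.fixture(scope="session")
def nonsignificant(gmap):
    return datasets.load_nonsignificant(gmap)


@pytest.fixture(scope="session")
def gene_table():
    return datasets.load_gene_table()


def make_line(line_id, season_means, rng, reps=5, sd=0.03, donor="D1"):
    """Gaussian replicates around per-season means, clipped to [0, 1]."""
    phenos = {
        s: list(np.clip(rng.normal(m, sd, reps), 0.0, 1.0))
        for s, m in season_means.items()
    }
    return SSSLLine(line_id, donor, None, phenos)
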