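import numpy as np
import pytest
from hypothesis import settings

from svdtax.species_io import Dataset, SpeciesRecord
from svdtax.svd_space import DistanceMatrix

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# Printed per-cluster cLtlf vectors for the 8-cluster mitochondrial runs
# (threshold clustering and k-means, both at rank 9) and the 8-cluster/rank-6
# configuration; frozen reference inputs for the quality statistics.
CLTLF_ASAP_K09 = [100, 225, 56, 56, 24, 40, 48, 13]
CLTLF_KMEANS_K09 = [100, 140, 48, 40, 81, 40, 60, 64]
CLTLF_8C_K06 = [100, 200, 56, 13, 100, 45, 24, 40]

# The canonical bird lineage through Subclassis (rank 10), per the published
# 14-rank table for Aythya americana.
AVES_PREFIX = (
    "Eukaryota", "Animalia", "Eumetazoa", "Bilateria", "Deuterostomia",
    "Chordata", "Vertebrata", "Gnathostomata", "Aves", "Carinatae",
)


def aves_lineages(n=10):
    """n bird lineages agreeing through rank 10 and diverging at rank 11."""
    return [
        AVES_PREFIX + (f"Ordo{i}", f"Fam{i}", f"Gen{i}", f"Sp{i}")
        for i in range(n)
    ]


@pytest.fixture
def aves_taxonomy():
    return {f"bird{i}": lin for i, lin in enumerate(aves_lineages(10))}


def distance_matrix_from(values, ids=None, k_used=1):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ids = tuple(ids) if ids else tuple(f"s{i}" for i in range(n))
    return DistanceMatrix(values, k_used, ids)


def random_distance_matrix(rng, n):
    """A random symmetric zero-diagonal matrix (points in the plane)."""
    pts = rng.normal(size=(n, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return distance_matrix_from(d)


@pytest.fixture
def tiny_dataset():
    """Four species over short hand-written sequences (no lineages)."""
    recs = [
        SpeciesRecord("spA", "MKVAMKVA"),
        SpeciesRecord("spB", "MKVAMKVC"),
        SpeciesRecord("spC", "WWYYWWYY"),
        SpeciesRecord("spD", "WWYYWWYW"),
    ]
    return Dataset(recs)
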