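import numpy as np
import pytest

from lwph.filtrations import WeightedPointCloud, euclidean_matrix, localized_weighted_matrix
from lwph.rips_persistence import barcodes_from_matrix
from lwph.structures_io import build_base_pair


@pytest.fixture(scope="session")
def at_pair():
    return build_base_pair("A-T")


@pytest.fixture(scope="session")
def gc_pair():
    return build_base_pair("G-C")


@pytest.fixture(scope="session")
def at_lph_barcode(at_pair):
    cloud = WeightedPointCloud.from_structure(at_pair)
    return barcodes_from_matrix(euclidean_matrix(cloud), max_scale=10.0)


@pytest.fixture(scope="session")
def gc_lph_barcode(gc_pair):
    cloud = WeightedPointCloud.from_structure(gc_pair)
    return barcodes_from_matrix(euclidean_matrix(cloud), max_scale=10.0)


@pytest.fixture(scope="session")
def at_lwph_barcode(at_pair):
    cloud = WeightedPointCloud.from_structure(at_pair)
    return barcodes_from_matrix(localized_weighted_matrix(cloud), max_scale=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_cloud(rng, n, scale=4.0, n_residues=3, n_molecules=2):
    pts = rng.uniform(0, scale, (n, 3))
    return WeightedPointCloud(
        pts,
        weights=rng.uniform(0.3, 1.0, n),
        residue_labels=[int(x) for x in rng.integers(0, n_residues, n)],
        molecule_labels=[int(x) for x in rng.integers(0, n_molecules, n)],
    )
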