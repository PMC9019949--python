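import numpy as np
import pytest

from diffqa.maps import DifferenceMap, ModelRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_symmetric_map(rng, n, low=0.0, high=25.0):
    """A random symmetric non-negative distance-like matrix with zero diagonal."""
    m = rng.uniform(low, high, size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


def make_record(rng, length, target_id="t0", model_id="m0", true_gdtts=None):
    u = np.triu(rng.normal(0.0, 1.0, size=(length, length)), k=1)
    return ModelRecord(target_id, model_id, DifferenceMap(u),
                       true_gdtts=true_gdtts)


@pytest.fixture
def tiny_pdb(tmp_path):
    """Write a minimal CA/CB PDB from explicit coordinates; returns a factory."""

    def _write(ca_coords, residue_names=None, name="model.pdb"):
        from diffqa.synthetic import write_pdb

        ca_coords = np.asarray(ca_coords, dtype=float)
        if residue_names is None:
            residue_names = ["ALA"] * len(ca_coords)
        path = tmp_path / name
        write_pdb(path, ca_coords, residue_names)
        return str(path)

    return _write
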