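import pytest

from npclust.fingerprints import fingerprint_set
from npclust.synthetic import generate_dataset


@pytest.fixture(scope="session")
def std_dataset():
    """Synthetic collection: 5 families (sizes 3-8) + 3 singletons, fixed seed."""
    compounds, truth = generate_dataset(
        n_families=5,
        family_size_distribution=(3, 4, 5, 6, 7, 8),
        n_singletons=3,
        seed=11,
    )
    return compounds, truth


@pytest.fixture(scope="session")
def std_fps(std_dataset):
    compounds, _ = std_dataset
    return fingerprint_set(compounds)


@pytest.fixture
def write_csv(tmp_path):
    """Write rows (dicts) to a CSV compound table and return its path."""

    def _write(rows, name="compounds.csv"):
        cols = ["compound_id", "smiles", "name", "kingdom", "year"]
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write(",".join(cols) + "\n")
            for row in rows:
                fh.write(",".join(str(row.get(c, "")) for c in cols) + "\n")
        return path

    return _write
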