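import numpy as np
import pytest

from tcmchromatin.catalog import load_default_modification_catalog
from tcmchromatin.simulate import GeneratorConfig, generate_bundle


@pytest.fixture(scope="session")
def modcat():
    return load_default_modification_catalog()


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition synthetic bundle shared across tests."""
    return generate_bundle(GeneratorConfig(seed=12345))


def write_tsv(path, header, rows):
    lines = ["\t".join(header)]
    lines += ["\t".join(str(c) for c in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def medicinal_tsv(tmp_path):
    """Small hand-written catalog with a duplicated id."""
    return write_tsv(
        tmp_path / "medicinals.tsv",
        ["medicinal_id", "scientific_name", "lineage", "nature", "flavors",
         "chemicals"],
        [
            ["M1", "Planta prima", "Plantae;Rosales;Rosa;Rosa prima",
             "hot", "sweet;mild pungent", "C1;C2"],
            ["M2", "Planta secunda", "Plantae;Rosales;Rosa;Rosa secunda",
             "cold", "bitter", "C3"],
            ["M1", "Planta prima", "Plantae;Rosales;Rosa;Rosa prima",
             "cold", "sour", "C4"],
            ["M3", "Planta tertia", "Plantae;Fagales;Quercus;Quercus tertia",
             "NA", "", "C5"],
        ])


def random_weight_matrix(rng, n):
    """Symmetric positive off-diagonal weights from random point distances."""
    pts = rng.random((n, 2))
    D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    np.fill_diagonal(D, 0.0)
    W = np.zeros_like(D)
    off = ~np.eye(n, dtype=bool)
    W[off] = 1.0 / D[off]
    return W
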