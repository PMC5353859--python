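import numpy as np
import pandas as pd
import pytest

from secrepath.catalogue import Catalogue, Component
from secrepath.network import Interaction


@pytest.fixture
def toy_catalogue() -> Catalogue:
    comps = [
        Component("Sec61a", subsystems=frozenset({"translocation"}),
                  complexes=frozenset({"Sec61"}),
                  functional_groups=frozenset({"translocon"})),
        Component("Sec61b", subsystems=frozenset({"translocation"}),
                  complexes=frozenset({"Sec61"}),
                  functional_groups=frozenset({"translocon"})),
        Component("Hspa5", subsystems=frozenset({"protein_folding", "UPR"}),
                  functional_groups=frozenset({"chaperones"})),
        Component("Psma1", subsystems=frozenset({"ERAD"}),
                  complexes=frozenset({"proteasome"})),
        Component("Psma2", subsystems=frozenset({"ERAD"}),
                  complexes=frozenset({"proteasome"})),
        Component("Xbp1", subsystems=frozenset({"UPR"})),
    ]
    return Catalogue(components=comps, species="mouse", source="fixture")


@pytest.fixture
def toy_interactions() -> list[Interaction]:
    return [
        Interaction("Sec61a", "Hspa5", "protein_protein"),
        Interaction("Xbp1", "Hspa5", "protein_DNA", directed=True),
    ]


@pytest.fixture
def toy_catalogue_file(tmp_path, toy_catalogue):
    from secrepath.catalogue import save_catalogue

    path = tmp_path / "catalogue.tsv"
    save_catalogue(toy_catalogue, path)
    return path


@pytest.fixture
def small_expression() -> pd.DataFrame:
    """12 genes x 10 samples: two tight modules of 4 plus 4 noise genes."""
    rng = np.random.default_rng(42)
    n_samples = 10
    f1 = rng.standard_normal(n_samples)
    f2 = rng.standard_normal(n_samples)
    rows = {}
    for i in range(4):
        rows[f"a{i}"] = f1 + rng.normal(0, 0.05, n_samples)
    for i in range(4):
        rows[f"b{i}"] = f2 + rng.normal(0, 0.05, n_samples)
    for i in range(4):
        rows[f"n{i}"] = rng.standard_normal(n_samples)
    return pd.DataFrame(rows).T.set_axis([f"s{j}" for j in range(n_samples)], axis=1)
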