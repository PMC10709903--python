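import numpy as np
import pytest

from mmkge.kg_data import AttributedKG, AttributeRecord, Triple
from mmkge.synthetic_data import SynthConfig, generate_attributed_kg


@pytest.fixture
def tiny_kg() -> AttributedKG:
    """Hand-built five-entity KG with one attribute of each modality."""
    triples = [
        Triple("p1", "ppi", "p2"),
        Triple("d1", "dpi", "p1"),
        Triple("p2", "assoc", "x1"),
        Triple("d1", "treats", "x1"),
        Triple("p1", "assoc", "x1"),
        Triple("p2", "ppi", "p1"),
    ]
    types = {"p1": "protein", "p2": "protein", "d1": "drug",
             "x1": "disease", "w1": "pathway"}
    triples.append(Triple("p1", "in_path", "w1"))
    attrs = {
        "p1": AttributeRecord("protein_sequence", "ACDEFGHIKLMNPQRSTVWY" * 2),
        "d1": AttributeRecord("molecule_string", "CC(=O)Oc1ccccc1"),
        "x1": AttributeRecord("text", "a chronic inflammatory disorder"),
    }
    return AttributedKG(types, {t.relation for t in triples}, triples, attrs)


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic attributed KG shared by read-only tests."""
    from mmkge.workflows import make_study
    return make_study(0, config=SynthConfig(seed=0, n_triples=800), n_pairs=30)


@pytest.fixture(scope="session")
def default_kg():
    kg, gt = generate_attributed_kg(SynthConfig(seed=11))
    return kg, gt
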