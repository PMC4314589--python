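import numpy as np
import pytest

from cofunet.core_io import AnnotationTable, TermInfo
from cofunet.gold_standard import GoldStandard, positives_from_annotation
from cofunet import synthetic as syn


@pytest.fixture
def tiny_gold() -> GoldStandard:
    """Six annotated genes, two 3-cliques: 6 positives, 9 negatives."""
    table = AnnotationTable()
    info = TermInfo(source="GO-BP", evidence_codes=frozenset({"IDA"}))
    table.add_term("T1", {"a", "b", "c"}, info)
    table.add_term("T2", {"d", "e", "f"}, info)
    return GoldStandard(
        positives=frozenset(positives_from_annotation(table)),
        annotated_genes=frozenset(table.genes()),
    )


@pytest.fixture
def module_gold():
    """Planted-module gold standard: 20 modules of 5 genes over 150 genes."""
    table, modules = syn.module_annotation((5,) * 20, 150)
    gold = GoldStandard(
        positives=frozenset(positives_from_annotation(table)),
        annotated_genes=frozenset(table.genes()),
    )
    return gold, modules


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240911)
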