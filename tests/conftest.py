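import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

import uprepeats as up


@pytest.fixture(scope="session")
def default_dataset():
    """One generated dataset under the default study conditions (500 genes,
    10 repeat classes, 40 genes planted with TSS<>MIR<>Alu, 20% repeat-free)."""
    return up.generate(up.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_catalog(default_dataset):
    ds = default_dataset
    return up.catalog_patterns(ds.genes, ds.repeats, rd=ds.config.rd)


@pytest.fixture
def small_genes():
    return [
        up.GeneModel("geneA", up.GenomicInterval("chr1", 5000, 9000, "+")),
        up.GeneModel("geneB", up.GenomicInterval("chr1", 20000, 26000, "-")),
    ]
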