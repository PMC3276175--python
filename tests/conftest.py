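import io

import numpy as np
import pytest

from plastidnc.genome import Annotation, GeneFeature, load_category_map


@pytest.fixture(scope="session")
def category_map():
    return load_category_map()


@pytest.fixture
def simple_annotation():
    """One cluster of two + genes and one lone - gene, length 2000."""
    return Annotation(
        2000,
        [
            GeneFeature("G1", 100, 400, "+", "protein", "photosynthesis", "op1"),
            GeneFeature("G2", 600, 900, "+", "protein", "photosynthesis", "op1"),
            GeneFeature("G3", 1200, 1500, "-", "protein", "gene_expression", "op2"),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20110701)


def make_gff3(lines, length=1000):
    body = "\n".join(lines)
    return io.StringIO(
        f"##gff-version 3\n##sequence-region chr 1 {length}\n{body}\n" if lines
        else f"##gff-version 3\n##sequence-region chr 1 {length}\n"
    )
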