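import shutil

import pytest

from pulrecon.reconciliation import PhyloTree


HAVE_BLAST = shutil.which("blastn") is not None and shutil.which("makeblastdb") is not None


@pytest.fixture
def species5() -> PhyloTree:
    return PhyloTree.from_newick("(((A,B),(C,D)),E);")


@pytest.fixture
def species8() -> PhyloTree:
    return PhyloTree.from_newick("((((A,B),(C,D)),((E,F),G)),H);")
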