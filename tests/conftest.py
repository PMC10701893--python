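import dendropy
import pytest

from mitomine.core_io import GeneticCode


@pytest.fixture(scope="session")
def code3() -> GeneticCode:
    return GeneticCode.from_ncbi(3)


@pytest.fixture(scope="session")
def code4() -> GeneticCode:
    return GeneticCode.from_ncbi(4)


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted",
        preserve_underscores=True,
    )


def balanced_tree(n_tips: int, branch_length: float) -> dendropy.Tree:
    """A fully balanced rooted tree with equal branch lengths."""
    labels = [f"t{i}" for i in range(n_tips)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{labels[lo]}:{branch_length}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{branch_length}"

    inner = build(0, n_tips)
    # root edge length on the top node is ignored
    return make_tree(f"{inner};")
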