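import pytest

from ogbench.model import GeneID, OrthogroupCollection, make_universe


def gid(token: str) -> GeneID:
    return GeneID.parse(token)


def gids(*tokens: str):
    return frozenset(gid(t) for t in tokens)


def collection(name, role, **groups):
    return OrthogroupCollection(
        name, role, {lab: frozenset(m) for lab, m in groups.items()}
    )


@pytest.fixture
def small_universe():
    """Five genes of one reference orthogroup's species plus a stray."""
    return make_universe(
        [gid(f"A|a{i}") for i in range(1, 5)] + [gid("A|x")]
    )


@pytest.fixture
def four_gene_refog():
    return collection("ref", "reference", R1=gids("A|a1", "A|a2", "A|a3", "A|a4"))
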