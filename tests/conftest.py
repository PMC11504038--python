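import pytest

from nlrevo import DomainHit, GeneTree
from nlrevo.nlr_identify import DomainArchitecture

_DOMAIN_NAME = {"nbarc": "NB-ARC", "tir": "TIR", "rpw8": "RPW8",
                "rxn": "Rx_N", "lrr": "LRR_1"}


def arch_from_flags(nbarc=False, tir=False, rpw8=False, rxn=False,
                    lrr=False) -> DomainArchitecture:
    """Build a DomainArchitecture from presence flags via synthetic hits."""
    flags = {"nbarc": nbarc, "tir": tir, "rpw8": rpw8, "rxn": rxn, "lrr": lrr}
    hits = [DomainHit("p", _DOMAIN_NAME[k], 100 * i + 1, 100 * i + 50, 1e-10)
            for i, (k, v) in enumerate(flags.items()) if v]
    return DomainArchitecture.from_hits("p", hits)


@pytest.fixture
def labeled_tree():
    def build(newick: str, species: dict) -> GeneTree:
        return GeneTree.from_newick(newick, species)

    return build
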