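import pytest

from haplocase.reference import load_reference, _data_path
from haplocase.haplotree import load_tree

CONTROL_REGION_WINDOW = ((16033, 16569), (1, 850))
FULL_GENOME = ((1, 16569),)


@pytest.fixture(scope="session")
def ref():
    return load_reference()


@pytest.fixture(scope="session")
def tree(ref):
    return load_tree(_data_path("haplotree_east_asian.tsv"), ref)


@pytest.fixture
def toy_tree(ref, tmp_path):
    """Small rooted tree with a back-mutation branch for classifier unit tests."""
    text = (
        "0\troot\n"
        "1\tM\t489C,16223T\n"
        "2\tM7b\t4164G,16297C\n"
        "3\tM7b1\t199C\n"
        "1\tN\t16519C\n"
        "2\tNback\t16223T,16519C!\n"
    )
    p = tmp_path / "toy.tsv"
    p.write_text(text)
    return load_tree(p, ref)


def path_profile(tree, name, region=FULL_GENOME, extra=()):
    """Profile carrying the full defining path of a tree node (test helper)."""
    from haplocase.calling import HaplotypeProfile
    from haplocase.simulate import _path_calls

    calls = [c for c in _path_calls(tree, name)
             if any(lo <= c.position <= hi for lo, hi in region)]
    return HaplotypeProfile(name, tuple(calls) + tuple(extra), region=region)
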