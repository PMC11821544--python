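import numpy as np
import pytest

from pseudocage import blocks, lattice, symcore


@pytest.fixture(scope="session")
def group():
    return symcore.icosahedral_rotations()


@pytest.fixture(scope="session")
def small_trimer():
    """Compact bar-tipped trimer used throughout: cheap but fully featured."""
    return blocks.synthetic_trimer(
        radius=3.0, n_residues_per_chain=8, seed=1, bar_residues=3
    )


@pytest.fixture(scope="session")
def t1_parent(group, small_trimer):
    return blocks.build_t1_parent(small_trimer, group=group)


@pytest.fixture(scope="session")
def cage_h2(small_trimer):
    lc = blocks.recommended_lattice_constant(small_trimer)
    return blocks.assemble_cage(lattice.layout(2, lc), small_trimer)


@pytest.fixture(scope="session")
def cage_h3(small_trimer):
    lc = blocks.recommended_lattice_constant(small_trimer)
    return blocks.assemble_cage(lattice.layout(3, lc), small_trimer)
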