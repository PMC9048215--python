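import numpy as np

from atsf.molecule import AtomRecord, MoleculeGraph


def toy_molecule(elements, coords):
    """A small chain-bonded toy molecule (bonds are irrelevant to descriptors)."""
    atoms = [
        AtomRecord(i, el, f"{el}{i}", np.asarray(c, float))
        for i, (el, c) in enumerate(zip(elements, coords))
    ]
    bonds = {(i, i + 1) for i in range(len(atoms) - 1)}
    return MoleculeGraph(atoms, bonds)
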