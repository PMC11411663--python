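import numpy as np
import pytest

from fodm.structure_io import EffectiveAtomSet, ResidueCentroid


def atom_line(serial, name, resname, chain, resseq, x, y, z,
              occ=1.0, altloc=" ", icode=" ", record="ATOM"):
    """One wwPDB v3.3 coordinate line."""
    element = name.strip()[0]
    return (f"{record:<6s}{serial:5d}  {name:<3s}{altloc}{resname:>3s} "
            f"{chain}{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}")


@pytest.fixture
def make_pdb():
    def _make(lines):
        return "\n".join(lines + ["END"]) + "\n"
    return _make


@pytest.fixture
def two_residue_pdb(make_pdb):
    """ALA-VAL dipeptide-like fixture, one chain, CA-only plus one CB."""
    return make_pdb([
        atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
        atom_line(2, "CB", "ALA", "A", 1, 2.0, 0.0, 0.0),
        atom_line(3, "CA", "VAL", "A", 2, 5.0, 0.0, 0.0),
    ])


@pytest.fixture
def make_eas():
    """Factory: EffectiveAtomSet from an (N, 3) array and optional letters."""
    def _make(coords, letters=None, label="test"):
        coords = np.asarray(coords, dtype=float)
        if letters is None:
            letters = ["A"] * len(coords)
        residues = [ResidueCentroid(residue_id=f"A:{i + 1}",
                                    one_letter=letters[i],
                                    centroid=coords[i])
                    for i in range(len(coords))]
        return EffectiveAtomSet(residues=residues, unit_label=label)
    return _make


@pytest.fixture
def random_cloud():
    """Factory: seeded random point cloud with a realistic spread."""
    def _make(seed=0, n=50, scale=8.0):
        rng = np.random.default_rng(seed)
        return rng.normal(scale=scale, size=(n, 3))
    return _make
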