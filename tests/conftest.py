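import numpy as np
import pytest

from inmkit import HingeSpec, make_hinge_protein


ONE_ATOM_PDB = (
    "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00"
    "           C\n"
    "END\n"
)


def _atom_line(serial, name, resname, chain, resid, xyz, element):
    pad = " " + name if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {pad:<4s} {resname:<3s} {chain}{resid:4d}"
            f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {element:>2s}\n")


@pytest.fixture(scope="session")
def two_chain_pdb():
    """3 residues: two in chain A, one in chain B."""
    lines = [
        _atom_line(1, "N", "ALA", "A", 1, (0, 0, 0), "N"),
        _atom_line(2, "CA", "ALA", "A", 1, (1.4, 0, 0), "C"),
        _atom_line(3, "CA", "GLY", "A", 2, (4.0, 1, 0), "C"),
        _atom_line(4, "CA", "SER", "B", 5, (8.0, 2, 1), "C"),
        _atom_line(5, "O", "SER", "B", 5, (9.0, 2, 1), "O"),
        "END\n",
    ]
    return "".join(lines)


@pytest.fixture(scope="session")
def multimodel_pdb():
    """5 MODEL blocks of the same 2-atom topology, distinct coordinates."""
    out = []
    for m in range(5):
        out.append(f"MODEL     {m + 1:4d}\n")
        out.append(_atom_line(1, "CA", "ALA", "A", 1,
                              (m + 0.25, 2 * m, -m), "C"))
        out.append(_atom_line(2, "CA", "GLY", "A", 2,
                              (m + 4.0, 2 * m + 1, -m + 0.5), "C"))
        out.append("ENDMDL\n")
    out.append("END\n")
    return "".join(out)


@pytest.fixture(scope="session")
def hinge_spec():
    return HingeSpec(n_per_domain=30, open_angle=120.0, closed_angle=60.0,
                     seed=0)


@pytest.fixture(scope="session")
def open_hinge(hinge_spec):
    return make_hinge_protein(hinge_spec, "open")


@pytest.fixture(scope="session")
def closed_hinge(hinge_spec):
    return make_hinge_protein(hinge_spec, "closed")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
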