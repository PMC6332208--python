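import math

import numpy as np
import pytest

from intercomap import MoleculeSelection, make_toy_complex

# ---------------------------------------------------------------------------
# hand-written PDB fixture: 2 chains x 2 residues, 2 atoms each


PDB_TWO_CHAIN = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       5.258   0.000   0.000  1.00  0.00           C
TER
ATOM      5  N   LYS B  10       0.000   4.000   0.000  1.00  0.00           N
ATOM      6  CA  LYS B  10       1.458   4.000   0.000  1.00  0.00           C
ATOM      7  N   ASP B  11       3.800   4.000   0.000  1.00  0.00           N
ATOM      8  CA  ASP B  11       5.258   4.000   0.000  1.00  0.00           C
TER
END
"""

PDB_WATERS_ONLY = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""

PDB_ALTLOC = """\
ATOM      1  N  ASER A   1       0.000   0.000   0.000  0.30  0.00           N
ATOM      2  N  BSER A   1       9.000   0.000   0.000  0.70  0.00           N
ATOM      3  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C
TER
ATOM      4  N   GLY B   1       0.000   3.000   0.000  1.00  0.00           N
TER
END
"""


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(PDB_TWO_CHAIN)
    return p


@pytest.fixture
def toy_model():
    return make_toy_complex(10, 8, seed=42)


@pytest.fixture
def sel_ab():
    return MoleculeSelection({"A"}), MoleculeSelection({"B"})


# ---------------------------------------------------------------------------
# independent brute-force oracles


def brute_force_min_distance(res1, res2):
    """Exhaustive double loop over heavy-atom pairs."""
    best = math.inf
    for a in res1.atoms:
        if not a.is_heavy:
            continue
        for b in res2.atoms:
            if not b.is_heavy:
                continue
            best = min(best, math.dist(a.coord, b.coord))
    return best


def brute_force_contact_pairs(model, sel1, sel2, cutoff):
    """All residue pairs in contact, by exhaustive all-pairs scan."""
    res1 = [r for r in model.residues if sel1.matches(r)]
    res2 = [r for r in model.residues if sel2.matches(r)]
    pairs = set()
    for r1 in res1:
        for r2 in res2:
            if brute_force_min_distance(r1, r2) <= cutoff:
                pairs.add((r1.key, r2.key))
    return pairs


def brute_force_rates(ensemble, sel1, sel2, cutoff):
    """Per-pair conservation rates by independent per-model tallying."""
    counts = {}
    for model in ensemble:
        for pair in brute_force_contact_pairs(model, sel1, sel2, cutoff):
            counts[pair] = counts.get(pair, 0) + 1
    return {p: c / ensemble.n_models for p, c in counts.items()}


def monte_carlo_atom_sasa(coords, radii_ext, i, n_mc, seed):
    """Seeded Monte-Carlo SASA estimate for atom i against expanded neighbours."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_mc, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts = coords[i] + radii_ext[i] * pts
    free = np.ones(n_mc, dtype=bool)
    for j in range(len(coords)):
        if j == i:
            continue
        free &= np.sum((pts - coords[j]) ** 2, axis=1) >= radii_ext[j] ** 2
    return 4.0 * np.pi * radii_ext[i] ** 2 * free.mean()
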