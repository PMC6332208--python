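"""Inter-molecular residue–residue contact maps.

Two residues are in contact when at least one pair of heavy atoms (one atom
from each residue) lies within the distance cutoff, boundary inclusive — the
CAPRI residue-contact definition at 5 Å. Classical and property maps of a
single structure conventionally use a 6 Å cutoff instead; both defaults are
exposed (:data:`CONSENSUS_CUTOFF`, :data:`CLASSICAL_CUTOFF`).

Contacts are annotated with a physicochemical pair class (both hydrophobic,
both polar, both charged, or mixed) and a distance-range bin, reproducing the
two single-structure map styles; the class table and bin edges are
user-overridable. Geometric hydrogen-bond detection across the interface is
also provided (donor/acceptor N,O within 3.5 Å, with a D–H···A angle test when
hydrogens are present) — a standard criterion, configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure import (
    Model,
    MoleculeSelection,
    Residue,
    ResidueKey,
    check_disjoint,
    select,
)

__all__ = [
    "CONSENSUS_CUTOFF",
    "CLASSICAL_CUTOFF",
    "DEFAULT_BIN_EDGES",
    "DEFAULT_PROPERTY_TABLE",
    "NO_BIN",
    "ContactRecord",
    "ContactMap",
    "min_heavy_atom_distance",
    "classify_contact_property",
    "assign_distance_bin",
    "compute_contact_map",
    "detect_hbonds",
    "interacting_residue_table",
    "dense_matrix",
    "sparse_table",
]

#: CAPRI-style residue contact cutoff used for consensus maps and ranking (Å).
CONSENSUS_CUTOFF = 5.0
#: Cutoff for classical/property maps of a single structure (Å).
CLASSICAL_CUTOFF = 6.0
#: Default upper edges of the distance-range bins (Å).
DEFAULT_BIN_EDGES = (7.0, 10.0, 13.0, 16.0)
#: Sentinel bin index for distances beyond the last edge.
NO_BIN = -1

# Standard hydropathy grouping of the 20 amino acids (user-overridable).
DEFAULT_PROPERTY_TABLE: dict[str, str] = {}
for _name in ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY", "CYS"):
    DEFAULT_PROPERTY_TABLE[_name] = "hydrophobic"
for _name in ("ASP", "GLU", "LYS", "ARG", "HIS"):
    DEFAULT_PROPERTY_TABLE[_name] = "charged"
for _name in ("SER", "THR", "ASN", "GLN", "TYR"):
    DEFAULT_PROPERTY_TABLE[_name] = "hydrophilic"

PROPERTY_CLASSES = (
    "hydrophobic-hydrophobic",
    "hydrophilic-hydrophilic",
    "charged-charged",
    "mixed",
)


@dataclass(frozen=True)
class ContactRecord:
    """One residue pair in contact: (sel1 residue, sel2 residue) ordered."""

    pair: tuple[ResidueKey, ResidueKey]
    min_dist: float
    property_class: str
    range_bin: int


@dataclass(frozen=True)
class ContactMap:
    """Set of inter-selection contacts of one model at a fixed cutoff."""

    records: dict  # (key1, key2) -> ContactRecord
    cutoff: float
    axis1: tuple[ResidueKey, ...]
    axis2: tuple[ResidueKey, ...]

    @property
    def pairs(self) -> set[tuple[ResidueKey, ResidueKey]]:
        return set(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pair) -> bool:
        return pair in self.records


def min_heavy_atom_distance(res1: Residue, res2: Residue) -> float:
    """Minimum Euclidean distance (Å) over all heavy-atom pairs."""
    return float(cdist(res1.heavy_coords(), res2.heavy_coords()).min())


def classify_contact_property(
    res1: Residue,
    res2: Residue,
    table: Optional[dict[str, str]] = None,
) -> str:
    """Physicochemical class of a residue pair; symmetric in its arguments.

    Pairs involving nucleotides or other non-amino-acid groups are "mixed";
    an amino acid missing from the class table triggers a warning.
    """
    if res1.polymer_class != "amino_acid" or res2.polymer_class != "amino_acid":
        return "mixed"
    table = DEFAULT_PROPERTY_TABLE if table is None else table
    classes = []
    for res in (res1, res2):
        cls = table.get(res.resname)
        if cls is None:
            warnings.warn(f"residue name {res.resname!r} not in property table", stacklevel=2)
            return "mixed"
        classes.append(cls)
    if classes[0] == classes[1]:
        return f"{classes[0]}-{classes[1]}"
    return "mixed"


def assign_distance_bin(d: float, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES) -> int:
    """Smallest bin index i with d <= bin_edges[i]; NO_BIN past the last edge."""
    for i, edge in enumerate(bin_edges):
        if d <= edge:
            return i
    return NO_BIN


def _selection_heavy_arrays(residues: Sequence[Residue]):
    """Stack heavy-atom coordinates of a residue list; returns (coords, owner)."""
    coords, owner = [], []
    for i, res in enumerate(residues):
        c = res.heavy_coords()
        coords.append(c)
        owner.append(np.full(len(c), i, dtype=int))
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.vstack(coords), np.concatenate(owner)


def compute_contact_map(
    model: Model,
    sel1: MoleculeSelection,
    sel2: MoleculeSelection,
    cutoff: float = CONSENSUS_CUTOFF,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    property_table: Optional[dict[str, str]] = None,
) -> ContactMap:
    """All inter-selection residue contacts of one model at ``cutoff`` Å.

    Candidate residue pairs are found with a k-d tree over heavy atoms; the
    minimum distance of each candidate pair is then evaluated exactly, so the
    result is identical to an exhaustive all-atom-pairs scan. Self pairs
    cannot occur because the two selections must be residue-disjoint (which
    also makes intra-chain, inter-domain maps well-formed).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    check_disjoint(model, sel1, sel2)
    res1 = select(model, sel1)
    res2 = select(model, sel2)
    axis1 = tuple(r.key for r in res1)
    axis2 = tuple(r.key for r in res2)
    records: dict[tuple[ResidueKey, ResidueKey], ContactRecord] = {}
    if res1 and res2:
        coords1, owner1 = _selection_heavy_arrays(res1)
        coords2, owner2 = _selection_heavy_arrays(res2)
        tree2 = cKDTree(coords2)
        # tiny padding so the exact <= comparison below is the sole arbiter
        neighbor_lists = tree2.query_ball_point(coords1, cutoff * (1 + 1e-12) + 1e-9)
        candidates: set[tuple[int, int]] = set()
        for a1, neigh in enumerate(neighbor_lists):
            i = owner1[a1]
            for a2 in neigh:
                candidates.add((int(i), int(owner2[a2])))
        for i, j in sorted(candidates):
            d = min_heavy_atom_distance(res1[i], res2[j])
            if d <= cutoff:
                pair = (res1[i].key, res2[j].key)
                records[pair] = ContactRecord(
                    pair=pair,
                    min_dist=d,
                    property_class=classify_contact_property(res1[i], res2[j], property_table),
                    range_bin=assign_distance_bin(d, bin_edges),
                )
    return ContactMap(records=records, cutoff=float(cutoff), axis1=axis1, axis2=axis2)


# ---------------------------------------------------------------------------
# hydrogen bonds

_DONOR_ACCEPTOR_ELEMENTS = frozenset({"N", "O"})
_MAX_COVALENT_H_DIST = 1.3  # Å, D-H bond detection


def _polar_atoms(residues: Sequence[Residue]):
    """(residue, atom) pairs whose element is N or O, plus attached hydrogens."""
    out = []
    for res in residues:
        hydrogens = [a for a in res.atoms if not a.is_heavy]
        for atom in res.heavy_atoms:
            if atom.element in _DONOR_ACCEPTOR_ELEMENTS:
                attached = [
                    h for h in hydrogens
                    if np.linalg.norm(h.xyz - atom.xyz) <= _MAX_COVALENT_H_DIST
                ]
                out.append((res, atom, attached))
    return out


def detect_hbonds(
    model: Model,
    sel1: MoleculeSelection,
    sel2: MoleculeSelection,
    max_dist: float = 3.5,
    min_angle_deg: float = 120.0,
) -> list[tuple[tuple, tuple, float]]:
    """Inter-selection hydrogen bonds by a geometric criterion.

    A donor heavy atom (N or O) and an acceptor heavy atom (N or O) on
    opposite sides form an H-bond when their distance is <= ``max_dist``; if
    the donor carries explicit hydrogens, at least one must give a D-H···A
    angle >= ``min_angle_deg``. Each pair is reported once per satisfied
    direction as ``(donor_atom_key, acceptor_atom_key, distance)`` where an
    atom key is ``(chain_id, resseq, icode, atom_name)``.
    """
    check_disjoint(model, sel1, sel2)
    polar1 = _polar_atoms(select(model, sel1))
    polar2 = _polar_atoms(select(model, sel2))
    out = []
    for side_a, side_b in ((polar1, polar2), (polar2, polar1)):
        for res_d, donor, hydrogens in side_a:
            for res_a, acceptor, _ in side_b:
                d = float(np.linalg.norm(donor.xyz - acceptor.xyz))
                if d > max_dist:
                    continue
                if hydrogens:
                    ok = False
                    for h in hydrogens:
                        v1 = donor.xyz - h.xyz
                        v2 = acceptor.xyz - h.xyz
                        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                        if denom == 0:
                            continue
                        angle = math.degrees(
                            math.acos(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))
                        )
                        if angle >= min_angle_deg:
                            ok = True
                            break
                    if not ok:
                        continue
                out.append(
                    (
                        (*res_d.key, donor.name),
                        (*res_a.key, acceptor.name),
                        d,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# tabular / matrix export

def _key_str(key: ResidueKey) -> str:
    c, n, ic = key
    return f"{c}:{n}{ic}"


def interacting_residue_table(cmap: ContactMap, model: Optional[Model] = None) -> pd.DataFrame:
    """One row per contact, sorted by axis order.

    Residue names are filled in when ``model`` is given, else left blank.
    """
    idx1 = {k: i for i, k in enumerate(cmap.axis1)}
    idx2 = {k: i for i, k in enumerate(cmap.axis2)}
    rows = []
    for pair in sorted(cmap.records, key=lambda p: (idx1[p[0]], idx2[p[1]])):
        rec = cmap.records[pair]
        k1, k2 = pair
        n1 = model.residue(k1).resname if model else ""
        n2 = model.residue(k2).resname if model else ""
        rows.append(
            {
                "res1": _key_str(k1),
                "res1_name": n1,
                "res2": _key_str(k2),
                "res2_name": n2,
                "min_dist": round(rec.min_dist, 3),
                "property_class": rec.property_class,
            }
        )
    return pd.DataFrame(
        rows, columns=["res1", "res1_name", "res2", "res2_name", "min_dist", "property_class"]
    )


def dense_matrix(cmap: ContactMap) -> pd.DataFrame:
    """Dense 0/1 contact matrix, rows = axis1, columns = axis2."""
    mat = np.zeros((len(cmap.axis1), len(cmap.axis2)), dtype=int)
    idx1 = {k: i for i, k in enumerate(cmap.axis1)}
    idx2 = {k: i for i, k in enumerate(cmap.axis2)}
    for (k1, k2) in cmap.records:
        mat[idx1[k1], idx2[k2]] = 1
    return pd.DataFrame(
        mat,
        index=[_key_str(k) for k in cmap.axis1],
        columns=[_key_str(k) for k in cmap.axis2],
    )


def sparse_table(cmap: ContactMap) -> pd.DataFrame:
    """Sparse triples (res1, res2, min_dist) for each contact, axis-ordered."""
    idx1 = {k: i for i, k in enumerate(cmap.axis1)}
    idx2 = {k: i for i, k in enumerate(cmap.axis2)}
    rows = [
        {
            "res1": _key_str(p[0]),
            "res2": _key_str(p[1]),
            "min_dist": round(cmap.records[p].min_dist, 3),
        }
        for p in sorted(cmap.records, key=lambda p: (idx1[p[0]], idx2[p[1]]))
    ]
    return pd.DataFrame(rows, columns=["res1", "res2", "min_dist"])
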