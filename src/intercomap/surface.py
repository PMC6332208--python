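"""Solvent-accessible surface area, interface area and buried residues.

SASA is computed with a built-in Shrake–Rupley implementation: each heavy atom
is covered with a deterministic golden-spiral point set on its solvent-expanded
sphere (radius + probe), and the accessible fraction is the share of points
not occluded by any neighbouring expanded sphere. The point set is fixed for a
given ``n_points`` — no random number generator is involved — so all areas are
bit-reproducible.

Interface area of a two-interactor complex follows the buried-surface
convention: half of ``SASA(sel1 alone) + SASA(sel2 alone) −
SASA(complex)``, where "alone" means the partner's atoms are removed.
Relative burial of a residue is its fractional SASA loss upon complex
formation; residues with >90% relative burial are conventionally called
fully buried.

Radii are a Chothia-style united-atom set (configurable); hydrogens are
excluded throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .contacts import CLASSICAL_CUTOFF, compute_contact_map, detect_hbonds
from .structure import (
    Model,
    MoleculeSelection,
    Residue,
    ResidueKey,
    check_disjoint,
    select,
)

__all__ = [
    "DEFAULT_RADII",
    "DEFAULT_PROBE",
    "DEFAULT_N_POINTS",
    "SasaResult",
    "InterfaceSummary",
    "sphere_points",
    "shrake_rupley_sasa",
    "interface_area",
    "buried_residues",
    "interface_summary",
    "burial_table",
]

#: Chothia-style united-atom van der Waals radii (Å), keyed by element.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_PROBE = 1.4  # Å, water probe
DEFAULT_N_POINTS = 960

#: Atom key used in per-atom tables: (chain_id, resseq, icode, atom_name).
AtomKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class SasaResult:
    per_atom: dict  # AtomKey -> Å²
    per_residue: dict  # ResidueKey -> Å²
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(sum(self.per_residue.values()))


@dataclass(frozen=True)
class InterfaceSummary:
    interface_area: float
    buried_residues_1: list  # (ResidueKey, relative_burial), descending
    buried_residues_2: list
    n_contacts: int
    hbonds: list

    def to_json(self) -> str:
        def _res(entries):
            return [
                {"chain": k[0], "resseq": k[1], "icode": k[2], "relative_burial": round(f, 4)}
                for k, f in entries
            ]

        return json.dumps(
            {
                "interface_area_A2": round(self.interface_area, 2),
                "n_contacts": self.n_contacts,
                "n_hbonds": len(self.hbonds),
                "buried_residues_1": _res(self.buried_residues_1),
                "buried_residues_2": _res(self.buried_residues_2),
                "hbonds": [
                    {"donor": list(d), "acceptor": list(a), "dist": round(x, 3)}
                    for d, a, x in self.hbonds
                ],
            },
            indent=2,
        )


@lru_cache(maxsize=8)
def sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = phi * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pts.setflags(write=False)
    return pts


def _atom_arrays(residues: Sequence[Residue], radii: dict[str, float]):
    keys: list[AtomKey] = []
    owner: list[ResidueKey] = []
    coords = []
    rads = []
    for res in residues:
        for atom in res.heavy_atoms:
            r = radii.get(atom.element)
            if r is None:
                raise ValueError(
                    f"no radius configured for element {atom.element!r} "
                    f"(atom {atom.name} of {res.label()})"
                )
            keys.append((*res.key, atom.name))
            owner.append(res.key)
            coords.append(atom.coord)
            rads.append(r)
    return keys, owner, np.asarray(coords, dtype=float), np.asarray(rads, dtype=float)


def shrake_rupley_sasa(
    residues: Sequence[Residue],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[dict[str, float]] = None,
) -> SasaResult:
    """Per-atom and per-residue solvent-accessible surface area (Å²).

    ``n_points`` sphere points per atom (>= 32); per-residue areas are the
    sums of the residue's per-atom areas.
    """
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    radii = DEFAULT_RADII if radii is None else radii
    keys, owner, coords, rads = _atom_arrays(residues, radii)
    unit = sphere_points(n_points)
    per_atom: dict[AtomKey, float] = {}
    per_residue: dict[ResidueKey, float] = {}
    if len(keys) == 0:
        return SasaResult({}, {}, probe, n_points)
    expanded = rads + probe
    tree = cKDTree(coords)
    r_max = float(expanded.max())
    for i in range(len(keys)):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], ri + r_max):
            if j == i:
                continue
            rj = expanded[j]
            d2 = np.sum((coords[i] - coords[j]) ** 2)
            if d2 >= (ri + rj) ** 2:
                continue
            occluded = np.sum((pts - coords[j]) ** 2, axis=1) < rj * rj
            accessible &= ~occluded
            if not accessible.any():
                break
        area = 4.0 * np.pi * ri * ri * accessible.sum() / n_points
        per_atom[keys[i]] = float(area)
        per_residue[owner[i]] = per_residue.get(owner[i], 0.0) + float(area)
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      probe_radius=probe, n_points=n_points)


def _complex_and_free_sasa(model, sel1, sel2, probe, n_points, radii):
    check_disjoint(model, sel1, sel2)
    res1 = select(model, sel1)
    res2 = select(model, sel2)
    if not res1 or not res2:
        raise ValueError("both selections must match at least one residue")
    free1 = shrake_rupley_sasa(res1, probe, n_points, radii)
    free2 = shrake_rupley_sasa(res2, probe, n_points, radii)
    bound = shrake_rupley_sasa(list(res1) + list(res2), probe, n_points, radii)
    return res1, res2, free1, free2, bound


def interface_area(
    model: Model,
    sel1: MoleculeSelection,
    sel2: MoleculeSelection,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[dict[str, float]] = None,
) -> float:
    """Buried-surface interface area (Å²), single-interface convention.

    ``(SASA(sel1) + SASA(sel2) − SASA(complex)) / 2`` with each selection's
    free-state SASA computed with the partner's atoms removed. Symmetric in
    the two selections and zero when they do not touch.
    """
    _, _, free1, free2, bound = _complex_and_free_sasa(model, sel1, sel2, probe, n_points, radii)
    return max(0.0, (free1.total + free2.total - bound.total) / 2.0)


def _relative_burial(residues, free: SasaResult, bound: SasaResult):
    out = []
    for res in residues:
        sasa_free = free.per_residue.get(res.key, 0.0)
        sasa_bound = bound.per_residue.get(res.key, 0.0)
        rel = 0.0 if sasa_free <= 0 else max(0.0, (sasa_free - sasa_bound) / sasa_free)
        out.append((res.key, rel))
    return out


def buried_residues(
    model: Model,
    sel1: MoleculeSelection,
    sel2: MoleculeSelection,
    min_rel_burial: float = 0.0,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[dict[str, float]] = None,
) -> tuple[list, list]:
    """Residues of each selection buried upon complex formation.

    Returns two lists of ``(residue key, relative_burial)`` with
    ``relative_burial = (SASA_free − SASA_complex)/SASA_free`` (0 when the
    free SASA is 0), filtered at ``min_rel_burial`` and sorted by descending
    burial. With ``min_rel_burial=0`` every residue with any burial is listed.
    """
    if not 0.0 <= min_rel_burial <= 1.0:
        raise ValueError("min_rel_burial must be in [0, 1]")
    res1, res2, free1, free2, bound = _complex_and_free_sasa(
        model, sel1, sel2, probe, n_points, radii
    )
    lists = []
    for residues, free in ((res1, free1), (res2, free2)):
        entries = [
            (k, rel)
            for k, rel in _relative_burial(residues, free, bound)
            if rel >= min_rel_burial and rel > 0.0
        ]
        entries.sort(key=lambda kr: -kr[1])
        lists.append(entries)
    return lists[0], lists[1]


def interface_summary(
    model: Model,
    sel1: MoleculeSelection,
    sel2: MoleculeSelection,
    cutoff: float = CLASSICAL_CUTOFF,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[dict[str, float]] = None,
) -> InterfaceSummary:
    """Classical interface characterization: area, buried residues, contacts, H-bonds."""
    res1, res2, free1, free2, bound = _complex_and_free_sasa(
        model, sel1, sel2, probe, n_points, radii
    )
    area = max(0.0, (free1.total + free2.total - bound.total) / 2.0)
    b1 = sorted(
        [(k, r) for k, r in _relative_burial(res1, free1, bound) if r > 0], key=lambda kr: -kr[1]
    )
    b2 = sorted(
        [(k, r) for k, r in _relative_burial(res2, free2, bound) if r > 0], key=lambda kr: -kr[1]
    )
    cmap = compute_contact_map(model, sel1, sel2, cutoff=cutoff)
    hbonds = detect_hbonds(model, sel1, sel2)
    return InterfaceSummary(
        interface_area=float(area),
        buried_residues_1=b1,
        buried_residues_2=b2,
        n_contacts=len(cmap),
        hbonds=hbonds,
    )


def burial_table(model: Model, sel1: MoleculeSelection, sel2: MoleculeSelection,
                 **kwargs) -> pd.DataFrame:
    """Per-residue SASA/burial TSV-ready table for both interactors."""
    res1, res2, free1, free2, bound = _complex_and_free_sasa(
        model, sel1, sel2,
        kwargs.get("probe", DEFAULT_PROBE),
        kwargs.get("n_points", DEFAULT_N_POINTS),
        kwargs.get("radii"),
    )
    rows = []
    for side, residues, free in ((1, res1, free1), (2, res2, free2)):
        for res in residues:
            sasa_free = free.per_residue.get(res.key, 0.0)
            sasa_bound = bound.per_residue.get(res.key, 0.0)
            rel = 0.0 if sasa_free <= 0 else max(0.0, (sasa_free - sasa_bound) / sasa_free)
            rows.append(
                {
                    "interactor": side,
                    "chain": res.chain_id,
                    "resseq": res.resseq,
                    "icode": res.icode,
                    "resname": res.resname,
                    "sasa_free": round(sasa_free, 3),
                    "sasa_complex": round(sasa_bound, 3),
                    "relative_burial": round(rel, 4),
                }
            )
    return pd.DataFrame(rows)
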