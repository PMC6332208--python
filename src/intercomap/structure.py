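"""Immutable structure/ensemble data model and PDB I/O.

Coordinates are in Ångström throughout. Residues are identified across an
ensemble by the author-assigned key ``(chain_id, resseq, icode)``; no sequence
alignment is ever attempted, so docking decoys and MD snapshots must share
chain IDs and residue numbering (as CAPRI-style ensembles do).

PDB reading is delegated to :mod:`gemmi`; on top of its parse this module
resolves alternate locations (highest occupancy wins, ties broken by file
order), applies the hetero policy (waters and non-polymer HETATM groups are
dropped by default, modified polymer residues such as MSE are kept) and infers
missing element symbols from atom names. Hydrogens and deuteriums are retained
in atom lists but flagged non-heavy; they never participate in contact or SASA
calculations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Model",
    "Ensemble",
    "MoleculeSelection",
    "ResidueKey",
    "PDBParseError",
    "EmptyStructureError",
    "parse_pdb",
    "load_ensemble",
    "select",
    "selection_keys",
    "check_disjoint",
    "write_pdb",
]

#: Residue key: (chain_id, author residue number, insertion code or "").
ResidueKey = tuple[str, int, str]

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})

# Two-letter element symbols that legitimately occur in polymer/het atom names.
_TWO_LETTER_ELEMENTS = frozenset(
    {"SE", "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "CU", "NI", "CO"}
)


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when parsing yields no polymer residues under the hetero policy."""


@dataclass(frozen=True)
class Atom:
    """A single atom with Å coordinates.

    ``element`` is always non-empty: when the PDB element column is blank it
    is inferred from the atom name.
    """

    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_heavy(self) -> bool:
        return self.element not in _HYDROGEN_ELEMENTS

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True)
class Residue:
    """A residue (amino acid, nucleotide or other group) with its atoms."""

    chain_id: str
    resseq: int
    icode: str
    resname: str
    polymer_class: str  # "amino_acid" | "nucleotide" | "other"
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.resseq, self.icode)

    @property
    def heavy_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.is_heavy)

    def heavy_coords(self) -> np.ndarray:
        """(n_heavy, 3) coordinate array of the residue's heavy atoms."""
        heavy = self.heavy_atoms
        if not heavy:
            raise ValueError(f"residue {self.key} has no heavy atoms")
        return np.array([a.coord for a in heavy], dtype=float)

    def label(self) -> str:
        ic = self.icode or ""
        return f"{self.chain_id}:{self.resname}{self.resseq}{ic}"


@dataclass(frozen=True)
class Model:
    """One coordinate model: an ordered list of residues grouped by chain."""

    model_id: Union[int, str]
    residues: tuple[Residue, ...]
    _by_key: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        by_key = {}
        for r in self.residues:
            if r.key in by_key:
                raise ValueError(f"duplicate residue key {r.key} in model {self.model_id}")
            by_key[r.key] = r
        object.__setattr__(self, "_by_key", by_key)

    def residue(self, key: ResidueKey) -> Optional[Residue]:
        return self._by_key.get(key)

    @property
    def residue_keys(self) -> tuple[ResidueKey, ...]:
        return tuple(r.key for r in self.residues)

    @property
    def chain_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Ensemble:
    """An ordered collection of models sharing chain IDs and numbering.

    ``residue_universe`` is the ordered union of residue keys over all models
    (first-seen order), used as the fixed axis ordering for consensus maps.
    """

    models: tuple[Model, ...]
    residue_universe: tuple[ResidueKey, ...] = field(default=())

    def __post_init__(self):
        if len(self.models) < 1:
            raise ValueError("an Ensemble needs at least one model")
        if not self.residue_universe:
            universe: list[ResidueKey] = []
            seen: set[ResidueKey] = set()
            for m in self.models:
                for k in m.residue_keys:
                    if k not in seen:
                        seen.add(k)
                        universe.append(k)
            object.__setattr__(self, "residue_universe", tuple(universe))

    @property
    def n_models(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __len__(self) -> int:
        return len(self.models)


@dataclass(frozen=True)
class MoleculeSelection:
    """One interactor: a set of chains, optionally restricted to residue ranges.

    ``residue_ranges`` entries are ``(chain_id, start, end)`` with both ends
    inclusive in author numbering. A chain named in a range is implicitly part
    of the selection; a chain in ``chain_ids`` with no range contributes all
    its residues.
    """

    chain_ids: frozenset[str]
    residue_ranges: tuple[tuple[str, int, int], ...] = ()

    def __init__(
        self,
        chain_ids: Iterable[str] = (),
        residue_ranges: Iterable[tuple[str, int, int]] = (),
    ):
        ranges = tuple((str(c), int(a), int(b)) for c, a, b in residue_ranges)
        chains = frozenset(str(c) for c in chain_ids) | frozenset(c for c, _, _ in ranges)
        if not chains:
            raise ValueError("selection must name at least one chain or range")
        for c, a, b in ranges:
            if a > b:
                raise ValueError(f"range {c}:{a}-{b} has start > end")
        object.__setattr__(self, "chain_ids", chains)
        object.__setattr__(self, "residue_ranges", ranges)

    def matches(self, res: Residue) -> bool:
        if res.chain_id not in self.chain_ids:
            return False
        chain_ranges = [(a, b) for c, a, b in self.residue_ranges if c == res.chain_id]
        if not chain_ranges:
            return True
        return any(a <= res.resseq <= b for a, b in chain_ranges)


def _infer_element(name: str) -> str:
    """Infer an element symbol from a PDB atom name."""
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        raise PDBParseError(f"cannot infer element for atom name {name!r}")
    if name and name[0].isdigit():  # e.g. 1HB2 style hydrogens
        return "H"
    two = stripped[:2].upper()
    if two in _TWO_LETTER_ELEMENTS and len(name.strip()) <= 2:
        return two
    return stripped[0].upper()


def _polymer_class(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None:
        if info.is_amino_acid():
            return "amino_acid"
        if info.is_nucleic_acid():
            return "nucleotide"
    return "other"


def _is_water(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return bool(info is not None and info.is_water())


def _resolve_altlocs(raw_atoms: list[Atom]) -> tuple[Atom, ...]:
    """Keep one altloc per atom name: highest occupancy, ties → first seen."""
    chosen: dict[str, Atom] = {}
    order: list[str] = []
    for atom in raw_atoms:
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
            order.append(atom.name)
        elif atom.occupancy > prev.occupancy:
            chosen[atom.name] = atom
    return tuple(chosen[n] for n in order)


def _convert_model(gmodel: gemmi.Model, model_id, hetero_policy: str) -> Model:
    residues: list[Residue] = []
    for chain in gmodel:
        for gres in chain:
            resname = gres.name.strip()
            if _is_water(resname):
                continue
            pclass = _polymer_class(resname)
            if pclass == "other" and hetero_policy == "exclude":
                continue
            raw: list[Atom] = []
            for ga in gres:
                el = ga.element.name if ga.element and ga.element.name not in ("X", "") else ""
                if not el:
                    el = _infer_element(ga.name)
                raw.append(
                    Atom(
                        name=ga.name,
                        element=el.upper(),
                        coord=(ga.pos.x, ga.pos.y, ga.pos.z),
                        occupancy=float(ga.occ),
                        altloc=(ga.altloc if ga.altloc != "\x00" else ""),
                    )
                )
            atoms = _resolve_altlocs(raw)
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            residues.append(
                Residue(
                    chain_id=chain.name,
                    resseq=gres.seqid.num,
                    icode=icode,
                    resname=resname,
                    polymer_class=pclass,
                    atoms=atoms,
                )
            )
    return Model(model_id=model_id, residues=tuple(residues))


def parse_pdb(path: Union[str, Path], hetero_policy: str = "exclude") -> Ensemble:
    """Parse a (possibly multi-model) PDB file into an :class:`Ensemble`.

    Parameters
    ----------
    path:
        PDB-format coordinate file. MODEL/ENDMDL blocks each become one
        :class:`Model` (model_id = MODEL number); a file without them yields a
        single model with ``model_id=1``.
    hetero_policy:
        ``"exclude"`` (default) drops waters and non-polymer HETATM groups;
        ``"include"`` keeps non-water hetero groups with
        ``polymer_class="other"``. Waters are always excluded.
    """
    if hetero_policy not in ("exclude", "include"):
        raise ValueError(f"unknown hetero_policy {hetero_policy!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise PDBParseError(f"{path}: {exc}") from exc
    models = []
    for gmodel in st:
        model_id = int(gmodel.num) if len(st) > 1 else 1
        models.append(_convert_model(gmodel, model_id, hetero_policy))
    models = [m for m in models if len(m) > 0]
    if not models:
        raise EmptyStructureError(
            f"{path}: no polymer residues after applying hetero_policy={hetero_policy!r}"
        )
    return Ensemble(models=tuple(models))


def load_ensemble(paths: Sequence[Union[str, Path]], hetero_policy: str = "exclude") -> Ensemble:
    """Build an ensemble from an ordered list of single-model PDB files.

    Model IDs are the filename stems; the residue universe is the ordered
    union over files. Files whose chain IDs differ from the first file's
    trigger a warning, but the union is still formed.
    """
    if not paths:
        raise ValueError("load_ensemble needs at least one path")
    models: list[Model] = []
    ref_chains: Optional[tuple[str, ...]] = None
    for p in paths:
        p = Path(p)
        ens = parse_pdb(p, hetero_policy=hetero_policy)
        if ens.n_models != 1:
            raise ValueError(f"{p}: multi-model file not allowed in a file-list ensemble")
        model = ens.models[0]
        model = Model(model_id=p.stem, residues=model.residues)
        if ref_chains is None:
            ref_chains = model.chain_ids
        elif model.chain_ids != ref_chains:
            warnings.warn(
                f"{p}: chain IDs {model.chain_ids} differ from {ref_chains}; "
                "residue universe is the union",
                stacklevel=2,
            )
        models.append(model)
    return Ensemble(models=tuple(models))


def select(model: Model, sel: MoleculeSelection) -> list[Residue]:
    """Residues of ``model`` matched by ``sel``, in model (file) order."""
    out = [r for r in model.residues if sel.matches(r)]
    if not out:
        warnings.warn(f"selection {sorted(sel.chain_ids)} matches no residue", stacklevel=2)
    return out


def selection_keys(model: Model, sel: MoleculeSelection) -> list[ResidueKey]:
    """Residue keys matched by ``sel``, in model order (no empty-match warning)."""
    return [r.key for r in model.residues if sel.matches(r)]


def check_disjoint(model: Model, sel1: MoleculeSelection, sel2: MoleculeSelection) -> None:
    """Raise if the two interactor selections share any residue of ``model``."""
    k1 = {r.key for r in model.residues if sel1.matches(r)}
    k2 = {r.key for r in model.residues if sel2.matches(r)}
    overlap = k1 & k2
    if overlap:
        raise ValueError(f"selections overlap on {len(overlap)} residues, e.g. {sorted(overlap)[:3]}")


def _format_atom_line(serial: int, atom: Atom, res: Residue) -> str:
    name = atom.name
    # column 13-16 alignment: 1-3 char names start in column 14
    if len(name) < 4 and not name[:1].isdigit() and len(atom.element) == 1:
        name = " " + name
    return (
        f"ATOM  {serial:5d} {name:<4s}{atom.altloc or ' '}{res.resname:>3s} "
        f"{res.chain_id[:1]}{res.resseq:4d}{res.icode or ' '}   "
        f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
        f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}\n"
    )


def write_pdb(models: Union[Model, Sequence[Model]], path: Union[str, Path],
              remarks: Sequence[str] = ()) -> None:
    """Write one model (single-model PDB) or several (MODEL/ENDMDL blocks)."""
    if isinstance(models, Model):
        models = [models]
    path = Path(path)
    with path.open("w") as fh:
        for text in remarks:
            fh.write(f"REMARK   6 {text}\n")
        multi = len(models) > 1
        for i, model in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL {i:>8d}\n")
            serial = 0
            prev_chain = None
            for res in model.residues:
                if prev_chain is not None and res.chain_id != prev_chain:
                    fh.write("TER\n")
                prev_chain = res.chain_id
                for atom in res.atoms:
                    serial += 1
                    fh.write(_format_atom_line(serial, atom, res))
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
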