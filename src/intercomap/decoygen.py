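"""Synthetic complexes, docking-decoy ensembles and MD-like snapshot ensembles.

Everything downstream (contact maps, consensus, ranking) is exercised on
structures built here, so no external coordinate files are needed. The
generator emulates, at desk scale, the ensembles the consensus approach was
designed for:

* a small rigid two-chain complex with a guaranteed interface (two facing
  rows of pseudo-residues, each a backbone-like N/CA/C triad plus a
  side-chain pseudo-atom pointing across the interface);
* labeled docking-decoy ensembles: "correct" decoys are small rigid-body
  perturbations of the ligand chain, "incorrect" decoys large ones, with the
  translation ranges chosen non-overlapping so the labels are separable by
  ligand RMSD by construction;
* MD-like ensembles: independent isotropic Gaussian coordinate jitter per
  snapshot, mimicking thermal fluctuation around a native interface.

All randomness flows through one ``numpy`` Generator seeded explicitly, so
every output is bit-reproducible for a fixed seed. Residue names are sampled
across all three physicochemical classes so property maps are exercised on
every class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure import Atom, Ensemble, Model, MoleculeSelection, Residue

__all__ = [
    "DecoySpec",
    "make_toy_complex",
    "make_decoy_ensemble",
    "make_md_like_ensemble",
    "ligand_rmsd",
]

# residue names per physicochemical class (subset of the full 20)
_NAME_POOL = (
    "LEU", "ILE", "VAL", "PHE", "ALA",   # hydrophobic
    "ASP", "LYS", "ARG", "GLU", "HIS",   # charged
    "SER", "THR", "ASN", "GLN", "TYR",   # hydrophilic/polar
)

_RES_SPACING = 3.8   # Å between consecutive pseudo-residues along a chain
_CHAIN_GAP = 7.0     # Å between the two chains' backbone rows
_JITTER = 0.12       # Å deterministic placement noise


@dataclass(frozen=True)
class DecoySpec:
    """Parameters of a labeled decoy ensemble.

    ``correct_perturb = (max rotation deg, max translation Å)`` and
    ``incorrect_perturb = (min rot, max rot, min trans, max trans)``; the
    incorrect translation minimum must exceed the correct maximum so the two
    label classes are separable by ligand RMSD.
    """

    n_models: int = 50
    f_correct: float = 0.2
    correct_perturb: tuple = (5.0, 1.0)
    incorrect_perturb: tuple = (20.0, 180.0, 8.0, 25.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.f_correct <= 1.0:
            raise ValueError("f_correct must be in [0, 1]")
        _, max_trans = self.correct_perturb
        _, _, min_trans_inc, _ = self.incorrect_perturb
        if min_trans_inc <= max_trans:
            raise ValueError(
                "incorrect translation minimum must exceed the correct maximum "
                "(label separability)"
            )

    @property
    def n_correct(self) -> int:
        return int(round(self.n_models * self.f_correct))


def _pseudo_residue(chain_id: str, resseq: int, resname: str, x: float,
                    y: float, side: float, rng: np.random.Generator) -> Residue:
    """Backbone-like triad plus a side-chain pseudo-atom pointing toward ``side``."""
    jitter = rng.normal(0.0, _JITTER, size=(4, 3))
    base = np.array(
        [
            [x - 1.2, y - side * 0.8, 0.0],   # N
            [x, y, 0.0],                       # CA
            [x + 1.2, y - side * 0.8, 0.0],   # C
            [x, y + side * 1.5, 0.4],          # CB (faces the partner chain)
        ]
    ) + jitter
    names = ("N", "CA", "C", "CB")
    elements = ("N", "C", "C", "C")
    atoms = tuple(
        Atom(name=n, element=e, coord=tuple(c)) for n, e, c in zip(names, elements, base)
    )
    return Residue(
        chain_id=chain_id,
        resseq=resseq,
        icode="",
        resname=resname,
        polymer_class="amino_acid",
        atoms=atoms,
    )


def make_toy_complex(n_res1: int, n_res2: int, seed: int) -> Model:
    """A two-chain complex (chains A and B) with a built-in interface.

    Chains run as parallel rows ``_CHAIN_GAP`` Å apart with side-chain
    pseudo-atoms pointing at each other, so every facing residue pair is a
    5 Å contact: the interface has at least ``min(n_res1, n_res2)`` contacts.
    Deterministic for a fixed seed.
    """
    if n_res1 < 3 or n_res2 < 3:
        raise ValueError("each chain needs at least 3 residues")
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(n_res1):
        name = _NAME_POOL[rng.integers(len(_NAME_POOL))]
        residues.append(_pseudo_residue("A", i + 1, name, i * _RES_SPACING, 0.0, +1.0, rng))
    offset = (n_res1 - n_res2) / 2.0 * _RES_SPACING
    for j in range(n_res2):
        name = _NAME_POOL[rng.integers(len(_NAME_POOL))]
        residues.append(
            _pseudo_residue("B", j + 1, name, offset + j * _RES_SPACING, _CHAIN_GAP, -1.0, rng)
        )
    return Model(model_id="native", residues=tuple(residues))


def _transform_chain(model: Model, chain_id: str, R: np.ndarray, t: np.ndarray,
                     model_id) -> Model:
    """Rigid transform of one chain about its own centroid; other chains untouched."""
    chain_coords = np.array(
        [a.coord for r in model.residues if r.chain_id == chain_id for a in r.atoms]
    )
    center = chain_coords.mean(axis=0)
    new_residues = []
    for res in model.residues:
        if res.chain_id != chain_id:
            new_residues.append(res)
            continue
        atoms = tuple(
            Atom(
                name=a.name,
                element=a.element,
                coord=tuple((R @ (a.xyz - center)) + center + t),
                occupancy=a.occupancy,
                altloc=a.altloc,
            )
            for a in res.atoms
        )
        new_residues.append(
            Residue(res.chain_id, res.resseq, res.icode, res.resname, res.polymer_class, atoms)
        )
    return Model(model_id=model_id, residues=tuple(new_residues))


def _random_rotation(rng: np.random.Generator, min_deg: float, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(min_deg, max_deg))
    return Rotation.from_rotvec(axis * angle).as_matrix()


def _random_translation(rng: np.random.Generator, min_len: float, max_len: float) -> np.ndarray:
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return direction * rng.uniform(min_len, max_len)


def make_decoy_ensemble(native: Model, spec: DecoySpec) -> tuple[Ensemble, pd.DataFrame]:
    """Labeled rigid-body decoy ensemble from a two-chain native complex.

    The second chain (the "ligand") is rigid-body perturbed: correct decoys
    with small rotations/translations, incorrect with large ones, per
    ``spec``. Model order is shuffled deterministically by the seed. Returns
    the ensemble plus a table (model_id, label, ligand_rmsd).
    """
    chains = native.chain_ids
    if len(chains) != 2:
        raise ValueError("native model must have exactly two chains")
    ligand_chain = chains[1]
    ligand_sel = MoleculeSelection(chain_ids={ligand_chain})
    rng = np.random.default_rng(spec.seed)
    n_correct = spec.n_correct
    plans = ["correct"] * n_correct + ["incorrect"] * (spec.n_models - n_correct)
    order = rng.permutation(spec.n_models)
    models, rows = [], []
    for slot, plan_idx in enumerate(order):
        label = plans[plan_idx]
        if label == "correct":
            max_rot, max_trans = spec.correct_perturb
            R = _random_rotation(rng, 0.0, max_rot)
            t = _random_translation(rng, 0.0, max_trans)
        else:
            min_rot, max_rot, min_trans, max_trans = spec.incorrect_perturb
            R = _random_rotation(rng, min_rot, max_rot)
            t = _random_translation(rng, min_trans, max_trans)
        model_id = f"model_{slot + 1:03d}"
        decoy = _transform_chain(native, ligand_chain, R, t, model_id)
        rows.append(
            {
                "model_id": model_id,
                "label": label,
                "ligand_rmsd": round(ligand_rmsd(decoy, native, ligand_sel), 4),
            }
        )
        models.append(decoy)
    return Ensemble(models=tuple(models)), pd.DataFrame(rows)


def make_md_like_ensemble(native: Model, n_snapshots: int, jitter_sd: float,
                          seed: int) -> Ensemble:
    """MD-like snapshots: independent per-atom isotropic Gaussian jitter (Å)."""
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    models = []
    for s in range(n_snapshots):
        residues = []
        for res in native.residues:
            atoms = tuple(
                Atom(
                    name=a.name,
                    element=a.element,
                    coord=tuple(a.xyz + rng.normal(0.0, jitter_sd, size=3))
                    if jitter_sd > 0
                    else a.coord,
                    occupancy=a.occupancy,
                    altloc=a.altloc,
                )
                for a in res.atoms
            )
            residues.append(
                Residue(res.chain_id, res.resseq, res.icode, res.resname,
                        res.polymer_class, atoms)
            )
        models.append(Model(model_id=f"snap_{s + 1:03d}", residues=tuple(residues)))
    return Ensemble(models=tuple(models))


def ligand_rmsd(model: Model, reference: Model, ligand_sel: MoleculeSelection) -> float:
    """Heavy-atom RMSD (Å) over the selection, without superposition.

    Receptor frames are assumed aligned (the generator guarantees it: only
    the ligand chain is moved), so this is the plain per-atom deviation.
    """
    diffs = []
    for res_ref in reference.residues:
        if not ligand_sel.matches(res_ref):
            continue
        res_mod = model.residue(res_ref.key)
        if res_mod is None:
            raise ValueError(f"residue {res_ref.key} missing from model {model.model_id}")
        mod_atoms = {a.name: a for a in res_mod.atoms if a.is_heavy}
        for a_ref in res_ref.heavy_atoms:
            a_mod = mod_atoms.get(a_ref.name)
            if a_mod is None:
                raise ValueError(
                    f"atom {a_ref.name} of {res_ref.key} missing from model {model.model_id}"
                )
            diffs.append(a_mod.xyz - a_ref.xyz)
    if not diffs:
        raise ValueError("selection matches no heavy atoms")
    diffs = np.asarray(diffs)
    return float(np.sqrt(np.mean(np.sum(diffs * diffs, axis=1))))
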