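"""Consensus contact analysis over model ensembles.

Given an ensemble of docking models or MD snapshots sharing residue numbering,
every inter-selection residue contact is assigned a conservation rate (contact
frequency): the fraction of models in which the pair is in contact at the
cutoff (5 Å CAPRI definition by default). The rates form a consensus map —
rendered on a linear gray scale, the more conserved the darker — or a "3D
consensus map" with the rate as a height axis. A model lacking a residue
simply lacks that residue's contacts; the denominator is always the ensemble
size.

The same machinery covers MD-trajectory contact conservation: contacts kept
in every snapshot (rate 1.0), and new/lost contacts relative to a reference
structure, including intra-chain inter-domain selections given as residue
ranges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import CONSENSUS_CUTOFF, ContactMap, compute_contact_map, _key_str
from .structure import Ensemble, Model, MoleculeSelection, ResidueKey

__all__ = [
    "ConsensusMap",
    "OverlayReport",
    "conservation_rates",
    "consensus_matrix",
    "export_3d_consensus",
    "conserved_contacts",
    "contact_difference",
    "model_overlay",
    "conserved_table",
]

Pair = tuple[ResidueKey, ResidueKey]


@dataclass(frozen=True)
class ConsensusMap:
    """Per-pair conservation rates over an ensemble.

    Only pairs observed in at least one model are stored, so every stored
    rate is a positive multiple of ``1/n_models``. ``axis1``/``axis2`` are the
    interactor residue orderings taken from the ensemble's residue universe.
    """

    rates: dict  # Pair -> float in (0, 1]
    n_models: int
    cutoff: float
    axis1: tuple[ResidueKey, ...]
    axis2: tuple[ResidueKey, ...]

    def rate(self, pair: Pair) -> float:
        return self.rates.get(pair, 0.0)

    def __len__(self) -> int:
        return len(self.rates)


@dataclass(frozen=True)
class OverlayReport:
    """A single model's contacts annotated with ensemble conservation rates."""

    model_id: object
    matched: list  # (Pair, rate) for every contact of the model
    mean_rate: float
    unmatched_native_like: Optional[list] = None


def _universe_axes(ensemble: Ensemble, sel1: MoleculeSelection, sel2: MoleculeSelection):
    axis1, axis2 = [], []
    seen1, seen2 = set(), set()
    for model in ensemble:
        for res in model.residues:
            if sel1.matches(res) and res.key not in seen1:
                seen1.add(res.key)
                axis1.append(res.key)
            elif sel2.matches(res) and res.key not in seen2:
                seen2.add(res.key)
                axis2.append(res.key)
    return tuple(axis1), tuple(axis2)


def conservation_rates(
    ensemble: Ensemble,
    sel1: MoleculeSelection,
    sel2: MoleculeSelection,
    cutoff: float = CONSENSUS_CUTOFF,
) -> ConsensusMap:
    """Contact conservation rates over the ensemble at ``cutoff`` Å.

    rate(pair) = (number of models where the pair is in contact) / n_models.
    """
    counts: dict[Pair, int] = {}
    for model in ensemble:
        cmap = compute_contact_map(model, sel1, sel2, cutoff=cutoff)
        for pair in cmap.records:
            counts[pair] = counts.get(pair, 0) + 1
    n = ensemble.n_models
    axis1, axis2 = _universe_axes(ensemble, sel1, sel2)
    return ConsensusMap(
        rates={p: c / n for p, c in counts.items()},
        n_models=n,
        cutoff=float(cutoff),
        axis1=axis1,
        axis2=axis2,
    )


def consensus_matrix(cmap: ConsensusMap) -> pd.DataFrame:
    """Dense rate matrix (axis1 × axis2); unobserved pairs are 0."""
    mat = np.zeros((len(cmap.axis1), len(cmap.axis2)))
    idx1 = {k: i for i, k in enumerate(cmap.axis1)}
    idx2 = {k: i for i, k in enumerate(cmap.axis2)}
    for (k1, k2), rate in cmap.rates.items():
        mat[idx1[k1], idx2[k2]] = rate
    return pd.DataFrame(
        mat,
        index=[_key_str(k) for k in cmap.axis1],
        columns=[_key_str(k) for k in cmap.axis2],
    )


def export_3d_consensus(
    cmap: ConsensusMap,
    highlight_models: Sequence[Model] = (),
    sel1: Optional[MoleculeSelection] = None,
    sel2: Optional[MoleculeSelection] = None,
) -> dict:
    """3D consensus dataset: (res1 index, res2 index, rate) triples as JSON-able dict.

    For each highlighted model, the subset of triples matching the model's own
    contacts is included (selections are required when highlighting). Even an
    incorrect pose may match some well-conserved, native-like contacts — the
    overlay makes that visible.
    """
    idx1 = {k: i for i, k in enumerate(cmap.axis1)}
    idx2 = {k: i for i, k in enumerate(cmap.axis2)}
    triples = [
        {"i": idx1[k1], "j": idx2[k2], "res1": _key_str(k1), "res2": _key_str(k2),
         "rate": rate}
        for (k1, k2), rate in sorted(cmap.rates.items(), key=lambda kv: (idx1[kv[0][0]], idx2[kv[0][1]]))
    ]
    dataset = {
        "n_models": cmap.n_models,
        "cutoff": cmap.cutoff,
        "axis1": [_key_str(k) for k in cmap.axis1],
        "axis2": [_key_str(k) for k in cmap.axis2],
        "triples": triples,
        "highlights": [],
    }
    if highlight_models:
        if sel1 is None or sel2 is None:
            raise ValueError("highlighting requires the two interactor selections")
        for model in highlight_models:
            mmap = compute_contact_map(model, sel1, sel2, cutoff=cmap.cutoff)
            matched = [
                t for t in triples if (cmap.axis1[t["i"]], cmap.axis2[t["j"]]) in mmap.records
            ]
            dataset["highlights"].append({"model_id": model.model_id, "matched": matched})
    return dataset


def conserved_contacts(cmap: ConsensusMap, min_rate: float) -> list[tuple[Pair, float]]:
    """Pairs with rate >= ``min_rate``, by descending rate, ties in axis order.

    ``min_rate=1.0`` yields exactly the contacts present in every model (the
    MD-conserved set); a vanishing threshold yields the union over models.
    """
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must be in [0, 1]")
    idx1 = {k: i for i, k in enumerate(cmap.axis1)}
    idx2 = {k: i for i, k in enumerate(cmap.axis2)}
    hits = [(p, r) for p, r in cmap.rates.items() if r >= min_rate]
    hits.sort(key=lambda pr: (-pr[1], idx1[pr[0][0]], idx2[pr[0][1]]))
    return hits


def contact_difference(
    cmap_ref: ContactMap,
    cmap_ens: ConsensusMap,
    lost_below: float = 0.0,
) -> tuple[list, list]:
    """New and lost contacts of an ensemble relative to a reference structure.

    new: ensemble pairs absent from the reference map, as (pair, rate).
    lost: reference pairs whose ensemble rate is 0 (default) or strictly below
    ``lost_below``, as (pair, rate).
    """
    new = [(p, r) for p, r in sorted(cmap_ens.rates.items()) if p not in cmap_ref.records]
    lost = []
    for p in sorted(cmap_ref.records):
        r = cmap_ens.rate(p)
        if (lost_below == 0.0 and r == 0.0) or (lost_below > 0.0 and r < lost_below):
            lost.append((p, r))
    return new, lost


def model_overlay(
    model: Model,
    cmap: ConsensusMap,
    sel1: MoleculeSelection,
    sel2: MoleculeSelection,
    cutoff: Optional[float] = None,
) -> OverlayReport:
    """Overlay one model on the consensus: its contacts with their ensemble rates.

    ``mean_rate`` is the arithmetic mean of the rates over the model's own
    contacts (pairs unseen in the ensemble contribute rate 0); it equals the
    model's consensus (CONSRANK) score.
    """
    cutoff = cmap.cutoff if cutoff is None else cutoff
    mmap = compute_contact_map(model, sel1, sel2, cutoff=cutoff)
    matched = [(p, cmap.rate(p)) for p in sorted(mmap.records)]
    if matched:
        mean = float(np.mean([r for _, r in matched]))
    else:
        warnings.warn(f"model {model.model_id} has no inter-selection contacts", stacklevel=2)
        mean = 0.0
    return OverlayReport(model_id=model.model_id, matched=matched, mean_rate=mean)


def conserved_table(entries: Sequence[tuple[Pair, float]]) -> pd.DataFrame:
    """(pair, rate) list as a TSV-ready table."""
    return pd.DataFrame(
        [
            {"res1": _key_str(p[0]), "res2": _key_str(p[1]), "rate": round(r, 6)}
            for p, r in entries
        ],
        columns=["res1", "res2", "rate"],
    )


def consensus_to_json(dataset: dict) -> str:
    return json.dumps(dataset, indent=2)
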