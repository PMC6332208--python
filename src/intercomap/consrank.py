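"""Consensus scoring and ranking of docking-model ensembles.

A model's consensus score is the arithmetic mean of the ensemble conservation
rates over the model's own inter-residue contacts at 5 Å (the CAPRI contact
definition); models are ranked by descending score, ties broken stably by
input order. Because the most conserved contacts across an ensemble of
docking poses tend to be the native ones, ensembles with an appreciable
fraction of correct solutions (empirically above ~10% for single-program
decoy sets) get their correct models enriched at the top of the ranking.

The score is normalized to [0, 1]: a model matching only contacts present in
every other model scores 1, a pose whose contacts appear nowhere else in the
ensemble scores 1/n_models, and a pose with no inter-selection contacts at
all scores 0 and sorts last. Rates are computed once over the full ensemble
(the scored model included) and reused for every member.

Enrichment diagnostics compare the number of correct models in the top N
positions against the random expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusMap, conservation_rates
from .contacts import CONSENSUS_CUTOFF, compute_contact_map
from .structure import Ensemble, Model, MoleculeSelection

__all__ = [
    "ModelScore",
    "EnrichmentResult",
    "score_model",
    "rank_ensemble",
    "enrichment",
    "ranking_table",
]


@dataclass(frozen=True)
class ModelScore:
    model_id: object
    score: float
    rank: int
    n_contacts: int
    label: str = "unknown"  # "correct" | "incorrect" | "unknown"


@dataclass(frozen=True)
class EnrichmentResult:
    """Correct-model enrichment among the top-ranked positions.

    ``enrichment_factor = (n_correct_top/top_n) / (total_correct/n_models)``;
    1.0 means no better than random, undefined (None) when nothing is labeled
    correct.
    """

    top_n: int
    n_correct_top: int
    expected_random: float
    enrichment_factor: Optional[float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "top_n": self.top_n,
                "n_correct_top": self.n_correct_top,
                "expected_random": round(self.expected_random, 4),
                "enrichment_factor": (
                    None if self.enrichment_factor is None else round(self.enrichment_factor, 4)
                ),
            },
            indent=2,
        )


def score_model(
    model: Model,
    cmap: ConsensusMap,
    sel1: MoleculeSelection,
    sel2: MoleculeSelection,
    cutoff: float = CONSENSUS_CUTOFF,
) -> float:
    """Mean ensemble conservation rate over the model's own contacts.

    A model with no inter-selection contacts scores 0 (no consensus support).
    """
    mmap = compute_contact_map(model, sel1, sel2, cutoff=cutoff)
    if not mmap.records:
        return 0.0
    return float(np.mean([cmap.rate(p) for p in mmap.records]))


def rank_ensemble(
    ensemble: Ensemble,
    sel1: MoleculeSelection,
    sel2: MoleculeSelection,
    cutoff: float = CONSENSUS_CUTOFF,
    labels: Optional[dict] = None,
) -> list[ModelScore]:
    """Score every member against the ensemble consensus and rank descending.

    Conservation rates are computed once for the whole ensemble; ties keep
    input order (stable sort), so the ranking is reproducible for a fixed
    model listing. ``labels`` maps model_id to "correct"/"incorrect".
    """
    if ensemble.n_models < 2:
        raise ValueError("ranking needs an ensemble of at least 2 models")
    cmap = conservation_rates(ensemble, sel1, sel2, cutoff=cutoff)
    scored = []
    for model in ensemble:
        mmap = compute_contact_map(model, sel1, sel2, cutoff=cutoff)
        score = float(np.mean([cmap.rate(p) for p in mmap.records])) if mmap.records else 0.0
        scored.append((model, score, len(mmap.records)))
    order = sorted(range(len(scored)), key=lambda i: -scored[i][1])
    out = []
    for rank, i in enumerate(order, start=1):
        model, score, n_contacts = scored[i]
        label = (labels or {}).get(model.model_id, "unknown")
        out.append(
            ModelScore(
                model_id=model.model_id,
                score=score,
                rank=rank,
                n_contacts=n_contacts,
                label=label,
            )
        )
    return out


def enrichment(scores: Sequence[ModelScore], top_n: int) -> EnrichmentResult:
    """Enrichment of correct models in the top ``top_n`` ranked positions."""
    if not 1 <= top_n <= len(scores):
        raise ValueError("top_n must be between 1 and the number of models")
    if any(s.label == "unknown" for s in scores):
        raise ValueError("enrichment requires a correct/incorrect label for every model")
    by_rank = sorted(scores, key=lambda s: s.rank)
    n_models = len(by_rank)
    total_correct = sum(1 for s in by_rank if s.label == "correct")
    n_correct_top = sum(1 for s in by_rank[:top_n] if s.label == "correct")
    expected = top_n * total_correct / n_models
    if total_correct == 0:
        factor = None
    else:
        factor = (n_correct_top / top_n) / (total_correct / n_models)
    return EnrichmentResult(
        top_n=top_n,
        n_correct_top=n_correct_top,
        expected_random=expected,
        enrichment_factor=factor,
    )


def ranking_table(scores: Sequence[ModelScore]) -> pd.DataFrame:
    """Ranking as a TSV-ready table: model_id, rank, score, n_contacts, label."""
    return pd.DataFrame(
        [
            {
                "model_id": s.model_id,
                "rank": s.rank,
                "score": round(s.score, 6),
                "n_contacts": s.n_contacts,
                "label": s.label,
            }
            for s in sorted(scores, key=lambda s: s.rank)
        ],
        columns=["model_id", "rank", "score", "n_contacts", "label"],
    )
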