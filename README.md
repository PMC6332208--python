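# intercomap

Inter-molecular contact maps, consensus contact analysis, and consensus-based
scoring of protein–protein docking models.

## What it does

When two molecules (proteins, or a protein and a nucleic acid) form a
complex, the interface can be summarized as an **inter-molecular contact
map**: a matrix over the residues of the two interactors with a dot wherever
the residue pair has at least one heavy-atom pair within a distance cutoff
(5 Å, the CAPRI residue-contact definition, for consensus work; 6 Å for
classical single-structure maps). The map is a fingerprint of the binding
mode and makes two complexes immediately comparable.

Given an *ensemble* of structures — docking decoys from one or several
programs, or molecular-dynamics snapshots — each contact *c* gets a
**conservation rate**

    ν(c) = (number of models in which c is present) / (number of models)

and the rates form a **consensus map** (grayscale: the more conserved the
contact, the darker the dot). Because the most conserved contacts across a
decoy ensemble tend to be the native ones, a docking model *m* with contact
set *C(m)* can be scored by its agreement with the consensus:

    S(m) = (1/|C(m)|) · Σ_{c ∈ C(m)} ν(c)  ∈ [0, 1]

Ranking by *S* enriches correct poses at the top of the list whenever the
ensemble contains an appreciable fraction (empirically ≳10%) of correct
solutions. The same machinery measures interface rigidity across MD
snapshots (contacts kept in every frame, new and lost contacts relative to a
reference structure), including intra-chain inter-domain interfaces selected
by residue ranges.

The package also characterizes a single interface in classical terms:
solvent-accessible surface area (built-in deterministic Shrake–Rupley),
buried interface area (half the SASA lost upon complex formation), per-residue
relative burial, and geometric hydrogen bonds.

A synthetic generator produces toy two-chain complexes, labeled rigid-body
decoy ensembles (small perturbations = correct, large = incorrect), and
MD-like jittered snapshot ensembles, so the whole pipeline runs and is tested
without any external data.

## Worked example

```python
from intercomap import (
    DecoySpec, MoleculeSelection, make_toy_complex, make_decoy_ensemble,
    rank_ensemble, enrichment,
)

native = make_toy_complex(12, 10, seed=3)            # chains A (12 res) and B (10 res)
ens, labels = make_decoy_ensemble(native, DecoySpec(n_models=50, f_correct=0.2, seed=3))
sel1, sel2 = MoleculeSelection({"A"}), MoleculeSelection({"B"})
scores = rank_ensemble(ens, sel1, sel2, labels=dict(zip(labels.model_id, labels.label)))
print([s.label for s in scores[:10]])
print(enrichment(scores, 10).enrichment_factor)
```

prints

```
['correct', 'correct', 'correct', 'correct', 'correct', 'correct', 'correct', 'correct', 'correct', 'correct']
5.0
```

— all 10 correct decoys (20% of 50 models) occupy the top 10 ranks, giving
the maximum possible top-10 enrichment factor of 5.0 over random expectation
(a factor of 1.0 would be chance level).

The same analyses are available from the shell:

```sh
intercomap gen --kind decoys --n-models 50 --seed 3 --outdir work
intercomap consrank work/decoys.pdb --mol1 A --mol2 B --labels work/labels.tsv --outdir work/rank
intercomap consensus work/decoys.pdb --mol1 A --mol2 B --outdir work/cons
intercomap contactmap work/native.pdb --mol1 A --mol2 B --outdir work/maps
```

Selections cover two-chain interactors (`--mol1 H,L`) and intra-chain
inter-domain ranges (`--mol1 A:1-120 --mol2 A:121-240`, inclusive).

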