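# Methods

## Contact definition

Two residues from different interactors are in contact when **at least one
pair of heavy atoms** (one atom from each residue) is separated by ≤ cutoff,
boundary inclusive. The default cutoff is 5.0 Å — the residue-contact
definition used by the CAPRI assessment — for everything consensus-related
(conservation rates, ranking, MD conservation), and 6.0 Å for classical and
property maps of a single structure. Hydrogens and deuteriums never count as
heavy atoms. The minimum heavy-atom distance of each candidate pair is
evaluated exactly; a k-d tree over heavy atoms (with a padded search radius)
only prunes the candidate list, so the result is identical to the exhaustive
all-atom-pairs scan, which the test suite verifies on 100 random complexes.

Interactor selections are sets of chains optionally restricted to inclusive
author-numbered residue ranges. The two selections must be residue-disjoint;
this makes intra-chain inter-domain maps (two ranges on one chain) well
formed with no self-pairs, while near-diagonal contacts remain allowed, as
inter-domain analysis requires.

## Property classes and distance-range bins

The physicochemical pair class uses a standard hydropathy grouping:
hydrophobic {ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, GLY, CYS}, charged
{ASP, GLU, LYS, ARG, HIS}, hydrophilic/polar {SER, THR, ASN, GLN, TYR}. A
pair is `X-X` when both residues share class `X`, otherwise `mixed`; pairs
involving nucleotides or unknown residue names are `mixed`. The table is an
argument, so alternative groupings can be supplied. Distance-range bins
default to upper edges (7, 10, 13, 16) Å, inclusive, also configurable; the
distance-range map is computed with the cutoff set to the last edge.

## Hydrogen bonds

No authoritative geometric criterion is attached to the interface H-bond
lists this package emulates, so a standard one is used and documented as this
package's own: donor and acceptor are heavy N or O atoms on opposite sides
with distance ≤ 3.5 Å; when the donor carries explicit hydrogens (identified
as H/D atoms within 1.3 Å in the same residue), at least one D–H···A angle
must be ≥ 120°. Without explicit hydrogens the distance criterion alone
decides, and each N/O–N/O pair can be reported once per donor→acceptor
direction. Both thresholds are parameters.

## SASA and interface area

SASA uses the Shrake–Rupley method with a deterministic golden-spiral point
set (default 960 points per atom, probe 1.4 Å): points on the
solvent-expanded sphere (r_vdW + probe) are tested against all neighbouring
expanded spheres, and the accessible fraction scales the sphere area. No RNG
is involved, so areas are bit-reproducible at fixed `n_points`. Radii are a
Chothia-style united-atom set (C 1.87, N 1.65, O 1.40, S 1.85, P 1.80,
Se 1.90 Å), exposed as a parameter because buried-area magnitudes depend on
the radii convention; an element with no configured radius is an error naming
the atom. A point exactly on a neighbour sphere counts as accessible (strict
`<` occlusion), so two exactly tangent atoms do not occlude each other.

Interface area follows the single-interface buried-surface convention:

    A_int = [ SASA(sel1 alone) + SASA(sel2 alone) − SASA(complex) ] / 2

with "alone" meaning the partner's atoms are removed and clamping at 0 for
numerically negative values. Relative burial of a residue is
(SASA_free − SASA_complex)/SASA_free, 0 when the free SASA is 0. Any residue
with positive burial counts as an interface residue; 90% is a conventional
reporting threshold for "fully buried", not part of the definition.

## Consensus rates and ranking

Conservation rates are contact counts divided by the ensemble size; a model
lacking a residue simply contributes no contacts for it (the denominator is
always `n_models`). This is the simplest reading of "fraction of models" and
keeps rates exact multiples of 1/n. Only observed pairs are stored; absent
pairs have rate 0 by definition.

The consensus (CONSRANK-style) score of a model is the arithmetic mean of
the ensemble rates over the model's own contacts at 5 Å — this package's
canonical definition, chosen because it is normalized to [0, 1], makes the
per-model overlay's mean rate and the ranking score the same number (asserted
to 1e-12 in tests), and leaves scores invariant under duplicating the
ensemble. Whether the historical implementation normalizes by the model's
contact count is not documented in the sources this design follows; the
choice here is declared, not inferred. A zero-contact model scores 0 and
sorts last; ties keep input order (stable sort). The scored model is included
in the rate denominator, mirroring a consensus computed once per ensemble.

Enrichment at top-N is `(n_correct_top/N)/(total_correct/n_models)`,
undefined (None) when nothing is labeled correct.

## Synthetic data

The generator emulates the study conditions at desk scale:

* **Toy complex** — two facing rows of pseudo-residues (backbone-like N/CA/C
  triad plus a CB-like side-chain atom pointing across the interface),
  3.8 Å residue spacing, 7 Å between backbone rows so facing side-chain
  atoms sit ~4 Å apart: every facing pair is a 5 Å contact by construction,
  with 0.12 Å placement noise for irregularity. Residue names are sampled
  across all three property classes.
* **Decoy ensembles** — the second chain is rigid-body perturbed about its
  centroid: correct decoys with rotation ≤ 5° and translation ≤ 1 Å,
  incorrect with rotation 20–180° and translation 8–25 Å. The default
  ensemble is 50 models with 20% correct, matching the regime where a
  consensus approach is expected to beat random (>10% correct). The
  disjoint translation ranges make labels separable by ligand RMSD, which is
  computed without superposition since only the ligand chain moves.
  Defaults live in `DecoySpec`; a spec whose ranges overlap is rejected.
* **MD-like ensembles** — independent per-atom isotropic Gaussian jitter per
  snapshot (default 0.3 Å in the CLI). This emulates thermal fluctuation
  about a rigid interface only: no collective motions, no side-chain
  rotamers, no drift. Tests passing on these ensembles therefore demonstrate
  the bookkeeping (rates, intersections, new/lost sets) and boundary-contact
  sensitivity, not realism of conformational sampling.

All randomness flows through `numpy.random.default_rng(seed)`; one stream
per operation, so outputs are byte-reproducible (the PDB writer emits fixed
3-decimal coordinates).

What the synthetic data does **not** model: real docking decoys cluster in
pose space rather than scattering uniformly; incorrect poses can share
partial interfaces with correct ones; chains are not internally flexible.
Consequently the measured enrichment factors (≈4.9 mean top-10 factor over
20 ensembles, near the theoretical maximum of 5 at 20% correct) are an upper
bound on what mixed-quality real ensembles give.

## Numerical choices and degenerate inputs

* All distance comparisons are inclusive (≤).
* Altloc resolution keeps the highest-occupancy conformer per atom name,
  ties broken by file order; waters are always dropped, non-polymer HETATM
  groups dropped by default (`hetero_policy="include"` keeps them), modified
  polymer residues such as MSE kept.
* Residue identity is `(chain_id, resseq, icode)`; no sequence alignment.
  Ensembles with mismatched numbering are the user's responsibility; file
  lists with differing chain IDs warn but still form the union universe.
* Empty selections yield empty maps with a warning, not an error; a
  zero-contact model in an overlay warns and reports mean rate 0.
* Contact-map min-distances use `scipy.spatial.distance.cdist`; independent
  recomputations with `math.dist` agree to ~1e-12 relative (ULP effects),
  which is the tolerance the dual-route tests use for distances. Set
  equality is always exact.
* The acceptance-scale problem sizes (complexes of ~20 residues, ensembles
  of 10–50 models, 100 oracle trials) were chosen so the full pipeline runs
  in seconds while exercising every code path; rates and ranks are
  size-independent bookkeeping, so nothing about the method changes at
  production scale beyond runtime.

## Known limitations

* PDB format only (no mmCIF); single-character chain IDs on write.
* The H-bond criterion is a generic geometric one, not byte-compatible with
  any specific web server's output.
* Interface-area magnitudes depend on the radii set and the halving
  convention; comparisons against published values should allow ~10% for
  convention differences.
* No CAPRI quality tiers (fnat/iRMSD/L-RMSD), no contact-specific weights,
  no pose clustering, no trajectory readers (MD snapshots must arrive as
  multi-model PDB), and no cross-sequence interface alignment: overlays and
  differences require shared numbering.
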