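import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intercomap import MoleculeSelection, compute_contact_map, min_heavy_atom_distance
from intercomap.contacts import (
    NO_BIN,
    assign_distance_bin,
    classify_contact_property,
    dense_matrix,
    detect_hbonds,
    interacting_residue_table,
    sparse_table,
)
from intercomap.structure import Atom, Model, Residue

from conftest import brute_force_contact_pairs, brute_force_min_distance


def make_residue(chain, resseq, resname, coords, elements=None, names=None,
                 polymer_class="amino_acid"):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    elements = elements or ["C"] * n
    names = names or [f"C{i}" for i in range(n)]
    atoms = tuple(
        Atom(name=nm, element=el, coord=tuple(c)) for nm, el, c in zip(names, elements, coords)
    )
    return Residue(chain, resseq, "", resname, polymer_class, atoms)


def make_model(*residues):
    return Model(model_id="t", residues=tuple(residues))


SEL_A = MoleculeSelection({"A"})
SEL_B = MoleculeSelection({"B"})


class TestMinDistance:
    def test_three_four_five_triangle(self):
        r1 = make_residue("A", 1, "ALA", [(0, 0, 0)])
        r2 = make_residue("B", 1, "GLY", [(3, 4, 0)])
        assert min_heavy_atom_distance(r1, r2) == pytest.approx(5.0)

    def test_minimum_over_atoms(self):
        r1 = make_residue("A", 1, "ALA", [(0, 0, 0), (10, 0, 0)])
        r2 = make_residue("B", 1, "GLY", [(4, 0, 0)])
        assert min_heavy_atom_distance(r1, r2) == pytest.approx(4.0)

    def test_hydrogens_ignored(self):
        r1 = make_residue("A", 1, "ALA", [(0, 0, 0), (4.5, 0, 0)], elements=["C", "H"],
                          names=["CA", "HA"])
        r2 = make_residue("B", 1, "GLY", [(5, 0, 0)])
        assert min_heavy_atom_distance(r1, r2) == pytest.approx(5.0)

    def test_no_heavy_atoms_is_error(self):
        r1 = make_residue("A", 1, "ALA", [(0, 0, 0)], elements=["H"], names=["H"])
        r2 = make_residue("B", 1, "GLY", [(1, 0, 0)])
        with pytest.raises(ValueError):
            min_heavy_atom_distance(r1, r2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_on_random_residues(self, seed):
        rng = np.random.default_rng(seed)
        r1 = make_residue("A", 1, "ALA", rng.uniform(-5, 5, size=(10, 3)))
        r2 = make_residue("B", 1, "GLY", rng.uniform(-5, 5, size=(10, 3)))
        assert min_heavy_atom_distance(r1, r2) == pytest.approx(
            brute_force_min_distance(r1, r2), rel=1e-12
        )


class TestContactMap:
    def test_boundary_distance_is_contact(self):
        # CAPRI definition: heavy atoms separated by <= 5 Å, boundary inclusive
        model = make_model(
            make_residue("A", 1, "ALA", [(0, 0, 0)]),
            make_residue("B", 1, "GLY", [(5.0, 0, 0)]),
        )
        cmap = compute_contact_map(model, SEL_A, SEL_B, cutoff=5.0)
        assert (("A", 1, ""), ("B", 1, "")) in cmap

    def test_just_beyond_cutoff_absent(self):
        model = make_model(
            make_residue("A", 1, "ALA", [(0, 0, 0)]),
            make_residue("B", 1, "GLY", [(5.001, 0, 0)]),
        )
        cmap = compute_contact_map(model, SEL_A, SEL_B, cutoff=5.0)
        assert len(cmap) == 0

    def test_toy_grid_equals_brute_force(self):
        rng = np.random.default_rng(7)
        residues = []
        for c, y in (("A", 0.0), ("B", 4.0)):
            for i in range(3):
                residues.append(
                    make_residue(c, i + 1, "ALA", rng.uniform(0, 1, (3, 3)) + [i * 3.0, y, 0])
                )
        model = make_model(*residues)
        cmap = compute_contact_map(model, SEL_A, SEL_B, cutoff=5.0)
        assert cmap.pairs == brute_force_contact_pairs(model, SEL_A, SEL_B, 5.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_oracle_equivalence_on_random_models(self, seed):
        """k-d-tree accelerated map is identical to the exhaustive scan."""
        rng = np.random.default_rng(seed)
        residues = []
        for c in ("A", "B"):
            for i in range(rng.integers(2, 6)):
                center = rng.uniform(-8, 8, 3)
                residues.append(
                    make_residue(c, i + 1, "ALA", center + rng.uniform(-2, 2, (4, 3)))
                )
        model = make_model(*residues)
        cutoff = float(rng.uniform(2.0, 8.0))
        cmap = compute_contact_map(model, SEL_A, SEL_B, cutoff=cutoff)
        oracle = brute_force_contact_pairs(model, SEL_A, SEL_B, cutoff)
        assert cmap.pairs == oracle
        for pair in cmap.pairs:
            r1 = model.residue(pair[0])
            r2 = model.residue(pair[1])
            assert cmap.records[pair].min_dist == pytest.approx(
                brute_force_min_distance(r1, r2), rel=1e-12
            )

    def test_swap_transposes(self, toy_model, sel_ab):
        s1, s2 = sel_ab
        fwd = compute_contact_map(toy_model, s1, s2, cutoff=5.0)
        rev = compute_contact_map(toy_model, s2, s1, cutoff=5.0)
        assert {(b, a) for a, b in fwd.pairs} == rev.pairs
        for (a, b), rec in fwd.records.items():
            assert rev.records[(b, a)].min_dist == rec.min_dist

    def test_monotone_in_cutoff(self, toy_model, sel_ab):
        s1, s2 = sel_ab
        prev = set()
        for cutoff in (3.0, 4.0, 5.0, 6.0, 8.0):
            pairs = compute_contact_map(toy_model, s1, s2, cutoff=cutoff).pairs
            assert prev <= pairs
            prev = pairs

    def test_overlapping_selections_rejected(self, toy_model):
        with pytest.raises(ValueError, match="overlap"):
            compute_contact_map(toy_model, MoleculeSelection({"A"}),
                                MoleculeSelection({"A", "B"}), cutoff=5.0)

    def test_intra_chain_ranges_have_no_self_pairs(self, toy_model):
        s1 = MoleculeSelection(residue_ranges=[("A", 1, 5)])
        s2 = MoleculeSelection(residue_ranges=[("A", 6, 10)])
        cmap = compute_contact_map(toy_model, s1, s2, cutoff=6.0)
        assert all(p[0] != p[1] for p in cmap.pairs)
        assert all(p[0][1] <= 5 < p[1][1] for p in cmap.pairs)


class TestPropertyClass:
    @pytest.mark.parametrize(
        "n1,n2,expected",
        [
            ("LEU", "ILE", "hydrophobic-hydrophobic"),
            ("ASP", "LYS", "charged-charged"),
            ("SER", "THR", "hydrophilic-hydrophilic"),
            ("SER", "PHE", "mixed"),
            ("GLU", "TYR", "mixed"),
        ],
    )
    def test_standard_pairs(self, n1, n2, expected):
        r1 = make_residue("A", 1, n1, [(0, 0, 0)])
        r2 = make_residue("B", 1, n2, [(1, 0, 0)])
        assert classify_contact_property(r1, r2) == expected
        assert classify_contact_property(r2, r1) == expected  # symmetric

    def test_nucleotide_pair_is_mixed(self):
        r1 = make_residue("A", 1, "LEU", [(0, 0, 0)])
        r2 = make_residue("B", 1, "DA", [(1, 0, 0)], polymer_class="nucleotide")
        assert classify_contact_property(r1, r2) == "mixed"

    def test_unknown_name_warns_mixed(self):
        r1 = make_residue("A", 1, "XXX", [(0, 0, 0)])
        r2 = make_residue("B", 1, "LEU", [(1, 0, 0)])
        with pytest.warns(UserWarning):
            assert classify_contact_property(r1, r2) == "mixed"

    def test_table_override(self):
        r1 = make_residue("A", 1, "SER", [(0, 0, 0)])
        r2 = make_residue("B", 1, "PHE", [(1, 0, 0)])
        table = {"SER": "hydrophobic", "PHE": "hydrophobic"}
        assert classify_contact_property(r1, r2, table) == "hydrophobic-hydrophobic"


class TestDistanceBins:
    @pytest.mark.parametrize(
        "d,expected",
        [(6.5, 0), (7.0, 0), (10.0, 1), (12.9, 2), (16.0, 3), (20.0, NO_BIN)],
    )
    def test_default_edges(self, d, expected):
        assert assign_distance_bin(d, (7, 10, 13, 16)) == expected


class TestHbonds:
    def _interface(self, *coords_elements):
        res = []
        for i, (chain, coords, elements, names) in enumerate(coords_elements):
            res.append(make_residue(chain, i + 1, "SER", coords, elements, names))
        return make_model(*res)

    def test_close_no_pair_reported_both_directions(self):
        model = self._interface(
            ("A", [(0, 0, 0)], ["N"], ["N"]),
            ("B", [(2.9, 0, 0)], ["O"], ["O"]),
        )
        hb = detect_hbonds(model, SEL_A, SEL_B)
        # no explicit hydrogens: both donor->acceptor directions satisfied
        assert len(hb) == 2
        assert all(d == pytest.approx(2.9) for *_, d in hb)

    def test_distant_pair_not_reported(self):
        model = self._interface(
            ("A", [(0, 0, 0)], ["N"], ["N"]),
            ("B", [(4.2, 0, 0)], ["O"], ["O"]),
        )
        assert detect_hbonds(model, SEL_A, SEL_B) == []

    def test_angle_criterion_with_hydrogens(self):
        # donor N with H pointing AWAY from acceptor: angle ~0°, rejected
        model = self._interface(
            ("A", [(0, 0, 0), (-1.0, 0, 0)], ["N", "H"], ["N", "H1"]),
            ("B", [(3.0, 0, 0)], ["O"], ["O"]),
        )
        hb = detect_hbonds(model, SEL_A, SEL_B)
        # A->B rejected by angle; B's O (no H) still donates to A's N
        assert [(d[0], a[0]) for d, a, _ in hb] == [("B", "A")]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        model = self._interface(
            ("A", rng.uniform(0, 4, (3, 3)), ["N", "O", "C"], ["N", "OG", "CB"]),
            ("B", rng.uniform(0, 4, (2, 3)), ["O", "N"], ["O", "ND2"]),
        )
        hb = detect_hbonds(model, SEL_A, SEL_B)
        expected = []
        resA, resB = model.residues
        for rd, ra in ((resA, resB), (resB, resA)):
            for d_atom in rd.atoms:
                if d_atom.element not in ("N", "O"):
                    continue
                for a_atom in ra.atoms:
                    if a_atom.element not in ("N", "O"):
                        continue
                    dist = float(np.linalg.norm(d_atom.xyz - a_atom.xyz))
                    if dist <= 3.5:
                        expected.append(((*rd.key, d_atom.name), (*ra.key, a_atom.name)))
        assert [(d, a) for d, a, _ in hb] == expected


class TestTables:
    def test_empty_map_gives_empty_table_with_header(self):
        model = make_model(
            make_residue("A", 1, "ALA", [(0, 0, 0)]),
            make_residue("B", 1, "GLY", [(50, 0, 0)]),
        )
        cmap = compute_contact_map(model, SEL_A, SEL_B, cutoff=5.0)
        table = interacting_residue_table(cmap, model)
        assert len(table) == 0
        assert list(table.columns) == [
            "res1", "res1_name", "res2", "res2_name", "min_dist", "property_class",
        ]

    def test_row_per_contact_in_axis_order(self, toy_model, sel_ab):
        s1, s2 = sel_ab
        cmap = compute_contact_map(toy_model, s1, s2, cutoff=6.0)
        table = interacting_residue_table(cmap, toy_model)
        assert len(table) == len(cmap)
        # axis order equals resseq order for the toy chains
        resseq1 = [int(k.split(":")[1]) for k in table["res1"]]
        assert resseq1 == sorted(resseq1)
        assert dense_matrix(cmap).to_numpy().sum() == len(cmap)
        assert len(sparse_table(cmap)) == len(cmap)
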