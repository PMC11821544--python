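"""Building blocks: synthetic trimers, sub-assembly extraction, cage assembly,
structure I/O."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from pseudocage import blocks, lattice, symcore


class TestSyntheticTrimer:
    def test_exact_c3_symmetry(self):
        tri = blocks.synthetic_trimer(15.0, 20, 0)
        assert len(tri.chains) == 3
        assert tri.c3_backbone_rmsd() < 1e-9

    def test_seed_determinism(self):
        a = blocks.synthetic_trimer(15.0, 20, 7)
        b = blocks.synthetic_trimer(15.0, 20, 7)
        assert np.array_equal(a.all_coords(), b.all_coords())
        c = blocks.synthetic_trimer(15.0, 20, 8)
        assert not np.array_equal(a.all_coords(), c.all_coords())

    def test_cross_chain_contact_count_matches_brute_force(self):
        """KD-tree census equals the all-pairs O(n^2) count at 4 A."""
        tri = blocks.synthetic_trimer(2.2, 8, 3, bar_residues=3)
        coords, owner = [], []
        for i, c in enumerate(tri.chains):
            hc = c.heavy_coords()
            coords.append(hc)
            owner.extend([i] * len(hc))
        xyz = np.vstack(coords)
        owner = np.array(owner)
        brute = sum(
            1
            for i in range(len(xyz))
            for j in range(i + 1, len(xyz))
            if owner[i] != owner[j] and np.linalg.norm(xyz[i] - xyz[j]) < 4.0
        )
        pairs = cKDTree(xyz).query_pairs(4.0)
        fast = sum(1 for i, j in pairs if owner[i] != owner[j])
        assert fast == brute

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            blocks.synthetic_trimer(-1.0, 20, 0)
        with pytest.raises(ValueError):
            blocks.synthetic_trimer(10.0, 3, 0)


class TestRelabel:
    def test_patterns(self, small_trimer):
        assert [c.label for c in blocks.relabel(small_trimer, "CCC").chains] == [
            "C1", "C2", "C3",
        ]
        aab = blocks.relabel(small_trimer, "AAB")
        letters = [c.label[0] for c in aab.chains]
        assert letters.count("A") == 2 and letters.count("B") == 1
        assert np.array_equal(aab.all_coords(), small_trimer.all_coords())

    def test_abc_unsupported(self, small_trimer):
        """The ABC heterotrimer route fails (off-target AAB/ABB species)."""
        with pytest.raises(ValueError, match="AAB/ABB"):
            blocks.relabel(small_trimer, "ABC")


class TestT1Parent:
    def test_sixty_chains_twenty_trimers(self, t1_parent):
        assert t1_parent.n_chains == 60
        assert t1_parent.metadata["n_trimers"] == 20
        assert not t1_parent.metadata.get("clash_warning", False)

    def test_invariant_under_group(self, t1_parent, group):
        cents = np.stack([c.centroid() for c in t1_parent.chains])
        tree = cKDTree(cents)
        for op in group.operators:
            d, _ = tree.query(cents @ op.matrix.T)
            assert d.max() < 1e-6 * np.abs(cents).max()

    def test_azimuth_scan_matches_scalar_minimizer(self, group, small_trimer):
        """Brute-force azimuth scan of the nearest inter-trimer distance
        agrees with scalar refinement of the same objective."""
        from scipy.optimize import minimize_scalar

        radius = blocks.build_t1_parent(small_trimer, group=group).metadata["radius"]

        def gap(az):
            m = blocks.build_t1_parent(
                small_trimer, radius=radius, azimuth=az, group=group
            )
            return blocks.nearest_intertrimer_distance(m)

        azs = np.arange(-20.0, 20.1, 2.5)
        vals = [gap(a) for a in azs]
        i = int(np.argmin(vals))
        res = minimize_scalar(gap, bounds=(azs[max(i - 1, 0)], azs[min(i + 1, len(azs) - 1)]),
                              method="bounded", options={"xatol": 0.05})
        assert res.fun <= min(vals) + 1e-6


class TestPentasymmetron:
    def test_fifteen_chains_ten_a_five_b(self, t1_parent, group):
        penta = blocks.extract_pentasymmetron(
            t1_parent, symcore.symmetry_axes(group, 5)[0]
        )
        labels = [c.label for c in penta.chains]
        assert len(labels) == 15
        assert sum(1 for l in labels if l[2] == "A") == 10
        assert sum(1 for l in labels if l[2] == "B") == 5

    def test_aa_contacts_form_five_cycle(self, t1_parent, group):
        """Brute-force contact graph among the 5 trimers is a single 5-cycle."""
        penta = blocks.extract_pentasymmetron(
            t1_parent, symcore.symmetry_axes(group, 5)[0]
        )
        edges = set()
        for i in range(5):
            ci = np.vstack([c.heavy_coords() for c in penta.trimers[i].chains])
            for j in range(i + 1, 5):
                cj = np.vstack([c.heavy_coords() for c in penta.trimers[j].chains])
                if cKDTree(ci).query(cj)[0].min() < 5.0:
                    edges.add((i, j))
        assert len(edges) == 5
        deg = {}
        for a, b in edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        assert set(deg.values()) == {2}

    def test_reexpansion_tiles_parent(self, t1_parent, group):
        """Expanding the pentasymmetron over the group reproduces exactly the
        20 parent trimer centres."""
        penta = blocks.extract_pentasymmetron(
            t1_parent, symcore.symmetry_axes(group, 5)[0]
        )
        pc = np.stack(
            [np.mean([c.centroid() for c in t.chains], axis=0) for t in penta.trimers]
        )
        images = {
            tuple(np.round(x, 3))
            for op in group.operators
            for x in pc @ op.matrix.T
        }
        parents = {
            tuple(np.round(np.mean([c.centroid() for c in v], axis=0), 3))
            for v in blocks._t1_trimers(t1_parent).values()
        }
        assert images == parents

    def test_requires_five_fold(self, t1_parent, group):
        with pytest.raises(ValueError):
            blocks.extract_pentasymmetron(
                t1_parent, symcore.symmetry_axes(group, 2)[0]
            )


class TestDisymmetron:
    def test_six_chains_two_a_four_b(self, t1_parent, group):
        dis = blocks.build_disymmetron(t1_parent, symcore.symmetry_axes(group, 2)[0])
        labels = [c.label for c in dis.chains]
        assert len(labels) == 6
        assert sum(1 for l in labels if l[2] == "A") == 2
        assert sum(1 for l in labels if l[2] == "B") == 4

    def test_aa_contact_straddles_two_fold(self, t1_parent, group):
        """The centroid of the A:A contact region (all near-minimal atom
        pairs, a C2-symmetric set) lies on the two-fold axis."""
        axis = symcore.symmetry_axes(group, 2)[0]
        dis = blocks.build_disymmetron(t1_parent, axis)
        a1 = dis.trimers[0].chains[0].heavy_coords()
        a2 = dis.trimers[1].chains[0].heavy_coords()
        d = np.linalg.norm(a1[:, None, :] - a2[None, :, :], axis=2)
        close = d <= d.min() + 0.5
        ii, jj = np.nonzero(close)
        mid = ((a1[ii] + a2[jj]) / 2.0).mean(axis=0)
        e = axis.direction
        assert np.linalg.norm(mid - np.dot(mid, e) * e) < 1e-6

    def test_two_fold_maps_trimers_exactly(self, t1_parent, group):
        axis = symcore.symmetry_axes(group, 2)[0]
        op2 = [op for op in symcore.stabilizer(group, axis) if op.order == 2][0]
        dis = blocks.build_disymmetron(t1_parent, axis)
        c1 = np.vstack([c.coords() for c in dis.trimers[0].chains])
        c2 = np.vstack([c.coords() for c in dis.trimers[1].chains])
        assert cKDTree(c2).query(c1 @ op2.matrix.T)[0].max() < 1e-6


class TestAssembly:
    @pytest.mark.parametrize("h", [2, 3, 4])
    def test_chain_counts_match_stoichiometry(self, small_trimer, h):
        lc = blocks.recommended_lattice_constant(small_trimer)
        model = blocks.assemble_cage(lattice.layout(h, lc), small_trimer)
        s = lattice.stoichiometry(h)
        assert model.n_chains == s.total_chains
        letters = {}
        for c in model.chains:
            letters[c.label[5]] = letters.get(c.label[5], 0) + 1
        assert letters.get("A", 0) == s.n_chains_A
        assert letters.get("B", 0) == s.n_chains_B
        assert letters.get("C", 0) == s.n_chains_C

    def test_cage_invariant_under_group(self, cage_h2, group):
        cents = np.stack([c.centroid() for c in cage_h2.chains])
        tree = cKDTree(cents)
        for op in group.operators[::5]:
            d, _ = tree.query(cents @ op.matrix.T)
            assert d.max() < 1e-6 * np.abs(cents).max()

    @pytest.mark.parametrize("h", [2, 3])
    def test_designed_cage_is_clash_free(self, small_trimer, h):
        lc = blocks.recommended_lattice_constant(small_trimer)
        model = blocks.assemble_cage(lattice.layout(h, lc), small_trimer)
        assert blocks.clash_count(model, 2.4) == 0

    def test_asu_sizes(self, cage_h2, cage_h3, group):
        """T chains in the asymmetric unit: 4 at T=4, 9 at T=9."""
        assert blocks.asymmetric_unit(cage_h2, group).n_chains == 4
        assert blocks.asymmetric_unit(cage_h3, group).n_chains == 9

    def test_missing_component_reported(self, small_trimer):
        lay = lattice.layout(3, 100.0)
        with pytest.raises(KeyError, match="ABB"):
            blocks.assemble_cage(lay, {"AAB": small_trimer, "CCC": small_trimer})


class TestStructureIO:
    def test_pdb_round_trip_precision(self, small_trimer, tmp_path):
        path = tmp_path / "trimer.pdb"
        blocks.write_structure(small_trimer, path)
        back = blocks.read_structure(path)
        assert back.n_chains == 3
        assert np.max(np.abs(back.all_coords() - small_trimer.all_coords())) <= 1e-3

    def test_mmcif_round_trip_many_chains(self, cage_h2, tmp_path):
        path = tmp_path / "cage.cif"
        blocks.write_structure(cage_h2, path)
        back = blocks.read_structure(path)
        assert back.n_chains == 240
        assert {c.label for c in back.chains} == {c.label for c in cage_h2.chains}

    def test_pdb_chain_label_overflow(self, cage_h2, tmp_path):
        with pytest.raises(ValueError, match="mmCIF"):
            blocks.write_structure(cage_h2, tmp_path / "cage.pdb")

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ValueError):
            blocks.read_structure(path)
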