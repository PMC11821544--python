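"""Mutant-pair scanning: contact rule, energy model, selection rule,
coevolution channel and the full planted disrupt/rescue recovery."""

import numpy as np
import pytest

from pseudocage import blocks, mutscan, symcore


def _chain(label, residues):
    """residues: list of (resname, ca, cb) with 1-based numbering."""
    atoms = []
    for ri, (rn, ca, cb) in enumerate(residues, start=1):
        atoms.append(blocks.AtomRecord("C", "CA", np.asarray(ca, float), ri, rn, label))
        atoms.append(blocks.AtomRecord("C", "CB", np.asarray(cb, float), ri, rn, label))
    return blocks.Chain(label, atoms)


@pytest.fixture()
def planted_interface():
    """Two chains whose residue 1 centres face each other: CA-CA 3.9 A
    (a contact by the 4 A heavy rule) but CB-CB 6.9 A, sized so that only
    TRP on the ALA side over-fills the gap and GLY on the VAL side
    relieves it again."""
    X = _chain("X", [
        ("ALA", (0, 0, 0), (-1.5, 0, 0)),
        ("ALA", (0, 15, 0), (0, 15, 1.5)),
        ("ALA", (0, 30, 0), (0, 30, 1.5)),
    ])
    Y = _chain("Y", [
        ("VAL", (3.9, 0, 0), (5.4, 0, 0)),
        ("ALA", (3.9, 15, 0), (3.9, 15, 1.5)),
        ("ALA", (3.9, 30, 0), (3.9, 30, 1.5)),
    ])
    return blocks.StructureModel([X, Y])


class TestContacts:
    def test_far_chains_have_no_contacts(self):
        a = _chain("A", [("ALA", (0, 0, 0), (0, 0, 1.5))] )
        b = _chain("B", [("ALA", (100, 0, 0), (100, 0, 1.5))])
        assert mutscan.interface_contacts(blocks.StructureModel([a, b])) == []

    def test_single_chain_rejected(self):
        a = _chain("A", [("ALA", (0, 0, 0), (0, 0, 1.5))])
        with pytest.raises(ValueError):
            mutscan.interface_contacts(blocks.StructureModel([a]))

    def test_planted_pair_found_and_matches_brute_force(self, small_trimer):
        """KD-tree contact enumeration equals the O(n^2) brute-force census
        on a synthetic trimer, including a planted 3.5 A cross-chain pair."""
        tri = blocks.synthetic_trimer(2.0, 8, 5, bar_residues=3)
        contacts = mutscan.interface_contacts(tri)
        heavy = []
        for c in tri.chains:
            for a in c.atoms:
                if a.is_heavy:
                    heavy.append((c.label, a.residue_index, a.coords))
        brute = set()
        for i in range(len(heavy)):
            for j in range(i + 1, len(heavy)):
                ci, ri, xi = heavy[i]
                cj, rj, xj = heavy[j]
                if ci != cj and np.linalg.norm(xi - xj) <= 4.0:
                    brute.add(tuple(sorted(((ci, ri), (cj, rj)))))
        got = {((c.chain_i, c.residue_i), (c.chain_j, c.residue_j)) for c in contacts}
        assert got == brute
        assert len(brute) > 0

    def test_contact_set_invariant_under_rigid_motion(self, planted_interface):
        before = mutscan.interface_contacts(planted_interface)
        R = symcore.rotation_matrix_about([1, 1, 1], 33.0)
        moved = planted_interface.transformed(R, np.array([5.0, -3.0, 2.0]))
        after = mutscan.interface_contacts(moved)
        key = lambda cs: [
            (c.chain_i, c.residue_i, c.chain_j, c.residue_j) for c in cs
        ]
        assert key(before) == key(after)

    def test_counting_conventions(self, planted_interface):
        contacts = mutscan.interface_contacts(planted_interface)
        assert len(mutscan.contact_positions(contacts)) >= 2
        merged = mutscan.merged_position_pairs(contacts)
        assert all(isinstance(p, tuple) and len(p) == 2 for p in merged)


class TestEnergyModel:
    def test_null_mutation_is_exactly_zero(self, planted_interface):
        model = mutscan.StericEnergyModel()
        assert mutscan.delta_scores(planted_interface, [], model) == (0.0, 0.0)

    def test_oversized_residue_at_tight_contact_disrupts(self, planted_interface):
        model = mutscan.StericEnergyModel()
        m = mutscan.MutationSpec("X", 1, "ALA", "TRP")
        d_score, d_ddg = mutscan.delta_scores(planted_interface, [m], model)
        assert d_score > 0 and d_ddg > 0

    def test_wrong_from_type_rejected(self, planted_interface):
        model = mutscan.StericEnergyModel()
        with pytest.raises(ValueError):
            mutscan.delta_scores(
                planted_interface, [mutscan.MutationSpec("X", 1, "GLY", "TRP")], model
            )
        with pytest.raises(KeyError):
            mutscan.delta_scores(
                planted_interface, [mutscan.MutationSpec("X", 99, "ALA", "TRP")], model
            )

    def test_additivity_for_disjoint_mutations(self, planted_interface):
        """Mutations farther apart than the interaction range contribute
        independently (pairwise-additive oracle)."""
        model = mutscan.StericEnergyModel()
        m1 = mutscan.MutationSpec("X", 1, "ALA", "TRP")
        m2 = mutscan.MutationSpec("Y", 3, "ALA", "TRP")
        d1 = mutscan.delta_scores(planted_interface, [m1], model)
        d2 = mutscan.delta_scores(planted_interface, [m2], model)
        d12 = mutscan.delta_scores(planted_interface, [m1, m2], model)
        assert d12[0] == pytest.approx(d1[0] + d2[0], abs=1e-9)
        assert d12[1] == pytest.approx(d1[1] + d2[1], abs=1e-9)

    def test_ddg_equals_cross_chain_definition(self, planted_interface):
        """ddG(structure) == total(oligomer) - sum total(isolated chains)."""
        model = mutscan.StericEnergyModel()
        whole = model.total(planted_interface)
        parts = sum(
            model.total(blocks.StructureModel([c])) for c in planted_interface.chains
        )
        assert model.ddg(planted_interface) == pytest.approx(whole - parts, abs=1e-12)


class TestScanAndSelect:
    def test_record_combinatorics(self, planted_interface):
        model = mutscan.StericEnergyModel()
        contacts = mutscan.interface_contacts(planted_interface)[:1]
        recs = mutscan.scan_pairs(planted_interface, contacts, ["GLY", "TRP"], model)
        assert len(recs) == 4  # 2 x 2 mutation combinations, singles included

    def test_wt_wt_record_is_all_zero(self, planted_interface):
        model = mutscan.StericEnergyModel()
        contacts = mutscan.interface_contacts(planted_interface)[:1]
        recs = mutscan.scan_pairs(
            planted_interface, contacts, ["ALA", "VAL"], model
        )
        wt = [r for r in recs if r.mutation_1.is_null and r.mutation_2.is_null]
        assert len(wt) == 1
        r = wt[0]
        assert (r.d_score_1, r.d_ddg_1, r.d_score_2, r.d_ddg_2,
                r.d_score_12, r.d_ddg_12) == (0,) * 6

    def test_recompute_subsample_matches(self, planted_interface):
        """Records re-evaluated independently through delta_scores agree
        exactly (recompute oracle)."""
        model = mutscan.StericEnergyModel()
        contacts = mutscan.interface_contacts(planted_interface)[:1]
        recs = mutscan.scan_pairs(planted_interface, contacts, ["GLY", "VAL", "TRP"], model)
        rng = np.random.default_rng(0)
        for r in rng.choice(recs, size=5, replace=False):
            muts = [m for m in (r.mutation_1, r.mutation_2) if not m.is_null]
            d = mutscan.delta_scores(planted_interface, muts, model) if muts else (0.0, 0.0)
            assert (r.d_score_12, r.d_ddg_12) == d

    def test_selection_rule_cases(self):
        def rec(s1, s2, s12):
            return mutscan.PairScanRecord(
                mutation_1=mutscan.MutationSpec("X", 1, "ALA", "TRP"),
                mutation_2=mutscan.MutationSpec("Y", 1, "VAL", "GLY"),
                d_score_1=s1, d_ddg_1=s1, d_score_2=s2, d_ddg_2=s2,
                d_score_12=s12, d_ddg_12=s12,
            )

        assert mutscan.select_pairs([rec(5.0, 3.0, -0.2)]) != []
        assert mutscan.select_pairs([rec(0.0, 0.0, -5.0)]) == []
        assert mutscan.select_pairs([rec(5.0, 0.0, 0.1)]) == []

    def test_selection_monotone_in_disrupt_threshold(self, planted_interface):
        model = mutscan.StericEnergyModel()
        contacts = mutscan.interface_contacts(planted_interface)[:1]
        recs = mutscan.scan_pairs(
            planted_interface, contacts, ["GLY", "ALA", "VAL", "PHE", "TRP"], model
        )
        prev = None
        for tau in (0.0, 0.01, 0.1, 1.0, 10.0):
            sel = {
                (str(r.mutation_1), str(r.mutation_2))
                for r in mutscan.select_pairs(recs, tau_disrupt=tau)
            }
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_full_pipeline_recovers_planted_pair(self, planted_interface):
        """contacts -> scan -> select returns exactly the planted
        (disrupt, rescue) pair: X1 ALA->TRP with Y1 VAL->GLY."""
        model = mutscan.StericEnergyModel()
        contacts = mutscan.interface_contacts(planted_interface)
        recs = mutscan.scan_pairs(planted_interface, contacts, ["GLY", "TRP"], model)
        sel = mutscan.select_pairs(recs)
        assert len(sel) == 1
        assert str(sel[0].mutation_1) == "X/ALA1TRP"
        assert str(sel[0].mutation_2) == "Y/VAL1GLY"


class TestCoevolution:
    def toy_stats(self):
        return [
            mutscan.CouplingStats(
                91, 118,
                f_obs={("H", "V"): 0.55, ("I", "V"): 0.01,
                       ("I", "Y"): 0.30, ("H", "Y"): 0.14},
                f_i={"H": 0.69, "I": 0.31},
                f_j={"V": 0.56, "Y": 0.44},
            )
        ]

    def test_depleted_wt_enriched_double_proposed(self):
        """A mutation depleted with the wild-type partner but enriched with
        a compensatory one is proposed (H91I with V118Y pattern)."""
        cands = mutscan.coevolution_select(self.toy_stats(), {91: "H", 118: "V"})
        top = cands[0]
        assert (top.mutation_position, top.mutation_aa) == (91, "I")
        assert (top.compensatory_position, top.compensatory_aa) == (118, "Y")
        assert top.e_with_wt < 1.0 < top.e_with_compensatory

    def test_independent_table_yields_nothing(self):
        f = {"A": 0.5, "B": 0.5}
        stats = [
            mutscan.CouplingStats(
                1, 2, {(a, b): 0.25 for a in "AB" for b in "AB"}, f, f
            )
        ]
        assert mutscan.coevolution_select(stats, {1: "A", 2: "A"}) == []

    def test_ranking_matches_brute_force(self):
        cands = mutscan.coevolution_select(self.toy_stats(), {91: "H", 118: "V"})
        scores = [c.rank_score for c in cands]
        assert scores == sorted(scores, reverse=True)
        st = self.toy_stats()[0]
        brute = []
        for m in ("I",):
            e_wt = st.enrichment(m, "V")
            if e_wt is not None and e_wt < 1.0:
                for c in ("Y",):
                    e_c = st.enrichment(m, c)
                    if e_c is not None and e_c > 1.0:
                        brute.append((91, m, 118, c))
        got = {
            (c.mutation_position, c.mutation_aa,
             c.compensatory_position, c.compensatory_aa)
            for c in cands
        }
        assert set(brute) <= got

    def test_zero_expected_frequency_skipped_with_warning(self):
        stats = [
            mutscan.CouplingStats(
                1, 2,
                {("A", "B"): 0.9, ("Q", "B"): 0.1},
                {"A": 1.0, "Q": 0.0},  # marginal of Q is zero -> f_exp = 0
                {"B": 1.0},
            )
        ]
        with pytest.warns(UserWarning):
            mutscan.coevolution_select(stats, {1: "A", 2: "B"})
        # a pseudocount resolves the zero cell instead of skipping it
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("error")
            mutscan.coevolution_select(stats, {1: "A", 2: "B"}, pseudocount=0.01)

    def test_coupling_table_round_trip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "i": [91] * 4, "j": [118] * 4,
                "a": ["H", "I", "I", "H"], "b": ["V", "V", "Y", "Y"],
                "f_obs": [0.55, 0.01, 0.30, 0.14],
                "f_i": [0.69, 0.31, 0.31, 0.69],
                "f_j": [0.56, 0.56, 0.44, 0.44],
            }
        )
        path = tmp_path / "couplings.tsv"
        df.to_csv(path, sep="\t", index=False)
        stats = mutscan.read_coupling_table(path)
        assert len(stats) == 1
        assert stats[0].enrichment("I", "Y") == pytest.approx(
            0.30 / (0.31 * 0.44)
        )
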