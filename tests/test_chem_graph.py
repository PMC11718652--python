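"""SMILES parser: examples, error reporting, distances, rings, valence."""

import numpy as np
import pytest

from hybridscreen.chem_graph import (
    AROMATIC,
    AromaticityError,
    MolecularGraph,
    ParenthesisError,
    RingClosureError,
    SmilesParseError,
    UNREACHABLE,
    UnknownElementError,
    ValenceError,
    parse_smiles,
    ring_info,
    topological_distances,
)


class TestParsing:
    def test_ethanol(self):
        g = parse_smiles("CCO")
        assert [a.element for a in g.atoms] == ["C", "C", "O"]
        assert len(g.bonds) == 2
        assert all(b.order_code == 1 for b in g.bonds)
        assert [a.implicit_h for a in g.atoms] == [3, 2, 1]

    def test_benzene(self):
        g = parse_smiles("c1ccccc1")
        assert len(g.atoms) == 6 and len(g.bonds) == 6
        assert all(a.aromatic and a.in_ring for a in g.atoms)
        assert all(b.order_code == AROMATIC for b in g.bonds)
        assert all(a.implicit_h == 1 for a in g.atoms)

    @pytest.mark.parametrize("smiles,elements,total_h", [
        ("c1ccncc1", "CCCNCC", [1, 1, 1, 0, 1, 1]),     # pyridine
        ("c1ccoc1", "CCCOC", [1, 1, 1, 0, 1]),          # furan
        ("c1ccsc1", "CCCSC", [1, 1, 1, 0, 1]),          # thiophene
        ("c1cc[nH]c1", "CCCNC", [1, 1, 1, 1, 1]),       # pyrrole
        ("CC(=O)[O-]", "CCOO", [3, 0, 0, 0]),           # acetate
        ("C[N+](C)(C)C", "CNCCC", [3, 0, 3, 3, 3]),     # tetramethylammonium
        ("O=S(=O)(N)c1ccccc1", "OSONCCCCCC",
         [0, 0, 0, 2, 0, 1, 1, 1, 1, 1]),               # sulfonamide, S(VI)
        ("OP(=O)(O)OC", "OPOOOC", [1, 0, 0, 1, 0, 3]),  # phosphate, P(V)
    ])
    def test_hydrogen_perception(self, smiles, elements, total_h):
        g = parse_smiles(smiles)
        assert "".join(a.element for a in g.atoms) == elements
        assert [a.total_h for a in g.atoms] == total_h

    def test_bracket_charge_and_h(self):
        g = parse_smiles("[NH4+]")
        atom = g.atoms[0]
        assert (atom.element, atom.formal_charge, atom.explicit_h,
                atom.total_h) == ("N", 1, 4, 4)

    def test_stereo_and_isotopes_ignored(self):
        plain = parse_smiles("NC(C)C(=O)O")
        decorated = parse_smiles("N[C@@H](C)C(=O)O")
        assert [a.element for a in decorated.atoms] == \
            [a.element for a in plain.atoms]
        assert parse_smiles("[13C]").atoms[0].element == "C"
        # directional bonds are plain single bonds
        g = parse_smiles("F/C=C/F")
        assert sorted(b.order_code for b in g.bonds) == [1, 1, 2]

    def test_percent_ring_closure(self):
        g = parse_smiles("C%10CCCCC%10")
        assert len(g.bonds) == 6
        assert all(a.in_ring for a in g.atoms)

    def test_dot_disconnection(self):
        g = parse_smiles("C.C")
        assert len(g.atoms) == 2 and len(g.bonds) == 0

    def test_round_trip_stability(self, corpus_smiles):
        for smi in corpus_smiles:
            a, b = parse_smiles(smi), parse_smiles(smi)
            assert a == b, smi


class TestErrors:
    @pytest.mark.parametrize("smiles,exc", [
        ("C1CC", RingClosureError),
        ("C1CC2", RingClosureError),
        ("C(C", ParenthesisError),
        ("CC)C", ParenthesisError),
        ("Cq", UnknownElementError),
        ("[Xx]", UnknownElementError),
        ("C(C)(C)(C)(C)C", ValenceError),
        ("O=C=O=C", ValenceError),
        ("cc", AromaticityError),
        ("cC", AromaticityError),
        ("", SmilesParseError),
        ("  ", SmilesParseError),
    ])
    def test_malformed_inputs_raise(self, smiles, exc):
        with pytest.raises(exc):
            parse_smiles(smiles)

    def test_error_names_position(self):
        with pytest.raises(RingClosureError, match="position 1"):
            parse_smiles("C1CC")


class TestTopologicalDistances:
    def test_chain(self):
        d = topological_distances(parse_smiles("CCO"))
        assert d[0, 2] == 2 and d[2, 0] == 2
        assert np.all(np.diag(d) == 0)

    def test_para_atoms_on_benzene(self):
        d = topological_distances(parse_smiles("c1ccccc1"))
        assert d[0, 3] == 3

    def test_disconnected_unreachable(self):
        d = topological_distances(parse_smiles("C.C"))
        assert d[0, 1] == UNREACHABLE

    def test_symmetry(self, corpus_smiles):
        for smi in corpus_smiles[:20]:
            d = topological_distances(parse_smiles(smi))
            assert np.array_equal(d, d.T)


class TestRings:
    def test_benzene_single_aromatic_ring(self):
        rings, aromatic = ring_info(parse_smiles("c1ccccc1"))
        assert rings == [[0, 1, 2, 3, 4, 5]]
        assert aromatic == [[0, 1, 2, 3, 4, 5]]

    def test_cyclopropane_not_aromatic(self):
        rings, aromatic = ring_info(parse_smiles("C1CC1"))
        assert len(rings) == 1 and len(rings[0]) == 3
        assert aromatic == []

    def test_naphthalene_two_fused_rings(self):
        rings, aromatic = ring_info(parse_smiles("c1ccc2ccccc2c1"))
        assert len(rings) == 2
        assert all(len(r) == 6 for r in rings)
        assert len(aromatic) == 2
        shared = set(rings[0]) & set(rings[1])
        assert len(shared) == 2

    def test_ring_flags_match_brute_force(self, corpus_smiles):
        """in_ring flags equal cycle membership from an exhaustive DFS."""
        def brute_force_cycle_atoms(graph: MolecularGraph) -> set:
            edges = [(b.atom_a, b.atom_b) for b in graph.bonds]
            adj = {i: set() for i in range(graph.n_atoms)}
            for a, b in edges:
                adj[a].add(b)
                adj[b].add(a)
            on_cycle = set()

            def dfs(start, node, visited):
                for nxt in adj[node]:
                    if nxt == start and len(visited) >= 3:
                        on_cycle.update(visited)
                    elif nxt not in visited and nxt > start:
                        dfs(start, nxt, visited | {nxt})

            for s in range(graph.n_atoms):
                dfs(s, s, frozenset({s}))
            return on_cycle

        checked = 0
        for smi in corpus_smiles:
            g = parse_smiles(smi)
            if g.n_atoms > 12:
                continue
            expected = brute_force_cycle_atoms(g)
            got = {a.index for a in g.atoms if a.in_ring}
            assert got == expected, smi
            checked += 1
        assert checked >= 5


class TestValenceOracle:
    def test_hydrogen_conservation(self, corpus_smiles):
        """Implicit H respects the valence table on >=50 molecules."""
        default = {"B": 3, "C": 4, "N": 3, "O": 2, "P": 3, "S": 2,
                   "F": 1, "Cl": 1, "Br": 1, "I": 1}
        assert len(corpus_smiles) >= 50
        for smi in corpus_smiles:
            g = parse_smiles(smi)
            sums = {a.index: 0.0 for a in g.atoms}
            arom = {a.index: 0 for a in g.atoms}
            for b in g.bonds:
                for end in (b.atom_a, b.atom_b):
                    if b.order_code == AROMATIC:
                        arom[end] += 1
                    else:
                        sums[end] += b.order_code
            for a in g.atoms:
                if a.explicit_h >= 0 or a.formal_charge != 0:
                    continue  # bracket/charged atoms follow their own rule
                bond_sum = sums[a.index] + arom[a.index]
                if a.aromatic and a.element not in ("O", "S"):
                    bond_sum += 1
                allowed = {default[a.element]}
                if a.element == "P":
                    allowed.add(5)
                if a.element == "S":
                    allowed.update((4, 6))
                assert a.implicit_h >= 0
                assert any(a.implicit_h + bond_sum == v for v in allowed), \
                    (smi, a)

    def test_total_h_matches_rdkit(self, corpus_smiles):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem

        agree = total = 0
        for smi in corpus_smiles:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            g = parse_smiles(smi)
            ours = sum(a.total_h for a in g.atoms)
            theirs = sum(at.GetTotalNumHs() for at in mol.GetAtoms())
            total += 1
            agree += ours == theirs
            assert g.n_atoms == mol.GetNumAtoms(), smi
        assert total >= 50
        assert agree == total
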