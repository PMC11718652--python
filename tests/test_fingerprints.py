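"""Morgan and pharmacophore fingerprints: worked examples, invariances,
and a rank-correlation cross-check against an independent toolkit."""

import numpy as np
import pytest

from hybridscreen.chem_graph import parse_smiles
from hybridscreen.fingerprints import (
    DISTANCE_BIN_EDGES,
    FAMILIES,
    PHARMACOPHORE_N_BITS,
    assign_pharmacophore_features,
    atom_invariants,
    decode_pharmacophore_bit,
    distance_bin,
    fold_bits,
    morgan_fingerprint,
    morgan_identifiers,
    pair_rank,
    pharmacophore_fingerprint,
)


class TestAtomInvariants:
    def test_degree_distinguishes_atoms(self):
        inv = atom_invariants(parse_smiles("CCO"))
        assert inv[0] != inv[1]  # CH3 vs CH2: degree 1 vs 2

    def test_identical_environments_hash_equal(self):
        inv = atom_invariants(parse_smiles("CCO"))
        inv2 = atom_invariants(parse_smiles("CCO"))
        assert inv == inv2

    def test_element_distinguishes_atoms(self):
        c = atom_invariants(parse_smiles("C"))[0]
        n = atom_invariants(parse_smiles("N"))[0]
        assert c != n


class TestMorgan:
    def test_single_atom_single_bit(self):
        fp = morgan_fingerprint(parse_smiles("C"), radius=2)
        assert len(fp.on_bits) == 1

    def test_ethanol_radius1_environment_count(self):
        assert len(morgan_identifiers(parse_smiles("CCO"), 1)) == 6
        fp = morgan_fingerprint(parse_smiles("CCO"), radius=1)
        assert len(fp.on_bits) <= 6

    def test_atom_order_invariance(self):
        assert morgan_fingerprint(parse_smiles("CCO")) == \
            morgan_fingerprint(parse_smiles("OCC"))

    def test_radius_monotonicity(self, corpus_smiles):
        for smi in corpus_smiles[:25]:
            g = parse_smiles(smi)
            for r in range(3):
                assert morgan_identifiers(g, r) <= morgan_identifiers(g, r + 1)

    def test_rejects_bad_parameters(self):
        g = parse_smiles("CC")
        with pytest.raises(ValueError):
            morgan_fingerprint(g, radius=7)
        with pytest.raises(ValueError):
            morgan_fingerprint(g, n_bits=1000)  # not a power of two


class TestFoldBits:
    @pytest.mark.parametrize("ids,n_bits,expected", [
        ({5, 2053}, 2048, {5}),
        (set(), 2048, set()),
        ({0, 1, 2}, 2048, {0, 1, 2}),
    ])
    def test_examples(self, ids, n_bits, expected):
        assert fold_bits(ids, n_bits) == expected

    def test_monotone_containment(self, corpus_smiles):
        for smi in corpus_smiles[:30]:
            pool = morgan_identifiers(parse_smiles(smi), 2)
            assert len(fold_bits(pool, 64)) <= len(pool)


class TestPharmacophoreFeatures:
    def test_benzene_single_aromatic_feature(self):
        feats = assign_pharmacophore_features(parse_smiles("c1ccccc1"))
        assert len(feats) == 1
        assert feats[0].family == "aromatic"
        assert feats[0].atom_indices == (0, 1, 2, 3, 4, 5)

    def test_phenol_features(self):
        feats = assign_pharmacophore_features(parse_smiles("Oc1ccccc1"))
        by_family = {(f.family, f.atom_indices) for f in feats}
        assert ("donor", (0,)) in by_family
        assert ("acceptor", (0,)) in by_family
        assert ("aromatic", (1, 2, 3, 4, 5, 6)) in by_family
        assert len(feats) == 3

    def test_acetate_features(self):
        feats = assign_pharmacophore_features(parse_smiles("CC(=O)[O-]"))
        fams = {(f.family, f.atom_indices) for f in feats}
        assert ("neg_ionizable", (3,)) in fams
        assert ("acceptor", (2,)) in fams
        assert ("acceptor", (3,)) in fams
        assert not any(f.family == "donor" for f in feats)

    def test_aliphatic_amine_is_pos_ionizable(self):
        feats = assign_pharmacophore_features(parse_smiles("CCN"))
        assert any(f.family == "pos_ionizable" for f in feats)
        # amide nitrogen is not
        feats = assign_pharmacophore_features(parse_smiles("CC(=O)N"))
        assert not any(f.family == "pos_ionizable" for f in feats)

    def test_carboxylic_acid_is_neg_ionizable(self):
        feats = assign_pharmacophore_features(parse_smiles("CC(=O)O"))
        assert any(f.family == "neg_ionizable" and f.atom_indices == (3,)
                   for f in feats)

    def test_deterministic_ordering(self, corpus_smiles):
        for smi in corpus_smiles[:20]:
            g = parse_smiles(smi)
            assert assign_pharmacophore_features(g) == \
                assign_pharmacophore_features(g)


class TestPharmacophoreFingerprint:
    def test_benzene_all_zero(self):
        fp = pharmacophore_fingerprint(parse_smiles("c1ccccc1"))
        assert fp.on_bits == ()
        assert fp.n_bits == PHARMACOPHORE_N_BITS == 126

    def test_phenol_three_bits(self):
        fp = pharmacophore_fingerprint(parse_smiles("Oc1ccccc1"))
        decoded = {decode_pharmacophore_bit(b) for b in fp.on_bits}
        assert decoded == {
            (("donor", "acceptor"), 0),
            (("donor", "aromatic"), 1),
            (("acceptor", "aromatic"), 1),
        }

    def test_featureless_molecule_all_zero(self):
        assert pharmacophore_fingerprint(parse_smiles("C")).on_bits == ()

    def test_disconnected_feature_pairs_skipped(self):
        # two phenols in separate components: no cross-component pairs
        one = pharmacophore_fingerprint(parse_smiles("Oc1ccccc1"))
        two = pharmacophore_fingerprint(parse_smiles("Oc1ccccc1.Oc1ccccc1"))
        assert set(two.on_bits) == set(one.on_bits)

    def test_bit_encoding_is_bijective(self):
        seen = set()
        for i, fa in enumerate(FAMILIES):
            for fb in FAMILIES[i:]:
                for b in range(len(DISTANCE_BIN_EDGES)):
                    bit = pair_rank(fa, fb) * len(DISTANCE_BIN_EDGES) + b
                    assert decode_pharmacophore_bit(bit) == ((fa, fb), b)
                    seen.add(bit)
        assert seen == set(range(126))

    @pytest.mark.parametrize("d,expected", [
        (0, 0), (1, 1), (2, 2), (3, 2), (4, 3), (5, 3), (6, 4), (7, 4),
        (8, 5), (50, 5),
    ])
    def test_distance_binning(self, d, expected):
        assert distance_bin(d) == expected

    def test_bits_always_below_126(self, corpus_smiles):
        for smi in corpus_smiles:
            fp = pharmacophore_fingerprint(parse_smiles(smi))
            assert all(0 <= b < 126 for b in fp.on_bits)


class TestPermutationInvariance:
    def test_rerooted_smiles_same_fingerprints(self, corpus_smiles):
        """Re-rooting/reordering a SMILES must not move any bit."""
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem

        checked = 0
        for smi in corpus_smiles:
            mol = Chem.MolFromSmiles(smi)
            if mol is None or mol.GetNumAtoms() < 3:
                continue
            ref_m = morgan_fingerprint(parse_smiles(smi))
            ref_p = pharmacophore_fingerprint(parse_smiles(smi))
            for root in range(0, mol.GetNumAtoms(), 3):
                alt = Chem.MolToSmiles(mol, rootedAtAtom=root,
                                       canonical=False)
                g = parse_smiles(alt)
                assert morgan_fingerprint(g) == ref_m, (smi, alt)
                assert pharmacophore_fingerprint(g) == ref_p, (smi, alt)
            checked += 1
            if checked >= 20:
                break
        assert checked >= 20


class TestReferenceToolkitCorrelation:
    def test_tanimoto_rank_correlation_with_rdkit(self, corpus_smiles):
        """Our Morgan Tanimoto ranking tracks RDKit's ECFP4 ranking."""
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem, DataStructs
        from rdkit.Chem import rdFingerprintGenerator
        from scipy.stats import spearmanr

        from hybridscreen.similarity import tanimoto

        query = "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21"
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2,
                                                        fpSize=2048)
        q_ours = morgan_fingerprint(parse_smiles(query))
        q_rd = gen.GetFingerprint(Chem.MolFromSmiles(query))
        ours, theirs = [], []
        for smi in corpus_smiles[:50]:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            ours.append(tanimoto(q_ours,
                                 morgan_fingerprint(parse_smiles(smi))))
            theirs.append(DataStructs.TanimotoSimilarity(
                q_rd, gen.GetFingerprint(mol)))
        assert len(ours) >= 50
        rho = spearmanr(ours, theirs).statistic
        assert rho > 0.7
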