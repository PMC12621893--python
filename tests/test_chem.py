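"""Molecule parsing, fingerprints, Tanimoto, and descriptor panel."""

import numpy as np
import pytest
from rdkit import Chem as RDChem

from delgem import chem
from delgem.errors import ConfigError, DimensionError, ParseError


class TestCanonicalize:
    def test_spelling_invariance(self):
        a = chem.canonicalize("C1=CC=CC=C1")
        b = chem.canonicalize("c1ccccc1")
        assert a.smiles_canonical == b.smiles_canonical
        assert a.n_heavy_atoms == 6

    def test_idempotence(self):
        for smi in ["CCO", "c1ccc2[nH]ccc2c1", "CN1CCN(CC1)C(=O)c1ccccc1",
                    "C/C=C/C", "C[C@H](N)C(=O)O"]:
            once = chem.canonicalize(smi)
            twice = chem.canonicalize(once.smiles_canonical)
            assert once.smiles_canonical == twice.smiles_canonical

    @pytest.mark.parametrize("bad", ["C1CC", "", "   ", "not_smiles", "C(("])
    def test_unparsable_raises(self, bad):
        with pytest.raises(ParseError):
            chem.canonicalize(bad)

    def test_parse_error_names_offender(self):
        with pytest.raises(ParseError, match="C1CC"):
            chem.canonicalize("C1CC")

    def test_salt_keeps_largest_fragment(self):
        mol = chem.canonicalize("CCN.Cl")
        assert mol.smiles_canonical == chem.canonicalize("CCN").smiles_canonical

    def test_stereo_and_charge_preserved(self):
        assert "@" in chem.canonicalize("C[C@H](N)C(=O)O").smiles_canonical
        assert "+" in chem.canonicalize("C[N+](C)(C)C").smiles_canonical


class TestFingerprint:
    def test_spelling_invariance(self):
        fa = chem.fingerprint(chem.canonicalize("c1ccccc1"))
        fb = chem.fingerprint(chem.canonicalize("C1=CC=CC=C1"))
        assert fa == fb

    def test_methane_has_at_least_one_bit(self):
        assert chem.fingerprint(chem.canonicalize("C")).popcount >= 1

    def test_benzene_differs_from_cyclohexane(self):
        fa = chem.fingerprint(chem.canonicalize("c1ccccc1"))
        fb = chem.fingerprint(chem.canonicalize("C1CCCCC1"))
        assert fa != fb

    def test_default_config(self):
        fp = chem.fingerprint(chem.canonicalize("CCO"))
        assert fp.n_bits == 2048 and fp.radius == 3
        assert fp.popcount <= fp.n_bits

    @pytest.mark.parametrize("radius,n_bits", [(-1, 2048), (3, 4), (3, 100)])
    def test_bad_config_raises(self, radius, n_bits):
        with pytest.raises(ConfigError):
            chem.fingerprint(chem.canonicalize("CCO"), radius=radius, n_bits=n_bits)

    def test_on_bits_match_packed_popcount(self):
        fp = chem.fingerprint(chem.canonicalize("CC(=O)Nc1ccccc1"))
        assert len(fp.on_bits) == fp.popcount


def _environment_set(smiles: str, radius: int) -> set:
    """Independent circular-environment oracle: the set of canonical SMILES
    of all atom-centered subgraphs up to the given bond radius."""
    mol = RDChem.MolFromSmiles(smiles)
    envs = set()
    for atom in mol.GetAtoms():
        for r in range(radius + 1):
            if r == 0:
                envs.add(atom.GetSmarts())
                continue
            bond_ids = RDChem.FindAtomEnvironmentOfRadiusN(mol, r, atom.GetIdx())
            if not bond_ids:
                continue
            frag = RDChem.PathToSubmol(mol, bond_ids)
            envs.add(RDChem.MolToSmiles(frag))
    return envs


class TestFingerprintOracle:
    """The fingerprint behaves as an ECFP-style circular environment hash."""

    SMALL = ["C", "CC", "CCO", "CCN", "c1ccccc1", "C1CCCCC1", "CC(=O)O",
             "c1ccncc1", "CC(C)C", "C1CCNCC1", "CC#N", "OCC(O)CO"]

    def test_identical_environment_sets_give_identical_bits(self):
        # different spellings of one molecule share an environment set and a fp
        spellings = ["c1ccccc1", "C1=CC=CC=C1"]
        envs = {frozenset(_environment_set(s, 3)) for s in spellings}
        fps = {chem.fingerprint(chem.canonicalize(s)) for s in spellings}
        assert len(envs) == 1 and len(fps) == 1

    def test_distinct_environment_sets_give_distinct_bits(self):
        fps = {}
        for smi in self.SMALL:
            fps[smi] = chem.fingerprint(chem.canonicalize(smi))
        for a in self.SMALL:
            for b in self.SMALL:
                if a == b:
                    continue
                if _environment_set(a, 3) != _environment_set(b, 3):
                    assert fps[a] != fps[b], (a, b)

    def test_tanimoto_matches_set_arithmetic(self):
        # packed-popcount Tanimoto equals brute-force set math on on-bits
        mols = [chem.canonicalize(s) for s in self.SMALL]
        fps = [chem.fingerprint(m) for m in mols]
        for i in range(len(fps)):
            for j in range(len(fps)):
                A, B = set(fps[i].on_bits), set(fps[j].on_bits)
                expected = len(A & B) / len(A | B) if A | B else 0.0
                assert chem.tanimoto(fps[i], fps[j]) == pytest.approx(expected)


class TestTanimoto:
    def test_self_similarity_is_one(self):
        fp = chem.fingerprint(chem.canonicalize("CCO"))
        assert chem.tanimoto(fp, fp) == 1.0

    def test_disjoint_is_zero_and_empty_empty_is_zero(self):
        mk = lambda bits: chem.Fingerprint(
            packed=np.packbits(bits), n_bits=16, radius=3
        )
        a = mk(np.array([1, 1, 0, 0] + [0] * 12, dtype=np.uint8))
        b = mk(np.array([0, 0, 1, 1] + [0] * 12, dtype=np.uint8))
        empty = mk(np.zeros(16, dtype=np.uint8))
        assert chem.tanimoto(a, b) == 0.0
        assert chem.tanimoto(empty, empty) == 0.0

    def test_hand_computed_overlap(self):
        mk = lambda idx: chem.Fingerprint(
            packed=np.packbits(np.isin(np.arange(16), idx).astype(np.uint8)),
            n_bits=16, radius=3,
        )
        assert chem.tanimoto(mk([1, 2, 3]), mk([2, 3, 4])) == pytest.approx(0.5)

    def test_width_mismatch_raises(self):
        a = chem.fingerprint(chem.canonicalize("CCO"), n_bits=1024)
        b = chem.fingerprint(chem.canonicalize("CCO"), n_bits=2048)
        with pytest.raises(DimensionError):
            chem.tanimoto(a, b)

    def test_symmetric_and_bounded_on_random_sample(self):
        from delgem import fixtures

        mols = [chem.canonicalize(s) for s in fixtures.make_corpus(100, 5)]
        fps = [chem.fingerprint(m) for m in mols]
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j = rng.integers(len(fps), size=2)
            t = chem.tanimoto(fps[i], fps[j])
            assert 0.0 <= t <= 1.0
            assert t == chem.tanimoto(fps[j], fps[i])


class TestPropertyPanel:
    def test_ethane(self):
        p = chem.property_panel(chem.canonicalize("CC"))
        assert p.rotatable_bonds == 0
        assert p.heteroatom_count == 0

    def test_pyridine_heteroatoms(self):
        assert chem.property_panel(chem.canonicalize("c1ccncc1")).heteroatom_count == 1

    def test_butane_rotatable(self):
        # the only non-terminal single C-C bond is C2-C3
        assert chem.property_panel(chem.canonicalize("CCCC")).rotatable_bonds == 1

    def test_amide_excluded_from_rotatable(self):
        # N-methylacetamide: the C(=O)-N bond does not count
        assert chem.property_panel(chem.canonicalize("CC(=O)NC")).rotatable_bonds == 0

    def test_benzene_mw(self):
        p = chem.property_panel(chem.canonicalize("c1ccccc1"))
        assert p.mw == pytest.approx(6 * 12.011 + 6 * 1.008, abs=0.01)

    def test_ranges(self):
        for smi in ["CCO", "c1ccccc1", "CN1CCN(CC1)C(=O)c1ccccc1"]:
            p = chem.property_panel(chem.canonicalize(smi))
            assert p.mw > 0
            assert 0.0 <= p.qed <= 1.0
            assert 1.0 <= p.sa_score <= 10.0

    def test_spelling_invariance(self):
        a = chem.property_panel(chem.canonicalize("C1=CC=CC=C1O"))
        b = chem.property_panel(chem.canonicalize("Oc1ccccc1"))
        assert a == b


class TestSmiIO:
    def test_round_trip(self, tmp_path):
        records = [("A1", "CCO"), ("A2", "c1ccccc1")]
        path = tmp_path / "t.smi"
        chem.write_smi(path, records)
        assert chem.read_smi(path) == records
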