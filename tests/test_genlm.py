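"""SMILES language model: tokenization, training, biasing, sampling."""

import numpy as np
import pytest

from delgem import chem, fixtures, genlm, scoring
from delgem.errors import ConfigError, ParseError


class TestTokenizer:
    @pytest.mark.parametrize(
        "smiles",
        [
            "CCO",
            "c1ccccc1",
            "CC(=O)Nc1ccc(Cl)cc1",
            "C[C@H](N)C(=O)O",
            "FC(F)(F)c1ccc(Br)cc1",
            "C1CC2(CC1)CCN(CC2)S(=O)(=O)C",
            "c1cc[nH]c1",
            "O=[N+]([O-])c1ccccc1",
        ],
    )
    def test_round_trip(self, smiles):
        assert "".join(genlm.tokenize(smiles)) == smiles

    def test_multichar_tokens_are_single(self):
        toks = genlm.tokenize("ClCCBr")
        assert toks == ["Cl", "C", "C", "Br"]
        assert genlm.tokenize("c1cc[nH]c1").count("[nH]") == 1

    def test_corpus_round_trips(self, corpus):
        for s in corpus[:500]:
            assert "".join(genlm.tokenize(s)) == s


class TestVocabulary:
    def test_encode_decode(self):
        vocab = genlm.TokenVocabulary.from_corpus(["CCO", "c1ccccc1"])
        ids = vocab.encode("CCO")
        assert ids[0] == vocab.bos_id and ids[-1] == vocab.eos_id
        assert vocab.decode(ids) == "CCO"

    def test_unknown_token_raises(self):
        vocab = genlm.TokenVocabulary.from_corpus(["CCO"])
        with pytest.raises(ParseError):
            vocab.encode("CCBr")

    def test_tokens_unique_and_reserved(self):
        vocab = genlm.TokenVocabulary.from_corpus(["CCO"])
        assert len(set(vocab.tokens)) == len(vocab.tokens)
        assert vocab.tokens[:3] == (genlm.PAD, genlm.BOS, genlm.EOS)


@pytest.fixture(scope="module")
def tiny_corpus():
    return fixtures.make_corpus(600, 31)


@pytest.fixture(scope="module")
def tiny_model(tiny_corpus):
    return genlm.pretrain(tiny_corpus, epochs=3, seed=5, hidden_dim=64, embed_dim=32)


class TestPretrain:
    def test_empty_corpus_raises(self):
        with pytest.raises(ConfigError):
            genlm.pretrain([], epochs=1, seed=0)

    def test_untrained_model_has_low_validity(self, tiny_corpus, tiny_model):
        untrained = genlm.pretrain(tiny_corpus, epochs=0, seed=5,
                                   hidden_dim=64, embed_dim=32)
        v_untrained = genlm.validity_rate(untrained, 300, seed=8)
        v_trained = genlm.validity_rate(tiny_model, 300, seed=8)
        assert v_trained > v_untrained

    def test_held_out_loss_decreases_within_tolerance(self, tiny_model):
        losses = tiny_model.training_meta["val_losses"]
        assert len(losses) == 4  # untrained + 3 epochs
        assert losses[-1] < losses[0]
        for e in range(1, len(losses)):
            assert losses[e] <= losses[e - 1] + 0.1

    def test_validity_after_toy_pretraining(self, pretrained):
        # 5,000-molecule corpus: at least half of 1,000 raw samples parse
        rate = genlm.validity_rate(pretrained, 1000, seed=9)
        assert rate >= 0.5


class TestSample:
    def test_seeded_determinism(self, tiny_model):
        a = genlm.sample(tiny_model, 50, seed=4)
        b = genlm.sample(tiny_model, 50, seed=4)
        assert [m.smiles_canonical for m in a] == [m.smiles_canonical for m in b]

    def test_n_one(self, tiny_model):
        assert len(genlm.sample(tiny_model, 1, seed=0)) <= 1

    def test_no_duplicate_canonical_smiles(self, pretrained):
        mols = genlm.sample(pretrained, 5000, seed=12)
        smis = [m.smiles_canonical for m in mols]
        assert len(smis) == len(set(smis))
        assert len(smis) <= 5000

    def test_source_ids_record_raw_index(self, tiny_model):
        mols = genlm.sample(tiny_model, 50, seed=4)
        for m in mols:
            assert m.source_id.startswith("sample")

    def test_bad_args(self, tiny_model):
        with pytest.raises(ConfigError):
            genlm.sample(tiny_model, 0, seed=1)
        with pytest.raises(ConfigError):
            genlm.sample_raw(tiny_model, 10, seed=1, temperature=0.0)


class TestBias:
    def test_zero_epochs_is_identity(self, tiny_model):
        biased = genlm.bias(tiny_model, ["CCO", "CCN"], epochs=0, seed=3)
        assert genlm.sample_raw(biased, 40, seed=7) == genlm.sample_raw(
            tiny_model, 40, seed=7
        )

    def test_input_model_unchanged(self, tiny_model):
        before = {k: v.copy() for k, v in tiny_model.params.items()}
        genlm.bias(tiny_model, ["CCO", "CCN", "CCCO"], epochs=2, seed=3)
        for k, v in tiny_model.params.items():
            assert np.array_equal(v, before[k])

    def test_empty_set_raises(self, tiny_model):
        with pytest.raises(ConfigError):
            genlm.bias(tiny_model, [], epochs=1, seed=0)

    def test_unparsable_members_skipped_with_warning(self, tiny_model):
        with pytest.warns(UserWarning, match="skipping"):
            biased = genlm.bias(
                tiny_model, ["CCO", "Xx%%bad"], epochs=1, seed=3
            )
        assert biased is not tiny_model

    def test_bias_improves_surrogate_score(self, pretrained, small_catalog, reference):
        """The pipeline's core property: fine-tuning on high-scoring
        molecules shifts sampling toward better-scoring chemistry."""
        records, truth = small_catalog
        lookup = dict(records)
        top = [lookup[i] for i in truth["planted_ids"]]
        target = scoring.SurrogateTarget(reference_fp=chem.fingerprint(reference))
        scorer = scoring.SurrogateScorer(target)

        pre = genlm.sample(pretrained, 500, seed=21)
        pre_scores = [s for s in scorer(pre) if np.isfinite(s)]
        biased = genlm.bias(pretrained, top, epochs=15, seed=5)
        post = genlm.sample(biased, 500, seed=21)
        post_scores = [s for s in scorer(post) if np.isfinite(s)]
        assert np.mean(post_scores) < np.mean(pre_scores)

    def test_bias_moves_samples_toward_top_set_centroid(self, pretrained,
                                                        small_catalog, reference):
        records, truth = small_catalog
        lookup = dict(records)
        top_fps = [
            chem.fingerprint(chem.canonicalize(lookup[i])) for i in truth["planted_ids"]
        ]

        def mean_sim_to_top(mols):
            sims = []
            for m in mols:
                fp = chem.fingerprint(m)
                sims.append(np.mean([chem.tanimoto(fp, t) for t in top_fps]))
            return np.mean(sims)

        lookup_smiles = [lookup[i] for i in truth["planted_ids"]]
        pre = genlm.sample(pretrained, 300, seed=22)
        biased = genlm.bias(pretrained, lookup_smiles, epochs=15, seed=5)
        post = genlm.sample(biased, 300, seed=22)
        assert mean_sim_to_top(post) > mean_sim_to_top(pre)

    def test_no_mode_collapse_onto_bias_set(self, pretrained, small_catalog):
        records, truth = small_catalog
        lookup = dict(records)
        top = [lookup[i] for i in truth["planted_ids"]]
        top_canonical = {chem.canonicalize(s).smiles_canonical for s in top}
        biased = genlm.bias(pretrained, top, epochs=15, seed=5)
        raw = genlm.sample_raw(biased, 400, seed=33)
        verbatim = 0
        for smi in raw:
            try:
                if chem.canonicalize(smi).smiles_canonical in top_canonical:
                    verbatim += 1
            except Exception:
                pass
        assert verbatim / len(raw) <= 0.5


class TestSerialization:
    def test_round_trip_bit_identical_sampling(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        genlm.save_model(tiny_model, path)
        loaded = genlm.load_model(path)
        assert loaded.vocabulary == tiny_model.vocabulary
        assert genlm.sample_raw(loaded, 100, seed=13) == genlm.sample_raw(
            tiny_model, 100, seed=13
        )

    def test_meta_preserved(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        genlm.save_model(tiny_model, path)
        loaded = genlm.load_model(path)
        assert loaded.training_meta == tiny_model.training_meta
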