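"""Encoder-decoder assembly: equivariance, masking, causality, decoding."""

import numpy as np
import pytest

from pairnovo.masses import WATER
from pairnovo.model import (
    ModelConfig,
    SpectrumTransformer,
    beam_search,
    load_checkpoint,
    peptide_mass,
    save_checkpoint,
)


@pytest.fixture(scope="module")
def tiny_pa(dictionary):
    return SpectrumTransformer(ModelConfig.tiny("pa"), dictionary, seed=0).eval()


@pytest.fixture(scope="module")
def batch(tiny_pa, small_dataset):
    return tiny_pa.prepare_batch(small_dataset[:6])


class TestModelConfig:
    def test_full_size_defaults(self):
        cfg = ModelConfig()
        assert (cfg.d_model, cfg.heads, cfg.d_head) == (512, 8, 64)
        assert cfg.encoder_depth == cfg.decoder_depth == 9
        assert cfg.dropout == 0.25
        assert cfg.top_peaks == 150 and cfg.max_peptide_length == 100
        assert (cfg.r_m, cfg.r_intensity, cfg.r_pw_prime, cfg.r_pw) == (1024, 256, 128, 64)

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=100, heads=8)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(variant="huge")


class TestEncoder:
    def test_permutation_equivariance_over_peaks(self, dictionary):
        """No positional encoding over peaks: permuting inputs permutes outputs."""
        for variant in ("base", "pa"):
            model = SpectrumTransformer(ModelConfig.tiny(variant), dictionary, seed=0).eval()
            rng = np.random.default_rng(4)
            n = 9
            mz = np.sort(rng.uniform(100, 1200, n))[None, :]
            inten = rng.uniform(0.1, 1.0, n)[None, :]
            mask = np.ones((1, n), dtype=bool)
            out = model.encoder(mz, inten, mask).data
            perm = rng.permutation(n)
            out_p = model.encoder(mz[:, perm], inten[:, perm], mask).data
            np.testing.assert_allclose(out_p, out[:, perm], atol=1e-8)

    def test_padded_peaks_do_not_leak_into_real_positions(self, dictionary):
        for variant in ("base", "pa"):
            model = SpectrumTransformer(ModelConfig.tiny(variant), dictionary, seed=1).eval()
            rng = np.random.default_rng(5)
            n = 7
            mz = np.sort(rng.uniform(100, 1200, n))[None, :]
            inten = rng.uniform(0.1, 1.0, n)[None, :]
            mask = np.ones((1, n), dtype=bool)
            out = model.encoder(mz, inten, mask).data
            mz_pad = np.concatenate([mz, np.full((1, 3), 700.0)], axis=1)
            inten_pad = np.concatenate([inten, np.full((1, 3), 0.5)], axis=1)
            mask_pad = np.concatenate([mask, np.zeros((1, 3), bool)], axis=1)
            out_pad = model.encoder(mz_pad, inten_pad, mask_pad).data
            np.testing.assert_allclose(out_pad[:, :n], out, atol=1e-6)

    def test_pa_with_zeroed_pairwise_parameters_equals_base(self, dictionary, batch):
        pa = SpectrumTransformer(ModelConfig.tiny("pa"), dictionary, seed=0).eval()
        base = SpectrumTransformer(ModelConfig.tiny("base"), dictionary, seed=0).eval()
        for name, p in pa.named_parameters():
            if "pairwise_net" in name or "bias_heads" in name:
                p.data[:] = 0.0
        shared = {k: v for k, v in pa.state_dict().items()
                  if "pairwise_net" not in k and "bias_heads" not in k}
        base.load_state_dict(shared)
        np.testing.assert_allclose(base.encode(batch).data, pa.encode(batch).data,
                                   atol=1e-6)

    def test_shared_pairwise_mlp_evaluated_once_per_forward(self, dictionary, batch,
                                                            monkeypatch):
        model = SpectrumTransformer(ModelConfig.tiny("pa"), dictionary, seed=0).eval()
        calls = {"n": 0}
        original = type(model.encoder.pairwise_net).forward

        def counting(self, phi):
            calls["n"] += 1
            return original(self, phi)

        monkeypatch.setattr(type(model.encoder.pairwise_net), "forward", counting)
        model.encode(batch)
        assert calls["n"] == 1

    def test_zero_peaks_rejected(self, tiny_pa):
        with pytest.raises(ValueError):
            tiny_pa.encoder(np.zeros((1, 0)), np.zeros((1, 0)), np.zeros((1, 0), bool))

    def test_base_encoder_parameter_count_matches_enumeration(self, dictionary):
        """Structural audit vs an independently computed closed form."""
        cfg = ModelConfig.tiny("base")
        model = SpectrumTransformer(cfg, dictionary, seed=0)
        d, h, hid = cfg.d_model, cfg.mlp_hidden, cfg.mlp_hidden
        proj = (cfg.r_m + cfg.r_intensity + 1) * cfg.d_model
        attn = 4 * (cfg.d_model + 1) * cfg.d_model
        mlp = (cfg.d_model + 1) * cfg.mlp_hidden + (cfg.mlp_hidden + 1) * cfg.d_model
        norms = 2 * 2 * cfg.d_model
        expected = proj + cfg.encoder_depth * (attn + mlp + norms)
        assert model.encoder.num_parameters() == expected


class TestDecoder:
    def test_causality_future_target_perturbation(self, tiny_pa, batch):
        targets = tiny_pa.encode_targets(batch["annotations"])
        memory = tiny_pa.encode(batch)
        logits = tiny_pa.decode_teacher_forced(memory, batch, targets).data
        t = 2
        perturbed = targets.copy()
        perturbed[:, t + 1] = (perturbed[:, t + 1] + 1) % len(tiny_pa.dictionary)
        logits_p = tiny_pa.decode_teacher_forced(memory, batch, perturbed).data
        np.testing.assert_allclose(logits_p[:, : t + 1], logits[:, : t + 1], atol=1e-10)
        assert not np.allclose(logits_p[:, t + 1 :], logits[:, t + 1 :])

    def test_target_longer_than_max_length_rejected(self, tiny_pa, batch):
        memory = tiny_pa.encode(batch)
        too_long = np.zeros((6, tiny_pa.cfg.max_peptide_length + 2), dtype=np.int64)
        with pytest.raises(ValueError, match="max_peptide_length"):
            tiny_pa.decode_teacher_forced(memory, batch, too_long)

    def test_decoder_parameter_count_matches_enumeration(self, dictionary):
        cfg = ModelConfig.tiny("pa")
        model = SpectrumTransformer(cfg, dictionary, seed=0)
        d, hid, vocab = cfg.d_model, cfg.mlp_hidden, len(dictionary)
        attn = 4 * (d + 1) * d
        layer = 2 * attn + ((d + 1) * hid + (hid + 1) * d) + 3 * 2 * d
        expected = (
            vocab * d  # token embedding
            + 11 * 32  # charge embedding
            + (cfg.r_m + 32 + 1) * d  # precursor projection
            + cfg.decoder_depth * layer
            + (d + 1) * vocab  # output head
        )
        assert model.decoder.num_parameters() == expected


class TestGreedyAndBeam:
    def test_greedy_is_deterministic(self, tiny_pa, small_dataset):
        a = tiny_pa.decode_greedy(small_dataset[:4])
        b = tiny_pa.decode_greedy(small_dataset[:4])
        for x, y in zip(a, b):
            assert x.tokens == y.tokens
            assert x.token_probs == y.token_probs

    def test_beam_one_equals_greedy(self, tiny_pa, small_dataset):
        for spec in small_dataset[:3]:
            greedy = tiny_pa.decode_greedy([spec])[0]
            beam = tiny_pa.decode_beam(spec, beams=1)
            assert beam.tokens == greedy.tokens

    def test_forced_eos_gives_empty_peptide(self, dictionary, small_dataset):
        model = SpectrumTransformer(ModelConfig.tiny("pa"), dictionary, seed=0).eval()
        model.decoder.out.weight.data[:] = 0.0
        model.decoder.out.bias.data[:] = 0.0
        model.decoder.out.bias.data[dictionary.eos_index] = 100.0
        pred = model.decode_greedy(small_dataset[:1])[0]
        assert pred.tokens == [] and pred.token_probs == []
        assert pred.peptide_mass == pytest.approx(WATER)

    def test_batched_and_single_greedy_agree(self, tiny_pa, small_dataset):
        batch_preds = tiny_pa.decode_greedy(small_dataset[:6])
        single_preds = [tiny_pa.decode_greedy([s])[0] for s in small_dataset[:6]]
        for a, b in zip(batch_preds, single_preds):
            assert a.tokens == b.tokens


class ToyTable:
    """Hand-set next-token log-probability tables over a 3-token vocab + EOS."""

    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        self.vocab = 4  # tokens 0..2, EOS=3
        self.eos = 3
        self.tables = {}
        self.rng = rng

    def __call__(self, prefix):
        key = tuple(prefix)
        if key not in self.tables:
            logits = self.rng.normal(scale=2.0, size=self.vocab)
            self.tables[key] = logits - np.log(np.exp(logits).sum())
        return self.tables[key]


def _enumerate_best(table, max_len):
    """Exhaustive search over all EOS-terminated sequences of length <= max_len."""
    best, best_score = None, -np.inf
    stack = [([], [])]
    while stack:
        tokens, logps = stack.pop()
        logprobs = table(tokens)
        eos_logps = logps + [logprobs[table.eos]]
        score = sum(eos_logps) / len(eos_logps)
        if score > best_score:
            best, best_score = tokens, score
        if len(tokens) < max_len:
            for v in range(table.vocab):
                if v != table.eos:
                    stack.append((tokens + [v], logps + [logprobs[v]]))
    return best, best_score


class TestBeamSearch:
    def test_matches_exhaustive_enumeration_on_toy_tables(self):
        for seed in range(5):
            table = ToyTable(seed)
            expected, _ = _enumerate_best(table, max_len=3)
            tokens, _ = beam_search(table, vocab_size=4, eos_index=3, max_len=3,
                                    beams=64)
            assert tokens == expected

    def test_score_never_decreases_with_more_beams(self):
        table = ToyTable(11)

        def best_score(beams):
            tokens, logps = beam_search(table, vocab_size=4, eos_index=3, max_len=3,
                                        beams=beams)
            full = logps + [table(tokens)[table.eos]]
            return sum(full) / len(full)

        scores = [best_score(b) for b in (1, 2, 4, 8, 16, 64)]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_invalid_beam_width_rejected(self):
        with pytest.raises(ValueError):
            beam_search(ToyTable(), vocab_size=4, eos_index=3, max_len=3, beams=0)


class TestPeptideMass:
    def test_single_glycine(self, dictionary):
        assert peptide_mass(["G"], dictionary) == pytest.approx(75.032025, abs=1e-9)

    def test_empty_is_water(self, dictionary):
        assert peptide_mass([], dictionary) == pytest.approx(WATER, abs=1e-12)

    def test_additivity(self, dictionary):
        diff = peptide_mass(["G", "G"], dictionary) - peptide_mass(["G"], dictionary)
        assert diff == pytest.approx(57.02146, abs=1e-9)

    def test_unknown_token_rejected(self, dictionary):
        with pytest.raises(KeyError):
            peptide_mass(["Z"], dictionary)


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path, dictionary, small_dataset):
        model = SpectrumTransformer(ModelConfig.tiny("pa"), dictionary, seed=3).eval()
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path).eval()
        assert restored.cfg == model.cfg
        assert restored.dictionary.tokens == dictionary.tokens
        a = model.decode_greedy(small_dataset[:3])
        b = restored.decode_greedy(small_dataset[:3])
        for x, y in zip(a, b):
            assert x.tokens == y.tokens
            np.testing.assert_array_equal(x.token_probs, y.token_probs)
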