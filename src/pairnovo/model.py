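"""Encoder-decoder transformer for de novo peptide sequencing.

Two encoder variants share one code path:

* ``base`` — standard multi-head self-attention over per-peak features.
* ``pa``   — pairwise attention: every encoder layer additionally receives an
  additive attention bias computed from the Fourier-encoded pairwise m/z
  differences (see :mod:`pairnovo.pairwise_attention`). The shared pairwise
  MLP is evaluated once per spectrum and adapted per layer by a small affine
  head.

The decoder is a standard autoregressive transformer with causal
self-attention and cross-attention to the encoder latents. Its start-of-
sequence input conditions on the precursor: the adjusted precursor mass
(m/z x charge) is Fourier-encoded with the m/z configuration and concatenated
with a learned charge embedding, then projected to the model width.

Peaks carry no positional encoding, so the encoder is permutation-equivariant
over peaks; decoder tokens use fixed sinusoidal positions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concatenate
from .featurize import FourierConfig, fourier_encode, pairwise_fourier
from .masses import WATER
from .nn import Dropout, Embedding, LayerNorm, Linear, Module
from .pairwise_attention import LayerBiasHead, MultiheadAttention, PairwiseBiasNet
from .spectra_io import Spectrum, TokenDictionary, preprocess

__all__ = [
    "ModelConfig",
    "Prediction",
    "SpectrumTransformer",
    "peptide_mass",
    "beam_search",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1
_CHARGE_EMBED_DIM = 32
_MAX_CHARGE = 10


@dataclass
class ModelConfig:
    """Architectural hyperparameters.

    Defaults are the full-size configuration: d_model=512 split over 8 heads
    of 64 units, 9 encoder and 9 decoder blocks, MLP hidden width 1024,
    dropout 0.25, Fourier dimensions r_m=1024 (wavelengths 0.001-10,000 Da),
    r_I=256 (1e-6-1), pairwise r_pw'=128 (m/z wavelengths) projected to
    r_pw=64, 150 retained peaks and a maximum peptide length of 100.
    """

    variant: str = "pa"
    d_model: int = 512
    heads: int = 8
    encoder_depth: int = 9
    decoder_depth: int = 9
    mlp_hidden: int = 1024
    dropout: float = 0.25
    r_m: int = 1024
    r_intensity: int = 256
    r_pw_prime: int = 128
    r_pw: int = 64
    mz_lambda: tuple = (0.001, 10_000.0)
    intensity_lambda: tuple = (1e-6, 1.0)
    top_peaks: int = 150
    max_peptide_length: int = 100

    def __post_init__(self):
        if self.variant not in ("base", "pa"):
            raise ValueError(f"variant must be 'base' or 'pa', got {self.variant!r}")
        if self.d_model % self.heads != 0:
            raise ValueError("d_model must be divisible by heads")
        if self.mlp_hidden < self.d_model:
            raise ValueError("mlp_hidden must be >= d_model")

    @property
    def d_head(self) -> int:
        return self.d_model // self.heads

    @property
    def mz_fourier(self) -> FourierConfig:
        return FourierConfig(self.r_m, *self.mz_lambda)

    @property
    def intensity_fourier(self) -> FourierConfig:
        return FourierConfig(self.r_intensity, *self.intensity_lambda)

    @property
    def pairwise_fourier_config(self) -> FourierConfig:
        # same wavelength range as the m/z features, fewer dimensions
        return FourierConfig(self.r_pw_prime, *self.mz_lambda)

    @classmethod
    def tiny(cls, variant: str = "pa") -> "ModelConfig":
        """Desk-scale configuration for CPU experiments and tests."""
        return cls(
            variant=variant, d_model=64, heads=8, encoder_depth=2, decoder_depth=2,
            mlp_hidden=128, dropout=0.1, r_m=128, r_intensity=32,
            r_pw_prime=32, r_pw=16, top_peaks=100, max_peptide_length=12,
        )


@dataclass
class Prediction:
    """A decoded peptide: tokens, their softmax probabilities, mass, confidence.

    ``confidence`` is the mean token probability, or -1 when the predicted
    mass fails the precursor ppm filter; None until scored (see
    :func:`pairnovo.evaluate.peptide_confidence`).
    """

    spectrum_id: str
    tokens: list[str]
    token_probs: list[float]
    peptide_mass: float
    confidence: float | None = None

    def __post_init__(self):
        if len(self.tokens) != len(self.token_probs):
            raise ValueError("tokens and token_probs must have equal length")


def peptide_mass(tokens: list[str], dictionary: TokenDictionary) -> float:
    """Neutral monoisotopic peptide mass: sum of residue masses plus water."""
    return dictionary.mass_of(tokens) + WATER


# -- layers -------------------------------------------------------------------


class _FeedForward(Module):
    def __init__(self, d_model: int, hidden: int, rng):
        super().__init__()
        self.lin1 = Linear(d_model, hidden, rng)
        self.lin2 = Linear(hidden, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class _EncoderLayer(Module):
    """Post-norm block: attention sublayer then MLP sublayer, with residuals."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.attn = MultiheadAttention(cfg.d_model, cfg.heads, rng)
        self.norm1 = LayerNorm(cfg.d_model)
        self.ff = _FeedForward(cfg.d_model, cfg.mlp_hidden, rng)
        self.norm2 = LayerNorm(cfg.d_model)
        self.drop = Dropout(cfg.dropout)

    def forward(self, x, mask, bias=None, rng=None):
        x = self.norm1(x + self.drop(
            self.attn(x, bias=bias, key_padding_mask=mask), rng))
        x = self.norm2(x + self.drop(self.ff(x), rng))
        return x


class _DecoderLayer(Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.self_attn = MultiheadAttention(cfg.d_model, cfg.heads, rng)
        self.norm1 = LayerNorm(cfg.d_model)
        self.cross_attn = MultiheadAttention(cfg.d_model, cfg.heads, rng)
        self.norm2 = LayerNorm(cfg.d_model)
        self.ff = _FeedForward(cfg.d_model, cfg.mlp_hidden, rng)
        self.norm3 = LayerNorm(cfg.d_model)
        self.drop = Dropout(cfg.dropout)

    def forward(self, x, memory, memory_mask, rng=None):
        x = self.norm1(x + self.drop(self.self_attn(x, causal=True), rng))
        x = self.norm2(x + self.drop(
            self.cross_attn(x, memory, key_padding_mask=memory_mask), rng))
        x = self.norm3(x + self.drop(self.ff(x), rng))
        return x


class SpectrumEncoder(Module):
    """Peak featurization plus a stack of (optionally pair-biased) blocks."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.peak_projection = Linear(cfg.r_m + cfg.r_intensity, cfg.d_model, rng)
        self.layers = [_EncoderLayer(cfg, rng) for _ in range(cfg.encoder_depth)]
        if cfg.variant == "pa":
            self.pairwise_net = PairwiseBiasNet(cfg.r_pw_prime, cfg.r_pw, rng)
            self.bias_heads = [LayerBiasHead(cfg.r_pw, cfg.heads, rng)
                               for _ in range(cfg.encoder_depth)]

    def forward(self, mz: np.ndarray, intensity: np.ndarray, mask: np.ndarray,
                rng=None):
        """Encode padded peak arrays (B, N); mask is True at real peaks."""
        if mz.shape[1] == 0:
            raise ValueError("cannot encode spectra with zero peaks")
        feats = np.concatenate(
            [fourier_encode(mz, self.cfg.mz_fourier),
             fourier_encode(intensity, self.cfg.intensity_fourier)], axis=-1)
        x = self.peak_projection(Tensor(feats))

        biases = [None] * len(self.layers)
        if self.cfg.variant == "pa":
            delta = mz[:, :, None] - mz[:, None, :]
            phi = pairwise_fourier(delta, self.cfg.pairwise_fourier_config)
            z = self.pairwise_net(Tensor(phi))  # shared: computed once
            biases = [head(z).transpose((0, 3, 1, 2)) for head in self.bias_heads]
        for layer, bias in zip(self.layers, biases):
            x = layer(x, mask, bias=bias, rng=rng)
        return x


class PeptideDecoder(Module):
    """Autoregressive token decoder with precursor-conditioned start input."""

    def __init__(self, cfg: ModelConfig, vocab_size: int, rng):
        super().__init__()
        self.cfg = cfg
        self.vocab_size = vocab_size
        self.token_embedding = Embedding(vocab_size, cfg.d_model, rng)
        self.charge_embedding = Embedding(_MAX_CHARGE + 1, _CHARGE_EMBED_DIM, rng)
        self.precursor_projection = Linear(cfg.r_m + _CHARGE_EMBED_DIM, cfg.d_model, rng)
        self.layers = [_DecoderLayer(cfg, rng) for _ in range(cfg.decoder_depth)]
        self.out = Linear(cfg.d_model, vocab_size, rng)
        self._positions = _sinusoidal_positions(cfg.max_peptide_length + 2, cfg.d_model)

    def _start_embedding(self, precursor_mass: np.ndarray, charge: np.ndarray) -> Tensor:
        mass_feats = Tensor(fourier_encode(precursor_mass, self.cfg.mz_fourier))
        charge_emb = self.charge_embedding(np.clip(charge, 0, _MAX_CHARGE))
        return self.precursor_projection(concatenate([mass_feats, charge_emb], axis=-1))

    def forward(self, memory: Tensor, memory_mask: np.ndarray, prev_tokens: np.ndarray,
                precursor_mass: np.ndarray, charge: np.ndarray, rng=None) -> Tensor:
        """Logits for the next token at every position.

        prev_tokens: (B, T-1) already-emitted tokens (teacher-forced gold or
        decoded prefix); position 0 of the decoder input is the precursor
        start embedding, so output position t predicts token t.
        """
        batch = memory.shape[0]
        t_in = prev_tokens.shape[1] + 1
        if t_in > self.cfg.max_peptide_length + 1:
            raise ValueError(
                f"target length {t_in - 1} exceeds max_peptide_length "
                f"{self.cfg.max_peptide_length}")
        start = self._start_embedding(precursor_mass, charge).reshape(batch, 1, -1)
        if prev_tokens.shape[1] > 0:
            tok = self.token_embedding(prev_tokens)
            x = concatenate([start, tok], axis=1)
        else:
            x = start
        x = x + Tensor(self._positions[:t_in])
        for layer in self.layers:
            x = layer(x, memory, memory_mask, rng=rng)
        return self.out(x)


def _sinusoidal_positions(length: int, d_model: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / (10_000.0 ** (2 * i / d_model))
    out = np.zeros((length, d_model))
    out[:, 0::2] = np.sin(angle)
    out[:, 1::2] = np.cos(angle)
    return out


# -- full model ---------------------------------------------------------------


class SpectrumTransformer(Module):
    """Full sequencing model: spectrum encoder + peptide decoder."""

    def __init__(self, cfg: ModelConfig, dictionary: TokenDictionary, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.dictionary = dictionary
        rng = np.random.default_rng(seed)
        self.encoder = SpectrumEncoder(cfg, rng)
        self.decoder = PeptideDecoder(cfg, len(dictionary), rng)

    # -- batching -------------------------------------------------------------

    def prepare_batch(self, spectra: list[Spectrum]) -> dict:
        """Preprocess and pad spectra into dense arrays (idempotent on
        already-preprocessed input)."""
        specs = [preprocess(s, self.cfg.top_peaks) for s in spectra]
        n_max = max(s.n_peaks for s in specs)
        batch = len(specs)
        mz = np.zeros((batch, n_max))
        intensity = np.zeros((batch, n_max))
        mask = np.zeros((batch, n_max), dtype=bool)
        for i, s in enumerate(specs):
            mz[i, : s.n_peaks] = s.mz
            intensity[i, : s.n_peaks] = s.intensity
            mask[i, : s.n_peaks] = True
        return {
            "mz": mz,
            "intensity": intensity,
            "mask": mask,
            "precursor_mass": np.array([s.adjusted_precursor_mass for s in specs]),
            "charge": np.array([s.charge for s in specs]),
            "ids": [s.spectrum_id for s in specs],
            "annotations": [s.annotation for s in specs],
        }

    def encode_targets(self, annotations: list[list[str]]) -> np.ndarray:
        """Token-index targets ending in EOS, PAD-padded to a common length."""
        d = self.dictionary
        seqs = [d.encode(a) + [d.eos_index] for a in annotations]
        t_max = max(len(s) for s in seqs)
        out = np.full((len(seqs), t_max), d.pad_index, dtype=np.int64)
        for i, s in enumerate(seqs):
            out[i, : len(s)] = s
        return out

    # -- forward passes -------------------------------------------------------

    def encode(self, batch: dict, rng=None) -> Tensor:
        return self.encoder(batch["mz"], batch["intensity"], batch["mask"], rng=rng)

    def decode_teacher_forced(self, memory: Tensor, batch: dict, targets: np.ndarray,
                              rng=None) -> Tensor:
        """Teacher-forced logits (B, T, vocab): position t sees targets < t."""
        prev = targets[:, :-1]
        return self.decoder(memory, batch["mask"], prev,
                            batch["precursor_mass"], batch["charge"], rng=rng)

    # -- decoding -------------------------------------------------------------

    def decode_greedy(self, spectra: list[Spectrum], batch_size: int = 100
                      ) -> list[Prediction]:
        """Greedy argmax decoding; deterministic for fixed weights."""
        self.eval()
        out: list[Prediction] = []
        for start in range(0, len(spectra), batch_size):
            out.extend(self._greedy_batch(spectra[start: start + batch_size]))
        return out

    def _greedy_batch(self, spectra: list[Spectrum]) -> list[Prediction]:
        d = self.dictionary
        batch = self.prepare_batch(spectra)
        memory = self.encode(batch)
        n = len(spectra)
        prev = np.zeros((n, 0), dtype=np.int64)
        done = np.zeros(n, dtype=bool)
        token_ids: list[list[int]] = [[] for _ in range(n)]
        token_probs: list[list[float]] = [[] for _ in range(n)]
        for _ in range(self.cfg.max_peptide_length + 1):
            logits = self.decoder(memory, batch["mask"], prev,
                                  batch["precursor_mass"], batch["charge"])
            probs = Tensor(logits.data[:, -1, :]).softmax(axis=-1).data
            probs[:, d.pad_index] = 0.0
            probs[:, d.sos_index] = 0.0
            choice = probs.argmax(axis=-1)
            for i in range(n):
                if done[i]:
                    continue
                if choice[i] == d.eos_index or len(token_ids[i]) >= self.cfg.max_peptide_length:
                    done[i] = True
                    continue
                token_ids[i].append(int(choice[i]))
                token_probs[i].append(float(probs[i, choice[i]]))
            if done.all():
                break
            prev = np.concatenate([prev, choice[:, None]], axis=1)
        preds = []
        for i in range(n):
            tokens = d.decode(token_ids[i])
            preds.append(Prediction(
                spectrum_id=batch["ids"][i], tokens=tokens,
                token_probs=token_probs[i],
                peptide_mass=peptide_mass(tokens, d)))
        return preds

    def decode_beam(self, spectrum: Spectrum, beams: int = 5) -> Prediction:
        """Beam search over token log-probabilities, scored by mean log-prob."""
        self.eval()
        d = self.dictionary
        batch = self.prepare_batch([spectrum])
        memory = self.encode(batch)

        def step_fn(prefix: list[int]) -> np.ndarray:
            prev = np.asarray([prefix], dtype=np.int64).reshape(1, len(prefix))
            logits = self.decoder(memory, batch["mask"], prev,
                                  batch["precursor_mass"], batch["charge"])
            row = logits.data[0, -1, :].copy()
            row[d.pad_index] = -np.inf
            row[d.sos_index] = -np.inf
            row -= row.max()
            return row - np.log(np.exp(row).sum())

        tokens_idx, logps = beam_search(
            step_fn, vocab_size=len(d), eos_index=d.eos_index,
            max_len=self.cfg.max_peptide_length, beams=beams)
        tokens = d.decode(tokens_idx)
        return Prediction(
            spectrum_id=spectrum.spectrum_id, tokens=tokens,
            token_probs=[float(np.exp(lp)) for lp in logps],
            peptide_mass=peptide_mass(tokens, d))


def beam_search(step_fn, vocab_size: int, eos_index: int, max_len: int,
                beams: int = 5) -> tuple[list[int], list[float]]:
    """Generic beam search.

    ``step_fn(prefix)`` returns a log-probability vector over the vocabulary
    given the decoded prefix (a list of token indices). Hypotheses are scored
    by mean token log-probability (EOS step included); hypotheses reaching
    the maximum length are force-terminated with their EOS log-probability so
    all hypotheses compete on the same footing.
    Returns (token indices without EOS, their log-probabilities).
    """
    if beams < 1:
        raise ValueError("beams must be >= 1")
    active: list[tuple[list[int], list[float]]] = [([], [])]
    finished: list[tuple[list[int], list[float], float]] = []

    def mean_score(logps: list[float]) -> float:
        return sum(logps) / len(logps) if logps else -np.inf

    for _ in range(max_len + 1):
        candidates: list[tuple[list[int], list[float]]] = []
        for tokens, logps in active:
            logprobs = step_fn(tokens)
            order = np.argsort(logprobs)[::-1][: beams + 1]
            for v in order:
                if not np.isfinite(logprobs[v]):
                    continue
                new_logps = logps + [float(logprobs[v])]
                if v == eos_index:
                    finished.append((tokens, new_logps, mean_score(new_logps)))
                else:
                    candidates.append((tokens + [int(v)], new_logps))
        if not candidates:
            break
        candidates.sort(key=lambda c: mean_score(c[1]), reverse=True)
        active = candidates[:beams]
        if active and len(active[0][0]) >= max_len:
            for tokens, logps in active:
                eos_logp = float(step_fn(tokens)[eos_index])
                full = logps + [eos_logp]
                finished.append((tokens, full, mean_score(full)))
            break
    if not finished:  # unreachable unless max_len == 0
        tokens, logps = active[0]
        return tokens, logps
    finished.sort(key=lambda f: f[2], reverse=True)
    tokens, logps, _ = finished[0]
    return tokens, logps[: len(tokens)]


# -- checkpointing ------------------------------------------------------------


def save_checkpoint(model: SpectrumTransformer, path) -> None:
    """Flat named-parameter archive plus serialized config and dictionary."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": dataclasses.asdict(model.cfg),
        "tokens": model.dictionary.tokens,
    }
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    np.savez(str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> SpectrumTransformer:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg_dict = dict(meta["config"])
        cfg_dict["mz_lambda"] = tuple(cfg_dict["mz_lambda"])
        cfg_dict["intensity_lambda"] = tuple(cfg_dict["intensity_lambda"])
        cfg = ModelConfig(**cfg_dict)
        dictionary = TokenDictionary(list(meta["tokens"]))
        model = SpectrumTransformer(cfg, dictionary, seed=0)
        state = {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
    model.load_state_dict(state)
    return model
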