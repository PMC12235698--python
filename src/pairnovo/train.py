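"""Teacher-forced training with linear learning-rate warmup.

Training minimizes mean token-level cross entropy (EOS included, PAD masked)
under teacher forcing, with Adam and a learning rate warmed up linearly to
its peak over ``warmup_steps`` optimizer steps and held constant afterwards.
Validation is scored per epoch by peptide precision (greedy decoding matched
against the ground truth), and the best-validation checkpoint is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import cross_entropy
from .model import ModelConfig, SpectrumTransformer, save_checkpoint
from .nn import Adam
from .spectra_io import Spectrum, TokenDictionary, build_token_dictionary

__all__ = ["TrainConfig", "FitResult", "lr_at_step", "sequence_loss", "fit"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Full-scale defaults: batch size 100, peak learning rate 2e-4 reached
    after 20,000 warmup steps. ``max_steps`` caps total optimizer steps
    (None = run all epochs); desk-scale runs use :meth:`tiny`.
    """

    batch_size: int = 100
    lr_peak: float = 2e-4
    warmup_steps: int = 20_000
    epochs: int = 30
    max_steps: int | None = None
    seed: int = 0
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.warmup_steps < 1:
            raise ValueError("warmup_steps must be >= 1")
        if self.lr_peak <= 0:
            raise ValueError("lr_peak must be positive")

    @classmethod
    def tiny(cls, seed: int = 0, max_steps: int = 1500) -> "TrainConfig":
        """Desk-scale schedule for CPU experiments: batch 32, peak lr 1e-3
        after a 100-step warmup."""
        return cls(batch_size=32, lr_peak=1e-3, warmup_steps=100,
                   epochs=1_000_000, max_steps=max_steps, seed=seed)


def lr_at_step(step: int, cfg: TrainConfig) -> float:
    """Linear warmup to lr_peak over warmup_steps, then constant."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return cfg.lr_peak * min(1.0, step / cfg.warmup_steps)


def sequence_loss(logits, targets: np.ndarray, pad_index: int):
    """Mean token cross entropy over non-PAD positions (EOS included)."""
    mask = np.asarray(targets) != pad_index
    if not mask.any():
        raise ValueError("all target positions are PAD")
    return cross_entropy(logits, targets, mask)


@dataclass
class FitResult:
    model: SpectrumTransformer
    history: list[dict] = field(default_factory=list)
    best_val_precision: float = -1.0
    best_state: dict | None = None


def _peptide_precision(model: SpectrumTransformer, spectra: list[Spectrum]) -> float:
    from .evaluate import match_amino_acids  # local import avoids a cycle

    preds = model.decode_greedy(spectra)
    hits = 0
    for pred, spec in zip(preds, spectra):
        result = match_amino_acids(pred.tokens, spec.annotation, model.dictionary)
        hits += int(result.peptide_match)
    return hits / len(spectra)


def fit(train_spectra: list[Spectrum], val_spectra: list[Spectrum],
        model_cfg: ModelConfig, train_cfg: TrainConfig,
        dictionary: TokenDictionary | None = None,
        run_dir=None, progress: bool = False) -> FitResult:
    """Train a model and return the best-validation checkpoint state.

    The token dictionary defaults to the one built from the training
    annotations. With a fixed seed the whole loss trajectory is reproducible.
    When ``run_dir`` is given, the final and best checkpoints plus a
    JSON-lines metric log are written there.
    """
    if not val_spectra:
        raise ValueError("validation set must be non-empty")
    annotations = [s.annotation for s in train_spectra if s.annotation]
    if dictionary is None:
        dictionary = build_token_dictionary(annotations)

    model = SpectrumTransformer(model_cfg, dictionary, seed=train_cfg.seed)
    optimizer = Adam(model.parameters(), lr=0.0)
    rng = np.random.default_rng(train_cfg.seed + 1)
    result = FitResult(model=model)

    step = 0
    log_fh = None
    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        log_fh = open(run_dir / "metrics.jsonl", "w")

    try:
        for epoch in range(train_cfg.epochs):
            model.train()
            order = rng.permutation(len(train_spectra))
            epoch_losses = []
            for start in range(0, len(order), train_cfg.batch_size):
                idx = order[start: start + train_cfg.batch_size]
                spectra = [train_spectra[i] for i in idx]
                batch = model.prepare_batch(spectra)
                targets = model.encode_targets(batch["annotations"])
                memory = model.encode(batch, rng=rng)
                logits = model.decode_teacher_forced(memory, batch, targets, rng=rng)
                loss = sequence_loss(logits, targets, dictionary.pad_index)
                optimizer.zero_grad()
                loss.backward()
                step += 1
                optimizer.lr = lr_at_step(step, train_cfg)
                optimizer.step()
                epoch_losses.append(loss.item())
                if progress and step % 100 == 0:
                    print(f"step {step}: loss {np.mean(epoch_losses[-100:]):.4f}")
                if train_cfg.max_steps is not None and step >= train_cfg.max_steps:
                    break
            val_precision = _peptide_precision(model, val_spectra)
            record = {
                "epoch": epoch,
                "step": step,
                "train_loss": float(np.mean(epoch_losses)),
                "val_peptide_precision": val_precision,
            }
            result.history.append(record)
            if log_fh is not None:
                log_fh.write(json.dumps(record) + "\n")
                log_fh.flush()
            if val_precision > result.best_val_precision:
                result.best_val_precision = val_precision
                result.best_state = model.state_dict()
                if run_dir is not None:
                    save_checkpoint(model, run_dir / "best.ckpt.npz")
            if train_cfg.max_steps is not None and step >= train_cfg.max_steps:
                break
    finally:
        if log_fh is not None:
            log_fh.close()

    if result.best_state is not None:
        model.load_state_dict(result.best_state)
    if run_dir is not None:
        save_checkpoint(model, run_dir / "final.ckpt.npz")
    return result
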