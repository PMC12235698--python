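"""Fixed sinusoidal (Fourier) features of m/z, intensity and pairwise m/z gaps.

A scalar x is encoded at r/2 geometrically spaced wavelengths: the first half
of the feature vector is sin(x / (lambda/2pi)) and the second half is cos of
the same arguments. The wavelength ladder is lambda(p) = lambda_min *
(lambda_max/lambda_min)^(p/r) with endpoints lambda(0) = lambda_min and
lambda(r) = lambda_max; the r/2 features sample its even indices p = 0, 2,
..., r-2, so each half sweeps the full lambda_min..lambda_max range.

The source formulation prints "sin" for both halves; we treat the second
half as the conventional cosine channel. The switch ``strict_sin`` restores
the literal sin-only variant for comparison.

Pairwise features encode every m/z difference m_i - m_j of a spectrum the
same way, yielding an N x N x r tensor that is the input of the pairwise
attention bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .spectra_io import Spectrum

__all__ = [
    "FourierConfig",
    "wavelength",
    "fourier_encode",
    "embed_peaks",
    "pairwise_diff",
    "pairwise_fourier",
    "MZ_FOURIER_DEFAULT",
    "INTENSITY_FOURIER_DEFAULT",
]


@dataclass(frozen=True)
class FourierConfig:
    """Dimension and wavelength range of one Fourier encoding."""

    r: int
    lambda_min: float
    lambda_max: float
    strict_sin: bool = False  # reproduce the literal sin-in-both-halves text

    def __post_init__(self):
        if self.r < 2 or self.r % 2 != 0:
            raise ValueError("feature dimension r must be even and >= 2")
        if not 0 < self.lambda_min <= self.lambda_max:
            raise ValueError("need 0 < lambda_min <= lambda_max")


#: Default m/z encoding: 1024 features over wavelengths 0.001-10,000 Da.
MZ_FOURIER_DEFAULT = FourierConfig(r=1024, lambda_min=0.001, lambda_max=10_000.0)
#: Default intensity encoding: 256 features over wavelengths 1e-6-1.
INTENSITY_FOURIER_DEFAULT = FourierConfig(r=256, lambda_min=1e-6, lambda_max=1.0)


def wavelength(p, cfg: FourierConfig) -> np.ndarray:
    """Wavelength of ladder index p: lambda_min*(lambda_max/lambda_min)^(p/r)."""
    p = np.asarray(p, dtype=np.float64)
    return cfg.lambda_min * (cfg.lambda_max / cfg.lambda_min) ** (p / cfg.r)


def fourier_encode(x, cfg: FourierConfig) -> np.ndarray:
    """Encode scalar(s) x into r sinusoidal features.

    x may be a scalar or an array; the feature dimension of size cfg.r is
    appended as the last axis. Output entries are in [-1, 1].
    """
    x = np.asarray(x, dtype=np.float64)
    p = 2 * np.arange(cfg.r // 2)  # even ladder indices: full wavelength sweep
    divisor = wavelength(p, cfg) / (2.0 * np.pi)
    args = x[..., None] / divisor
    second = np.sin(args) if cfg.strict_sin else np.cos(args)
    return np.concatenate([np.sin(args), second], axis=-1)


def embed_peaks(spectrum: Spectrum, m_cfg: FourierConfig, intensity_cfg: FourierConfig,
                projection) -> Tensor:
    """Per-peak features: Fourier(m/z) ++ Fourier(intensity), linearly projected.

    ``projection`` is a learned linear map (r_m + r_I) -> d (an ``nn.Linear``);
    returns the N x d peak-feature matrix the encoder consumes.
    """
    feats = np.concatenate(
        [fourier_encode(spectrum.mz, m_cfg), fourier_encode(spectrum.intensity, intensity_cfg)],
        axis=-1,
    )
    if feats.shape[-1] != projection.in_features:
        raise ValueError(
            f"projection expects {projection.in_features} inputs, features have {feats.shape[-1]}"
        )
    return projection(Tensor(feats))


def pairwise_diff(mz) -> np.ndarray:
    """All pairwise m/z differences: D[i, j] = m_i - m_j (antisymmetric)."""
    mz = np.asarray(mz, dtype=np.float64)
    return mz[:, None] - mz[None, :]


def pairwise_fourier(delta: np.ndarray, cfg: FourierConfig) -> np.ndarray:
    """Fourier-encode an N x N difference matrix into N x N x r features.

    Under the index swap i<->j the sin half is odd and the cos half is even,
    mirroring the antisymmetry of the difference matrix.
    """
    return fourier_encode(np.asarray(delta, dtype=np.float64), cfg)
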