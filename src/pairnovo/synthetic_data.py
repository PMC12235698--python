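"""Synthetic annotated spectra: b/y fragment ladders with controlled corruption.

The generator emulates the statistical structure a sequencing model exploits:
each spectrum is the singly protonated b- and y-ion ladder of a sampled
peptide (successive ladder peaks differ by exactly one residue mass),
degraded by peak dropout, Gaussian m/z jitter and uniform noise peaks. The
precursor is reported at charge 2.

It deliberately does *not* model fragment intensities, isotope envelopes,
other ion series or co-fragmentation; see the package methods note for what
that implies about conclusions drawn from synthetic benchmarks.

``ladder_oracle`` is an independent non-neural solver: a dynamic program
that reads the peptide straight off the b-ion ladder. It serves as a
round-trip check on the generator and as a reference solver in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masses import PROTON, WATER
from .spectra_io import Spectrum, TokenDictionary, build_token_dictionary
from .spectra_io import _token_mass

__all__ = [
    "SimConfig",
    "default_dictionary",
    "sample_peptide",
    "theoretical_spectrum",
    "corrupt_spectrum",
    "generate_dataset",
    "ladder_oracle",
]

#: Ten residues whose masses are pairwise distinct by well over typical jitter.
DEFAULT_ALPHABET = ("G", "A", "S", "P", "V", "T", "L", "N", "D", "K")


@dataclass
class SimConfig:
    """Generator settings.

    Defaults define the package's standard desk-scale task: 10-residue
    unambiguous alphabet, peptide lengths 5-8, 10% peak dropout, 0.001 Da
    m/z jitter and 5 uniform noise peaks in 50-1500 m/z.
    """

    alphabet: tuple = DEFAULT_ALPHABET
    length_range: tuple = (5, 8)
    peak_dropout: float = 0.1
    mz_jitter_sd: float = 0.001
    n_noise_peaks: int = 5
    mz_range: tuple = (50.0, 1500.0)
    seed: int = 0
    unambiguous: bool = True  # require residue masses separated beyond jitter

    def __post_init__(self):
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")
        if not 0 <= self.peak_dropout < 1:
            raise ValueError("peak_dropout must be in [0, 1)")
        if self.mz_jitter_sd < 0:
            raise ValueError("mz_jitter_sd must be >= 0")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= lo <= hi")
        if self.unambiguous:
            masses = sorted(_token_mass(t) for t in self.alphabet)
            gap = min((b - a for a, b in zip(masses, masses[1:])), default=np.inf)
            if gap <= 3 * self.mz_jitter_sd:
                raise ValueError(
                    f"alphabet residue masses must be pairwise distinct by more "
                    f"than 3x the m/z jitter ({3 * self.mz_jitter_sd:.4g} Da); "
                    f"closest pair differs by {gap:.4g} Da")


def default_dictionary(cfg: SimConfig | None = None) -> TokenDictionary:
    """Token dictionary over the simulation alphabet."""
    alphabet = DEFAULT_ALPHABET if cfg is None else cfg.alphabet
    return build_token_dictionary([[t] for t in alphabet])


def sample_peptide(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    """I.i.d. residues; length uniform over the configured range."""
    lo, hi = cfg.length_range
    length = int(rng.integers(lo, hi + 1))
    return [cfg.alphabet[i] for i in rng.integers(0, len(cfg.alphabet), size=length)]


def theoretical_spectrum(peptide: list[str], dictionary: TokenDictionary,
                         spectrum_id: str = "synthetic") -> Spectrum:
    """Noise-free singly charged b/y ladder of a peptide.

    b_k = prefix_k + m_p, y_k = suffix_k + water + m_p for every cleavage
    site k = 1..L-1 (2(L-1) peaks, unit intensities); the precursor is
    reported at charge 2: (peptide mass + 2 m_p) / 2.
    """
    if len(peptide) < 2:
        raise ValueError("need at least 2 residues to fragment")
    masses = np.array([dictionary.residue_mass[t] for t in peptide])
    prefix = np.cumsum(masses)[:-1]
    total = masses.sum()
    b_ions = prefix + PROTON
    y_ions = (total - prefix) + WATER + PROTON
    mz = np.sort(np.concatenate([b_ions, y_ions]))
    return Spectrum(
        spectrum_id=spectrum_id,
        mz=mz,
        intensity=np.ones_like(mz),
        precursor_mz=(total + WATER + 2 * PROTON) / 2,
        charge=2,
        annotation=list(peptide),
    )


def corrupt_spectrum(spectrum: Spectrum, cfg: SimConfig,
                     rng: np.random.Generator) -> Spectrum:
    """Apply dropout, m/z jitter and uniform noise peaks; keep the annotation."""
    keep = rng.random(spectrum.n_peaks) >= cfg.peak_dropout
    mz = spectrum.mz[keep]
    intensity = spectrum.intensity[keep]
    if cfg.mz_jitter_sd > 0:
        mz = mz + rng.normal(0.0, cfg.mz_jitter_sd, size=mz.shape)
    if cfg.n_noise_peaks > 0:
        lo, hi = cfg.mz_range
        noise_mz = rng.uniform(lo, hi, size=cfg.n_noise_peaks)
        noise_intensity = rng.uniform(0.05, 1.0, size=cfg.n_noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        intensity = np.concatenate([intensity, noise_intensity])
    order = np.argsort(mz)
    return Spectrum(
        spectrum_id=spectrum.spectrum_id,
        mz=mz[order],
        intensity=intensity[order],
        precursor_mz=spectrum.precursor_mz,
        charge=spectrum.charge,
        annotation=spectrum.annotation,
    )


def generate_dataset(n: int, cfg: SimConfig,
                     dictionary: TokenDictionary | None = None) -> list[Spectrum]:
    """n corrupted annotated spectra; bit-reproducible for a fixed cfg.seed."""
    if dictionary is None:
        dictionary = default_dictionary(cfg)
    rng = np.random.default_rng(cfg.seed)
    spectra = []
    for i in range(n):
        peptide = sample_peptide(cfg, rng)
        spec = theoretical_spectrum(peptide, dictionary, spectrum_id=f"synthetic-{i}")
        spectra.append(corrupt_spectrum(spec, cfg, rng))
    return spectra


def ladder_oracle(spectrum: Spectrum, dictionary: TokenDictionary,
                  tolerance: float = 0.01) -> list[str] | None:
    """Read the peptide off the b-ion ladder by dynamic programming.

    Nodes are a virtual start at m/z = m_p, every observed peak, and a
    virtual end at total residue mass + m_p (total derived from the charge-2
    precursor). Edges connect nodes whose m/z gap matches a residue mass
    within ``tolerance``. Among all start-to-end paths, only those of
    maximal length (explaining the most peaks) are considered — residue-sum
    coincidences such as G+G vs N otherwise make every peptide containing
    the pair ambiguous via a peak-skipping shortcut. Returns the peptide
    Candidate readings are the maximal-length paths (those explaining the
    most peaks); interleaved y-ion peaks can still offer alternative
    readings of equal length (a b-gap L+P split as P then L through a y
    peak), so candidates are rescored by how many observed peaks their
    *full* theoretical b/y spectrum explains within tolerance. Returns the
    peptide when the best-explaining reading is unique, else None
    (ambiguity and failure are both None).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    total = spectrum.precursor_mz * spectrum.charge - 2 * PROTON - WATER
    nodes = np.concatenate([[PROTON], np.sort(spectrum.mz), [total + PROTON]])
    n = nodes.size
    residues = list(dictionary.residue_mass.items())
    heaviest = max(m for _, m in residues)

    # per node: path length -> distinct token sequences (capped: distinct
    # prefixes stay distinct downstream, so the cap cannot merge readings)
    cap = 16
    table: list[dict[int, set]] = [dict() for _ in range(n)]
    table[0][0] = {()}
    for j in range(1, n):
        for i in range(j):
            if not table[i]:
                continue
            gap = nodes[j] - nodes[i]
            if gap > heaviest + tolerance:
                continue
            for token, mass in residues:
                if abs(gap - mass) < tolerance:
                    for length, prefixes in table[i].items():
                        entry = table[j].setdefault(length + 1, set())
                        for p in prefixes:
                            if len(entry) < cap:
                                entry.add(p + (token,))
    if not table[-1]:
        return None
    readings = sorted(table[-1][max(table[-1])])
    if len(readings) == 1:
        return list(readings[0])

    def explained(reading: tuple) -> int:
        masses = np.array([dictionary.residue_mass[t] for t in reading])
        prefix = np.cumsum(masses)[:-1]
        theory = np.concatenate([prefix + PROTON,
                                 (masses.sum() - prefix) + WATER + PROTON])
        return int(sum(np.abs(theory - mz).min() < tolerance for mz in spectrum.mz))

    scores = [explained(r) for r in readings]
    best = max(scores)
    winners = [r for r, s in zip(readings, scores) if s == best]
    return list(winners[0]) if len(winners) == 1 else None
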