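"""Spectrum records, MGF input/output, preprocessing and the token dictionary.

An MS2 spectrum is a list of (m/z, intensity) peaks with a precursor m/z and
charge. Annotated spectra additionally carry the ground-truth peptide as a
token sequence, one token per residue with an optional bracketed mass
modification, e.g. ``M[+15.995]``.

Community MGF files are inconsistent about what PEPMASS holds, so the
precursor mass used downstream is always re-derived as precursor m/z x charge
(without subtracting the proton masses of the charge state; see
:func:`adjust_precursor_mass`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from pyteomics import mgf as _mgf

from .masses import MONOISOTOPIC

__all__ = [
    "Spectrum",
    "TokenDictionary",
    "MGFParseError",
    "read_mgf",
    "write_mgf",
    "adjust_precursor_mass",
    "preprocess",
    "parse_modified_sequence",
    "format_sequence",
    "build_token_dictionary",
]

PAD, SOS, EOS = "<pad>", "<sos>", "<eos>"

_TOKEN_RE = re.compile(r"([A-Z])(\[([+-]?\d+(?:\.\d+)?)\])?")
_MOD_RE = re.compile(r"^([A-Z])\[([+-]\d+(?:\.\d+)?)\]$")


class MGFParseError(ValueError):
    """Raised for malformed MGF blocks; the message names the block index."""


@dataclass
class Spectrum:
    """One MS2 scan.

    mz / intensity are parallel float arrays; ``adjusted_precursor_mass`` is
    precursor m/z x charge. ``annotation`` is the ground-truth peptide as a
    token list, or None for unannotated spectra.
    """

    spectrum_id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    charge: int
    annotation: list[str] | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")

    @property
    def n_peaks(self) -> int:
        return self.mz.size

    @property
    def adjusted_precursor_mass(self) -> float:
        return adjust_precursor_mass(self.precursor_mz, self.charge)


def adjust_precursor_mass(precursor_mz: float, charge: int) -> float:
    """Precursor m/z multiplied by charge.

    This is the PEPMASS harmonisation applied to the input files: the product
    m/z x z, deliberately *not* corrected by charge x proton mass, so it is a
    consistent model input rather than a chemically neutral mass.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if precursor_mz <= 0:
        raise ValueError(f"precursor m/z must be positive, got {precursor_mz}")
    return precursor_mz * charge


def parse_modified_sequence(seq: str) -> list[str]:
    """Split a peptide string into residue tokens.

    Grammar: one-letter residue, optionally followed by a bracketed signed
    mass delta, e.g. ``"AM[+15.995]K"`` -> ``["A", "M[+15.995]", "K"]``.
    Deltas are normalized to carry an explicit sign.
    """
    tokens: list[str] = []
    pos = 0
    for m in _TOKEN_RE.finditer(seq):
        if m.start() != pos:
            raise ValueError(f"cannot parse sequence {seq!r} at position {pos}")
        residue, _, delta = m.groups()
        if delta is not None:
            if not delta.startswith(("+", "-")):
                delta = "+" + delta
            tokens.append(f"{residue}[{delta}]")
        else:
            tokens.append(residue)
        pos = m.end()
    if pos != len(seq) or not tokens:
        raise ValueError(f"cannot parse sequence {seq!r} at position {pos}")
    return tokens


def format_sequence(tokens: list[str]) -> str:
    return "".join(tokens)


def _token_mass(token: str) -> float:
    m = _MOD_RE.match(token)
    if m:
        base, delta = m.group(1), float(m.group(2))
    else:
        base, delta = token, 0.0
    if base not in MONOISOTOPIC:
        raise KeyError(f"no canonical monoisotopic mass for token {token!r}")
    return MONOISOTOPIC[base] + delta


@dataclass
class TokenDictionary:
    """Bijection between residue/modification tokens and indices.

    Indices 0..2 are the specials PAD, SOS, EOS; residue tokens follow in
    sorted order. Every residue token carries a monoisotopic residue mass.
    """

    tokens: list[str]
    index_of: dict[str, int] = field(init=False)
    residue_mass: dict[str, float] = field(init=False)

    def __post_init__(self):
        specials = [PAD, SOS, EOS]
        if self.tokens[:3] != specials:
            self.tokens = specials + [t for t in self.tokens if t not in specials]
        self.index_of = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index_of) != len(self.tokens):
            raise ValueError("duplicate tokens")
        self.residue_mass = {t: _token_mass(t) for t in self.tokens[3:]}

    @property
    def pad_index(self) -> int:
        return self.index_of[PAD]

    @property
    def sos_index(self) -> int:
        return self.index_of[SOS]

    @property
    def eos_index(self) -> int:
        return self.index_of[EOS]

    @property
    def residue_tokens(self) -> list[str]:
        return self.tokens[3:]

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, tokens: list[str]) -> list[int]:
        return [self.index_of[t] for t in tokens]

    def decode(self, indices) -> list[str]:
        return [self.tokens[int(i)] for i in indices]

    def mass_of(self, tokens: list[str]) -> float:
        """Total residue mass (no water) of a token sequence."""
        return float(sum(self.residue_mass[t] for t in tokens))


def build_token_dictionary(annotations: list[list[str]]) -> TokenDictionary:
    """Enumerate the residue tokens observed in annotated sequences."""
    if not annotations:
        raise ValueError("cannot build a token dictionary from zero annotations")
    observed = sorted({t for seq in annotations for t in seq})
    bad = [t for t in observed if _MOD_RE.match(t) is None and t not in MONOISOTOPIC]
    bad += [t for t in observed if _MOD_RE.match(t) and _MOD_RE.match(t).group(1) not in MONOISOTOPIC]
    if bad:
        raise KeyError(f"tokens without a canonical residue mass: {sorted(set(bad))}")
    return TokenDictionary([PAD, SOS, EOS] + observed)


# -- MGF ----------------------------------------------------------------------


def read_mgf(path) -> list[Spectrum]:
    """Read an annotated MGF file into Spectrum records.

    Each BEGIN IONS block must carry PEPMASS and CHARGE; an optional SEQ line
    holds the ground-truth modified peptide. Peaks are kept in file order.
    """
    path = str(path)
    with open(path) as fh:
        text = fh.read()
    if text.count("BEGIN IONS") != text.count("END IONS"):
        raise MGFParseError(
            f"block {text.count('END IONS')}: BEGIN IONS without matching END IONS"
        )

    spectra: list[Spectrum] = []
    with _mgf.MGF(path, convert_arrays=1) as reader:
        index = 0
        while True:
            try:
                entry = next(reader)
            except StopIteration:
                break
            except Exception as exc:  # pyteomics raises on non-numeric peak lines
                raise MGFParseError(f"block {index}: {exc}") from exc
            params = entry["params"]
            try:
                precursor_mz = float(params["pepmass"][0])
                charge = int(params["charge"][0])
            except KeyError as exc:
                raise MGFParseError(f"block {index}: missing {exc} line") from exc
            annotation = None
            if "seq" in params:
                annotation = parse_modified_sequence(str(params["seq"]))
            spectra.append(
                Spectrum(
                    spectrum_id=str(params.get("title", f"index={index}")),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    precursor_mz=precursor_mz,
                    charge=charge,
                    annotation=annotation,
                )
            )
            index += 1
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    """Write spectra as MGF; annotated spectra get a SEQ line."""
    if not spectra:
        raise ValueError("refusing to write an empty MGF file")
    entries = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": s.precursor_mz,
            "charge": s.charge,
        }
        if s.annotation is not None:
            params["seq"] = format_sequence(s.annotation)
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    with open(str(path), "w") as fh:
        _mgf.write(entries, fh)


# -- preprocessing ------------------------------------------------------------


def preprocess(spectrum: Spectrum, top_peaks: int = 150) -> Spectrum:
    """Keep the top-N most intense peaks, base-peak-normalize, sort by m/z.

    After preprocessing the base peak has intensity exactly 1, at most
    ``top_peaks`` peaks remain, and peaks are in ascending m/z order (the
    encoder is permutation-equivariant, so the order is purely cosmetic).
    Idempotent.
    """
    if spectrum.n_peaks == 0:
        raise ValueError("cannot preprocess a spectrum with no peaks")
    if np.all(spectrum.intensity == 0):
        raise ValueError("degenerate spectrum: all intensities are zero")
    if spectrum.n_peaks > top_peaks:
        keep = np.argsort(spectrum.intensity, kind="stable")[::-1][:top_peaks]
        keep.sort()
    else:
        keep = np.arange(spectrum.n_peaks)
    mz = spectrum.mz[keep]
    intensity = spectrum.intensity[keep]
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    intensity = intensity / intensity.max()
    return replace(spectrum, mz=mz, intensity=intensity)
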