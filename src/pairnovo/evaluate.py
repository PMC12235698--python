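"""Evaluation: amino-acid matching, confidence scoring, precision-coverage.

Amino-acid matching follows the DeepNovo convention: predicted and true
residues are aligned by a two-pointer walk over cumulative prefix masses, and
an aligned residue pair counts as matched when the residue masses differ by
less than 0.1 Da and either the prefix or the suffix masses differ by less
than 0.5 Da. A peptide is matched when every residue of both sequences
matches.

Peptide confidence is the mean softmax probability of the emitted residues;
it is overridden to -1 when the predicted peptide mass deviates from the
spectrum's precursor mass by more than 50 ppm. By default the precursor
reference is the proton-corrected neutral mass (m/z x z - z x m_p); the
model-input convention (plain m/z x z) is available via ``ppm_reference``.

Precision at coverage c ranks predictions by confidence (stable, descending),
keeps the top ceil(c*N), and reports the fraction of kept predictions whose
peptide matched. At c = 1 the denominator is all spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .masses import PROTON
from .model import Prediction, peptide_mass
from .spectra_io import Spectrum, TokenDictionary

__all__ = [
    "MatchResult",
    "match_amino_acids",
    "peptide_confidence",
    "score_predictions",
    "PrecisionCoverageCurve",
    "precision_at_coverage",
    "precision_coverage_curve",
    "aa_precision",
]

AA_MASS_TOL = 0.1  # Da, residue-mass agreement
PREFIX_MASS_TOL = 0.5  # Da, prefix-or-suffix agreement
PPM_LIMIT = 50.0


@dataclass(frozen=True)
class MatchResult:
    n_aa_matched: int
    n_aa_pred: int
    n_aa_true: int
    peptide_match: bool


def match_amino_acids(pred: list[str], true: list[str],
                      dictionary: TokenDictionary) -> MatchResult:
    """DeepNovo-style residue matching via two-pointer mass walks.

    A forward pass walks cumulative *prefix* masses: when the prefix masses
    agree within 0.5 Da the pointer pair advances in lockstep and counts a
    match if the residue masses also agree within 0.1 Da; otherwise the
    pointer with the smaller prefix advances. A backward pass then walks
    cumulative *suffix* masses the same way from the C-terminal ends down to
    the last forward-matched pair, realizing the prefix-OR-suffix rule.
    This agrees with the exhaustive monotone-pairing optimum except for rare
    configurations where prefix- and suffix-consistent pairs interleave.
    """
    pm = [dictionary.residue_mass[t] for t in pred]
    tm = [dictionary.residue_mass[t] for t in true]
    pred_prefix = np.concatenate([[0.0], np.cumsum(pm)])
    true_prefix = np.concatenate([[0.0], np.cumsum(tm)])

    matched = 0
    i = j = 0
    last_i = last_j = -1
    while i < len(pm) and j < len(tm):
        if abs(pred_prefix[i + 1] - true_prefix[j + 1]) < PREFIX_MASS_TOL:
            if abs(pm[i] - tm[j]) < AA_MASS_TOL:
                matched += 1
                last_i, last_j = i, j
            i += 1
            j += 1
        elif pred_prefix[i + 1] < true_prefix[j + 1]:
            i += 1
        else:
            j += 1

    pred_suffix = pred_prefix[-1] - pred_prefix  # mass of pred[a:]
    true_suffix = true_prefix[-1] - true_prefix
    a, b = len(pm) - 1, len(tm) - 1
    while a > last_i and b > last_j:
        if abs(pred_suffix[a] - true_suffix[b]) < PREFIX_MASS_TOL:
            if abs(pm[a] - tm[b]) < AA_MASS_TOL:
                matched += 1
            a -= 1
            b -= 1
        elif pred_suffix[a] < true_suffix[b]:
            a -= 1  # lighter suffix: move outward to grow it
        else:
            b -= 1

    peptide_match = matched == len(pm) == len(tm)
    return MatchResult(matched, len(pm), len(tm), peptide_match)


def peptide_confidence(prediction: Prediction, spectrum: Spectrum,
                       dictionary: TokenDictionary,
                       ppm_reference: str = "neutral") -> float:
    """Mean residue probability, or -1 if the precursor ppm filter fires.

    ppm_reference 'neutral' compares the predicted neutral peptide mass with
    m/z x z - z x m_p; 'adjusted' compares the water-and-proton-uncorrected
    model input mass m/z x z instead.
    """
    if ppm_reference not in ("neutral", "adjusted"):
        raise ValueError("ppm_reference must be 'neutral' or 'adjusted'")
    if not prediction.tokens:
        return -1.0
    pred_mass = peptide_mass(prediction.tokens, dictionary)
    observed = spectrum.precursor_mz * spectrum.charge
    if ppm_reference == "neutral":
        observed -= spectrum.charge * PROTON
    ppm = abs(observed - pred_mass) / pred_mass * 1e6
    if ppm > PPM_LIMIT:
        return -1.0
    return float(np.mean(prediction.token_probs))


def score_predictions(predictions: list[Prediction], spectra: list[Spectrum],
                      dictionary: TokenDictionary,
                      ppm_reference: str = "neutral") -> list[tuple[MatchResult, float]]:
    """Match each prediction against its spectrum's annotation and score it."""
    results = []
    for pred, spec in zip(predictions, spectra):
        if spec.annotation is None:
            raise ValueError(f"spectrum {spec.spectrum_id} has no ground truth")
        conf = peptide_confidence(pred, spec, dictionary, ppm_reference)
        pred.confidence = conf
        results.append((match_amino_acids(pred.tokens, spec.annotation, dictionary), conf))
    return results


def _sorted_by_confidence(results):
    order = np.argsort([-conf for _, conf in results], kind="stable")
    return [results[i] for i in order]


def precision_at_coverage(results: list[tuple[MatchResult, float]],
                          coverage: float) -> float:
    """Peptide precision among the top confidence-ranked coverage fraction."""
    if not results:
        raise ValueError("no results to evaluate")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    ranked = _sorted_by_confidence(results)
    kept = ranked[: int(np.ceil(coverage * len(ranked)))]
    return sum(m.peptide_match for m, _ in kept) / len(kept)


@dataclass(frozen=True)
class PrecisionCoverageCurve:
    """(coverage, precision) points, one per prefix of the confidence ranking."""

    points: tuple

    @property
    def coverages(self):
        return np.array([c for c, _ in self.points])

    @property
    def precisions(self):
        return np.array([p for _, p in self.points])


def precision_coverage_curve(results) -> PrecisionCoverageCurve:
    if not results:
        raise ValueError("no results to evaluate")
    ranked = _sorted_by_confidence(results)
    n = len(ranked)
    hits = np.cumsum([m.peptide_match for m, _ in ranked])
    points = tuple(((k + 1) / n, float(hits[k]) / (k + 1)) for k in range(n))
    return PrecisionCoverageCurve(points)


def aa_precision(results: list[tuple[MatchResult, float]]) -> float:
    """Matched residues over predicted residues, pooled over all spectra."""
    pred_total = sum(m.n_aa_pred for m, _ in results)
    if pred_total == 0:
        return 0.0
    return sum(m.n_aa_matched for m, _ in results) / pred_total
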