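"""Amino-acid matching, confidence scoring and precision-coverage curves."""

import numpy as np
import pytest

from pairnovo.evaluate import (
    AA_MASS_TOL,
    PREFIX_MASS_TOL,
    MatchResult,
    aa_precision,
    match_amino_acids,
    peptide_confidence,
    precision_at_coverage,
    precision_coverage_curve,
)
from pairnovo.masses import PROTON
from pairnovo.model import Prediction, peptide_mass
from pairnovo.spectra_io import Spectrum


def brute_force_max_matches(pred, true, dictionary):
    """Exhaustive monotone-pairing oracle: LCS-style DP maximizing matched
    pairs under the residue-mass and prefix-or-suffix tolerance rules."""
    pm = [dictionary.residue_mass[t] for t in pred]
    tm = [dictionary.residue_mass[t] for t in true]
    pp = np.concatenate([[0.0], np.cumsum(pm)])
    tp = np.concatenate([[0.0], np.cumsum(tm)])

    def compatible(i, j):
        if abs(pm[i] - tm[j]) >= AA_MASS_TOL:
            return False
        prefix = abs(pp[i + 1] - tp[j + 1])
        suffix = abs((pp[-1] - pp[i]) - (tp[-1] - tp[j]))
        return prefix < PREFIX_MASS_TOL or suffix < PREFIX_MASS_TOL

    n, m = len(pm), len(tm)
    table = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            table[i, j] = max(table[i - 1, j], table[i, j - 1],
                              table[i - 1, j - 1] + compatible(i - 1, j - 1))
    return int(table[n, m])


class TestMatchAminoAcids:
    def test_identical_sequences_fully_match(self, full_dictionary):
        tokens = list("PEPTIDE")
        r = match_amino_acids(tokens, tokens, full_dictionary)
        assert r == MatchResult(7, 7, 7, True)

    def test_leucine_isoleucine_isobaric_match(self, full_dictionary):
        r = match_amino_acids(list("LGK"), list("IGK"), full_dictionary)
        assert r.n_aa_matched == 3 and r.peptide_match

    def test_double_glycine_vs_asparagine(self, full_dictionary):
        """G+G sums to N's residue mass, but the per-residue 0.1 Da test
        fails at the first positions; only K matches via the suffix rule."""
        r = match_amino_acids(list("GGK"), list("NK"), full_dictionary)
        assert r.n_aa_matched == 1
        assert not r.peptide_match

    def test_matched_count_bounded_by_lengths(self, full_dictionary):
        rng = np.random.default_rng(0)
        residues = full_dictionary.residue_tokens
        for _ in range(100):
            pred = [residues[i] for i in rng.integers(0, 20, rng.integers(1, 7))]
            true = [residues[i] for i in rng.integers(0, 20, rng.integers(1, 7))]
            r = match_amino_acids(pred, true, full_dictionary)
            assert r.n_aa_matched <= min(r.n_aa_pred, r.n_aa_true)
            if r.peptide_match:
                assert r.n_aa_matched == r.n_aa_pred == r.n_aa_true

    def test_agrees_with_exhaustive_monotone_pairing_oracle(self, full_dictionary):
        rng = np.random.default_rng(1)
        residues = full_dictionary.residue_tokens
        for _ in range(500):
            pred = [residues[i] for i in rng.integers(0, 20, rng.integers(1, 7))]
            true = [residues[i] for i in rng.integers(0, 20, rng.integers(1, 7))]
            walk = match_amino_acids(pred, true, full_dictionary).n_aa_matched
            oracle = brute_force_max_matches(pred, true, full_dictionary)
            assert walk == oracle, (pred, true)

    def test_unknown_token_rejected(self, full_dictionary):
        with pytest.raises(KeyError):
            match_amino_acids(["X1"], ["G"], full_dictionary)


def _spectrum_for_mass(neutral_mass, charge=2):
    return Spectrum("s", np.array([100.0]), np.array([1.0]),
                    (neutral_mass + charge * PROTON) / charge, charge)


class TestPeptideConfidence:
    def test_mean_of_token_probs(self, dictionary):
        tokens = ["G", "A", "S"]
        pred = Prediction("s", tokens, [0.8, 0.9, 1.0],
                          peptide_mass(tokens, dictionary))
        spec = _spectrum_for_mass(pred.peptide_mass)
        assert peptide_confidence(pred, spec, dictionary) == pytest.approx(0.9)

    def test_large_mass_deviation_gives_minus_one(self, dictionary):
        tokens = ["G", "A", "S"]
        m = peptide_mass(tokens, dictionary)
        pred = Prediction("s", tokens, [0.9, 0.9, 0.9], m)
        spec = _spectrum_for_mass(m * (1 + 200e-6))  # 200 ppm off
        assert peptide_confidence(pred, spec, dictionary) == -1.0

    def test_boundary_is_strict_more_than_50_ppm(self, dictionary):
        tokens = ["G", "A", "S"]
        m = peptide_mass(tokens, dictionary)
        pred = Prediction("s", tokens, [0.9, 0.9, 0.9], m)
        just_inside = _spectrum_for_mass(m + m * 49.99e-6)
        just_outside = _spectrum_for_mass(m + m * 50.01e-6)
        assert peptide_confidence(pred, just_inside, dictionary) == pytest.approx(0.9)
        assert peptide_confidence(pred, just_outside, dictionary) == -1.0

    def test_empty_prediction_gives_minus_one(self, dictionary):
        pred = Prediction("s", [], [], 18.010565)
        assert peptide_confidence(pred, _spectrum_for_mass(500.0), dictionary) == -1.0

    def test_adjusted_reference_skips_proton_correction(self, dictionary):
        tokens = ["G", "A", "S"]
        m = peptide_mass(tokens, dictionary)
        pred = Prediction("s", tokens, [1.0, 1.0, 1.0], m)
        charge = 2
        spec = Spectrum("s", np.array([100.0]), np.array([1.0]), m / charge, charge)
        # m/z*z == m exactly: passes under 'adjusted', fails under 'neutral'
        assert peptide_confidence(pred, spec, dictionary, "adjusted") == 1.0
        assert peptide_confidence(pred, spec, dictionary, "neutral") == -1.0


def _results(flags_and_confs):
    return [(MatchResult(0, 1, 1, flag), conf) for flag, conf in flags_and_confs]


class TestPrecisionCoverage:
    def test_full_coverage_is_match_fraction(self):
        results = _results([(True, 0.9), (True, 0.5), (True, 0.3), (False, 0.1)])
        assert precision_at_coverage(results, 1.0) == 0.75

    def test_half_coverage_keeps_top_confidence(self):
        results = _results([(True, 0.9), (True, 0.8), (False, 0.2), (False, 0.1)])
        assert precision_at_coverage(results, 0.5) == 1.0

    def test_all_matches_give_one_at_every_coverage(self):
        results = _results([(True, c) for c in (0.9, 0.5, 0.2)])
        for cov in (0.34, 0.67, 1.0):
            assert precision_at_coverage(results, cov) == 1.0

    def test_full_coverage_invariant_to_confidences(self):
        rng = np.random.default_rng(2)
        flags = rng.random(50) < 0.4
        a = _results(list(zip(flags, rng.random(50))))
        b = _results(list(zip(flags, rng.random(50))))
        assert precision_at_coverage(a, 1.0) == precision_at_coverage(b, 1.0)

    def test_empty_or_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            precision_at_coverage([], 1.0)
        with pytest.raises(ValueError):
            precision_at_coverage(_results([(True, 0.5)]), 0.0)

    def test_curve_single_correct_result(self):
        curve = precision_coverage_curve(_results([(True, 0.7)]))
        assert curve.points == ((1.0, 1.0),)

    def test_curve_wrong_first_then_right(self):
        curve = precision_coverage_curve(_results([(False, 0.9), (True, 0.4)]))
        assert curve.points == ((0.5, 0.0), (1.0, 0.5))

    def test_curve_final_point_equals_direct_counting(self):
        rng = np.random.default_rng(3)
        flags = rng.random(100) < 0.3
        results = _results(list(zip(flags, rng.random(100))))
        curve = precision_coverage_curve(results)
        assert curve.points[-1][0] == 1.0
        assert curve.points[-1][1] == pytest.approx(flags.sum() / 100)

    def test_ties_broken_by_input_order(self):
        results = _results([(False, 0.5), (True, 0.5)])
        curve = precision_coverage_curve(results)
        assert curve.points[0] == (0.5, 0.0)


def test_aa_precision_pools_over_spectra():
    results = [(MatchResult(2, 3, 3, False), 0.5), (MatchResult(4, 4, 4, True), 0.9)]
    assert aa_precision(results) == pytest.approx(6 / 7)
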