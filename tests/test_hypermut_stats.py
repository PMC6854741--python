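"""Substitution matrices, context profiles, chi-square test, hypermutant calls."""

import math

import numpy as np
import pytest
from scipy import special, stats

from threedpcr import (EditingModel, TargetSequence, chi_square_context,
                       classify_hypermutants, context_report, expected_context,
                       generate_target, mutation_matrix, observed_context,
                       reverse_complement, simulate_editing)
from threedpcr.editing_sim import CONTEXTS
from threedpcr.hypermut_stats import AnalysisError, NoEditableSitesError

from conftest import random_target, tpc_model

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _brute_expected(seq, strand):
    """Independent dinucleotide scan for expected context percentages."""
    ctxs = []
    if strand in ("plus", "both"):
        ctxs += [seq[i - 1] for i in range(1, len(seq)) if seq[i] == "C"]
    if strand in ("minus", "both"):
        rc = reverse_complement(seq)
        ctxs += [rc[i - 1] for i in range(1, len(rc)) if rc[i] == "C"]
    return {f"{n}pC": 100 * ctxs.count(n) / len(ctxs) for n in "ACGT"}


class TestMutationMatrix:
    def test_identical_clones_zero_offdiagonal(self, target_500):
        mm = mutation_matrix(target_500, [target_500.seq] * 3)
        assert mm.total_substitutions == 0
        assert mm.n_clones == 3

    def test_single_forced_substitution(self):
        target = generate_target(60, 0.5, seed=50)
        i = target.seq.index("C")
        clone = target.seq[:i] + "T" + target.seq[i + 1:]
        mm = mutation_matrix(target, [clone])
        assert mm.counts.loc["C", "T"] == 1
        assert mm.total_substitutions == 1

    def test_matches_position_scan_oracle(self):
        rng = np.random.default_rng(51)
        bases = "ACGT"
        for _ in range(50):
            target = random_target(rng, length=80)
            clones = []
            for _ in range(3):
                mol = [bases[rng.integers(4)] if rng.random() < 0.1 else b
                       for b in target.seq]
                clones.append("".join(mol))
            mm = mutation_matrix(target, clones)
            for r in bases:
                for o in bases:
                    if r == o:
                        continue
                    brute = sum(rb == r and ob == o
                                for clone in clones
                                for rb, ob in zip(target.seq, clone))
                    assert mm.counts.loc[r, o] == brute

    def test_n_positions_skipped(self):
        target = TargetSequence(id="n", seq="AN" + "ACGT" * 13)
        clone = "GG" + "ACGT" * 13
        mm = mutation_matrix(target, [clone])
        assert mm.counts.loc["A", "G"] == 1  # only the non-N mismatch counted
        assert mm.total_substitutions == 1

    def test_length_mismatch_names_clone(self, target_500):
        with pytest.raises(AnalysisError, match="clone 1"):
            mutation_matrix(target_500, [target_500.seq, target_500.seq[:-1]])


class TestExpectedContext:
    def test_single_context_sequence(self):
        target = TargetSequence(id="tc", seq="TC" * 30)
        exp = expected_context(target, strand="plus")
        assert exp == {"ApC": 0.0, "CpC": 0.0, "GpC": 0.0, "TpC": 100.0}

    def test_two_context_enumeration(self):
        target = TargetSequence(id="aacc", seq="AACC" * 15)
        exp = expected_context(target, strand="plus")
        assert exp["ApC"] == pytest.approx(50.0)
        assert exp["CpC"] == pytest.approx(50.0)

    def test_sums_to_100_and_matches_brute_force(self):
        rng = np.random.default_rng(52)
        for _ in range(50):
            target = random_target(rng, length=1000)
            for strand in ("plus", "minus", "both"):
                exp = expected_context(target, strand=strand)
                assert sum(exp.values()) == pytest.approx(100.0, abs=1e-6)
                brute = _brute_expected(target.seq, strand)
                for c in CONTEXTS:
                    assert exp[c] == pytest.approx(brute[c])

    def test_no_editable_sites_error(self):
        target = TargetSequence(id="at", seq="AT" * 30)
        with pytest.raises(NoEditableSitesError):
            expected_context(target, strand="plus")


class TestObservedContext:
    def test_plus_strand_event_reads_reference_neighbour(self):
        target = TargetSequence(id="p", seq="ATCA" + "A" * 48)
        clone = "ATTA" + "A" * 48
        assert observed_context(target, [clone]) == \
            {"ApC": 0, "CpC": 0, "GpC": 0, "TpC": 1}

    def test_minus_strand_event_reads_complemented_3prime(self):
        # G->A at position 1; context = base 3' of the G (A), complemented -> TpC
        target = TargetSequence(id="m", seq="TGAA" + "T" * 48)
        clone = "TAAA" + "T" * 48
        assert observed_context(target, [clone]) == \
            {"ApC": 0, "CpC": 0, "GpC": 0, "TpC": 1}

    def test_matches_ground_truth_edits(self):
        rng = np.random.default_rng(53)
        for _ in range(50):
            target = random_target(rng, length=200)
            ms = simulate_editing(target, tpc_model(0.6, rate=0.3), 5,
                                  seed=int(rng.integers(2**31)))
            obs = observed_context(target, ms.molecules)
            truth = {c: 0 for c in CONTEXTS}
            for edits in ms.true_edits:
                for pos, strand in edits:
                    if strand == "+":
                        truth[target.seq[pos - 1] + "pC"] += 1
                    else:
                        truth[COMP[target.seq[pos + 1]] + "pC"] += 1
            assert obs == truth
            assert sum(obs.values()) == sum(len(e) for e in ms.true_edits)


class TestChiSquareContext:
    def test_perfect_fit(self):
        obs = {c: 25 for c in CONTEXTS}
        exp = {c: 25.0 for c in CONTEXTS}
        chi2, p, _ = chi_square_context(obs, exp)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_extreme_table(self):
        obs = {"ApC": 0, "CpC": 0, "GpC": 0, "TpC": 20}
        exp = {c: 25.0 for c in CONTEXTS}
        chi2, p, flags = chi_square_context(obs, exp)
        assert chi2 == pytest.approx(60.0)   # 3*(0-5)^2/5 + (20-5)^2/5
        assert flags["df"] == 3

    def test_p_value_against_survival_function(self):
        rng = np.random.default_rng(54)
        for _ in range(100):
            obs = {c: int(rng.integers(0, 50)) for c in CONTEXTS}
            if sum(obs.values()) == 0:
                obs["TpC"] = 1
            raw = rng.dirichlet(np.ones(4))
            exp = {c: 100 * w for c, w in zip(CONTEXTS, raw)}
            chi2, p, flags = chi_square_context(obs, exp)
            total = sum(obs.values())
            stat = sum((obs[c] - total * exp[c] / 100) ** 2 / (total * exp[c] / 100)
                       for c in CONTEXTS if exp[c] > 0)
            # independent evaluation via the regularized upper incomplete gamma
            p_ref = special.gammaincc(flags["df"] / 2, stat / 2)
            assert chi2 == pytest.approx(stat, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-8)

    def test_scale_consistency(self):
        obs = {"ApC": 5, "CpC": 10, "GpC": 3, "TpC": 42}
        exp = {"ApC": 20.0, "CpC": 30.0, "GpC": 25.0, "TpC": 25.0}
        chi2_1, _, _ = chi_square_context(obs, exp)
        chi2_3, _, _ = chi_square_context({c: 3 * v for c, v in obs.items()}, exp)
        assert chi2_3 == pytest.approx(3 * chi2_1)

    def test_zero_expectation_category_dropped(self):
        obs = {"ApC": 2, "CpC": 0, "GpC": 0, "TpC": 18}
        exp = {"ApC": 0.0, "CpC": 50.0, "GpC": 0.0, "TpC": 50.0}
        chi2, p, flags = chi_square_context(obs, exp)
        assert set(flags["dropped_zero_expectation"]) == {"ApC", "GpC"}
        assert flags["df"] == 1

    def test_undefined_when_all_expected_zero(self):
        with pytest.raises(ValueError, match="undefined"):
            chi_square_context({"ApC": 1, "CpC": 0, "GpC": 0, "TpC": 0},
                               {c: 0.0 for c in CONTEXTS})


class TestContextReport:
    def test_modal_context_and_significance(self, target_500):
        ms = simulate_editing(target_500, tpc_model(0.8, rate=0.4), 20, seed=55)
        rep = context_report(target_500, ms.molecules)
        assert rep.modal_context == "TpC"
        assert rep.p_value < 0.05
        assert rep.n_events == sum(rep.observed.values())

    def test_no_events_reported_as_status(self, target_500):
        rep = context_report(target_500, [target_500.seq])
        assert rep.p_value is None
        assert rep.modal_context is None
        assert rep.flags["status"] == "no editable events"


class TestClassifyHypermutants:
    def test_unedited_clone_is_background(self, target_500):
        assert classify_hypermutants([target_500.seq], target_500) == ["background"]

    def test_heavy_editing_is_hypermutated(self):
        target = generate_target(300, 0.45, seed=56)
        c_pos = [i for i, b in enumerate(target.seq) if b == "C"][:15]
        mol = list(target.seq)
        for i in c_pos:
            mol[i] = "T"
        labels = classify_hypermutants(["".join(mol)], target,
                                       background_rate=1e-4)
        assert labels == ["hypermutated"]

    def test_matches_exact_binomial_tail_oracle(self):
        rng = np.random.default_rng(57)
        target = generate_target(200, 0.5, seed=58)
        n_sites = sum(b in "CG" for b in target.seq)
        c_pos = [i for i, b in enumerate(target.seq) if b == "C"]
        g_pos = [i for i, b in enumerate(target.seq) if b == "G"]
        p_bg = 5e-4
        for _ in range(100):
            k = int(rng.integers(0, 8))
            mol = list(target.seq)
            picks = rng.choice(len(c_pos) + len(g_pos), size=k, replace=False)
            for idx in picks:
                if idx < len(c_pos):
                    mol[c_pos[idx]] = "T"
                else:
                    mol[g_pos[idx - len(c_pos)]] = "A"
            (label,) = classify_hypermutants(["".join(mol)], target, p_bg)
            # exact tail by direct summation of the binomial pmf
            tail = 1.0 - sum(math.comb(n_sites, j) * p_bg**j
                             * (1 - p_bg) ** (n_sites - j)
                             for j in range(k))
            expect = "hypermutated" if (k >= 2 and tail < 1e-3) else "background"
            assert label == expect
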