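"""Hypermutation analysis of clone sets against a reference amplicon.

Given sequenced clones of a 3DPCR band, this module computes the 4x4
substitution matrix, the 5' dinucleotide context profile of edited
cytidines, the composition-based expected context percentages

    %NpC = 100 * (# NpC dinucleotides) / (# eligible Cs),

a chi-square goodness-of-fit test of observed against expected context, and
a per-clone hypermutant call.

Strand convention: a C->T substitution is a plus-strand deamination whose
context is the reference base 5' of the C; a G->A substitution is a
minus-strand deamination whose context is read on the complementary strand,
i.e. the reference base 3' of the G, complemented.  This is the standard
APOBEC reporting convention and makes plus- and minus-strand events
poolable.  Clones must match the reference length: 3DPCR amplicons are
fixed-length and only substitutions are modelled, so no alignment is
attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .editing_sim import CONTEXTS
from .target_io import TargetSequence

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class AnalysisError(ValueError):
    """Raised for malformed analysis input (e.g. clone/reference length mismatch)."""


class NoEditableSitesError(ValueError):
    """Raised when a reference has no context-eligible cytidine."""


@dataclass
class MutationMatrix:
    """4x4 reference-base x observed-base substitution counts over a clone set."""

    counts: pd.DataFrame
    n_clones: int
    n_positions: int

    @property
    def total_substitutions(self) -> int:
        off = self.counts.values.copy()
        np.fill_diagonal(off, 0)
        return int(off.sum())

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")

    def to_dict(self) -> dict:
        return {"counts": {r: {o: int(self.counts.loc[r, o]) for o in BASES}
                           for r in BASES},
                "n_clones": self.n_clones,
                "n_positions": self.n_positions,
                "total_substitutions": self.total_substitutions}


@dataclass
class ContextReport:
    """Observed vs expected 5'NpC context of edited cytidines.

    ``observed`` holds event counts per context; ``expected_pct`` the
    composition-based percentages; ``chi2``/``p_value`` the goodness-of-fit
    test; ``modal_context`` the context with the largest observed count
    (None when there are no events).  ``flags`` records categories dropped
    for zero expectation and any expected count below 5 (validity warning).
    """

    observed: dict[str, int]
    expected_pct: dict[str, float]
    chi2: float | None
    p_value: float | None
    modal_context: str | None
    n_events: int
    n_dropped: int = 0
    flags: dict = field(default_factory=dict)

    @property
    def observed_pct(self) -> dict[str, float]:
        total = sum(self.observed.values())
        if total == 0:
            return {c: 0.0 for c in CONTEXTS}
        return {c: 100.0 * self.observed[c] / total for c in CONTEXTS}

    def to_dict(self) -> dict:
        return {"observed": self.observed,
                "observed_pct": self.observed_pct,
                "expected_pct": self.expected_pct,
                "chi2": self.chi2, "p_value": self.p_value,
                "modal_context": self.modal_context,
                "n_events": self.n_events, "n_dropped": self.n_dropped,
                "flags": self.flags}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _check_lengths(reference: TargetSequence, clones: list[str]) -> None:
    for i, clone in enumerate(clones):
        if len(clone) != len(reference):
            raise AnalysisError(
                f"clone {i} has length {len(clone)} != reference "
                f"{len(reference)} ({reference.id}); indels are not modelled")


def mutation_matrix(reference: TargetSequence,
                    clones: list[str]) -> MutationMatrix:
    """Count substitutions per (reference base, observed base) pair.

    Positions where either the reference or the clone carries N are skipped.
    """
    _check_lengths(reference, clones)
    counts = pd.DataFrame(0, index=list(BASES), columns=list(BASES), dtype=int)
    ref = reference.seq
    for clone in clones:
        for r, o in zip(ref, clone):
            if r == "N" or o == "N":
                continue
            if r != o:
                counts.loc[r, o] += 1
    return MutationMatrix(counts=counts, n_clones=len(clones),
                          n_positions=len(reference))


def _eligible_plus_contexts(seq: str) -> list[str]:
    """5' contexts of plus-strand eligible Cs (C with unambiguous 5' base)."""
    return [seq[i - 1] + "pC" for i in range(1, len(seq))
            if seq[i] == "C" and seq[i - 1] in "ACGT"]


def _eligible_minus_contexts(seq: str) -> list[str]:
    """Contexts of minus-strand eligible Cs (reference Gs), read on the
    complementary strand: the base 3' of the G, complemented."""
    return [_COMP[seq[i + 1]] + "pC" for i in range(len(seq) - 1)
            if seq[i] == "G" and seq[i + 1] in "ACGT"]


def expected_context(reference: TargetSequence,
                     strand: str = "both") -> dict[str, float]:
    """Composition-based expected context percentages, assuming no bias.

    For each N in {A,C,G,T}: 100 * (# NpC) / (# eligible Cs), pooled over the
    requested strand(s).  Minus-strand Cs are reference Gs with context read
    5'->3' on the reverse complement.
    """
    if strand not in ("plus", "minus", "both"):
        raise ValueError(f"strand must be plus/minus/both, got {strand!r}")
    contexts: list[str] = []
    if strand in ("plus", "both"):
        contexts += _eligible_plus_contexts(reference.seq)
    if strand in ("minus", "both"):
        contexts += _eligible_minus_contexts(reference.seq)
    if not contexts:
        raise NoEditableSitesError(
            f"{reference.id}: no editable sites on strand {strand!r}")
    total = len(contexts)
    return {c: 100.0 * contexts.count(c) / total for c in CONTEXTS}


def observed_context(reference: TargetSequence,
                     clones: list[str]) -> dict[str, int]:
    """Count edited-C events per 5' context, pooled over both strands.

    An edited site is a reference C read as T (plus-strand event, context =
    reference 5' neighbour) or a reference G read as A (minus-strand event,
    context = reference 3' neighbour, complemented).  Events without a
    defined unambiguous context are dropped with a logged count; all other
    substitution classes are ignored here (they are background, captured by
    the mutation matrix).
    """
    _check_lengths(reference, clones)
    ref = reference.seq
    counts = {c: 0 for c in CONTEXTS}
    dropped = 0
    for clone in clones:
        for i, (r, o) in enumerate(zip(ref, clone)):
            if r == "C" and o == "T":
                if i > 0 and ref[i - 1] in "ACGT":
                    counts[ref[i - 1] + "pC"] += 1
                else:
                    dropped += 1
            elif r == "G" and o == "A":
                if i < len(ref) - 1 and ref[i + 1] in "ACGT":
                    counts[_COMP[ref[i + 1]] + "pC"] += 1
                else:
                    dropped += 1
    if dropped:
        logger.info("%d edited-C events dropped for undefined 5' context", dropped)
    return counts


def chi_square_context(observed: dict[str, int],
                       expected_pct: dict[str, float]
                       ) -> tuple[float, float, dict]:
    """Goodness-of-fit of observed context counts against expected percentages.

    The classical statistic sum((O_i - E_i)^2 / E_i) with
    E_i = total_observed * expected_pct_i / 100, evaluated over categories
    with E_i > 0; degrees of freedom = retained categories - 1.  Returns
    ``(chi2, p_value, flags)`` where flags records dropped zero-expectation
    categories and expected counts below 5 (chi-square validity warning).
    """
    total = sum(observed.values())
    if total < 1:
        raise ValueError("chi-square test requires at least one observed event")
    if all(expected_pct.get(c, 0.0) == 0.0 for c in CONTEXTS):
        raise ValueError("all expected percentages are zero: test undefined")
    retained = [c for c in CONTEXTS if expected_pct.get(c, 0.0) > 0.0]
    dropped = [c for c in CONTEXTS if c not in retained]
    obs = np.array([observed.get(c, 0) for c in retained], dtype=float)
    exp = np.array([total * expected_pct[c] / 100.0 for c in retained])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(retained) - 1
    if df == 0:
        p_value = 1.0
    else:
        p_value = float(stats.chi2.sf(chi2, df))
    flags = {
        "dropped_zero_expectation": dropped,
        "low_expected": [c for c, e in zip(retained, exp) if e < 5],
        "df": df,
    }
    return chi2, p_value, flags


def context_report(reference: TargetSequence, clones: list[str],
                   strand: str = "both") -> ContextReport:
    """Full observed-vs-expected context analysis of a clone set."""
    expected = expected_context(reference, strand=strand)
    observed = observed_context(reference, clones)
    n_events = sum(observed.values())
    if n_events == 0:
        return ContextReport(observed=observed, expected_pct=expected,
                             chi2=None, p_value=None, modal_context=None,
                             n_events=0, flags={"status": "no editable events"})
    chi2, p, flags = chi_square_context(observed, expected)
    modal = max(CONTEXTS, key=lambda c: observed[c])
    return ContextReport(observed=observed, expected_pct=expected,
                         chi2=chi2, p_value=p, modal_context=modal,
                         n_events=n_events, flags=flags)


def classify_hypermutants(clones: list[str], reference: TargetSequence,
                          background_rate: float = 1e-4) -> list[str]:
    """Label each clone ``hypermutated`` or ``background``.

    A clone is hypermutated iff its pooled C->T plus G->A count k satisfies
    the one-sided binomial tail P(X >= k | n = reference C/G sites,
    p = background_rate) < 0.001 and k >= 2.  Deterministic.
    """
    if not 0.0 <= background_rate < 1.0:
        raise ValueError("background_rate must lie in [0, 1)")
    _check_lengths(reference, clones)
    ref = reference.seq
    n_sites = sum(b in "CG" for b in ref)
    labels = []
    for clone in clones:
        k = sum((r == "C" and o == "T") or (r == "G" and o == "A")
                for r, o in zip(ref, clone))
        tail = float(stats.binom.sf(k - 1, n_sites, background_rate))
        labels.append("hypermutated" if (k >= 2 and tail < 1e-3)
                      else "background")
    return labels


def plot_context(report: ContextReport, path: str | Path,
                 title: str = "Deamination dinucleotide context") -> None:
    """Bar plot of observed vs expected context percentages."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(CONTEXTS))
    obs = [report.observed_pct[c] for c in CONTEXTS]
    exp = [report.expected_pct[c] for c in CONTEXTS]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(x - 0.2, obs, width=0.4, color="0.2", label="observed")
    ax.bar(x + 0.2, exp, width=0.4, color="white", edgecolor="0.2",
           label="expected")
    ax.set_xticks(x)
    ax.set_xticklabels([c.replace("p", "") for c in CONTEXTS])
    ax.set_ylabel("% of edited Cs")
    label = title
    if report.p_value is not None and report.p_value < 0.05:
        label += " (*)"
    ax.set_title(label)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
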