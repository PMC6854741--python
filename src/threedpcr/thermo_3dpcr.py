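"""Differential DNA denaturation PCR (3DPCR) model.

3DPCR exploits the fact that deaminated DNA is AT-enriched: GC pairs hold
three hydrogen bonds, AT pairs two, so edited templates denature at lower
temperatures.  Running PCR across a gradient of denaturation temperatures
(Td) therefore amplifies mutated DNA selectively below the *restrictive*
temperature -- the lowest Td at which the unedited reference still amplifies.
The lowest Td yielding product ("last retrieved band") indicates how heavily
edited the most AT-enriched templates are.

The melting temperature is modelled as a calibrated linear proxy:

    Tm(molecule) = restrictive_td - delta_per_sub * (# GC->AT substitutions)

rather than nearest-neighbour thermodynamics, because wet-lab Td values are
amplicon- and buffer-specific; only the anchor plus a per-substitution
decrement transfers between settings.  Amplification is all-or-none: a
molecule is a template at Td iff Td >= Tm - epsilon, which captures the
threshold selectivity (reported up to 10^4-fold) that dominates 3DPCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .editing_sim import MoleculeSet
from .target_io import TargetSequence


class NoTemplatesError(ValueError):
    """Raised when a 3DPCR simulation is given an empty population."""


class NoBandError(ValueError):
    """Raised when sampling a temperature that yielded no band."""


@dataclass(frozen=True)
class TmModel:
    """Linear GC-count melting-temperature proxy.

    Parameters
    ----------
    restrictive_td
        Temperature (degC) assigned to the unedited reference: the lowest
        denaturation temperature at which it amplifies.  Default 85.7 degC,
        a typical restrictive Td for a moderate-GC ~500-bp amplicon.
    delta_per_sub
        Tm decrement (degC) per GC->AT substitution.  Default 0.04 degC,
        roughly 1 degC per 1% composition change on a 500-bp amplicon.
    epsilon
        Amplification tolerance (degC): a molecule amplifies at Td iff
        Td >= Tm - epsilon.  Default 0.
    """

    restrictive_td: float = 85.7
    delta_per_sub: float = 0.04
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_per_sub <= 0:
            raise ValueError("delta_per_sub must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class GradientResult:
    """Recovery status across a denaturation-temperature gradient.

    ``positive`` maps each gradient Td to the number of amplifiable
    molecules; ``recovered_ids`` to their identifiers.  ``last_positive_td``
    is the lowest Td with at least ``min_templates`` amplifiable molecules
    (the last retrieved band), or None if no Td yields a band.
    """

    gradient: list[float]
    positive: dict[float, int]
    recovered_ids: dict[float, list[str]]
    last_positive_td: float | None
    min_templates: int
    restrictive_td: float

    def to_table(self):
        """Per-Td recovery table (Td descending) as a pandas DataFrame."""
        import pandas as pd
        rows = [{"td": round(td, 1),
                 "recovered": self.positive[td],
                 "band": self.positive[td] >= self.min_templates}
                for td in self.gradient]
        return pd.DataFrame(rows)


def gc_to_at_count(reference: TargetSequence, molecule: str) -> int:
    """Number of positions where the reference has G/C and the molecule A/T."""
    if len(molecule) != len(reference):
        raise ValueError(
            f"molecule length {len(molecule)} != reference {len(reference)}")
    ref_arr = np.frombuffer(reference.seq.encode("ascii"), dtype=np.uint8)
    mol_arr = np.frombuffer(molecule.encode("ascii"), dtype=np.uint8)
    ref_gc = (ref_arr == ord("G")) | (ref_arr == ord("C"))
    mol_at = (mol_arr == ord("A")) | (mol_arr == ord("T"))
    return int(np.count_nonzero(ref_gc & mol_at))


def melting_temperature(molecule: str, reference: TargetSequence,
                        model: TmModel) -> float:
    """Tm of a molecule under the linear GC-count proxy.

    Equals ``restrictive_td`` for the reference itself; each GC->AT
    substitution lowers it by ``delta_per_sub``.  Substitutions that do not
    convert a G/C to an A/T contribute nothing.
    """
    return model.restrictive_td - model.delta_per_sub * gc_to_at_count(
        reference, molecule)


def default_gradient(restrictive_td: float, n_steps: int = 12,
                     span_below: float = 5.0, span_above: float = 4.0) -> list[float]:
    """Equally spaced descending Td gradient around the restrictive Td.

    Default: 12 wells from restrictive_td - 5 degC to restrictive_td + 4 degC
    (step ~0.8 degC), mimicking typical printed gradient spreads.
    """
    if n_steps < 2:
        raise ValueError("gradient needs at least 2 steps")
    tds = np.linspace(restrictive_td - span_below, restrictive_td + span_above,
                      n_steps)
    return [float(t) for t in tds[::-1]]


def simulate_3dpcr(ms: MoleculeSet, gradient: list[float], model: TmModel,
                   min_templates: int = 1) -> GradientResult:
    """Evaluate recovery at every gradient Td (deterministic, no sampling).

    A molecule is amplifiable at Td iff Td >= Tm(molecule) - epsilon; a Td is
    positive iff at least ``min_templates`` molecules are amplifiable.
    Recovered sets are nested along the gradient by construction.
    """
    if not gradient:
        raise ValueError("gradient must be non-empty")
    if min_templates < 1:
        raise ValueError("min_templates must be >= 1")
    if len(ms.molecules) == 0:
        raise NoTemplatesError("empty molecule set: no templates")

    tms = np.array([melting_temperature(mol, ms.reference, model)
                    for mol in ms.molecules])
    ids = ms.ids
    grad_sorted = sorted(gradient, reverse=True)
    positive: dict[float, int] = {}
    recovered: dict[float, list[str]] = {}
    last_positive: float | None = None
    for td in grad_sorted:
        ok = td >= tms - model.epsilon
        rec = [ids[i] for i in np.nonzero(ok)[0]]
        positive[td] = len(rec)
        recovered[td] = rec
        if len(rec) >= min_templates:
            last_positive = td
    return GradientResult(gradient=grad_sorted, positive=positive,
                          recovered_ids=recovered,
                          last_positive_td=last_positive,
                          min_templates=min_templates,
                          restrictive_td=model.restrictive_td)


def sample_band(gr: GradientResult, td: float, n_clones: int,
                seed: int) -> list[str]:
    """Sample molecule identifiers from the band recovered at ``td``.

    Uniform without replacement; if ``n_clones`` exceeds the recovered count
    the sample is drawn with replacement and a warning is logged.
    Deterministic given ``seed``.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if td not in gr.positive or gr.positive[td] < gr.min_templates:
        raise NoBandError(f"no band at {td:.1f} degC")
    pool = gr.recovered_ids[td]
    rng = np.random.default_rng(seed)
    if n_clones > len(pool):
        import logging
        logging.getLogger(__name__).warning(
            "requested %d clones but only %d recovered at %.1f degC; "
            "sampling with replacement", n_clones, len(pool), td)
        idx = rng.integers(0, len(pool), size=n_clones)
    else:
        idx = rng.choice(len(pool), size=n_clones, replace=False)
    return [pool[i] for i in idx]
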