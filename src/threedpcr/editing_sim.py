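"""Simulate APOBEC-style cytidine deamination of a molecule population.

Cytidine deaminases convert C to U in single-stranded DNA (or 5-methyl-C to
T); after amplification either lesion is read as a C->T substitution on the
edited strand, i.e. C->T or G->A on the reported plus strand depending on
which strand was exposed.  The simulator models:

* a per-molecule strand choice (plus only, minus only, or a fair coin),
* a 5' dinucleotide context preference (the APOBEC hallmark is 5'TpC),
* dC vs 5Me-dC substrate labelling (sequence outcome is identical -- both
  lesions read as T -- so the substrate only annotates reports),
* an optional uniform background substitution error.

Each eligible cytidine on the chosen strand is edited independently with
probability ``rate * w(context) / max(w)``, so ``rate`` is exactly the
editing probability at the most-preferred context.  A cytidine with no 5'
neighbour (first position of its strand, or an N neighbour) has no defined
context and is ineligible.

Minus-strand editing is realised by applying the plus-strand rule to the
reverse complement, which guarantees exact strand symmetry: a minus-only
simulation of a target is, site by site, the plus-only simulation of its
reverse complement under the same seed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .target_io import TargetSequence, reverse_complement, write_fasta

logger = logging.getLogger(__name__)

CONTEXTS = ("ApC", "CpC", "GpC", "TpC")

StrandPolicy = Literal["plus_only", "minus_only", "both_random"]
Substrate = Literal["dC", "me5dC"]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class EditingModel:
    """Parameters of the deamination process.

    Parameters
    ----------
    rate
        Expected edited fraction of eligible cytidines per molecule at the
        most-preferred context, in [0, 1].  ``rate=0`` with ``error_rate=0``
        is the catalytically dead control.
    context_weights
        Relative preference for the 5' neighbour of the edited C, keyed by
        ``ApC``/``CpC``/``GpC``/``TpC``; non-negative, summing to 1.
    strand_policy
        Which strand each molecule exposes to the enzyme.
    substrate
        ``dC`` or ``me5dC``; label only, the sequence outcome is the same.
    error_rate
        Background non-deamination substitution probability per base
        (uniform over the three alternative bases), default 0.
    """

    rate: float
    context_weights: dict[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in CONTEXTS})
    strand_policy: StrandPolicy = "both_random"
    substrate: Substrate = "dC"
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate must lie in [0, 1], got {self.rate}")
        if set(self.context_weights) != set(CONTEXTS):
            raise ValueError(f"context_weights must have keys {CONTEXTS}")
        if any(w < 0 for w in self.context_weights.values()):
            raise ValueError("context weights must be non-negative")
        total = sum(self.context_weights.values())
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"context weights must sum to 1, got {total}")
        if self.strand_policy not in ("plus_only", "minus_only", "both_random"):
            raise ValueError(f"unknown strand_policy {self.strand_policy!r}")
        if self.substrate not in ("dC", "me5dC"):
            raise ValueError(f"unknown substrate {self.substrate!r}")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must lie in [0, 1), got {self.error_rate}")


@dataclass
class MoleculeSet:
    """A population of edited molecules with their ground-truth edits.

    ``true_edits[m]`` lists ``(position, strand)`` pairs in plus-strand
    0-based coordinates; strand ``'+'`` means the reference C was deaminated
    (read C->T), strand ``'-'`` means the complementary-strand C under a
    reference G was deaminated (read G->A).
    """

    reference: TargetSequence
    molecules: list[str]
    true_edits: list[list[tuple[int, str]]]
    model: EditingModel
    seed: int

    def __post_init__(self) -> None:
        ref_len = len(self.reference)
        for m, mol in enumerate(self.molecules):
            if len(mol) != ref_len:
                raise ValueError(
                    f"molecule {m} has length {len(mol)} != reference {ref_len}")

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def ids(self) -> list[str]:
        return [f"mol{m:05d}" for m in range(len(self.molecules))]

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(zip(self.ids, self.molecules), path)

    def edits_to_tsv(self, path: str | Path) -> None:
        """Sidecar of true edits: molecule id, 1-based position, strand, ref, alt."""
        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["molecule", "position", "strand", "ref", "alt"])
            for mid, edits in zip(self.ids, self.true_edits):
                for pos, strand in edits:
                    ref = self.reference.seq[pos]
                    alt = "T" if strand == "+" else "A"
                    w.writerow([mid, pos + 1, strand, ref, alt])


def plus_strand_edit_probabilities(seq: str, model: EditingModel) -> np.ndarray:
    """Per-position probability of a plus-strand deamination event.

    Zero everywhere except at eligible Cs (a C with an unambiguous 5'
    neighbour), where it is ``rate * w(context) / max(w)``.
    """
    weights = model.context_weights
    w_max = max(weights.values())
    p = np.zeros(len(seq))
    if w_max == 0 or model.rate == 0:
        return p
    for i in range(1, len(seq)):
        if seq[i] == "C" and seq[i - 1] in "ACGT":
            p[i] = model.rate * weights[seq[i - 1] + "pC"] / w_max
    return p


def eligible_site_count(target: TargetSequence, strand_policy: StrandPolicy) -> float:
    """Mean number of context-eligible cytidines per molecule under a policy.

    For ``both_random`` this is the average of the two strand counts, since
    each molecule exposes one strand with probability 1/2.
    """
    plus = int(np.count_nonzero(plus_strand_edit_probabilities(
        target.seq, EditingModel(rate=1.0))))
    minus = int(np.count_nonzero(plus_strand_edit_probabilities(
        reverse_complement(target.seq), EditingModel(rate=1.0))))
    if strand_policy == "plus_only":
        return float(plus)
    if strand_policy == "minus_only":
        return float(minus)
    return (plus + minus) / 2.0


def simulate_editing(target: TargetSequence, model: EditingModel,
                     n_molecules: int, seed: int) -> MoleculeSet:
    """Generate a deaminated molecule population.

    Deterministic given ``seed``.  Edits within a molecule are independent
    (no processivity).  Background errors, when enabled, are applied after
    editing at positions not already edited.
    """
    if n_molecules <= 0:
        raise ValueError(f"n_molecules must be positive, got {n_molecules}")
    seq = target.seq
    L = len(seq)
    if model.rate > 0 and not any(b in "CG" for b in seq):
        logger.warning("reference %s has no C or G: zero-edit output", target.id)

    rng = np.random.default_rng(seed)
    if model.strand_policy == "both_random":
        minus_row = rng.random(n_molecules) < 0.5
    elif model.strand_policy == "minus_only":
        minus_row = np.ones(n_molecules, dtype=bool)
    else:
        minus_row = np.zeros(n_molecules, dtype=bool)

    u = rng.random((n_molecules, L))
    p_plus = plus_strand_edit_probabilities(seq, model)
    p_rc = plus_strand_edit_probabilities(reverse_complement(seq), model)

    # plus-strand edits in plus coordinates; minus-strand edits evaluated in
    # reverse-complement coordinates, then mirrored back (rc j <-> plus L-1-j)
    mask_plus = (u < p_plus[None, :]) & ~minus_row[:, None]
    mask_minus = (u < p_rc[None, :])[:, ::-1] & minus_row[:, None]

    ref_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    mols = np.tile(ref_arr, (n_molecules, 1))
    mols[mask_plus] = ord("T")
    mols[mask_minus] = ord("A")

    if model.error_rate > 0:
        edited = mask_plus | mask_minus
        err = (rng.random((n_molecules, L)) < model.error_rate) & ~edited
        # uniform choice among the 3 alternative bases
        offsets = rng.integers(1, 4, size=(n_molecules, L))
        base_idx = np.zeros((n_molecules, L), dtype=np.int64)
        lut = np.zeros(256, dtype=np.int64)
        for k, b in enumerate(b"ACGT"):
            lut[b] = k
        base_idx = lut[mols]
        alt_idx = (base_idx + offsets) % 4
        alt_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)[alt_idx]
        mols[err] = alt_bytes[err]

    molecules = [row.tobytes().decode("ascii") for row in mols]
    true_edits: list[list[tuple[int, str]]] = []
    for m in range(n_molecules):
        edits = [(int(i), "+") for i in np.nonzero(mask_plus[m])[0]]
        edits += [(int(i), "-") for i in np.nonzero(mask_minus[m])[0]]
        edits.sort()
        true_edits.append(edits)

    return MoleculeSet(reference=target, molecules=molecules,
                       true_edits=true_edits, model=model, seed=seed)


def mutation_load(ms: MoleculeSet) -> np.ndarray:
    """Per-molecule substitutions per kb relative to the reference.

    load = (positions differing from reference) / (reference length) * 1000.
    """
    ref_arr = np.frombuffer(ms.reference.seq.encode("ascii"), dtype=np.uint8)
    loads = np.empty(len(ms.molecules))
    for m, mol in enumerate(ms.molecules):
        mol_arr = np.frombuffer(mol.encode("ascii"), dtype=np.uint8)
        loads[m] = np.count_nonzero(mol_arr != ref_arr)
    return loads / len(ms.reference) * 1000.0
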