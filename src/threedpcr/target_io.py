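"""Target sequence handling: FASTA I/O and synthetic amplicon generation.

The amplicon targets used in 3DPCR experiments (antibiotic-resistance genes,
mitochondrial loci, proto-oncogene fragments, viral hypervariable regions)
are short PCR products, typically a few hundred base pairs with moderate GC
content.  When no real amplicon sequence is available, :func:`generate_target`
produces a synthetic stand-in with controlled length and base composition so
that editing and selective-amplification behaviour can be studied end to end.

Coordinates are 0-based half-open internally; human-readable reports use
1-based closed positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STRICT_ALPHABET = frozenset("ACGT")
ANALYSIS_ALPHABET = frozenset("ACGTN")
# IUPAC ambiguity codes tolerated on input; mapped to N and excluded from counts
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MIN_AMPLICON_LENGTH = 50


class FastaFormatError(ValueError):
    """Raised for unreadable or empty FASTA input."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside the allowed alphabet."""


@dataclass(frozen=True)
class TargetSequence:
    """A reference amplicon against which editing and analysis are defined.

    Parameters
    ----------
    id
        Short text label (FASTA record id).
    seq
        Uppercase nucleotide string over A/C/G/T (plus N in analysis mode).
    description
        Free-text description carried through to FASTA output.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise AlphabetError(f"{self.id}: empty sequence")
        bad = set(self.seq) - ANALYSIS_ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.id}: illegal characters {sorted(bad)}; expected A/C/G/T/N"
            )
        if len(self.seq) < MIN_AMPLICON_LENGTH:
            raise ValueError(
                f"{self.id}: length {len(self.seq)} below minimum amplicon "
                f"length {MIN_AMPLICON_LENGTH}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc_fraction(self) -> float:
        """Observed G+C fraction (N excluded from the denominator)."""
        counted = [b for b in self.seq if b != "N"]
        if not counted:
            return 0.0
        gc = sum(b in "GC" for b in counted)
        return gc / len(counted)


def _normalize_seq(raw: str, record_id: str) -> str:
    """Uppercase, convert U->T, map IUPAC ambiguity codes to N."""
    seq = raw.upper().replace("U", "T")
    cleaned = []
    n_ambiguous = 0
    for ch in seq:
        if ch in STRICT_ALPHABET:
            cleaned.append(ch)
        elif ch in IUPAC_AMBIGUOUS:
            cleaned.append("N")
            if ch != "N":
                n_ambiguous += 1
        else:
            raise FastaFormatError(
                f"record {record_id!r}: illegal character {ch!r}"
            )
    if n_ambiguous:
        logger.warning(
            "record %r: %d IUPAC ambiguity codes mapped to N", record_id, n_ambiguous
        )
    return "".join(cleaned)


def read_fasta(path: str | Path) -> list[TargetSequence]:
    """Read all records of a FASTA file as :class:`TargetSequence` objects.

    Sequences are uppercased, U is converted to T, and IUPAC ambiguity codes
    are mapped to N with a logged warning.  Record order is preserved.

    Raises
    ------
    FastaFormatError
        If the file contains no records or illegal characters.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = _normalize_seq(str(rec.seq), rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(TargetSequence(id=rec.id, seq=seq, description=desc))
    return out


def write_fasta(targets: Iterable[TargetSequence | tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    """Write sequences to FASTA with fixed line width (default 70 columns).

    Accepts :class:`TargetSequence` objects or plain ``(id, seq)`` pairs.
    """
    records = []
    for t in targets:
        if isinstance(t, TargetSequence):
            records.append(SeqRecord(Seq(t.seq), id=t.id, description=t.description))
        else:
            rid, seq = t
            records.append(SeqRecord(Seq(seq), id=rid, description=""))
    path = Path(path)
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def generate_target(length: int, gc_fraction: float = 0.45, seed: int = 0,
                    id: str | None = None) -> TargetSequence:
    """Generate a random amplicon of given length and GC composition.

    Bases are drawn i.i.d. with P(G) = P(C) = ``gc_fraction``/2 and
    P(A) = P(T) = (1 - ``gc_fraction``)/2.  Deterministic for identical
    ``(length, gc_fraction, seed)``.

    Parameters
    ----------
    length
        Amplicon length in bp; must be at least 50.
    gc_fraction
        Target G+C fraction in [0, 1].  Default 0.45, a typical moderate-GC
        amplicon composition.
    seed
        Seed for the random generator.
    """
    if length < MIN_AMPLICON_LENGTH:
        raise ValueError(f"length must be >= {MIN_AMPLICON_LENGTH}, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must lie in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    probs = [
        (1 - gc_fraction) / 2,  # A
        gc_fraction / 2,        # C
        gc_fraction / 2,        # G
        (1 - gc_fraction) / 2,  # T
    ]
    bases = rng.choice(np.array(list("ACGT")), size=length, p=probs)
    seq = "".join(bases)
    if id is None:
        id = f"synthetic_{length}bp_gc{gc_fraction:g}_seed{seed}"
    return TargetSequence(id=id, seq=seq,
                          description=f"synthetic amplicon length={length} "
                                      f"gc={gc_fraction:g} seed={seed}")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the alphabet {A,C,G,T,N}."""
    bad = set(seq) - ANALYSIS_ALPHABET
    if bad:
        raise AlphabetError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]
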