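"""Oligonucleotide primitives: validation, reverse complement, mismatch algebra.

Everything here operates on plain uppercase IUPAC DNA strings (no gaps).
Gapped comparisons belong to :mod:`probesense.probe_design`, which consumes
alignments; keeping gaps out of this module makes the oligo algebra total.

Positions are 1-based in every user-facing argument and message (the
molecular-biology convention) and 0-based only internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes mapped to the set of bases each one stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

#: Watson–Crick complement, extended to ambiguity codes (R<->Y, K<->M,
#: S and W self-complementary, B<->V, D<->H, N<->N).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class SequenceError(ValueError):
    """Raised when a sequence fails IUPAC validation or a length precondition."""


@dataclass(frozen=True)
class MismatchPolicy:
    """How symbol pairs are compared.

    ambiguity_mode
        ``strict``: two symbols match iff they are the same letter (the
        convention used for plain A/C/G/T panels — never silently changes
        a published mismatch count).  ``iupac_overlap``: symbols match iff
        their IUPAC base sets intersect.
    gap_mode
        Only consulted by alignment-window scoring: ``mismatch`` counts a
        gap opposite a base as a mismatch (a gap cannot hybridise);
        ``exclude`` drops the column from the comparison.
    Comparison is always case-insensitive (inputs are upper-cased on entry).
    """

    ambiguity_mode: Literal["strict", "iupac_overlap"] = "strict"
    gap_mode: Literal["mismatch", "exclude"] = "mismatch"

    def __post_init__(self) -> None:
        if self.ambiguity_mode not in ("strict", "iupac_overlap"):
            raise ValueError(f"unknown ambiguity_mode {self.ambiguity_mode!r}")
        if self.gap_mode not in ("mismatch", "exclude"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")

    def symbols_match(self, a: str, b: str) -> bool:
        if self.ambiguity_mode == "strict":
            return a == b
        return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


STRICT = MismatchPolicy()


def validate_sequence(raw: str) -> str:
    """Normalise *raw* to an uppercase IUPAC DNA string.

    Whitespace and FASTA-style line breaks are tolerated and removed.
    U (RNA) is transliterated to T with a warning.  Any other character
    outside the IUPAC alphabet raises :class:`SequenceError` naming the
    offending character and its 1-based position (counted after
    whitespace removal).
    """
    if not isinstance(raw, str):
        raise SequenceError(f"sequence must be text, got {type(raw).__name__}")
    cleaned = "".join(raw.split()).upper()
    if "U" in cleaned:
        warnings.warn("U transliterated to T (RNA-style input)", stacklevel=2)
        logger.warning("sequence contained U; transliterated to T")
        cleaned = cleaned.replace("U", "T")
    for i, ch in enumerate(cleaned):
        if ch not in IUPAC_ALPHABET:
            raise SequenceError(
                f"invalid character {ch!r} at position {i + 1}: "
                "not an IUPAC nucleotide code"
            )
    return cleaned


@dataclass(frozen=True)
class Oligo:
    """A validated single-stranded DNA oligo.

    ``five_prime_modifier`` carries free-text 5' chemistry such as the
    thiol + six-carbon spacer ``"HS-S-(CH2)6"`` used to couple capture
    probes to gold surfaces.
    """

    id: str
    sequence: str
    five_prime_modifier: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        if not self.sequence:
            raise SequenceError(f"oligo {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    """Watson–Crick complement of the reversed sequence (5'->3' convention).

    Ambiguity codes map to their IUPAC complements; an involution on all
    IUPAC strings.  The empty string maps to itself.
    """
    seq = validate_sequence(seq)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(seq))


def _check_equal_length(a: str, b: str) -> None:
    if len(a) != len(b):
        raise SequenceError(
            f"position-wise comparison needs equal lengths, got {len(a)} and {len(b)}"
            " (align the sequences first)"
        )


def mismatch_count(a: str, b: str, policy: MismatchPolicy = STRICT) -> int:
    """Hamming-style mismatch count between two equal-length sequences.

    Strict mode counts positions with different letters; ``iupac_overlap``
    counts positions whose IUPAC base sets are disjoint.  Unequal lengths
    are an error — alignment is the caller's job.
    """
    a, b = validate_sequence(a), validate_sequence(b)
    _check_equal_length(a, b)
    return sum(1 for x, y in zip(a, b) if not policy.symbols_match(x, y))


def percent_mismatch(a: str, b: str, policy: MismatchPolicy = STRICT) -> float:
    """100 x mismatch_count / length, at full precision.

    Use :func:`round` (or ``round_percent``) for the nearest-integer
    reporting convention, e.g. 14/31 -> 45.16 -> "45%".
    """
    a, b = validate_sequence(a), validate_sequence(b)
    _check_equal_length(a, b)
    if len(a) == 0:
        raise SequenceError("percent mismatch undefined for zero-length sequences")
    return 100.0 * mismatch_count(a, b, policy) / len(a)


def round_percent(p: float) -> int:
    """Nearest-integer percent (half away from zero), the reporting convention."""
    return int(p + 0.5) if p >= 0 else -int(-p + 0.5)


def introduce_mismatches(
    seq: str, edits: Sequence[tuple[int, str]]
) -> str:
    """Substitute single bases at the given 1-based positions.

    Each edit is ``(position, replacement_base)``.  A replacement equal to
    the original base is a no-op and logged as a warning.  Positions out of
    range or multi-character/invalid replacements raise
    :class:`SequenceError`.
    """
    seq = validate_sequence(seq)
    out = list(seq)
    for pos, base in edits:
        if not 1 <= pos <= len(seq):
            raise SequenceError(
                f"edit position {pos} out of range 1..{len(seq)}"
            )
        base = validate_sequence(base)
        if len(base) != 1:
            raise SequenceError(f"replacement must be a single IUPAC base, got {base!r}")
        if out[pos - 1] == base:
            warnings.warn(
                f"edit at position {pos} replaces {base} with itself (no effect)",
                stacklevel=2,
            )
        out[pos - 1] = base
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA I/O for oligo panels
# ---------------------------------------------------------------------------

_MODIFIER_KEY = "5mod="


def read_oligo_fasta(path: str | Path) -> list[Oligo]:
    """Read an oligo panel from FASTA.

    A ``5mod=...`` token in the description is parsed back into
    ``five_prime_modifier``; the rest of the description is kept verbatim.
    """
    from Bio import SeqIO

    oligos: list[Oligo] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc_tokens = rec.description.split()[1:]  # drop the id token
        modifier = None
        rest: list[str] = []
        for tok in desc_tokens:
            if tok.startswith(_MODIFIER_KEY):
                modifier = tok[len(_MODIFIER_KEY):]
            else:
                rest.append(tok)
        oligos.append(
            Oligo(
                id=rec.id,
                sequence=str(rec.seq),
                five_prime_modifier=modifier,
                description=" ".join(rest),
            )
        )
    if not oligos:
        raise SequenceError(f"no FASTA records found in {path}")
    return oligos


def write_oligo_fasta(oligos: Iterable[Oligo], path: str | Path) -> None:
    """Write an oligo panel to single-line FASTA, round-trippable by the reader."""
    with open(path, "w") as fh:
        for o in oligos:
            desc = []
            if o.five_prime_modifier:
                desc.append(f"{_MODIFIER_KEY}{o.five_prime_modifier}")
            if o.description:
                desc.append(o.description)
            header = " ".join([o.id, *desc])
            fh.write(f">{header}\n{o.sequence}\n")


def load_reference_panel() -> dict[str, Oligo]:
    """The published Cuora amboinensis cytb biosensor oligo panel.

    Nine oligos keyed by their short labels: the thiolated 31-mer capture
    probe (ssBT), its reverse complement (RC, the fully complementary
    target), one- and three-base mismatch variants of RC (1MN, 3MN),
    reverse-complementary cytb oligos of four common meat species — cow
    (CW), buffalo (BF), horse (GT), duck (CK) — and a noncomplementary
    control (NC).
    """
    with resources.as_file(
        resources.files("probesense").joinpath("data/cuora_cytb_panel.fasta")
    ) as p:
        return {o.id: o for o in read_oligo_fasta(p)}
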