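"""DNA alphabet utilities: IUPAC matching, reverse complement, frame-aware translation.

Coordinates are 0-based half-open internally; every user-facing interface
(files, CLI) uses 1-based inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = [
    "IUPAC_CODES",
    "CodingContext",
    "SequenceError",
    "iupac_match",
    "is_transition",
    "is_transversion",
    "normalize_dna",
    "reverse_complement",
    "translate",
]

#: IUPAC nucleotide ambiguity codes mapped to the concrete bases they admit.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_CONCRETE = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SequenceError(ValueError):
    """Raised for malformed DNA input (bad alphabet, coordinates out of range)."""


def normalize_dna(seq: str, *, allow_iupac: bool = False, what: str = "sequence") -> str:
    """Upper-case ``seq``, map U to T, and validate its alphabet.

    Target sequences must be concrete (A/C/G/T only): the method reasons about
    exact alleles and their translation, so ambiguity codes are rejected unless
    ``allow_iupac`` is set (used for PAM patterns).
    """
    s = seq.upper().replace("U", "T")
    allowed = IUPAC_CODES.keys() if allow_iupac else _CONCRETE
    for i, base in enumerate(s):
        if base not in allowed:
            raise SequenceError(
                f"invalid character {base!r} at position {i + 1} in {what}"
            )
    return s


def iupac_match(pattern: str, site: str) -> bool:
    """True iff each base of ``site`` belongs to the IUPAC class at the same
    position of ``pattern``. Lengths must agree."""
    if len(pattern) != len(site):
        raise SequenceError(
            f"pattern length {len(pattern)} != site length {len(site)}"
        )
    p = normalize_dna(pattern, allow_iupac=True, what="pattern")
    s = normalize_dna(site, what="site")
    return all(base in IUPAC_CODES[code] for code, base in zip(p, s))


def reverse_complement(seq: str) -> str:
    """Standard reverse complement over {A,C,G,T}."""
    s = normalize_dna(seq)
    return str(Seq(s).reverse_complement())


@dataclass(frozen=True)
class CodingContext:
    """A coding-strand DNA stretch plus the reading-frame offset.

    ``frame_offset`` is the 0-based index of the first base of the first
    complete codon; ``sense_strand`` records whether ``sequence`` is the
    mRNA-like strand (callers flip upstream of this type).
    """

    sequence: str
    frame_offset: int = 0
    sense_strand: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_dna(self.sequence))
        if self.frame_offset not in (0, 1, 2):
            raise SequenceError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")
        if len(self.sequence) < 3:
            raise SequenceError("coding sequence must be at least one codon long")


def translate(seq: str | CodingContext, frame_offset: int = 0) -> str:
    """Translate complete codons from ``frame_offset`` with the standard
    nuclear code; stops render as '*'; a trailing partial codon is dropped.

    Only the standard code is supported — variants on the mitochondrial code
    are out of scope for this tool.
    """
    if isinstance(seq, CodingContext):
        frame_offset = seq.frame_offset
        seq = seq.sequence
    else:
        seq = normalize_dna(seq)
    if frame_offset not in (0, 1, 2):
        raise SequenceError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    n_codons = (len(seq) - frame_offset) // 3
    if n_codons <= 0:
        return ""
    coding = seq[frame_offset : frame_offset + 3 * n_codons]
    return str(Seq(coding).translate())


def is_transition(ref_base: str, var_base: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine substitution."""
    r = normalize_dna(ref_base, what="ref_base")
    v = normalize_dna(var_base, what="var_base")
    if len(r) != 1 or len(v) != 1 or r == v:
        raise SequenceError(f"not a substitution: {ref_base!r} -> {var_base!r}")
    return (r in _PURINES) == (v in _PURINES)


def is_transversion(ref_base: str, var_base: str) -> bool:
    """Purine<->pyrimidine substitution."""
    return not is_transition(ref_base, var_base)
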