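"""Low-level DNA string helpers shared across modules.

Sequences are plain Python ``str`` over the uppercase alphabet
``{A, C, G, T, N}`` (degenerate IUPAC letters appear only in restriction
enzyme recognition sequences).
"""

from __future__ import annotations

import re

# full IUPAC complement so enzyme recognition strings can be reverse-complemented
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: IUPAC degenerate letter -> the set of concrete bases it stands for
IUPAC_BASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_DNA_RE = re.compile(r"^[ACGTN]+$")


def revcomp(seq: str) -> str:
    """Reverse complement of an (IUPAC) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    """True iff *seq* is non-empty and contains only A/C/G/T/N."""
    return bool(seq) and _DNA_RE.match(seq) is not None


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases in *seq* (N counts as non-GC)."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def iupac_pattern(recognition: str) -> re.Pattern[str]:
    """Compile an IUPAC recognition sequence to a regex over A/C/G/T.

    Raises ``ValueError`` naming the offending letter for non-IUPAC input.
    Matches are over concrete genomic sequence, so N in the genome never
    matches (the pattern only admits A/C/G/T).
    """
    parts = []
    for letter in recognition.upper():
        try:
            bases = IUPAC_BASES[letter]
        except KeyError:
            raise ValueError(f"invalid IUPAC letter {letter!r} in {recognition!r}") from None
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def iupac_matches(recognition: str, seq: str) -> bool:
    """True iff *seq* (concrete DNA) matches *recognition* base by base."""
    if len(seq) != len(recognition):
        return False
    return all(b in IUPAC_BASES.get(r, "") for r, b in zip(recognition.upper(), seq))


def is_palindromic(recognition: str) -> bool:
    """True iff the recognition sequence equals its own reverse complement."""
    return recognition.upper() == revcomp(recognition.upper())
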