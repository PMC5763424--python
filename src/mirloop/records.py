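"""RNA sequence records and alphabet canonicalization.

Sequences are stored uppercase over the RNA alphabet {A, C, G, U}; DNA-style
input (``T``/``t``) and lowercase letters are accepted and mapped on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RNA_ALPHABET = frozenset("ACGU")

_CANONICAL = str.maketrans("acgutT", "ACGUUU")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a character outside {A,C,G,U,T} (any case)."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"illegal character {char!r} at position {position} "
            "(expected A/C/G/U/T, any case)"
        )


def canonicalize(raw_sequence: str) -> str:
    """Map a raw nucleotide string to the canonical RNA alphabet.

    Uppercases the input and replaces ``T`` with ``U``.  Rejects empty input
    and any character outside the DNA/RNA alphabet, reporting its position.
    """
    if not raw_sequence:
        raise ValueError("sequence must be non-empty")
    seq = raw_sequence.translate(_CANONICAL)
    for pos, char in enumerate(seq):
        if char not in RNA_ALPHABET:
            raise SequenceAlphabetError(raw_sequence[pos], pos)
    return seq


@dataclass(frozen=True)
class RnaRecord:
    """An identified RNA sequence with an optional species label.

    Parameters
    ----------
    id : str
        Record identifier, unique within a dataset.
    sequence : str
        Canonical sequence over {A, C, G, U}.  Raw input is canonicalized
        (uppercased, T mapped to U) at construction.
    species : str, optional
        Species label; ``None`` for unlabeled records.
    """

    id: str
    sequence: str
    species: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        object.__setattr__(self, "sequence", canonicalize(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)
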