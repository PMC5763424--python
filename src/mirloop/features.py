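"""The 98-dimensional hairpin feature vector.

Layout (fixed, version-stamped schema):

* 64 trinucleotide relative frequencies, keys ``AAA`` .. ``UUU`` in
  lexicographic order (A < C < G < U).  Overlapping windows, counts divided
  by ``L - 2``, so the block sums to 1 for any sequence of length >= 3.
* 32 triplet structure-sequence counts.  The dot-bracket string is first
  "unified" (every ``)`` replaced by ``(``, i.e. positions are reduced to
  paired/unpaired); each 3-window is coded by its first nucleotide plus the
  3-character paired/unpaired pattern, giving 4 x 8 = 32 codes.  Raw counts,
  summing to ``L - 2``.
* ``MFE`` — the structure's energy score as produced by the folding backend.
* ``GU_pairs`` — number of base pairs joining a G with a U (wobble pairs).
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .folding import SecondaryStructure
from .records import RnaRecord

__all__ = [
    "SCHEMA_VERSION",
    "NUCLEOTIDES",
    "STRUCTURE_PATTERNS",
    "TRINUCLEOTIDES",
    "TRIPLET_CODES",
    "FEATURE_NAMES",
    "N_FEATURES",
    "ngram_frequencies",
    "unify_brackets",
    "triplet_structure_features",
    "gu_pair_count",
    "extract_features",
    "feature_frame",
]

SCHEMA_VERSION = "mirloop-features-1"

NUCLEOTIDES = "ACGU"

#: The 8 paired/unpaired patterns of a 3-window after bracket unification,
#: ordered with '(' before '.' position by position.
STRUCTURE_PATTERNS = ("(((", "((.", "(.(", "(..", ".((", ".(.", "..(", "...")

TRINUCLEOTIDES = tuple("".join(p) for p in product(NUCLEOTIDES, repeat=3))

#: Nucleotide-major, pattern-minor: 'A(((', 'A((.', ..., 'U...'.
TRIPLET_CODES = tuple(n + p for n in NUCLEOTIDES for p in STRUCTURE_PATTERNS)

FEATURE_NAMES = TRINUCLEOTIDES + TRIPLET_CODES + ("MFE", "GU_pairs")
N_FEATURES = len(FEATURE_NAMES)  # 98

_TRINUC_INDEX = {kmer: i for i, kmer in enumerate(TRINUCLEOTIDES)}
_TRIPLET_INDEX = {code: i for i, code in enumerate(TRIPLET_CODES)}


def ngram_frequencies(seq: str, n: int = 3) -> np.ndarray:
    """Relative frequencies of the 4**n overlapping n-grams, in lexicographic
    order.  Counts are divided by the number of windows, ``L - n + 1``, so
    the vector sums to 1; rejects sequences shorter than ``n``.
    """
    length = len(seq)
    if length < n:
        raise ValueError(f"sequence of length {length} too short for {n}-grams")
    if n == 3:
        index = _TRINUC_INDEX
    else:
        index = {
            "".join(p): i for i, p in enumerate(product(NUCLEOTIDES, repeat=n))
        }
    counts = np.zeros(len(index))
    for i in range(length - n + 1):
        counts[index[seq[i : i + n]]] += 1
    return counts / (length - n + 1)


def unify_brackets(dotbracket: str) -> str:
    """Collapse strand direction: every ``)`` becomes ``(``.

    After unification a position is only paired ``(`` or unpaired ``.``;
    the map is idempotent.
    """
    return dotbracket.replace(")", "(")


def triplet_structure_features(seq: str, unified: str) -> np.ndarray:
    """Counts of the 32 triplet structure-sequence codes.

    Each window ``i`` contributes the code ``seq[i] + unified[i:i+3]``.
    Windows slide over the whole sequence (loop included); the counts sum
    to ``L - 2``.
    """
    if len(seq) != len(unified):
        raise ValueError(
            f"sequence length {len(seq)} != structure length {len(unified)}"
        )
    if len(seq) < 3:
        raise ValueError("need at least 3 nucleotides for triplet features")
    counts = np.zeros(len(TRIPLET_CODES))
    for i in range(len(seq) - 2):
        counts[_TRIPLET_INDEX[seq[i] + unified[i : i + 3]]] += 1
    return counts


def gu_pair_count(seq: str, pairs) -> float:
    """Number of base pairs whose partners are {G, U} in either order."""
    count = 0
    for i, j in pairs:
        if i >= len(seq) or j >= len(seq):
            raise IndexError(f"pair ({i}, {j}) outside sequence of length {len(seq)}")
        if {seq[i], seq[j]} == {"G", "U"}:
            count += 1
    return float(count)


def extract_features(record: RnaRecord, structure: SecondaryStructure) -> np.ndarray:
    """Assemble the full 98-vector [ngram(64) | triplet(32) | MFE | GU]."""
    seq = record.sequence
    if len(seq) != len(structure):
        raise ValueError(
            f"record {record.id}: sequence length {len(seq)} != "
            f"structure length {len(structure)}"
        )
    unified = unify_brackets(structure.dotbracket)
    return np.concatenate(
        [
            ngram_frequencies(seq, 3),
            triplet_structure_features(seq, unified),
            [structure.energy],
            [gu_pair_count(seq, structure.pairs)],
        ]
    )


def feature_frame(records, structures) -> pd.DataFrame:
    """Feature matrix for parallel lists of records and structures.

    Returns a DataFrame with the schema columns, indexed by record id.
    """
    if len(records) != len(structures):
        raise ValueError("records and structures differ in length")
    rows = [extract_features(rec, st) for rec, st in zip(records, structures)]
    return pd.DataFrame(
        rows, index=pd.Index([r.id for r in records], name="id"),
        columns=list(FEATURE_NAMES),
    )
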