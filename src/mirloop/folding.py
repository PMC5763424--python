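"""RNA secondary-structure prediction.

Two backends produce a dot-bracket structure and an energy score per
sequence:

* ``external`` — the ViennaRNA thermodynamic folder (python bindings when
  importable, otherwise the ``RNAfold`` executable).  Energy is the minimum
  free energy (MFE) in kcal/mol.
* ``fallback`` — a deterministic Nussinov-style dynamic program that
  maximizes the number of Watson-Crick + G-U wobble pairs subject to a
  minimum hairpin-loop size.  Energy is the negated pair count, so that for
  both backends lower energy means a more extensively paired structure.

The default resolution order tries the external backend first and falls
back to the internal one, recording which backend produced each structure.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "SecondaryStructure",
    "FoldingBackendUnavailable",
    "pairs_from_dotbracket",
    "fold_fallback",
    "fold_external",
    "fold",
    "MIN_LOOP",
    "CANONICAL_PAIRS",
]

#: Minimum number of unpaired nucleotides enclosed by a base pair
#: (steric hairpin-loop constraint).
MIN_LOOP = 3

#: Pairs admitted by the fallback folder: Watson-Crick plus the G-U wobble.
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


class FoldingBackendUnavailable(RuntimeError):
    """The external thermodynamic folding backend cannot be used."""


class DotBracketError(ValueError):
    """Malformed dot-bracket string; ``index`` is the first offending position."""

    def __init__(self, message: str, index: int):
        self.index = index
        super().__init__(f"{message} at index {index}")


@dataclass(frozen=True)
class SecondaryStructure:
    """A non-crossing secondary structure for one sequence.

    Attributes
    ----------
    dotbracket : str
        Structure string over ``(``, ``)``, ``.`` with the same length as
        the sequence.
    pairs : frozenset of (int, int)
        Base pairs as 0-based ``(i, j)`` tuples with ``i < j``, exactly the
        matching derived from ``dotbracket``.
    energy : float
        MFE in kcal/mol (external backend) or negated pair count (fallback).
    backend : str
        ``"external"`` or ``"fallback"``.
    """

    dotbracket: str
    pairs: frozenset
    energy: float
    backend: str

    def __post_init__(self):
        derived = pairs_from_dotbracket(self.dotbracket)
        if derived != self.pairs:
            raise ValueError("pairs do not match the dot-bracket string")
        if self.backend not in ("external", "fallback"):
            raise ValueError(f"unknown backend {self.backend!r}")

    def __len__(self) -> int:
        return len(self.dotbracket)


def pairs_from_dotbracket(dotbracket: str) -> frozenset:
    """Derive the base-pair set from a dot-bracket string (stack matching).

    Returns 0-based ``(i, j)`` pairs with ``i < j``.  Raises
    :class:`DotBracketError` on the first unbalanced bracket or on a
    character outside ``(``, ``)``, ``.``.
    """
    stack: list[int] = []
    pairs = set()
    for idx, char in enumerate(dotbracket):
        if char == "(":
            stack.append(idx)
        elif char == ")":
            if not stack:
                raise DotBracketError("unmatched ')'", idx)
            pairs.add((stack.pop(), idx))
        elif char != ".":
            raise DotBracketError(f"illegal character {char!r}", idx)
    if stack:
        raise DotBracketError("unmatched '('", stack[-1])
    return frozenset(pairs)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def fold_fallback(seq: str, min_loop: int = MIN_LOOP) -> SecondaryStructure:
    """Fold by base-pair maximization (Nussinov dynamic program).

    Maximizes the number of canonical + wobble pairs subject to
    ``j - i >= min_loop + 1`` for every pair ``(i, j)``.  The traceback is
    deterministic: at each subinterval the 5'-most position is paired with
    the smallest admissible partner that achieves the optimum, and pairing
    is preferred over leaving it unpaired on ties.  Energy is the negated
    pair count.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("sequence must be non-empty")
    # best[i][j] = max pairs in seq[i..j]; intervals shorter than a hairpin
    # loop stay 0.
    best = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            row_i1 = best[i + 1]
            score = row_i1[j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(seq[i], seq[k]):
                    cand = 1 + (row_i1[k - 1] if k - 1 > i else 0)
                    if k + 1 <= j:
                        cand += best[k + 1][j]
                    if cand > score:
                        score = cand
            best[i][j] = score

    structure = ["."] * n
    pairs = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        target = best[i][j]
        if target == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if not _can_pair(seq[i], seq[k]):
                continue
            cand = 1 + (best[i + 1][k - 1] if k - 1 > i else 0)
            if k + 1 <= j:
                cand += best[k + 1][j]
            if cand == target:
                structure[i], structure[k] = "(", ")"
                pairs.add((i, k))
                stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return SecondaryStructure(
        dotbracket="".join(structure),
        pairs=frozenset(pairs),
        energy=-float(len(pairs)),
        backend="fallback",
    )


@lru_cache(maxsize=1)
def _vienna_module():
    try:
        import RNA  # ViennaRNA python bindings

        return RNA
    except ImportError:
        return None


def fold_external(seq: str) -> SecondaryStructure:
    """Fold with the ViennaRNA thermodynamic model (MFE structure).

    Uses the python bindings when importable, otherwise shells out to the
    ``RNAfold`` executable and parses its second output line
    (``dotbracket ( MFE )``).  Raises :class:`FoldingBackendUnavailable`
    when neither route works, so callers can fall back.
    """
    rna = _vienna_module()
    if rna is not None:
        dotbracket, mfe = rna.fold(seq)
        return SecondaryStructure(
            dotbracket=dotbracket,
            pairs=pairs_from_dotbracket(dotbracket),
            energy=float(mfe),
            backend="external",
        )
    exe = shutil.which("RNAfold")
    if exe is None:
        raise FoldingBackendUnavailable("neither ViennaRNA bindings nor RNAfold found")
    try:
        proc = subprocess.run(
            [exe, "--noPS"],
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
    except (OSError, subprocess.CalledProcessError) as exc:
        raise FoldingBackendUnavailable(f"RNAfold failed: {exc}") from exc
    lines = proc.stdout.strip().splitlines()
    if len(lines) < 2:
        raise FoldingBackendUnavailable(f"unparseable RNAfold output: {proc.stdout!r}")
    structure_line = lines[1]
    try:
        dotbracket, energy_part = structure_line.split(None, 1)
        mfe = float(energy_part.strip().strip("()"))
    except ValueError as exc:
        raise FoldingBackendUnavailable(
            f"unparseable RNAfold line: {structure_line!r}"
        ) from exc
    return SecondaryStructure(
        dotbracket=dotbracket,
        pairs=pairs_from_dotbracket(dotbracket),
        energy=mfe,
        backend="external",
    )


def fold(seq: str, backend: str = "auto", min_loop: int = MIN_LOOP) -> SecondaryStructure:
    """Fold one sequence with the requested backend.

    ``backend="auto"`` tries the external thermodynamic folder first and
    silently drops to the internal pair-maximization fallback when it is
    unavailable; the chosen backend is recorded on the returned structure.
    """
    if backend == "external":
        return fold_external(seq)
    if backend == "fallback":
        return fold_fallback(seq, min_loop=min_loop)
    if backend != "auto":
        raise ValueError(f"unknown backend {backend!r}")
    try:
        return fold_external(seq)
    except FoldingBackendUnavailable:
        return fold_fallback(seq, min_loop=min_loop)
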