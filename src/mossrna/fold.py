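"""RNA secondary-structure folding backends.

Two interchangeable backends produce a :class:`FoldResult`:

``vienna``
    Minimum-free-energy folding through the ViennaRNA python bindings
    (deterministic, no pseudoknots).  The default when the bindings are
    importable.

``maxpair``
    A maximum-base-pairing dynamic program (Nussinov recursion) with a
    minimum hairpin loop of 3 unpaired bases.  Pure python, used as a
    dependency-free test backend and for short sequences.

Both accept DNA and transcribe internally; pair tables are 0-based with
``None`` for unpaired positions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq import transcribe

try:  # pragma: no cover - availability depends on the interpreter build
    import RNA as _vienna
except ImportError:  # pragma: no cover
    _vienna = None

MIN_LOOP = 3

_RNA_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


@dataclass
class FoldResult:
    """A folded sequence: dot-bracket structure, pair table and score.

    ``score`` is the backend's objective: free energy in kcal/mol for the
    thermodynamic backend (lower is better) or the number of base pairs for
    the max-pairing backend (higher is better).
    """

    sequence: str  # RNA
    structure: str  # dot-bracket
    pair_table: list[int | None]
    score: float
    backend: str

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pair_table)
                   if j is not None and j > i)


def pair_table_from_dotbracket(structure: str) -> list[int | None]:
    table: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            table[i], table[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return table


def _fold_vienna(rna: str) -> FoldResult:
    structure, mfe = _vienna.fold(rna)
    return FoldResult(rna, structure, pair_table_from_dotbracket(structure),
                      float(mfe), "vienna")


def max_pairing_table(rna: str) -> list[list[int]]:
    """Fill the Nussinov DP matrix of maximal pair counts for rna[i..j]."""
    n = len(rna)
    can_pair = [[(rna[i], rna[j]) in _RNA_PAIRS for j in range(n)] for i in range(n)]
    dp = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            # i unpaired, or i pairs with some k in (i+MIN_LOOP, j]
            best = dp[i + 1][j]
            row = can_pair[i]
            dpi1 = dp[i + 1]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if row[k]:
                    cand = 1 + dpi1[k - 1] + (dp[k + 1][j] if k + 1 <= j else 0)
                    if cand > best:
                        best = cand
            dp[i][j] = best
    return dp


def _traceback(rna, dp, i, j, pairs):
    while i < j:
        if j - i <= MIN_LOOP:
            return
        if dp[i][j] == dp[i + 1][j]:
            i += 1
            continue
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (rna[i], rna[k]) in _RNA_PAIRS:
                cand = 1 + dp[i + 1][k - 1] + (dp[k + 1][j] if k + 1 <= j else 0)
                if cand == dp[i][j]:
                    pairs.append((i, k))
                    _traceback(rna, dp, i + 1, k - 1, pairs)
                    i, j = k + 1, j
                    break
        else:  # pragma: no cover - matrix is internally consistent
            raise AssertionError("traceback failed")


def _fold_maxpair(rna: str) -> FoldResult:
    n = len(rna)
    table: list[int | None] = [None] * n
    if n <= MIN_LOOP + 1:
        return FoldResult(rna, "." * n, table, 0.0, "maxpair")
    dp = max_pairing_table(rna)
    pairs: list[tuple[int, int]] = []
    _traceback(rna, dp, 0, n - 1, pairs)
    structure = ["."] * n
    for i, j in pairs:
        table[i], table[j] = j, i
        structure[i], structure[j] = "(", ")"
    return FoldResult(rna, "".join(structure), table, float(dp[0][n - 1]),
                      "maxpair")


def fold(seq: str, backend: str = "auto") -> FoldResult:
    """Fold a DNA or RNA sequence with the requested backend."""
    rna = transcribe(seq.upper())
    if backend == "auto":
        backend = "vienna" if _vienna is not None else "maxpair"
    if backend == "vienna":
        if _vienna is None:
            raise RuntimeError("ViennaRNA python bindings are not available")
        return _fold_vienna(rna)
    if backend == "maxpair":
        return _fold_maxpair(rna)
    raise ValueError(f"unknown folding backend: {backend!r}")
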