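"""RNA secondary-structure prediction for hairpin evaluation.

Two engines sit behind one contract:

* ``vienna`` — the ViennaRNA thermodynamic nearest-neighbour model
  (used when the ``RNA`` bindings are importable; the default);
* ``nussinov`` — a built-in stacking-energy Nussinov variant: base pairs
  score GC −2.0, AU −1.5, GU −1.0 kcal/mol, a hairpin loop costs +3.0,
  minimum loop size 3. A simple, fully deterministic model whose optimal
  pairings are exactly checkable by enumeration on small instances.

Both return a nested (pseudoknot-free) dot-bracket structure and a free
energy ≤ 0 for any structure with at least one pair; the all-unpaired
structure has energy 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from .seq import to_rna, VALID_RNA

try:  # ViennaRNA python bindings
    import RNA as _vienna
except ImportError:  # pragma: no cover - depends on environment
    _vienna = None

PAIR_ENERGY = {
    ("G", "C"): -2.0, ("C", "G"): -2.0,
    ("A", "U"): -1.5, ("U", "A"): -1.5,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
LOOP_PENALTY = 3.0
MIN_LOOP = 3


@dataclass(frozen=True)
class FoldResult:
    structure: str  # dot-bracket
    energy: float  # kcal/mol
    pairs: tuple[tuple[int, int], ...]  # 0-based (i, j), i < j

    @property
    def partner(self) -> dict[int, int]:
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def paired(self, start: int, end: int) -> list[int]:
        """Paired positions within [start, end)."""
        p = self.partner
        return [i for i in range(start, end) if i in p]


def pairs_from_dotbracket(structure: str) -> tuple[tuple[int, int], ...]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return tuple(sorted(pairs))


def _check_rna(seq: str) -> str:
    s = to_rna(seq)
    bad = set(s) - VALID_RNA
    if bad:
        raise ValueError(f"non-RNA characters: {sorted(bad)!r}")
    return s


def _nussinov(seq: str) -> FoldResult:
    """Minimum pair-energy nested structure (stacking-lite model)."""
    n = len(seq)
    E = [[0.0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i][j - 1]  # j unpaired
            for k in range(i, j - MIN_LOOP):
                e = PAIR_ENERGY.get((seq[k], seq[j]))
                if e is None:
                    continue
                left = E[i][k - 1] if k > i else 0.0
                inner = E[k + 1][j - 1]
                cand = left + e + inner
                if cand < best:
                    best = cand
            E[i][j] = best
    # traceback
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if E[i][j] == (E[i][j - 1] if j - 1 >= i else 0.0):
            stack.append((i, j - 1))
            continue
        for k in range(i, j - MIN_LOOP):
            e = PAIR_ENERGY.get((seq[k], seq[j]))
            if e is None:
                continue
            left = E[i][k - 1] if k > i else 0.0
            inner = E[k + 1][j - 1]
            if abs(left + e + inner - E[i][j]) < 1e-9:
                pairs.append((k, j))
                stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
    pairs.sort()
    structure = ["."] * n
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    # hairpin loops: closing pairs with no pair nested directly inside
    partner = {i: j for i, j in pairs}
    n_loops = 0
    for i, j in pairs:
        if not any(i < a and b < j for a, b in pairs if (a, b) != (i, j)):
            n_loops += 1
    energy = sum(PAIR_ENERGY[(seq[i], seq[j])] for i, j in pairs)
    energy += LOOP_PENALTY * n_loops
    if energy > 0:  # loop penalty outweighs pairing: report unpaired
        return FoldResult("." * n, 0.0, ())
    return FoldResult("".join(structure), round(energy, 2), tuple(pairs))


def default_engine() -> str:
    return "vienna" if _vienna is not None else "nussinov"


def fold(sequence: str, engine: str = "auto") -> FoldResult:
    """Fold an RNA sequence (length ≤ 400) into its minimum-energy nested
    structure under the selected energy model."""
    seq = _check_rna(sequence)
    if len(seq) > 400:
        raise ValueError("fold() accepts sequences of length ≤ 400")
    if not seq:
        return FoldResult("", 0.0, ())
    if engine == "auto":
        engine = default_engine()
    if engine == "vienna":
        if _vienna is None:
            raise RuntimeError("ViennaRNA bindings are not available")
        structure, mfe = _vienna.fold(seq)
        return FoldResult(structure, round(float(mfe), 2),
                          pairs_from_dotbracket(structure))
    if engine == "nussinov":
        return _nussinov(seq)
    raise ValueError(f"unknown fold engine: {engine!r}")


def duplex_energy(mirna: str, site: str, engine: str = "auto") -> float:
    """Free energy of the antiparallel miRNA/target-site duplex.

    With the thermodynamic engine this is ``RNA.duplexfold``; the built-in
    model scores the gapless antiparallel pairing position by position.
    Used for the duplex-MFE acceptance ratio, where the same engine scores
    the perfect-complement reference so model constants cancel.
    """
    a = _check_rna(mirna)
    b = _check_rna(site)
    if engine == "auto":
        engine = default_engine()
    if engine == "vienna":
        if _vienna is None:
            raise RuntimeError("ViennaRNA bindings are not available")
        return round(float(_vienna.duplexfold(a, b).energy), 2)
    # built-in: pair a 5'→3' against b 3'→5'
    rb = b[::-1]
    e = 0.0
    for x, y in zip(a, rb):
        e += PAIR_ENERGY.get((x, y), 0.0)
    return round(e, 2)
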