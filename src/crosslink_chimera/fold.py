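"""Minimum-energy RNA secondary-structure models with pair constraints.

The default evaluator scores a structure as the sum of its base-pair
energies (G·C -3.0, A·U -2.0, G·U -1.0 kcal/mol, minimum hairpin loop of
3 nt) and minimises it by Nussinov-style dynamic programming.  The table is
deliberately simple so that results are bit-stable and checkable against
exhaustive structure enumeration; a nearest-neighbour engine (ViennaRNA's
RNAfold, if installed) can be swapped in behind the same interface,
changing energies but not pipeline logic.

Constraints are expressed as forced pairs (each position may then pair only
with its partner, and no pair may cross a forced pair) plus unpairable
positions; both are honoured exactly by the dynamic program.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

DEFAULT_PAIR_SCORES: dict[frozenset[str], float] = {
    frozenset("GC"): -3.0,
    frozenset("AU"): -2.0,
    frozenset("GU"): -1.0,
}

DEFAULT_MIN_LOOP = 3


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def pair_score(a: str, b: str, scores=None) -> float:
    """Energy of pairing bases ``a`` and ``b``; 0.0 when they cannot pair."""
    scores = DEFAULT_PAIR_SCORES if scores is None else scores
    if a == b:
        return 0.0
    return scores.get(frozenset((a, b)), 0.0)


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    if a == b:
        return False
    key = frozenset((a, b))
    if key == frozenset("GU"):
        return allow_gu
    return key in (frozenset("GC"), frozenset("AU"))


@dataclass(frozen=True)
class FoldResult:
    energy: float
    pairs: tuple[tuple[int, int], ...]
    structure: str  # dot-bracket


def dot_bracket(n: int, pairs: Iterable[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


def structure_energy(seq: str, pairs: Iterable[tuple[int, int]], scores=None) -> float:
    seq = to_rna(seq)
    return sum(pair_score(seq[i], seq[j], scores) for i, j in pairs)


class InternalEvaluator:
    """Pair-sum energy model minimised by constrained Nussinov DP."""

    name = "internal"

    def __init__(self, scores=None, min_loop: int = DEFAULT_MIN_LOOP):
        self.scores = DEFAULT_PAIR_SCORES if scores is None else dict(scores)
        self.min_loop = min_loop

    # -- pair admissibility ------------------------------------------------
    def _score_matrix(self, seq: str, forced: Sequence[tuple[int, int]],
                      unpairable: frozenset[int]) -> np.ndarray:
        n = len(seq)
        S = np.full((n + 1, n + 1), np.inf)
        forced_by_pos: dict[int, int] = {}
        for a, b in forced:
            forced_by_pos[a] = b
            forced_by_pos[b] = a
        for i in range(n):
            if i in unpairable:
                continue
            for j in range(i + self.min_loop + 1, n):
                if j in unpairable:
                    continue
                s = self.scores.get(frozenset((seq[i], seq[j])), 0.0) if seq[i] != seq[j] else 0.0
                if s >= 0.0:
                    continue
                if forced_by_pos.get(i, j) != j or forced_by_pos.get(j, i) != i:
                    continue
                if any(self._crosses(i, j, a, b) for a, b in forced):
                    continue
                S[i, j] = s
        return S

    @staticmethod
    def _crosses(p: int, q: int, a: int, b: int) -> bool:
        if (p, q) == (a, b):
            return False
        in_p = a < p < b
        in_q = a < q < b
        return in_p != in_q

    def fold(self, seq: str, forced_pairs: Sequence[tuple[int, int]] = (),
             unpairable: Iterable[int] = ()) -> FoldResult:
        """Constrained minimum-energy structure of ``seq``.

        Every forced pair must be admissible (complementary, loop-feasible);
        a ``ValueError`` is raised otherwise.  Ties are resolved by a
        deterministic traceback that pairs the leftmost position with its
        nearest admissible partner.
        """
        seq = to_rna(seq)
        n = len(seq)
        forced = tuple(sorted((min(a, b), max(a, b)) for a, b in forced_pairs))
        blocked = frozenset(unpairable)
        for a, b in forced:
            if not (0 <= a < b < n):
                raise ValueError(f"forced pair ({a}, {b}) out of range")
            if b - a <= self.min_loop:
                raise ValueError(f"forced pair ({a}, {b}) violates the minimum loop")
            if not can_pair(seq[a], seq[b]):
                raise ValueError(f"forced pair ({a}, {b}) is not complementary")
            if a in blocked or b in blocked:
                raise ValueError(f"forced pair ({a}, {b}) uses an unpairable position")
        for x in range(len(forced)):
            for y in range(x + 1, len(forced)):
                a, b = forced[x]
                c, d = forced[y]
                if len({a, b, c, d}) < 4 or self._crosses(c, d, a, b):
                    raise ValueError(f"forced pairs {forced[x]} and {forced[y]} are incompatible")

        S = self._score_matrix(seq, forced, blocked)
        E = self._fill(n, S)
        pairs = self._traceback(n, S, E)
        got = set(pairs)
        if not all(fp in got for fp in forced):
            raise AssertionError("optimal structure is missing a forced pair")
        return FoldResult(energy=float(E[0, n - 1]) if n else 0.0,
                          pairs=tuple(sorted(pairs)),
                          structure=dot_bracket(n, pairs))

    def _fill(self, n: int, S: np.ndarray) -> np.ndarray:
        E = np.zeros((n + 2, n + 2))
        ml = self.min_loop
        for span in range(ml + 1, n):
            for i in range(n - span):
                j = i + span
                ks = np.arange(i + ml + 1, j + 1)
                vals = S[i, ks] + E[i + 1, ks - 1] + E[ks + 1, j]
                best = vals.min()
                unpaired = E[i + 1, j]
                E[i, j] = best if best < unpaired else unpaired
        return E

    def _traceback(self, n: int, S: np.ndarray, E: np.ndarray) -> list[tuple[int, int]]:
        pairs: list[tuple[int, int]] = []
        stack = [(0, n - 1)] if n else []
        ml = self.min_loop
        while stack:
            i, j = stack.pop()
            while i < j - ml:
                target = E[i, j]
                chosen = None
                for k in range(i + ml + 1, j + 1):
                    if S[i, k] < np.inf and abs(S[i, k] + E[i + 1, k - 1] + E[k + 1, j] - target) < 1e-9:
                        chosen = k
                        break
                if chosen is None:
                    i += 1
                    continue
                pairs.append((i, chosen))
                if chosen + 1 <= j:
                    stack.append((chosen + 1, j))
                i, j = i + 1, chosen - 1
        return pairs


class ViennaRNAEvaluator:
    """Adapter running the RNAfold executable as the energy engine.

    Nearest-neighbour energies differ from the internal table, but the
    interface (fold with forced pairs / unpairable positions) is the same;
    constraints are passed through RNAfold's constraint syntax.
    """

    name = "vienna"

    def __init__(self, executable: str = "RNAfold"):
        if shutil.which(executable) is None:
            raise RuntimeError(f"{executable} not found on PATH")
        self.executable = executable
        self.min_loop = 3

    def fold(self, seq: str, forced_pairs: Sequence[tuple[int, int]] = (),
             unpairable: Iterable[int] = ()) -> FoldResult:
        seq = to_rna(seq)
        n = len(seq)
        constraint = ["."] * n
        for a, b in forced_pairs:
            a, b = min(a, b), max(a, b)
            constraint[a], constraint[b] = "(", ")"
        for x in unpairable:
            constraint[x] = "x"
        args = [self.executable, "--noPS"]
        use_constraint = bool(forced_pairs) or bool(list(unpairable))
        if use_constraint:
            args.append("-C")
        inp = seq + ("\n" + "".join(constraint) if use_constraint else "") + "\n"
        out = subprocess.run(args, input=inp, capture_output=True, text=True, check=True).stdout
        line = out.strip().splitlines()[-1]
        structure = line.split()[0]
        energy = float(line[line.rindex("(") + 1 : line.rindex(")")])
        return FoldResult(energy=energy, pairs=_pairs_from_dotbracket(structure),
                          structure=structure)


def _pairs_from_dotbracket(structure: str) -> tuple[tuple[int, int], ...]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    return tuple(sorted(pairs))


def get_evaluator(name: str = "internal"):
    if name == "internal":
        return InternalEvaluator()
    if name == "vienna":
        return ViennaRNAEvaluator()
    raise ValueError(f"unknown energy engine {name!r}")
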