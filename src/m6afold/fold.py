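"""RNA secondary-structure prediction under the simplified nearest-neighbor model.

Three entry points:

``fold_mfe``
    Minimum-free-energy structure via interval dynamic programming
    (Zuker-style V/M/W recurrences) with deterministic tie-breaking.
``subopt``
    *Complete*, duplicate-free enumeration of every structure within an
    energy window of the MFE (Wuchty-style backtracking with exact
    lower-bound pruning from the DP tables).
``enumerate_all_structures``
    Brute-force enumeration of every valid structure of a short sequence,
    scored by the independent loop-decomposition scorer
    (:func:`m6afold.energy.structure_energy`). Intended as a test oracle.

All energies are integer centi-kcal/mol internally; the public containers
carry kcal/mol floats and 1-based pair coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .energy import (DEFAULT_MODEL, EnergyModel, can_pair, pair_type,
                     structure_energy, two_loop_energy, validate_sequence)
from .errors import TruncationError, ValidationError
from .structure import SecondaryStructure

_INF = 10 ** 9
#: hard guard for the O(n^4) dynamic program
MAX_FOLD_LENGTH = 120
#: hard guard for brute-force enumeration
MAX_ENUM_LENGTH = 22


@dataclass
class SuboptEnsemble:
    """Suboptimal ensemble: structures sorted by (energy, dot-bracket)."""

    structures: list
    mfe: float
    window: float
    mode: str = "kcal"  # 'kcal' or 'percent'

    def __len__(self):
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    def __getitem__(self, idx):
        return self.structures[idx]


class _Fold:
    """DP tables and structure generators for one (sequence, model) pair."""

    def __init__(self, seq: str, model: EnergyModel):
        self.seq = seq
        self.model = model
        self.n = len(seq)
        self._fill()

    def _tau(self, i: int, j: int) -> int:
        return self.model.terminal_penalty(pair_type(self.seq[i], self.seq[j]))

    def _pairable(self, i: int, j: int) -> bool:
        return (j - i - 1 >= self.model.min_loop
                and can_pair(self.seq[i], self.seq[j]))

    def _fill(self) -> None:
        n, m = self.n, self.model
        ml, c, b = m.min_loop, m.ml_unpaired, m.ml_branch
        V = [[_INF] * n for _ in range(n)]
        M = [[_INF] * n for _ in range(n)]
        for span in range(1, n):
            for i in range(n - span):
                j = i + span
                if self._pairable(i, j):
                    best = m.hairpin_energy(j - i - 1) + self._tau(i, j)
                    # stack / bulge / internal loop
                    for k in range(i + 1, j - 1):
                        row = V[k]
                        for l in range(k + ml + 1, j):
                            if row[l] < _INF:
                                e = two_loop_energy(self.seq, m, i, j, k, l) + row[l]
                                if e < best:
                                    best = e
                    # multiloop closure, decomposed by the last branch (k, l)
                    base = m.ml_init + b + self._tau(i, j)
                    for k in range(i + 2, j - 1):
                        mi = M[i + 1][k - 1]
                        if mi >= _INF:
                            continue
                        row = V[k]
                        for l in range(k + ml + 1, j):
                            if row[l] < _INF:
                                e = (base + mi + b + self._tau(k, l) + row[l]
                                     + c * (j - 1 - l))
                                if e < best:
                                    best = e
                    V[i][j] = best
                # multiloop segment with >= 1 branch, anchored on position j
                bm = _INF
                if j - 1 >= i and M[i][j - 1] < _INF:
                    bm = M[i][j - 1] + c
                for k in range(i, j - ml):
                    if V[k][j] >= _INF:
                        continue
                    branch = b + self._tau(k, j) + V[k][j]
                    e = c * (k - i) + branch
                    if e < bm:
                        bm = e
                    if k - 1 >= i and M[i][k - 1] < _INF:
                        e = M[i][k - 1] + branch
                        if e < bm:
                            bm = e
                M[i][j] = bm
        self.V, self.M = V, M
        # exterior-loop minima
        W = [[0] * n for _ in range(n)]
        for j in range(n):
            for i in range(j, -1, -1):
                best = W[i + 1][j] if i + 1 <= j else 0
                for k in range(i + ml + 1, j + 1):
                    if V[i][k] < _INF:
                        e = V[i][k] + self._tau(i, k) + (W[k + 1][j] if k + 1 <= j else 0)
                        if e < best:
                            best = e
                W[i][j] = best
        self._Wtab = W

    def _w(self, i: int, j: int) -> int:
        return 0 if i > j else self._Wtab[i][j]

    @property
    def mfe(self) -> int:
        return self._w(0, self.n - 1)

    # -- complete enumeration within an absolute energy budget -------------
    # Each generator realises a *unique* decomposition of its structure
    # class, so the union of yields is duplicate-free by construction.

    def gen_w(self, i, j, budget):
        if i > j:
            yield (0, ())
            return
        ml = self.model.min_loop
        if self._w(i + 1, j) <= budget:
            yield from self.gen_w(i + 1, j, budget)
        for k in range(i + ml + 1, j + 1):
            if self.V[i][k] >= _INF:
                continue
            t = self._tau(i, k)
            rest = self._w(k + 1, j)
            if self.V[i][k] + t + rest > budget:
                continue
            for ev, pv in self.gen_v(i, k, budget - t - rest):
                for ew, pw in self.gen_w(k + 1, j, budget - t - ev):
                    yield (ev + t + ew, pv + pw)

    def gen_v(self, i, j, budget):
        if self.V[i][j] > budget:
            return
        m, ml = self.model, self.model.min_loop
        eh = m.hairpin_energy(j - i - 1) + self._tau(i, j)
        if eh <= budget:
            yield (eh, ((i, j),))
        for k in range(i + 1, j - 1):
            for l in range(k + ml + 1, j):
                if self.V[k][l] >= _INF:
                    continue
                e2 = two_loop_energy(self.seq, m, i, j, k, l)
                if e2 + self.V[k][l] > budget:
                    continue
                for ev, p in self.gen_v(k, l, budget - e2):
                    yield (e2 + ev, p + ((i, j),))
        base = m.ml_init + m.ml_branch + self._tau(i, j)
        c = m.ml_unpaired
        for k in range(i + 2, j - 1):
            mi = self.M[i + 1][k - 1]
            if mi >= _INF:
                continue
            for l in range(k + ml + 1, j):
                if self.V[k][l] >= _INF:
                    continue
                tail = c * (j - 1 - l)
                bt = m.ml_branch + self._tau(k, l)
                if base + mi + bt + self.V[k][l] + tail > budget:
                    continue
                for em, pm in self.gen_m(i + 1, k - 1,
                                         budget - base - bt - self.V[k][l] - tail):
                    for ev, pv in self.gen_v(k, l, budget - base - em - bt - tail):
                        yield (base + em + bt + ev + tail, pm + pv + ((i, j),))

    def gen_m(self, i, j, budget):
        if i > j or self.M[i][j] > budget:
            return
        m, ml, c = self.model, self.model.min_loop, self.model.ml_unpaired
        if j - 1 >= i and self.M[i][j - 1] + c <= budget:
            for e, p in self.gen_m(i, j - 1, budget - c):
                yield (e + c, p)
        for k in range(i, j - ml):
            if self.V[k][j] >= _INF:
                continue
            bt = m.ml_branch + self._tau(k, j)
            e0 = c * (k - i) + bt
            if e0 + self.V[k][j] <= budget:
                for ev, pv in self.gen_v(k, j, budget - e0):
                    yield (e0 + ev, pv)
            if k - 1 >= i and self.M[i][k - 1] < _INF:
                if self.M[i][k - 1] + bt + self.V[k][j] <= budget:
                    for em, pm in self.gen_m(i, k - 1, budget - bt - self.V[k][j]):
                        for ev, pv in self.gen_v(k, j, budget - bt - em):
                            yield (em + bt + ev, pm + pv)


def _to_structure(seq: str, pairs, energy_cc: int) -> SecondaryStructure:
    return SecondaryStructure(seq,
                              frozenset((i + 1, j + 1) for (i, j) in pairs),
                              energy_cc / 100.0)


def has_lonely_pair(structure: SecondaryStructure) -> bool:
    """True if any helix consists of a single, unstacked base pair."""
    ps = structure.pairs
    return any((i + 1, j - 1) not in ps and (i - 1, j + 1) not in ps
               for (i, j) in ps)


def _check_length(seq: str, limit: int) -> None:
    if len(seq) > limit:
        raise ValidationError(
            f"sequence of {len(seq)} nt exceeds the {limit}-nt guard")


def subopt(sequence: str, model: EnergyModel = DEFAULT_MODEL,
           window: float = 3.0, mode: str = "kcal",
           max_structures: int = 50_000,
           allow_lonely: bool = True) -> SuboptEnsemble:
    """Every valid structure within an energy window above the MFE.

    Parameters
    ----------
    window : float
        In ``mode='kcal'``, the absolute width in kcal/mol (the set of
        structures with E <= MFE + window). In ``mode='percent'``, the
        threshold is MFE + |MFE| * window / 100 — the convention used by
        percent-difference suboptimal folders, made explicit here because a
        percentage of a negative energy is otherwise ambiguous.
    max_structures : int
        Combinatorial-explosion guard; exceeding it raises TruncationError.
    allow_lonely : bool
        When False, structures containing isolated (unstacked) pairs are
        removed from the enumeration.
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    seq = validate_sequence(sequence)
    _check_length(seq, MAX_FOLD_LENGTH)
    fold = _Fold(seq, model)
    mfe = fold.mfe
    if mode == "kcal":
        thr = mfe + int(round(window * 100))
    elif mode == "percent":
        thr = mfe + int(round(abs(mfe) * window / 100.0))
    else:
        raise ValidationError(f"unknown window mode {mode!r}")
    raw = []
    for count, (e, pairs) in enumerate(fold.gen_w(0, len(seq) - 1, thr), start=1):
        if count > max_structures:
            raise TruncationError(
                f"suboptimal enumeration exceeded {max_structures} structures",
                count)
        raw.append((e, pairs))
    structures = [_to_structure(seq, p, e) for (e, p) in raw]
    if not allow_lonely:
        structures = [s for s in structures if not has_lonely_pair(s)]
    structures.sort(key=lambda s: (s.energy, s.dotbracket))
    return SuboptEnsemble(structures, mfe / 100.0, window, mode)


def fold_mfe(sequence: str, model: EnergyModel = DEFAULT_MODEL,
             allow_lonely: bool = True,
             max_structures: int = 50_000) -> SecondaryStructure:
    """Minimum-free-energy structure; ties break toward 5ʹ-most pairing.

    With ``allow_lonely=False`` the search widens the enumeration window
    until a lonely-pair-free structure appears (the empty structure at
    0 kcal/mol guarantees termination).
    """
    if allow_lonely:
        ens = subopt(sequence, model, window=0.0, max_structures=max_structures)
        return ens[0]
    width = 0.0
    while True:
        ens = subopt(sequence, model, window=width, allow_lonely=False,
                     max_structures=max_structures)
        if len(ens):
            return ens[0]
        width = max(1.0, width * 2)
        if ens.mfe + width > 1.0:  # past the empty structure; cannot happen
            raise RuntimeError("no lonely-pair-free structure found")


def enumerate_all_structures(sequence: str, model: EnergyModel = DEFAULT_MODEL,
                             max_len: int = MAX_ENUM_LENGTH) -> list:
    """Exhaustive brute-force enumeration of all valid structures.

    Recursively builds every non-crossing pair set that respects the allowed
    pair table and the hairpin minimum, scoring each with the independent
    loop-decomposition scorer. Guarded to short sequences; this is the test
    oracle for the dynamic program, not a production folder.
    """
    seq = validate_sequence(sequence)
    _check_length(seq, max_len)
    ml = model.min_loop

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if i >= j:
            return ((),)
        out = list(rec(i + 1, j))
        for k in range(i + ml + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        return tuple(out)

    structures = [_to_structure(seq, pairs, structure_energy(seq, pairs, model))
                  for pairs in rec(0, len(seq) - 1)]
    rec.cache_clear()
    structures.sort(key=lambda s: (s.energy, s.dotbracket))
    return structures
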