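"""Simplified nearest-neighbor free-energy model for RNA secondary structure.

The model assigns a free energy (kcal/mol at 37 °C) to any pseudoknot-free
structure by loop decomposition: stacking terms for adjacent base pairs,
length-dependent penalties for hairpin/bulge/internal loops, an affine
multiloop cost, and a terminal penalty for helix-closing AU/GU pairs.
Stacking is orientation-collapsed (keyed by the unordered pair types of the
two stacked pairs), which keeps the table small and automatically satisfies
the strand-reversal symmetry a physical stack must have.

Energies are stored as integer centi-kcal/mol so that suboptimal-ensemble
thresholds and set comparisons are exact; the public API reports kcal/mol.
This is deliberately a *simplified* Turner-style parameterization — it ranks
structures sensibly but does not reproduce any specific published table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

from .errors import ValidationError

RNA_ALPHABET = frozenset("ACGU")

#: canonical pair types, orientation collapsed
_PAIR_TYPE = {
    ("A", "U"): "AU", ("U", "A"): "AU",
    ("G", "C"): "GC", ("C", "G"): "GC",
    ("G", "U"): "GU", ("U", "G"): "GU",
}

# log-extrapolation coefficient ~ 1.75 * R * 310 K, in centi-kcal/mol
_LOOP_EXTRAP = 108


def pair_type(a: str, b: str) -> str | None:
    """Return 'AU', 'GC' or 'GU' for a canonical pair, else None."""
    return _PAIR_TYPE.get((a, b))


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIR_TYPE


def _default_stack() -> dict[str, int]:
    # unordered pair-type keys, centi-kcal/mol
    return {
        "AU:AU": -110, "AU:GC": -220, "AU:GU": -80,
        "GC:GC": -330, "GC:GU": -150, "GU:GU": -50,
    }


def _default_hairpin() -> dict[int, int]:
    return {3: 540, 4: 560, 5: 570, 6: 540, 7: 600, 8: 550, 9: 640}


def _default_bulge() -> dict[int, int]:
    return {1: 380, 2: 280, 3: 320, 4: 360, 5: 400, 6: 440}


def _default_internal() -> dict[int, int]:
    return {2: 150, 3: 220, 4: 280, 5: 320, 6: 360}


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor parameter set (all energies integer centi-kcal/mol)."""

    stack: dict[str, int] = field(default_factory=_default_stack)
    hairpin: dict[int, int] = field(default_factory=_default_hairpin)
    bulge: dict[int, int] = field(default_factory=_default_bulge)
    internal: dict[int, int] = field(default_factory=_default_internal)
    internal_asym: int = 60          # per nt of |n1 - n2|
    internal_asym_max: int = 300
    ml_init: int = 340               # multiloop initiation
    ml_branch: int = 40              # per branch, including the closing pair
    ml_unpaired: int = 10            # per unpaired nt inside a multiloop
    terminal_au: int = 50            # helix-terminal AU or GU penalty
    min_loop: int = 3                # minimum unpaired nt in a hairpin loop
    version: str = "m6afold-simple-nn-1"

    # -- term lookups ------------------------------------------------------

    def stack_energy(self, outer: str, inner: str) -> int:
        """Stacking term for pair types `outer` on `inner` ('AU'/'GC'/'GU')."""
        key = ":".join(sorted((outer, inner)))
        return self.stack[key]

    def _looked_up(self, table: dict[int, int], n: int) -> int:
        if n in table:
            return table[n]
        nmax = max(table)
        return table[nmax] + int(round(_LOOP_EXTRAP * math.log(n / nmax)))

    def hairpin_energy(self, n: int) -> int:
        if n < self.min_loop:
            raise ValidationError(f"hairpin loop of {n} nt below min_loop={self.min_loop}")
        return self._looked_up(self.hairpin, n)

    def bulge_energy(self, n: int) -> int:
        return self._looked_up(self.bulge, n)

    def internal_energy(self, n1: int, n2: int) -> int:
        base = self._looked_up(self.internal, n1 + n2)
        asym = min(self.internal_asym * abs(n1 - n2), self.internal_asym_max)
        return base + asym

    def terminal_penalty(self, ptype: str) -> int:
        return self.terminal_au if ptype in ("AU", "GU") else 0

    # -- (de)serialization -------------------------------------------------

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("hairpin", "bulge", "internal"):
            d[k] = {str(n): v for n, v in d[k].items()}
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EnergyModel":
        d = json.loads(text)
        for k in ("hairpin", "bulge", "internal"):
            d[k] = {int(n): v for n, v in d[k].items()}
        return cls(**d)


DEFAULT_MODEL = EnergyModel()


def validate_sequence(sequence: str) -> str:
    """Uppercase, T→U, and check the RNA alphabet; returns the normalized string."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def two_loop_energy(seq: str, model: EnergyModel, i: int, j: int, k: int, l: int) -> int:
    """Energy of the loop between closing pair (i,j) and interior pair (k,l).

    0-based indices with i < k < l < j. Covers stacks (n1 = n2 = 0), bulges
    and internal loops. Length-1 bulges retain the flanking stack and carry
    no terminal penalty; larger loops add terminal penalties for both pairs.
    """
    n1 = k - i - 1
    n2 = j - l - 1
    po = pair_type(seq[i], seq[j])
    pi = pair_type(seq[k], seq[l])
    if po is None or pi is None:
        raise ValidationError("two_loop_energy called on non-canonical pair")
    if n1 == 0 and n2 == 0:
        return model.stack_energy(po, pi)
    if n1 == 0 or n2 == 0:
        n = n1 + n2
        e = model.bulge_energy(n)
        if n == 1:
            return e + model.stack_energy(po, pi)
        return e + model.terminal_penalty(po) + model.terminal_penalty(pi)
    return (model.internal_energy(n1, n2)
            + model.terminal_penalty(po) + model.terminal_penalty(pi))


def structure_energy(seq: str, pairs, model: EnergyModel = DEFAULT_MODEL) -> int:
    """Score a complete structure by loop decomposition (centi-kcal/mol).

    `pairs` is an iterable of 0-based (i, j) tuples, i < j. This scorer walks
    the loop tree of the given pair set directly and is independent of the
    dynamic-programming recurrences in :mod:`m6afold.fold`, which makes it
    usable as an oracle against them. The empty structure scores 0.
    """
    pairs = sorted(pairs)
    if not pairs:
        return 0
    partner = {}
    for (i, j) in pairs:
        partner[i] = j
        partner[j] = i

    def children_of(lo: int, hi: int) -> tuple[list[tuple[int, int]], int]:
        """Maximal pairs directly inside [lo, hi]; also count of unpaired nt."""
        kids, unpaired, p = [], 0, lo
        while p <= hi:
            if p in partner and partner[p] > p:
                kids.append((p, partner[p]))
                p = partner[p] + 1
            else:
                unpaired += 1
                p += 1
        return kids, unpaired

    total = 0
    # exterior loop: terminal penalties only
    top, _ = children_of(0, len(seq) - 1)
    for (i, j) in top:
        total += model.terminal_penalty(pair_type(seq[i], seq[j]))

    stack_ = list(top)
    while stack_:
        i, j = stack_.pop()
        kids, unpaired = children_of(i + 1, j - 1)
        po = pair_type(seq[i], seq[j])
        if po is None:
            raise ValidationError(f"non-canonical pair {seq[i]}-{seq[j]} not scorable")
        if not kids:
            total += model.hairpin_energy(j - i - 1) + model.terminal_penalty(po)
        elif len(kids) == 1:
            total += two_loop_energy(seq, model, i, j, *kids[0])
        else:
            total += (model.ml_init
                      + model.ml_branch * (1 + len(kids))
                      + model.ml_unpaired * unpaired
                      + model.terminal_penalty(po))
            for (k, l) in kids:
                total += model.terminal_penalty(pair_type(seq[k], seq[l]))
        stack_.extend(kids)
    return total
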