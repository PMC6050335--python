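"""Secondary-structure container plus Vienna dot-bracket and CT file adapters.

Coordinates in :class:`SecondaryStructure` are 1-based and fully closed
throughout the package (position 1 is the first nucleotide; a pair (i, j)
includes both endpoints). Internally the folding engine works 0-based and
converts at this boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .energy import can_pair, validate_sequence
from .errors import ParseError, ValidationError


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA sequence with a non-crossing set of base pairs and an energy.

    Parameters
    ----------
    sequence : str
        RNA string over {A, C, G, U}.
    pairs : frozenset of (int, int)
        1-based pairs with i < j.
    energy : float or None
        Free energy in kcal/mol; None for imported structures without one.
    modified : tuple of int
        1-based positions carrying an N6-methyl mark (m6A). The flag does not
        change pairing legality — m6A pairs as A.
    """

    sequence: str
    pairs: frozenset = frozenset()
    energy: float | None = None
    modified: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))

    # -- derived views -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.sequence)

    def partner_map(self) -> dict[int, int]:
        """1-based position → 1-based partner, for paired positions only."""
        out = {}
        for (i, j) in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def is_paired(self, i: int) -> bool:
        return i in self.partner_map()

    # -- validation --------------------------------------------------------

    def validate(self, min_loop: int = 3, canonical_only: bool = True) -> None:
        """Check pair-set invariants; raises ValidationError on the first failure."""
        seen = set()
        ordered = sorted(self.pairs)
        for (i, j) in ordered:
            if not (1 <= i < j <= self.n):
                raise ValidationError(f"pair ({i},{j}) out of range for length {self.n}")
            if i in seen or j in seen:
                raise ValidationError(f"position in more than one pair near ({i},{j})")
            seen.update((i, j))
            if canonical_only and not can_pair(self.sequence[i - 1], self.sequence[j - 1]):
                raise ValidationError(
                    f"pair ({i},{j}) {self.sequence[i-1]}-{self.sequence[j-1]} not allowed")
        # crossing check
        for a, (i, j) in enumerate(ordered):
            for (k, l) in ordered[a + 1:]:
                if k >= j:
                    break
                if i < k < j < l:
                    raise ValidationError(f"crossing pairs ({i},{j}) and ({k},{l})")
        # hairpin min_loop: pairs with no enclosed pair
        partner = self.partner_map()
        for (i, j) in ordered:
            if not any(i < k < j for k in partner):
                if j - i - 1 < min_loop:
                    raise ValidationError(
                        f"hairpin closed by ({i},{j}) has {j-i-1} nt < min_loop={min_loop}")

    # -- dot-bracket -------------------------------------------------------

    @property
    def dotbracket(self) -> str:
        chars = ["."] * self.n
        for (i, j) in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    @classmethod
    def from_dotbracket(cls, sequence: str, db: str,
                        energy: float | None = None) -> "SecondaryStructure":
        sequence = validate_sequence(sequence)
        if len(db) != len(sequence):
            raise ParseError(
                f"structure length {len(db)} != sequence length {len(sequence)}")
        stack, pairs = [], []
        for pos, c in enumerate(db, start=1):
            if c == "(":
                stack.append(pos)
            elif c == ")":
                if not stack:
                    raise ParseError(f"unbalanced ')' at position {pos}")
                pairs.append((stack.pop(), pos))
            elif c != ".":
                raise ParseError(f"illegal character {c!r} at position {pos}")
        if stack:
            raise ParseError(f"unbalanced '(' at position {stack[-1]}")
        return cls(sequence, frozenset(pairs), energy)

    def to_vienna(self) -> str:
        """Sequence line + structure line with optional ' (energy)' suffix."""
        suffix = f" ({self.energy:.2f})" if self.energy is not None else ""
        return f"{self.sequence}\n{self.dotbracket}{suffix}"


_ENERGY_RE = re.compile(r"^([.()]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def parse_vienna(text: str) -> list[SecondaryStructure]:
    """Parse Vienna-style records: optional '>name', sequence line, then one
    or more structure lines (each optionally suffixed with '(energy)')."""
    lines = [ln.rstrip() for ln in text.splitlines()]
    out: list[SecondaryStructure] = []
    seq = None
    for lineno, ln in enumerate(lines, start=1):
        if not ln or ln.startswith(">"):
            seq = None if ln.startswith(">") else seq
            continue
        token = ln.split()[0]
        if set(token.upper()) <= set("ACGUTN"):
            seq = token
            continue
        # anything else is a structure line; bad characters become ParseErrors
        if seq is None:
            raise ParseError("structure line before any sequence line", lineno)
        m = _ENERGY_RE.match(ln)
        if m:
            db, energy = m.group(1), float(m.group(2))
        else:
            db, energy = token, None
        try:
            out.append(SecondaryStructure.from_dotbracket(seq, db, energy))
        except ParseError as e:
            raise ParseError(str(e), lineno) from None
    return out


# -- CT format -------------------------------------------------------------

def write_ct(structures: Iterable[SecondaryStructure], path: str | Path) -> None:
    """Write structures in the standard 6-column CT layout."""
    with open(path, "w") as fh:
        for s in structures:
            energy = f" energy = {s.energy:.2f}" if s.energy is not None else ""
            fh.write(f"{s.n}{energy}\n")
            partner = s.partner_map()
            for i in range(1, s.n + 1):
                nxt = i + 1 if i < s.n else 0
                fh.write(f"{i}\t{s.sequence[i-1]}\t{i-1}\t{nxt}\t{partner.get(i, 0)}\t{i}\n")


def read_ct(path: str | Path) -> list[SecondaryStructure]:
    """Read one or more concatenated CT records."""
    lines = Path(path).read_text().splitlines()
    out: list[SecondaryStructure] = []
    idx = 0
    while idx < len(lines):
        header = lines[idx].strip()
        if not header:
            idx += 1
            continue
        try:
            n = int(header.split()[0])
        except ValueError:
            raise ParseError(f"expected CT header with length, got {header!r}", idx + 1)
        m = re.search(r"energy\s*=\s*(-?\d+(?:\.\d+)?)", header, re.IGNORECASE)
        energy = float(m.group(1)) if m else None
        body = lines[idx + 1: idx + 1 + n]
        if len(body) < n:
            raise ParseError(f"CT record truncated: expected {n} rows", idx + 1)
        seq_chars, pairs = [], set()
        for off, row in enumerate(body):
            fields = row.split()
            if len(fields) < 6:
                raise ParseError("CT row has fewer than 6 columns", idx + 2 + off)
            i, base, p = int(fields[0]), fields[1], int(fields[4])
            if i != off + 1:
                raise ParseError(f"CT row index {i} out of order", idx + 2 + off)
            seq_chars.append(base)
            if p:
                if not (1 <= p <= n):
                    raise ParseError(f"pair index {p} out of range", idx + 2 + off)
                pairs.add((min(i, p), max(i, p)))
        out.append(SecondaryStructure("".join(seq_chars), frozenset(pairs), energy))
        idx += 1 + n
    return out


def import_structures(path: str | Path, fmt: str = "dotbracket",
                      min_loop: int = 3) -> list[SecondaryStructure]:
    """Load externally predicted structures (Vienna dot-bracket or CT).

    Imported structures may contain non-canonical pairs (some predictors emit
    mismatches), so only pairing *consistency* (non-crossing, single partner,
    min_loop) is validated here.
    """
    if fmt == "dotbracket":
        structures = parse_vienna(Path(path).read_text())
    elif fmt == "ct":
        structures = read_ct(path)
    else:
        raise ValidationError(f"unknown structure format {fmt!r}")
    for s in structures:
        s.validate(min_loop=min_loop, canonical_only=False)
    return structures
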