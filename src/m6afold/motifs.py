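"""Classification of a focal adenosine's secondary-structure context.

Every structure maps to exactly one of eight categories describing the
methylation site (the focal A):

``duplex_AU`` / ``duplex_AY``
    A paired (to U, or to a non-U base Y) inside a helix — both flanking
    stacks intact.
``fiveB_AU`` / ``fiveB_AY``
    junctional A–U / A–Y pair with >= 1 unpaired (bulged) nucleotide
    immediately 5ʹ of the A. This is the motif that methylation stabilizes.
``AU_threeB`` / ``AY_threeB``
    junctional pair with the bulge immediately 3ʹ of the A.
``partner_bulge``
    junctional pair with the bulge adjacent to the partner nucleotide
    (on the opposite strand) rather than the A.
``unpaired``
    A without a partner (loop, bulge, single strand).

Engines that only emit canonical pairs never pair A with a non-U base; for
those, an unpaired A facing exactly one unpaired nucleotide across an
internal loop, immediately adjacent to a canonical pair, is *imputed* as an
A–Y mismatch (the standard workaround for predictors that reject
mismatches). The per-category ΔΔG tables translate hairpin melting
measurements into energy offsets used to re-rank suboptimal ensembles as if
the focal A were methylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from .energy import pair_type
from .errors import ValidationError
from .fold import SuboptEnsemble
from .structure import SecondaryStructure

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MotifCategory(str, Enum):
    DUPLEX_AU = "duplex_AU"
    DUPLEX_AY = "duplex_AY"
    UNPAIRED = "unpaired"
    FIVEB_AU = "fiveB_AU"
    FIVEB_AY = "fiveB_AY"
    AU_THREEB = "AU_threeB"
    AY_THREEB = "AY_threeB"
    PARTNER_BULGE = "partner_bulge"


#: categories counted toward the 5ʹ-bulge motif with any partner base
FIVEB_ANY = (MotifCategory.FIVEB_AU, MotifCategory.FIVEB_AY)


@dataclass(frozen=True)
class MotifCall:
    """Category assignment of the focal A within one structure."""

    category: MotifCategory
    a_index: int                 # 1-based
    partner: int | None = None   # 1-based, None iff no (real or imputed) pair
    partner_base: str | None = None
    junctional: bool = False
    bulge_side: str = "none"     # '5p_of_a', '3p_of_a', 'partner', 'none'
    bulge_len: int = 0
    imputed: bool = False        # partner assigned by mismatch imputation


@dataclass(frozen=True)
class SiteWindow:
    """A window of transcript sequence centered (by convention) on one A."""

    sequence: str
    a_index: int                 # 1-based position of the focal A
    source_id: str = ""
    source_pos: int | None = None  # 1-based coordinate on the source strand
    strand: str = "+"

    def __post_init__(self):
        if not (1 <= self.a_index <= len(self.sequence)):
            raise ValidationError("a_index outside window")
        if self.sequence[self.a_index - 1] != "A":
            raise ValidationError(
                f"window base at a_index is {self.sequence[self.a_index - 1]!r}, not A")

    @property
    def length(self) -> int:
        return len(self.sequence)


class WindowOutOfBounds(ValidationError):
    """Site too close to a transcript end to host the requested window."""


def extract_window(transcript: str, position: int, length: int = 41,
                   a_offset: int = 21, transcript_id: str = "",
                   strand: str = "+") -> SiteWindow:
    """Cut a window of `length` nt with the site A at position `a_offset`.

    `position` is 1-based on the forward strand; minus-strand sites are
    extracted from the reverse complement (coordinates flipped accordingly).
    Raises WindowOutOfBounds when the window does not fit, and
    ValidationError when the addressed base is not an A.
    """
    if strand not in ("+", "-"):
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    if not (1 <= position <= len(transcript)):
        raise ValidationError(f"position {position} outside transcript")
    seq = transcript
    if strand == "-":
        seq = reverse_complement(transcript)
        position = len(transcript) - position + 1
    if seq[position - 1] != "A":
        raise ValidationError(
            f"base at site {position} ({strand}) is {seq[position-1]!r}, not A")
    start = position - (a_offset - 1)
    end = start + length - 1
    if start < 1 or end > len(seq):
        raise WindowOutOfBounds(
            f"window [{start},{end}] out of bounds for transcript of {len(seq)} nt")
    return SiteWindow(seq[start - 1:end], a_offset, transcript_id, position, strand)


# -- classification --------------------------------------------------------

def _unpaired_run(partner: dict, n: int, start: int, step: int) -> int:
    """Length of the unpaired run from `start` moving by `step`."""
    run, p = 0, start
    while 1 <= p <= n and p not in partner:
        run += 1
        p += step
    return run


def _impute_mismatch(structure: SecondaryStructure, a: int,
                     partner: dict) -> int | None:
    """Partner position for an unpaired A facing a 1-nt gap across a pair.

    The A must be immediately adjacent to a pair; the position directly
    across that pair must be unpaired and be the *only* unpaired position in
    its run (a 1-nt internal-loop face). When both neighbors qualify the 3ʹ
    one wins (the motif's stacking partner).
    """
    n = structure.n
    for q in (a + 1, a - 1):
        if not (1 <= q <= n) or q not in partner:
            continue
        p = partner[q]
        if pair_type(structure.sequence[q - 1], structure.sequence[p - 1]) is None:
            continue
        f = p - (a - q)
        if not (1 <= f <= n) or f in partner:
            continue
        if f - 1 >= 1 and f + 1 <= n and (f - 1) in partner and (f + 1) in partner:
            return f
    return None


def classify_motif(structure: SecondaryStructure, a_index: int) -> MotifCall:
    """Assign the focal A of one structure to exactly one motif category.

    Decision order: pairing status (with mismatch imputation for unpaired
    A's facing a 1-nt internal-loop gap) → junctional test (either flanking
    stack broken) → bulge side with precedence 5ʹ-of-A > 3ʹ-of-A > partner
    side. A junctional pair with no unpaired flank at all (e.g. a helix end
    at the molecule boundary) stays in the duplex category, with the
    junctional flag set.
    """
    n = structure.n
    if not (1 <= a_index <= n):
        raise ValidationError(f"a_index {a_index} outside structure of {n} nt")
    if structure.sequence[a_index - 1] != "A":
        raise ValidationError(
            f"base at a_index is {structure.sequence[a_index - 1]!r}, not A")
    partner = structure.partner_map()
    a = a_index
    imputed = False
    if a in partner:
        j = partner[a]
    else:
        j = _impute_mismatch(structure, a, partner)
        if j is None:
            return MotifCall(MotifCategory.UNPAIRED, a)
        imputed = True
    pbase = structure.sequence[j - 1]
    au = pbase == "U"

    # junctional iff either flanking stack of the (possibly imputed) pair
    # (i, j) is broken: inner (i+1, j-1) and outer (i-1, j+1) both present?
    lo, hi = min(a, j), max(a, j)
    inner_ok = partner.get(lo + 1) == hi - 1
    outer_ok = partner.get(lo - 1) == hi + 1
    junctional = not (inner_ok and outer_ok)

    def call(cat, side="none", blen=0):
        return MotifCall(cat, a, j, pbase, junctional, side, blen, imputed)

    if not junctional:
        return call(MotifCategory.DUPLEX_AU if au else MotifCategory.DUPLEX_AY)

    # note: for imputed pairs the A-side runs can never reach the imputed
    # partner (the adjacent real pair separates the two loop faces), and the
    # partner-side runs are empty by the imputation condition (f±1 paired)
    five_len = _unpaired_run(partner, n, a - 1, -1)
    three_len = _unpaired_run(partner, n, a + 1, +1)
    if five_len:
        cat = MotifCategory.FIVEB_AU if au else MotifCategory.FIVEB_AY
        return call(cat, "5p_of_a", five_len)
    if three_len:
        cat = MotifCategory.AU_THREEB if au else MotifCategory.AY_THREEB
        return call(cat, "3p_of_a", three_len)
    p5 = _unpaired_run(partner, n, j - 1, -1)
    p3 = _unpaired_run(partner, n, j + 1, +1)
    if p5 or p3:
        return call(MotifCategory.PARTNER_BULGE, "partner", max(p5, p3))
    cat = MotifCategory.DUPLEX_AU if au else MotifCategory.DUPLEX_AY
    return call(cat)


# -- methylation-aware re-ranking ------------------------------------------

@dataclass(frozen=True)
class M6APenaltyTable:
    """Per-category ΔΔG offsets (kcal/mol) applied when the focal A is m6A.

    Signed convention: negative = methylation stabilizes the structure.
    Values derive from hairpin melting contrasts of designed constructs;
    applying them to arbitrary sequence contexts is an approximation, which
    is recorded in the `approximate` field for downstream metadata.
    """

    offsets: dict = field(default_factory=dict)
    condition: str = "with_mg"
    approximate: bool = True

    def offset(self, category: MotifCategory) -> float:
        return float(self.offsets.get(MotifCategory(category), 0.0))


#: measured at 37 °C in 3 mM Mg2+ (hairpin constructs)
PENALTIES_WITH_MG = M6APenaltyTable(
    offsets={
        MotifCategory.FIVEB_AU: -0.9,
        MotifCategory.DUPLEX_AU: +0.6,
        MotifCategory.AU_THREEB: +1.2,
        MotifCategory.UNPAIRED: +0.7,
        MotifCategory.PARTNER_BULGE: +0.4,
    },
    condition="with_mg")

#: measured at 37 °C without Mg2+; categories not re-measured keep the
#: with-Mg2+ value where the underlying study found similar behaviour
PENALTIES_NO_MG = M6APenaltyTable(
    offsets={
        MotifCategory.FIVEB_AU: -0.3,
        MotifCategory.DUPLEX_AU: +0.8,
        MotifCategory.AU_THREEB: +1.2,
        MotifCategory.UNPAIRED: +0.7,
        MotifCategory.PARTNER_BULGE: +1.4,
    },
    condition="no_mg")


@dataclass(frozen=True)
class RerankResult:
    ensemble: SuboptEnsemble
    mfe_changed: bool
    original_best: SecondaryStructure
    new_best: SecondaryStructure
    approximate: bool = True


def rerank_with_m6a(ensemble: SuboptEnsemble, a_index: int,
                    penalties: M6APenaltyTable = PENALTIES_WITH_MG) -> RerankResult:
    """Apply per-category m6A ΔΔG offsets and re-sort the ensemble.

    Models the energetic bias of methylation: structures presenting the A in
    a 5ʹ-bulge junction gain stability relative to duplex/bulge contexts, so
    a higher-energy junctional structure can overtake the unmethylated MFE.
    """
    if not len(ensemble):
        raise ValidationError("cannot re-rank an empty ensemble")
    adjusted = []
    for s in ensemble:
        cat = classify_motif(s, a_index).category
        adjusted.append(replace(s, energy=round(s.energy + penalties.offset(cat), 6),
                                modified=(a_index,)))
    adjusted.sort(key=lambda s: (s.energy, s.dotbracket))
    old_best = ensemble[0]
    new_best = adjusted[0]
    changed = new_best.pairs != old_best.pairs
    new_ens = SuboptEnsemble(adjusted, adjusted[0].energy,
                             ensemble.window, ensemble.mode)
    return RerankResult(new_ens, changed, old_best, new_best,
                        approximate=penalties.approximate)
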