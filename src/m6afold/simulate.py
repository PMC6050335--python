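"""Seeded generators for every input the analysis stages consume.

These emulate the study's data-generating conditions: folded-fraction
melting curves on an 81-point 15–95 °C grid with Gaussian noise
(σ = 0.01 fraction units by default), anisotropy titrations of 2 nM labeled
RNA with σ = 0.002, transcript-like random sequences with planted DRACH
consensus sites, and designed hairpin windows whose minimum-free-energy
structure realises a requested motif category (ground-truth labels
attached). All generators are pure functions of their spec: the same seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .binding import TitrationCurve, anisotropy_one_site, anisotropy_two_site
from .errors import ValidationError
from .melt import MeltingCurve, fraction_folded_duplex, fraction_folded_hairpin
from .motifs import MotifCategory, SiteWindow
from .structure import SecondaryStructure
from .survey import DRACH_RE


@dataclass(frozen=True)
class GeneratorSpec:
    """Reproducibility contract for a generator: seed, size, noise level."""

    seed: int
    n: int = 1
    sigma: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.n < 0:
            raise ValidationError("n must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# -- biophysics curves -----------------------------------------------------

def gen_melting_curve(spec: GeneratorSpec, model: str, tm: float, dh: float,
                      ct: float | None = None,
                      t_min_c: float = 15.0, t_max_c: float = 95.0,
                      n_points: int = 81) -> MeltingCurve:
    """Folded-fraction melting curve on a uniform Celsius grid plus noise."""
    if model == "duplex":
        fn = fraction_folded_duplex
        if ct is None:
            raise ValidationError("duplex generator requires ct")
    elif model == "hairpin":
        fn = fraction_folded_hairpin
    else:
        raise ValidationError(f"unknown melting model {model!r}")
    T = np.linspace(t_min_c, t_max_c, n_points) + 273.15
    y = fn(T, tm, dh)
    if spec.sigma > 0:
        y = y + spec.rng().normal(0.0, spec.sigma, size=y.shape)
    return MeltingCurve(T, y, signal_kind="fraction", ct=ct)


def gen_titration(spec: GeneratorSpec, model: str, params: dict,
                  rt: float, conc_grid) -> TitrationCurve:
    """Anisotropy titration from the one- or two-site model plus noise.

    ``params``: one_site needs {kd, a, b}; two_site needs {kd1, kd2, a, b, c}.
    A zero-protein point is prepended if the grid lacks one.
    """
    lt = np.sort(np.asarray(conc_grid, dtype=float))
    if lt[0] > 0:
        lt = np.concatenate(([0.0], lt))
    if model == "one_site":
        at = anisotropy_one_site(lt, rt, params["kd"], params["a"], params["b"])
    elif model == "two_site":
        at = anisotropy_two_site(lt, params["kd1"], params["kd2"],
                                 params["a"], params["b"], params["c"])
    else:
        raise ValidationError(f"unknown binding model {model!r}")
    if spec.sigma > 0:
        at = at + spec.rng().normal(0.0, spec.sigma, size=at.shape)
    return TitrationCurve(lt, at, rt)


# -- transcript-like sequences ---------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGU"))[rng.choice(4, size=length, p=p)])


def _random_drach(rng: np.random.Generator) -> str:
    return ("AGU"[rng.integers(3)] + "AG"[rng.integers(2)] + "AC"
            + "ACU"[rng.integers(3)])


def gen_transcripts(spec: GeneratorSpec, n_transcripts: int,
                    length: int = 500, drach_density: float = 0.004,
                    gc: float = 0.5):
    """Random transcripts with DRACH 5-mers planted at recorded positions.

    ``drach_density`` is planted sites per nucleotide; the recorded site is
    the A of the AC core (third position of the 5-mer). Returns
    (transcripts: dict id→sequence, sites: list of (id, position, strand)).
    """
    if drach_density < 0:
        raise ValidationError("drach_density must be >= 0")
    n_sites = int(round(drach_density * length))
    if n_sites * 10 > length:
        raise ValidationError(
            f"drach_density {drach_density} too high for length {length}")
    rng = spec.rng()
    transcripts: dict[str, str] = {}
    sites: list[tuple[str, int, str]] = []
    for t in range(n_transcripts):
        tid = f"synthetic_tx_{t+1:04d}"
        seq = list(_random_seq(rng, length, gc))
        placed: list[int] = []
        attempts = 0
        while len(placed) < n_sites and attempts < 100 * max(n_sites, 1):
            attempts += 1
            start = int(rng.integers(0, length - 4))
            if any(abs(start - p) < 5 for p in placed):
                continue
            seq[start:start + 5] = _random_drach(rng)
            placed.append(start)
        if len(placed) < n_sites:
            raise ValidationError(
                f"could not place {n_sites} non-overlapping DRACH sites")
        transcripts[tid] = "".join(seq)
        sites.extend((tid, start + 3, "+") for start in sorted(placed))
    return transcripts, sites


# -- designed motif windows ------------------------------------------------

#: category → (sequence, designed dot-bracket, 1-based focal-A index).
#: Each design's minimum-free-energy structure under the default model is
#: the designed structure (asserted in the test suite); the A–Y categories
#: rely on mismatch imputation across a 1-nt internal-loop face.
MOTIF_TEMPLATES: dict[MotifCategory, tuple[str, str, int]] = {
    MotifCategory.FIVEB_AU:      ("GGCGACUUUCGAGUGCC",   "(((.(((....))))))", 5),
    MotifCategory.DUPLEX_AU:     ("GGCAGCUUCGGCUGCC",    "((((((....))))))", 4),
    MotifCategory.UNPAIRED:      ("GGCGCUAAUGCGCC",      "(((((....)))))", 7),
    MotifCategory.AU_THREEB:     ("GGCAGCUCUUCGGAGUGCC", "((((.(((....)))))))", 4),
    MotifCategory.PARTNER_BULGE: ("GGCACUCGAAAGUCGCC",   "((((((....))).)))", 4),
    MotifCategory.DUPLEX_AY:     ("GGCAGCUUCGGCCGCC",    "(((.((....)).)))", 4),
    MotifCategory.FIVEB_AY:      ("GGCAAGCUUCGGCCGCC",   "(((..((....)).)))", 5),
    MotifCategory.AY_THREEB:     ("GGCAAGCUUCGGCCGCC",   "(((..((....)).)))", 4),
}


@dataclass(frozen=True)
class MotifFixture:
    """A designed window with its ground-truth structure and category."""

    window: SiteWindow
    structure: SecondaryStructure
    category: MotifCategory


def _allocate(n: int, fractions: dict) -> dict:
    """Largest-remainder allocation of n items to the requested mix."""
    cats = sorted(fractions, key=lambda c: MotifCategory(c).value)
    raw = {c: n * float(fractions[c]) for c in cats}
    counts = {c: int(np.floor(raw[c])) for c in cats}
    rest = n - sum(counts.values())
    for c in sorted(cats, key=lambda c: (raw[c] - counts[c]), reverse=True)[:rest]:
        counts[c] += 1
    return counts


def gen_motif_windows(spec: GeneratorSpec,
                      category_mix: dict) -> list[MotifFixture]:
    """`spec.n` labeled window fixtures in the requested category mix.

    Allocation is deterministic (largest remainder); the order of the output
    is a seeded shuffle so downstream consumers cannot rely on grouping.
    """
    total = float(sum(category_mix.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"category fractions sum to {total}, not 1")
    counts = _allocate(spec.n, category_mix)
    fixtures: list[MotifFixture] = []
    for cat, k in counts.items():
        cat = MotifCategory(cat)
        seq, db, a = MOTIF_TEMPLATES[cat]
        st = SecondaryStructure.from_dotbracket(seq, db)
        for i in range(k):
            w = SiteWindow(seq, a, source_id=f"{cat.value}_{i+1:03d}")
            fixtures.append(MotifFixture(w, st, cat))
    rng = spec.rng()
    order = rng.permutation(len(fixtures))
    return [fixtures[i] for i in order]


def gen_motif_transcriptome(spec: GeneratorSpec, category_mix: dict,
                            spacer: int = 24):
    """Transcripts built from motif templates separated by poly-A spacers.

    Poly-A spacers cannot pair among themselves and cannot out-compete the
    designed stems, so a 41-nt window around each planted site folds into
    the template's designed structure. Returns (transcripts, sites,
    categories) with sites in the (id, position, '+') site-list dialect —
    the ground truth for end-to-end survey recovery.
    """
    fixtures = gen_motif_windows(spec, category_mix)
    pad = "A" * spacer
    transcripts: dict[str, str] = {}
    sites: list[tuple[str, int, str]] = []
    categories: list[MotifCategory] = []
    per_tx = 5
    for t in range(0, len(fixtures), per_tx):
        tid = f"motif_tx_{t // per_tx + 1:04d}"
        parts, pos = [pad], len(pad)
        for fx in fixtures[t:t + per_tx]:
            sites.append((tid, pos + fx.window.a_index, "+"))
            categories.append(fx.category)
            parts.append(fx.window.sequence)
            pos += len(fx.window.sequence)
            parts.append(pad)
            pos += len(pad)
        transcripts[tid] = "".join(parts)
    return transcripts, sites, categories
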