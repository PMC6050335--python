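"""Site-set surveys: motif populations across energy thresholds.

For each methylation-site window the lowest-energy structure determines the
MFE-mode category counts; in threshold mode a site counts toward the
5ʹ-bulge motif (``fiveB_AU``, or ``fiveB_AX`` = any partner base) if *any*
structure within the energy window exhibits it. Fractions are counts over
the number of surveyed sites, so threshold-mode fractions are monotone
non-decreasing in the window width by set inclusion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .energy import DEFAULT_MODEL, EnergyModel
from .errors import ValidationError
from .fold import SuboptEnsemble, subopt
from .motifs import FIVEB_ANY, MotifCategory, SiteWindow, classify_motif

#: m6A consensus 5-mer: D = A/G/U, R = A/G, then the AC core, H = A/C/U
DRACH_RE = re.compile(r"[AGU][AG]AC[ACU]")


def has_drach(sequence: str) -> bool:
    return DRACH_RE.search(sequence) is not None


@dataclass(frozen=True)
class SurveyResult:
    """Per-category populations for one site set at one energy threshold."""

    n_sites: int
    threshold: float | None            # kcal/mol above MFE; None = MFE only
    category_counts: dict = field(default_factory=dict)
    fiveB_AU_fraction: float = 0.0     # junctional A–U with 5ʹ bulge
    fiveB_AX_fraction: float = 0.0     # any partner base (AU ∪ AY)
    n_skipped: int = 0

    @property
    def category_fractions(self) -> dict:
        if self.n_sites == 0:
            return {k: 0.0 for k in self.category_counts}
        return {k: v / self.n_sites for k, v in self.category_counts.items()}


def survey_sites(windows: Sequence[SiteWindow],
                 ensembles: Sequence[SuboptEnsemble],
                 threshold: float | None = None) -> SurveyResult:
    """Survey one ensemble per window.

    MFE-mode (``threshold=None``): each site contributes the category of its
    single lowest-energy structure; counts sum to the number of sites.
    Threshold mode: a site counts toward the 5ʹ-bulge fractions if any
    structure with energy <= MFE + threshold shows the motif (category
    counts still report the MFE classification). Sites with an empty
    ensemble are excluded and tallied in ``n_skipped``.
    """
    if len(windows) != len(ensembles):
        raise ValidationError("need exactly one ensemble per window")
    counts = {c: 0 for c in MotifCategory}
    n_au = n_ax = n = skipped = 0
    for w, ens in zip(windows, ensembles):
        if not len(ens):
            skipped += 1
            continue
        n += 1
        counts[classify_motif(ens[0], w.a_index).category] += 1
        if threshold is None:
            cats = {classify_motif(ens[0], w.a_index).category}
        else:
            cutoff = ens.mfe + threshold + 1e-9
            cats = {classify_motif(s, w.a_index).category
                    for s in ens if s.energy <= cutoff}
        if MotifCategory.FIVEB_AU in cats:
            n_au += 1
        if cats & set(FIVEB_ANY):
            n_ax += 1
    frac = (lambda k: k / n if n else 0.0)
    return SurveyResult(n_sites=n, threshold=threshold,
                        category_counts={c.value: v for c, v in counts.items()},
                        fiveB_AU_fraction=frac(n_au),
                        fiveB_AX_fraction=frac(n_ax),
                        n_skipped=skipped)


def survey_over_thresholds(windows: Sequence[SiteWindow],
                           thresholds: Sequence[float] = (0.0, 1.0, 2.0, 3.0),
                           model: EnergyModel = DEFAULT_MODEL,
                           max_structures: int = 50_000) -> list[SurveyResult]:
    """Fold each window once at the widest threshold, then survey each level."""
    if any(t < 0 for t in thresholds):
        raise ValidationError("thresholds must be >= 0")
    widest = max(thresholds)
    ensembles = [subopt(w.sequence, model, window=widest,
                        max_structures=max_structures) for w in windows]
    return [survey_sites(windows, ensembles, threshold=t) for t in thresholds]


def make_control_sites(transcripts: dict[str, str], n: int, seed: int,
                       length: int = 41, a_offset: int = 21,
                       max_attempts_per_site: int = 200) -> list[SiteWindow]:
    """Randomly sample A-centered windows containing no DRACH match.

    Emulates the construction of unmethylated control sites: uniform draws
    of (transcript, position) accepted when the addressed base is an A, the
    window fits, and the window sequence has no DRACH consensus anywhere.
    Deterministic for a given seed.
    """
    if not transcripts:
        raise ValidationError("no transcripts given")
    rng = np.random.default_rng(seed)
    ids = sorted(transcripts)
    out: list[SiteWindow] = []
    attempts = 0
    budget = max_attempts_per_site * n
    while len(out) < n and attempts < budget:
        attempts += 1
        tid = ids[int(rng.integers(len(ids)))]
        seq = transcripts[tid]
        if len(seq) < length:
            continue
        pos = int(rng.integers(a_offset, len(seq) - (length - a_offset) + 1))
        if seq[pos - 1] != "A":
            continue
        start = pos - (a_offset - 1)
        window = seq[start - 1:start - 1 + length]
        if has_drach(window):
            continue
        out.append(SiteWindow(window, a_offset, tid, pos, "+"))
    if len(out) < n:
        raise ValidationError(
            f"could only place {len(out)}/{n} control sites in "
            f"{attempts} attempts")
    return out
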