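"""Malthusian relative fitness from pairwise competition assays.

A test strain is mixed ~1:1 with a fluorescent (mCherry) reference
strain, the mix is subcultured 1/64 (1/32 under formaldehyde) and grown
to stationary phase, and the test-strain fraction is measured by flow
cytometry before (F0) and after (F1) growth.  Relative fitness is the
ratio of realized Malthusian parameters assuming an E-fold population
expansion:

    W = log(F1 * E / F0) / log((1 - F1) * E / (1 - F0))

W is invariant to the logarithm base and equals 1 exactly when F1 = F0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    CensoredCompetitionError,
    DomainError,
    LowEventCountWarning,
    NearFixationWarning,
    ValidationError,
)

#: Counting floor of the cytometry protocol; fewer events warns.
MIN_EVENTS = 1000


@dataclass
class CompetitionRaw:
    """Fluorescent-positive and total event counts at t0 and t1."""

    positives_t0: int
    total_t0: int
    positives_t1: int
    total_t1: int

    def __post_init__(self) -> None:
        for pos, tot, tag in (
            (self.positives_t0, self.total_t0, "t0"),
            (self.positives_t1, self.total_t1, "t1"),
        ):
            if tot < 1:
                raise ValidationError(f"total events at {tag} must be >= 1")
            if pos > tot:
                raise ValidationError(f"positives exceed total events at {tag}")
            if pos <= 0 or pos >= tot:
                raise CensoredCompetitionError(
                    f"fraction at {tag} is at fixation (positives={pos}/{tot}); W is undefined"
                )
            if tot < MIN_EVENTS:
                warnings.warn(
                    f"only {tot} events at {tag}; the assay counts at least {MIN_EVENTS}",
                    LowEventCountWarning,
                )


@dataclass
class CompetitionResult:
    F0: float
    F1: float
    expansion: float
    W: float


def gate_fractions(raw: CompetitionRaw, test_is_nonfluorescent: bool = True) -> tuple[float, float]:
    """Test-strain fractions (F0, F1) from event counts.

    The reference strain carries the fluorophore, so by default the
    test-strain fraction is 1 - positives/total; set
    ``test_is_nonfluorescent=False`` when the test strain is the tagged
    one.
    """
    f0 = raw.positives_t0 / raw.total_t0
    f1 = raw.positives_t1 / raw.total_t1
    if test_is_nonfluorescent:
        f0, f1 = 1.0 - f0, 1.0 - f1
    for f, tag in ((f0, "F0"), (f1, "F1")):
        if min(f, 1.0 - f) < 0.005:
            warnings.warn(f"{tag} = {f:.4f} is near fixation", NearFixationWarning)
    return f0, f1


def malthusian_fitness(F0: float, F1: float, expansion: float) -> float:
    """Relative fitness W of the test strain over one competition cycle."""
    if not (0.0 < F0 < 1.0 and 0.0 < F1 < 1.0):
        raise ValidationError("F0 and F1 must lie strictly inside (0, 1)")
    if expansion <= 1.0:
        raise ValidationError("expansion factor must exceed 1")
    if F1 == F0:
        return 1.0
    test_fold = F1 * expansion / F0
    ref_fold = (1.0 - F1) * expansion / (1.0 - F0)
    if test_fold <= 1.0:
        raise DomainError(
            f"test strain declined ({test_fold:.3g}-fold): W undefined under growth assumption"
        )
    if ref_fold <= 1.0:
        raise DomainError(
            f"reference strain declined ({ref_fold:.3g}-fold): W undefined under growth assumption"
        )
    return math.log(test_fold) / math.log(ref_fold)


def estimate_competition(
    raw: CompetitionRaw,
    expansion: float,
    test_is_nonfluorescent: bool = True,
) -> CompetitionResult:
    """Gate fractions and compute W in one step."""
    f0, f1 = gate_fractions(raw, test_is_nonfluorescent=test_is_nonfluorescent)
    return CompetitionResult(f0, f1, expansion, malthusian_fitness(f0, f1, expansion))


def fitness_summary(results: list[CompetitionResult]) -> tuple[float, float, int]:
    """Replicate mean W, standard error of the mean, and n."""
    if not results:
        raise ValidationError("no competition results to summarize")
    w = np.array([r.W for r in results])
    sem = float(w.std(ddof=1) / math.sqrt(len(w))) if len(w) > 1 else 0.0
    return float(w.mean()), sem, len(w)
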