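"""CFU/mL estimation from replicate serial-dilution spot plating.

A sample is serially diluted 1:10 down to 10**-6 and small fixed-volume
spots (10 uL by default) are plated at every dilution.  The density is
read from the most dilute spot whose colony count falls in a countable
range, pooled with the neighbouring, more dilute spot.  Because a 1:10
series makes the two pooled spots carry 1.1x the colonies expected at
the less dilute one, dividing the pooled count by 1.1 x dilution x
volume gives an unbiased density estimate:

    E[c_a + c_b] = lam * v * (d_a + d_b) = lam * v * 1.1 * d_a
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import UnresolvableSeriesError, ValidationError

#: Sentinel for "too numerous to count" spots in input tables.
TNTC = "TNTC"


def _is_tntc(value) -> bool:
    return isinstance(value, str) and value.strip().upper() == TNTC


@dataclass
class SpotSeries:
    """One replicate dilution series of colony counts for one sample.

    ``dilution_exponents`` are base-10 exponents (0 for undiluted, -6 for
    the 10**-6 dilution) in strictly decreasing order; ``counts`` holds a
    nonnegative integer or the string ``"TNTC"`` per exponent.
    """

    sample_id: str
    replicate_id: str
    dilution_exponents: Sequence[int]
    counts: Sequence[int | str]
    spot_volume_ml: float = 0.010

    def __post_init__(self) -> None:
        self.dilution_exponents = tuple(int(e) for e in self.dilution_exponents)
        if len(self.dilution_exponents) == 0:
            raise ValidationError("empty dilution series")
        if len(self.counts) != len(self.dilution_exponents):
            raise ValidationError("one count required per dilution exponent")
        if any(b >= a for a, b in zip(self.dilution_exponents, self.dilution_exponents[1:])):
            raise ValidationError("dilution exponents must be strictly decreasing")
        if self.spot_volume_ml <= 0:
            raise ValidationError("spot volume must be positive")
        cleaned: list[int | str] = []
        for c in self.counts:
            if _is_tntc(c):
                cleaned.append(TNTC)
                continue
            ci = int(c)
            if ci != c or ci < 0:
                raise ValidationError(f"counts must be nonnegative integers or TNTC, got {c!r}")
            cleaned.append(ci)
        self.counts = tuple(cleaned)


@dataclass
class CfuEstimate:
    """Density estimate from one spot series.

    ``censored`` is set when every spot was zero: the true density lies
    below the plating limit of detection and ``cfu_per_ml`` is reported
    as 0 (the detection limit is attached downstream by the tolerance
    module).
    """

    cfu_per_ml: float
    dilutions_used: tuple[int, ...] = field(default_factory=tuple)
    pooled_count: int = 0
    censored: bool = False


@dataclass
class PooledCfu:
    """Mean/SD summary over replicate estimates (technical or biological)."""

    mean: float
    sd: float
    n: int
    any_censored: bool = False


def estimate_cfu(
    series: SpotSeries,
    countable_range: tuple[int, int] = (3, 150),
    literal_1p1_multiplier: bool = False,
) -> CfuEstimate:
    """Estimate CFU/mL from one replicate spot series.

    The anchor spot is the most dilute one whose count lies inside
    ``countable_range``.  It is pooled with the next, more dilute spot
    (whatever its count -- at high dilution a handful of colonies is
    still a valid Poisson observation) and the pooled count is divided
    by ``(d_a + d_b) * volume``.  With adjacent tenfold dilutions this
    is the classic "sum divided by 1.1 times the less dilute fraction"
    rule.  If the anchor is the last spot the single-spot estimate
    ``count / (d * volume)`` is used.  If no spot is in range but
    positive counts exist, all numeric spots are pooled (low-count
    fallback, still unbiased).  All-zero series are censored.

    ``literal_1p1_multiplier=True`` multiplies rather than divides by
    1.1 -- the rule exactly as the source protocol words it.  It inflates
    every estimate by the constant 1.21, so frequency ratios downstream
    are unaffected.
    """
    lo, hi = countable_range
    if lo < 1:
        raise ValidationError("countable_range minimum must be >= 1")
    if hi < lo:
        raise ValidationError("countable_range must satisfy min <= max")
    counts = series.counts
    exps = series.dilution_exponents
    v = series.spot_volume_ml

    if _is_tntc(counts[-1]):
        raise UnresolvableSeriesError(
            f"series {series.sample_id}/{series.replicate_id}: most dilute spot is TNTC"
        )

    numeric = [(i, c) for i, c in enumerate(counts) if not _is_tntc(c)]
    in_range = [i for i, c in numeric if lo <= c <= hi]

    if in_range:
        a = max(in_range)  # most dilute countable spot
        # pool with the next-more-dilute neighbour; if the countable spot
        # is already the last one, pool with the previous (less dilute)
        # spot instead so the pair is always the two highest dilutions
        # around the countable endpoint
        if a + 1 < len(counts) and not _is_tntc(counts[a + 1]):
            lo_i, hi_i = a, a + 1
        elif a > 0 and not _is_tntc(counts[a - 1]):
            lo_i, hi_i = a - 1, a
        else:
            d_a = 10.0 ** exps[a]
            return CfuEstimate(counts[a] / (d_a * v), (exps[a],), int(counts[a]))
        d_a = 10.0 ** exps[lo_i]  # dilution fraction of the LESS dilute spot
        d_b = 10.0 ** exps[hi_i]
        pooled = counts[lo_i] + counts[hi_i]
        if literal_1p1_multiplier:
            cfu = pooled * 1.1 / (d_a * v)
        else:
            cfu = pooled / ((d_a + d_b) * v)
        return CfuEstimate(cfu, (exps[lo_i], exps[hi_i]), int(pooled))

    positive = [(i, c) for i, c in numeric if c > 0]
    if positive:
        # Low-count series: pool every numeric spot against the summed
        # dilution fractions, the unbiased use of all information.
        idx = [i for i, _ in numeric]
        pooled = sum(c for _, c in numeric)
        denom = sum(10.0 ** exps[i] for i in idx) * v
        return CfuEstimate(pooled / denom, tuple(exps[i] for i in idx), int(pooled))

    if any(_is_tntc(c) for c in counts):
        raise UnresolvableSeriesError(
            f"series {series.sample_id}/{series.replicate_id}: TNTC spots but no countable spot"
        )
    return CfuEstimate(0.0, tuple(), 0, censored=True)


def pool_replicates(estimates: Sequence[CfuEstimate]) -> PooledCfu:
    """Arithmetic mean and sample SD (n-1) over replicate estimates.

    Censored members enter as 0 with the flag propagated, matching the
    plating protocol's handling of below-detection replicates.
    """
    if len(estimates) == 0:
        raise ValidationError("cannot pool an empty replicate group")
    values = np.array([e.cfu_per_ml for e in estimates], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return PooledCfu(mean, sd, len(values), any(e.censored for e in estimates))


def detection_limit_density(spot_volume_ml: float, spots_per_sample: int) -> int:
    """Smallest density (CFU/mL) observable as >= 1 colony over all spots."""
    if spot_volume_ml <= 0 or spots_per_sample <= 0:
        raise ValidationError("volume and spot count must be positive")
    return int(math.ceil(1.0 / (spot_volume_ml * spots_per_sample)))
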