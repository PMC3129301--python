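"""Kimura two-parameter divergence between the two LTRs of an element, and the
molecular-clock conversion of that divergence into an insertion date.

At insertion the two long terminal repeats of a retrotransposon are identical;
they then accumulate substitutions independently.  With transition and
transversion difference proportions *P* and *Q* over *n* compared sites, the
K2P distance is

    D = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

with the standard error of Kimura (1980).  The insertion date follows from
``T = D / (2 r)`` where *r* is the substitution rate per site per year
(default 1.3e-8, the plant LTR-retrotransposon rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_formats import GAP, NucSequence
from .pairwise_align import AlignedPair, ScoringScheme, global_align

#: substitution rate per site per year for plant LTR retrotransposons
DEFAULT_RATE = 1.3e-8

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """K2P correction undefined: observed divergence beyond the correctable range."""

    def __init__(self, P: float, Q: float):
        super().__init__(
            f"K2P distance undefined for P={P:.4f}, Q={Q:.4f} "
            f"(needs 1-2P-Q > 0 and 1-2Q > 0): sequences saturated"
        )
        self.P = P
        self.Q = Q


class NoComparableSitesError(ValueError):
    """No alignment columns left after removing gap/N columns."""


class NotDatableError(ValueError):
    """Element cannot be dated (e.g. truncated: only one LTR present)."""


@dataclass(frozen=True)
class SitePatternCounts:
    """Compared-site count with transition (P) and transversion (Q) proportions."""

    n: int
    P: float
    Q: float

    def __post_init__(self) -> None:
        if self.n < 0 or self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError(f"invalid site patterns n={self.n} P={self.P} Q={self.Q}")


@dataclass(frozen=True)
class K2PResult:
    D: float
    SE: float

    def __post_init__(self) -> None:
        if self.D < 0 or self.SE < 0:
            raise ValueError("negative distance or SE")


@dataclass(frozen=True)
class DatingResult:
    """Insertion age in years, with the rate used and propagated uncertainty."""

    T: float
    T_se: float
    r: float

    @property
    def T_mya(self) -> float:
        return self.T / 1e6


@dataclass(frozen=True)
class DatingReport:
    """Full per-element dating record: divergence diagnostics plus the date."""

    element_id: str
    n: int
    P: float
    Q: float
    D: float
    SE: float
    dating: DatingResult


def count_site_patterns(p: AlignedPair, deletion: str = "complete") -> SitePatternCounts:
    """Classify aligned columns into transition/transversion differences.

    Complete deletion: any column holding a gap or ``N`` in either row is
    excluded before proportions are computed.
    """
    if deletion != "complete":
        raise ValueError(f"unsupported deletion option {deletion!r}")
    n = ts = tv = 0
    for ca, cb in zip(p.gapped_a, p.gapped_b):
        if ca in (GAP, "N") or cb in (GAP, "N"):
            continue
        n += 1
        if ca == cb:
            continue
        if (ca in _PURINES) == (cb in _PURINES):
            ts += 1  # purine<->purine or pyrimidine<->pyrimidine
        else:
            tv += 1
    if n == 0:
        raise NoComparableSitesError("no comparable sites after complete deletion")
    return SitePatternCounts(n, ts / n, tv / n)


def k2p_distance(c: SitePatternCounts) -> K2PResult:
    """K2P distance with Kimura's (1980) large-sample standard error."""
    if c.n == 0:
        raise NoComparableSitesError("n = 0")
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(c.P, c.Q)
    D = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    c1 = 1.0 / w1
    c2 = 1.0 / w2
    c3 = 0.5 * (c1 + c2)
    var = (c1 * c1 * c.P + c3 * c3 * c.Q - (c1 * c.P + c3 * c.Q) ** 2) / c.n
    return K2PResult(D, math.sqrt(max(var, 0.0)))


def date_insertion(k: K2PResult, r: float = DEFAULT_RATE) -> DatingResult:
    """Convert LTR-LTR divergence to years since insertion: ``T = D / (2 r)``."""
    if r <= 0:
        raise ValueError(f"substitution rate must be positive, got {r}")
    return DatingResult(T=k.D / (2.0 * r), T_se=k.SE / (2.0 * r), r=r)


def date_element(element: NucSequence, ltr, scheme: ScoringScheme | None = None,
                 r: float = DEFAULT_RATE, deletion: str = "complete") -> DatingReport:
    """Date one element from its two LTRs: extract, align, count, correct, convert.

    ``ltr`` is an ``ltr_detect.LTRPair``; truncated elements (one LTR) raise
    :class:`NotDatableError`, saturation propagates as :class:`SaturationError`.
    """
    if ltr is None or not ltr.is_complete():
        raise NotDatableError(
            f"{element.id}: both LTRs are required for LTR-divergence dating"
        )
    ltr5 = element.subsequence(ltr.start5, ltr.end5, suffix="/LTR5")
    ltr3 = element.subsequence(ltr.start3, ltr.end3, suffix="/LTR3")
    pair = global_align(ltr5, ltr3, scheme)
    counts = count_site_patterns(pair, deletion)
    k = k2p_distance(counts)
    return DatingReport(
        element_id=element.id, n=counts.n, P=counts.P, Q=counts.Q,
        D=k.D, SE=k.SE, dating=date_insertion(k, r),
    )
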