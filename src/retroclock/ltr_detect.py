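"""Locate the two terminal direct repeats (LTRs) of a retroelement.

The element is compared with itself: exact k-mer seeds shared between a 5'
copy and a downstream 3' copy are grouped by diagonal (offset between the two
copies) and greedily extended allowing mismatches.  Candidates are then ranked
by how close the repeat copies sit to the element termini ("terminality"),
then identity, then length — mimicking how terminal repeats are picked from a
dot-plot style self-comparison.  Boundaries are finally snapped onto the
canonical retroviral termini: LTRs start with 5'-TG and end with CA-3'.

Only direct repeats on the same strand are considered; LTRs are direct by
definition.  The main diagonal (the trivial self-match) is excluded.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

from .io_formats import NucSequence

DEFAULT_MIN_LEN = 80
DEFAULT_MIN_IDENTITY = 0.80
DEFAULT_MAX_LTR_FRAC = 0.40
DEFAULT_SEED_K = 12
DEFAULT_MOTIF_WINDOW = 5

# X-drop extension scores
_MATCH = 1
_MISMATCH = -2
_XDROP = 12


@dataclass(frozen=True)
class LTRPair:
    """Coordinates (1-based inclusive) of the two LTR copies of one element.

    ``motif_ok`` flags whether the 5' LTR starts with TG and the 3' LTR ends
    with CA.  Truncated elements carry only one copy: the missing side is None.
    """

    start5: int | None
    end5: int | None
    start3: int | None
    end3: int | None
    identity: float = 0.0
    motif_ok: tuple[bool, bool] = (False, False)

    def is_complete(self) -> bool:
        return None not in (self.start5, self.end5, self.start3, self.end3)

    def __post_init__(self) -> None:
        if self.is_complete() and not (self.start5 <= self.end5 < self.start3 <= self.end3):
            raise ValueError(
                f"LTR coordinates out of order: "
                f"{self.start5}..{self.end5} / {self.start3}..{self.end3}"
            )
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")

    @property
    def len5(self) -> int | None:
        return None if self.start5 is None else self.end5 - self.start5 + 1

    @property
    def len3(self) -> int | None:
        return None if self.start3 is None else self.end3 - self.start3 + 1


def _extend(seq: str, i0: int, i1: int, off: int, limit_lo: int, limit_hi: int):
    """Greedy X-drop extension of the exact match seq[i0:i1] == seq[i0+off:i1+off].

    0-based half-open input coords; returns (lo, hi) half-open maximal-scoring
    extent of the 5' copy.  ``limit_lo``/``limit_hi`` bound the 5' copy so the
    two copies never overlap.
    """
    score = best = (i1 - i0) * _MATCH
    best_lo, best_hi = i0, i1
    # extend left
    lo = i0
    cur = score
    k = i0 - 1
    while k >= limit_lo and cur > best - _XDROP:
        cur += _MATCH if seq[k] == seq[k + off] else _MISMATCH
        if cur > best:
            best = cur
            lo = k
        k -= 1
    best_lo = lo
    # extend right from the best-left state
    cur = best
    hi = i1
    k = i1
    while k + off < len(seq) and k < limit_hi and cur > best - _XDROP:
        cur += _MATCH if seq[k] == seq[k + off] else _MISMATCH
        if cur > best:
            best = cur
            hi = k + 1
        k += 1
    best_hi = hi
    return best_lo, best_hi


def find_terminal_repeats(element: NucSequence,
                          min_len: int = DEFAULT_MIN_LEN,
                          min_identity: float = DEFAULT_MIN_IDENTITY,
                          max_ltr_len: int | None = None,
                          seed_k: int = DEFAULT_SEED_K) -> list[LTRPair]:
    """Find candidate terminal direct-repeat pairs by self-comparison.

    Returns candidates sorted best-first by (terminality, identity, length);
    an empty list means nothing met the thresholds.
    """
    seq = element.residues
    L = len(seq)
    if L < 2 * min_len:
        raise ValueError(f"{element.id}: length {L} < 2*min_len ({2 * min_len})")
    if max_ltr_len is None:
        max_ltr_len = int(DEFAULT_MAX_LTR_FRAC * L)
    max_ltr_len = max(max_ltr_len, min_len)

    # seed: positions of each k-mer
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(L - seed_k + 1):
        index[seq[i : i + seed_k]].append(i)

    # collect seed hits per diagonal offset; cap repetitive k-mers
    diagonals: dict[int, list[int]] = defaultdict(list)
    for positions in index.values():
        if len(positions) < 2 or len(positions) > 50:
            continue
        for x in range(len(positions)):
            for y in range(x + 1, len(positions)):
                off = positions[y] - positions[x]
                if off >= min_len:  # excludes the main diagonal and tiny shifts
                    diagonals[off].append(positions[x])

    candidates: list[LTRPair] = []
    seen: set[tuple[int, int, int, int]] = set()
    for off, starts in diagonals.items():
        starts.sort()
        # merge nearby seeds on one diagonal, extend each cluster once
        prev = None
        anchors = []
        for s in starts:
            if prev is None or s - prev > 2 * seed_k:
                anchors.append(s)
            prev = s
        for s in anchors:
            lo, hi = _extend(seq, s, s + seed_k, off,
                             limit_lo=0, limit_hi=off)  # 5' copy must end before 3' copy starts
            length = hi - lo
            if length < min_len or length > max_ltr_len:
                continue
            n_match = sum(1 for k in range(lo, hi) if seq[k] == seq[k + off])
            identity = n_match / length
            if identity < min_identity:
                continue
            key = (lo, hi, lo + off, hi + off)
            if key in seen:
                continue
            seen.add(key)
            candidates.append(LTRPair(
                start5=lo + 1, end5=hi, start3=lo + off + 1, end3=hi + off,
                identity=identity,
                motif_ok=(seq[lo : lo + 2] == "TG", seq[hi + off - 2 : hi + off] == "CA"),
            ))

    def rank(c: LTRPair):
        terminality = (c.start5 - 1) + (L - c.end3)
        return (terminality, -c.identity, -(c.len5 or 0))

    candidates.sort(key=rank)
    return candidates


def anchor_motifs(element: NucSequence, candidate: LTRPair,
                  window: int = DEFAULT_MOTIF_WINDOW) -> LTRPair:
    """Snap candidate boundaries onto the TG...CA termini if found nearby.

    Searches within ±window of the 5' LTR start for a TG and within ±window of
    the 3' LTR end for a CA, preferring the smallest shift; the paired
    boundaries (3' start, 5' end) shift by the same amounts so the two copies
    keep equal length.  Without a hit the candidate is returned unchanged with
    the corresponding motif flag false.
    """
    if not candidate.is_complete():
        return candidate
    seq = element.residues
    L = len(seq)

    def best_shift(test) -> int | None:
        for d in sorted(range(-window, window + 1), key=lambda x: (abs(x), x)):
            if test(d):
                return d
        return None

    def tg_at(d: int) -> bool:
        p = candidate.start5 - 1 + d  # 0-based
        return 0 <= p and p + 2 <= L and seq[p : p + 2] == "TG"

    def ca_at(d: int) -> bool:
        p = candidate.end3 + d  # 0-based exclusive end
        return 2 <= p <= L and seq[p - 2 : p] == "CA"

    ds = best_shift(tg_at)
    de = best_shift(ca_at)
    start5 = candidate.start5 + (ds or 0)
    start3 = candidate.start3 + (ds or 0)
    end3 = candidate.end3 + (de or 0)
    end5 = candidate.end5 + (de or 0)
    if not (1 <= start5 <= end5 < start3 <= end3 <= L):
        return replace(candidate, motif_ok=(False, False))
    return LTRPair(
        start5=start5, end5=end5, start3=start3, end3=end3,
        identity=candidate.identity,
        motif_ok=(ds is not None, de is not None),
    )


def detect_ltrs(element: NucSequence, **kwargs) -> LTRPair | None:
    """Convenience: top-ranked candidate with motif anchoring, or None."""
    window = kwargs.pop("window", DEFAULT_MOTIF_WINDOW)
    cands = find_terminal_repeats(element, **kwargs)
    if not cands:
        return None
    return anchor_motifs(element, cands[0], window=window)
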