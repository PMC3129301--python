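"""Exact affine-gap global alignment of two nucleotide sequences.

Used to align the two LTRs of one element before divergence estimation.  The
dynamic program is the standard three-state Gotoh recursion; a gap of length
``L`` costs ``gap_open + (L - 1) * gap_extend`` (so ``gap_open == gap_extend``
degenerates to linear gap costs).  Traceback tie-breaking is fixed — diagonal,
then up (gap in *b*), then left (gap in *a*) — so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .io_formats import GAP, NucSequence

_NEG_INF = np.int64(-(2**40))

_CODE = np.full(256, 4, dtype=np.int8)  # N and anything odd -> 4
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores stored as magnitudes: mismatch/gap values are penalties."""

    match: int = 2
    mismatch: int = 1
    gap_open: int = 5
    gap_extend: int = 1
    free_end_gaps: bool = False

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties are stored as non-negative magnitudes")


@dataclass(frozen=True)
class AlignedPair:
    """A pairwise global alignment; degapping the rows reproduces the inputs."""

    gapped_a: str
    gapped_b: str
    score: int

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("aligned rows differ in length")
        for ca, cb in zip(self.gapped_a, self.gapped_b):
            if ca == GAP and cb == GAP:
                raise ValueError("gap/gap column in alignment")

    @property
    def identity(self) -> float:
        return pair_identity(self)

    def __len__(self) -> int:
        return len(self.gapped_a)


def pair_identity(p: AlignedPair) -> float:
    """Matches over columns holding a residue in both rows; 0 if none exist."""
    both = matches = 0
    for ca, cb in zip(p.gapped_a, p.gapped_b):
        if ca != GAP and cb != GAP:
            both += 1
            if ca == cb and ca != "N":
                matches += 1
    return matches / both if both else 0.0


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend, free_ends):  # pragma: no cover - numba
    n, m = a.size, b.size
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    E = np.empty((n + 1, m + 1), dtype=np.int64)  # gap in a (left moves)
    F = np.empty((n + 1, m + 1), dtype=np.int64)  # gap in b (up moves)
    H[0, 0] = 0
    E[0, 0] = F[0, 0] = _NEG_INF
    for i in range(1, n + 1):
        F[i, 0] = 0 if free_ends else -(gap_open + (i - 1) * gap_extend)
        H[i, 0] = F[i, 0]
        E[i, 0] = _NEG_INF
    for j in range(1, m + 1):
        E[0, j] = 0 if free_ends else -(gap_open + (j - 1) * gap_extend)
        H[0, j] = E[0, j]
        F[0, j] = _NEG_INF
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != 4 and b[j - 1] != 4) else -mismatch
            e = E[i, j - 1] - gap_extend
            eh = H[i, j - 1] - gap_open
            E[i, j] = eh if eh >= e else e
            f = F[i - 1, j] - gap_extend
            fh = H[i - 1, j] - gap_open
            F[i, j] = fh if fh >= f else f
            d = H[i - 1, j - 1] + s
            best = d
            if F[i, j] > best:
                best = F[i, j]
            if E[i, j] > best:
                best = E[i, j]
            H[i, j] = best
    return H, E, F


def global_align(a: NucSequence, b: NucSequence,
                 scheme: ScoringScheme | None = None) -> AlignedPair:
    """Maximum-score global alignment of ``a`` and ``b`` under the affine scheme.

    Mismatches involving ``N`` score as mismatches (N never rewards a match).
    Raises ``ValueError`` on empty input.
    """
    scheme = scheme or ScoringScheme()
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    ac = _CODE[np.frombuffer(a.residues.encode(), dtype=np.uint8)]
    bc = _CODE[np.frombuffer(b.residues.encode(), dtype=np.uint8)]
    H, E, F = _gotoh_fill(
        ac, bc, scheme.match, scheme.mismatch, scheme.gap_open,
        scheme.gap_extend, scheme.free_end_gaps,
    )
    n, m = len(ac), len(bc)
    out_a: list[str] = []
    out_b: list[str] = []
    go = scheme.gap_open
    i, j, state = n, m, "H"
    score = int(H[n, m])
    if scheme.free_end_gaps:
        # semi-global: trailing gaps are free, so end at the best cell on the
        # last row/column and pad the short side with terminal gaps
        bi = int(np.argmax(H[:, m]))
        bj = int(np.argmax(H[n, :]))
        if H[bi, m] >= H[n, bj]:
            score = int(H[bi, m])
            out_a.extend(reversed(a.residues[bi:]))
            out_b.extend(GAP * (n - bi))
            i = bi
        else:
            score = int(H[n, bj])
            out_a.extend(GAP * (m - bj))
            out_b.extend(reversed(b.residues[bj:]))
            j = bj
    while i > 0 or j > 0:
        if state == "H":
            if scheme.free_end_gaps and (i == 0 or j == 0):
                break  # leading gaps are free: stop here
            if i == 0:
                state = "E"
            elif j == 0:
                state = "F"
            else:
                ai, bj_ = a.residues[i - 1], b.residues[j - 1]
                s = scheme.match if (ai == bj_ and ai != "N") else -scheme.mismatch
                # tie order: diagonal, then up (F), then left (E)
                if H[i, j] == H[i - 1, j - 1] + s:
                    out_a.append(ai)
                    out_b.append(bj_)
                    i -= 1
                    j -= 1
                elif H[i, j] == F[i, j]:
                    state = "F"
                else:
                    state = "E"
        elif state == "F":  # gap in b, consume a[i]
            out_a.append(a.residues[i - 1])
            out_b.append(GAP)
            state = "H" if F[i, j] == H[i - 1, j] - go else "F"
            i -= 1
        else:  # state == "E": gap in a, consume b[j]
            out_a.append(GAP)
            out_b.append(b.residues[j - 1])
            state = "H" if E[i, j] == H[i, j - 1] - go else "E"
            j -= 1
    # leading free end gaps
    out_a.extend(reversed(a.residues[:i]))
    out_b.extend(GAP * i)
    out_a.extend(GAP * j)
    out_b.extend(reversed(b.residues[:j]))
    return AlignedPair("".join(reversed(out_a)), "".join(reversed(out_b)), score)
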