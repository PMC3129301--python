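"""Synthetic LTR-retrotransposon families with known ground truth.

Emulates the anatomy and history that the dating and phylogeny stages assume:
full-length elements are two identical terminal direct repeats (LTRs, starting
5'-TG and ending CA-3') flanking an internal region; after insertion each LTR
copy accumulates substitutions independently under the K80 (Kimura
two-parameter) process at a per-site yearly rate ``r`` with
transition/transversion rate ratio κ, so the expected LTR-LTR divergence of an
element inserted T years ago is about ``2 r T``.  Families of conserved-domain
sequences are evolved down a two-level tree (group stems, then members),
giving genome-labelled, natively aligned sets with planted group structure.

No indel process is simulated: synthetic families stay gap-free, so estimator
behaviour is tested separately from alignment quality.  Truncated ("-1p")
copies lacking one LTR can be emitted to exercise the not-datable path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import Alignment, NucSequence
from .k2p_dating import DEFAULT_RATE
from .ltr_detect import LTRPair

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# transition partner of A,C,G,T (A<->G, C<->T)
_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.int8)
# the two transversion partners of each base
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    ltr_len 1500 bp and internal_len 6000 bp match the scale of gypsy-family
    elements in wheat BAC annotations (solo LTRs ~1.5 kb, full elements ~9 kb);
    r is the plant LTR-retrotransposon substitution rate per site per year;
    κ = 2 is the conventional transition/transversion rate ratio.
    """

    ltr_len: int = 1500
    internal_len: int = 6000
    domain_len: int = 800
    r: float = DEFAULT_RATE
    kappa: float = 2.0
    base_comp: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ltr_len < 80:
            raise ValueError("ltr_len must be >= 80")
        if self.r <= 0 or self.kappa <= 0:
            raise ValueError("r and kappa must be positive")
        if abs(sum(self.base_comp) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one emitted element."""

    element_id: str
    ltr: LTRPair | None
    T: float
    genome_label: str | None = None
    group_id: str | None = None
    truncated: bool = False


def _k80_probs(d: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-target transversion prob) after expected
    ``d`` substitutions per site under K80 with ts/tv rate ratio κ."""
    beta = d / (kappa + 2.0)
    alpha = kappa * beta
    e4 = np.exp(-4.0 * beta)
    e2 = np.exp(-2.0 * (alpha + beta))
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e4
    return p_ts, p_tv_each


def random_sequence(length: int, cfg: SimConfig, rng: np.random.Generator) -> str:
    codes = rng.choice(4, size=length, p=np.asarray(cfg.base_comp))
    return _BASES[codes].tobytes().decode("ascii")


def evolve_copy(seq: str, t_total: float, cfg: SimConfig,
                rng: np.random.Generator) -> str:
    """Evolve ``seq`` for ``t_total`` years under K80 at rate ``cfg.r``.

    Sites substitute independently with the closed-form K80 site-change
    probabilities at expected divergence ``r * t_total``; no indels.
    """
    if t_total < 0:
        raise ValueError("t_total must be non-negative")
    if t_total == 0:
        return seq
    d = cfg.r * t_total
    p_ts, p_tv = _k80_probs(d, cfg.kappa)
    codes = np.searchsorted(_BASES, np.frombuffer(seq.encode(), dtype=np.uint8))
    # map A,C,G,T byte order: _BASES sorted is A,C,G,T already
    u = rng.random(codes.size)
    out = codes.copy()
    ts_mask = u < p_ts
    tv1_mask = (~ts_mask) & (u < p_ts + p_tv)
    tv2_mask = (~ts_mask) & (~tv1_mask) & (u < p_ts + 2 * p_tv)
    out[ts_mask] = _TS_PARTNER[codes[ts_mask]]
    out[tv1_mask] = _TV_PARTNERS[codes[tv1_mask], 0]
    out[tv2_mask] = _TV_PARTNERS[codes[tv2_mask], 1]
    return _BASES[out].tobytes().decode("ascii")


def simulate_element(cfg: SimConfig, T: float, rng: np.random.Generator,
                     element_id: str = "element", genome_label: str | None = None,
                     truncate: str | None = None) -> tuple[NucSequence, SimTruth]:
    """Emit one element inserted ``T`` years ago, with exact truth coordinates.

    The ancestral LTR is forced to start TG and end CA; each emitted LTR copy
    is an independent K80 realisation over time ``T``.  ``truncate`` may be
    ``"5p"`` or ``"3p"`` to delete that LTR (a "-1p"-style damaged copy).
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    anc_ltr = "TG" + random_sequence(cfg.ltr_len - 4, cfg, rng) + "CA"
    internal = random_sequence(cfg.internal_len, cfg, rng)
    ltr5 = evolve_copy(anc_ltr, T, cfg, rng)
    ltr3 = evolve_copy(anc_ltr, T, cfg, rng)
    L = cfg.ltr_len
    if truncate is None:
        residues = ltr5 + internal + ltr3
        ltr = LTRPair(
            start5=1, end5=L,
            start3=L + cfg.internal_len + 1, end3=2 * L + cfg.internal_len,
            identity=sum(a == b for a, b in zip(ltr5, ltr3)) / L,
            motif_ok=(ltr5.startswith("TG"), ltr3.endswith("CA")),
        )
        truncated = False
    elif truncate == "5p":
        residues = internal + ltr3
        ltr = LTRPair(start5=None, end5=None,
                      start3=cfg.internal_len + 1, end3=cfg.internal_len + L)
        truncated = True
    elif truncate == "3p":
        residues = ltr5 + internal
        ltr = LTRPair(start5=1, end5=L, start3=None, end3=None)
        truncated = True
    else:
        raise ValueError(f"truncate must be None, '5p' or '3p', got {truncate!r}")
    seq = NucSequence(element_id, residues, genome_label)
    return seq, SimTruth(element_id, ltr, T, genome_label, truncated=truncated)


@dataclass(frozen=True)
class GroupSpec:
    """One planted family group: its genome of origin and divergence times.

    ``stem_time``: years separating the group ancestor from the family root;
    ``crown_time``: upper bound of the per-member divergence times, drawn
    uniformly from (0, crown_time].
    """

    group_id: str
    genome_label: str
    n_members: int
    stem_time: float
    crown_time: float


def simulate_family(cfg: SimConfig, groups: Sequence[GroupSpec],
                    rng: np.random.Generator
                    ) -> tuple[Alignment, dict[str, str], list[SimTruth]]:
    """Evolve a shared ancestral domain down a two-level tree of groups/members.

    Returns a gap-free multiple alignment, an id -> genome-label map, and the
    per-member truth (group id and drawn insertion time).  Deterministic for a
    given generator state.
    """
    if not groups:
        raise ValueError("need at least 1 group")
    if any(g.n_members < 2 for g in groups):
        raise ValueError("each group needs at least 2 members")
    root = random_sequence(cfg.domain_len, cfg, rng)
    rows: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    truths: list[SimTruth] = []
    for g in groups:
        stem = evolve_copy(root, g.stem_time, cfg, rng)
        for k in range(g.n_members):
            t = float(rng.uniform(0.0, g.crown_time)) if g.crown_time > 0 else 0.0
            member = evolve_copy(stem, t, cfg, rng)
            mid = f"{g.group_id}_{g.genome_label}_{k + 1}"
            rows.append((mid, member))
            labels[mid] = g.genome_label
            truths.append(SimTruth(mid, None, t, g.genome_label, g.group_id))
    return Alignment(tuple(rows)), labels, truths
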