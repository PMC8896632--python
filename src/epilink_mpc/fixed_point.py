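"""Fixed-point representation of the match score and precision selection.

The secure circuits compute on L-bit integers (L in {8, 16, 32, 64}).  The
two real-valued quantities of the score — field weights and field
similarities — are quantized to ``lw`` and ``ls`` fractional bits:

* weights are rescaled so the largest weight saturates its range,
  ``w_i -> round(w_i / w_max * (2^lw - 1))``;
* similarities live on the scale ``2^ls`` (equality: a bit shifted left by
  ``ls``; Dice: rounding integer division of ``2*H_and << ls`` by
  ``H_x + H_y``);
* the threshold becomes ``T_q = round(T * 2^ls)`` so the match predicate
  ``s > T*w`` holds at scale ``2^(lw+ls)`` on both sides.

The widest intermediate is the cross product ``z = s * w'`` of the
tie-solving comparison: a sum of n weighted similarities (length
``ceil(log2 n) + lw + ls``) times a sum of n weights (length
``ceil(log2 n) + lw``), i.e. ``ceil(log2 n^2) + 2*lw + ls`` bits.  The
precision choice therefore distributes ``r = L - ceil(log2 n^2)`` bits as

    lw = ceil(r/3), ls = floor(r/3)   if r mod 3 == 2,
    lw = floor(r/3), ls = ceil(r/3)   otherwise,

which satisfies ``2*lw + ls = r`` exactly — L is filled completely
(lw counts twice in the widest product) while provably never overflowing.
Rounding is half-away-from-zero throughout.

This module is the exact integer oracle for the gate-level circuit model:
``fixed_record_score`` computes precisely what the circuits compute.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from itertools import permutations
from typing import Sequence

from .config_records import (
    ConfigError,
    ExchangeGroup,
    LinkageConfig,
    Record,
)
from .epilink_reference import MatchResult, ScorePair, tie_solving_greater

__all__ = [
    "PrecisionPlan",
    "QuantizedConfig",
    "choose_precisions",
    "quantize_weights",
    "quantize_threshold",
    "quantize_config",
    "rounding_int_div",
    "round_half_away",
    "fixed_field_similarity",
    "fixed_group_score",
    "fixed_record_score",
    "fixed_best_match",
]


@dataclass(frozen=True)
class PrecisionPlan:
    """Bit budget of the fixed-point pipeline.

    ``r = L - ceil(log2(n^2))`` bits are split so that ``2*lw + ls = r``,
    hence ``ceil(log2 n^2) + 2*lw + ls <= L``: no arithmetic wire can
    overflow.
    """

    L: int
    n: int
    r: int
    lw: int
    ls: int

    @property
    def header_bits(self) -> int:
        return self.L - self.r  # ceil(log2 n^2)

    def max_product_bits(self) -> int:
        return self.header_bits + 2 * self.lw + self.ls

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _ceil_log2(value: int) -> int:
    if value < 1:
        raise ValueError("ceil_log2 requires a positive integer")
    return (value - 1).bit_length()


def choose_precisions(L: int, n: int) -> PrecisionPlan:
    """Select the (lw, ls) precisions for word size ``L`` and ``n`` fields."""
    if L not in (8, 16, 32, 64):
        raise ConfigError(f"bit-length must be one of 8/16/32/64, got {L}")
    if n < 1:
        raise ConfigError("field count must be >= 1")
    r = L - _ceil_log2(n * n)
    if r < 2:
        raise ConfigError(
            f"too many fields (n={n}) for bit-length L={L}: only {r} bits "
            "left for the fixed-point precisions"
        )
    if r % 3 == 2:
        lw = -(-r // 3)  # ceil
        ls = r // 3
    else:
        lw = r // 3
        ls = -(-r // 3)
    plan = PrecisionPlan(L=L, n=n, r=r, lw=lw, ls=ls)
    assert plan.max_product_bits() <= L
    return plan


def round_half_away(x: float) -> int:
    """Round to nearest with halves away from zero (the ``⌊·⌉`` rule)."""
    if x >= 0:
        return math.floor(x + 0.5)
    return math.ceil(x - 0.5)


def quantize_weights(weights: Sequence[float], lw: int) -> list[int]:
    """Rescale weights so the maximum maps to ``2^lw - 1``, then round."""
    if any(w <= 0 for w in weights):
        raise ConfigError("all weights must be positive for quantization")
    w_max = max(weights)
    top = (1 << lw) - 1
    return [round_half_away(w / w_max * top) for w in weights]


def quantize_threshold(T: float, ls: int) -> int:
    """Fixed-point threshold ``round(T * 2^ls)``; T=1 maps to 2^ls."""
    if not 0.0 < T <= 1.0:
        raise ConfigError(f"threshold must be in (0,1], got {T}")
    return round_half_away(T * (1 << ls))


def rounding_int_div(numerator: int, denominator: int, ls: int) -> int:
    """Rounding division at scale ``2^ls``: ``((a << ls) + b/2) / b``.

    Truncating integer division throughout, so the result is
    ``round_half_up(a * 2^ls / b)``.  A zero denominator returns 0 by
    convention (both Bloom filters empty).
    """
    if numerator < 0 or denominator < 0:
        raise ValueError("rounding_int_div requires non-negative operands")
    if denominator == 0:
        return 0
    return ((numerator << ls) + denominator // 2) // denominator


@dataclass(frozen=True)
class QuantizedConfig:
    """A validated configuration with all real numbers quantized.

    ``weights`` are the integer field weights (the maximum saturates
    ``2^lw - 1``), ``threshold_q``/``tentative_q`` the thresholds at scale
    ``2^ls``.
    """

    config: LinkageConfig
    plan: PrecisionPlan
    weights: tuple[int, ...]
    threshold_q: int
    tentative_q: int | None

    def weight_of(self, name: str) -> int:
        return self.weights[self.config.field_names.index(name)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "plan": asdict(self.plan),
                "weights": dict(zip(self.config.field_names, self.weights)),
                "threshold_q": self.threshold_q,
                "tentative_q": self.tentative_q,
            }
        )


def quantize_config(
    config: LinkageConfig, L: int | None = None
) -> QuantizedConfig:
    """Quantize a validated configuration for word size L (default: config's)."""
    if config.weights is None:
        config = config.validated()
    L = config.bit_length if L is None else L
    plan = choose_precisions(L, config.n_fields)
    return QuantizedConfig(
        config=config,
        plan=plan,
        weights=tuple(quantize_weights(config.weights, plan.lw)),
        threshold_q=quantize_threshold(config.threshold, plan.ls),
        tentative_q=(
            None
            if config.tentative_threshold is None
            else quantize_threshold(config.tentative_threshold, plan.ls)
        ),
    )


# ---------------------------------------------------------------------------
# Integer scoring (the circuit oracle)
# ---------------------------------------------------------------------------

def fixed_field_similarity(x_enc, y_enc, spec, ls: int) -> int:
    """Quantized field similarity in ``0 .. 2^ls``."""
    if spec.comparator == "equality":
        return (1 << ls) if x_enc == y_enc else 0
    inter = (x_enc & y_enc).hamming
    return rounding_int_div(2 * inter, x_enc.hamming + y_enc.hamming, ls)


def _check_product(s: int, w: int, L: int) -> None:
    if s * w >= (1 << L):
        raise OverflowError(
            f"tie-solving product {s}*{w} exceeds {L} bits; "
            "precision plan violated"
        )


def _int_tie_greater(p1: ScorePair, p2: ScorePair, L: int) -> bool:
    _check_product(p1.s, p2.w, L)
    _check_product(p2.s, p1.w, L)
    return tie_solving_greater(p1, p2)


def fixed_group_score(
    x: Record,
    y: Record,
    group: ExchangeGroup,
    qconfig: QuantizedConfig,
) -> ScorePair:
    """Integer exchange-group score: permutation maximum, truncated
    averaged weights ``(w_i + w_j) // 2``."""
    ls = qconfig.plan.ls
    L = qconfig.plan.L
    members = group.members
    best: ScorePair | None = None
    for image in permutations(members):
        s = 0
        w = 0
        for i, j in zip(members, image):
            if not (x.delta[i] and y.delta[j]):
                continue
            w_ij = (qconfig.weight_of(i) + qconfig.weight_of(j)) // 2
            sim = fixed_field_similarity(
                x.encoded[i], y.encoded[j], qconfig.config.field(i), ls
            )
            s += w_ij * sim
            w += w_ij
        candidate = ScorePair(s, w)
        if best is None or _int_tie_greater(candidate, best, L):
            best = candidate
    assert best is not None
    return best


def fixed_record_score(
    x: Record, y: Record, qconfig: QuantizedConfig
) -> ScorePair:
    """Exact integer score pair: ``s`` at scale ``2^(lw+ls)``, ``w`` at
    scale ``2^lw`` (relative to the rescaled weights)."""
    config = qconfig.config
    ls = qconfig.plan.ls
    s = 0
    w = 0
    for group in config.exchange_groups:
        gs, gw = fixed_group_score(x, y, group, qconfig)
        s += gs
        w += gw
    for name in config.ungrouped_fields():
        if not (x.delta[name] and y.delta[name]):
            continue
        weight = qconfig.weight_of(name)
        s += weight * fixed_field_similarity(
            x.encoded[name], y.encoded[name], config.field(name), ls
        )
        w += weight
    return ScorePair(int(s), int(w))


def fixed_score_value(pair: ScorePair, ls: int) -> float:
    """The [0,1] score a fixed pair represents: ``s / (w * 2^ls)``."""
    if pair.w == 0:
        return 0.0
    return pair.s / (pair.w * (1 << ls))


def score_deviation_experiment(
    pairs: Sequence[tuple[Record, Record]],
    config: LinkageConfig,
    L: int,
) -> float:
    """Maximum |fixed-point score - float score| over record pairs.

    Both scores are normalized to [0, 1] (the fixed value as
    ``s / (w * 2^ls)``); pairs whose denominators are zero on both sides
    contribute 0.  This is the accuracy experiment behind the choice of L:
    the deviation stays below 1% for L=16, 0.1% for L=32 and below 1e-4
    for L=64 on random-pair corpora.
    """
    from .epilink_reference import record_score

    qconfig = quantize_config(config, L)
    ls = qconfig.plan.ls
    worst = 0.0
    for x, y in pairs:
        ref = record_score(x, y, config)
        fix = fixed_record_score(x, y, qconfig)
        ref_val = ref.s / ref.w if ref.w else 0.0
        fix_val = fix.s / (fix.w * (1 << ls)) if fix.w else 0.0
        worst = max(worst, abs(ref_val - fix_val))
    return worst


def fixed_best_match(
    x: Record, db: Sequence[Record], qconfig: QuantizedConfig
) -> MatchResult:
    """Best match under exact integer scoring and integer thresholding.

    The match predicate is ``s > T_q * w`` with both sides at scale
    ``2^(lw+ls)``; overflow of any tie-solving product raises (it cannot
    happen when the precision plan's invariants hold).
    """
    if not db:
        raise ValueError("fixed_best_match requires a non-empty database")
    L = qconfig.plan.L
    scored = [
        (fixed_record_score(x, y, qconfig), j) for j, y in enumerate(db)
    ]

    def fold(items):
        if len(items) == 1:
            return items[0]
        mid = (len(items) + 1) // 2
        left = fold(items[:mid])
        right = fold(items[mid:])
        return right if _int_tie_greater(right[0], left[0], L) else left

    (s, w), j_star = fold(scored)
    match = int(s > qconfig.threshold_q * w)
    tentative = 0
    if qconfig.tentative_q is not None and not match:
        tentative = int(qconfig.tentative_q * w < s)
    return MatchResult(
        index=j_star, match=match, tentative=tentative, score=ScorePair(s, w)
    )
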