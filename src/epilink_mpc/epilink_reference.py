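"""Floating-point reference implementation of the EpiLink match score.

The similarity score of two records is a normalized weighted sum of
per-field similarities,

    S(x, y) = s(x, y) / w(x, y)
            = sum_i  delta_i * w_i * sim_i(x_i, y_i)
            / sum_i  delta_i * w_i,

where ``delta_i`` is 1 only when both field values are non-empty, so
missing fields drop out of numerator and denominator alike.  The division
is never materialized: scores travel as ``(s, w)`` pairs and are compared
with the *tie-solving order*

    (s1, w1) > (s2, w2)  :<=>  s1*w2 > s2*w1  or  (s1*w2 = s2*w1 and w1 > w2),

which compares quotients by cross-multiplication and, on equal quotients,
prefers the pair with the larger denominator (more fields contributed).
It also handles zero denominators: a (0, 0) pair loses against anything
with w > 0.

Exchange groups (e.g. given/sur/birth name) are scored as the maximum,
under this order, over all permutations of the group's fields, with the
averaged weight w_{i,sigma(i)} = (w_i + w_sigma(i)) / 2, which absorbs
accidentally swapped entries and keeps the score symmetric in x and y.

``best_match`` selects the best database record by a balanced binary-tree
fold of the tie-solving comparison and tests the winner against the
threshold(s); ``match_cardinality`` counts the queries with an
above-threshold partner.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import NamedTuple, Sequence

from .bloom_encoding import BloomVector, dice_similarity
from .config_records import (
    MAX_GROUP_SIZE,
    ConfigError,
    ExchangeGroup,
    FieldSpec,
    LinkageConfig,
    Record,
)

__all__ = [
    "ScorePair",
    "MatchResult",
    "field_similarity",
    "tie_solving_greater",
    "group_score",
    "record_score",
    "best_match",
    "match_cardinality",
]


class ScorePair(NamedTuple):
    """Numerator (field-weight sum) and denominator (weight sum) of a score.

    ``(0, 0)`` means "no comparable fields".  Works for floats and for the
    fixed-point integers of the circuit pipeline alike.
    """

    s: float
    w: float

    @property
    def quotient(self) -> float:
        return self.s / self.w if self.w else 0.0


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one best-match query.

    ``index`` is the 0-based index of the best-scoring database record;
    ``match`` is 1 iff its score exceeds the match threshold; ``tentative``
    is 1 iff the score falls in the optional band between the tentative and
    the match threshold (tentative implies not match).
    """

    index: int
    match: int
    tentative: int
    score: ScorePair


def field_similarity(x_enc, y_enc, spec: FieldSpec) -> float:
    """Similarity of two non-empty encoded field values in [0, 1]."""
    if spec.comparator == "equality":
        if isinstance(x_enc, BloomVector) or isinstance(y_enc, BloomVector):
            raise ConfigError(
                f"field {spec.name!r}: equality comparator got a Bloom vector"
            )
        return 1.0 if x_enc == y_enc else 0.0
    if not isinstance(x_enc, BloomVector) or not isinstance(y_enc, BloomVector):
        raise ConfigError(
            f"field {spec.name!r}: dice comparator needs Bloom vectors"
        )
    return dice_similarity(x_enc, y_enc)


def tie_solving_greater(p1: ScorePair, p2: ScorePair) -> bool:
    """Strict tie-solving comparison of two never-divided quotients."""
    s1, w1 = p1
    s2, w2 = p2
    lhs = s1 * w2
    rhs = s2 * w1
    return lhs > rhs or (lhs == rhs and w1 > w2)


def _pair_delta(x: Record, y: Record, i: str, j: str) -> int:
    return x.delta[i] * y.delta[j]


def group_score(
    x: Record,
    y: Record,
    group: ExchangeGroup,
    config: LinkageConfig,
) -> ScorePair:
    """Score pair of one exchange group: max over field permutations.

    For each permutation sigma of the group, field i of x is compared with
    field sigma(i) of y at the averaged weight (w_i + w_sigma(i)) / 2, and
    the permutation winning under the tie-solving order is returned.
    """
    members = group.members
    if len(members) > MAX_GROUP_SIZE:
        raise ConfigError(
            f"exchange group {members} exceeds the size cap {MAX_GROUP_SIZE}"
        )
    best: ScorePair | None = None
    for image in permutations(members):
        s = 0.0
        w = 0.0
        for i, j in zip(members, image):
            if not _pair_delta(x, y, i, j):
                continue
            w_ij = (config.weight_of(i) + config.weight_of(j)) / 2.0
            sim = field_similarity(
                x.encoded[i], y.encoded[j], config.field(i)
            )
            s += w_ij * sim
            w += w_ij
        candidate = ScorePair(s, w)
        if best is None or tie_solving_greater(candidate, best):
            best = candidate
    assert best is not None
    return best


def record_score(x: Record, y: Record, config: LinkageConfig) -> ScorePair:
    """Total score pair: exchange-group maxima plus ungrouped identity terms."""
    if config.weights is None:
        raise ConfigError("config not validated")
    s = 0.0
    w = 0.0
    for group in config.exchange_groups:
        gs, gw = group_score(x, y, group, config)
        s += gs
        w += gw
    for name in config.ungrouped_fields():
        if not _pair_delta(x, y, name, name):
            continue
        weight = config.weight_of(name)
        s += weight * field_similarity(
            x.encoded[name], y.encoded[name], config.field(name)
        )
        w += weight
    return ScorePair(s, w)


def _fold_best(
    pairs: Sequence[tuple[ScorePair, int]]
) -> tuple[ScorePair, int]:
    """Balanced binary-tree fold under the tie-solving order.

    At every fold node the right operand wins only if strictly greater;
    on full equality (equal cross-products and equal denominators) the
    earlier candidate survives, which makes the result independent of the
    tree shape.
    """
    if len(pairs) == 1:
        return pairs[0]
    mid = (len(pairs) + 1) // 2
    left = _fold_best(pairs[:mid])
    right = _fold_best(pairs[mid:])
    return right if tie_solving_greater(right[0], left[0]) else left


def best_match(
    x: Record, db: Sequence[Record], config: LinkageConfig
) -> MatchResult:
    """Best-scoring database record for query ``x`` plus threshold bits.

    The match bit is ``[s* > T * w*]``; with a tentative threshold
    configured, the tentative bit marks ``T_tent * w* < s* <= T * w*``.
    """
    if not db:
        raise ValueError("best_match requires a non-empty database")
    scored = [(record_score(x, y, config), j) for j, y in enumerate(db)]
    (s, w), j_star = _fold_best(scored)
    match = int(s > config.threshold * w)
    tentative = 0
    if config.tentative_threshold is not None and not match:
        tentative = int(config.tentative_threshold * w < s)
    return MatchResult(
        index=j_star, match=match, tentative=tentative, score=ScorePair(s, w)
    )


def match_cardinality(
    X: Sequence[Record], Y: Sequence[Record], config: LinkageConfig
) -> int:
    """Number of queries in X with an above-threshold partner in Y.

    Equals the sum of best-match bits; bounded above by ``len(X)``.
    Tentative matches count as non-matches.
    """
    if not X or not Y:
        raise ValueError("match_cardinality requires non-empty record lists")
    return sum(best_match(x, Y, config).match for x in X)
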