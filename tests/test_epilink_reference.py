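"""Reference EpiLink score: tie order, exchange groups, best match."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epilink_mpc.bloom_encoding import BloomVector
from epilink_mpc.config_records import (
    ExchangeGroup,
    FieldSpec,
    LinkageConfig,
    Record,
    validate_config,
)
from epilink_mpc.epilink_reference import (
    ScorePair,
    best_match,
    field_similarity,
    group_score,
    match_cardinality,
    record_score,
    tie_solving_greater,
)

pairs_strategy = st.tuples(
    st.integers(0, 50), st.integers(0, 50)
).map(lambda t: ScorePair(min(t), max(t)))  # s <= w


class TestTieSolvingOrder:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            ((2, 4), (1, 2), True),   # equal quotients, larger denominator
            ((1, 2), (0, 0), True),   # zero denominator loses
            ((0, 0), (1, 2), False),
            ((3, 4), (2, 4), True),
            ((2, 4), (3, 4), False),
            ((0, 0), (0, 0), False),  # full equality: not strictly greater
        ],
    )
    def test_examples(self, p1, p2, expected):
        assert tie_solving_greater(ScorePair(*p1), ScorePair(*p2)) is expected

    @given(pairs_strategy, pairs_strategy)
    @settings(max_examples=200, deadline=None)
    def test_totality(self, p1, p2):
        """Exactly one of >, <, or full cross-product-and-w equality."""
        gt = tie_solving_greater(p1, p2)
        lt = tie_solving_greater(p2, p1)
        equal = p1.s * p2.w == p2.s * p1.w and p1.w == p2.w
        assert [gt, lt, equal].count(True) == 1

    @given(pairs_strategy, pairs_strategy, pairs_strategy)
    @settings(max_examples=200, deadline=None)
    def test_transitivity(self, a, b, c):
        if tie_solving_greater(a, b) and tie_solving_greater(b, c):
            assert tie_solving_greater(a, c)


def _two_name_config(threshold=0.8):
    return validate_config(
        LinkageConfig(
            fields=(
                FieldSpec("first", "dice", 64, weight=4.0),
                FieldSpec("last", "dice", 64, weight=6.0),
            ),
            exchange_groups=(ExchangeGroup(("first", "last")),),
            threshold=threshold,
            bloom_length=64,
            bloom_hashes=3,
        )
    )


def _name_record(config, **values):
    return Record.from_values(values, config)


class TestExchangeGroups:
    def test_swapped_names_recovered_as_full_match(self):
        config = _two_name_config()
        x = _name_record(config, first="JOHN", last="SMITH")
        y = _name_record(config, first="SMITH", last="JOHN")
        pair = group_score(
            x, y, config.exchange_groups[0], config
        )
        assert pair.s == pytest.approx(pair.w)  # similarity 1 via swap
        assert pair.w == pytest.approx(10.0)  # both averaged weights

    def test_all_y_fields_empty_gives_zero_pair(self):
        config = _two_name_config()
        x = _name_record(config, first="JOHN", last="SMITH")
        y = _name_record(config, first="", last="")
        assert group_score(x, y, config.exchange_groups[0], config) == (0, 0)

    def test_group_score_equals_bruteforce_permutation_max(self, rng):
        """Oracle: enumerate all permutations by hand for |G| in {2,3,4}."""
        for size in (2, 3, 4):
            names = [f"n{i}" for i in range(size)]
            config = validate_config(
                LinkageConfig(
                    fields=tuple(
                        FieldSpec(n, "dice", 32, weight=float(i + 1))
                        for i, n in enumerate(names)
                    ),
                    exchange_groups=(ExchangeGroup(tuple(names)),),
                    bloom_length=32,
                    bloom_hashes=3,
                )
            )
            for _ in range(20):
                def rand_rec():
                    values = {}
                    for n in names:
                        if rng.random() < 0.15:
                            values[n] = ""
                        else:
                            length = 3 + int(rng.integers(6))
                            values[n] = "".join(
                                chr(65 + c)
                                for c in rng.integers(0, 26, length)
                            )
                    return Record.from_values(values, config)

                x, y = rand_rec(), rand_rec()
                best = None
                for image in permutations(names):
                    s = w = 0.0
                    for i, j in zip(names, image):
                        if not (x.delta[i] and y.delta[j]):
                            continue
                        w_ij = (config.weight_of(i) + config.weight_of(j)) / 2
                        sim = field_similarity(
                            x.encoded[i], y.encoded[j], config.field(i)
                        )
                        s += w_ij * sim
                        w += w_ij
                    cand = ScorePair(s, w)
                    if best is None or tie_solving_greater(cand, best):
                        best = cand
                assert group_score(
                    x, y, config.exchange_groups[0], config
                ) == best


class TestRecordScore:
    def test_identical_records_score_one(self, small_config):
        rec = Record.from_values(
            dict(first_name="ANNA", last_name="SCHMIDT", birth_name="WEBER",
                 city="BERLIN", birth_day=7, birth_month=3, birth_year=1980,
                 zip=10115),
            small_config,
        )
        s, w = record_score(rec, rec, small_config)
        assert s == pytest.approx(w)
        assert w > 0

    def test_half_match_on_equal_weight_equality_fields(
        self, tiny_equality_config
    ):
        x = Record.from_values({"a": 1, "b": 2}, tiny_equality_config)
        y = Record.from_values({"a": 1, "b": 3}, tiny_equality_config)
        s, w = record_score(x, y, tiny_equality_config)
        assert s / w == pytest.approx(0.5)

    def test_empty_candidate_gives_zero_pair(self, tiny_equality_config):
        x = Record.from_values({"a": 1, "b": 2}, tiny_equality_config)
        y = Record.from_values({"a": "", "b": ""}, tiny_equality_config)
        assert record_score(x, y, tiny_equality_config) == (0, 0)

    def test_score_symmetric_in_x_and_y(self, small_config, rng):
        recs = _random_records(small_config, rng, 12)
        for x, y in zip(recs[:6], recs[6:]):
            sx = record_score(x, y, small_config)
            sy = record_score(y, x, small_config)
            qx = sx.s / sx.w if sx.w else 0.0
            qy = sy.s / sy.w if sy.w else 0.0
            assert qx == pytest.approx(qy, abs=1e-12)
            # averaged weights also make the denominators agree
            assert sx.w == pytest.approx(sy.w, abs=1e-9)

    def test_score_pair_in_range(self, small_config, rng):
        for x, y in zip(
            _random_records(small_config, rng, 10),
            _random_records(small_config, rng, 10),
        ):
            s, w = record_score(x, y, small_config)
            assert 0.0 <= s <= w + 1e-9


from conftest import random_default_records as _random_records


class TestBestMatch:
    def test_exact_copy_wins_with_match_bit(self, small_config, rng):
        db = _random_records(small_config, rng, 9)
        x = db[5]
        result = best_match(x, db, small_config)
        assert result.index == 5
        assert result.match == 1

    def test_dissimilar_database_still_returns_an_index(
        self, tiny_equality_config
    ):
        x = Record.from_values({"a": 1, "b": 2}, tiny_equality_config)
        db = [
            Record.from_values({"a": 10 + i, "b": 20 + i},
                               tiny_equality_config)
            for i in range(4)
        ]
        result = best_match(x, db, tiny_equality_config)
        assert result.match == 0
        assert 0 <= result.index < 4

    def test_identical_best_candidates_lowest_index_wins(
        self, tiny_equality_config
    ):
        x = Record.from_values({"a": 1, "b": 2}, tiny_equality_config)
        filler = Record.from_values({"a": 9, "b": 9}, tiny_equality_config)
        twin = Record.from_values({"a": 1, "b": 2}, tiny_equality_config)
        db = [filler, filler, twin, filler, twin]
        assert best_match(x, db, tiny_equality_config).index == 2

    def test_fold_equals_naive_argmax_loop(self, small_config, rng):
        """Oracle: a left-to-right scan with the same strict comparison."""
        for n in (1, 2, 3, 7, 17, 64):
            db = _random_records(small_config, rng, n)
            x = _random_records(small_config, rng, 1)[0]
            result = best_match(x, db, small_config)
            best_j, best_pair = 0, record_score(x, db[0], small_config)
            for j in range(1, n):
                pair = record_score(x, db[j], small_config)
                if tie_solving_greater(pair, best_pair):
                    best_j, best_pair = j, pair
            assert result.index == best_j
            assert result.score == best_pair

    def test_empty_database_rejected(self, tiny_equality_config):
        x = Record.from_values({"a": 1, "b": 2}, tiny_equality_config)
        with pytest.raises(ValueError):
            best_match(x, [], tiny_equality_config)

    def test_tentative_band_between_thresholds(self):
        config = validate_config(
            LinkageConfig(
                fields=(
                    FieldSpec("a", "equality", 8, weight=1.0),
                    FieldSpec("b", "equality", 8, weight=1.0),
                ),
                threshold=0.75,
                tentative_threshold=0.25,
            )
        )
        x = Record.from_values({"a": 1, "b": 2}, config)
        half = Record.from_values({"a": 1, "b": 3}, config)
        result = best_match(x, [half], config)
        assert result.match == 0
        assert result.tentative == 1


class TestMatchCardinality:
    def test_three_by_three_toy_counts_one(self, tiny_equality_config):
        """Exhaustive pairwise scoring of the toy set leaves one match."""
        make = lambda a, b: Record.from_values(
            {"a": a, "b": b}, tiny_equality_config
        )
        X = [make(65, 1), make(66, 2), make(67, 3)]
        Y = [make(65, 1), make(66, 9), make(90, 9)]
        # (A,1)/(A,1): S=1 > 0.75; (B,2)/(B,9): S=0.5; (C,3)/(Z,9): S=0
        assert match_cardinality(X, Y, tiny_equality_config) == 1

    def test_disjoint_sets_count_zero(self, tiny_equality_config):
        make = lambda a, b: Record.from_values(
            {"a": a, "b": b}, tiny_equality_config
        )
        X = [make(1, 1), make(2, 2)]
        Y = [make(30, 30), make(40, 40)]
        assert match_cardinality(X, Y, tiny_equality_config) == 0

    def test_self_linkage_counts_everything(self, small_config, rng):
        records = _random_records(small_config, rng, 8)
        # fully distinct, fully populated records match themselves
        records = [
            r for r in records if all(r.delta[n] for n in r.delta)
        ] or _random_records(small_config, rng, 3)
        n = match_cardinality(records, records, small_config)
        assert n == len(records)
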