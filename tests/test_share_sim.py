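"""Secret-sharing simulator: gadget correctness and end-to-end equality."""

import numpy as np
import pytest
from scipy import stats

from conftest import random_default_records
from epilink_mpc.circuit_model import build_bestmatch_circuit
from epilink_mpc.fixed_point import quantize_config
from epilink_mpc.share_sim import (
    MessageLog,
    SharePair,
    TripleStore,
    _Engine,
    evaluate_shared,
    reconstruct,
    run_bestmatch_shared,
    share,
    split_inputs,
)


def _engine(L=32, seed=0, capacity=None):
    class _Dummy:
        pass

    circuit = _Dummy()
    circuit.L = L
    return _Engine(
        circuit,
        TripleStore(seed, L, capacity=capacity),
        np.random.default_rng(seed + 1),
        MessageLog(),
    )


class TestSharing:
    def test_one_bit_values_roundtrip_exhaustively(self):
        for domain in ("B", "A"):
            for v in (0, 1):
                for seed in range(8):
                    assert reconstruct(share(v, domain, 1, seed)) == v

    def test_arithmetic_zero_shares_are_negatives(self):
        pair = share(0, "A", 16, 3)
        assert (pair.a + pair.b) % (1 << 16) == 0

    def test_fixed_seed_reproducible(self):
        assert share(123, "B", 16, 9) == share(123, "B", 16, 9)

    def test_roundtrip_many_random_values(self, rng):
        for _ in range(1000):
            width = int(rng.integers(1, 33))
            v = int(rng.integers(0, 1 << width))
            domain = "B" if rng.random() < 0.5 else "A"
            assert reconstruct(share(v, domain, width, int(rng.integers(2**31)))) == v

    def test_boolean_and_arithmetic_reconstruction_rules(self):
        assert reconstruct(SharePair(0b1010, 0b0110, "B", 4)) == 0b1100
        L = 16
        assert reconstruct(SharePair((1 << L) - 1, 1, "A", L)) == 0

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError):
            share(4, "B", 2, 0)

    def test_share_marginals_look_uniform(self):
        """Chi-square sanity check: each party's share of a fixed value is
        (seed-)uniform over its domain."""
        counts = np.zeros(16, dtype=int)
        for seed in range(4096):
            counts[share(5, "B", 4, seed).a] += 1
        assert stats.chisquare(counts).pvalue > 1e-3


class TestBeaverGadgets:
    def test_and_exhaustive_truth_table(self):
        eng = _engine()
        for x in (0, 1):
            for y in (0, 1):
                for seed in range(4):
                    xs = share(x, "B", 1, seed)
                    ys = share(y, "B", 1, seed + 100)
                    z = eng.beaver_and(xs, ys, 1)
                    assert reconstruct(z) == (x & y)

    def test_arithmetic_multiplication_random_32bit(self, rng):
        eng = _engine(L=32)
        mask = (1 << 32) - 1
        for _ in range(200):
            x = int(rng.integers(0, 1 << 32))
            y = int(rng.integers(0, 1 << 32))
            z = eng.beaver_mul(
                share(x, "A", 32, int(rng.integers(2**31))),
                share(y, "A", 32, int(rng.integers(2**31))),
            )
            assert reconstruct(z) == (x * y) & mask

    def test_adder_exhaustive_width_four(self):
        eng = _engine()
        for x in range(16):
            for y in range(16):
                for cin in (0, 1):
                    total, carry = eng.bool_adder(
                        share(x, "B", 4, x * 31 + y),
                        share(y, "B", 4, 77 + x + 16 * y),
                        4, cin=cin,
                    )
                    full = x + y + cin
                    assert reconstruct(total) == full & 0xF
                    assert reconstruct(carry) == full >> 4

    def test_comparison_and_equality_random(self, rng):
        eng = _engine()
        for _ in range(150):
            w = int(rng.integers(2, 17))
            x = int(rng.integers(0, 1 << w))
            y = int(rng.integers(0, 1 << w))
            xs = share(x, "B", w, int(rng.integers(2**31)))
            ys = share(y, "B", w, int(rng.integers(2**31)))
            assert reconstruct(eng.bool_gt(xs, ys, w)) == int(x > y)
            assert reconstruct(eng.bool_eq(xs, ys, w)) == int(x == y)

    def test_mux_and_conversions(self, rng):
        eng = _engine(L=16)
        for _ in range(60):
            w = int(rng.integers(1, 13))
            a = int(rng.integers(0, 1 << w))
            b = int(rng.integers(0, 1 << w))
            sel = int(rng.integers(0, 2))
            out = eng.bool_mux(
                share(sel, "B", 1, 5),
                share(a, "B", w, 6),
                share(b, "B", w, 7),
                w,
            )
            assert reconstruct(out) == (a if sel else b)
            # B2A then A2B is the identity on the value
            ar = eng.b2a(share(a, "B", w, 8))
            assert reconstruct(ar) == a
            back = eng.a2b(ar)
            assert reconstruct(back) == a

    def test_triple_exhaustion_raises(self):
        eng = _engine(capacity=2)
        x = share(1, "B", 1, 0)
        eng.beaver_and(x, x, 1)
        eng.beaver_and(x, x, 1)
        with pytest.raises(RuntimeError, match="exhausted"):
            eng.beaver_and(x, x, 1)


class TestEndToEnd:
    def test_full_bestmatch_reconstruction_equals_cleartext(
        self, small_config, rng
    ):
        from epilink_mpc.circuit_model import run_bestmatch_circuit

        qc = quantize_config(small_config)
        circuit = build_bestmatch_circuit(qc, 8, "GMW/A")
        db = random_default_records(small_config, rng, 8)
        x = random_default_records(small_config, rng, 1)[0]
        clear = run_bestmatch_circuit(circuit, x, db)
        log = MessageLog()
        shared = run_bestmatch_shared(circuit, x, db, seed=42, log=log)
        assert shared == clear
        assert log.round > 0 and log.total_bytes() > 0

    def test_outputs_remain_shared_until_reconstruction(
        self, small_config, rng
    ):
        qc = quantize_config(small_config)
        circuit = build_bestmatch_circuit(qc, 2, "GMW/A")
        db = random_default_records(small_config, rng, 2)
        x = random_default_records(small_config, rng, 1)[0]
        inputs_a, inputs_b = split_inputs(circuit, x, db)
        triples = TripleStore(1, circuit.L)
        out = evaluate_shared(circuit, inputs_a, inputs_b, triples, rng=2)
        assert isinstance(out["match"], SharePair)

    def test_party_role_swap_is_transparent(self, small_config, rng):
        """Swapping which slot holds which share never changes the
        reconstructed output."""
        qc = quantize_config(small_config)
        circuit = build_bestmatch_circuit(qc, 3, "GMW/A")
        db = random_default_records(small_config, rng, 3)
        x = random_default_records(small_config, rng, 1)[0]
        first = run_bestmatch_shared(circuit, x, db, seed=11)
        second = run_bestmatch_shared(circuit, x, db, seed=12)
        assert first == second

    def test_missing_party_input_rejected(self, small_config, rng):
        qc = quantize_config(small_config)
        circuit = build_bestmatch_circuit(qc, 2, "GMW/A")
        db = random_default_records(small_config, rng, 2)
        x = random_default_records(small_config, rng, 1)[0]
        inputs_a, inputs_b = split_inputs(circuit, x, db)
        inputs_b.popitem()
        with pytest.raises(ValueError, match="missing"):
            evaluate_shared(
                circuit, inputs_a, inputs_b, TripleStore(0, circuit.L)
            )
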