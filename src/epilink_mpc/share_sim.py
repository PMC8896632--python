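"""Simulated semi-honest two-party evaluation of the circuit on shares.

This module demonstrates the secure-computation decomposition end to end,
*functionally*: wires carry XOR shares (Boolean domain) or additive shares
mod ``2^L`` (arithmetic domain), linear gates are evaluated locally, and
every AND/MUL consumes a precomputed multiplication triple ``(a, b, c=ab)``
handed out by a seeded trusted dealer.  Comparisons, equality tests,
multiplexers and domain conversions are decomposed into the textbook
XOR/AND gadgets (a Kogge-Stone carry computation for additions and
comparisons, an AND-reduce for equality, one masked AND per multiplexer).
Both parties run in one process with an explicit message log, so round and
traffic structure can be inspected.

This is a correctness simulator, not a secure implementation: the dealer
replaces oblivious-transfer-based triple generation, and no cryptographic
transport exists.  What it preserves exactly is the protocol arithmetic —
``reconstruct(evaluate_shared(...))`` equals the cleartext circuit
evaluation on every input — and the share-level view: each party's share
of any wire is individually uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .circuit_model import Circuit, CircuitOutput, bind_records
from .config_records import Record
from .epilink_reference import ScorePair

__all__ = [
    "SharePair",
    "TripleStore",
    "MessageLog",
    "share",
    "reconstruct",
    "evaluate_shared",
    "split_inputs",
    "run_bestmatch_shared",
]


@dataclass(frozen=True)
class SharePair:
    """The two parties' shares of one wire.

    Boolean domain: ``a XOR b`` is the plaintext; arithmetic domain:
    ``(a + b) mod 2^L``.
    """

    a: int
    b: int
    domain: str  # "B" or "A"
    width: int


def _rand_bits(rng: np.random.Generator, width: int) -> int:
    nbytes = (width + 7) // 8 or 1
    return int.from_bytes(rng.bytes(nbytes), "little") & ((1 << width) - 1)


def share(
    value: int,
    domain: str,
    width: int,
    rng: np.random.Generator | int,
) -> SharePair:
    """Split ``value`` into a uniformly masked share pair."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    mask = (1 << width) - 1
    if not 0 <= value <= mask:
        raise ValueError(f"value {value} out of range for width {width}")
    r = _rand_bits(rng, width)
    if domain == "B":
        return SharePair(r, value ^ r, "B", width)
    return SharePair(r, (value - r) & mask, "A", width)


def reconstruct(pair: SharePair) -> int:
    """Combine the two shares back into the plaintext wire value."""
    mask = (1 << pair.width) - 1
    if pair.domain == "B":
        return (pair.a ^ pair.b) & mask
    return (pair.a + pair.b) & mask


class TripleStore:
    """Dealer-seeded stream of multiplication triples per domain.

    ``capacity`` bounds the number of triples that may be drawn (AND and
    MUL gates each consume one); drawing past it raises, modelling an
    undersized setup phase.
    """

    def __init__(self, seed: int, L: int, capacity: int | None = None):
        self.rng = np.random.default_rng(seed)
        self.L = L
        self.capacity = capacity
        self.used = 0

    def _take(self) -> None:
        self.used += 1
        if self.capacity is not None and self.used > self.capacity:
            raise RuntimeError(
                "multiplication triples exhausted: setup phase provided "
                f"only {self.capacity}"
            )

    def bool_triple(self, width: int):
        """Shares of random (a, b, c = a AND b) bitmasks."""
        self._take()
        a = _rand_bits(self.rng, width)
        b = _rand_bits(self.rng, width)
        c = a & b
        a1 = _rand_bits(self.rng, width)
        b1 = _rand_bits(self.rng, width)
        c1 = _rand_bits(self.rng, width)
        return (a1, a ^ a1), (b1, b ^ b1), (c1, c ^ c1)

    def arith_triple(self):
        """Shares of random (a, b, c = a*b mod 2^L)."""
        self._take()
        mask = (1 << self.L) - 1
        a = _rand_bits(self.rng, self.L)
        b = _rand_bits(self.rng, self.L)
        c = (a * b) & mask
        a1 = _rand_bits(self.rng, self.L)
        b1 = _rand_bits(self.rng, self.L)
        c1 = _rand_bits(self.rng, self.L)
        return (a1, (a - a1) & mask), (b1, (b - b1) & mask), \
            (c1, (c - c1) & mask)


@dataclass
class MessageLog:
    """Transcript of simulated exchanges: one entry per message."""

    messages: list = field(default_factory=list)
    round: int = 0

    def exchange(self, nbytes: int) -> None:
        """One synchronous opening: both directions, one round."""
        self.round += 1
        self.messages.append(
            {"round": self.round, "direction": "A->B", "bytes": nbytes}
        )
        self.messages.append(
            {"round": self.round, "direction": "B->A", "bytes": nbytes}
        )

    def total_bytes(self) -> int:
        return sum(m["bytes"] for m in self.messages)


class _Engine:
    """Walks the DAG once, keeping a SharePair per wire."""

    def __init__(self, circuit: Circuit, triples: TripleStore,
                 rng: np.random.Generator, log: MessageLog):
        self.circuit = circuit
        self.L = circuit.L
        self.triples = triples
        self.rng = rng
        self.log = log

    # -- primitive protocols --------------------------------------------
    def _open(self, width: int) -> None:
        self.log.exchange((width + 7) // 8)

    def beaver_and(self, x: SharePair, y: SharePair, width: int) -> SharePair:
        (a1, a2), (b1, b2), (c1, c2) = self.triples.bool_triple(width)
        d = (x.a ^ a1) ^ (x.b ^ a2)  # both parties' blinded differences,
        e = (y.a ^ b1) ^ (y.b ^ b2)  # opened to each other
        self._open(2 * width)
        z1 = c1 ^ (d & b1) ^ (e & a1) ^ (d & e)
        z2 = c2 ^ (d & b2) ^ (e & a2)
        return SharePair(z1, z2, "B", width)

    def beaver_mul(self, x: SharePair, y: SharePair) -> SharePair:
        mask = (1 << self.L) - 1
        (a1, a2), (b1, b2), (c1, c2) = self.triples.arith_triple()
        d = ((x.a - a1) + (x.b - a2)) & mask
        e = ((y.a - b1) + (y.b - b2)) & mask
        self._open(2 * self.L)
        z1 = (c1 + d * b1 + e * a1 + d * e) & mask
        z2 = (c2 + d * b2 + e * a2) & mask
        return SharePair(z1, z2, "A", self.L)

    def _ext(self, x: SharePair, width: int) -> SharePair:
        """Zero-extend a Boolean share pair (shares extend bit-wise)."""
        return SharePair(x.a, x.b, "B", width)

    def bool_not(self, x: SharePair) -> SharePair:
        mask = (1 << x.width) - 1
        return SharePair(x.a ^ mask, x.b, "B", x.width)

    def bool_adder(
        self, x: SharePair, y: SharePair, width: int, cin: int = 0
    ):
        """Kogge-Stone addition of Boolean-shared words; returns
        (sum mod 2^width, carry-out)."""
        x = self._ext(x, width)
        y = self._ext(y, width)
        p = SharePair(x.a ^ y.a, x.b ^ y.b, "B", width)
        g = self.beaver_and(x, y, width)
        if cin:
            g = SharePair(g.a ^ (p.a & 1), g.b ^ (p.b & 1), "B", width)
        G, P = g, p
        shift_amount = 1
        while shift_amount < width:
            G_shift = SharePair(
                (G.a << shift_amount) & ((1 << width) - 1),
                (G.b << shift_amount) & ((1 << width) - 1),
                "B", width,
            )
            P_shift = SharePair(
                (P.a << shift_amount) & ((1 << width) - 1),
                (P.b << shift_amount) & ((1 << width) - 1),
                "B", width,
            )
            t = self.beaver_and(P, G_shift, width)
            G = SharePair(G.a ^ t.a, G.b ^ t.b, "B", width)
            P = self.beaver_and(P, P_shift, width)
            shift_amount *= 2
        carries = SharePair(
            ((G.a << 1) | (cin & 1)) & ((1 << width) - 1),
            (G.b << 1) & ((1 << width) - 1),
            "B", width,
        )
        total = SharePair(
            p.a ^ carries.a, p.b ^ carries.b, "B", width
        )
        carry_out = SharePair(
            (G.a >> (width - 1)) & 1, (G.b >> (width - 1)) & 1, "B", 1
        )
        return total, carry_out

    def bool_ge(self, x: SharePair, y: SharePair, width: int) -> SharePair:
        """[x >= y] via the carry of x + NOT(y) + 1."""
        _, carry = self.bool_adder(x, self.bool_not(self._ext(y, width)),
                                   width, cin=1)
        return carry

    def bool_gt(self, x: SharePair, y: SharePair, width: int) -> SharePair:
        ge = self.bool_ge(y, x, width)  # y >= x
        return SharePair(ge.a ^ 1, ge.b, "B", 1)  # NOT

    def bool_eq(self, x: SharePair, y: SharePair, width: int) -> SharePair:
        """AND-reduce of the complemented XOR difference."""
        x = self._ext(x, width)
        y = self._ext(y, width)
        z = self.bool_not(SharePair(x.a ^ y.a, x.b ^ y.b, "B", width))
        # pad to a power of two with public 1-bits on party A's share
        w = 1 << (width - 1).bit_length() if width > 1 else 1
        pad = ((1 << w) - 1) ^ ((1 << width) - 1)
        z = SharePair(z.a | pad, z.b, "B", w)
        while w > 1:
            half = w // 2
            lo = SharePair(z.a & ((1 << half) - 1),
                           z.b & ((1 << half) - 1), "B", half)
            hi = SharePair(z.a >> half, z.b >> half, "B", half)
            z = self.beaver_and(lo, hi, half)
            w = half
        return SharePair(z.a & 1, z.b & 1, "B", 1)

    def bool_mux(self, sel: SharePair, x: SharePair, y: SharePair,
                 width: int) -> SharePair:
        """y XOR sel*(x XOR y); bit replication of sel is share-local."""
        x = self._ext(x, width)
        y = self._ext(y, width)
        mask = (1 << width) - 1
        sel_ext = SharePair(mask if sel.a & 1 else 0,
                            mask if sel.b & 1 else 0, "B", width)
        diff = SharePair(x.a ^ y.a, x.b ^ y.b, "B", width)
        t = self.beaver_and(sel_ext, diff, width)
        return SharePair(y.a ^ t.a, y.b ^ t.b, "B", width)

    def bit_to_arith(self, bit: SharePair) -> SharePair:
        """b1 XOR b2 = b1 + b2 - 2*b1*b2: each party inputs its share bit
        as a private arithmetic value, one Beaver multiplication."""
        mask = (1 << self.L) - 1
        in1 = share(bit.a & 1, "A", self.L, self.rng)
        in2 = share(bit.b & 1, "A", self.L, self.rng)
        prod = self.beaver_mul(in1, in2)
        return SharePair(
            (in1.a + in2.a - 2 * prod.a) & mask,
            (in1.b + in2.b - 2 * prod.b) & mask,
            "A", self.L,
        )

    def b2a(self, x: SharePair) -> SharePair:
        """Boolean word to arithmetic: per-bit conversion, weighted sum."""
        mask = (1 << self.L) - 1
        acc_a = 0
        acc_b = 0
        for i in range(x.width):
            bit = SharePair((x.a >> i) & 1, (x.b >> i) & 1, "B", 1)
            ar = self.bit_to_arith(bit)
            acc_a = (acc_a + (ar.a << i)) & mask
            acc_b = (acc_b + (ar.b << i)) & mask
        return SharePair(acc_a, acc_b, "A", self.L)

    def a2b(self, x: SharePair) -> SharePair:
        """Arithmetic to Boolean: both parties re-input their additive
        shares as Boolean words and add them with the shared adder."""
        in1 = share(x.a, "B", self.L, self.rng)
        in2 = share(x.b, "B", self.L, self.rng)
        total, _ = self.bool_adder(in1, in2, self.L)
        return total

    # -- gate dispatch ---------------------------------------------------
    def run(self, bindings: dict[int, int]) -> dict[int, SharePair]:
        wires: dict[int, SharePair] = {}
        mask_L = (1 << self.L) - 1
        for node in self.circuit.nodes:
            op = node.op
            ins = node.inputs
            if op == "INPUT":
                wires[node.idx] = share(
                    bindings[node.idx], node.domain, node.width, self.rng
                )
                continue
            if op == "CONST":
                wires[node.idx] = SharePair(
                    node.const, 0, node.domain, node.width
                )
                continue
            x = wires[ins[0]] if ins else None
            if op == "XOR":
                y = wires[ins[1]]
                wires[node.idx] = SharePair(
                    x.a ^ y.a, x.b ^ y.b, "B", node.width
                )
            elif op == "NOT":
                wires[node.idx] = self.bool_not(self._ext(x, node.width))
            elif op == "SHIFT":
                if node.domain == "A":
                    if node.shift < 0:
                        raise ValueError(
                            "right shift is not local on additive shares"
                        )
                    factor = 1 << node.shift
                    wires[node.idx] = SharePair(
                        (x.a * factor) & mask_L, (x.b * factor) & mask_L,
                        "A", self.L,
                    )
                else:
                    wmask = (1 << node.width) - 1
                    if node.shift >= 0:
                        a, b = x.a << node.shift, x.b << node.shift
                    else:
                        a, b = x.a >> -node.shift, x.b >> -node.shift
                    wires[node.idx] = SharePair(
                        a & wmask, b & wmask, "B", node.width
                    )
            elif op == "AND":
                wires[node.idx] = self.beaver_and(
                    self._ext(x, node.width),
                    self._ext(wires[ins[1]], node.width),
                    node.width,
                )
            elif op == "ADD":
                y = wires[ins[1]]
                if node.domain == "A":
                    wires[node.idx] = SharePair(
                        (x.a + y.a) & mask_L, (x.b + y.b) & mask_L,
                        "A", self.L,
                    )
                else:
                    total, _ = self.bool_adder(x, y, node.width)
                    wires[node.idx] = total
            elif op == "MUL":
                y = wires[ins[1]]
                if node.domain == "A":
                    wires[node.idx] = self.beaver_mul(x, y)
                else:
                    # Boolean-protocol multiplication: schoolbook on the
                    # shared word via AND + adder stages.
                    wires[node.idx] = self._bool_mul(x, y, node.width)
            elif op == "GT":
                w = max(x.width, wires[ins[1]].width)
                wires[node.idx] = self.bool_gt(x, wires[ins[1]], w)
            elif op == "EQ":
                w = max(x.width, wires[ins[1]].width)
                wires[node.idx] = self.bool_eq(x, wires[ins[1]], w)
            elif op == "MUX":
                sel = wires[ins[0]]
                a, b = wires[ins[1]], wires[ins[2]]
                if node.domain == "A":
                    sa = self.bit_to_arith(sel)
                    diff = SharePair(
                        (a.a - b.a) & mask_L, (a.b - b.b) & mask_L,
                        "A", self.L,
                    )
                    prod = self.beaver_mul(sa, diff)
                    wires[node.idx] = SharePair(
                        (b.a + prod.a) & mask_L, (b.b + prod.b) & mask_L,
                        "A", self.L,
                    )
                else:
                    wires[node.idx] = self.bool_mux(sel, a, b, node.width)
            elif op == "B2A":
                wires[node.idx] = self.b2a(x)
            elif op == "A2B":
                wires[node.idx] = self.a2b(x)
            else:  # pragma: no cover
                raise ValueError(f"unknown op {op}")
        return wires

    def _bool_mul(self, x: SharePair, y: SharePair, width: int) -> SharePair:
        x = self._ext(x, width)
        y = self._ext(y, width)
        partials = []
        for i in range(width):
            bit = SharePair((y.a >> i) & 1, (y.b >> i) & 1, "B", 1)
            row = self.bool_mux(
                bit, x, SharePair(0, 0, "B", width), width
            )
            partials.append(SharePair(
                (row.a << i) & ((1 << width) - 1),
                (row.b << i) & ((1 << width) - 1),
                "B", width,
            ))
        acc = partials[0]
        for p in partials[1:]:
            acc, _ = self.bool_adder(acc, p, width)
        return acc


def split_inputs(circuit: Circuit, x: Record, db: Sequence[Record]):
    """Each party's private input assignment (query vs database)."""
    bindings = bind_records(circuit, x, db)
    inputs_a = {i: v for i, v in bindings.items()
                if circuit.nodes[i].party == "A"}
    inputs_b = {i: v for i, v in bindings.items()
                if circuit.nodes[i].party == "B"}
    return inputs_a, inputs_b


def evaluate_shared(
    circuit: Circuit,
    inputs_a: dict[int, int],
    inputs_b: dict[int, int],
    triples: TripleStore,
    rng: np.random.Generator | int | None = None,
    log: MessageLog | None = None,
) -> dict[str, SharePair]:
    """Evaluate the whole circuit on shares; outputs remain shared.

    ``inputs_a``/``inputs_b`` map input-node ids to the owning party's
    plaintext values (see :func:`split_inputs`).  Raises if an input node
    is assigned by the wrong party.
    """
    if rng is None:
        rng = np.random.default_rng(triples.rng.integers(2**31))
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    bindings: dict[int, int] = {}
    for node in circuit.input_nodes():
        source = inputs_a if node.party == "A" else inputs_b
        if node.idx not in source:
            raise ValueError(
                f"party {node.party} input {node.key} missing"
            )
        bindings[node.idx] = source[node.idx]
    engine = _Engine(circuit, triples, rng, log or MessageLog())
    wires = engine.run(bindings)
    return {name: wires[idx] for name, idx in circuit.outputs.items()}


def run_bestmatch_shared(
    circuit: Circuit,
    x: Record,
    db: Sequence[Record],
    seed: int = 0,
    log: MessageLog | None = None,
) -> CircuitOutput:
    """Share, evaluate and reconstruct a full best-match query."""
    inputs_a, inputs_b = split_inputs(circuit, x, db)
    triples = TripleStore(seed, circuit.L)
    shares = evaluate_shared(
        circuit, inputs_a, inputs_b, triples, rng=seed + 1, log=log
    )
    return CircuitOutput(
        index=reconstruct(shares["index"]),
        match=reconstruct(shares["match"]),
        tentative=(
            reconstruct(shares["tentative"]) if "tentative" in shares else 0
        ),
        score=ScorePair(
            reconstruct(shares["s"]), reconstruct(shares["w"])
        ),
    )
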