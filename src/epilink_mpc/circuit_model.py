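"""Word-level gate model of the secure best-match circuit.

Secure two-party evaluation admits no data-dependent control flow: every
branch is evaluated, every loop unrolled.  The best-match computation
therefore becomes a fixed DAG that, for one query record and N database
records,

1. scores all N pairs in parallel (weighted sums of per-field
   similarities, computed on the quantized fixed-point values),
2. selects the maximum score — kept as a never-divided ``(s, w)`` pair —
   with its index by a balanced binary-tree fold of a *maximum-quotient*
   comparator (cross products ``z1 = s1*w2``, ``z2 = s2*w1``, the
   tie-solving order, and multiplexers routing ``(s, w, index)``), and
3. tests the winner against the threshold, ``s* > T_q * w*``.

Gates live in one of two protocol domains: Boolean/logic (protocol β,
realized as GMW or Yao) and arithmetic mod ``2^L`` (protocol α, either the
same as β or additive arithmetic sharing), with explicit conversion nodes
where the domains differ.  Equality comparison is a Boolean equality
reduce followed by a free shift; Dice similarity is a bitwise AND,
Hamming-weight adder trees, and a combinational rounding integer division
``(2*H_and << ls + den/2) / den`` built from compare/subtract/multiplex
steps (the same I/O contract as a compiled division block: dividend width
``lh + 1``, quotient width ``ls + 1``).

Round accounting is structural: XOR, NOT, shifts and constants are free;
every other gate level costs one communication round; Yao-based variants
run in a constant number of rounds regardless of depth.  The model
reproduces the *shape* of the published round counts — affine in
``ceil(log2 N)`` because only the fold depends on N — and
:func:`round_model_predict` calibrates the absolute counts from two
anchor measurements published for an ABY-based implementation of this
linkage circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .config_records import Record
from .epilink_reference import ScorePair
from .fixed_point import QuantizedConfig

__all__ = [
    "CircuitVariant",
    "VARIANTS",
    "CircuitNode",
    "Circuit",
    "CircuitOutput",
    "build_bestmatch_circuit",
    "bind_records",
    "evaluate_cleartext",
    "run_bestmatch_circuit",
    "structural_rounds",
    "circuit_stats",
    "round_model_predict",
    "REFERENCE_ROUND_ANCHORS",
    "YAO_ROUNDS",
]

# Round counts published for an ABY-based implementation of this linkage
# circuit (GMW/A variant) at database sizes 1 and 100; they calibrate the
# affine round model a + c*ceil(log2 N).
REFERENCE_ROUND_ANCHORS: tuple[tuple[int, int], ...] = ((1, 266), (100, 378))

# Yao garbling needs a database-size-independent number of interaction
# rounds (transfer of the garbled circuit and of the input keys).
YAO_ROUNDS = 2

FREE_OPS = frozenset({"INPUT", "CONST", "XOR", "NOT", "SHIFT"})


@dataclass(frozen=True)
class CircuitVariant:
    """Protocol assignment: β for Boolean/logic parts, α for arithmetic."""

    name: str
    boolean_protocol: str  # "B" (GMW) or "Y" (Yao)
    arithmetic_protocol: str  # same as boolean, or "A"

    @property
    def mixed(self) -> bool:
        return self.boolean_protocol != self.arithmetic_protocol


VARIANTS = {
    "GMW": CircuitVariant("GMW", "B", "B"),
    "GMW/A": CircuitVariant("GMW/A", "B", "A"),
    "Yao": CircuitVariant("Yao", "Y", "Y"),
    "Yao/A": CircuitVariant("Yao/A", "Y", "A"),
}


def get_variant(variant: str | CircuitVariant) -> CircuitVariant:
    if isinstance(variant, CircuitVariant):
        return variant
    try:
        return VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown circuit variant {variant!r}; pick one of "
            f"{sorted(VARIANTS)}"
        ) from None


class CircuitNode:
    """One typed gate.  ``domain`` is "B" (Boolean word of ``width`` bits)
    or "A" (residue mod 2^L); ``depth`` counts round-costing levels."""

    __slots__ = (
        "idx", "op", "domain", "width", "inputs", "const", "shift",
        "party", "key", "depth",
    )

    def __init__(self, idx, op, domain, width, inputs=(), const=None,
                 shift=0, party=None, key=None, depth=0):
        self.idx = idx
        self.op = op
        self.domain = domain
        self.width = width
        self.inputs = inputs
        self.const = const
        self.shift = shift
        self.party = party
        self.key = key
        self.depth = depth


@dataclass
class Circuit:
    """A built best-match DAG (nodes in topological order)."""

    L: int
    variant: CircuitVariant
    N: int
    nodes: list[CircuitNode] = field(default_factory=list)
    outputs: dict[str, int] = field(default_factory=dict)
    index_width: int = 1

    @property
    def depth(self) -> int:
        return max(self.nodes[i].depth for i in self.outputs.values())

    def input_nodes(self) -> list[CircuitNode]:
        return [n for n in self.nodes if n.op == "INPUT"]


class _Builder:
    def __init__(self, L: int, variant: CircuitVariant):
        self.L = L
        self.variant = variant
        self.nodes: list[CircuitNode] = []

    def _new(self, op, domain, width, inputs=(), **kw) -> int:
        depth = max((self.nodes[i].depth for i in inputs), default=0)
        if op not in FREE_OPS:
            depth += 1
        node = CircuitNode(
            len(self.nodes), op, domain, width, tuple(inputs),
            depth=depth, **kw
        )
        self.nodes.append(node)
        return node.idx

    # -- leaf nodes ------------------------------------------------------
    def inp(self, party, key, domain, width):
        return self._new("INPUT", domain, width, party=party, key=key)

    def const(self, value, domain, width):
        return self._new("CONST", domain, width, const=int(value))

    # -- free ops --------------------------------------------------------
    def xor(self, a, b):
        n = self.nodes[a]
        return self._new("XOR", n.domain, max(n.width, self.nodes[b].width),
                         (a, b))

    def not_(self, a):
        n = self.nodes[a]
        return self._new("NOT", n.domain, n.width, (a,))

    def shift(self, a, amount, width=None):
        n = self.nodes[a]
        if width is None:
            width = n.width + amount if amount > 0 else n.width
        return self._new("SHIFT", n.domain, width, (a,), shift=amount)

    # -- round-costing ops ----------------------------------------------
    def and_(self, a, b):
        n = self.nodes[a]
        return self._new("AND", n.domain, max(n.width, self.nodes[b].width),
                         (a, b))

    def add(self, a, b, width):
        return self._new("ADD", self.nodes[a].domain, width, (a, b))

    def mul(self, a, b, width):
        return self._new("MUL", self.nodes[a].domain, width, (a, b))

    def gt(self, a, b):
        return self._new("GT", self.nodes[a].domain, 1, (a, b))

    def eq(self, a, b):
        return self._new("EQ", self.nodes[a].domain, 1, (a, b))

    def mux(self, sel, a, b):
        n = self.nodes[a]
        return self._new("MUX", n.domain, max(n.width, self.nodes[b].width),
                         (sel, a, b))

    # -- conversions -----------------------------------------------------
    def to_arith(self, a):
        """β -> α conversion point (no-op when α = β)."""
        if not self.variant.mixed:
            return a
        return self._new("B2A", "A", self.L, (a,))

    def to_bool(self, a):
        """α -> β conversion point (no-op when α = β)."""
        if self.nodes[a].domain != "A":
            return a
        return self._new("A2B", "B", self.L, (a,))

    # -- composite builders ---------------------------------------------
    def add_tree(self, items, width):
        """Balanced binary adder tree (minimizes depth)."""
        layer = list(items)
        while len(layer) > 1:
            nxt = []
            for i in range(0, len(layer) - 1, 2):
                nxt.append(self.add(layer[i], layer[i + 1], width))
            if len(layer) % 2:
                nxt.append(layer[-1])
            layer = nxt
        return layer[0]

    def hamming_weight(self, a, m):
        """Balanced adder tree over the m single-bit slices of ``a``."""
        bits = [self.shift(a, -i, width=1) for i in range(m)]
        layer = bits
        total = 1
        while len(layer) > 1:
            total *= 2
            width = min(_clog2(total + 1), _clog2(m + 1))
            nxt = []
            for i in range(0, len(layer) - 1, 2):
                nxt.append(self.add(layer[i], layer[i + 1], width))
            if len(layer) % 2:
                nxt.append(layer[-1])
            layer = nxt
        return layer[0]

    def sub(self, a, b, width):
        """Two's-complement subtraction a - b (mod 2^width)."""
        nb = self.not_(b)
        s1 = self.add(a, nb, width)
        one = self.const(1, self.nodes[a].domain, width)
        return self.add(s1, one, width)

    def rounding_div(self, num, den, ls):
        """Combinational restoring division: quotient of
        ``(num + den/2) / den`` with ``num`` already shifted by ``ls``.
        Quotient width ls+1 (the value can reach exactly 2^ls)."""
        wr = self.nodes[num].width
        r = num
        qbits = []
        for t in range(ls, -1, -1):
            d_t = self.shift(den, t, width=wr)
            ge = self.not_(self.gt(d_t, r))  # r >= den << t
            r_sub = self.sub(r, d_t, wr)
            r = self.mux(ge, r_sub, r)
            qbits.append(self.shift(ge, t, width=ls + 1))
        q = qbits[0]
        for b in qbits[1:]:
            q = self.xor(q, b)  # disjoint bit positions
        return q


def _clog2(value: int) -> int:
    return (value - 1).bit_length() if value > 1 else 0


# ---------------------------------------------------------------------------
# Best-match circuit construction
# ---------------------------------------------------------------------------

def _dice_sim(b: _Builder, xb, hx, yb, hy, m, ls):
    """Dice similarity subcircuit (β): AND, Hamming weights, rounding
    division.  Output width ls+1 at scale 2^ls.  With an all-zero
    denominator the raw quotient bits are garbage, but every use is
    multiplied by the pairwise empty-flag, which is then 0."""
    lh = _clog2(m + 1)
    inter = b.and_(xb, yb)
    h_and = b.hamming_weight(inter, m)
    den = b.add(hx, hy, lh + 1)
    num = b.shift(h_and, ls + 1, width=lh + ls + 2)  # 2*H_and << ls
    half = b.shift(den, -1, width=lh + 1)
    acc = b.add(num, half, lh + ls + 2)
    return b.rounding_div(acc, den, ls)


def _equal_sim(b: _Builder, xv, yv, ls):
    """Equality subcircuit (β): equality bit shifted to scale 2^ls."""
    bit = b.eq(xv, yv)
    return b.shift(bit, ls, width=ls + 1)


def _max_quotient(b: _Builder, q1, q2, with_index: bool):
    """MaxQuotient': the larger of two (s, w[, index]) under the
    tie-solving order; the right operand wins only if strictly greater."""
    s1, w1 = q1[0], q1[1]
    s2, w2 = q2[0], q2[1]
    z1 = b.mul(s1, w2, b.L)
    z2 = b.mul(s2, w1, b.L)
    z1b, z2b = b.to_bool(z1), b.to_bool(z2)
    w1b, w2b = b.to_bool(w1), b.to_bool(w2)
    gt = b.gt(z2b, z1b)  # right strictly above left
    eq = b.eq(z2b, z1b)
    wgt = b.gt(w2b, w1b)
    c = b.xor(gt, b.and_(eq, wgt))  # gt and eq are mutually exclusive
    s = b.mux(c, s2, s1)
    w = b.mux(c, w2, w1)
    if with_index:
        return (s, w, b.mux(c, q2[2], q1[2]))
    return (s, w)


def _score_subcircuit(b, qconfig: QuantizedConfig, x_in, y_in):
    """Score pair (s, w) of one record pair in protocol α."""
    config = qconfig.config
    ls = qconfig.plan.ls
    m = config.bloom_length
    sims_a: dict[tuple[str, str], int] = {}
    deltas_a: dict[tuple[str, str], int] = {}

    def sim_arith(i: str, j: str) -> int:
        if (i, j) not in sims_a:
            spec = config.field(i)
            if spec.comparator == "dice":
                sim_b = _dice_sim(
                    b, x_in[i]["val"], x_in[i]["hw"],
                    y_in[j]["val"], y_in[j]["hw"], m, ls,
                )
            else:
                sim_b = _equal_sim(b, x_in[i]["val"], y_in[j]["val"], ls)
            sims_a[(i, j)] = b.to_arith(sim_b)
        return sims_a[(i, j)]

    def delta_arith(i: str, j: str) -> int:
        if (i, j) not in deltas_a:
            pair = b.and_(x_in[i]["delta"], y_in[j]["delta"])
            deltas_a[(i, j)] = b.to_arith(pair)
        return deltas_a[(i, j)]

    def weighted_term(i: str, j: str, weight: int):
        d = delta_arith(i, j)
        w_c = b.const(weight, b.nodes[d].domain, b.L)
        w_eff = b.mul(d, w_c, b.L)
        s_eff = b.mul(w_eff, sim_arith(i, j), b.L)
        return s_eff, w_eff

    from itertools import permutations as _perms

    s_parts, w_parts = [], []
    for group in config.exchange_groups:
        members = group.members
        best = None
        for image in _perms(members):
            terms = [
                weighted_term(
                    i, j,
                    (qconfig.weight_of(i) + qconfig.weight_of(j)) // 2,
                )
                for i, j in zip(members, image)
            ]
            s_sigma = b.add_tree([t[0] for t in terms], b.L)
            w_sigma = b.add_tree([t[1] for t in terms], b.L)
            cand = (s_sigma, w_sigma)
            best = cand if best is None else _max_quotient(
                b, best, cand, with_index=False
            )
        s_parts.append(best[0])
        w_parts.append(best[1])
    for name in config.ungrouped_fields():
        s_eff, w_eff = weighted_term(name, name, qconfig.weight_of(name))
        s_parts.append(s_eff)
        w_parts.append(w_eff)
    return b.add_tree(s_parts, b.L), b.add_tree(w_parts, b.L)


def build_bestmatch_circuit(
    qconfig: QuantizedConfig,
    N: int,
    variant: str | CircuitVariant = "GMW/A",
) -> Circuit:
    """Build the full best-match DAG for one query against N records.

    Inputs are the encoded fields (Bloom masks / lb-bit integers), their
    Hamming weights and the per-field empty flags; the query is party A's
    private input, the database party B's.  Outputs: the winning index
    (Boolean, ceil(log2 N) bits), the match bit, the tentative bit (when a
    tentative threshold is configured) and the winning (s, w) pair.
    """
    if N < 1:
        raise ValueError("database size N must be >= 1")
    variant = get_variant(variant)
    config = qconfig.config
    b = _Builder(qconfig.plan.L, variant)
    m = config.bloom_length
    lh = _clog2(m + 1)

    def record_inputs(party: str, tag: tuple) -> dict:
        fields = {}
        for spec in config.fields:
            key = tag + (spec.name,)
            entry = {
                "delta": b.inp(party, key + ("delta",), "B", 1),
            }
            if spec.comparator == "dice":
                mask = b.inp(party, key + ("val",), "B", m)
                entry["val"] = mask
                entry["hw"] = b.hamming_weight(mask, m)
            else:
                entry["val"] = b.inp(
                    party, key + ("val",), "B", spec.bit_length
                )
            fields[spec.name] = entry
        return fields

    x_in = record_inputs("A", ("x",))
    index_width = max(1, _clog2(N))
    scored = []
    for j in range(N):
        y_in = record_inputs("B", ("y", j))
        s, w = _score_subcircuit(b, qconfig, x_in, y_in)
        idx = b.const(j, "B", index_width)
        scored.append((s, w, idx))

    def fold(items):
        if len(items) == 1:
            return items[0]
        mid = (len(items) + 1) // 2
        return _max_quotient(
            b, fold(items[:mid]), fold(items[mid:]), with_index=True
        )

    s_star, w_star, idx_star = fold(scored)

    def threshold_bit(t_q: int) -> int:
        t_c = b.const(t_q, b.nodes[w_star].domain, b.L)
        rhs = b.mul(w_star, t_c, b.L)
        return b.gt(b.to_bool(s_star), b.to_bool(rhs))

    match = threshold_bit(qconfig.threshold_q)
    outputs = {
        "index": idx_star,
        "match": match,
        "s": s_star,
        "w": w_star,
    }
    if qconfig.tentative_q is not None:
        above_tent = threshold_bit(qconfig.tentative_q)
        outputs["tentative"] = b.and_(above_tent, b.not_(match))
    circuit = Circuit(
        L=qconfig.plan.L,
        variant=variant,
        N=N,
        nodes=b.nodes,
        outputs=outputs,
        index_width=index_width,
    )
    return circuit


# ---------------------------------------------------------------------------
# Cleartext evaluation
# ---------------------------------------------------------------------------

def bind_records(
    circuit: Circuit, x: Record, db: Sequence[Record]
) -> dict[int, int]:
    """Map every input node to its integer value from the given records."""
    if len(db) != circuit.N:
        raise ValueError(
            f"circuit built for N={circuit.N} records, got {len(db)}"
        )
    bindings: dict[int, int] = {}
    for node in circuit.input_nodes():
        key = node.key
        if key[0] == "x":
            record, name, kind = x, key[1], key[2]
        else:
            record, name, kind = db[key[1]], key[2], key[3]
        if kind == "delta":
            bindings[node.idx] = record.delta[name]
        elif record.delta[name]:
            enc = record.encoded[name]
            bindings[node.idx] = enc.to_int() if hasattr(enc, "to_int") else enc
        else:
            bindings[node.idx] = 0
    return bindings


@dataclass(frozen=True)
class CircuitOutput:
    index: int
    match: int
    tentative: int
    score: ScorePair


def evaluate_cleartext(
    circuit: Circuit,
    bindings: dict[int, int],
    return_trace: bool = False,
):
    """Gate-by-gate integer evaluation (Boolean ops bitwise on the node
    width, arithmetic ops mod 2^L); no data-dependent control flow."""
    values = [0] * len(circuit.nodes)
    for node in circuit.nodes:
        op = node.op
        mask = (1 << node.width) - 1
        ins = node.inputs
        if op == "INPUT":
            v = bindings[node.idx]
        elif op == "CONST":
            v = node.const
        elif op == "XOR":
            v = values[ins[0]] ^ values[ins[1]]
        elif op == "AND":
            v = values[ins[0]] & values[ins[1]]
        elif op == "NOT":
            v = ~values[ins[0]]
        elif op == "ADD":
            v = values[ins[0]] + values[ins[1]]
        elif op == "MUL":
            v = values[ins[0]] * values[ins[1]]
        elif op == "GT":
            v = int(values[ins[0]] > values[ins[1]])
        elif op == "EQ":
            v = int(values[ins[0]] == values[ins[1]])
        elif op == "MUX":
            v = values[ins[1]] if values[ins[0]] else values[ins[2]]
        elif op == "SHIFT":
            v = (
                values[ins[0]] << node.shift
                if node.shift >= 0
                else values[ins[0]] >> -node.shift
            )
        elif op in ("A2B", "B2A"):
            v = values[ins[0]]
        else:  # pragma: no cover
            raise ValueError(f"unknown op {op}")
        values[node.idx] = v & mask
    out = circuit.outputs
    result = CircuitOutput(
        index=values[out["index"]],
        match=values[out["match"]],
        tentative=values[out["tentative"]] if "tentative" in out else 0,
        score=ScorePair(values[out["s"]], values[out["w"]]),
    )
    if return_trace:
        return result, values
    return result


def run_bestmatch_circuit(
    circuit: Circuit, x: Record, db: Sequence[Record]
) -> CircuitOutput:
    """Bind records and evaluate in cleartext."""
    return evaluate_cleartext(circuit, bind_records(circuit, x, db))


# ---------------------------------------------------------------------------
# Round accounting
# ---------------------------------------------------------------------------

def structural_rounds(
    circuit: Circuit, variant: str | CircuitVariant | None = None
) -> int:
    """Modeled communication rounds of one evaluation.

    Yao-based variants: a constant, independent of the circuit.  GMW-based
    variants: the depth counting AND/MUL/GT/EQ/MUX/conversions as one
    round per level and XOR/NOT/shift/constants as free.
    """
    variant = circuit.variant if variant is None else get_variant(variant)
    if variant.boolean_protocol == "Y":
        return YAO_ROUNDS
    return circuit.depth


def circuit_stats(circuit: Circuit) -> dict:
    """Gate counts by type, depth, modeled rounds and widest wire."""
    counts: dict[str, int] = {}
    for node in circuit.nodes:
        counts[node.op] = counts.get(node.op, 0) + 1
    return {
        "variant": circuit.variant.name,
        "N": circuit.N,
        "L": circuit.L,
        "gates": dict(sorted(counts.items())),
        "total_nodes": len(circuit.nodes),
        "depth": circuit.depth,
        "modeled_rounds": structural_rounds(circuit),
        "max_wire_width": max(n.width for n in circuit.nodes),
    }


def round_model_predict(
    anchors: Sequence[tuple[int, int]], N: int
) -> int:
    """Affine round model ``rounds(N) = a + c * ceil(log2 N)``.

    Calibrated through two anchor measurements (sizes with distinct
    ``ceil(log2 N)``); the per-level increment ``c`` must come out as an
    integer, otherwise the anchors are inconsistent with the model.
    """
    (n1, r1), (n2, r2) = anchors
    t1, t2 = _clog2(max(n1, 1)), _clog2(max(n2, 1))
    if t1 == t2:
        raise ValueError("anchors need distinct ceil(log2 N) values")
    num, den = r2 - r1, t2 - t1
    if num % den:
        raise ValueError(
            f"anchors imply a non-integral per-level increment {num}/{den}"
        )
    c = num // den
    a = r1 - c * t1
    return a + c * _clog2(max(N, 1))
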