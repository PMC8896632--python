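"""End-to-end linkage pipelines, evaluation metrics and LID management.

``run_linkage`` answers, for every record of set A, the best-match query
against set B — with a choice of engines that all implement the same
ideal functionality:

* ``reference``  — vectorized double-precision scoring (the ideal),
* ``fixed_point``— vectorized exact integer scoring at the configured
  fixed-point precisions (what the circuits compute),
* ``circuit``    — gate-by-gate cleartext evaluation of the built DAG,
* ``shared``     — simulated two-party evaluation on secret shares.

The fixed-point family agrees exactly among itself; the floating-point
reference can differ only for queries whose score sits within one
quantization step of the threshold.  ``match_cardinality`` mode reports
just the number of queries with an above-threshold partner.

``evaluate_linkage`` scores predictions against ground truth (precision,
recall, TP/FP/FN); undefined ratios are reported as absent rather than 0.

The linkage-ID (LID) machinery models confidential pseudonym management:
a linkage service holds one secret key per party, hands out encrypted
random IDs, and after a linkage re-keys the matched ID (appending the
match bit) or issues a fresh random one — match and non-match tokens are
format-identical, so two colluding parties cannot compare IDs to learn
match status.  Encryption is an authenticated XOR-keystream scheme with a
zero-padding validity check; a functional model, not a hardened KMS.
"""

from __future__ import annotations

import hashlib
import hmac as hmac_mod
import json
import secrets
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .circuit_model import build_bestmatch_circuit, run_bestmatch_circuit
from .config_records import ConfigError, LinkageConfig, Record
from .epilink_reference import MatchResult, ScorePair
from .fixed_point import QuantizedConfig, quantize_config
from .share_sim import run_bestmatch_shared
from .synthetic_data import GroundTruth

__all__ = [
    "LinkageReport",
    "LinkageMetrics",
    "run_linkage",
    "evaluate_linkage",
    "LinkageService",
    "lid_issue",
    "lid_without_service",
]

ENGINES = ("reference", "fixed_point", "circuit", "shared")
MODES = ("best_match", "cardinality")


@dataclass(frozen=True)
class LinkageMetrics:
    """Contingency counts of predicted match pairs against ground truth."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float | None:
        total = self.tp + self.fp
        return self.tp / total if total else None

    @property
    def recall(self) -> float | None:
        total = self.tp + self.fn
        return self.tp / total if total else None

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


@dataclass(frozen=True)
class LinkageReport:
    """Outcome of one linkage run.

    ``results`` holds one :class:`MatchResult` per A-record (best-match
    mode); ``cardinality`` is the number of match bits set.  ``metrics``
    is attached by :meth:`evaluated`.
    """

    mode: str
    engine: str
    cardinality: int
    results: tuple[MatchResult, ...] | None = None
    metrics: LinkageMetrics | None = None

    def predicted_pairs(self) -> list[tuple[int, int]]:
        if self.results is None:
            raise ValueError("cardinality-mode report has no per-query pairs")
        return [
            (k, r.index) for k, r in enumerate(self.results) if r.match
        ]

    def evaluated(self, truth: GroundTruth) -> "LinkageReport":
        return replace(
            self, metrics=evaluate_linkage(self.predicted_pairs(), truth)
        )

    def to_json(self) -> str:
        payload = {
            "mode": self.mode,
            "engine": self.engine,
            "cardinality": self.cardinality,
        }
        if self.metrics is not None:
            payload.update(self.metrics.as_dict())
        return json.dumps(payload)

    def results_jsonl(self) -> str:
        if self.results is None:
            return ""
        lines = [
            json.dumps(
                {
                    "query_index": k,
                    "best_index": r.index,
                    "match": r.match,
                    "tentative": r.tentative,
                    "s": r.score.s,
                    "w": r.score.w,
                }
            )
            for k, r in enumerate(self.results)
        ]
        return "\n".join(lines)


def evaluate_linkage(
    predicted: Sequence[tuple[int, int]], truth: GroundTruth
) -> LinkageMetrics:
    """Count TP/FP/FN of predicted (indexA, indexB) match pairs."""
    truth_set = set(truth.pairs)
    predicted_set = set(predicted)
    if len(predicted_set) != len(predicted):
        raise ValueError("duplicate predicted pairs")
    tp = len(predicted_set & truth_set)
    return LinkageMetrics(
        tp=tp, fp=len(predicted_set) - tp, fn=len(truth_set) - tp
    )


# ---------------------------------------------------------------------------
# Vectorized engines
# ---------------------------------------------------------------------------

class _ColumnArrays:
    """Per-field numpy columns of one record set."""

    def __init__(self, records: Sequence[Record], config: LinkageConfig):
        self.n = len(records)
        self.delta: dict[str, np.ndarray] = {}
        self.bits: dict[str, np.ndarray] = {}
        self.hw: dict[str, np.ndarray] = {}
        self.values: dict[str, np.ndarray] = {}
        m = config.bloom_length
        for spec in config.fields:
            name = spec.name
            delta = np.fromiter(
                (r.delta[name] for r in records), dtype=bool, count=self.n
            )
            self.delta[name] = delta
            if spec.comparator == "dice":
                mat = np.zeros((self.n, m), dtype=np.float32)
                hw = np.zeros(self.n, dtype=np.int64)
                for i, r in enumerate(records):
                    if delta[i]:
                        vec = r.encoded[name]
                        mat[i, :] = vec.bits
                        hw[i] = vec.hamming
                self.bits[name] = mat
                self.hw[name] = hw
            else:
                self.values[name] = np.fromiter(
                    (r.encoded[name] if delta[i] else -1
                     for i, r in enumerate(records)),
                    dtype=np.int64, count=self.n,
                )


def _pair_terms(
    a: _ColumnArrays, b: _ColumnArrays, config: LinkageConfig,
    qconfig: QuantizedConfig | None, rows: slice, i: str, j: str,
):
    """delta mask and similarity matrix for x-field i vs y-field j.

    Float similarities for the reference engine (``qconfig is None``),
    integers at scale 2^ls otherwise.
    """
    spec = config.field(i)
    mask = a.delta[i][rows][:, None] & b.delta[j][None, :]
    if spec.comparator == "dice":
        inter = np.rint(
            a.bits[i][rows] @ b.bits[j].T
        ).astype(np.int64)
        den = a.hw[i][rows][:, None] + b.hw[j][None, :]
        safe = np.maximum(den, 1)
        if qconfig is None:
            sim = (2.0 * inter) / safe
        else:
            ls = qconfig.plan.ls
            sim = ((2 * inter << ls) + safe // 2) // safe
        sim = np.where(mask & (den > 0), sim, 0)
    else:
        equal = a.values[i][rows][:, None] == b.values[j][None, :]
        if qconfig is None:
            sim = np.where(mask & equal, 1.0, 0.0)
        else:
            sim = np.where(mask & equal, 1 << qconfig.plan.ls, 0)
    return mask, sim


def _tie_take(cs, cw, bs, bw):
    """Elementwise tie-solving order: where does (cs, cw) beat (bs, bw)?"""
    lhs = cs * bw
    rhs = bs * cw
    return (lhs > rhs) | ((lhs == rhs) & (cw > bw))


def _score_block(
    a: _ColumnArrays, b: _ColumnArrays, config: LinkageConfig,
    qconfig: QuantizedConfig | None, rows: slice,
):
    """(s, w) matrices for one block of queries against the whole of B."""
    from itertools import permutations

    integer = qconfig is not None

    def weight(name):
        return qconfig.weight_of(name) if integer else config.weight_of(name)

    def avg_weight(i, j):
        if integer:
            return (qconfig.weight_of(i) + qconfig.weight_of(j)) // 2
        return (config.weight_of(i) + config.weight_of(j)) / 2.0

    n_rows = len(range(*rows.indices(a.n)))
    dtype = np.int64 if integer else np.float64
    s_total = np.zeros((n_rows, b.n), dtype=dtype)
    w_total = np.zeros((n_rows, b.n), dtype=dtype)

    for group in config.exchange_groups:
        members = group.members
        terms = {}
        for i in members:
            for j in members:
                mask, sim = _pair_terms(a, b, config, qconfig, rows, i, j)
                w_ij = avg_weight(i, j)
                w_eff = np.where(mask, w_ij, 0).astype(dtype)
                terms[(i, j)] = (w_eff * sim.astype(dtype), w_eff)
        best_s = best_w = None
        for image in permutations(members):
            s_sig = sum(terms[(i, j)][0] for i, j in zip(members, image))
            w_sig = sum(terms[(i, j)][1] for i, j in zip(members, image))
            if best_s is None:
                best_s, best_w = s_sig, w_sig
            else:
                take = _tie_take(s_sig, w_sig, best_s, best_w)
                best_s = np.where(take, s_sig, best_s)
                best_w = np.where(take, w_sig, best_w)
        s_total += best_s
        w_total += best_w

    for name in config.ungrouped_fields():
        mask, sim = _pair_terms(a, b, config, qconfig, rows, name, name)
        w_eff = np.where(mask, weight(name), 0).astype(dtype)
        s_total += w_eff * sim.astype(dtype)
        w_total += w_eff
    return s_total, w_total


def _row_best(s_row, w_row):
    """Best index of one query row under the tie-solving order."""
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(w_row > 0, s_row / np.maximum(w_row, 1e-300), -1.0)
    top = q.max()
    # exact tie resolution among near-maximal candidates only
    candidates = np.flatnonzero(q >= top - 1e-9 * max(abs(top), 1.0))
    best = int(candidates[0])
    for j in candidates[1:]:
        if _tie_take(s_row[j], w_row[j], s_row[best], w_row[best]):
            best = int(j)
    return best


def _vectorized_linkage(
    A: Sequence[Record], B: Sequence[Record], config: LinkageConfig,
    qconfig: QuantizedConfig | None, block: int,
) -> list[MatchResult]:
    cols_a = _ColumnArrays(A, config)
    cols_b = _ColumnArrays(B, config)
    if qconfig is None:
        threshold, tentative = config.threshold, config.tentative_threshold
    else:
        threshold, tentative = qconfig.threshold_q, qconfig.tentative_q
    results: list[MatchResult] = []
    for start in range(0, cols_a.n, block):
        rows = slice(start, min(start + block, cols_a.n))
        s_mat, w_mat = _score_block(cols_a, cols_b, config, qconfig, rows)
        for r in range(s_mat.shape[0]):
            j = _row_best(s_mat[r], w_mat[r])
            s, w = s_mat[r, j], w_mat[r, j]
            match = int(s > threshold * w)
            tent = 0
            if tentative is not None and not match:
                tent = int(tentative * w < s)
            if qconfig is None:
                pair = ScorePair(float(s), float(w))
            else:
                pair = ScorePair(int(s), int(w))
            results.append(
                MatchResult(index=j, match=match, tentative=tent, score=pair)
            )
    return results


def run_linkage(
    A: Sequence[Record],
    B: Sequence[Record],
    config: LinkageConfig,
    mode: str = "best_match",
    engine: str = "reference",
    block: int = 256,
    seed: int = 0,
    variant: str = "GMW/A",
) -> LinkageReport:
    """Best-match every record of A against B with the chosen engine.

    A full cross-linkage performs exactly ``len(A)`` best-match queries
    (``O(M*N)`` pair scores; no blocking or candidate filtering).  The
    ``circuit`` and ``shared`` engines build the DAG once and rebind it
    per query; they are exact but meant for small corpora.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if engine not in ENGINES:
        raise ConfigError(f"unknown engine {engine!r}; pick from {ENGINES}")
    if not A or not B:
        raise ValueError("run_linkage requires non-empty record sets")
    if config.weights is None:
        config = config.validated()

    if engine == "reference":
        results = _vectorized_linkage(A, B, config, None, block)
    elif engine == "fixed_point":
        qconfig = quantize_config(config)
        if qconfig.plan.L > 32:
            raise ConfigError(
                "the vectorized fixed-point engine supports L <= 32 "
                "(tie products must fit int64)"
            )
        results = _vectorized_linkage(A, B, config, qconfig, block)
    else:
        qconfig = quantize_config(config)
        circuit = build_bestmatch_circuit(qconfig, len(B), variant)
        results = []
        for k, x in enumerate(A):
            if engine == "circuit":
                out = run_bestmatch_circuit(circuit, x, B)
            else:
                out = run_bestmatch_shared(
                    circuit, x, B, seed=seed * 100003 + k
                )
            results.append(
                MatchResult(
                    index=out.index,
                    match=out.match,
                    tentative=out.tentative,
                    score=out.score,
                )
            )
    cardinality = sum(r.match for r in results)
    return LinkageReport(
        mode=mode,
        engine=engine,
        cardinality=cardinality,
        results=None if mode == "cardinality" else tuple(results),
    )


# ---------------------------------------------------------------------------
# Linkage-ID management (functional model)
# ---------------------------------------------------------------------------

_ZERO_PAD = 8
_ID_BYTES = 16
_NONCE = 16
_TAG = 16


def _keystream(key: bytes, nonce: bytes, length: int) -> bytes:
    out = b""
    counter = 0
    while len(out) < length:
        out += hashlib.sha256(
            key + nonce + counter.to_bytes(4, "big")
        ).digest()
        counter += 1
    return out[:length]


class LinkageService:
    """In-process pseudonym service: per-party keys, opaque LID tokens.

    Tokens encrypt ``zero-padding || random ID || match bit`` under the
    receiving party's key (XOR keystream + HMAC tag).  The zero padding
    lets the service verify token validity and ownership; fresh randomness
    on every non-match makes match and non-match tokens indistinguishable
    without the key.
    """

    def __init__(self, seed: int | None = None):
        self._keys: dict[str, bytes] = {}
        self._rng = (
            secrets.SystemRandom() if seed is None
            else np.random.default_rng(seed)
        )

    def _random_bytes(self, n: int) -> bytes:
        if isinstance(self._rng, np.random.Generator):
            return self._rng.bytes(n)
        return bytes(self._rng.getrandbits(8) for _ in range(n))

    def register_party(self, party: str) -> None:
        if party not in self._keys:
            self._keys[party] = self._random_bytes(32)

    def _encrypt(self, party: str, plaintext: bytes) -> str:
        key = self._keys[party]
        nonce = self._random_bytes(_NONCE)
        ct = bytes(
            p ^ k for p, k in zip(
                plaintext, _keystream(key, nonce, len(plaintext))
            )
        )
        tag = hmac_mod.new(key, nonce + ct, hashlib.sha256).digest()[:_TAG]
        return (nonce + ct + tag).hex()

    def _decrypt(self, party: str, token: str) -> bytes:
        key = self._keys[party]
        raw = bytes.fromhex(token)
        nonce, ct, tag = raw[:_NONCE], raw[_NONCE:-_TAG], raw[-_TAG:]
        expect = hmac_mod.new(key, nonce + ct, hashlib.sha256).digest()[:_TAG]
        if not hmac_mod.compare_digest(tag, expect):
            raise ValueError("LID token failed authentication")
        plaintext = bytes(
            c ^ k for c, k in zip(ct, _keystream(key, nonce, len(ct)))
        )
        if plaintext[:_ZERO_PAD] != b"\x00" * _ZERO_PAD:
            raise ValueError("LID token failed the zero-padding check")
        return plaintext

    def generate_ids(self, party: str, count: int) -> list[str]:
        """Random LIDs for all of a party's records, encrypted to it."""
        self.register_party(party)
        tokens = []
        for _ in range(count):
            lid = self._random_bytes(_ID_BYTES)
            tokens.append(self._encrypt(
                party, b"\x00" * _ZERO_PAD + lid + b"\x00"
            ))
        return tokens

    def issue(
        self, remote_party: str, remote_token: str,
        client_party: str, match: int,
    ) -> str:
        """Re-key the matched remote LID (with the match bit appended) or
        issue a fresh random LID on non-match; outputs look identical."""
        self.register_party(client_party)
        if match:
            plaintext = self._decrypt(remote_party, remote_token)
            lid = plaintext[_ZERO_PAD : _ZERO_PAD + _ID_BYTES]
            body = lid + b"\x01"
        else:
            body = self._random_bytes(_ID_BYTES) + b"\x00"
        return self._encrypt(client_party, b"\x00" * _ZERO_PAD + body)

    def open_lid(self, party: str, token: str) -> tuple[bytes, int]:
        """Service-side decryption: (ID, match bit).  Requires the consent
        step of the workflow; modeled as a plain method here."""
        plaintext = self._decrypt(party, token)
        return (
            plaintext[_ZERO_PAD : _ZERO_PAD + _ID_BYTES],
            plaintext[-1],
        )


def lid_issue(
    service: LinkageService,
    remote_party: str,
    remote_token: str,
    client_party: str,
    match: int,
) -> str:
    """Functional wrapper around :meth:`LinkageService.issue`."""
    return service.issue(remote_party, remote_token, client_party, match)


def lid_without_service(
    randomness_local: bytes, randomness_remote: bytes, match: int
) -> bytes:
    """In-circuit LID alternative: XOR of both parties' per-record
    randomness on a match, the remote party's randomness otherwise.
    Both outcomes are equal-length opaque strings."""
    if len(randomness_local) != len(randomness_remote):
        raise ValueError("per-record randomness lengths differ")
    if match:
        return bytes(
            a ^ b for a, b in zip(randomness_local, randomness_remote)
        )
    return randomness_remote
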