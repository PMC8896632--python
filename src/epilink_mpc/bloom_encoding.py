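"""Bigram tokenization, Bloom-filter encoding and Dice similarity.

String fields are compared fault-tolerantly: a string is tokenized into
overlapping character bigrams, each bigram sets up to ``k`` bits of a
fixed-length bitmask via a seeded double-hashing family, and two strings
are compared through the Sørensen-Dice coefficient of their bitmasks,

    sim(x, y) = 2 * Hw(Bl(x) & Bl(y)) / (Hw(Bl(x)) + Hw(Bl(y))),

where ``Hw`` is the Hamming weight.  The coefficient is insensitive to the
number of zero bits, so it measures *relative* overlap of the encoded
bigram sets.  A single-letter change touches at most two bigrams and hence
flips at most ``2k`` bits of the mask.

The Bloom filters here are an encoding convenience for circuit-friendly
similarity, not a privacy mechanism.
"""

from __future__ import annotations

import hashlib
import unicodedata
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BloomVector",
    "bigrams",
    "bloom_encode",
    "dice_similarity",
    "normalize_text",
]


def normalize_text(text: str) -> str:
    """Uppercase, trim and strip diacritics to plain ASCII.

    ``"Müller "`` becomes ``"MULLER"``; characters with no ASCII
    decomposition are dropped.
    """
    text = unicodedata.normalize("NFKD", text.strip().upper())
    return text.encode("ascii", "ignore").decode("ascii")


def bigrams(text: str, padded: bool = False) -> list[str]:
    """Overlapping 2-character tokens of ``text``.

    The default convention is unpadded: ``"SMITH"`` yields
    ``["SM", "MI", "IT", "TH"]`` and a single character yields itself as
    its own token, so a non-empty name never produces an empty token list.
    With ``padded=True`` the text is framed as ``_text_`` before
    tokenization (the alternative convention some deployments use).
    """
    if padded and text:
        text = f"_{text}_"
    if len(text) == 1:
        return [text]
    return [text[i : i + 2] for i in range(len(text) - 1)]


@dataclass(frozen=True)
class BloomVector:
    """Fixed-length bitmask with its cached Hamming weight.

    ``bits`` is a boolean array of length ``m``; bit index 0 is the least
    significant position in integer and hex serializations.
    """

    bits: np.ndarray
    hamming: int = field(init=False)

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=bool)
        object.__setattr__(self, "bits", bits)
        object.__setattr__(self, "hamming", int(bits.sum()))

    def __len__(self) -> int:
        return self.bits.size

    def __and__(self, other: "BloomVector") -> "BloomVector":
        if len(self) != len(other):
            raise ValueError(
                f"Bloom length mismatch: {len(self)} vs {len(other)}"
            )
        return BloomVector(self.bits & other.bits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BloomVector):
            return NotImplemented
        return len(self) == len(other) and bool(
            np.array_equal(self.bits, other.bits)
        )

    def to_int(self) -> int:
        """Bitmask as an integer (bit i of the mask = array index i)."""
        value = 0
        for i in np.flatnonzero(self.bits):
            value |= 1 << int(i)
        return value

    def to_hex(self) -> str:
        """Hex serialization for debug dumps (LSB = bit 0)."""
        nbytes = (len(self) + 7) // 8
        return self.to_int().to_bytes(nbytes, "little").hex()


def _token_hashes(token: str, salt: bytes) -> tuple[int, int]:
    digest = hashlib.blake2b(token.encode("utf-8"), key=salt, digest_size=16)
    raw = digest.digest()
    h1 = int.from_bytes(raw[:8], "little")
    h2 = int.from_bytes(raw[8:], "little") | 1  # odd stride
    return h1, h2


def bloom_encode(
    text: str,
    m: int,
    k: int,
    salt: bytes = b"epilink-bloom",
    padded: bool = False,
) -> BloomVector:
    """Encode ``text`` as an ``m``-bit Bloom filter with ``k`` hash functions.

    Each bigram ``t`` sets the bits ``(h1(t) + i*h2(t)) mod m`` for
    ``i = 0..k-1`` (double hashing with two keyed 64-bit hashes), so it sets
    at most ``k`` bits.  The encoding is deterministic given
    ``(text, m, k, salt, padded)``; the text is normalized first.
    """
    if m < 1 or k < 1:
        raise ValueError("bloom parameters require m >= 1 and k >= 1")
    bits = np.zeros(m, dtype=bool)
    for token in bigrams(normalize_text(text), padded=padded):
        h1, h2 = _token_hashes(token, salt)
        for i in range(k):
            bits[(h1 + i * h2) % m] = True
    return BloomVector(bits)


def dice_similarity(a: BloomVector, b: BloomVector) -> float:
    """Sørensen-Dice coefficient of two equal-length Bloom filters.

    Returns ``2*H(a&b) / (H(a)+H(b))`` in [0, 1]; two all-zero vectors
    compare as 0.0 by convention (nothing was encoded on either side).
    """
    if len(a) != len(b):
        raise ValueError(f"Bloom length mismatch: {len(a)} vs {len(b)}")
    denom = a.hamming + b.hamming
    if denom == 0:
        return 0.0
    return 2.0 * (a & b).hamming / denom
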