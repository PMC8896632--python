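"""Synthetic identity data: overlapping record sets with controlled errors.

Linkage quality can only be evaluated against known ground truth, so this
module generates it: a clean population of person-like records (names from
frequency-weighted synthetic name banks, dates of birth uniform over
1940-2005, ZIP codes tied to cities), split into two sets A and B with a
configurable overlap fraction, and a corruption model that perturbs the
B-side copies field by field.  The per-field error rate is interpreted as
the probability that the two registrations of the same person disagree on
that field: string fields receive one random edit (substitution,
transposition, deletion or insertion), date and ZIP fields a digit
perturbation; separate rates control blanked fields (missingness) and
accidental swaps of exchange-group fields.

The generator is deterministic per seed, and corruption never touches the
ground-truth bookkeeping.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _namebank
from .config_records import LinkageConfig, Record, records_from_frame

__all__ = [
    "CorruptionSpec",
    "GroundTruth",
    "generate_population",
    "split_with_overlap",
    "corrupt",
    "corrupt_frame",
    "generate_linkage_problem",
    "STUDY_SIZE",
    "STUDY_OVERLAP",
    "STUDY_ERROR_RATE",
]

# The headline study conditions: two sets of 10,000 records, 60% overlap,
# 10% per-field error rate.
STUDY_SIZE = 10_000
STUDY_OVERLAP = 0.6
STUDY_ERROR_RATE = 0.1

LETTERS = string.ascii_uppercase

STRING_FIELDS = ("first_name", "last_name", "birth_name", "city")
DATE_FIELDS = ("birth_day", "birth_month", "birth_year")


@dataclass(frozen=True)
class CorruptionSpec:
    """Error model applied to one side of the overlapping records.

    ``error_rate`` hits each field independently; the edit mix weights the
    four string-edit operations.  ``missing_rate`` blanks a field
    (delta -> 0), ``swap_rate`` exchanges the given and surname (the error
    exchange groups exist to absorb).
    """

    error_rate: float = STUDY_ERROR_RATE
    edit_mix: tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2)
    missing_rate: float = 0.01
    swap_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.error_rate, self.missing_rate, self.swap_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rate {p} outside [0,1]")
        if abs(sum(self.edit_mix) - 1.0) > 1e-9:
            raise ValueError("edit mix weights must sum to 1")


@dataclass(frozen=True)
class GroundTruth:
    """Injective mapping from indices in A to co-referent indices in B."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("ground truth must be injective on both sides")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["indexA", "indexB"])


def generate_population(
    count: int,
    config: LinkageConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``count`` distinct clean person records.

    Names come from the frequency-weighted synthetic banks; the birth name
    equals the surname except for a 15% married-name fraction, so every
    field is populated (delta = 1 everywhere) before corruption.  Returns
    a DataFrame in the CSV dialect the record loader reads.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    given, p_given = _namebank.given_names()
    sur, p_sur = _namebank.surnames()
    city_names, p_city = _namebank.cities()
    zips = _namebank.city_zip_codes()

    first = rng.choice(len(given), size=count, p=p_given)
    last = rng.choice(len(sur), size=count, p=p_sur)
    married = rng.random(count) < 0.15
    maiden = rng.choice(len(sur), size=count, p=p_sur)
    city_idx = rng.choice(len(city_names), size=count, p=p_city)
    zip_codes = [
        zips[c][rng.integers(len(zips[c]))] for c in city_idx
    ]
    month = rng.integers(1, 13, size=count)
    day = rng.integers(1, 29, size=count)  # valid in every month
    year = rng.integers(1940, 2006, size=count)

    frame = pd.DataFrame(
        {
            "first_name": [given[i] for i in first],
            "last_name": [sur[i] for i in last],
            "birth_name": [
                sur[m] if is_married else sur[i]
                for i, m, is_married in zip(last, maiden, married)
            ],
            "city": [city_names[i] for i in city_idx],
            "birth_day": day.astype(str),
            "birth_month": month.astype(str),
            "birth_year": year.astype(str),
            "zip": zip_codes,
        }
    )
    return frame


def split_with_overlap(
    population: pd.DataFrame,
    size_a: int,
    size_b: int,
    overlap: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Split a population into two sets sharing ``overlap`` of the smaller.

    ``round(overlap * min(size_a, size_b))`` entities appear in both sets
    (at shuffled positions); all other entities are distinct.  Returns
    (A, B, truth) with positional ground truth.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0,1]")
    n_shared = round(overlap * min(size_a, size_b))
    needed = size_a + size_b - n_shared
    if len(population) < needed:
        raise ValueError(
            f"population of {len(population)} records cannot supply "
            f"{needed} distinct entities"
        )
    rng = np.random.default_rng(seed)
    entities = rng.permutation(len(population))[:needed]
    shared = entities[:n_shared]
    only_a = entities[n_shared : n_shared + (size_a - n_shared)]
    only_b = entities[n_shared + (size_a - n_shared) :]

    a_entities = np.concatenate([shared, only_a]).astype(int)
    b_entities = np.concatenate([shared, only_b]).astype(int)
    perm_a = rng.permutation(size_a)
    perm_b = rng.permutation(size_b)
    a_order = a_entities[np.argsort(perm_a)]
    b_order = b_entities[np.argsort(perm_b)]

    pos_a = {int(e): i for i, e in enumerate(a_order)}
    pos_b = {int(e): i for i, e in enumerate(b_order)}
    truth = GroundTruth(
        tuple(sorted((pos_a[int(e)], pos_b[int(e)]) for e in shared))
    )
    frame_a = population.iloc[a_order].reset_index(drop=True)
    frame_b = population.iloc[b_order].reset_index(drop=True)
    return frame_a, frame_b, truth


# ---------------------------------------------------------------------------
# Corruption
# ---------------------------------------------------------------------------

def _edit_string(value: str, op: int, rng: np.random.Generator) -> str:
    if not value:
        return value
    i = int(rng.integers(len(value)))
    letter = LETTERS[rng.integers(26)]
    if op == 0:  # substitute
        while letter == value[i]:
            letter = LETTERS[rng.integers(26)]
        return value[:i] + letter + value[i + 1 :]
    if op == 1:  # transpose adjacent
        if len(value) < 2:
            return letter + value
        i = min(i, len(value) - 2)
        return value[:i] + value[i + 1] + value[i] + value[i + 2 :]
    if op == 2:  # delete
        if len(value) < 2:
            return value  # keep non-empty: deletion would blank the field
        return value[:i] + value[i + 1 :]
    return value[:i] + letter + value[i:]  # insert


def _perturb_digits(value: str, rng: np.random.Generator,
                    lo: int, hi: int) -> str:
    """Replace the value with a different draw from its valid range."""
    new = int(rng.integers(lo, hi + 1))
    while str(new) == value:
        new = int(rng.integers(lo, hi + 1))
    return str(new)


_FIELD_RANGES = {
    "birth_day": (1, 28),
    "birth_month": (1, 12),
    "birth_year": (1940, 2005),
}


def _corrupt_values(
    values: dict[str, str],
    spec: CorruptionSpec,
    rng: np.random.Generator,
) -> dict[str, str]:
    out = dict(values)
    if rng.random() < spec.swap_rate:
        out["first_name"], out["last_name"] = (
            out["last_name"], out["first_name"],
        )
    edit_p = np.asarray(spec.edit_mix)
    for name, value in list(out.items()):
        if not value:
            continue
        if rng.random() < spec.error_rate:
            if name in _FIELD_RANGES:
                lo, hi = _FIELD_RANGES[name]
                out[name] = _perturb_digits(value, rng, lo, hi)
            elif name == "zip":
                i = int(rng.integers(len(value)))
                digit = str(rng.integers(10))
                while digit == value[i]:
                    digit = str(rng.integers(10))
                out[name] = value[:i] + digit + value[i + 1 :]
            else:
                op = int(rng.choice(4, p=edit_p))
                out[name] = _edit_string(value, op, rng)
        if rng.random() < spec.missing_rate:
            out[name] = ""
    return out


def corrupt(
    record: Record | dict,
    spec: CorruptionSpec,
    config: LinkageConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Corrupt one record (or raw value mapping) under the error model.

    Deterministic per ``spec.seed`` when no generator is passed.  With a
    :class:`Record` input (requires ``config``) the result is re-encoded;
    a plain dict comes back as a dict.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if isinstance(record, Record):
        if config is None:
            raise ValueError("corrupting a Record requires the config")
        values = _corrupt_values(dict(record.raw), spec, rng)
        return Record.from_values(values, config)
    return _corrupt_values(dict(record), spec, rng)


def corrupt_frame(
    frame: pd.DataFrame, spec: CorruptionSpec
) -> pd.DataFrame:
    """Corrupt every row of a table; row order (and hence any positional
    ground truth) is preserved."""
    rng = np.random.default_rng(spec.seed)
    rows = [
        _corrupt_values(row, spec, rng)
        for row in frame.to_dict("records")
    ]
    return pd.DataFrame(rows, columns=frame.columns)


def generate_linkage_problem(
    config: LinkageConfig,
    size_a: int = STUDY_SIZE,
    size_b: int = STUDY_SIZE,
    overlap: float = STUDY_OVERLAP,
    corruption: CorruptionSpec | None = None,
    seed: int = 0,
) -> tuple[list[Record], list[Record], GroundTruth]:
    """End-to-end harness: population, split, B-side corruption, encoding.

    Returns encoded record lists (A clean, B corrupted) and the ground
    truth.  All randomness derives from ``seed``.
    """
    if corruption is None:
        corruption = CorruptionSpec(seed=seed + 2)
    population = generate_population(
        size_a + size_b, config=config, seed=seed
    )
    frame_a, frame_b, truth = split_with_overlap(
        population, size_a, size_b, overlap, seed=seed + 1
    )
    frame_b = corrupt_frame(frame_b, corruption)
    return (
        records_from_frame(frame_a, config),
        records_from_frame(frame_b, config),
        truth,
    )
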