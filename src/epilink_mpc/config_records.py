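"""Linkage configuration, field weighting and record ingestion.

A linkage configuration lists the identity fields that enter the match
score, how each is compared (exact equality for dates and ZIP codes, Dice
similarity of Bloom filters for names), and the Fellegi-Sunter-style log
frequency weight of each field,

    w_i = log2((1 - e_i) / f_i),

where ``e_i`` is the assumed per-field error rate and ``f_i`` the average
value frequency (the probability that two random records agree on the
field by chance).  Rare, reliable fields therefore weigh more.  Fields that
are prone to accidental swapping at data entry (given / sur / birth name)
can be grouped into *exchange groups*, whose scoring maximizes over field
permutations.

Records are ingested from CSV; every field carries a non-emptiness flag
``delta`` and, when non-empty, a comparison-ready encoding (a Bloom filter
for dice fields, an ``lb``-bit integer for equality fields).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import pandas as pd

from .bloom_encoding import BloomVector, bloom_encode

__all__ = [
    "ConfigError",
    "FieldSpec",
    "ExchangeGroup",
    "LinkageConfig",
    "Record",
    "compute_field_weight",
    "validate_config",
    "load_config",
    "load_records",
    "records_from_frame",
    "write_records",
    "default_config",
    "DEFAULT_MISSING_TOKENS",
]

DEFAULT_MISSING_TOKENS = ("", "NA", "N/A", "NULL", "NONE", ".")

COMPARATORS = ("equality", "dice")

MAX_GROUP_SIZE = 4  # |G|! permutations are enumerated; 4! = 24


class ConfigError(ValueError):
    """Invalid linkage configuration."""


def compute_field_weight(e: float, f: float) -> float:
    """Field weight ``log2((1-e)/f)`` from error rate ``e`` and frequency ``f``.

    Strictly decreasing in both arguments.  Raises :class:`ConfigError`
    when the weight would be negative (``f > 1 - e``) or when ``e``/``f``
    leave their ranges; ``f = 1 - e`` yields weight 0 (an uninformative
    field).
    """
    if not 0.0 <= e < 1.0:
        raise ConfigError(f"error rate must be in [0,1), got {e}")
    if not 0.0 < f <= 1.0:
        raise ConfigError(f"frequency must be in (0,1], got {f}")
    if f > 1.0 - e:
        raise ConfigError(
            f"negative weight: frequency {f} > 1 - error rate {1 - e}"
        )
    return math.log2((1.0 - e) / f)


@dataclass(frozen=True)
class FieldSpec:
    """One identity field: comparator, encoded bit-length and weight source.

    The weight may be given directly (``weight=``) or derived from
    ``(error_rate, frequency)``; ``resolved_weight`` returns whichever
    applies.  ``bit_length`` is the width of the encoded value: the Bloom
    filter length for dice fields, the integer width for equality fields.
    """

    name: str
    comparator: str
    bit_length: int
    error_rate: float | None = None
    frequency: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ConfigError(
                f"field {self.name!r}: unknown comparator {self.comparator!r}"
            )
        if self.bit_length < 1:
            raise ConfigError(f"field {self.name!r}: bit_length must be >= 1")

    def resolved_weight(self) -> float:
        if self.weight is not None:
            if self.weight < 0:
                raise ConfigError(f"field {self.name!r}: negative weight")
            return float(self.weight)
        if self.error_rate is None or self.frequency is None:
            raise ConfigError(
                f"field {self.name!r}: needs weight or (error_rate, frequency)"
            )
        try:
            return compute_field_weight(self.error_rate, self.frequency)
        except ConfigError as err:
            raise ConfigError(f"field {self.name!r}: {err}") from None


@dataclass(frozen=True)
class ExchangeGroup:
    """Ordered set of field names whose accidental swaps are absorbed."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if len(self.members) < 2:
            raise ConfigError("exchange group needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ConfigError("exchange group has repeated members")

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class LinkageConfig:
    """Full linkage configuration.

    ``threshold`` is the match threshold ``T`` on the normalized score in
    (0, 1]; an optional ``tentative_threshold`` below it opens a
    tentative-match band.  ``bit_length`` is the arithmetic word size L of
    the fixed-point circuits; ``bloom_length``/``bloom_hashes`` are the
    Bloom parameters (m, k) shared by all dice fields.  ``validate_config``
    attaches the derived weights and fixed-point precisions (lw, ls).
    """

    fields: tuple[FieldSpec, ...]
    exchange_groups: tuple[ExchangeGroup, ...] = ()
    threshold: float = 0.58
    tentative_threshold: float | None = None
    bit_length: int = 32
    bloom_length: int = 500
    bloom_hashes: int = 10
    bloom_salt: bytes = b"epilink-bloom"
    bloom_padded: bool = False
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS
    weights: tuple[float, ...] | None = None  # attached by validate_config
    weight_precision: int | None = None  # lw
    similarity_precision: int | None = None  # ls

    def __post_init__(self) -> None:
        object.__setattr__(self, "fields", tuple(self.fields))
        object.__setattr__(
            self,
            "exchange_groups",
            tuple(
                g if isinstance(g, ExchangeGroup) else ExchangeGroup(tuple(g))
                for g in self.exchange_groups
            ),
        )

    # -- convenience accessors -------------------------------------------
    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields)

    def field(self, name: str) -> FieldSpec:
        for spec in self.fields:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def weight_of(self, name: str) -> float:
        if self.weights is None:
            raise ConfigError("config not validated: weights not attached")
        return self.weights[self.field_names.index(name)]

    def ungrouped_fields(self) -> tuple[str, ...]:
        grouped = {m for g in self.exchange_groups for m in g}
        return tuple(n for n in self.field_names if n not in grouped)

    def validated(self) -> "LinkageConfig":
        return validate_config(self)


def validate_config(config: LinkageConfig) -> LinkageConfig:
    """Check a configuration and attach derived weights and precisions.

    Rejects: thresholds outside (0, 1], a tentative threshold at or above
    the match threshold, L outside {8, 16, 32, 64}, duplicate or unknown
    field names in groups, overlapping groups, mixed comparison types
    within a group, and groups larger than the permutation cap.
    Validation is idempotent: validating a validated config is a no-op.
    """
    names = [f.name for f in config.fields]
    if not names:
        raise ConfigError("configuration has no fields")
    if len(set(names)) != len(names):
        raise ConfigError("duplicate field names")
    if not 0.0 < config.threshold <= 1.0:
        raise ConfigError(
            f"threshold must be in (0,1], got {config.threshold}"
        )
    if config.tentative_threshold is not None:
        if not 0.0 < config.tentative_threshold < config.threshold:
            raise ConfigError(
                "tentative threshold must lie in (0, threshold)"
            )
    if config.bit_length not in (8, 16, 32, 64):
        raise ConfigError(
            f"arithmetic bit-length must be one of 8/16/32/64, "
            f"got {config.bit_length}"
        )
    seen: set[str] = set()
    for group in config.exchange_groups:
        if len(group) > MAX_GROUP_SIZE:
            raise ConfigError(
                f"exchange group {group.members} exceeds the size cap "
                f"{MAX_GROUP_SIZE}"
            )
        comparators = set()
        for member in group:
            if member not in names:
                raise ConfigError(
                    f"exchange group references unknown field {member!r}"
                )
            if member in seen:
                raise ConfigError(
                    f"field {member!r} appears in more than one exchange group"
                )
            seen.add(member)
            comparators.add(config.field(member).comparator)
        if len(comparators) > 1:
            raise ConfigError(
                f"exchange group {group.members} has mixed comparison types"
            )
    weights = tuple(f.resolved_weight() for f in config.fields)

    from .fixed_point import choose_precisions  # deferred: avoids a cycle

    plan = choose_precisions(config.bit_length, len(names))
    return replace(
        config,
        weights=weights,
        weight_precision=plan.lw,
        similarity_precision=plan.ls,
    )


# ---------------------------------------------------------------------------
# JSON configuration
# ---------------------------------------------------------------------------

def load_config(source: Union[str, Path, IO[str], Mapping]) -> LinkageConfig:
    """Parse and validate a JSON linkage configuration.

    Schema::

        {"fields": [{"name", "comparator", "bit_length",
                     "error_rate", "frequency" | "weight"}],
         "exchange_groups": [[names...]],
         "threshold", "tentative_threshold",
         "L", "bloom": {"length", "hashes"}}
    """
    if isinstance(source, Mapping):
        raw = source
    elif isinstance(source, (str, Path)):
        raw = json.loads(Path(source).read_text())
    else:
        raw = json.load(source)
    fields = tuple(
        FieldSpec(
            name=f["name"],
            comparator=f["comparator"],
            bit_length=int(f["bit_length"]),
            error_rate=f.get("error_rate"),
            frequency=f.get("frequency"),
            weight=f.get("weight"),
        )
        for f in raw["fields"]
    )
    bloom = raw.get("bloom", {})
    config = LinkageConfig(
        fields=fields,
        exchange_groups=tuple(
            ExchangeGroup(tuple(g)) for g in raw.get("exchange_groups", ())
        ),
        threshold=float(raw.get("threshold", 0.58)),
        tentative_threshold=raw.get("tentative_threshold"),
        bit_length=int(raw.get("L", 32)),
        bloom_length=int(bloom.get("length", 500)),
        bloom_hashes=int(bloom.get("hashes", 10)),
    )
    return validate_config(config)


def default_config(
    bit_length: int = 32,
    bloom_length: int = 500,
    bloom_hashes: int = 10,
    threshold: float = 0.58,
    tentative_threshold: float | None = 0.40,
) -> LinkageConfig:
    """The package's default 8-field configuration.

    Four dice-compared string fields (given name, surname, birth name,
    city) and four equality-compared fields (day, month and year of birth,
    ZIP code), with the three name fields forming an exchange group.  The
    error rates assume a 10% per-field discrepancy between two registrations
    of the same person; the frequencies are the value-collision
    probabilities of the bundled synthetic population (see the methods
    note), so the weights are package defaults for that population, not
    universal constants.
    """
    fields = (
        FieldSpec("first_name", "dice", bloom_length, 0.10, 0.0041),
        FieldSpec("last_name", "dice", bloom_length, 0.10, 0.0012),
        FieldSpec("birth_name", "dice", bloom_length, 0.10, 0.0012),
        FieldSpec("city", "dice", bloom_length, 0.10, 0.0062),
        FieldSpec("birth_day", "equality", 5, 0.10, 0.036),
        FieldSpec("birth_month", "equality", 4, 0.10, 1.0 / 12.0),
        FieldSpec("birth_year", "equality", 11, 0.10, 1.0 / 66.0),
        FieldSpec("zip", "equality", 17, 0.10, 0.001),
    )
    return validate_config(
        LinkageConfig(
            fields=fields,
            exchange_groups=(
                ExchangeGroup(("first_name", "last_name", "birth_name")),
            ),
            threshold=threshold,
            tentative_threshold=tentative_threshold,
            bit_length=bit_length,
            bloom_length=bloom_length,
            bloom_hashes=bloom_hashes,
        )
    )


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Record:
    """One record: raw values, per-field emptiness flags and encodings.

    ``delta[name]`` is 1 iff the field is non-empty; ``encoded[name]`` is
    present exactly for non-empty fields and holds a :class:`BloomVector`
    (dice fields) or an ``lb``-bit integer (equality fields).
    """

    raw: Mapping[str, str]
    delta: Mapping[str, int]
    encoded: Mapping[str, Union[int, BloomVector]]

    @classmethod
    def from_values(
        cls, values: Mapping[str, object], config: LinkageConfig
    ) -> "Record":
        raw: dict[str, str] = {}
        delta: dict[str, int] = {}
        encoded: dict[str, Union[int, BloomVector]] = {}
        for spec in config.fields:
            value = values.get(spec.name)
            text = "" if value is None else str(value).strip()
            if pd.isna(value) or text.upper() in config.missing_tokens:
                raw[spec.name] = ""
                delta[spec.name] = 0
                continue
            raw[spec.name] = text
            delta[spec.name] = 1
            if spec.comparator == "dice":
                encoded[spec.name] = bloom_encode(
                    text,
                    config.bloom_length,
                    config.bloom_hashes,
                    salt=config.bloom_salt,
                    padded=config.bloom_padded,
                )
            else:
                try:
                    number = int(text)
                except ValueError:
                    raise ConfigError(
                        f"field {spec.name!r}: equality value {text!r} "
                        "is not an integer"
                    ) from None
                if not 0 <= number < (1 << spec.bit_length):
                    raise ConfigError(
                        f"field {spec.name!r}: value {number} does not fit "
                        f"in {spec.bit_length} bits"
                    )
                encoded[spec.name] = number
        return cls(raw=raw, delta=delta, encoded=encoded)


def records_from_frame(
    frame: pd.DataFrame, config: LinkageConfig
) -> list[Record]:
    """Encode every row of a DataFrame as a :class:`Record` (row order kept)."""
    missing = [n for n in config.field_names if n not in frame.columns]
    if missing:
        raise ConfigError(f"CSV is missing configured columns: {missing}")
    return [
        Record.from_values(row, config)
        for row in frame[list(config.field_names)].to_dict("records")
    ]


def load_records(
    source: Union[str, Path, IO[str]], config: LinkageConfig
) -> list[Record]:
    """Read a CSV table (UTF-8, header row) into encoded records.

    Empty cells and the configured missing tokens set ``delta = 0``.
    Record index ``j`` is the 0-based row order.
    """
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    return records_from_frame(frame, config)


def write_records(
    records: Iterable[Record],
    target: Union[str, Path, IO[str]],
    config: LinkageConfig,
) -> None:
    """Write records back to CSV in the dialect ``load_records`` reads."""
    rows = [
        {name: rec.raw.get(name, "") for name in config.field_names}
        for rec in records
    ]
    pd.DataFrame(rows, columns=list(config.field_names)).to_csv(
        target, index=False
    )
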