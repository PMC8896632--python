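"""Shared fixtures: small configs and deterministically generated corpora."""

import numpy as np
import pytest

from epilink_mpc import default_config
from epilink_mpc.bloom_encoding import BloomVector
from epilink_mpc.config_records import (
    ExchangeGroup,
    FieldSpec,
    LinkageConfig,
    Record,
    validate_config,
)


@pytest.fixture(scope="session")
def config():
    """Default 8-field configuration at full Bloom length."""
    return default_config()


@pytest.fixture(scope="session")
def small_config():
    """Default field layout with short Bloom filters — keeps circuits and
    shared evaluations small while exercising the full structure."""
    return default_config(bloom_length=32, bloom_hashes=3)


@pytest.fixture(scope="session")
def tiny_equality_config():
    """Two equal-weight equality fields; handy for exact arithmetic."""
    return validate_config(
        LinkageConfig(
            fields=(
                FieldSpec("a", "equality", 8, weight=2.0),
                FieldSpec("b", "equality", 8, weight=2.0),
            ),
            threshold=0.75,
        )
    )


def make_record(config, **values) -> Record:
    return Record.from_values(values, config)


def random_bloom(rng: np.random.Generator, m: int, density: float = 0.12):
    return BloomVector(rng.random(m) < density)


def random_default_records(config, rng, n, missing_rate=0.1):
    """Random records over small value pools for the default field layout."""
    given_pool = ["ANNA", "PETER", "MARIA", "HANS", "JULIA", "KLAUS"]
    sur_pool = ["SCHMIDT", "WEBER", "MUELLER", "KOCH", "WOLF"]
    city_pool = ["BERLIN", "KOELN", "MAINZ"]
    records = []
    for _ in range(n):
        values = {
            "first_name": given_pool[rng.integers(len(given_pool))],
            "last_name": sur_pool[rng.integers(len(sur_pool))],
            "birth_name": sur_pool[rng.integers(len(sur_pool))],
            "city": city_pool[rng.integers(len(city_pool))],
            "birth_day": int(rng.integers(1, 29)),
            "birth_month": int(rng.integers(1, 13)),
            "birth_year": int(rng.integers(1940, 2006)),
            "zip": int(rng.integers(10000, 99999)),
        }
        for key in list(values):
            if rng.random() < missing_rate:
                values[key] = ""
        records.append(Record.from_values(values, config))
    return records


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (no order coupling)."""
    return np.random.default_rng(20240917)
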