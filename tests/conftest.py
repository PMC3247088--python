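from __future__ import annotations

import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle helpers

from privrisk import AttributeSchema, Microdata, Record

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_names_table(names: list[str | None]) -> Microdata:
    """A one-identifier-column Microdata from a plain list of names."""
    schema = AttributeSchema.build([("name", "identifier", "text")])
    return Microdata(
        schema=schema,
        records=[Record(f"r{i}", {"name": n}) for i, n in enumerate(names)],
    )


@pytest.fixture
def names_table():
    return make_names_table


@pytest.fixture
def small_table():
    """Three-record table with gender/location/age quasi-identifiers."""
    schema = AttributeSchema.build([
        ("first", "identifier", "text"),
        ("gender", "quasi_identifier", "category"),
        ("location", "quasi_identifier", "category"),
        ("age", "quasi_identifier", "integer"),
    ])
    rows = [
        ("ann", "F", "Town", 30),
        ("anne", "F", "Town", 30),
        ("bob", "M", "Town", 41),
    ]
    return Microdata(
        schema=schema,
        records=[
            Record(f"r{i}", dict(zip(("first", "gender", "location", "age"), row)))
            for i, row in enumerate(rows)
        ],
    )
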