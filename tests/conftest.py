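import math

import pytest
from hypothesis import HealthCheck, settings

from icdmap.codesystem import Code, CodeSystem

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_system(system_id, rows):
    """rows: (code_id, description, parent_id, chapter_id) tuples."""
    return CodeSystem(system_id, [Code(*row) for row in rows])


@pytest.fixture
def cholera_system():
    """4-level chain matching the classic cholera hierarchy, plus a sibling."""
    return make_system(
        "icd9",
        [
            ("001-139", "Infectious and parasitic diseases", "", "ch1"),
            ("001-009", "Intestinal infectious diseases", "001-139", "ch1"),
            ("001", "Cholera", "001-009", "ch1"),
            ("001.0", "Cholera due to V. cholerae", "001", "ch1"),
            ("001.1", "Cholera due to V. cholerae el tor", "001", "ch1"),
        ],
    )


@pytest.fixture
def two_chapter_system():
    return make_system(
        "sys",
        [
            ("A", "alpha chapter", "", "A"),
            ("A.1", "alpha block", "A", "A"),
            ("A.1.1", "alpha leaf one", "A.1", "A"),
            ("A.1.2", "alpha leaf two", "A.1", "A"),
            ("B", "beta chapter", "", "B"),
            ("B.1", "beta leaf", "B", "B"),
        ],
    )


def brute_force_cosine(a, b):
    """Independent scalar cosine for oracle comparisons."""
    dot = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    return dot / (na * nb)
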