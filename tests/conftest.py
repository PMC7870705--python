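import numpy as np
import pytest

from segdist.core import SegregationCounts

# The published T1 genotype counts with their printed transmission
# efficiencies: S22B complementation rows at 2 printed decimals, S22A
# rows at 3.  Used across the inference and acceptance tests.
S22B_TABLE = [
    ("Eco72I", (13, 20, 0), 0.0),
    ("XmnI_a", (26, 21, 5), 0.16),
    ("SalI", (18, 41, 19), 0.51),
    ("XmnI_b", (15, 12, 2), 0.12),
    ("non_transgenic", (42, 43, 5), 0.11),
]

S22A_TABLE = [
    ("S22A_j1", (54, 57, 17), 0.239),
    ("S22A_j2", (19, 20, 0), 0.000),
    ("S22A_j3", (46, 55, 2), 0.042),
    ("empty_vector", (35, 41, 0), 0.000),
]

# Printed exact-test p-values of each transgenic family against the
# non-transgenic control (42, 43, 5), with their printed decimal places.
S22B_PVALUES = [
    ("Eco72I", (13, 20, 0), 0.32, 2),
    ("XmnI_a", (26, 21, 5), 0.52, 2),
    ("SalI", (18, 41, 19), 0.00017, 5),
    ("XmnI_b", (15, 12, 2), 0.74, 2),
]

CONTROL_COUNTS = (42, 43, 5)


@pytest.fixture
def control_counts() -> SegregationCounts:
    return SegregationCounts(*CONTROL_COUNTS)


def random_count_triples(rng: np.random.Generator, size: int, max_n: int = 200):
    """Random SegregationCounts with at least one homozygote (k identifiable)."""
    out = []
    while len(out) < size:
        n = int(rng.integers(3, max_n))
        k = float(rng.uniform(0.02, 0.98))
        counts = rng.multinomial(n, [(1 - k) / 2, 0.5, k / 2])
        if counts[0] + counts[2] > 0:
            out.append(SegregationCounts(*(int(c) for c in counts)))
    return out
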