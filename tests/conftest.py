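import math
from pathlib import Path

import pytest

from acidostab.io import ProteinRecord
from acidostab.substitution import load_reference_counts

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write raw FASTA text to a temp file and return its path."""

    def _write(text: str, name: str = "test.fa") -> Path:
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture(scope="session")
def reference_matrix():
    """The bundled 393-pair substitution count matrix."""
    return load_reference_counts()


@pytest.fixture(scope="session")
def published_ratio_table():
    """Published count/ratio/mark cells: {(ap, np): (count, ratio, mark)}."""
    table = {}
    with open(DATA_DIR / "published_substitution_ratios.tsv") as fh:
        next(fh)
        for line in fh:
            r, c, count, ratio, mark = line.rstrip("\n").split("\t")
            table[(r, c)] = (int(count), float(ratio) if ratio else None, mark)
    return table


def fisher_oracle(table) -> float:
    """Two-sided Fisher exact p by brute-force hypergeometric enumeration.

    Exact integer arithmetic; sums the probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (with the conventional 1 + 1e-7 relative slack).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def pmf(k: int) -> float:
        return math.comb(r1, k) * math.comb(r2, c1 - k) / denom

    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    p_obs = pmf(a)
    total = 0.0
    for k in range(lo, hi + 1):
        p = pmf(k)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)
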