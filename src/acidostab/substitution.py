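"""Directional AP/NP residue substitution matrix with exact-test bias calls.

The matrix is indexed ``counts[r][c]`` = number of aligned, non-gap,
standard-residue columns with AP residue ``r`` and NP residue ``c``; cell
(r, c) therefore represents the *forward* (NP -> AP) substitution c -> r and
its mirror cell (c, r) the reverse event.  The directional ratio of a cell
is ``counts[r][c] / counts[c][r]``.

Significance of the bias of each unordered residue pair is assessed with a
two-sided Fisher exact test.  Several 2x2 constructions are available
because the appropriate conditioning is genuinely debatable:

``occurrence`` (default)
    ``[[n_fwd, N_r - n_fwd], [n_rev, N_c - n_rev]]`` where ``N_k`` is the
    total number of counted columns in which residue k occurs (either
    role).  Asks whether c -> r conversions are more frequent, relative to
    each residue's opportunity, than r -> c conversions.
``ap-occurrence``
    as above with margins restricted to occurrences in the AP role.
``global``
    ``[[n_fwd, T - n_fwd], [n_rev, T - n_rev]]`` with T the total number
    of off-diagonal (mismatch) columns.
``independence``
    the classical single-cell enrichment test of ``counts[r][c]`` against
    the remainder of the matrix (the only per-cell-asymmetric option).
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .io import PairwiseAlignment
from .orthologs import OrthologPair
from .tables import STANDARD_AA, SUBSTITUTION_ORDER

__all__ = [
    "SubstitutionMatrix",
    "count_substitutions",
    "substitution_ratios",
    "substitution_significance",
    "load_reference_counts",
    "CONSTRUCTIONS",
    "round_ratio",
]

NS = "not-significant"
FWD = "forward-favored"
REV = "reverse-favored"

CONSTRUCTIONS = ("occurrence", "ap-occurrence", "global", "independence")

_STD = set(STANDARD_AA)


@dataclasses.dataclass
class SubstitutionMatrix:
    """20x20 directional counts plus derived ratios / p-values / calls."""

    residues: str = SUBSTITUTION_ORDER
    counts: np.ndarray = None  # int, counts[r][c]: AP r, NP c
    ratios: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    calls: np.ndarray | None = None  # object array of NS/FWD/REV
    construction: str | None = None

    def __post_init__(self) -> None:
        n = len(self.residues)
        if self.counts is None:
            self.counts = np.zeros((n, n), dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over the residue order")

    def index(self, residue: str) -> int:
        return self.residues.index(residue)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def total_offdiag(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def ratio(self, ap: str, np_res: str) -> float:
        return float(self.ratios[self.index(ap), self.index(np_res)])

    def call_totals(self) -> tuple[int, int, int]:
        """(significant, forward-favored, reverse-favored) cell counts."""
        if self.calls is None:
            raise ValueError("significance not computed")
        f = int((self.calls == FWD).sum())
        r = int((self.calls == REV).sum())
        return f + r, f, r


def round_ratio(numerator: int, denominator: int, places: int = 2) -> float:
    """Display rounding of a count ratio: exact decimal, half-up."""
    if denominator == 0:
        return float("inf") if numerator else float("nan")
    q = Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))


def _labelled(items) -> Iterable[PairwiseAlignment]:
    """Yield alignments with the AP sequence in row a."""
    for item in items:
        if isinstance(item, OrthologPair):
            yield item.alignment
        elif isinstance(item, tuple) and len(item) == 2:
            aln, ap_row = item
            if ap_row not in ("a", "b"):
                raise ValueError(f"AP role label must be 'a' or 'b', got {ap_row!r}")
            yield aln if ap_row == "a" else aln.swapped()
        else:
            raise TypeError(
                "alignments must carry an AP role label: pass OrthologPair "
                "items or (PairwiseAlignment, 'a'|'b') tuples"
            )


def count_substitutions(alignments, residues: str = SUBSTITUTION_ORDER) -> SubstitutionMatrix:
    """Tally aligned columns into the directional count matrix.

    Gap columns and columns containing ambiguity codes are skipped.
    """
    idx = {res: i for i, res in enumerate(residues)}
    counts = np.zeros((len(residues), len(residues)), dtype=np.int64)
    for aln in _labelled(alignments):
        for ap_res, np_res in aln.columns():
            if ap_res in _STD and np_res in _STD:
                counts[idx[ap_res], idx[np_res]] += 1
    return SubstitutionMatrix(residues=residues, counts=counts)


def substitution_ratios(m: SubstitutionMatrix) -> SubstitutionMatrix:
    """Fill directional ratios; diagonal reported as 1 by convention."""
    c = m.counts
    n = len(m.residues)
    ratios = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                ratios[i, j] = 1.0
            elif c[j, i] > 0:
                ratios[i, j] = c[i, j] / c[j, i]
            elif c[i, j] > 0:
                ratios[i, j] = np.inf  # forward events, no reverse events
            # else 0/0 stays NaN (undefined)
    m.ratios = ratios
    return m


def _fisher_tables(m: SubstitutionMatrix, construction: str):
    """Yield ((i, j), 2x2 table) for every off-diagonal cell."""
    c = m.counts
    n = len(m.residues)
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    occ = rows + cols
    T = m.total_offdiag
    Tall = m.total
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            fwd, rev = int(c[i, j]), int(c[j, i])
            if construction == "occurrence":
                table = [[fwd, int(occ[i]) - fwd], [rev, int(occ[j]) - rev]]
            elif construction == "ap-occurrence":
                table = [[fwd, int(rows[i]) - fwd], [rev, int(rows[j]) - rev]]
            elif construction == "global":
                table = [[fwd, T - fwd], [rev, T - rev]]
            elif construction == "independence":
                table = [
                    [fwd, int(rows[i]) - fwd],
                    [int(cols[j]) - fwd, Tall - int(rows[i]) - int(cols[j]) + fwd],
                ]
            else:
                raise ValueError(f"unknown construction {construction!r}")
            yield (i, j), table


def substitution_significance(
    m: SubstitutionMatrix,
    alpha: float = 1e-10,
    construction: str = "occurrence",
) -> SubstitutionMatrix:
    """Two-sided Fisher exact tests and directional bias calls.

    A cell is called favored in the direction of its larger count when
    p < alpha; equal counts are never called.  The diagonal is excluded.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    c = m.counts
    n = len(m.residues)
    pvalues = np.ones((n, n))
    calls = np.full((n, n), NS, dtype=object)
    for (i, j), table in _fisher_tables(m, construction):
        p = float(fisher_exact(table, alternative="two-sided")[1])
        pvalues[i, j] = p
        if p < alpha and c[i, j] != c[j, i]:
            calls[i, j] = FWD if c[i, j] > c[j, i] else REV
    m.pvalues = pvalues
    m.calls = calls
    m.construction = construction
    return m


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def load_reference_counts() -> SubstitutionMatrix:
    """The published directional substitution counts observed across the
    393 AP-NP ortholog pair alignments (bundled)."""
    path = resources.files("acidostab.data") / "substitution_counts.tsv"
    return read_counts_tsv(path)


def read_counts_tsv(path) -> SubstitutionMatrix:
    with open(str(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        residues = "".join(header[1:])
        rows = []
        order = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            order.append(parts[0])
            rows.append([int(x) for x in parts[1:]])
    counts = np.array(rows, dtype=np.int64)
    if "".join(order) != residues:
        raise ValueError("row order does not match column order")
    return SubstitutionMatrix(residues=residues, counts=counts)


def write_matrix_tsv(m: SubstitutionMatrix, path: str | Path) -> None:
    """Two lines per residue row: counts, then display-rounded ratios."""
    res = m.residues
    with open(path, "w") as fh:
        fh.write("ap_np\t" + "\t".join(res) + "\n")
        for i, r in enumerate(res):
            fh.write(r + "\t" + "\t".join(str(int(x)) for x in m.counts[i]) + "\n")
            cells = []
            for j in range(len(res)):
                if i == j:
                    cells.append("-")
                else:
                    cells.append(f"{round_ratio(int(m.counts[i, j]), int(m.counts[j, i])):.2f}")
            fh.write("\t" + "\t".join(cells) + "\n")


def write_matrix_long(m: SubstitutionMatrix, path: str | Path) -> None:
    res = m.residues
    with open(path, "w") as fh:
        fh.write("ap_residue\tnp_residue\tcount\treverse_count\tratio\tp_value\tcall\n")
        for i, r in enumerate(res):
            for j, c in enumerate(res):
                if i == j:
                    continue
                ratio = m.ratios[i, j] if m.ratios is not None else ""
                p = m.pvalues[i, j] if m.pvalues is not None else ""
                call = m.calls[i, j] if m.calls is not None else ""
                fh.write(
                    f"{r}\t{c}\t{int(m.counts[i, j])}\t{int(m.counts[j, i])}\t"
                    f"{ratio}\t{p}\t{call}\n"
                )
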