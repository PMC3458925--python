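"""Build the non-redundant AP-NP ortholog pair set.

Stage order: reciprocal best hits + e-value / length / similarity filters,
transmembrane-protein removal (from an externally supplied id set),
single-linkage redundancy clustering, and finally the length window.
Every stage is order-independent under the documented tie-breaks and the
pipeline report records the count after each stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

from .io import BlastHit, PairwiseAlignment, ProteinRecord, align_pair, default_aligner

__all__ = [
    "OrthologPair",
    "PipelineReport",
    "reciprocal_best_hits",
    "filter_pairs",
    "remove_membrane_proteins",
    "cluster_redundancy",
    "length_window",
    "build_pairs",
]


@dataclasses.dataclass
class OrthologPair:
    """An AP/NP ortholog pair with its alignment and hit statistics."""

    ap: ProteinRecord
    np: ProteinRecord
    alignment: PairwiseAlignment  # AP row first
    evalue_ab: float = 0.0
    evalue_ba: float = 0.0
    percent_similarity: float = 100.0

    @property
    def best_evalue(self) -> float:
        return min(self.evalue_ab, self.evalue_ba)


@dataclasses.dataclass
class PipelineReport:
    n_ap_input: int = 0
    n_np_input: int = 0
    n_rbh: int = 0
    n_after_filters: int = 0
    n_after_membrane: int = 0
    n_clusters: int = 0
    n_after_redundancy: int = 0
    n_final: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _best_hit(hits: Iterable[BlastHit]) -> dict[str, BlastHit]:
    """Best hit per query: smallest e-value, ties by higher identity then
    lexically smallest subject id."""
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key = (h.evalue, -h.percent_identity, h.subject_id)
        cur_key = (cur.evalue, -cur.percent_identity, cur.subject_id)
        if key < cur_key:
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Sequence[BlastHit],
    hits_ba: Sequence[BlastHit],
    evalue_max: float = 1e-10,
) -> list[tuple[str, str]]:
    """(a, b) pairs where each is the other's best hit, both e-values below
    ``evalue_max`` (strict)."""
    best_ab = _best_hit(hits_ab)
    best_ba = _best_hit(hits_ba)
    out = []
    for a, hit in sorted(best_ab.items()):
        b = hit.subject_id
        back = best_ba.get(b)
        if back is None or back.subject_id != a:
            continue
        if hit.evalue < evalue_max and back.evalue < evalue_max:
            out.append((a, b))
    return out


def filter_pairs(
    pairs: Sequence[OrthologPair],
    max_len_diff_frac: float = 0.05,
    min_similarity: float = 30.0,
) -> list[OrthologPair]:
    """Keep pairs with |len difference| strictly below ``max_len_diff_frac``
    of the shorter sequence and similarity strictly above ``min_similarity``."""
    kept = []
    for p in pairs:
        shorter = min(p.ap.length, p.np.length)
        if abs(p.ap.length - p.np.length) >= max_len_diff_frac * shorter:
            continue
        if not p.percent_similarity > min_similarity:
            continue
        kept.append(p)
    return kept


def remove_membrane_proteins(
    pairs: Sequence[OrthologPair], membrane_ids: set[str]
) -> list[OrthologPair]:
    """Drop any pair whose AP or NP member is in the membrane id set."""
    return [p for p in pairs if p.ap.id not in membrane_ids and p.np.id not in membrane_ids]


def _sequences_link(
    a: ProteinRecord,
    b: ProteinRecord,
    min_coverage: float,
    max_identity: float,
    aligner,
) -> bool:
    aln = align_pair(a, b, aligner)
    if aln.identity_fraction < max_identity:
        return False
    return aln.coverage("a") >= min_coverage and aln.coverage("b") >= min_coverage


def cluster_redundancy(
    pairs: Sequence[OrthologPair],
    min_coverage: float = 0.5,
    max_identity: float = 0.25,
    aligner=None,
    report: PipelineReport | None = None,
) -> list[OrthologPair]:
    """Greedy single-linkage clustering over all member sequences.

    Two sequences link when pairwise identity >= ``max_identity`` with
    alignment coverage >= ``min_coverage`` of both.  Pairs sharing a linked
    sequence fall in one cluster; the retained representative is the pair
    with the smallest best e-value, ties broken by the lexically smallest
    AP id.
    """
    if aligner is None:
        aligner = default_aligner()
    n = len(pairs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    seqs: list[tuple[int, ProteinRecord]] = []
    for i, p in enumerate(pairs):
        seqs.append((i, p.ap))
        seqs.append((i, p.np))
    for a in range(len(seqs)):
        ia, ra = seqs[a]
        for b in range(a + 1, len(seqs)):
            ib, rb = seqs[b]
            if find(ia) == find(ib):
                continue
            if ra.sequence == rb.sequence or _sequences_link(
                ra, rb, min_coverage, max_identity, aligner
            ):
                union(ia, ib)

    clusters: dict[int, list[OrthologPair]] = {}
    for i, p in enumerate(pairs):
        clusters.setdefault(find(i), []).append(p)
    survivors = [
        min(members, key=lambda p: (p.best_evalue, p.ap.id))
        for members in clusters.values()
    ]
    survivors.sort(key=lambda p: p.ap.id)
    if report is not None:
        report.n_clusters = len(clusters)
    return survivors


def length_window(
    records: Sequence, min_len: int = 50, max_len: int = 600
) -> list:
    """Keep items with min_len < length < max_len (strict).

    Accepts ProteinRecord or OrthologPair items; for pairs both members
    must pass.
    """
    out = []
    for item in records:
        if isinstance(item, OrthologPair):
            ok = min_len < item.ap.length < max_len and min_len < item.np.length < max_len
        else:
            ok = min_len < item.length < max_len
        if ok:
            out.append(item)
    return out


def build_pairs(
    ap_records: Sequence[ProteinRecord],
    np_records: Sequence[ProteinRecord],
    hits_ab: Sequence[BlastHit] | None = None,
    hits_ba: Sequence[BlastHit] | None = None,
    membrane_ids: set[str] | None = None,
    evalue_max: float = 1e-10,
    max_len_diff_frac: float = 0.05,
    min_similarity: float = 30.0,
    min_coverage: float = 0.5,
    max_identity: float = 0.25,
    min_len: int = 50,
    max_len: int = 600,
    aligner=None,
) -> tuple[list[OrthologPair], PipelineReport]:
    """Run the full pipeline from proteomes (plus optional BLAST hits).

    Without precomputed hits, candidate pairing matches records
    positionally (pre-paired inputs, e.g. simulator output or mate files)
    and similarity falls back to internal alignment identity.
    """
    if aligner is None:
        aligner = default_aligner()
    report = PipelineReport(n_ap_input=len(ap_records), n_np_input=len(np_records))
    ap_by_id = {r.id: r for r in ap_records}
    np_by_id = {r.id: r for r in np_records}

    candidates: list[OrthologPair] = []
    if hits_ab is not None and hits_ba is not None:
        rbh = reciprocal_best_hits(hits_ab, hits_ba, evalue_max)
        ev_ab = {(h.query_id, h.subject_id): h for h in hits_ab}
        ev_ba = {(h.query_id, h.subject_id): h for h in hits_ba}
        for a, b in rbh:
            ra, rb = ap_by_id[a], np_by_id[b]
            aln = align_pair(ra, rb, aligner)
            fwd, rev = ev_ab[(a, b)], ev_ba[(b, a)]
            sim = (
                fwd.percent_similarity
                if fwd.percent_similarity is not None
                else 100.0 * aln.identity_fraction
            )
            candidates.append(
                OrthologPair(ra, rb, aln, fwd.evalue, rev.evalue, sim)
            )
    else:
        for ra, rb in zip(ap_records, np_records):
            aln = align_pair(ra, rb, aligner)
            candidates.append(
                OrthologPair(ra, rb, aln, 0.0, 0.0, 100.0 * aln.identity_fraction)
            )
    report.n_rbh = len(candidates)

    pairs = filter_pairs(candidates, max_len_diff_frac, min_similarity)
    report.n_after_filters = len(pairs)
    pairs = remove_membrane_proteins(pairs, membrane_ids or set())
    report.n_after_membrane = len(pairs)
    pairs = cluster_redundancy(pairs, min_coverage, max_identity, aligner, report)
    report.n_after_redundancy = len(pairs)
    pairs = length_window(pairs, min_len, max_len)
    report.n_final = len(pairs)
    return pairs, report


def write_pair_table(pairs: Sequence[OrthologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "ap_id\tnp_id\tap_length\tnp_length\tidentity\tsimilarity\tevalue_ab\tevalue_ba\n"
        )
        for p in pairs:
            fh.write(
                f"{p.ap.id}\t{p.np.id}\t{p.ap.length}\t{p.np.length}\t"
                f"{p.alignment.identity_fraction:.4f}\t{p.percent_similarity:.2f}\t"
                f"{p.evalue_ab:g}\t{p.evalue_ba:g}\n"
            )
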