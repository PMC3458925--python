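"""Synthetic AP/NP ortholog-pair generator.

Emulates the statistical structure of real AP-NP ortholog sets: paired
sequences at controllable identity, directional residue-substitution
biases (e.g. N -> D enriched in the NP -> AP direction) and the resulting
composition shifts.  The NP sequence is drawn i.i.d. from a background
composition (default: the published NP composition means); the AP mate is
derived by mutating each site independently with a global substitution
rate, drawing the target residue from the background re-weighted by the
per-(from, to) bias multipliers.  Optional single-residue indels with
geometric extension are applied after substitutions (off by default).

The generator is not a phylogenetic simulator: sites are independent,
there is no rate heterogeneity, and the two roles share one background.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import PairwiseAlignment, ProteinRecord
from .scoring import SCORING_FEATURES
from .substitution import SubstitutionMatrix
from .tables import STANDARD_AA, SUBSTITUTION_ORDER

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "reference_background",
    "generate_pairs",
    "generate_separable_deltas",
]


def reference_background() -> dict[str, float]:
    """NP composition means of the published 393-pair study, normalised."""
    path = resources.files("acidostab.data") / "composition_reference.tsv"
    comp = {}
    with open(str(path)) as fh:
        next(fh)
        for line in fh:
            res, _, _, mean_np, _ = line.split("\t")
            comp[res] = float(mean_np)
    total = sum(comp.values())
    return {res: v / total for res, v in comp.items()}


def study_bias_map() -> dict[tuple[str, str], float]:
    """Directional bias multipliers emulating the reported AP composition
    trends: enrichment of Thr/Ala/Pro and depletion of Gln/Asn/Tyr/Ile.

    Multipliers scale the mutation flux *into* each residue from every
    source; their magnitudes are calibrated so that, at the default
    substitution rate, the realised AP-minus-NP composition deltas are of
    the order observed in the real 393-pair data (about +0.010 for T,
    -0.008 for Y, etc.).
    """
    into = {"T": 1.7, "A": 1.25, "P": 1.2, "Q": 0.45, "N": 0.55, "Y": 0.05, "I": 0.6}
    return {
        (src, tgt): mult
        for tgt, mult in into.items()
        for src in STANDARD_AA
        if src != tgt
    }


@dataclasses.dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the real study's conditions."""

    n_pairs: int = 393
    length_range: tuple[int, int] = (51, 599)
    background_composition: Mapping[str, float] | None = None
    substitution_rate: float = 0.3
    bias_map: Mapping[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    indel_rate: float = 0.0
    indel_extend: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError(f"degenerate length range {self.length_range}")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0 <= self.indel_rate <= 1:
            raise ValueError("indel_rate must be in [0, 1]")
        if self.background_composition is None:
            self.background_composition = reference_background()
        total = sum(self.background_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")
        for (f, t), mult in self.bias_map.items():
            if mult < 0:
                raise ValueError(f"bias multiplier for {(f, t)} must be >= 0")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth: per-pair true alignments plus realised event counts."""

    alignments: list[PairwiseAlignment]  # AP row first
    substitution_counts: SubstitutionMatrix
    expected_composition_delta: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_pairs": len(self.alignments),
            "substitution_counts": {
                "residues": self.substitution_counts.residues,
                "counts": self.substitution_counts.counts.tolist(),
            },
            "expected_composition_delta": self.expected_composition_delta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _mutation_kernel(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Background vector and per-source target distributions (zero self)."""
    aas = list(STANDARD_AA)
    bg = np.array([cfg.background_composition[a] for a in aas])
    kernel = np.tile(bg, (len(aas), 1))
    for i, src in enumerate(aas):
        for j, tgt in enumerate(aas):
            mult = cfg.bias_map.get((src, tgt), 1.0)
            kernel[i, j] = bg[j] * mult
        kernel[i, i] = 0.0
        kernel[i] /= kernel[i].sum()
    return bg, kernel


def generate_pairs(
    cfg: SyntheticConfig,
) -> tuple[list[ProteinRecord], list[ProteinRecord], SyntheticTruth]:
    """Generate AP records, NP records (i-th entries are mates) and truth."""
    rng = np.random.default_rng(cfg.seed)
    aas = np.array(list(STANDARD_AA))
    bg, kernel = _mutation_kernel(cfg)
    aa_index = {a: i for i, a in enumerate(STANDARD_AA)}

    sub_order_idx = {res: i for i, res in enumerate(SUBSTITUTION_ORDER)}
    counts = np.zeros((20, 20), dtype=np.int64)

    ap_records, np_records, alignments = [], [], []
    lo, hi = cfg.length_range
    for k in range(cfg.n_pairs):
        L = int(rng.integers(lo, hi + 1))
        np_idx = rng.choice(20, size=L, p=bg)
        ap_idx = np_idx.copy()
        mutate = rng.random(L) < cfg.substitution_rate
        for pos in np.nonzero(mutate)[0]:
            src = np_idx[pos]
            ap_idx[pos] = rng.choice(20, p=kernel[src])
        np_seq = "".join(aas[np_idx])
        ap_seq = "".join(aas[ap_idx])
        ap_row, np_row = ap_seq, np_seq
        if cfg.indel_rate > 0:
            ap_row, np_row = _apply_indels(ap_row, np_row, cfg, rng)
        ap_rec = ProteinRecord(f"AP_{k:05d}", ap_row.replace("-", ""))
        np_rec = ProteinRecord(f"NP_{k:05d}", np_row.replace("-", ""))
        aln = PairwiseAlignment(ap_row, np_row)
        for a, b in aln.columns():
            if a != "-" and b != "-":
                counts[sub_order_idx[a], sub_order_idx[b]] += 1
        ap_records.append(ap_rec)
        np_records.append(np_rec)
        alignments.append(aln)

    truth = SyntheticTruth(
        alignments=alignments,
        substitution_counts=SubstitutionMatrix(
            residues=SUBSTITUTION_ORDER, counts=counts
        ),
        expected_composition_delta=_expected_delta(cfg, bg, kernel, aa_index),
    )
    return ap_records, np_records, truth


def _apply_indels(ap_row: str, np_row: str, cfg: SyntheticConfig, rng) -> tuple[str, str]:
    """Single-residue indels with geometric extension, after substitutions."""
    aas = list(STANDARD_AA)
    bg = [cfg.background_composition[a] for a in aas]
    out_a, out_b = [], []
    for a, b in zip(ap_row, np_row):
        if rng.random() < cfg.indel_rate:
            length = 1 + rng.geometric(1 - cfg.indel_extend) - 1
            if rng.random() < 0.5:  # insertion in AP
                for _ in range(length):
                    out_a.append(str(rng.choice(aas, p=bg)))
                    out_b.append("-")
            else:  # deletion from AP
                for _ in range(length):
                    out_a.append("-")
                    out_b.append(str(rng.choice(aas, p=bg)))
        out_a.append(a)
        out_b.append(b)
    return "".join(out_a), "".join(out_b)


def _expected_delta(cfg, bg, kernel, aa_index) -> dict[str, float]:
    """Expected AP-minus-NP composition change per residue."""
    rate = cfg.substitution_rate
    delta = {}
    for a, i in aa_index.items():
        gain = rate * float(np.dot(bg, kernel[:, i]))
        loss = rate * bg[i]
        delta[a] = gain - loss
    return delta


# ---------------------------------------------------------------------------
# Separable deltas for the scoring optimizer
# ---------------------------------------------------------------------------

def generate_separable_deltas(
    n: int,
    margin: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    planted_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Delta rows for the ten scoring features that a planted weight vector
    separates with at least ``margin`` before noise.

    Returns (X, w_planted); every row satisfies ``X @ w > 0`` pre-noise.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    rng = np.random.default_rng(seed)
    d = len(SCORING_FEATURES)
    if planted_weights is None:
        w = rng.uniform(-1, 1, size=d)
        w[np.abs(w) < 0.2] = 0.2 * np.sign(w[np.abs(w) < 0.2] + 1e-12)
    else:
        w = np.asarray(planted_weights, dtype=float)
    if n == 0:
        return np.empty((0, d)), w
    u = w / np.linalg.norm(w)
    along = rng.uniform(margin, max(margin * 2, 1.0), size=n) / np.linalg.norm(w)
    ortho = rng.normal(scale=0.3, size=(n, d))
    ortho -= np.outer(ortho @ u, u)
    X = np.outer(along, u) + ortho
    # rescale rows into the symmetric-mode bound; scaling preserves the
    # sign of X @ w, so separation survives
    row_max = np.maximum(1.0, np.abs(X).max(axis=1))
    X = X / row_max[:, None]
    if noise_sd > 0:
        X = np.clip(X + rng.normal(scale=noise_sd, size=X.shape), -1.0, 1.0)
    return X, w
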