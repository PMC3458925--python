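"""Sequence-derived features: compositions, dipeptides, physicochemical indices.

Conventions
-----------
* ``c_`` features are absolute counts, ``x_`` features are normalised by
  chain length (``L`` for residues and categories, ``L - 1`` for dipeptides).
* Tolerated ambiguity codes (X, B, Z, U, J, O) are skipped in every
  numerator but still count toward the length denominators, so compositions
  of flagged records remain comparable with clean ones.
* The physicochemical indices (pI, instability, GRAVY) are computed on the
  ambiguity-free sequence via Biopython's ProtParam machinery
  (Bjellqvist pKa bisection for pI, the DIWV dipeptide table for the
  instability index, Kyte-Doolittle hydropathy for GRAVY).
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .catalogue import AA_SORTED, DIPEPTIDES, FeatureCatalogue, feature_catalogue
from .io import ProteinRecord
from .tables import (
    ALIPHATIC_INDEX_COEFF,
    CATEGORY_SETS,
    INSTABILITY_THRESHOLD,
    MAX_ASA,
    RESIDUE_PI,
    STANDARD_AA,
    SULFUR_AA,
)

__all__ = [
    "compute_features",
    "protparam_indices",
    "category_features",
    "ProteinFeaturizer",
    "feature_matrix",
    "write_feature_matrix",
]

_STD = set(STANDARD_AA)


def _counts(seq: str) -> Counter:
    return Counter(c for c in seq if c in _STD)


def protparam_indices(p: ProteinRecord) -> dict[str, float]:
    """pI, mean residue pI, instability index/class, aliphatic index, GRAVY.

    Requires at least one standard residue after dropping ambiguity codes.
    """
    clean = p.cleaned()
    if not clean:
        raise ValueError(f"record {p.id!r} has no standard residues")
    pa = ProteinAnalysis(clean)
    counts = _counts(clean)
    n = len(clean)
    mole_percent = {aa: 100.0 * counts.get(aa, 0) / n for aa in STANDARD_AA}
    aliphatic_index = sum(
        coeff * mole_percent[aa] for aa, coeff in ALIPHATIC_INDEX_COEFF.items()
    )
    instability = pa.instability_index()
    return {
        "pI": pa.isoelectric_point(),
        "pI_avg": sum(RESIDUE_PI[c] for c in clean) / n,
        "instability_index": instability,
        "instability_class": 1.0 if instability > INSTABILITY_THRESHOLD else 0.0,
        "aliphatic_index": aliphatic_index,
        "gravy": pa.gravy(),
    }


def category_features(p: ProteinRecord) -> dict[str, float]:
    """Counts and fractions for the residue categories, charge and sulfur."""
    counts = _counts(p.sequence)
    L = p.length
    out: dict[str, float] = {}
    for name, members in CATEGORY_SETS.items():
        c = sum(counts.get(aa, 0) for aa in members)
        out[f"c_{name}"] = float(c)
        out[f"x_{name}"] = c / L
    net = out["c_positive"] - out["c_negative"]
    out["c_net_charge"] = net
    out["x_net_charge"] = net / L
    out["c_sulfur"] = float(sum(counts.get(aa, 0) for aa in SULFUR_AA))
    n_std = sum(counts.values())
    out["asa_max_mean"] = (
        sum(MAX_ASA[aa] * k for aa, k in counts.items()) / n_std if n_std else 0.0
    )
    return out


def compute_features(
    p: ProteinRecord,
    external: Mapping[str, float] | None = None,
    catalogue: FeatureCatalogue | None = None,
) -> dict[str, float]:
    """Compute the full catalogue for one record.

    All native entries are filled; external entries are taken from the
    ``external`` mapping when given, otherwise set to NaN.  ``external``
    may only name catalogue entries marked external.
    """
    cat = catalogue or feature_catalogue()
    L = p.length
    counts = _counts(p.sequence)
    values: dict[str, float] = {"length": float(L)}

    for aa in AA_SORTED:
        c = counts.get(aa, 0)
        values[f"c_{aa}"] = float(c)
        values[f"x_{aa}"] = c / L

    dipep = Counter(
        p.sequence[i : i + 2]
        for i in range(L - 1)
        if p.sequence[i] in _STD and p.sequence[i + 1] in _STD
    )
    denom = L - 1 if L > 1 else 1  # length-1 sequences: all dipeptide features 0
    for dp in DIPEPTIDES:
        c = dipep.get(dp, 0)
        values[f"c_{dp}"] = float(c)
        values[f"x_{dp}"] = c / denom

    values.update(category_features(p))
    values.update(protparam_indices(p))

    ext_names = set(cat.external_names)
    if external:
        unknown = set(external) - ext_names
        if unknown:
            raise ValueError(f"unknown external feature names: {sorted(unknown)}")
    for name in ext_names:
        values[name] = float(external[name]) if external and name in external else float("nan")

    return {name: values[name] for name in cat.names}


def feature_matrix(
    records: Iterable[ProteinRecord],
    external: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Feature DataFrame: one row per record, columns in catalogue order."""
    cat = feature_catalogue()
    rows = {}
    for rec in records:
        ext = external.get(rec.id) if external else None
        rows[rec.id] = compute_features(rec, external=ext, catalogue=cat)
    return pd.DataFrame.from_dict(rows, orient="index", columns=cat.names)


def write_feature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """TSV export; missing external values become empty cells."""
    df.to_csv(path, sep="\t", index_label="id", na_rep="")


class ProteinFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer mapping protein records to feature rows.

    Parameters
    ----------
    subset : "native", "all", or an explicit list of feature names.
        Columns to emit; the default emits the 871 natively computable
        features so the output contains no missing values.
    """

    def __init__(self, subset: str | list[str] = "native"):
        self.subset = subset

    def fit(self, X: Iterable[ProteinRecord], y=None) -> "ProteinFeaturizer":
        cat = feature_catalogue()
        if isinstance(self.subset, str):
            if self.subset == "native":
                names = cat.native_names
            elif self.subset == "all":
                names = cat.names
            else:
                raise ValueError(f"unknown subset {self.subset!r}")
        else:
            unknown = [n for n in self.subset if n not in cat]
            if unknown:
                raise ValueError(f"unknown feature names: {unknown}")
            names = list(self.subset)
        self.feature_names_out_ = names
        return self

    def transform(self, X: Iterable[ProteinRecord]) -> pd.DataFrame:
        if not hasattr(self, "feature_names_out_"):
            raise ValueError("ProteinFeaturizer is not fitted")
        return feature_matrix(X)[self.feature_names_out_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)
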