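"""Residue alphabets, category sets and per-residue reference tables.

Everything here is plain data so that alternative conventions (different
category memberships, a different max-ASA scale) can be swapped in without
touching the feature code.
"""

from __future__ import annotations

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Tolerated ambiguity / non-standard codes.  They count toward sequence
#: length but are excluded from every composition numerator.
AMBIGUOUS_AA = frozenset("XBZUJO")

#: Canonical residue ordering used when rendering the substitution matrix:
#: uncharged polar, nonpolar, charged.
SUBSTITUTION_ORDER = "SQNTCGAHMYFVLPIWDEKR"

# ---------------------------------------------------------------------------
# Residue category sets.  Small / tiny / aromatic follow the published
# catalogue; the remaining memberships are package conventions (the source
# catalogue names the categories without listing members).
# ---------------------------------------------------------------------------
CATEGORY_SETS: dict[str, frozenset[str]] = {
    "positive": frozenset("KR"),
    "negative": frozenset("DE"),
    "charged": frozenset("KRDE"),
    "small": frozenset("TD"),
    "tiny": frozenset("GASP"),
    "aromatic": frozenset("FHYW"),
    "aliphatic": frozenset("AILV"),
    "hydrophobic": frozenset("ACFILMVW"),
    "polar": frozenset("DEHKNQRSTY"),
    "hbond": frozenset("DEHKNQRSTWY"),  # side chains able to H-bond
}

#: Residues contributing sulfur atoms (one each).
SULFUR_AA = frozenset("CM")

#: Aliphatic-index coefficients: AI = x_A + 2.9*x_V + 3.9*(x_I + x_L),
#: with x in mole percent.
ALIPHATIC_INDEX_COEFF = {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}

#: Theoretical maximum solvent-accessible surface area per residue (A^2),
#: Gly-X-Gly tripeptide scale.  Editable; the mean-ASA feature averages
#: these values over the sequence.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Isoelectric points of the free amino acids, used for the mean
#: per-residue pI feature (pIa).
RESIDUE_PI: dict[str, float] = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07,
    "E": 3.22, "Q": 5.65, "G": 5.97, "H": 7.59, "I": 6.02,
    "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48, "P": 6.30,
    "S": 5.68, "T": 5.60, "W": 5.89, "Y": 5.66, "V": 5.96,
}

#: Instability-index threshold separating "stable" from "unstable".
INSTABILITY_THRESHOLD = 40.0
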