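"""Per-residue composition comparison between AP and NP ortholog members.

For each of the 20 residues the composition feature (``x_<res>``) is
compared across pairs with a two-sided unpaired two-sample t-test (Welch by
default) and a two-sided paired t-test.  The paired test is the more
meaningful of the two here since each AP protein has a designated NP
ortholog, which controls for protein-family composition effects.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .tables import SUBSTITUTION_ORDER

__all__ = ["CompositionComparison", "composition_tests", "write_composition_tsv"]


@dataclasses.dataclass(frozen=True)
class CompositionComparison:
    residue: str
    mean_ap: float
    sd_ap: float
    mean_np: float
    sd_np: float
    p_unpaired: float
    p_paired: float
    direction: str  # increased-in-AP | decreased-in-AP | ns
    degenerate: bool = False


def _paired_p(diff: np.ndarray) -> tuple[float, bool]:
    """Two-sided paired-t p-value with the degenerate-variance convention:
    all differences zero -> p = 1; constant non-zero shift -> p = 0."""
    if np.std(diff, ddof=1) == 0:
        return (1.0 if np.allclose(diff, 0) else 0.0), True
    return float(stats.ttest_rel(diff, np.zeros_like(diff))[1]), False


def composition_tests(
    pairs: Sequence[tuple[Mapping[str, float], Mapping[str, float]]],
    residues: str = SUBSTITUTION_ORDER,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> list[CompositionComparison]:
    """Compare AP vs NP composition for each residue.

    ``pairs`` holds (ap_features, np_features) mappings that contain the
    ``x_<residue>`` composition features.  Requires at least two pairs.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for t-tests")
    out = []
    for res in residues:
        key = f"x_{res}"
        ap = np.array([float(a[key]) for a, _ in pairs])
        np_ = np.array([float(b[key]) for _, b in pairs])
        if np.std(ap, ddof=1) == 0 and np.std(np_, ddof=1) == 0:
            p_unpaired = 1.0 if np.allclose(ap.mean(), np_.mean()) else 0.0
        else:
            p_unpaired = float(stats.ttest_ind(ap, np_, equal_var=equal_var)[1])
        p_paired, degenerate = _paired_p(ap - np_)
        if p_paired < alpha and ap.mean() > np_.mean():
            direction = "increased-in-AP"
        elif p_paired < alpha and ap.mean() < np_.mean():
            direction = "decreased-in-AP"
        else:
            direction = "ns"
        out.append(
            CompositionComparison(
                residue=res,
                mean_ap=float(ap.mean()),
                sd_ap=float(ap.std(ddof=1)),
                mean_np=float(np_.mean()),
                sd_np=float(np_.std(ddof=1)),
                p_unpaired=p_unpaired,
                p_paired=p_paired,
                direction=direction,
                degenerate=degenerate,
            )
        )
    return out


def write_composition_tsv(rows: Sequence[CompositionComparison], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "residue\tmean_ap\tsd_ap\tmean_np\tsd_np\tp_unpaired\tp_paired\tdirection\n"
        )
        for r in rows:
            fh.write(
                f"{r.residue}\t{r.mean_ap:.4f}\t{r.sd_ap:.4f}\t{r.mean_np:.4f}\t"
                f"{r.sd_np:.4f}\t{r.p_unpaired:.3g}\t{r.p_paired:.3g}\t{r.direction}\n"
            )
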