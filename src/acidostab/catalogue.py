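"""The 889-entry sequence feature catalogue.

Entries follow a deterministic, documented ordering: groups appear in the
order below, and within a group counts precede compositions and residues /
dipeptides follow alphabetical order.  871 entries are natively computable
from the bare sequence; the remaining 18 come from external structure
predictors (secondary structure, burial, disorder, surface accessibility)
and are only ever ingested from sidecar files.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Literal

from .tables import STANDARD_AA

__all__ = ["CatalogueEntry", "FeatureCatalogue", "feature_catalogue"]

AA_SORTED = sorted(STANDARD_AA)
DIPEPTIDES = ["".join(p) for p in itertools.product(AA_SORTED, repeat=2)]

GROUP_LENGTH = "length"
GROUP_AA = "amino acid counts and compositions"
GROUP_DIPEPTIDE = "dipeptide counts and compositions"
GROUP_CHARGE = "charged residues and net charge"
GROUP_CATEGORY = "small/tiny/aromatic/aliphatic/hydrophobic/polar residues"
GROUP_HBOND = "side-chain hydrogen-bond capable residues"
GROUP_SULFUR = "sulfur atoms"
GROUP_ASA = "mean maximum solvent-accessible surface area"
GROUP_PI = "isoelectric point"
GROUP_INSTABILITY = "instability index and class"
GROUP_ALIPHATIC_INDEX = "aliphatic index"
GROUP_GRAVY = "GRAVY hydropathy"
GROUP_SECONDARY = "predicted secondary structure"
GROUP_BURIAL = "predicted buried/exposed residues"
GROUP_DISORDER = "predicted disordered segments"
GROUP_RSA = "mean relative surface accessibility"
GROUP_ZFIT = "mean Z-fit of the RSA prediction"


@dataclasses.dataclass(frozen=True)
class CatalogueEntry:
    name: str
    group: str
    computable: Literal["native", "external"]


class FeatureCatalogue:
    """Ordered list of catalogue entries with name/group lookups."""

    def __init__(self, entries: list[CatalogueEntry]):
        self.entries = entries
        self._by_name = {e.name: e for e in entries}
        if len(self._by_name) != len(entries):
            raise ValueError("duplicate feature names in catalogue")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def subset(self, computable: str) -> list[str]:
        return [e.name for e in self.entries if e.computable == computable]

    @property
    def native_names(self) -> list[str]:
        return self.subset("native")

    @property
    def external_names(self) -> list[str]:
        return self.subset("external")

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for e in self.entries:
            sizes[e.group] = sizes.get(e.group, 0) + 1
        return sizes


def _native(name: str, group: str) -> CatalogueEntry:
    return CatalogueEntry(name, group, "native")


def _external(name: str, group: str) -> CatalogueEntry:
    return CatalogueEntry(name, group, "external")


def feature_catalogue() -> FeatureCatalogue:
    """Build the canonical 889-entry catalogue (871 native, 18 external)."""
    entries: list[CatalogueEntry] = [_native("length", GROUP_LENGTH)]

    for aa in AA_SORTED:
        entries.append(_native(f"c_{aa}", GROUP_AA))
    for aa in AA_SORTED:
        entries.append(_native(f"x_{aa}", GROUP_AA))

    for dp in DIPEPTIDES:
        entries.append(_native(f"c_{dp}", GROUP_DIPEPTIDE))
    for dp in DIPEPTIDES:
        entries.append(_native(f"x_{dp}", GROUP_DIPEPTIDE))

    for name in ("positive", "negative", "charged"):
        entries.append(_native(f"c_{name}", GROUP_CHARGE))
        entries.append(_native(f"x_{name}", GROUP_CHARGE))
    entries.append(_native("c_net_charge", GROUP_CHARGE))
    entries.append(_native("x_net_charge", GROUP_CHARGE))

    for name in ("small", "tiny", "aromatic", "aliphatic", "hydrophobic", "polar"):
        entries.append(_native(f"c_{name}", GROUP_CATEGORY))
        entries.append(_native(f"x_{name}", GROUP_CATEGORY))

    entries.append(_native("c_hbond", GROUP_HBOND))
    entries.append(_native("x_hbond", GROUP_HBOND))
    entries.append(_native("c_sulfur", GROUP_SULFUR))
    entries.append(_native("asa_max_mean", GROUP_ASA))
    entries.append(_native("pI", GROUP_PI))
    entries.append(_native("pI_avg", GROUP_PI))
    entries.append(_native("instability_index", GROUP_INSTABILITY))
    entries.append(_native("instability_class", GROUP_INSTABILITY))
    entries.append(_native("aliphatic_index", GROUP_ALIPHATIC_INDEX))
    entries.append(_native("gravy", GROUP_GRAVY))

    for name in ("helix", "sheet", "coil"):
        entries.append(_external(f"c_ss_{name}", GROUP_SECONDARY))
        entries.append(_external(f"x_ss_{name}", GROUP_SECONDARY))
    for name in ("buried", "exposed"):
        entries.append(_external(f"c_{name}", GROUP_BURIAL))
        entries.append(_external(f"x_{name}", GROUP_BURIAL))
    for name in ("coils", "rem465", "hotloops"):
        entries.append(_external(f"len_{name}", GROUP_DISORDER))
        entries.append(_external(f"x_{name}", GROUP_DISORDER))
    entries.append(_external("rsa_mean", GROUP_RSA))
    entries.append(_external("zfit_mean", GROUP_ZFIT))

    return FeatureCatalogue(entries)
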