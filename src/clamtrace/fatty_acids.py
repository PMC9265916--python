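"""Fatty-acid profile feature engineering.

The pipeline works with the relative composition of 15 phospholipid fatty
acids (five saturated, five monounsaturated, five polyunsaturated), expressed
as percent of total identified FAs.  Ecological interpretation rests on
source-biomarker sums — diatom (20:5n-3 + 16:1n-7), flagellate
(18:1n-9 + 22:6n-3) and bacterial (17:0 + 18:1n-7) FAs — and on the DHA/EPA
and PUFA/SFA ratios, which index dinoflagellate- vs diatom-dominated diets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "SFA_NAMES",
    "MUFA_NAMES",
    "PUFA_NAMES",
    "FA_NAMES",
    "FA_CLASS_MAP",
    "CSIA_FA_NAMES",
    "FAProfile",
    "relative_composition",
    "biomarker_summary",
]

SFA_NAMES = ("14:0", "15:0", "16:0", "17:0", "18:0")
MUFA_NAMES = ("16:1n-7", "18:1n-7", "18:1n-9", "20:1n-7", "20:1n-9")
PUFA_NAMES = ("18:2n-6", "18:3n-3", "20:4n-6", "20:5n-3", "22:6n-3")
#: The fixed 15-FA panel, in reporting order.
FA_NAMES = SFA_NAMES + MUFA_NAMES + PUFA_NAMES

FA_CLASS_MAP: dict[str, str] = {
    **{n: "SFA" for n in SFA_NAMES},
    **{n: "MUFA" for n in MUFA_NAMES},
    **{n: "PUFA" for n in PUFA_NAMES},
}

#: FAs whose individual δ13C is resolvable by GC-C-IRMS (two SFAs, four
#: MUFAs; PUFA peaks overlap and are not measured).
CSIA_FA_NAMES = ("16:0", "18:0", "18:1n-7", "18:1n-9", "20:1n-7", "20:1n-9")

_BIOMARKERS = {
    "diatom": ("20:5n-3", "16:1n-7"),
    "flagellate": ("18:1n-9", "22:6n-3"),
    "bacteria": ("17:0", "18:1n-7"),
}


@dataclass
class FAProfile:
    """Relative FA composition: percent of total identified FAs.

    ``abundances`` maps FA name → relative % and must sum to 100 (±1e-6);
    ``class_map`` assigns each FA to SFA/MUFA/PUFA.
    """

    abundances: dict[str, float]
    class_map: dict[str, str] = field(default_factory=lambda: dict(FA_CLASS_MAP))

    def __post_init__(self) -> None:
        for name, pct in self.abundances.items():
            if pct < 0:
                raise ValueError(f"negative abundance for {name}: {pct}")
            if name not in self.class_map:
                raise ValueError(f"FA {name!r} missing from class_map")
        total = sum(self.abundances.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"abundances must sum to 100, got {total!r}")

    def class_total(self, fa_class: str) -> float:
        """Summed relative % of one class (SFA, MUFA or PUFA)."""
        return sum(
            pct for name, pct in self.abundances.items() if self.class_map[name] == fa_class
        )


def relative_composition(raw: Mapping[str, float]) -> FAProfile:
    """Normalize raw FA quantities (areas, concentrations) to percent.

    Each entry becomes ``100 × raw_i / Σ raw``; the result is
    scale-invariant, so peak areas and absolute concentrations give the same
    profile.
    """
    if not raw:
        raise ValueError("raw composition is empty")
    for name, value in raw.items():
        if value < 0:
            raise ValueError(f"negative quantity for {name}: {value}")
    total = float(sum(raw.values()))
    if total <= 0:
        raise ValueError("all-zero FA quantities: cannot normalize")
    return FAProfile(abundances={name: 100.0 * v / total for name, v in raw.items()})


def biomarker_summary(profile: FAProfile) -> dict[str, float]:
    """Source-biomarker sums and diet ratios for one profile.

    Returns ``diatom_pct``, ``flagellate_pct``, ``bacteria_pct`` (each the
    sum of its two marker FAs), ``dha_epa_ratio`` (22:6n-3 / 20:5n-3) and
    ``pufa_sfa_ratio`` (ΣPUFA / ΣSFA).  A zero EPA yields NaN for DHA/EPA
    rather than raising, so summaries over many samples stay total.
    """
    abundances = profile.abundances
    needed = {fa for pair in _BIOMARKERS.values() for fa in pair}
    missing = sorted(needed - set(abundances))
    if missing:
        raise KeyError(f"profile is missing biomarker FA(s): {', '.join(missing)}")

    out = {
        f"{source}_pct": sum(abundances[fa] for fa in pair)
        for source, pair in _BIOMARKERS.items()
    }
    epa = abundances["20:5n-3"]
    dha = abundances["22:6n-3"]
    out["dha_epa_ratio"] = dha / epa if epa > 0 else math.nan
    sfa = profile.class_total("SFA")
    out["pufa_sfa_ratio"] = profile.class_total("PUFA") / sfa if sfa > 0 else math.nan
    return out
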