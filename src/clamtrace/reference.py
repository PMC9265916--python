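"""Bundled reference outcomes of the Manila-clam origin study.

These are the published cross-validated classification counts the toolkit's
report arithmetic is validated against: the four-province confusion
matrices for each assay tier, and the three-country stepwise correct-count
summary.  They are data (inputs), not computed results — the per-sample
measurements behind them were never deposited, so the counts themselves
cannot be regenerated; what the package can and does reproduce exactly is
every percentage derived from them.
"""

from __future__ import annotations

import numpy as np

from ._round import percent_2dp_trunc
from .lda import ConfusionMatrix

__all__ = [
    "reference_confusion",
    "REFERENCE_CONFUSIONS",
    "STEPWISE_COUNTRY_COUNTS",
    "stepwise_total_pct",
]

_PROVINCES = ["CC", "GN", "JB", "JN"]

#: Published LOOCV confusion counts (rows = true, cols = predicted) for the
#: four Korean provinces under each assay tier.
REFERENCE_CONFUSIONS: dict[str, ConfusionMatrix] = {
    "dual_isotope": ConfusionMatrix(
        classes=list(_PROVINCES),
        counts=np.array([
            [21, 0, 3, 1],
            [0, 19, 2, 5],
            [0, 2, 15, 8],
            [0, 0, 12, 14],
        ]),
    ),
    "fa_profile": ConfusionMatrix(
        classes=list(_PROVINCES),
        counts=np.array([
            [15, 0, 0, 0],
            [0, 12, 0, 0],
            [0, 0, 12, 0],
            [0, 0, 0, 12],
        ]),
    ),
    "csia_fa": ConfusionMatrix(
        classes=list(_PROVINCES),
        counts=np.array([
            [14, 0, 1, 0],
            [0, 12, 0, 0],
            [1, 0, 7, 4],
            [0, 0, 0, 12],
        ]),
    ),
}

#: Published three-country stepwise summary: per country and tier,
#: (cohort size, LOOCV-correct count).
STEPWISE_COUNTRY_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "dual_isotope": {"CHN": (15, 4), "KOR": (102, 98), "NK": (16, 1)},
    "fa_profile": {"CHN": (3, 3), "KOR": (51, 51), "NK": (3, 2)},
    "csia_fa": {"CHN": (3, 3), "KOR": (51, 51), "NK": (3, 3)},
}


def reference_confusion(name: str) -> ConfusionMatrix:
    """One of the bundled reference confusion matrices by tier name."""
    try:
        cm = REFERENCE_CONFUSIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown reference confusion {name!r}; available: {sorted(REFERENCE_CONFUSIONS)}"
        ) from None
    return ConfusionMatrix(classes=list(cm.classes), counts=cm.counts.copy())


def stepwise_total_pct(tier_name: str) -> float:
    """Pooled cross-validated % for one tier of the three-country summary."""
    counts = STEPWISE_COUNTRY_COUNTS[tier_name]
    total = sum(n for n, _ in counts.values())
    correct = sum(c for _, c in counts.values())
    return percent_2dp_trunc(correct, total)
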