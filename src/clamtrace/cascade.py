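"""Tiered (stepwise) origin authentication.

Samples are first classified with cheap bulk δ13C/δ15N; those not
authenticated are escalated to richer, costlier assays — the 15-FA relative
profile, then compound-specific δ13C of individual FAs.  Each tier is a
min–max-scaled LDA evaluated by leave-one-out cross-validation on its
cohort; routing decides which samples a later tier must measure.

Two routing policies are provided:

- ``"sample_misclassified"`` — escalate exactly the samples the tier's
  LOOCV got wrong (the strict reading of "unclassified samples");
- ``"site_rate_below"`` — escalate every sample of any class whose
  per-class prediction rate falls below a threshold τ (default 100%), then
  optionally keep only the first ``subsample_k`` samples per site.  k = 3
  reproduces the triplicate escalation design: 17 sites × 3 = 51 clams.

Two evaluation modes:

- ``"nested"`` — each tier re-routes; only still-unauthenticated samples
  reach the next tier;
- ``"parallel"`` — routing happens once after tier 1 and every later tier
  evaluates that same fixed cohort, the reporting arithmetic used when the
  escalated subsample is assayed with each richer method independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .fatty_acids import CSIA_FA_NAMES, FA_NAMES
from .lda import ConfusionMatrix, LoocvResult, loocv

__all__ = [
    "CascadeTier",
    "TierOutcome",
    "CascadeResult",
    "default_tiers",
    "route_unauthenticated",
    "run_cascade",
    "prediction_rates",
    "stepwise_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class CascadeTier:
    """One assay tier: its feature block and LDA settings."""

    name: str
    feature_names: list[str]
    priors_mode: str = "proportional"
    scaling_policy: str = "prefit"

    def __post_init__(self) -> None:
        if not self.feature_names:
            raise ValueError(f"tier {self.name!r}: feature_names must be non-empty")


@dataclass
class TierOutcome:
    """LOOCV result of one tier on its evaluated cohort."""

    tier: CascadeTier
    cohort_ids: list[str]
    loocv: LoocvResult
    per_class_pct: dict
    overall_pct: float


@dataclass
class CascadeResult:
    """Full cascade outcome: per-tier confusions plus the routing ledger.

    The ledger has one row per input sample: the tier at which its final
    label was assigned, a status flag (``authenticated`` — correct tier
    prediction, not escalated; ``unescalated`` — its class was flagged but
    the sample was not in the escalated subsample; ``final_tier`` — label
    assigned at the cascade's last evaluated tier), and the final label.
    """

    tiers: list[TierOutcome] = field(default_factory=list)
    ledger: pd.DataFrame | None = None
    label_column: str = "region"

    def final_labels(self) -> dict[str, str]:
        return dict(zip(self.ledger["sample_id"], self.ledger["final_label"]))


def default_tiers() -> list[CascadeTier]:
    """The canonical three-tier protocol.

    Tier 1: bulk δ13C/δ15N (cheap, every sample); tier 2: the 15-FA
    relative profile; tier 3: compound-specific δ13C of the six
    GC-IRMS-resolvable FAs.
    """
    from .synthetic import CSIA_PREFIX

    return [
        CascadeTier(name="dual_isotope", feature_names=["d13C", "d15N"]),
        CascadeTier(name="fa_profile", feature_names=list(FA_NAMES)),
        CascadeTier(
            name="csia_fa",
            feature_names=[f"{CSIA_PREFIX}{fa}" for fa in CSIA_FA_NAMES],
        ),
    ]


def prediction_rates(cm: ConfusionMatrix) -> dict:
    """Report-style rates from a confusion matrix.

    Per-class % = 100 × diagonal / row sum, half-up to one decimal;
    overall % = 100 × trace / total, truncated to two decimals.
    """
    return {"per_class": cm.per_class_rates(), "overall": cm.overall_rate()}


def _evaluation_frame(cohort: pd.DataFrame, result: LoocvResult, label_column: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": cohort["sample_id"].to_numpy(),
            "site_id": cohort["site_id"].to_numpy(),
            "label": result.true_labels,
            "predicted": result.predicted_labels,
        }
    )


def route_unauthenticated(
    evaluation: pd.DataFrame,
    policy: str = "site_rate_below",
    tau: float = 100.0,
    subsample_k: int | None = None,
) -> list[str]:
    """Select sample_ids to escalate to the next tier.

    ``evaluation`` needs columns sample_id, site_id, label, predicted (one
    row per LOOCV-evaluated sample).  See the module docstring for the two
    policies.  Returns sample ids sorted by (site_id, sample_id); with
    ``subsample_k`` set, at most k per site (first k by sample_id).
    """
    required = {"sample_id", "site_id", "label", "predicted"}
    if not required.issubset(evaluation.columns):
        raise ValueError(f"evaluation frame needs columns {sorted(required)}")

    if policy == "sample_misclassified":
        routed = evaluation.loc[evaluation["label"] != evaluation["predicted"]]
    elif policy == "site_rate_below":
        if not (0 < tau <= 100):
            raise ValueError(f"tau must be in (0, 100], got {tau}")
        correct = evaluation["label"] == evaluation["predicted"]
        rate = 100.0 * correct.groupby(evaluation["label"]).mean()
        flagged = set(rate.index[rate < tau])
        routed = evaluation.loc[evaluation["label"].isin(flagged)]
    else:
        raise ValueError(f"unknown routing policy {policy!r}")

    routed = routed.sort_values(["site_id", "sample_id"])
    if subsample_k is not None:
        if subsample_k < 1:
            raise ValueError("subsample_k must be >= 1")
        for site, group in routed.groupby("site_id"):
            if len(group) < subsample_k:
                logger.info(
                    "site %s routed %d sample(s), fewer than k=%d; taking all",
                    site, len(group), subsample_k,
                )
        routed = routed.groupby("site_id", group_keys=False).head(subsample_k)
    return routed["sample_id"].tolist()


def _check_features(cohort: pd.DataFrame, tier: CascadeTier) -> None:
    missing_cols = [c for c in tier.feature_names if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"tier {tier.name!r}: dataset lacks feature(s) {missing_cols}")
    block = cohort[tier.feature_names]
    if block.isna().any().any():
        bad = block.isna().any(axis=1)
        sample = cohort.loc[bad, "sample_id"].iloc[0]
        feature = block.columns[block.loc[bad].isna().any(axis=0)][0]
        raise ValueError(
            f"tier {tier.name!r}: routed sample {sample!r} is missing feature {feature!r}"
        )


def run_cascade(
    samples: pd.DataFrame,
    tiers: list[CascadeTier],
    label_column: str = "region",
    policy: str = "site_rate_below",
    tau: float = 100.0,
    subsample_k: int | None = 3,
    mode: str = "nested",
) -> CascadeResult:
    """Run the stepwise protocol over an ordered list of tiers.

    Tier 1 is evaluated on all samples; unauthenticated material is routed
    onward per ``policy``/``tau``/``subsample_k``.  Samples keep the LOOCV
    prediction of the tier at which they stop; the last tier's predictions
    are final for everything that reaches it.  Every input sample receives
    exactly one final label.
    """
    if not tiers:
        raise ValueError("need at least one tier")
    if mode not in ("nested", "parallel"):
        raise ValueError(f"unknown mode {mode!r}")
    if label_column not in samples.columns:
        raise ValueError(f"dataset lacks label column {label_column!r}")

    ledger_rows: dict[str, dict] = {}
    outcomes: list[TierOutcome] = []
    cohort = samples.reset_index(drop=True)

    for t, tier in enumerate(tiers):
        _check_features(cohort, tier)
        result = loocv(
            cohort[tier.feature_names].to_numpy(dtype=float),
            cohort[label_column].to_numpy(),
            priors_mode=tier.priors_mode,
            scaling_policy=tier.scaling_policy,
        )
        rates = prediction_rates(result.confusion)
        outcomes.append(
            TierOutcome(
                tier=tier,
                cohort_ids=cohort["sample_id"].tolist(),
                loocv=result,
                per_class_pct=rates["per_class"],
                overall_pct=rates["overall"],
            )
        )
        evaluation = _evaluation_frame(cohort, result, label_column)
        is_last = t == len(tiers) - 1
        route_now = (t == 0) if mode == "parallel" else True

        if is_last or not route_now:
            routed_ids: list[str] = [] if is_last else cohort["sample_id"].tolist()
            if is_last:
                for _, row in evaluation.iterrows():
                    ledger_rows[row["sample_id"]] = {
                        "sample_id": row["sample_id"],
                        "site_id": row["site_id"],
                        label_column: row["label"],
                        "final_tier": tier.name,
                        "status": "final_tier",
                        "final_label": row["predicted"],
                    }
                break
            continue

        routed_full = set(
            route_unauthenticated(evaluation, policy=policy, tau=tau, subsample_k=None)
        )
        routed_ids = route_unauthenticated(
            evaluation, policy=policy, tau=tau, subsample_k=subsample_k
        )
        routed_set = set(routed_ids)
        for _, row in evaluation.iterrows():
            sid = row["sample_id"]
            if sid in routed_set:
                continue
            status = "unescalated" if sid in routed_full else "authenticated"
            ledger_rows[sid] = {
                "sample_id": sid,
                "site_id": row["site_id"],
                label_column: row["label"],
                "final_tier": tier.name,
                "status": status,
                "final_label": row["predicted"],
            }
        if not routed_ids:
            logger.info("tier %s authenticated everything; short-circuiting", tier.name)
            break
        cohort = cohort.loc[cohort["sample_id"].isin(routed_set)].reset_index(drop=True)

    ledger = pd.DataFrame(ledger_rows.values()).reset_index(drop=True)
    assert len(ledger) == len(samples), "ledger must cover every input exactly once"
    return CascadeResult(tiers=outcomes, ledger=ledger, label_column=label_column)


def stepwise_summary(result: CascadeResult) -> pd.DataFrame:
    """Report table: per class and tier, 'cohort_n (loocv-correct_n)'.

    Final row gives each tier's pooled cross-validated percentage
    (truncated to two decimals).
    """
    classes: list = []
    for outcome in result.tiers:
        for cls in outcome.loocv.confusion.classes:
            if cls not in classes:
                classes.append(cls)
    table: dict[str, list[str]] = {}
    for outcome in result.tiers:
        cm = outcome.loocv.confusion
        col = []
        for cls in classes:
            if cls in cm.classes:
                i = cm.classes.index(cls)
                col.append(f"{int(cm.counts[i].sum())} ({int(cm.counts[i, i])})")
            else:
                col.append("-")
        col.append(f"{outcome.overall_pct:.2f}%")
        table[outcome.tier.name] = col
    frame = pd.DataFrame(table, index=classes + ["Total (Cross-Val)%"])
    frame.index.name = result.label_column
    return frame
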