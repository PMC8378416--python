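"""Treatment-benefit evaluation: matched pairs, c-for-benefit, group calibration.

Predicted benefit is the per-patient difference in the probability of
functional independence (mRS 0-2) with vs without EVT. Its observable
counterpart comes from pairs of patients matched on predicted benefit but
discordant for treatment: the pair's observed benefit is the treated
member's good-outcome indicator minus the control member's (in {-1, 0, 1}).
The c-for-benefit is the concordance between predicted and observed benefit
across such pairs. Group-level calibration compares the mean predicted
benefit with the observed arm difference in P(mRS 0-2) within quintiles of
predicted benefit or within the low/moderate/high classes cut at 1% and 10%.

In the all-treated registry setting the "arms" are successful vs
unsuccessful reperfusion (eTICI >= 2b); the resulting contrast is a
surrogate for treatment benefit, never a causal estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import FittedOrdinalModel
from .validation import UndefinedMetricError, concordance_index

__all__ = [
    "BENEFIT_CLASS_CUTS",
    "BENEFIT_CLASS_LABELS",
    "MatchedPairs",
    "BenefitGroupTable",
    "match_by_predicted_benefit",
    "c_for_benefit",
    "benefit_group_calibration",
    "registry_surrogate_benefit",
]

BENEFIT_CLASS_CUTS = (0.01, 0.10)
BENEFIT_CLASS_LABELS = ("low", "moderate", "high")


@dataclass
class MatchedPairs:
    """Treated/control pairs matched on predicted benefit.

    ``table`` columns: treated_id, control_id, treated_benefit,
    control_benefit, pair_predicted (mean of the two members' predicted
    benefits), pair_observed (treated good-outcome indicator minus control's).
    """

    table: pd.DataFrame
    arm_col: str = "evt"
    n_dropped: int = 0
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _benefit_frame(
    cohort: pd.DataFrame, model: Optional[FittedOrdinalModel], benefit_col: str
) -> pd.Series:
    if model is not None:
        return pd.Series(
            model.predicted_benefit(cohort)["benefit"].to_numpy(), index=cohort.index
        )
    if benefit_col not in cohort.columns:
        raise ValueError(f"no model given and column {benefit_col!r} absent")
    return cohort[benefit_col]


def match_by_predicted_benefit(
    cohort: pd.DataFrame,
    seed: int = 0,
    *,
    model: Optional[FittedOrdinalModel] = None,
    benefit_col: str = "benefit",
    arm_col: str = "evt",
    outcome_col: str = "mrs_90d",
    method: str = "rank",
) -> MatchedPairs:
    """Pair each treated patient with a control of similar predicted benefit.

    The larger arm is randomly down-sampled (seeded) to the size of the
    smaller; both arms are then sorted by predicted benefit and paired
    rank-by-rank (``method="rank"``, default, deterministic) or by greedy
    nearest-neighbor on predicted benefit (``method="nearest"``, for
    sensitivity analysis). Every retained patient appears in exactly one pair.
    """
    if method not in ("rank", "nearest"):
        raise ValueError(f"unknown matching method {method!r}")
    benefit = _benefit_frame(cohort, model, benefit_col)
    arm = cohort[arm_col].to_numpy().astype(int)
    y_good = (cohort[outcome_col].to_numpy().astype(int) <= 2).astype(int)
    ids = cohort.index.to_numpy()

    idx_t = np.flatnonzero(arm == 1)
    idx_c = np.flatnonzero(arm == 0)
    if len(idx_t) == 0 or len(idx_c) == 0:
        raise ValueError(f"both {arm_col} arms must be nonempty")

    rng = np.random.default_rng(seed)
    m = min(len(idx_t), len(idx_c))
    n_dropped = abs(len(idx_t) - len(idx_c))
    if len(idx_t) > m:
        idx_t = idx_t[np.sort(rng.choice(len(idx_t), size=m, replace=False))]
    elif len(idx_c) > m:
        idx_c = idx_c[np.sort(rng.choice(len(idx_c), size=m, replace=False))]

    b = benefit.to_numpy()

    def sorted_by_benefit(idx: np.ndarray) -> np.ndarray:
        return idx[np.lexsort((idx, b[idx]))]  # ties broken by position: deterministic

    st = sorted_by_benefit(idx_t)
    sc = sorted_by_benefit(idx_c)
    if method == "nearest":
        # greedy: repeatedly take the globally closest remaining pair
        order_t, order_c = list(st), list(sc)
        pairs_t, pairs_c = [], []
        while order_t:
            # with both lists sorted, scan current heads' best partners
            best = None
            for ti, t in enumerate(order_t):
                pos = np.searchsorted([b[c] for c in order_c], b[t])
                for cj in (pos - 1, pos):
                    if 0 <= cj < len(order_c):
                        d = abs(b[t] - b[order_c[cj]])
                        if best is None or d < best[0]:
                            best = (d, ti, cj)
            _, ti, cj = best
            pairs_t.append(order_t.pop(ti))
            pairs_c.append(order_c.pop(cj))
        st, sc = np.array(pairs_t), np.array(pairs_c)

    table = pd.DataFrame(
        {
            "treated_id": ids[st],
            "control_id": ids[sc],
            "treated_benefit": b[st],
            "control_benefit": b[sc],
            "pair_predicted": (b[st] + b[sc]) / 2.0,
            "pair_observed": y_good[st] - y_good[sc],
        }
    )
    return MatchedPairs(table=table, arm_col=arm_col, n_dropped=n_dropped, seed=seed)


def c_for_benefit(pairs: MatchedPairs | pd.DataFrame) -> float:
    """Concordance between predicted and observed benefit over pairs-of-pairs.

    The probability that of two randomly chosen matched pairs with different
    observed benefit, the pair with the greater observed benefit also has the
    higher predicted benefit; predicted ties count 0.5, observed ties are
    excluded from numerator and denominator.
    """
    table = pairs.table if isinstance(pairs, MatchedPairs) else pairs
    if len(table) < 2:
        raise UndefinedMetricError("c-for-benefit needs at least two pairs")
    obs = table["pair_observed"].to_numpy().astype(int)
    pred = table["pair_predicted"].to_numpy().astype(float)
    if np.unique(obs).size < 2:
        raise UndefinedMetricError(
            "c-for-benefit undefined: all pairs share one observed benefit"
        )
    return concordance_index(pred, obs, larger_outcome_is_better=True)


@dataclass
class BenefitGroupTable:
    """Per-group predicted vs observed benefit.

    ``table`` columns: group, lower, upper, n_treated, n_control,
    mean_predicted_benefit, observed_benefit (arm difference in the
    proportion of mRS 0-2; NaN and flagged when an arm is empty).
    """

    table: pd.DataFrame
    grouping: str
    surrogate: bool = False
    flagged_groups: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _group_table(
    benefit: np.ndarray,
    arm: np.ndarray,
    y_good: np.ndarray,
    grouping: str,
) -> tuple[pd.DataFrame, list]:
    if grouping == "quintiles":
        qs = np.quantile(benefit, np.linspace(0, 1, 6))
        edges = np.unique(qs)
        if edges.size < 2:  # all benefits equal: one group
            edges = np.array([benefit.min() - 1e-12, benefit.max() + 1e-12])
        idx = np.clip(np.searchsorted(edges, benefit, side="right") - 1, 0, edges.size - 2)
        labels = [f"Q{i + 1}" for i in range(edges.size - 1)]
        lowers, uppers = edges[:-1], edges[1:]
    elif grouping == "classes":
        cuts = np.array(BENEFIT_CLASS_CUTS)
        idx = np.searchsorted(cuts, benefit, side="left")
        labels = list(BENEFIT_CLASS_LABELS)
        lowers = np.array([-np.inf, cuts[0], cuts[1]])
        uppers = np.array([cuts[0], cuts[1], np.inf])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    flagged = []
    for gi, label in enumerate(labels):
        mask = idx == gi
        n_t = int(np.sum(mask & (arm == 1)))
        n_c = int(np.sum(mask & (arm == 0)))
        mean_pred = float(benefit[mask].mean()) if mask.any() else np.nan
        if n_t > 0 and n_c > 0:
            observed = float(y_good[mask & (arm == 1)].mean() - y_good[mask & (arm == 0)].mean())
        else:
            observed = np.nan
            if mask.any():
                flagged.append(label)
        rows.append(
            {
                "group": label,
                "lower": float(lowers[gi]),
                "upper": float(uppers[gi]),
                "n_treated": n_t,
                "n_control": n_c,
                "mean_predicted_benefit": mean_pred,
                "observed_benefit": observed,
            }
        )
    return pd.DataFrame(rows), flagged


def benefit_group_calibration(
    cohort: pd.DataFrame,
    model: Optional[FittedOrdinalModel] = None,
    grouping: str = "quintiles",
    *,
    benefit_col: str = "benefit",
    arm_col: str = "evt",
    outcome_col: str = "mrs_90d",
) -> BenefitGroupTable:
    """Predicted vs observed treatment benefit by predicted-benefit group.

    Quintile bounds come from the cohort's own predicted-benefit
    distribution; the three-class grouping cuts at exactly 1% and 10%
    predicted benefit. Groups with an empty arm are flagged and their
    observed benefit reported as undefined (NaN).
    """
    benefit = _benefit_frame(cohort, model, benefit_col).to_numpy()
    arm = cohort[arm_col].to_numpy().astype(int)
    y_good = (cohort[outcome_col].to_numpy().astype(int) <= 2).astype(int)
    table, flagged = _group_table(benefit, arm, y_good, grouping)
    return BenefitGroupTable(table=table, grouping=grouping, flagged_groups=flagged)


def registry_surrogate_benefit(
    cohort: pd.DataFrame,
    model: Optional[FittedOrdinalModel] = None,
    grouping: str = "classes",
    *,
    benefit_col: str = "benefit",
    outcome_col: str = "mrs_90d",
) -> BenefitGroupTable:
    """Reperfusion-surrogate contrast in an all-treated registry.

    Identical to :func:`benefit_group_calibration` but the "arms" are
    successful (eTICI >= 2b) vs unsuccessful reperfusion. The output is
    labeled a surrogate contrast: reperfusion is not randomized, so this is
    not a causal benefit estimate.
    """
    if "etici_success" not in cohort.columns or cohort["etici_success"].isna().any():
        raise ValueError("registry cohort must have a complete etici_success column")
    if "evt" in cohort.columns and not (cohort["evt"].to_numpy().astype(int) == 1).all():
        raise ValueError("registry cohorts must be all-treated (evt == 1)")
    out = benefit_group_calibration(
        cohort,
        model,
        grouping,
        benefit_col=benefit_col,
        arm_col="etici_success",
        outcome_col=outcome_col,
    )
    out.surrogate = True
    return out
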