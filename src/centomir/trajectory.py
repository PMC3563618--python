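"""Cross-sectional age-trajectory classification of miRNA expression.

Given expression values for ordered age bins (the oldest bin being the
exceptional-longevity group), a miRNA's trajectory is classified as:

``age_related``
    Expression changes monotonically with age across *all* bins, the
    oldest included, and the youngest-vs-oldest contrast is significant --
    the change simply tracks chronological age.

``longevity_associated``
    Expression changes monotonically across the control (non-longevity)
    bins with a significant youngest-vs-oldest-control contrast, while the
    longevity group is statistically indistinguishable from the youngest
    bin yet differs from at least one intermediate elderly bin -- youthful
    expression is preserved in the exceptionally long-lived.

``none``
    Anything else.

Group contrasts use the two-sample Student's t-test (equal-variance by
default, Welch optional). A p-value exactly equal to alpha counts as
significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AgeSeries:
    """Ordered (label, values) age bins; the last bin is the longevity
    group unless ``longevity_label`` says otherwise."""

    groups: list[tuple[str, np.ndarray]]
    longevity_label: str | None = None

    def __post_init__(self):
        if len(self.groups) < 3:
            raise ValueError("need at least 3 age groups")
        self.groups = [(lab, np.asarray(v, dtype=float)) for lab, v in self.groups]
        for lab, v in self.groups:
            if len(v) < 2:
                raise ValueError(f"group {lab!r} has n < 2")
        labels = [lab for lab, _ in self.groups]
        if self.longevity_label is None:
            self.longevity_label = labels[-1]
        if self.longevity_label not in labels:
            raise ValueError(f"longevity group {self.longevity_label!r} not present")
        if labels[-1] != self.longevity_label:
            raise ValueError("longevity group must be the oldest (last) bin")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        group_order: list[str] | None = None,
        longevity_label: str | None = None,
        group_col: str = "age_group",
        value_col: str = "value",
    ) -> "AgeSeries":
        if group_order is None:
            group_order = list(dict.fromkeys(df[group_col]))
        groups = [
            (g, df.loc[df[group_col] == g, value_col].to_numpy()) for g in group_order
        ]
        return cls(groups, longevity_label)


@dataclass
class TrajectoryCall:
    mode: str  # age_related | longevity_associated | none
    control_trend_p: float
    pairwise_p: pd.DataFrame
    evidence: dict[str, bool] = field(default_factory=dict)


def group_ttest(a, b, equal_var: bool = True) -> float:
    """Two-sided two-sample t-test p-value.

    Degenerate case: both groups constant with equal means has no contrast
    to test; p = 1 by convention.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def _monotone(means) -> bool:
    d = np.diff(means)
    return bool(np.all(d > 0) or np.all(d < 0))


def classify_trajectory(
    series: AgeSeries, alpha: float = 0.05, equal_var: bool = True
) -> TrajectoryCall:
    labels = [lab for lab, _ in series.groups]
    values = dict(series.groups)
    means = np.array([values[lab].mean() for lab in labels])
    k = len(labels)
    pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for i in range(k):
        for j in range(i + 1, k):
            p = group_ttest(values[labels[i]], values[labels[j]], equal_var=equal_var)
            pmat.iloc[i, j] = pmat.iloc[j, i] = p

    def significant(p):  # boundary p == alpha counts as significant
        return p <= alpha

    longevity = series.longevity_label
    controls = labels[:-1]
    youngest, oldest_control = controls[0], controls[-1]
    control_trend_p = pmat.loc[youngest, oldest_control]
    evidence = {
        "control_means_monotone": _monotone(means[:-1]),
        "control_endpoint_significant": significant(control_trend_p),
        "longevity_matches_youngest": not significant(pmat.loc[longevity, youngest]),
        "longevity_differs_from_elderly": any(
            significant(pmat.loc[longevity, g]) for g in controls[1:]
        ),
        "all_means_monotone": _monotone(means),
        "endpoint_significant": significant(pmat.loc[youngest, longevity]),
    }
    if (
        evidence["control_means_monotone"]
        and evidence["control_endpoint_significant"]
        and evidence["longevity_matches_youngest"]
        and evidence["longevity_differs_from_elderly"]
    ):
        mode = "longevity_associated"
    elif evidence["all_means_monotone"] and evidence["endpoint_significant"]:
        mode = "age_related"
    else:
        mode = "none"
    return TrajectoryCall(mode, float(control_trend_p), pmat, evidence)


def classify_table(
    df: pd.DataFrame,
    group_order: list[str],
    longevity_label: str | None = None,
    alpha: float = 0.05,
    mirna_col: str = "mirna",
    group_col: str = "age_group",
    value_col: str = "value",
) -> pd.DataFrame:
    """Classify every miRNA in a long-format table (miRNA, sample,
    age_group, value); returns one row per miRNA."""
    rows = []
    for mirna, block in df.groupby(mirna_col, sort=True):
        series = AgeSeries.from_frame(block, group_order, longevity_label, group_col, value_col)
        call = classify_trajectory(series, alpha=alpha)
        row = {"mirna": mirna, "mode": call.mode, "control_trend_p": call.control_trend_p}
        row.update({f"evidence_{k}": v for k, v in call.evidence.items()})
        rows.append(row)
    return pd.DataFrame(rows)
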