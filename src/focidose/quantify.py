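"""Group summaries and statistics for per-nucleus focus counts.

The tidy count table has one row per analysed nucleus, keyed by animal,
exposure group, tissue and cell class.  Because animals — not nuclei —
are the experimental unit, the default group summary first averages
within each animal and then reports mean ± SD over the animal means
(four animals per group in the reference design).  Pooling over nuclei
is available as an alternative unit.

Group comparisons use one-way ANOVA on the chosen unit followed by the
Tukey HSD all-pairs test (Tukey–Kramer for unbalanced designs), with
adjusted p-values from the studentized-range distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ["animal_id", "group", "tissue", "cell_class",
                    "nucleus_id", "n_foci"]

#: exposure groups of the reference design
GROUPS = ("control", "4h", "25h")


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy per-nucleus count table invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns {missing}")
    if len(table) == 0:
        raise ValueError("count table is empty")
    if (table["n_foci"] < 0).any():
        raise ValueError("n_foci must be non-negative")
    dup = table.duplicated(subset=["animal_id", "tissue", "nucleus_id"])
    if dup.any():
        raise ValueError("(animal_id, tissue, nucleus_id) must be unique")
    return table


@dataclass
class GroupSummary:
    group: str
    cell_class: str
    n_animals: int
    n_nuclei: int
    mean_foci: float
    sd_foci: float  # NaN (flagged) when undefined
    sd_defined: bool
    animal_means: dict[str, float]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False  # zero within-group variance, nonzero between


@dataclass
class TukeyComparison:
    group_a: str
    group_b: str
    mean_diff: float  # mean_a - mean_b
    q: float
    p_adj: float


@dataclass
class TukeyResult:
    comparisons: list[TukeyComparison]
    df_within: int
    k: int


def summarize_groups(
    table: pd.DataFrame, unit: str = "animal"
) -> list[GroupSummary]:
    """Mean ± SD foci per nucleus, per (group, cell class) stratum.

    ``unit='animal'`` (default): per-animal means first, SD over animals
    (undefined and flagged for a single animal).  ``unit='nucleus'``:
    pooled over all nuclei in the stratum.
    """
    validate_count_table(table)
    if unit not in ("animal", "nucleus"):
        raise ValueError("unit must be 'animal' or 'nucleus'")
    out: list[GroupSummary] = []
    for (group, cell_class), sub in table.groupby(
        ["group", "cell_class"], sort=False
    ):
        animal_means = sub.groupby("animal_id")["n_foci"].mean()
        if unit == "animal":
            values = animal_means.to_numpy(dtype=float)
        else:
            values = sub["n_foci"].to_numpy(dtype=float)
        sd_defined = len(values) > 1
        out.append(GroupSummary(
            group=str(group), cell_class=str(cell_class),
            n_animals=animal_means.size, n_nuclei=len(sub),
            mean_foci=float(values.mean()),
            sd_foci=float(values.std(ddof=1)) if sd_defined else float("nan"),
            sd_defined=sd_defined,
            animal_means={str(a): float(m) for a, m in animal_means.items()},
        ))
    return out


def summary_table(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {"group": s.group, "cell_class": s.cell_class,
         "n_animals": s.n_animals, "n_nuclei": s.n_nuclei,
         "mean_foci": s.mean_foci, "sd_foci": s.sd_foci}
        for s in summaries
    ])


def zero_foci_fraction(table: pd.DataFrame) -> pd.DataFrame:
    """Fraction of nuclei with no focus at all, per (group, cell class)."""
    validate_count_table(table)
    rows = []
    for (group, cell_class), sub in table.groupby(
        ["group", "cell_class"], sort=False
    ):
        rows.append({
            "group": group, "cell_class": cell_class, "n_nuclei": len(sub),
            "zero_fraction": float((sub["n_foci"] == 0).mean()),
        })
    return pd.DataFrame(rows)


def count_histogram(table: pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Fraction of nuclei per integer focus count, per stratum.

    Fractions sum to 1 per stratum and the histogram mean equals the
    direct per-stratum mean count.
    """
    validate_count_table(table)
    rows = []
    for key, sub in table.groupby(by, sort=False):
        counts = sub["n_foci"].value_counts(normalize=True).sort_index()
        for n, frac in counts.items():
            rows.append({by: key, "n_foci": int(n), "fraction": float(frac)})
    return pd.DataFrame(rows)


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Fixed-effects one-way ANOVA: F = MS_between / MS_within."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one value")
    N = sum(len(g) for g in groups)
    df_between = k - 1
    df_within = N - k
    if df_within < 1:
        raise ValueError("need N - k >= 1 residual degrees of freedom")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df_between=df_between,
                               df_within=df_within, p=1.0)
        return AnovaResult(F=math.inf, df_between=df_between,
                           df_within=df_within, p=0.0, degenerate=True)
    F = ms_between / ms_within
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), df_between=df_between,
                       df_within=df_within, p=p)


def tukey_hsd(
    groups: list[np.ndarray], names: list[str] | None = None
) -> TukeyResult:
    """Tukey HSD (Tukey–Kramer) all-pairs comparisons after ANOVA.

    q_ij = |mean_i - mean_j| / sqrt(MS_within * (1/n_i + 1/n_j) / 2);
    adjusted p from the studentized-range distribution with (k, df_within).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    names = names or [f"group{i}" for i in range(k)]
    if len(names) != k:
        raise ValueError("names must match the number of groups")
    anova = one_way_anova(groups)
    ms_within = (
        sum(((g - g.mean()) ** 2).sum() for g in groups) / anova.df_within
    )
    comparisons = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = groups[i].mean() - groups[j].mean()
            if ms_within == 0.0:
                q = math.inf if diff != 0 else 0.0
                p_adj = 0.0 if diff != 0 else 1.0
            else:
                se = math.sqrt(
                    ms_within * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
                    / 2.0
                )
                q = abs(diff) / se
                p_adj = float(
                    stats.studentized_range.sf(q, k, anova.df_within)
                )
            comparisons.append(TukeyComparison(
                group_a=names[i], group_b=names[j], mean_diff=float(diff),
                q=float(q), p_adj=min(max(p_adj, 0.0), 1.0),
            ))
    return TukeyResult(comparisons=comparisons, df_within=anova.df_within, k=k)


def compare_groups(
    table: pd.DataFrame, cell_class: str, unit: str = "animal"
) -> tuple[AnovaResult, TukeyResult]:
    """ANOVA + Tukey HSD across exposure groups for one cell class."""
    validate_count_table(table)
    sub = table[table["cell_class"] == cell_class]
    if len(sub) == 0:
        raise ValueError(f"no rows for cell class {cell_class!r}")
    names, groups = [], []
    for group, g in sub.groupby("group", sort=False):
        if unit == "animal":
            values = g.groupby("animal_id")["n_foci"].mean().to_numpy()
        else:
            values = g["n_foci"].to_numpy(dtype=float)
        names.append(str(group))
        groups.append(values)
    return one_way_anova(groups), tukey_hsd(groups, names=names)
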