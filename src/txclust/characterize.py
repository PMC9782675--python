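"""Cluster characterization by standardized mean differences.

Each cluster is profiled against the overall cohort (cluster members
included in the reference, matching the usual registry-phenotyping
convention): continuous variables via the two-group SMD with the
quadratic-mean pooled SD, binary/categorical variables via per-level
indicator SMDs.  Entries with |SMD| above the cutoff (default 0.3) are the
cluster's key features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortError, CohortTable
from .consensus import ClusterAssignment


@dataclass
class CharacterizationConfig:
    smd_cutoff: float = 0.3
    comparison: str = "cluster_vs_overall"

    def __post_init__(self) -> None:
        if self.smd_cutoff <= 0:
            raise CohortError("smd_cutoff must be positive")
        if self.comparison not in ("cluster_vs_overall", "cluster_vs_rest"):
            raise CohortError(
                "comparison must be cluster_vs_overall or cluster_vs_rest"
            )


def smd_continuous(
    mean_a: float, sd_a: float, mean_b: float, sd_b: float
) -> float:
    """(mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2)/2); NaN when the pooled
    SD is zero (undefined, excluded from key features)."""
    if sd_a < 0 or sd_b < 0:
        raise CohortError("standard deviations must be non-negative")
    pooled = math.sqrt((sd_a**2 + sd_b**2) / 2.0)
    if pooled == 0:
        return float("nan")
    return (mean_a - mean_b) / pooled


def smd_proportion(p_a: float, p_b: float) -> float:
    """Indicator-variable SMD: (p_a - p_b) / sqrt((p_a(1-p_a)+p_b(1-p_b))/2).

    When both proportions are degenerate (0 or 1): equal proportions give
    0, unequal give NaN (undefined)."""
    if not (0 <= p_a <= 1 and 0 <= p_b <= 1):
        raise CohortError("proportions must lie in [0, 1]")
    denom = math.sqrt((p_a * (1 - p_a) + p_b * (1 - p_b)) / 2.0)
    if denom == 0:
        return 0.0 if p_a == p_b else float("nan")
    return (p_a - p_b) / denom


@dataclass
class SMDProfile:
    cluster_id: int
    table: pd.DataFrame  # variable, level, cluster_summary, overall_summary, smd, key_feature

    @property
    def key_features(self) -> pd.DataFrame:
        return self.table[self.table["key_feature"]]


def smd_profile(
    cohort: CohortTable,
    assignment: ClusterAssignment,
    config: CharacterizationConfig | None = None,
) -> list[SMDProfile]:
    """One profile per cluster, entries sorted by |SMD| descending.

    Every schema variable appears exactly once per profile — continuous
    variables as a single row, binary/categorical/ordinal variables as one
    indicator row per level.
    """
    config = config or CharacterizationConfig()
    labels = np.asarray(assignment.labels)
    if len(labels) != cohort.n:
        raise CohortError("assignment does not cover the cohort")
    if not cohort.is_complete():
        raise CohortError("cohort must be complete (imputed) for profiling")
    profiles = []
    for c in sorted(np.unique(labels)):
        in_c = labels == c
        if not in_c.any():
            raise CohortError(f"cluster {c} is empty")
        if config.comparison == "cluster_vs_overall":
            ref = np.ones_like(in_c, dtype=bool)
        else:
            ref = ~in_c
        rows = []
        for name, spec in cohort.schema.items():
            col = cohort.data[name]
            if spec.kind == "continuous":
                x_c, x_r = col[in_c], col[ref]
                smd = smd_continuous(
                    x_c.mean(), x_c.std(ddof=1), x_r.mean(), x_r.std(ddof=1)
                )
                rows.append(
                    {
                        "variable": name,
                        "level": "",
                        "cluster_summary": f"{x_c.mean():.2f} ± {x_c.std(ddof=1):.2f}",
                        "overall_summary": f"{x_r.mean():.2f} ± {x_r.std(ddof=1):.2f}",
                        "smd": smd,
                    }
                )
            else:
                for lvl in spec.levels:
                    p_c = float((col[in_c] == lvl).mean())
                    p_r = float((col[ref] == lvl).mean())
                    rows.append(
                        {
                            "variable": name,
                            "level": str(lvl),
                            "cluster_summary": f"{p_c:.1%}",
                            "overall_summary": f"{p_r:.1%}",
                            "smd": smd_proportion(p_c, p_r),
                        }
                    )
        table = pd.DataFrame(rows)
        table["key_feature"] = table["smd"].abs() > config.smd_cutoff
        table.loc[table["smd"].isna(), "key_feature"] = False
        table = table.reindex(
            table["smd"].abs().sort_values(ascending=False, na_position="last").index
        ).reset_index(drop=True)
        profiles.append(SMDProfile(cluster_id=int(c), table=table))
    return profiles


def region_proportions(
    assignment: ClusterAssignment, region_labels
) -> pd.DataFrame:
    """Cluster mix per UNOS region: rows are regions (with transplant
    counts), columns are the fraction of the region's subjects in each
    cluster; fractions sum to 1 per row."""
    regions = np.asarray(region_labels)
    labels = np.asarray(assignment.labels)
    if len(regions) != len(labels):
        raise CohortError("need one region label per subject")
    valid = set(range(1, 12))
    unknown = set(np.unique(regions)) - valid
    if unknown:
        raise CohortError(f"unknown UNOS region labels: {sorted(unknown)}")
    clusters = sorted(np.unique(labels))
    rows = []
    for r in sorted(np.unique(regions)):
        in_r = regions == r
        n_r = int(in_r.sum())
        row = {"region": int(r), "n_transplants": n_r}
        for c in clusters:
            row[f"cluster_{c}"] = float((labels[in_r] == c).mean())
        rows.append(row)
    return pd.DataFrame(rows)
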