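"""Group-level analyses: edge-wise reduction tests with FDR control, the
direct/indirect edge typology with its hemispheric chi-square, mNC ANOVAs
with Tukey post-hocs, ipsi/contralesional analyses, and tumor-volume
correlations.

Conventions
-----------
* Edge-wise tests are one-tailed (patient < control) pooled-variance t
  tests, Benjamini-Hochberg corrected within the 45 edges of one
  subgroup-vs-control comparison (``fdr_family="pooled"`` corrects across
  all comparisons jointly instead).
* A significantly reduced edge is *direct* if at least one endpoint belongs
  to the lesioned subsystem, *indirect* if both endpoints lie in
  non-neoplastic modules.  Midline and cerebellar nodes belong to no
  subsystem and can never make an edge direct.
* The typology chi-square pools left-lesion groups against right-lesion
  groups.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .rois import SUBSYSTEM_LABELS, SUBSYSTEMS, NODE_ORDER
from .stats import (
    ContingencyTable,
    TestResult,
    bh_fdr,
    chi_square_independence,
    mixed_anova_main_within,
    paired_t,
    pearson_corr,
    tukey_hsd,
    anova_oneway_raw,
    two_sample_t,
)

__all__ = [
    "edgewise_reduction_test",
    "classify_edge",
    "direct_edge_count",
    "typology_counts",
    "hemispheric_typology_test",
    "mnc_group_analysis",
    "ipsi_contra_analysis",
    "tv_correlation",
    "MNC_INDICES",
]

MNC_INDICES = ("lfcw", "rfcw", "fcb", "fcg")

_LEFT_POOL = ("LFG", "LTG")
_RIGHT_POOL = ("RFG", "RTG")


def edgewise_reduction_test(
    patients: pd.DataFrame,
    controls: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-edge one-tailed (patient < control) t tests, FDR-corrected
    across the edges of this comparison.

    ``patients`` and ``controls`` are subjects x edges tables of Fisher-z
    values sharing identical columns.  Returns a DataFrame indexed by edge
    with t, df, p, p_adj and a significance flag.
    """
    if list(patients.columns) != list(controls.columns):
        raise ValueError("patient and control edge tables must share columns")
    if len(patients) < 2 or len(controls) < 2:
        raise ValueError("each side needs at least 2 subjects")
    rows = []
    for col in patients.columns:
        res = two_sample_t(
            patients[col].to_numpy(), controls[col].to_numpy(),
            tail="less", equal_var=equal_var,
        )
        rows.append({"edge": col, "t": res.statistic, "df": res.df, "p": res.p})
    table = pd.DataFrame(rows).set_index("edge")
    reject, adj = bh_fdr(table["p"].to_numpy(), alpha=alpha, method=fdr_method)
    table["p_adj"] = adj
    table["significant"] = reject
    return table


def classify_edge(
    edge: tuple[str, str] | str, lesioned_subsystem: str
) -> str:
    """Direct/indirect typology of a (significantly reduced) edge.

    Direct iff at least one endpoint node belongs to the lesioned
    subsystem; otherwise indirect.
    """
    if lesioned_subsystem not in SUBSYSTEM_LABELS:
        raise ValueError(f"unknown subsystem {lesioned_subsystem!r}")
    if isinstance(edge, str):
        a, b = edge.split("--")
    else:
        a, b = edge
    for n in (a, b):
        if n not in NODE_ORDER:
            raise KeyError(f"unknown node name: {n!r}")
    members = set(SUBSYSTEMS[lesioned_subsystem])
    return "direct" if (a in members or b in members) else "indirect"


def direct_edge_count(subsystem: str) -> int:
    """Number of the 45 edges that are direct for a given subsystem."""
    from .rois import edge_keys

    return sum(classify_edge(e, subsystem) == "direct" for e in edge_keys())


def typology_counts(
    significant_edges: Mapping[str, Sequence[str]],
    group_subsystems: Mapping[str, str],
) -> pd.DataFrame:
    """Pool significant reduced edges into the hemisphere x type 2x2 table.

    ``significant_edges`` maps a patient group label to its significant
    edge list; ``group_subsystems`` maps the group to its lesioned
    subsystem.  Rows: left- and right-lesion pools; columns: direct,
    indirect.
    """
    counts = pd.DataFrame(
        0, index=["left", "right"], columns=["direct", "indirect"], dtype=int
    )
    for group, edges in significant_edges.items():
        if group in _LEFT_POOL:
            pool = "left"
        elif group in _RIGHT_POOL:
            pool = "right"
        else:
            raise ValueError(f"unknown patient group {group!r}")
        subsystem = group_subsystems[group]
        for e in edges:
            counts.loc[pool, classify_edge(e, subsystem)] += 1
    return counts


def hemispheric_typology_test(counts: pd.DataFrame) -> TestResult:
    """Pearson chi-square on the pooled hemisphere x edge-type table."""
    return chi_square_independence(
        ContingencyTable(
            counts.to_numpy(),
            row_labels=tuple(counts.index),
            col_labels=tuple(counts.columns),
        )
    )


def mnc_group_analysis(
    profiles: pd.DataFrame,
    group_col: str = "group",
    alpha: float = 0.05,
) -> dict[str, dict]:
    """One-way ANOVA plus all-pairs Tukey HSD for each mNC index.

    ``profiles`` holds one row per subject with a group label column and
    the four index columns.  Patient-vs-control pairs are flagged in the
    Tukey output.
    """
    groups = list(dict.fromkeys(profiles[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out: dict[str, dict] = {}
    for index in MNC_INDICES:
        samples = [profiles.loc[profiles[group_col] == g, index].to_numpy() for g in groups]
        anova = anova_oneway_raw(samples)
        tukey = tukey_hsd(samples, alpha=alpha, labels=groups)
        for res in tukey:
            pair = res.extra["pair"]
            res.extra["vs_control"] = "HC" in pair
        out[index] = {"anova": anova, "tukey": tukey}
    return out


def ipsi_contra_analysis(
    profiles: pd.DataFrame,
    group_col: str = "group",
    ipsi_col: str = "ipsi_fcw",
    contra_col: str = "contra_fcw",
) -> dict:
    """Mixed-design analysis of ipsi- vs contralesional within-hemisphere
    connectivity across patient subgroups.

    Returns the main effect of hemisphere side (two-level within-subject
    factor, group as between-subject factor) plus a paired t test within
    each subgroup.
    """
    for col in (ipsi_col, contra_col):
        if profiles[col].isna().any():
            bad = profiles.index[profiles[col].isna()][0]
            raise ValueError(f"missing {col} for subject {bad!r}")
    mixed = mixed_anova_main_within(
        profiles[ipsi_col].to_numpy(),
        profiles[contra_col].to_numpy(),
        profiles[group_col].to_numpy(),
    )
    paired = {}
    for g in dict.fromkeys(profiles[group_col]):
        sub = profiles[profiles[group_col] == g]
        paired[g] = paired_t(sub[ipsi_col].to_numpy(), sub[contra_col].to_numpy())
    return {"mixed_anova": mixed, "paired": paired}


def tv_correlation(
    profiles: pd.DataFrame,
    volumes: Optional[pd.Series] = None,
    group_col: str = "group",
    volume_col: str = "tumor_volume_cm3",
) -> pd.DataFrame:
    """Pearson correlation of each mNC index with tumor volume, per
    subgroup.  Returns rows (group, index) with r, p and n."""
    df = profiles.copy()
    if volumes is not None:
        df[volume_col] = volumes
    rows = []
    for g in dict.fromkeys(df[group_col]):
        sub = df[df[group_col] == g]
        if len(sub) < 4:
            raise ValueError(f"subgroup {g!r} has fewer than 4 subjects")
        for index in MNC_INDICES:
            res = pearson_corr(sub[volume_col].to_numpy(), sub[index].to_numpy())
            rows.append(
                {"group": g, "index": index, "r": res.statistic, "p": res.p,
                 "n": len(sub)}
            )
    return pd.DataFrame(rows).set_index(["group", "index"])
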