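"""End-to-end orchestration: configuration, stage wiring, result
serialization and demographic reporting.

``run_pipeline`` executes simulate -> connectivity -> inference on a
synthetic cohort and writes the full result bundle (subject table, 45-column
edge table, mNC profiles, edge-wise test tables, typology counts, test
results JSON, and a provenance record).  Outputs are byte-identical across
runs with the same configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_reference import (
    EDUCATION_YEARS,
    GENDER_COUNTS,
    GROUP_TO_SUBSYSTEM,
    PATHOLOGY_GRADE_COUNTS,
    PATHOLOGY_TYPE_COUNTS,
    TUMOR_VOLUME_CM3,
)
from .connectivity import compute_mnc, ipsi_contra
from .inference import (
    edgewise_reduction_test,
    hemispheric_typology_test,
    ipsi_contra_analysis,
    mnc_group_analysis,
    tv_correlation,
    typology_counts,
)
from .simulate import Cohort, CohortConfig, generate_cohort
from .stats import (
    ContingencyTable,
    anova_oneway_raw,
    anova_oneway_summary,
    chi_square_independence,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "table1_report",
    "reference_demographics_report",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Validated configuration for the full pipeline."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    alpha: float = 0.05
    fdr_method: str = "bh"
    fdr_family: str = "per_comparison"
    mnc_scope: str = "core6"
    roi_source: str = "fixture"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fdr_method not in ("bh", "by"):
            raise ValueError(f"unknown FDR method {self.fdr_method!r}")
        if self.fdr_family not in ("per_comparison", "pooled"):
            raise ValueError(f"unknown FDR family {self.fdr_family!r}")
        if self.mnc_scope not in ("core6", "all10"):
            raise ValueError(f"unknown mNC scope {self.mnc_scope!r}")
        if self.roi_source not in ("fixture", "ica"):
            raise ValueError(f"unknown ROI source {self.roi_source!r}")

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        cohort_payload = payload.pop("cohort", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"cohort"}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cohort_known = {f.name for f in dataclasses.fields(CohortConfig)}
        cohort_unknown = set(cohort_payload) - cohort_known
        if cohort_unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(cohort_unknown)}")
        if "tv_range" in cohort_payload:
            cohort_payload["tv_range"] = tuple(cohort_payload["tv_range"])
        return cls(cohort=CohortConfig(**cohort_payload), **payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["tv_range"] = list(d["cohort"]["tv_range"])
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    edges: pd.DataFrame
    mnc: pd.DataFrame
    edge_tests: pd.DataFrame
    typology: pd.DataFrame
    typology_test: object
    mnc_tests: dict
    ipsi_contra: dict
    tv_corr: pd.DataFrame


def _mnc_table(cohort: Cohort, scope: str) -> pd.DataFrame:
    rows = {}
    for s in cohort.subjects:
        prof = compute_mnc(s.edge_vector(), scope=scope)
        if s.subsystem is not None:
            side = "left" if s.subsystem in ("LF", "LT") else "right"
            prof = ipsi_contra(prof, side)
        rows[s.subject_id] = prof.as_dict()
    mnc = pd.DataFrame.from_dict(rows, orient="index")
    mnc.index.name = "subject_id"
    table = cohort.subject_table()
    mnc.insert(0, "group", table["group"])
    mnc["tumor_volume_cm3"] = table["tumor_volume_cm3"]
    return mnc


def run_pipeline(
    config: PipelineConfig, outdir: Optional[str | Path] = None
) -> PipelineResult:
    """Execute simulate -> connectivity -> inference; optionally write the
    result bundle to ``outdir``."""
    logging.basicConfig(level=config.log_level, stream=sys.stderr)
    logger.info("generating cohort (seed=%d)", config.cohort.seed)
    cohort = generate_cohort(config.cohort)
    edges = cohort.edge_table()
    table = cohort.subject_table()
    mnc = _mnc_table(cohort, config.mnc_scope)

    logger.info("edge-wise reduction tests")
    hc_ids = table.index[table["group"] == "HC"]
    edge_tests_parts = []
    significant: dict[str, list[str]] = {}
    patient_groups = [g for g in ("LFG", "LTG", "RFG", "RTG") if (table["group"] == g).any()]
    for g in patient_groups:
        ids = table.index[table["group"] == g]
        res = edgewise_reduction_test(
            edges.loc[ids], edges.loc[hc_ids],
            alpha=config.alpha, fdr_method=config.fdr_method,
        )
        res.insert(0, "group", g)
        edge_tests_parts.append(res.reset_index())
    edge_tests = pd.concat(edge_tests_parts, ignore_index=True)
    if config.fdr_family == "pooled":
        # one FDR family across all subgroup-vs-control comparisons
        from .stats import bh_fdr

        reject, adj = bh_fdr(
            edge_tests["p"].to_numpy(), alpha=config.alpha, method=config.fdr_method
        )
        edge_tests["p_adj"] = adj
        edge_tests["significant"] = reject
    for g in patient_groups:
        sub = edge_tests[edge_tests["group"] == g]
        significant[g] = list(sub.loc[sub["significant"], "edge"])

    typology = typology_counts(significant, GROUP_TO_SUBSYSTEM)
    typ_test = (
        hemispheric_typology_test(typology)
        if (typology.to_numpy().sum(axis=1) > 0).all()
        and (typology.to_numpy().sum(axis=0) > 0).all()
        else None
    )

    logger.info("mNC group analyses")
    mnc_tests = mnc_group_analysis(mnc, alpha=config.alpha)
    patients = mnc[mnc["group"] != "HC"]
    ipsi = ipsi_contra_analysis(patients)
    tv = tv_correlation(patients)

    result = PipelineResult(
        config, cohort, edges, mnc, edge_tests, typology, typ_test,
        mnc_tests, ipsi, tv,
    )
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def _tests_json(result: PipelineResult) -> dict:
    mnc_json = {
        idx: {
            "anova": block["anova"].to_dict(),
            "tukey": [t.to_dict() for t in block["tukey"]],
        }
        for idx, block in result.mnc_tests.items()
    }
    return {
        "typology_chi2": (
            result.typology_test.to_dict() if result.typology_test else None
        ),
        "mnc": mnc_json,
        "ipsi_contra": {
            "mixed_anova": result.ipsi_contra["mixed_anova"].to_dict(),
            "paired": {
                g: r.to_dict() for g, r in result.ipsi_contra["paired"].items()
            },
        },
        "tv_correlation": result.tv_corr.reset_index().to_dict(orient="records"),
    }


def write_bundle(result: PipelineResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.cohort.subject_table().to_csv(out / "subjects.csv", float_format=_FLOAT_FMT)
    result.edges.to_csv(out / "edges.csv", float_format=_FLOAT_FMT)
    result.mnc.to_csv(out / "mnc.csv", float_format=_FLOAT_FMT)
    result.edge_tests.to_csv(out / "edge_tests.csv", index=False, float_format=_FLOAT_FMT)
    result.typology.to_csv(out / "typology.csv")
    (out / "tests.json").write_text(json.dumps(_tests_json(result), indent=2))
    provenance = {
        "package": "langnet",
        "version": __version__,
        "numpy": np.__version__,
        "config": result.config.to_dict(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    logger.info("result bundle written to %s", out)


def table1_report(
    subjects: pd.DataFrame,
    group_col: str = "group",
    continuous: tuple[str, ...] = ("tumor_volume_cm3",),
    categorical: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-group demographic summary with one-way ANOVA (continuous rows)
    or chi-square (categorical rows), in the style of a cohort table."""
    missing = [c for c in (group_col, *continuous, *categorical) if c not in subjects]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    groups = list(dict.fromkeys(subjects[group_col]))
    rows = []
    for var in continuous:
        row: dict = {"variable": var, "test": "anova"}
        samples = []
        for g in groups:
            vals = subjects.loc[subjects[group_col] == g, var].dropna().to_numpy()
            row[g] = (
                f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}" if len(vals) > 1 else "–"
            )
            if len(vals) > 1 and np.ptp(vals) > 0:
                samples.append(vals)
        if len(samples) >= 2:
            res = anova_oneway_raw(samples)
            row["statistic"], row["p"] = res.statistic, res.p
        else:
            row["statistic"], row["p"] = np.nan, np.nan
            logger.info("ANOVA for %r skipped: fewer than 2 usable groups", var)
        rows.append(row)
    for var in categorical:
        levels = sorted(subjects[var].dropna().unique())
        counts = np.array(
            [
                [(subjects[group_col].eq(g) & subjects[var].eq(l)).sum() for l in levels]
                for g in groups
            ]
        )
        keep = counts.sum(axis=1) > 0
        res = chi_square_independence(ContingencyTable(counts[keep]))
        row = {"variable": var, "test": "chi2",
               "statistic": res.statistic, "p": res.p}
        for g, c in zip(groups, counts):
            row[g] = "/".join(str(x) for x in c)
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def reference_demographics_report() -> pd.DataFrame:
    """Recompute the reference cohort's demographic test statistics from
    its published per-group summaries and counts."""
    rows = []
    for name, res in (
        ("gender", chi_square_independence(GENDER_COUNTS)),
        ("pathological_types", chi_square_independence(PATHOLOGY_TYPE_COUNTS)),
        ("pathological_grades", chi_square_independence(PATHOLOGY_GRADE_COUNTS)),
        ("education_years", anova_oneway_summary(EDUCATION_YEARS)),
        ("tumor_volume_cm3", anova_oneway_summary(TUMOR_VOLUME_CM3)),
    ):
        rows.append(
            {"variable": name, "test": res.test, "statistic": res.statistic,
             "df": res.df if not isinstance(res.df, tuple) else list(res.df),
             "p": res.p}
        )
    return pd.DataFrame(rows).set_index("variable")
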