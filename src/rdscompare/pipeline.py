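"""End-to-end study analysis: filter, estimate, test, render comparison tables.

``run_analysis`` reproduces the structure of a dual-frame comparison report:

* **table1** — registry variables (gender, citizenship) across the full PR
  sample, the PR study population (completed questionnaires) and the RDS
  analysis set, unweighted and inverse-degree weighted;
* **table2** — sociodemographic and lifestyle variables across the two
  study populations;
* **table3** — health and healthcare-utilisation variables;

each with exact Clopper-Pearson intervals for the unweighted columns,
chain-clustered logit intervals for the weighted column, Pearson chi-square
for the unweighted two-arm comparisons and first-order Rao-Scott corrected
chi-square for the weighted ones, plus an equilibrium diagnostic per
attribute and t-test / negative-binomial models for network size.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import equilibrium as eq
from . import estimators as est
from . import stat_tests as st
from .errors import InputError, RDSCompareError, SchemaError
from .recruitment import (
    ParticipantRecord,
    build_forest,
    filter_analysis_set,
    records_from_frame,
)

SCHEMA_VERSION = "1"

PR_FLAG_COLUMNS = ("invalid", "invited", "responded")


def response_rate(responded: int, drawn: int, invalid: int) -> float:
    """Survey response in percent: 100 * responded / (drawn - invalid)."""
    if invalid > drawn or invalid < 0:
        raise InputError(f"need 0 <= invalid <= drawn, got {invalid}/{drawn}")
    if drawn == invalid:
        raise InputError("all addresses invalid: response undefined")
    if not 0 <= responded <= drawn - invalid:
        raise InputError(
            f"need 0 <= responded <= drawn - invalid, got {responded}"
        )
    return 100.0 * responded / (drawn - invalid)


@dataclass
class AnalysisConfig:
    """What to tabulate and how to filter/test.

    ``table1_variables`` are the registry variables known for every drawn PR
    member; ``table2_variables``/``table3_variables`` default to every other
    attribute (table3 empty) when left ``None``.  ``category_map`` pools
    rare categories before tabulation; categories whose pooled total count
    across the two study populations stays below ``min_count`` are excluded
    from the comparisons.
    """

    table1_variables: tuple[str, ...] = ("gender", "citizenship")
    table2_variables: tuple[str, ...] | None = None
    table3_variables: tuple[str, ...] | None = None
    network_size_variable: bool = True
    min_wave: int = 2
    equilibrium_tolerance: float = 0.02
    level: float = 0.95
    alpha: float = 0.05
    continuity_2x2: bool = True
    category_map: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    min_count: int = 5
    degree_cap: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["table1_variables"] = list(self.table1_variables)
        d["table2_variables"] = (
            None if self.table2_variables is None else list(self.table2_variables)
        )
        d["table3_variables"] = (
            None if self.table3_variables is None else list(self.table3_variables)
        )
        d["category_map"] = {k: dict(v) for k, v in self.category_map.items()}
        return d


DEFAULT_TABLE3 = ("unwell", "cardiovascular", "neurological", "dental_checkup", "gp_visit")


@dataclass
class StudyReport:
    schema_version: str
    provenance: dict
    recruitment: dict
    response: dict
    tables: dict
    comparisons: list
    equilibrium: list
    network_size: dict
    exclusions: list

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "provenance": self.provenance,
            "recruitment": self.recruitment,
            "response": self.response,
            "tables": self.tables,
            "comparisons": self.comparisons,
            "equilibrium": self.equilibrium,
            "network_size": self.network_size,
            "exclusions": self.exclusions,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(**{k: d[k] for k in (
            "schema_version", "provenance", "recruitment", "response",
            "tables", "comparisons", "equilibrium", "network_size",
            "exclusions",
        )})

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        return cls.from_dict(json.loads(text))


def _coerce_records(data) -> tuple[list[ParticipantRecord], pd.DataFrame | None]:
    if data is None:
        return [], None
    if isinstance(data, pd.DataFrame):
        df = data
        flags = df[[c for c in PR_FLAG_COLUMNS if c in df.columns]].copy()
        recs = records_from_frame(df.drop(columns=list(flags.columns)))
        return recs, flags if len(flags.columns) else None
    return list(data), None


def _mapped(value: str, variable: str, config: AnalysisConfig) -> str:
    return config.category_map.get(variable, {}).get(value, value)


def _values_of(records: Iterable[ParticipantRecord], variable: str,
               config: AnalysisConfig) -> dict[str, str]:
    out = {}
    for r in records:
        if variable in r.attributes:
            out[r.participant_id] = _mapped(r.attributes[variable], variable, config)
    return out


def _count_rows(values: Sequence[str], variable: str, arm: str,
                level: float) -> list[dict]:
    n = len(values)
    cats = sorted(set(values))
    rows = []
    for c in cats:
        pe = est.unweighted_estimate(c, sum(v == c for v in values), n, level)
        rows.append({"variable": variable, "category": c, "arm": arm,
                     **pe.to_dict()})
    return rows


def run_analysis(pr, rds, config: AnalysisConfig | None = None) -> StudyReport:
    """Full deterministic analysis of the two arms; either arm may be None.

    ``pr``/``rds`` are participant tables (DataFrames in the standard
    schema, or sequences of :class:`ParticipantRecord`).  Raises
    :class:`SchemaError` on malformed input and stage-labelled
    :class:`RDSCompareError` subclasses otherwise.
    """
    config = config or AnalysisConfig()
    pr_records, pr_flags = _coerce_records(pr)
    rds_records, _ = _coerce_records(rds)
    if not pr_records and not rds_records:
        raise SchemaError("no input records in either arm")

    exclusions: list[dict] = []
    recruitment: dict = {}
    response: dict = {}
    tables: dict[str, list] = {"table1": [], "table2": [], "table3": []}
    comparisons: list[dict] = []
    equilibrium_block: list[dict] = []
    network_block: dict = {}

    # ---- PR arm -----------------------------------------------------------
    pr_study: list[ParticipantRecord] = []
    if pr_records:
        if any(r.arm != "PR" for r in pr_records):
            raise SchemaError("pr table contains non-PR records")
        pr_study = [r for r in pr_records if r.complete]
        recruitment["pr_drawn"] = len(pr_records)
        recruitment["pr_completed"] = len(pr_study)
        if pr_flags is not None and "invalid" in pr_flags.columns:
            invalid = int(pr_flags["invalid"].astype(bool).sum())
            recruitment["pr_invalid"] = invalid
            recruitment["pr_invited"] = len(pr_records) - invalid
            response["rate_percent"] = response_rate(
                len(pr_study), len(pr_records), invalid
            )

    # ---- RDS arm ----------------------------------------------------------
    rds_analysis: list[ParticipantRecord] = []
    weights = None
    forest = None
    if rds_records:
        forest = build_forest(rds_records)
        analysis_ids = filter_analysis_set(forest, min_wave=config.min_wave)
        rds_analysis = [forest.records[pid] for pid in sorted(analysis_ids)]
        recruitment["rds_total"] = forest.size
        recruitment["rds_seeds"] = len(forest.seeds)
        recruitment["rds_analysis_set"] = len(rds_analysis)
        recruitment["rds_chains_retained"] = len(
            {forest.chain[r.participant_id] for r in rds_analysis}
        )
        if rds_analysis:
            degrees = {}
            for r in rds_analysis:
                if r.network_size is None:
                    raise SchemaError(
                        f"RDS analysis participant {r.participant_id!r} has "
                        "no network_size; weights are undefined"
                    )
                degrees[r.participant_id] = r.network_size
            weights = est.rds_weights(
                degrees,
                {r.participant_id: forest.chain[r.participant_id]
                 for r in rds_analysis},
                cap=config.degree_cap,
            )
        for var in sorted({v for r in rds_records for v in r.attributes}):
            try:
                equilibrium_block.append(
                    eq.equilibrium_report(
                        forest, var, tolerance=config.equilibrium_tolerance
                    )
                )
            except RDSCompareError as exc:
                equilibrium_block.append({"attribute": var, "skipped": str(exc)})

    # ---- variable lists ---------------------------------------------------
    all_attrs = sorted(
        {v for r in (list(pr_records) + list(rds_records)) for v in r.attributes}
    )
    t1 = [v for v in config.table1_variables if v in all_attrs]
    t3 = (
        [v for v in DEFAULT_TABLE3 if v in all_attrs]
        if config.table3_variables is None
        else [v for v in config.table3_variables if v in all_attrs]
    )
    t2 = (
        [v for v in all_attrs if v not in t1 and v not in t3]
        if config.table2_variables is None
        else [v for v in config.table2_variables if v in all_attrs]
    )

    def weighted_estimates(var):
        vals = _values_of(rds_analysis, var, config)
        if weights is None or set(vals) != set(weights.weights):
            return None
        return est.rds_weighted_ci(vals, weights, level=config.level)

    def add_variable(table: str, var: str) -> None:
        arms: dict[str, list[str]] = {}
        if table == "table1" and pr_records:
            arms["pr_sample"] = [
                _mapped(r.attributes[var], var, config)
                for r in pr_records if var in r.attributes
            ]
        if pr_study:
            arms["pr_study"] = [
                _mapped(r.attributes[var], var, config)
                for r in pr_study if var in r.attributes
            ]
        if rds_analysis:
            arms["rds_unweighted"] = [
                _mapped(r.attributes[var], var, config)
                for r in rds_analysis if var in r.attributes
            ]

        # rare-category exclusion, judged on the two study populations
        study_vals = arms.get("pr_study", []) + arms.get("rds_unweighted", [])
        rare = {
            c for c in set(study_vals)
            if study_vals.count(c) < config.min_count
        }
        if rare:
            exclusions.append(
                {"variable": var, "categories": sorted(rare),
                 "reason": f"fewer than {config.min_count} cases"}
            )

        for arm, vals in arms.items():
            if vals:
                tables[table].extend(
                    _count_rows(vals, var, arm, config.level)
                )
        west = None
        if rds_analysis and weights is not None:
            try:
                west = weighted_estimates(var)
            except RDSCompareError as exc:
                exclusions.append(
                    {"variable": var, "categories": [],
                     "reason": f"weighted estimate failed: {exc}"}
                )
        if west:
            tables[table].extend(
                {"variable": var, "category": c, "arm": "rds_weighted",
                 **pe.to_dict()}
                for c, pe in west.items()
            )

        # two-arm comparisons between the study populations
        pv = arms.get("pr_study", [])
        rv = arms.get("rds_unweighted", [])
        if not pv or not rv:
            return
        cats = sorted((set(pv) | set(rv)) - rare)
        if len(cats) < 2:
            exclusions.append(
                {"variable": var, "categories": cats,
                 "reason": "fewer than 2 usable categories; comparison skipped"}
            )
            return
        counts = [[pv.count(c) for c in cats], [rv.count(c) for c in cats]]
        comp: dict = {"variable": var, "categories": cats,
                      "arms": ["pr_study", "rds_unweighted"],
                      "table": counts}
        try:
            res = st.pearson_chi2(counts)
            comp["unweighted"] = res.to_dict()
            comp["unweighted"]["significant"] = bool(res.p_value < config.alpha)
        except RDSCompareError as exc:
            comp["unweighted"] = {"skipped": str(exc)}
        if west is not None and all(c in west for c in cats):
            n_rds = len(rds_analysis)
            scaled = [
                [pv.count(c) for c in cats],
                [west[c].estimate / 100.0 * n_rds for c in cats],
            ]
            vals = _values_of(rds_analysis, var, config)
            try:
                dhat = st.estimate_design_effect(vals, weights)
                res = st.rao_scott_chi2(
                    scaled,
                    design_effect=dhat,
                    continuity=config.continuity_2x2 and len(cats) == 2,
                )
                comp["weighted"] = res.to_dict()
                comp["weighted"]["table"] = scaled
                comp["weighted"]["significant"] = bool(
                    res.p_value < config.alpha
                )
            except RDSCompareError as exc:
                comp["weighted"] = {"skipped": str(exc)}
        comparisons.append(comp)

    for var in t1:
        add_variable("table1", var)
    for var in t2:
        add_variable("table2", var)
    for var in t3:
        add_variable("table3", var)

    # ---- network size -----------------------------------------------------
    if config.network_size_variable:
        pr_sizes = [r.network_size for r in pr_study if r.network_size is not None]
        rds_sizes = [r.network_size for r in rds_analysis
                     if r.network_size is not None]
        if pr_sizes:
            a = np.asarray(pr_sizes, dtype=float)
            network_block["pr_mean"] = float(a.mean())
            network_block["pr_se"] = float(a.std(ddof=1) / np.sqrt(a.size))
            network_block["pr_n"] = int(a.size)
        if rds_sizes:
            b = np.asarray(rds_sizes, dtype=float)
            network_block["rds_mean"] = float(b.mean())
            network_block["rds_se"] = float(b.std(ddof=1) / np.sqrt(b.size))
            network_block["rds_n"] = int(b.size)
            if weights is not None:
                wm, wse = est.weighted_mean_se(
                    {r.participant_id: float(r.network_size)
                     for r in rds_analysis}, weights
                )
                network_block["rds_weighted_mean"] = wm
                network_block["rds_weighted_se"] = wse
        if pr_sizes and rds_sizes and len(pr_sizes) >= 2 and len(rds_sizes) >= 2:
            network_block["t_test"] = st.welch_t_test(pr_sizes, rds_sizes).to_dict()
            y = np.concatenate([pr_sizes, rds_sizes])
            g = np.concatenate([np.zeros(len(pr_sizes)), np.ones(len(rds_sizes))])
            try:
                nb = st.negbin_regression(y, g)
                network_block["negbin_unweighted"] = {
                    "coefficient": nb.coefficient, "se": nb.se,
                    "p_value": nb.p_value, "alpha": nb.alpha,
                }
                if weights is not None:
                    w_rds = np.array(
                        [weights.weights[r.participant_id] for r in rds_analysis]
                    )
                    w = np.concatenate(
                        [np.ones(len(pr_sizes)), w_rds * len(rds_analysis)]
                    )
                    nbw = st.negbin_regression(y, g, weights=w)
                    network_block["negbin_weighted"] = {
                        "coefficient": nbw.coefficient, "se": nbw.se,
                        "p_value": nbw.p_value, "alpha": nbw.alpha,
                    }
            except RDSCompareError as exc:
                network_block["negbin_skipped"] = str(exc)

    cfg_dict = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    provenance = {
        "config": cfg_dict,
        "config_sha256": digest,
        "n_pr_input": len(pr_records),
        "n_rds_input": len(rds_records),
        "package": "rdscompare",
        "alpha_note": f"significance flags at alpha={config.alpha}, "
                      "no multiple-testing adjustment",
    }
    return StudyReport(
        schema_version=SCHEMA_VERSION,
        provenance=provenance,
        recruitment=recruitment,
        response=response,
        tables=tables,
        comparisons=comparisons,
        equilibrium=equilibrium_block,
        network_size=network_block,
        exclusions=exclusions,
    )


def render_tables(report: StudyReport, out_dir, fmt: str = "csv") -> list[str]:
    """Write the report; ``fmt`` is ``"csv"`` (three delimited tables +
    comparisons) or ``"json"`` (single report file).  Percentages are
    rendered to one decimal (half-up), intervals as ``"low to high"``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    written = []
    if fmt == "json":
        path = os.path.join(out_dir, "report.json")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(report.to_json())
        return [path]
    if fmt != "csv":
        raise InputError(f"unknown report format {fmt!r}")
    for name, rows in report.tables.items():
        path = os.path.join(out_dir, f"{name}.csv")
        recs = []
        for r in rows:
            recs.append(
                {
                    "variable": r["variable"],
                    "category": r["category"],
                    "arm": r["arm"],
                    "n": r["n"],
                    "x": r["x"],
                    "percent": est.format_percent(r["estimate"]),
                    "ci": (
                        f"{est.format_percent(r['ci_low'])} to "
                        f"{est.format_percent(r['ci_high'])}"
                        if r["ci_low"] is not None
                        else ""
                    ),
                    "method": r["method"],
                }
            )
        pd.DataFrame(
            recs,
            columns=["variable", "category", "arm", "n", "x", "percent",
                     "ci", "method"],
        ).to_csv(path, index=False)
        written.append(path)
    comp_rows = []
    for c in report.comparisons:
        for kind in ("unweighted", "weighted"):
            if kind in c and "skipped" not in c[kind]:
                comp_rows.append(
                    {
                        "variable": c["variable"],
                        "comparison": kind,
                        "statistic": c[kind]["statistic"],
                        "df": c[kind]["df"],
                        "p_value": c[kind]["p_value"],
                        "correction": c[kind]["correction"],
                        "design_effect": c[kind]["design_effect"],
                    }
                )
    path = os.path.join(out_dir, "comparisons.csv")
    pd.DataFrame(
        comp_rows,
        columns=["variable", "comparison", "statistic", "df", "p_value",
                 "correction", "design_effect"],
    ).to_csv(path, index=False)
    written.append(path)
    return written
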