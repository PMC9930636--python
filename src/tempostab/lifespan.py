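"""Cohort-level analysis: age binning, group tests, lifespan regression.

Subjects are partitioned into three lifespan cohorts (young 18-40, middle
41-60, old 61-88) and into 5-year bins starting at 18 (the first bin is
18-20 and the last 81-88). Entropy (or any per-subject stability summary)
is compared across groups with the Wilcoxon rank-sum test and across
conditions within subject with the Wilcoxon signed-rank test, after
normality screening (Jarque-Bera and D'Agostino-Pearson omnibus); p-values
are reported uncorrected. The lifespan trend is summarized by a quadratic
regression E ~ b0 + b1*age + b2*age^2 with the age term mean-centered, whose
curvature sign distinguishes U-shaped from inverted-U trajectories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import (
    BoldTimeSeries,
    NetworkDefinition,
    SubjectTable,
    default_networks,
    read_subject_table,
    read_timeseries,
    read_network_definition,
    write_matrix,
)

__all__ = [
    "AGE_BINS",
    "CohortAssignment",
    "GroupComparisonResult",
    "LifespanRegressionFit",
    "assign_cohorts",
    "compare_groups",
    "ushape_regression",
    "network_subset",
    "run_pipeline",
]

logger = logging.getLogger("tempostab")

AGE_BINS: list[tuple[int, int]] = [(18, 20)] + [
    (lo, lo + 4) for lo in range(21, 77, 5)
] + [(81, 88)]

GROUP_RANGES = {"young": (18, 40), "middle": (41, 60), "old": (61, 88)}


@dataclass
class CohortAssignment:
    subject_id: str
    age_years: float
    group: str
    age_bin: str


def _bin_label(age: float) -> str:
    for lo, hi in AGE_BINS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"age {age} outside the lifespan range [18, 88]")


def _group_label(age: float) -> str:
    for name, (lo, hi) in GROUP_RANGES.items():
        if lo <= age <= hi:
            return name
    raise ValueError(f"age {age} outside the lifespan range [18, 88]")


def assign_cohorts(table: SubjectTable | pd.DataFrame) -> list[CohortAssignment]:
    """Deterministic 5-year bin and lifespan group for every subject.

    Ages are binned by integer truncation, so bins tile [18, 88] without
    overlap (e.g. 40.7 falls in 36-40 and group young).
    """
    frame = table.frame if isinstance(table, SubjectTable) else table
    ages = frame.groupby("subject_id")["age_years"].first()
    bad = [s for s, a in ages.items() if not 18 <= a <= 88]
    if bad:
        raise ValueError(f"ages outside [18, 88] for subjects: {bad}")
    return [
        CohortAssignment(
            subject_id=str(sid),
            age_years=float(age),
            group=_group_label(int(np.floor(age))),
            age_bin=_bin_label(int(np.floor(age))),
        )
        for sid, age in ages.items()
    ]


@dataclass
class GroupComparisonResult:
    test: str  # "wilcoxon_rank_sum" | "wilcoxon_sign_rank"
    statistic: float
    p_value: float
    group_labels: tuple[str, str]
    normality_flags: dict = field(default_factory=dict)


def _normality_flags(values: np.ndarray, label: str) -> dict:
    out: dict = {}
    v = np.asarray(values, float)
    if len(v) >= 8 and np.ptp(v) > 0:
        jb = stats.jarque_bera(v)
        dp = stats.normaltest(v)
        out[label] = {
            "jarque_bera_p": float(jb.pvalue),
            "dagostino_pearson_p": float(dp.pvalue),
        }
    else:
        out[label] = {"jarque_bera_p": float("nan"), "dagostino_pearson_p": float("nan")}
    return out


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]], paired: bool = False
) -> GroupComparisonResult:
    """Nonparametric two-sample comparison with normality screening.

    Unpaired samples use the Wilcoxon rank-sum test; paired samples (e.g.
    the same subjects under two conditions) the Wilcoxon signed-rank test.
    P-values are raw (uncorrected).
    """
    if len(values_by_group) != 2:
        raise ValueError(
            f"expected exactly 2 groups, got {len(values_by_group)}: "
            f"{sorted(values_by_group)}"
        )
    (la, va), (lb, vb) = [(k, np.asarray(v, float)) for k, v in values_by_group.items()]
    if min(len(va), len(vb)) < 3:
        raise ValueError("need at least 3 values per group")
    flags = {**_normality_flags(va, la), **_normality_flags(vb, lb)}
    if paired:
        if len(va) != len(vb):
            raise ValueError(
                f"paired comparison requires equal lengths ({len(va)} vs {len(vb)})"
            )
        if np.all(va == vb):
            raise ValueError(
                "all paired differences are zero; the signed-rank test is degenerate"
            )
        stat, p = stats.wilcoxon(va, vb)
        test = "wilcoxon_sign_rank"
    else:
        stat, p = stats.ranksums(va, vb)
        test = "wilcoxon_rank_sum"
    return GroupComparisonResult(
        test=test,
        statistic=float(stat),
        p_value=float(p),
        group_labels=(la, lb),
        normality_flags=flags,
    )


@dataclass
class LifespanRegressionFit:
    coefficients: dict  # intercept, age, age2 (age mean-centered)
    p_values: dict
    r_squared: float
    curvature_sign: int
    age_mean: float
    n: int


def ushape_regression(ages, values) -> LifespanRegressionFit:
    """Quadratic-in-age least squares fit of a per-subject summary.

    Age is mean-centered before squaring for conditioning. A positive
    age^2 coefficient indicates a U shape (minimum in midlife); negative,
    an inverted U.
    """
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    if len(ages) != len(values):
        raise ValueError("ages and values must be the same length")
    if len(ages) < 10:
        raise ValueError(f"need n >= 10 for the quadratic fit, got {len(ages)}")
    if np.var(ages) == 0:
        raise ValueError("age variance is zero; the design is rank-deficient")
    a = ages - ages.mean()
    design = np.column_stack([np.ones_like(a), a, a**2])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient quadratic design (too few distinct ages)")
    fit = sm.OLS(values, design).fit()
    coefs = dict(zip(("intercept", "age", "age2"), map(float, fit.params)))
    pvals = dict(zip(("intercept", "age", "age2"), map(float, fit.pvalues)))
    return LifespanRegressionFit(
        coefficients=coefs,
        p_values=pvals,
        r_squared=float(fit.rsquared),
        curvature_sign=int(np.sign(coefs["age2"])),
        age_mean=float(ages.mean()),
        n=len(ages),
    )


def network_subset(ts: BoldTimeSeries, net: NetworkDefinition) -> BoldTimeSeries:
    """Restrict a time series to a named network's regions (order preserved)."""
    if net.n_atlas_regions is not None and net.n_atlas_regions != ts.n_regions:
        # network defined for a different atlas size; validate against ts
        pass
    idx = net.zero_based()
    if idx.max() >= ts.n_regions:
        raise ValueError(
            f"network {net.name!r} index {idx.max() + 1} exceeds the series' "
            f"{ts.n_regions} regions"
        )
    return BoldTimeSeries(
        values=ts.values[idx, :],
        tr_seconds=ts.tr_seconds,
        region_labels=[ts.region_labels[i] for i in idx],
        subject_id=ts.subject_id,
        condition=ts.condition,
    )


# ---------------------------------------------------------------------------
# end-to-end orchestration


def run_pipeline(
    config: Mapping | str | Path,
    series: Mapping[tuple[str, str], BoldTimeSeries] | None = None,
) -> dict:
    """Run the full per-subject stability analysis plus group statistics.

    ``config`` is a mapping (or a YAML file path) with keys:

    - ``subjects``: path to the manifest CSV (subject_id, age_years,
      condition, path) — optional when ``series`` supplies data in memory
      along with a ``subject_table`` entry;
    - ``tr_seconds`` (default 2.0), ``estimator`` (``phase`` | ``window``),
      ``window_length``, ``k`` (default 3), ``metrics`` (default
      ``["angle"]``), ``networks`` (path, ``"default"``, or null for whole
      brain only), ``bins`` (default 256), ``ar`` (bool), ``ar_max_order``,
      ``ar_lag``, ``outdir``.

    Results: per-subject stability matrices (written when ``outdir`` is
    set), an entropy table, pairwise group tests, and the lifespan
    quadratic fit per condition. Deterministic for a fixed config.
    """
    import yaml

    from .model import TemporalStabilityModel

    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text())
    cfg = dict(config)

    outdir = Path(cfg["outdir"]) if cfg.get("outdir") else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "pipeline.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    if "subject_table" in cfg and series is not None:
        table = cfg["subject_table"]
        if not isinstance(table, SubjectTable):
            table = SubjectTable(pd.DataFrame(table))
    else:
        table = read_subject_table(cfg["subjects"])
    tr = float(cfg.get("tr_seconds", 2.0))
    estimator = cfg.get("estimator", "phase")
    metrics = list(cfg.get("metrics", ["angle"]))
    k = int(cfg.get("k", 3))
    bins = int(cfg.get("bins", 256))
    do_ar = bool(cfg.get("ar", False))

    networks: list[NetworkDefinition | None] = [None]
    net_cfg = cfg.get("networks")
    if net_cfg == "default":
        networks = [None] + [n for n in default_networks() if n.name != "whole_brain"]
    elif net_cfg:
        networks = [None] + read_network_definition(net_cfg)

    entropy_rows = []
    ar_rows = []
    matrices: dict[tuple, np.ndarray] = {}
    for _, row in table.frame.iterrows():
        sid, cond = str(row.subject_id), str(row.condition)
        if series is not None and (sid, cond) in series:
            ts = series[(sid, cond)]
        else:
            p = Path(row.path)
            if not p.exists():
                raise FileNotFoundError(
                    f"time series for subject {sid}, condition {cond} not found: {p}"
                )
            ts = read_timeseries(p, tr_seconds=tr, subject_id=sid,
                                 condition=cond if cond in ("rest", "movie", "smt") else "synthetic")
        for net in networks:
            sub_ts = network_subset(ts, net) if net is not None else ts
            net_name = net.name if net is not None else "whole_brain"
            logger.info("subject=%s condition=%s network=%s: fitting", sid, cond, net_name)
            try:
                model = TemporalStabilityModel(
                    sub_ts,
                    estimator="phase_coherence" if estimator == "phase" else "sliding_window",
                    window_length=cfg.get("window_length"),
                    k=k,
                )
                res = model.fit(
                    metrics=metrics,
                    bins=bins,
                    compute_ar=do_ar,
                    ar_max_order=int(cfg.get("ar_max_order", 20)),
                    ar_lag=int(cfg.get("ar_lag", 1)),
                )
            except Exception as err:
                logger.error(
                    "subject=%s condition=%s network=%s failed: %s", sid, cond, net_name, err
                )
                raise RuntimeError(
                    f"pipeline failed for subject {sid}, condition {cond}, "
                    f"network {net_name}: {err}"
                ) from err
            for metric in metrics:
                mat = res.stability[metric].values
                matrices[(sid, cond, net_name, metric)] = mat
                if outdir is not None:
                    write_matrix(
                        mat, outdir / f"{sid}_{cond}_{net_name}_{metric}_stability.csv"
                    )
                entropy_rows.append(
                    {
                        "subject_id": sid,
                        "age_years": float(row.age_years),
                        "condition": cond,
                        "network": net_name,
                        "metric": metric,
                        "entropy": res.entropy[metric].entropy_bits,
                    }
                )
                if do_ar:
                    sel = res.ar_selection[metric]
                    ar_rows.append(
                        {
                            "subject_id": sid,
                            "condition": cond,
                            "network": net_name,
                            "metric": metric,
                            "selected_order": sel.selected_order,
                            "aic_min": float(np.min(sel.aic_curve)),
                        }
                    )

    entropy_table = pd.DataFrame(entropy_rows)

    # group statistics per metric/network: condition pairs (paired within
    # subject, signed-rank) and lifespan groups within condition (rank-sum)
    assignments = {a.subject_id: a for a in assign_cohorts(table)}
    test_rows = []
    for (metric, net_name), sub in entropy_table.groupby(["metric", "network"]):
        conds = sorted(sub.condition.unique())
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                a = sub[sub.condition == conds[i]].set_index("subject_id").entropy
                b = sub[sub.condition == conds[j]].set_index("subject_id").entropy
                common = a.index.intersection(b.index)
                if len(common) >= 3:
                    try:
                        r = compare_groups(
                            {conds[i]: a[common].values, conds[j]: b[common].values},
                            paired=True,
                        )
                    except ValueError as err:
                        logger.warning("condition test %s vs %s skipped: %s",
                                       conds[i], conds[j], err)
                        continue
                    test_rows.append(
                        {
                            "metric": metric, "network": net_name,
                            "comparison": f"{conds[i]}_vs_{conds[j]}",
                            "test": r.test, "statistic": r.statistic, "p_value": r.p_value,
                        }
                    )
        for cond in conds:
            sc = sub[sub.condition == cond]
            by_group: dict[str, np.ndarray] = {}
            for g in ("young", "middle", "old"):
                ids = [s for s, a in assignments.items() if a.group == g]
                vals = sc[sc.subject_id.isin(ids)].entropy.values
                if len(vals) >= 3:
                    by_group[g] = vals
            groups = sorted(by_group)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    r = compare_groups(
                        {groups[i]: by_group[groups[i]], groups[j]: by_group[groups[j]]},
                        paired=False,
                    )
                    test_rows.append(
                        {
                            "metric": metric, "network": net_name,
                            "comparison": f"{cond}:{groups[i]}_vs_{groups[j]}",
                            "test": r.test, "statistic": r.statistic, "p_value": r.p_value,
                        }
                    )
    group_tests = pd.DataFrame(test_rows)

    lifespan_fits = {}
    for (metric, net_name, cond), sub in entropy_table.groupby(
        ["metric", "network", "condition"]
    ):
        if len(sub) >= 10 and sub.age_years.nunique() >= 3:
            fit = ushape_regression(sub.age_years.values, sub.entropy.values)
            lifespan_fits[f"{metric}:{net_name}:{cond}"] = {
                "coefficients": fit.coefficients,
                "p_values": fit.p_values,
                "r_squared": fit.r_squared,
                "curvature_sign": fit.curvature_sign,
                "n": fit.n,
            }

    if outdir is not None:
        entropy_table.to_csv(outdir / "entropy_table.csv", index=False)
        group_tests.to_csv(outdir / "group_tests.csv", index=False)
        (outdir / "lifespan_fit.json").write_text(json.dumps(lifespan_fits, indent=2))
        if ar_rows:
            pd.DataFrame(ar_rows).to_csv(outdir / "ar_orders.csv", index=False)

    return {
        "entropy_table": entropy_table,
        "group_tests": group_tests,
        "lifespan_fits": lifespan_fits,
        "ar_orders": pd.DataFrame(ar_rows) if ar_rows else None,
        "stability_matrices": matrices,
        "cohorts": list(assignments.values()),
    }
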