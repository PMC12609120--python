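"""Cohort-level aggregation, endotype/risk assignment and statistics.

Sections are averaged in two stages — sections within a pancreas region
first, then regions within a donor — so donors contribute equally no
matter how many sections were available per region.  Donor-level metric
vectors feed the group comparisons:

* two groups: Mann-Whitney U per metric, Benjamini-Hochberg adjustment
  across the metric family;
* three or more groups on one variable: Kruskal-Wallis with Tukey
  all-pairs post hoc;
* groups crossed with bins/classes: type-II two-factor ANOVA with a
  Tukey (all pairs) or Dunnett (each group vs control) post hoc, chosen
  explicitly, never inferred.

Type 1 diabetes donors are split into pancreatic endotypes by age at
clinical diagnosis (T1DE1 < 13 years, T1DE2 >= 13 years).
Autoantibody-positive donors without diabetes are called high risk of
progression when at least three of four indicators are present: genetic
risk score >= 50th percentile, reported insulitis, HLA class I
hyperexpression, IA2A positivity.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .pipeline import SectionProfile

__all__ = [
    "DonorRecord",
    "CohortResult",
    "AGE_BRACKETS",
    "ENDOTYPE_AGE_CUTOFF_YEARS",
    "aggregate_donor",
    "assign_endotype",
    "assign_aab_risk",
    "group_mean_ci",
    "mann_whitney_bh",
    "kruskal_tukey",
    "anova2_posthoc",
    "compare_groups",
    "pancreas_weight_foldchange",
    "spatial_plot",
]

logger = logging.getLogger("eoquant")

#: default age brackets (years): 0-1, 2-6, 7-12, 13-17, >=18
AGE_BRACKETS = ((0, 1), (2, 6), (7, 12), (13, 17), (18, float("inf")))
ENDOTYPE_AGE_CUTOFF_YEARS = 13.0
RISK_CRITERIA = ("grs_ge_50th", "insulitis_reported",
                 "hlaI_hyperexpression", "ia2a_positive")
MIN_GROUP_N = 3


@dataclass
class DonorRecord:
    """Demographics and clinical flags for one donor."""

    donor_id: str
    age_years: float
    group: str  # ND, T1D, AAb_single, AAb_multi
    age_at_diagnosis_years: float | None = None
    duration_years: float | None = None
    aab_flags: frozenset[str] = frozenset()  # subset of GADA/mIAA/IA2A/ZnT8A
    grs_ge_50th: bool | None = None
    insulitis_reported: bool | None = None
    hlaI_hyperexpression: bool | None = None
    pancreas_weight_g: float | None = None


@dataclass
class CohortResult:
    """Group summaries (mean with 95% CI) and the statistical test table."""

    group_summary: pd.DataFrame  # group, metric, mean, ci_lo, ci_hi, n
    tests: pd.DataFrame  # comparison, metric, statistic, p_raw, p_adj, procedure
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# aggregation


def aggregate_donor(sections: list[SectionProfile]) -> pd.Series:
    """Two-stage mean: sections -> pancreas region -> donor.

    Every metric is first averaged over the sections of each region,
    then across regions, so an over-sampled region does not dominate
    the donor value.
    """
    if not sections:
        raise ValueError("need at least one section")
    if any(s.tissue_area_mm2 <= 0 for s in sections):
        raise ValueError("section with zero tissue area")
    df = pd.DataFrame([s.metrics for s in sections])
    df["region"] = [s.region for s in sections]
    return df.groupby("region").mean().mean(axis=0)


def aggregate_cohort(sections: list[SectionProfile]) -> pd.DataFrame:
    """Donor-level metric table (one row per donor) from many sections."""
    by_donor: dict[str, list[SectionProfile]] = {}
    for s in sections:
        by_donor.setdefault(s.donor_id, []).append(s)
    rows = {d: aggregate_donor(ss) for d, ss in sorted(by_donor.items())}
    out = pd.DataFrame(rows).T
    out.index.name = "donor_id"
    return out


# ---------------------------------------------------------------------------
# endotype and risk


def assign_endotype(donor: DonorRecord) -> str:
    """T1DE1 (diagnosis < 13 y), T1DE2 (>= 13 y), or NA."""
    if donor.group != "T1D" or donor.age_at_diagnosis_years is None or \
            not np.isfinite(donor.age_at_diagnosis_years):
        return "NA"
    return ("T1DE1" if donor.age_at_diagnosis_years < ENDOTYPE_AGE_CUTOFF_YEARS
            else "T1DE2")


def assign_aab_risk(donor: DonorRecord) -> str:
    """High/low risk of progression for AAb+ donors; NA otherwise.

    High iff >= 3 of: GRS >= 50th percentile, reported insulitis, HLA-I
    hyperexpression, IA2A+.  A missing flag counts as false (logged).
    """
    if donor.group not in ("AAb_single", "AAb_multi"):
        return "NA"
    flags = {
        "grs_ge_50th": donor.grs_ge_50th,
        "insulitis_reported": donor.insulitis_reported,
        "hlaI_hyperexpression": donor.hlaI_hyperexpression,
        "ia2a_positive": "IA2A" in donor.aab_flags,
    }
    n_true = 0
    for name, value in flags.items():
        if value is None:
            logger.warning("donor %s: missing flag %s treated as false",
                           donor.donor_id, name)
            continue
        n_true += bool(value)
    return "high" if n_true >= 3 else "low"


# ---------------------------------------------------------------------------
# statistics


def group_mean_ci(metrics: pd.DataFrame, groups: pd.Series,
                  confidence: float = 0.95) -> pd.DataFrame:
    """Per-group mean and t-interval CI for every metric column."""
    rows = []
    for g, sub in metrics.groupby(groups):
        n = len(sub)
        for col in metrics.columns:
            vals = sub[col].dropna().to_numpy(float)
            mean = float(vals.mean()) if len(vals) else float("nan")
            if len(vals) > 1 and np.std(vals) > 0:
                sem = stats.sem(vals)
                half = sem * stats.t.ppf(0.5 + confidence / 2, len(vals) - 1)
            else:
                half = 0.0
            rows.append({"group": g, "metric": col, "n": n, "mean": mean,
                         "ci_lo": mean - half, "ci_hi": mean + half})
    return pd.DataFrame(rows)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min over j >= i of p_(j)·m/j, capped at 1; monotone
    non-decreasing with the rank of the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return float("nan"), 1.0  # degenerate: all tied
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_bh(metrics: pd.DataFrame, groups: pd.Series,
                    metric_family: list[str] | None = None) -> pd.DataFrame:
    """Mann-Whitney U per metric with BH adjustment across the family.

    Exactly two groups required, each with >= 3 donors (below that the
    comparison is skipped and flagged).
    """
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValueError("mann_whitney_bh needs exactly two groups")
    family = metric_family or list(metrics.columns)
    g0 = metrics.loc[groups == names[0], family]
    g1 = metrics.loc[groups == names[1], family]
    comparison = f"{names[0]} vs {names[1]}"
    if len(g0) < MIN_GROUP_N or len(g1) < MIN_GROUP_N:
        return pd.DataFrame([{
            "comparison": comparison, "metric": m, "statistic": float("nan"),
            "p_raw": float("nan"), "p_adj": float("nan"),
            "procedure": "mann-whitney+bh", "note": "skipped: n < 3"}
            for m in family])
    rows = []
    for m in family:
        u, p = _mwu(g0[m].to_numpy(float), g1[m].to_numpy(float))
        rows.append({"comparison": comparison, "metric": m,
                     "statistic": u, "p_raw": p,
                     "procedure": "mann-whitney+bh", "note": ""})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out[["comparison", "metric", "statistic", "p_raw", "p_adj",
                "procedure", "note"]]


def kruskal_tukey(values: pd.Series, groups: pd.Series,
                  metric: str = "value") -> pd.DataFrame:
    """Kruskal-Wallis across >= 3 groups, Tukey HSD all-pairs post hoc."""
    names = sorted(groups.unique())
    if len(names) < 3:
        raise ValueError("kruskal_tukey needs >= 3 groups")
    samples = [values[groups == g].dropna().to_numpy(float) for g in names]
    if any(len(s) < MIN_GROUP_N for s in samples):
        return pd.DataFrame([{"comparison": "omnibus", "metric": metric,
                              "statistic": float("nan"), "p_raw": float("nan"),
                              "p_adj": float("nan"),
                              "procedure": "kruskal-wallis",
                              "note": "skipped: n < 3"}])
    flat = np.concatenate(samples)
    if np.all(flat == flat[0]):
        h, p = float("nan"), 1.0
    else:
        h, p = stats.kruskal(*samples)
    rows = [{"comparison": "omnibus", "metric": metric, "statistic": float(h),
             "p_raw": float(p), "p_adj": float(p),
             "procedure": "kruskal-wallis", "note": ""}]
    tk = pairwise_tukeyhsd(values.to_numpy(float), groups.to_numpy(), alpha=0.05)
    frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    for _, r in frame.iterrows():
        rows.append({"comparison": f"{r['group1']} vs {r['group2']}",
                     "metric": metric, "statistic": float(r["meandiff"]),
                     "p_raw": float(r["p-adj"]), "p_adj": float(r["p-adj"]),
                     "procedure": "tukey", "note": ""})
    return pd.DataFrame(rows)


def anova2_posthoc(long: pd.DataFrame, value: str = "value",
                   group: str = "group", factor: str = "eo_bin",
                   posthoc: str = "tukey",
                   control: str | None = None) -> pd.DataFrame:
    """Type-II two-factor ANOVA (group x bin/class) with post hoc tests.

    ``posthoc`` is ``"tukey"`` (all pairs of groups within each factor
    level) or ``"dunnett"`` (each group vs ``control`` within each
    level); the choice is explicit, never inferred.
    """
    if posthoc == "dunnett" and control is None:
        raise ValueError("dunnett post hoc requires a control group")
    if posthoc not in ("tukey", "dunnett"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    df = long[[value, group, factor]].dropna().copy()
    df.columns = ["value", "grp", "fac"]
    model = smf.ols("value ~ C(grp) * C(fac)", data=df).fit()
    an = sm.stats.anova_lm(model, typ=2)
    rows = [{"comparison": term, "metric": value,
             "statistic": float(an.loc[term, "F"]),
             "p_raw": float(an.loc[term, "PR(>F)"]),
             "p_adj": float(an.loc[term, "PR(>F)"]),
             "procedure": "anova2-typeII", "note": ""}
            for term in an.index if term != "Residual"]
    for lev, sub in df.groupby("fac"):
        names = sorted(sub["grp"].unique())
        sizes = sub.groupby("grp").size()
        if len(names) < 2 or (sizes < MIN_GROUP_N).any():
            continue
        if posthoc == "tukey":
            tk = pairwise_tukeyhsd(sub["value"].to_numpy(float),
                                   sub["grp"].to_numpy(), alpha=0.05)
            frame = pd.DataFrame(tk.summary().data[1:],
                                 columns=tk.summary().data[0])
            for _, r in frame.iterrows():
                rows.append({
                    "comparison": f"{r['group1']} vs {r['group2']} @ {lev}",
                    "metric": value, "statistic": float(r["meandiff"]),
                    "p_raw": float(r["p-adj"]), "p_adj": float(r["p-adj"]),
                    "procedure": "tukey", "note": ""})
        elif posthoc == "dunnett":
            others = [g for g in names if g != control]
            if control not in names or not others:
                continue
            ctl = sub.loc[sub["grp"] == control, "value"].to_numpy(float)
            samp = [sub.loc[sub["grp"] == g, "value"].to_numpy(float)
                    for g in others]
            res = stats.dunnett(*samp, control=ctl)
            for g, stat, p in zip(others, np.atleast_1d(res.statistic),
                                  np.atleast_1d(res.pvalue)):
                rows.append({"comparison": f"{g} vs {control} @ {lev}",
                             "metric": value, "statistic": float(stat),
                             "p_raw": float(p), "p_adj": float(p),
                             "procedure": "dunnett", "note": ""})
    return pd.DataFrame(rows)


def compare_groups(metrics: pd.DataFrame, groups: pd.Series,
                   metric_family: list[str] | None = None,
                   posthoc: str = "tukey",
                   control: str | None = None) -> CohortResult:
    """Dispatch the comparison matching the design.

    Two groups: Mann-Whitney + BH across the metric family.  Three or
    more: Kruskal-Wallis + Tukey per metric.  Groups with fewer than 3
    donors cause the affected tests to be skipped and flagged.
    """
    family = metric_family or list(metrics.columns)
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if n_groups == 2:
        tests = mann_whitney_bh(metrics, groups, family)
    else:
        tests = pd.concat(
            [kruskal_tukey(metrics[m], groups, metric=m) for m in family],
            ignore_index=True)
    summary = group_mean_ci(metrics[family], groups)
    return CohortResult(group_summary=summary, tests=tests,
                        config={"posthoc": posthoc, "control": control,
                                "family": family})


# ---------------------------------------------------------------------------
# pancreas weight


def pancreas_weight_foldchange(weights_by_bracket: dict | "pd.Series"
                               ) -> pd.DataFrame:
    """Fold change of median pancreas weight vs the previous age bracket.

    ``weights_by_bracket`` maps ordered bracket label -> sequence of
    weights (g).  The first bracket has no fold change; an empty bracket
    produces a gap, and the next fold is taken against the last
    non-empty bracket, flagged in the output.
    """
    labels = list(weights_by_bracket.keys())
    rows = []
    prev_median, prev_label = None, None
    for lab in labels:
        w = np.asarray(list(weights_by_bracket[lab]), dtype=float)
        if len(w) == 0:
            rows.append({"bracket": lab, "median_g": float("nan"),
                         "fold_change": float("nan"), "vs_bracket": None,
                         "note": "empty bracket"})
            continue
        med = float(np.median(w))
        if prev_median is None:
            rows.append({"bracket": lab, "median_g": med,
                         "fold_change": float("nan"), "vs_bracket": None,
                         "note": "first bracket"})
        else:
            note = ""
            if labels.index(lab) - labels.index(prev_label) > 1:
                note = f"previous bracket empty; compared to {prev_label}"
            rows.append({"bracket": lab, "median_g": med,
                         "fold_change": med / prev_median,
                         "vs_bracket": prev_label, "note": note})
        prev_median, prev_label = med, lab
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial plots


def spatial_plot(section: SectionProfile, path=None, color_by: str = "bin",
                 header: dict | None = None):
    """Scatter of EO centroids, point size proportional to size bin.

    ``color_by`` is ``"bin"`` (viridis over bins 0-9) or ``"class"``
    (one colour per content class).  Returns the matplotlib figure;
    saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    xs = [o.centroid[0] for o in section.objects]
    ys = [o.centroid[1] for o in section.objects]
    bins = np.array([o.eo_bin for o in section.objects], dtype=float)
    sizes = 8.0 + 14.0 * bins  # strictly increasing with bin
    if color_by == "class":
        palette = {"InsOnly": "#1b9e77", "InsGluc": "#7570b3",
                   "GlucOnly": "#d95f02"}
        colors = [palette.get(o.content_class, "grey")
                  for o in section.objects]
        sc = ax.scatter(xs, ys, s=sizes, c=colors, alpha=0.8,
                        edgecolors="none")
    else:
        sc = ax.scatter(xs, ys, s=sizes, c=bins, cmap="viridis",
                        vmin=0, vmax=9, alpha=0.8, edgecolors="none")
        fig.colorbar(sc, ax=ax, label="EO bin")
    parts = [f"{section.donor_id} {section.region}"]
    for key in ("age", "group", "duration"):
        if header and key in header:
            parts.append(f"{key}: {header[key]}")
    ax.set_title(" | ".join(parts), fontsize=9)
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.invert_yaxis()  # image convention: origin top-left
    ax.set_aspect("equal")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
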