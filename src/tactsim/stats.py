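"""Group statistics and correlation screens for the battery outcomes.

Group comparisons are ordinary least-squares linear models of the form
``outcome ~ group + age + group:age``. The group main effect is reported
with its F statistic and partial eta squared (type-II sums of squares,
interaction retained); pairwise contrasts between the age-adjusted group
means use Tukey's studentized-range procedure over the family of group
estimates, with Cohen's d defined as the adjusted mean difference over
the pooled residual standard deviation.

Correlation screens are Pearson correlations between a tactile metric
and each subscale of a questionnaire, with Bonferroni adjustment by the
number of subscales in that questionnaire (p multiplied, capped at 1).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.stats import studentized_range

from .instruments import INSTRUMENTS, SCREENS, mask_for


@dataclass(frozen=True)
class ContrastResult:
    """One Tukey-adjusted pairwise contrast (``group_b`` minus ``group_a``)."""

    group_a: str
    group_b: str
    estimate: float
    t: float
    df: float
    p_tukey: float
    cohens_d: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.group_a, self.group_b)


@dataclass(frozen=True)
class GroupComparisonResult:
    outcome: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float
    interaction_p: float
    interaction_flag: bool
    n: int
    contrasts: tuple[ContrastResult, ...] = field(default=())

    def contrast(self, group_a: str, group_b: str) -> ContrastResult:
        for c in self.contrasts:
            if c.pair == (group_a, group_b):
                return c
            if c.pair == (group_b, group_a):
                return ContrastResult(group_a, group_b, -c.estimate, -c.t,
                                      c.df, c.p_tukey, -c.cohens_d)
        raise KeyError((group_a, group_b))


def partial_eta_squared(model, term: str) -> float:
    """Partial eta squared SS_term / (SS_term + SS_residual) for a fitted OLS."""
    aov = sm.stats.anova_lm(model, typ=2)
    if term not in aov.index:
        raise KeyError(f"term {term!r} not in model")
    ss_term = float(aov.loc[term, "sum_sq"])
    ss_resid = float(aov.loc["Residual", "sum_sq"])
    return partial_eta_squared_from_ss(ss_term, ss_resid)


def partial_eta_squared_from_ss(ss_term: float, ss_resid: float) -> float:
    if ss_term + ss_resid <= 0:
        raise ValueError("zero total variation")
    return ss_term / (ss_term + ss_resid)


def _order_groups(levels) -> list[str]:
    """TDC first (reference group for reading contrasts), then alphabetical."""
    levels = sorted(str(g) for g in levels)
    if "TDC" in levels:
        levels.remove("TDC")
        levels.insert(0, "TDC")
    return levels


def group_comparison(table: pd.DataFrame, outcome: str,
                     group_col: str = "group",
                     age_col: str | None = "age_years"
                     ) -> GroupComparisonResult:
    """Age-adjusted group comparison of one outcome column.

    Fits ``outcome ~ C(group) * age`` and reports the group main effect
    (type-II F, p, partial eta squared) with the interaction retained and
    flagged when its p < 0.05. All pairwise contrasts are always computed
    (from the additive model's adjusted means) with Tukey-adjusted p
    values for the family of group estimates. With ``age_col=None`` the
    model reduces to a classical one-way layout.
    """
    cols = [outcome, group_col] + ([age_col] if age_col else [])
    data = table[cols].dropna()
    data = data.rename(columns={outcome: "y", group_col: "grp"})
    if age_col:
        data = data.rename(columns={age_col: "age"})
    data["grp"] = data["grp"].astype(str)
    counts = data["grp"].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 observations each")
    groups = _order_groups(counts.index)
    data["grp"] = pd.Categorical(data["grp"], categories=groups)

    full_formula = "y ~ C(grp) * age" if age_col else "y ~ C(grp)"
    full = smf.ols(full_formula, data=data).fit()
    aov = sm.stats.anova_lm(full, typ=2)
    ss_grp = float(aov.loc["C(grp)", "sum_sq"])
    ss_resid = float(aov.loc["Residual", "sum_sq"])
    inter_p = float(aov.loc["C(grp):age", "PR(>F)"]) if age_col else float("nan")

    additive_formula = "y ~ C(grp) + age" if age_col else "y ~ C(grp)"
    additive = smf.ols(additive_formula, data=data).fit()
    k = len(groups)
    dfr = float(additive.df_resid)
    mse = float(additive.mse_resid)
    params = additive.params
    cov = additive.cov_params()

    def coef_name(g: str) -> str | None:
        return None if g == groups[0] else f"C(grp)[T.{g}]"

    contrasts = []
    for ga, gb in itertools.combinations(groups, 2):
        c = pd.Series(0.0, index=params.index)
        for g, sign in ((gb, 1.0), (ga, -1.0)):
            name = coef_name(g)
            if name is not None:
                c[name] += sign
        est = float(c @ params)
        se = math.sqrt(float(c @ cov @ c))
        t = est / se
        p_tuk = float(studentized_range.sf(abs(t) * math.sqrt(2.0), k, dfr))
        contrasts.append(ContrastResult(ga, gb, est, t, dfr, min(p_tuk, 1.0),
                                        est / math.sqrt(mse)))

    return GroupComparisonResult(
        outcome=outcome,
        F=float(aov.loc["C(grp)", "F"]),
        df_num=float(aov.loc["C(grp)", "df"]),
        df_den=float(aov.loc["Residual", "df"]),
        p=float(aov.loc["C(grp)", "PR(>F)"]),
        partial_eta_sq=partial_eta_squared_from_ss(ss_grp, ss_resid),
        interaction_p=inter_p,
        interaction_flag=bool(inter_p < 0.05),
        n=len(data),
        contrasts=tuple(contrasts),
    )


def age_adjusted_cohens_d(table: pd.DataFrame, outcome: str, group_b: str,
                          group_a: str = "TDC", group_col: str = "group",
                          age_col: str = "age_years") -> float:
    """Cohen's d for ``group_b`` vs ``group_a``, adjusted for age.

    Lightweight two-group path (plain least squares on
    ``[1, is_group_b, age]``) used inside calibration loops; agrees with
    the corresponding :func:`group_comparison` contrast.
    """
    sub = table[table[group_col].isin((group_a, group_b))]
    sub = sub[[outcome, group_col, age_col]].dropna()
    y = sub[outcome].to_numpy(float)
    g = (sub[group_col] == group_b).to_numpy(float)
    age = sub[age_col].to_numpy(float)
    n = y.size
    if n < 4 or g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("need >= 2 observations per group")
    X = np.column_stack([np.ones(n), g, age])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = math.sqrt(float(resid @ resid) / (n - 3))
    return float(beta[1]) / sd


@dataclass(frozen=True)
class CorrelationResult:
    metric: str
    scale: str
    n: int
    r: float
    p_raw: float
    p_bonferroni: float
    multiplier: int

    @property
    def significant(self) -> bool:
        return self.p_bonferroni < 0.05

    @property
    def trend(self) -> bool:
        return self.p_bonferroni < 0.10


def correlate_bonferroni(metric: pd.Series, scales: pd.DataFrame,
                         multiplier: int,
                         metric_name: str | None = None
                         ) -> list[CorrelationResult]:
    """Pearson correlation screen of one metric against questionnaire subscales.

    Pairs are formed pairwise-complete; each subscale's two-sided p value
    is multiplied by ``multiplier`` and capped at 1.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    metric_name = metric_name or (metric.name or "metric")
    results = []
    for col in scales.columns:
        pair = pd.concat([metric, scales[col]], axis=1).dropna()
        if len(pair) < 3:
            raise ValueError(f"fewer than 3 complete pairs for {col}")
        x = pair.iloc[:, 0].to_numpy(float)
        y = pair.iloc[:, 1].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero-variance column in pair ({col})")
        r, p = sps.pearsonr(x, y)
        results.append(CorrelationResult(
            metric=metric_name, scale=str(col), n=len(pair),
            r=float(r), p_raw=float(p),
            p_bonferroni=min(1.0, float(p) * multiplier),
            multiplier=int(multiplier)))
    return results


# ---------------------------------------------------------------------------
# full analysis report

OUTCOME_METRICS = ("threshold", "median_rt_ms", "accuracy", "n_reversals")


def _threshold_wide(participants: pd.DataFrame,
                    outcomes: pd.DataFrame) -> pd.DataFrame:
    wide = outcomes.pivot(index="participant_id", columns="protocol_id",
                          values="threshold")
    wide.columns = [f"{c}_threshold" for c in wide.columns]
    return participants.set_index("participant_id").join(wide)


def analysis_report(participants: pd.DataFrame, outcomes: pd.DataFrame,
                    questionnaires: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """All group comparisons and correlation screens, as tidy tables.

    ``participants`` carries participant_id/group/age_years; ``outcomes``
    is the per-protocol outcome table; ``questionnaires`` is wide
    (participant_id plus one column per instrument subscale). Returns
    ``{"group_comparisons": ..., "contrasts": ..., "correlations": ...}``.
    The ``bf10`` column is a placeholder kept for schema compatibility.
    """
    merged = outcomes.merge(
        participants[["participant_id", "group", "age_years"]],
        on="participant_id", validate="many_to_one")

    gc_rows, ct_rows = [], []
    for protocol in sorted(merged["protocol_id"].unique()):
        sub = merged[merged["protocol_id"] == protocol]
        for metric in OUTCOME_METRICS:
            res = group_comparison(sub, metric)
            gc_rows.append(dict(
                protocol=protocol, outcome=metric, F=res.F,
                df_num=res.df_num, df_den=res.df_den, p=res.p,
                partial_eta_sq=res.partial_eta_sq,
                interaction_p=res.interaction_p,
                interaction_flag=res.interaction_flag, n=res.n, bf10=""))
            for c in res.contrasts:
                ct_rows.append(dict(
                    protocol=protocol, outcome=metric, group_a=c.group_a,
                    group_b=c.group_b, estimate=c.estimate, t=c.t, df=c.df,
                    p_tukey=c.p_tukey, cohens_d=c.cohens_d, bf10=""))

    thresholds = _threshold_wide(participants, outcomes)
    q = questionnaires.set_index("participant_id")
    q = q.reindex(thresholds.index)
    metric_cols = [c for c in thresholds.columns if c.endswith("_threshold")]

    corr_rows = []
    for screen, inst_names in SCREENS.items():
        for inst_name in inst_names:
            inst = INSTRUMENTS[inst_name]
            mask = mask_for(inst.analysis_mask, thresholds["group"])
            cols = [c for c in inst.columns() if c in q.columns]
            if not cols:
                continue
            scales = q.loc[mask, cols]
            for mcol in metric_cols:
                metric = thresholds.loc[mask, mcol]
                if metric.notna().sum() < 3:
                    continue
                for res in correlate_bonferroni(metric, scales,
                                                inst.multiplier, mcol):
                    corr_rows.append(dict(
                        screen=screen, instrument=inst_name,
                        metric=res.metric, scale=res.scale, n=res.n,
                        r=res.r, p_raw=res.p_raw,
                        p_bonferroni=res.p_bonferroni,
                        multiplier=res.multiplier,
                        significant=res.significant, trend=res.trend))

    return {
        "group_comparisons": pd.DataFrame(gc_rows),
        "contrasts": pd.DataFrame(ct_rows),
        "correlations": pd.DataFrame(corr_rows),
    }


def save_report(report: dict[str, pd.DataFrame], outdir) -> None:
    """Write the analysis report as CSV tables plus one combined JSON."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    combined = {}
    for name, df in report.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
        combined[name] = df.to_dict(orient="records")
    with open(outdir / "report.json", "w") as fh:
        json.dump(combined, fh, indent=2, default=str)
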