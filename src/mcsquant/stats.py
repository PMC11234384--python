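"""Group comparisons mirroring standard reporting in cell-biology imaging:
mean +/- s.d./s.e.m., two-tailed Student's t-tests, one-way ANOVA with
Tukey's test, and repeated-measures ANOVA with Bonferroni-adjusted paired
comparisons for matched experiments.  Significance threshold alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05

DESIGNS = ("two_group_paired", "two_group_unpaired", "oneway_tukey", "rm_bonferroni")


@dataclass
class StatsResult:
    summaries: pd.DataFrame  # group, n, mean, sd, sem
    omnibus_p: float
    pairwise: pd.DataFrame  # group1, group2, p_adj, significant
    method: str
    matched: bool = False

    @property
    def significant(self) -> bool:
        return self.omnibus_p < ALPHA


def _summarize(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for g, v in values_by_group.items():
        v = np.asarray(v, dtype=float)
        rows.append(
            {
                "group": g,
                "n": len(v),
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "sem": v.std(ddof=1) / np.sqrt(len(v)),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    values_by_group: dict[str, list | np.ndarray],
    design: str = "oneway_tukey",
    equal_var: bool = True,
    replicate_ids: dict[str, list] | None = None,
) -> StatsResult:
    """Compare groups with the named procedure; two-tailed throughout.

    ``two_group_*`` designs use Student's t (classical equal-variance by
    default; ``equal_var=False`` gives Welch).  ``oneway_tukey`` is one-way
    ANOVA with Tukey's HSD pairwise comparisons.  ``rm_bonferroni`` is a
    repeated-measures one-way ANOVA on complete blocks (every replicate
    measured in every condition) with Bonferroni-adjusted paired t-tests.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    names = list(groups)
    summaries = _summarize(groups)

    if design in ("two_group_paired", "two_group_unpaired"):
        if len(groups) != 2:
            raise ValueError("two-group designs require exactly two groups")
        a, b = (groups[n] for n in names)
        if design == "two_group_paired":
            if len(a) != len(b):
                raise ValueError("paired design requires equal group sizes")
            res = sps.ttest_rel(a, b)
        else:
            res = sps.ttest_ind(a, b, equal_var=equal_var)
        p = float(res.pvalue)
        if np.isnan(p):  # zero-variance degenerate case (identical groups)
            p = 1.0
        pairwise = pd.DataFrame(
            {
                "group1": [names[0]],
                "group2": [names[1]],
                "p_adj": [p],
                "significant": [p < ALPHA],
            }
        )
        return StatsResult(
            summaries,
            omnibus_p=p,
            pairwise=pairwise,
            method=design,
            matched=design == "two_group_paired",
        )

    if design == "oneway_tukey":
        omnibus = float(sps.f_oneway(*groups.values()).pvalue)
        values = np.concatenate([groups[n] for n in names])
        labels = np.concatenate([[n] * len(groups[n]) for n in names])
        tk = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
        tbl = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        pairwise = pd.DataFrame(
            {
                "group1": tbl["group1"],
                "group2": tbl["group2"],
                "p_adj": np.asarray(tk.pvalues, dtype=float),
                "significant": np.asarray(tk.reject, dtype=bool),
            }
        )
        return StatsResult(summaries, omnibus_p=omnibus, pairwise=pairwise, method=design)

    # rm_bonferroni: complete blocks required
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1:
        raise ValueError("repeated-measures design requires complete blocks")
    n_rep = sizes.pop()
    long = pd.DataFrame(
        {
            "value": np.concatenate([groups[n] for n in names]),
            "condition": np.concatenate([[n] * n_rep for n in names]),
            "subject": np.tile(np.arange(n_rep), len(names)),
        }
    )
    rm = AnovaRM(long, depvar="value", subject="subject", within=["condition"]).fit()
    omnibus = float(rm.anova_table["Pr > F"].iloc[0])
    pairs = list(combinations(names, 2))
    raw = [float(sps.ttest_rel(groups[g1], groups[g2]).pvalue) for g1, g2 in pairs]
    adj = np.minimum(np.asarray(raw) * len(pairs), 1.0)
    pairwise = pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "p_adj": adj,
            "significant": adj < ALPHA,
        }
    )
    return StatsResult(
        summaries, omnibus_p=omnibus, pairwise=pairwise, method=design, matched=True
    )
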