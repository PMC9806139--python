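"""Split-plot (mixed) ANOVA and post-hoc contrasts.

The study design is one between-subjects factor (lesion group) crossed
with one within-subjects factor (assessment day), each subject measured
at every day.  The classical univariate split-plot decomposition is

    SS_total = SS_group + SS_subj(group)  +  SS_time + SS_time:group + SS_error

with the group effect tested against the between-subject error
(subjects within groups) and the time and interaction effects against
the within-subject error.  With a single between factor the Type I/II
sums of squares for group coincide; for unbalanced group sizes the time
marginal means are sample-size weighted.  No sphericity correction is
applied — the random-intercept (compound-symmetric) error structure the
simulator produces satisfies sphericity, and uncorrected degrees of
freedom are reported.

Post hoc, group means are compared pairwise at each time point with
Fisher's LSD (unadjusted t tests, conventionally read only after a
significant omnibus F), and each group is compared across time points
with one-way ANOVA followed by Bonferroni-adjusted pairwise tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidParameterError

log = logging.getLogger(__name__)


@dataclass
class AnovaTerm:
    source: str
    ss: float
    df_num: int
    df_den: int
    ms: float
    f: float
    p: float


@dataclass
class MixedAnovaTable:
    """Split-plot decomposition: group, time and their interaction."""

    terms: dict[str, AnovaTerm]
    n_subjects: int
    group_sizes: dict[str, int]
    ss_subjects: float = 0.0
    ss_error: float = 0.0
    ms_subjects: float = float("nan")
    ms_error: float = float("nan")
    dropped_subjects: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": t.source,
                "SS": t.ss,
                "df_num": t.df_num,
                "df_den": t.df_den,
                "MS": t.ms,
                "F": t.f,
                "p": t.p,
            }
            for t in self.terms.values()
        ]
        return pd.DataFrame(rows)


def _f_ratio(ms_num: float, ms_den: float, df_num: int, df_den: int) -> tuple[float, float]:
    if ms_den <= 0.0 or df_den <= 0:
        return float("nan"), float("nan")
    f = ms_num / ms_den
    return f, float(sps.f.sf(f, df_num, df_den))


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "day",
    between: str = "group",
    subject: str = "subject",
) -> MixedAnovaTable:
    """Split-plot ANOVA of long-format measurements.

    Subjects with missing cells are dropped listwise with a logged
    warning.  Requires at least two groups and two time points.
    """
    df = data[[subject, between, within, dv]].dropna()
    counts = df.groupby(subject)[within].nunique()
    t = int(df[within].nunique())
    complete = counts[counts == t].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        log.warning("dropping %d subject(s) with incomplete time series: %s", len(dropped), dropped)
        df = df[df[subject].isin(complete)]
    groups = df.groupby(subject)[between].first()
    g = int(groups.nunique())
    n = int(groups.size)
    if g < 2 or t < 2:
        raise InsufficientDataError("mixed ANOVA needs >= 2 groups and >= 2 time points")
    if len(df) != n * t:
        raise InvalidParameterError("expected exactly one value per subject per time point")

    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = df.groupby(subject)[dv].mean()
    group_of = groups
    group_means = df.groupby(between)[dv].mean()
    time_means = df.groupby(within)[dv].mean()
    cell_means = df.groupby([between, within])[dv].mean()
    n_g = groups.value_counts().to_dict()

    ss_between_subj = t * float(((subj_means - grand) ** 2).sum())
    ss_group = t * float(sum(n_g[gr] * (group_means[gr] - grand) ** 2 for gr in n_g))
    ss_subj = ss_between_subj - ss_group
    ss_time = n * float(((time_means - grand) ** 2).sum())
    ss_cells = float(
        sum(
            n_g[gr] * (cell_means[(gr, tm)] - grand) ** 2
            for gr, tm in cell_means.index
        )
    )
    ss_inter = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_cells - ss_subj

    df_group, df_subj = g - 1, n - g
    df_time, df_inter = t - 1, (g - 1) * (t - 1)
    df_error = (n - g) * (t - 1)
    ms_subj = ss_subj / df_subj if df_subj else float("nan")
    ms_error = ss_error / df_error if df_error else float("nan")

    terms = {}
    for name, ss, dn, dd, ms_den in (
        ("group", ss_group, df_group, df_subj, ms_subj),
        ("time", ss_time, df_time, df_error, ms_error),
        ("time:group", ss_inter, df_inter, df_error, ms_error),
    ):
        ms = ss / dn
        f, p = _f_ratio(ms, ms_den, dn, dd)
        terms[name] = AnovaTerm(name, ss, dn, dd, ms, f, p)

    return MixedAnovaTable(
        terms=terms,
        n_subjects=n,
        group_sizes={str(k): int(v) for k, v in n_g.items()},
        ss_subjects=ss_subj,
        ss_error=ss_error,
        ms_subjects=ms_subj,
        ms_error=ms_error,
        dropped_subjects=[str(s) for s in dropped],
    )


def lsd_posthoc(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    ms_error: float | None = None,
    df_error: int | None = None,
    alpha: float = 0.05,
    require_significant_omnibus: bool = True,
) -> pd.DataFrame:
    """Fisher's LSD pairwise group contrasts at one time point.

    By default the pooled error is the one-way ANOVA error of the data
    at hand (SPSS's behaviour when groups are compared separately at
    each time point); an externally pooled ``ms_error``/``df_error`` may
    be supplied instead.  LSD p-values are deliberately unadjusted; when
    ``require_significant_omnibus`` is set, the ``significant`` column
    is forced False unless the omnibus F test at this time point is
    itself significant.
    """
    grp = data.groupby(between)[dv]
    means, ns = grp.mean(), grp.count()
    labels = [lab for lab in means.index if ns[lab] >= 1]
    if len(labels) < 2:
        raise InsufficientDataError("LSD needs >= 2 groups")
    if ms_error is None:
        sse = float(sum(((g - g.mean()) ** 2).sum() for _, g in grp))
        df_error = int(ns.sum() - len(labels))
        ms_error = sse / df_error if df_error else float("nan")
    elif df_error is None:
        raise InvalidParameterError("df_error required when ms_error is supplied")

    k = len(labels)
    ssb = float(sum(ns[lab] * (means[lab] - np.average(means[labels], weights=ns[labels])) ** 2
                    for lab in labels))
    f_omni = (ssb / (k - 1)) / ms_error if ms_error > 0 else float("nan")
    p_omni = float(sps.f.sf(f_omni, k - 1, df_error)) if np.isfinite(f_omni) else float("nan")
    omnibus_ok = (not require_significant_omnibus) or (p_omni < alpha)

    rows = []
    for a, b in itertools.combinations(labels, 2):
        diff = float(means[a] - means[b])
        se = float(np.sqrt(ms_error * (1.0 / ns[a] + 1.0 / ns[b])))
        if se > 0:
            tval = diff / se
            p = float(2.0 * sps.t.sf(abs(tval), df_error))
        else:
            tval, p = 0.0, 1.0
        rows.append(
            {
                "group1": a,
                "group2": b,
                "mean_diff": diff,
                "se": se,
                "t": tval,
                "p": p,
                "significant": bool(omnibus_ok and p < alpha),
                "omnibus_F": f_omni,
                "omnibus_p": p_omni,
            }
        )
    return pd.DataFrame(rows)


def oneway_bonferroni(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "day",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA across time points with Bonferroni pairwise tests.

    For a single group's measurements: omnibus one-way F across the time
    points, then all pairwise contrasts on the pooled error with
    Bonferroni-adjusted p-values, ``p_adj = min(1, p * m)`` for the
    ``m = t(t-1)/2`` comparisons.
    """
    grp = data.groupby(within, sort=False)[dv]
    means, ns = grp.mean(), grp.count()
    labels = list(means.index)
    if len(labels) < 2:
        raise InsufficientDataError("need >= 2 time points")
    sse = float(sum(((g - g.mean()) ** 2).sum() for _, g in grp))
    df_error = int(ns.sum() - len(labels))
    ms_error = sse / df_error if df_error else float("nan")
    grand = float(np.average(means[labels], weights=ns[labels]))
    ssb = float(sum(ns[lab] * (means[lab] - grand) ** 2 for lab in labels))
    if ms_error > 0:
        f_omni = (ssb / (len(labels) - 1)) / ms_error
        p_omni = float(sps.f.sf(f_omni, len(labels) - 1, df_error))
    else:
        f_omni, p_omni = 0.0, float("nan")

    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(labels, 2):
        diff = float(means[a] - means[b])
        se = float(np.sqrt(ms_error * (1.0 / ns[a] + 1.0 / ns[b])))
        if se > 0:
            tval = diff / se
            p = float(2.0 * sps.t.sf(abs(tval), df_error))
        else:
            tval, p = 0.0, 1.0
        rows.append(
            {
                "time1": a,
                "time2": b,
                "mean_diff": diff,
                "se": se,
                "t": tval,
                "p_raw": p,
                "p_bonf": min(1.0, p * m),
                "significant": bool(min(1.0, p * m) < alpha),
                "omnibus_F": f_omni,
                "omnibus_p": p_omni,
            }
        )
    return pd.DataFrame(rows)
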