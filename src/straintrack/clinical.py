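"""Clinical endpoints and trial statistics.

The Mayo score (0-12) compounds four subscores (stool frequency, rectal
bleeding, endoscopy, physician global assessment), each 0-3.  Remission
at first follow-up is a total score <= 2 together with an endoscopic
subscore that improved by at least one point; response is a drop of 3+
total points.  Arm contrasts on remission counts use the two-sided
Fisher exact test; repeated-measures outcomes use generalized
estimating equations with an AR(1) working correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

CLINICAL_COLUMNS = [
    "subject_id",
    "visit",
    "stool_frequency",
    "rectal_bleeding",
    "endoscopy",
    "physician_global",
    "total",
]


@dataclass(frozen=True)
class MayoScore:
    """One visit's Mayo assessment; ``total`` must equal the subscore sum."""

    subject_id: str
    visit: str
    stool_frequency: int
    rectal_bleeding: int
    endoscopy: int
    physician_global: int

    def __post_init__(self) -> None:
        for name in ("stool_frequency", "rectal_bleeding", "endoscopy", "physician_global"):
            v = getattr(self, name)
            if not 0 <= v <= 3:
                raise ValueError(f"{name}={v} outside 0-3")

    @property
    def total(self) -> int:
        return (
            self.stool_frequency
            + self.rectal_bleeding
            + self.endoscopy
            + self.physician_global
        )


def remission(d0: MayoScore, f1: MayoScore) -> bool:
    """Total Mayo <= 2 at follow-up with endoscopic improvement >= 1."""
    return f1.total <= 2 and (d0.endoscopy - f1.endoscopy) >= 1


def responder(d0: MayoScore, f1: MayoScore) -> bool:
    """Total Mayo score decreased by 3 or more points."""
    return (d0.total - f1.total) >= 3


@dataclass
class FisherResult:
    p_two_sided: float
    sample_log_odds: float
    wald_ci_95: tuple[float, float]
    odds_ratio: float


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher exact test for a 2x2 table, with Wald interval.

    The two-sided p-value is the point-probability method: the sum of
    hypergeometric point probabilities no larger than that of the
    observed table.  The sample log odds ratio ln(ad/bc) and its 95%
    Wald interval (+-1.96 * sqrt(1/a + 1/b + 1/c + 1/d)) are reported;
    with a zero cell they are undefined (NaN) while p remains valid.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or (t % 1 != 0).any():
        raise ValueError("cells must be nonnegative integers")
    a, b = t[0]
    c, d = t[1]
    p = float(scipy.stats.fisher_exact(t, alternative="two-sided").pvalue)
    if min(a, b, c, d) > 0:
        lor = math.log((a * d) / (b * c)) if a * d != b * c else 0.0
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci = (lor - 1.96 * se, lor + 1.96 * se)
        orat = (a * d) / (b * c)
    else:
        lor = float("nan")
        ci = (float("nan"), float("nan"))
        orat = float("nan")
    return FisherResult(p_two_sided=p, sample_log_odds=lor, wald_ci_95=ci, odds_ratio=orat)


@dataclass
class RankTestResult:
    statistic: float
    p_two_sided: float


def mann_whitney_u(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U (exact for small tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return RankTestResult(statistic=float(res.statistic), p_two_sided=float(res.pvalue))


def wilcoxon_signed_rank(before, after) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired observations."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size == 0 or before.shape != after.shape:
        raise ValueError("paired samples must be non-empty and equal length")
    diffs = after - before
    if np.all(diffs == 0):
        raise ValueError("all paired differences are zero")
    res = scipy.stats.wilcoxon(before, after, alternative="two-sided")
    return RankTestResult(statistic=float(res.statistic), p_two_sided=float(res.pvalue))


@dataclass
class GeeContrastResult:
    statistic: float
    p: float
    df: int
    terms: list[str]


def gee_contrast(
    data: pd.DataFrame,
    response: str,
    covariate: str,
    subject: str = "subject_id",
    time: str = "weeks_since_fmt",
    null_terms: tuple[str, ...] = ("weeks_since_fmt",),
    categorical: bool | None = None,
) -> GeeContrastResult:
    """Wald-type contrast for one covariate under a GEE repeated-measures model.

    Fits ``response ~ null_terms + covariate`` with an AR(1) working
    correlation ordered by ``time`` within subject and a robust
    (sandwich) covariance, then tests all coefficients belonging to the
    covariate jointly with a Wald chi-square.  GEE has no likelihood, so
    this working Wald contrast stands in for a likelihood-ratio test.
    """
    df = data.dropna(subset=[response, covariate, subject, time]).copy()
    counts = df.groupby(subject).size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 subjects with >= 2 observations each")
    if categorical is None:
        categorical = not pd.api.types.is_numeric_dtype(df[covariate])
    if df[covariate].nunique() < 2:
        # no contrast to estimate
        return GeeContrastResult(statistic=0.0, p=1.0, df=0, terms=[])
    term = f"C({covariate})" if categorical else covariate
    rhs = " + ".join(list(null_terms) + [term])
    df = df.sort_values([subject, time])
    # integer time order within subject for the AR(1) structure
    df["_t"] = df.groupby(subject)[time].rank(method="first").astype(int) - 1
    model = smf.gee(
        f"{response} ~ {rhs}",
        groups=subject,
        data=df,
        time=df["_t"],
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Autoregressive(grid=True),
    )
    try:
        fit = model.fit(maxiter=100)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ValueError(f"GEE model not estimable: {exc}") from exc
    names = [n for n in fit.params.index if n == term or n.startswith(term + "[")
             or (not categorical and n == covariate)]
    if not names:
        names = [n for n in fit.params.index if covariate in n and n != "Intercept"]
    if not names:
        raise ValueError(f"covariate {covariate!r} dropped from design (collinear?)")
    constraint = ", ".join(f"{n} = 0" for n in names)
    wald = fit.wald_test(constraint, scalar=True)
    return GeeContrastResult(
        statistic=float(wald.statistic), p=float(wald.pvalue), df=len(names), terms=names
    )


# ---------------------------------------------------------------------------
# Clinical table I/O and arm-level summaries


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def mayo_from_row(row: pd.Series) -> MayoScore:
    return MayoScore(
        subject_id=str(row["subject_id"]),
        visit=str(row["visit"]),
        stool_frequency=int(row["stool_frequency"]),
        rectal_bleeding=int(row["rectal_bleeding"]),
        endoscopy=int(row["endoscopy"]),
        physician_global=int(row["physician_global"]),
    )


def remission_table(
    clinical: pd.DataFrame,
    arms: pd.Series,
    include_withdrawals: bool = True,
) -> pd.DataFrame:
    """Per-arm remission counts from a long clinical table (visits D0, F1).

    Patients without an F1 record are counted as non-remission when
    ``include_withdrawals`` (withdrawal due to worsening symptoms),
    otherwise excluded.  Returns one row per arm with columns
    ``remitted`` and ``not_remitted``.
    """
    rows = []
    for subject, grp in clinical.groupby("subject_id"):
        visits = {str(r["visit"]): mayo_from_row(r) for _, r in grp.iterrows()}
        if "D0" not in visits:
            continue
        if "F1" not in visits:
            if include_withdrawals:
                rows.append((subject, False))
            continue
        rows.append((subject, remission(visits["D0"], visits["F1"])))
    df = pd.DataFrame(rows, columns=["subject_id", "remitted"])
    df["arm"] = df["subject_id"].map(arms)
    out = (
        df.groupby("arm")["remitted"]
        .agg(remitted="sum", n="count")
        .assign(not_remitted=lambda d: d["n"] - d["remitted"])
        .drop(columns="n")
    )
    return out.astype(int)
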