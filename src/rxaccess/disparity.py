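"""Quartile disparity analysis of ln-transformed PWMSD.

Each sociodemographic covariate (tract-level % poverty, % higher education,
% Black/African American, % Hispanic/Latino) is categorised into quartiles of
its distribution across tracts.  For each covariate separately, a Gaussian
GLM (equivalently OLS) regresses ln(PWMSD) on indicator variables for
quartiles 2–4 with quartile 1 — the lowest covariate values — as referent,
optionally adjusting for population density.  Coefficient covariance uses a
heteroskedasticity-consistent sandwich estimator (HC3 by default; HC0/HC1
available for sensitivity), with Wald inference against the normal reference.

Because the outcome is log-transformed, a coefficient beta is reported as a
percent difference in distance, (e^beta − 1)·100, with the confidence
interval transformed from beta ± z·SE.  A negative percent difference means a
shorter distance, i.e. greater spatial access.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "QuartileAssignment",
    "QuartileModelResult",
    "QuartileDisparityModel",
    "QuartileDisparityResults",
    "assign_quartiles",
    "quartile_descriptives",
    "fit_quartile_glm",
    "to_percent_difference",
    "binned_trends",
]

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")
DEFAULT_COVARIATES = ("pct_poverty", "pct_higher_ed", "pct_black_aa", "pct_hispanic")
HC_TYPES = ("HC0", "HC1", "HC3")
Z_95 = 1.96  # normal reference for 95% intervals


@dataclass(frozen=True)
class QuartileAssignment:
    """Rank-based quartile labels for one covariate across tracts."""

    covariate: str
    labels: pd.Series  # index: tract id, values in QUARTILE_LABELS
    cut_points: tuple[float, float, float]  # upper covariate value of Q1..Q3

    def counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {q: int(vc.get(q, 0)) for q in QUARTILE_LABELS}


@dataclass
class QuartileModelResult:
    """Per-covariate GLM output on the ln-km scale and the percent scale."""

    covariate: str
    hc_type: str
    n: int
    intercept: float
    adjust_for: tuple[str, ...] = ()
    rows: list[dict] = field(default_factory=list)  # one per level Q2..Q4 (+ adj)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=[
                "covariate", "level", "beta", "robust_se",
                "pct_diff", "ci_low", "ci_high", "p_value",
            ],
        )


def assign_quartiles(values, ids) -> QuartileAssignment:
    """Split tracts into four near-equal-count groups by covariate rank.

    Sorting is by (value, id) so the split is deterministic under any
    permutation of the input and under ties.  Group sizes are n//4 with the
    remainder distributed to the lowest quartiles first; Q1 always holds the
    lowest covariate values.
    """
    values = np.asarray(values, dtype=float)
    ids = [str(i) for i in ids]
    n = len(values)
    if n != len(ids):
        raise ValueError("values and ids must align")
    if n < 4:
        raise ValueError(f"need at least 4 observations to form quartiles, got {n}")
    bad = [ids[i] for i in range(n) if not math.isfinite(values[i])]
    if bad:
        raise ValueError(f"non-finite covariate value for tract(s) {bad}")

    order = sorted(range(n), key=lambda i: (values[i], ids[i]))
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    labels = {}
    cuts = []
    pos = 0
    for q, size in enumerate(sizes):
        for i in order[pos : pos + size]:
            labels[ids[i]] = QUARTILE_LABELS[q]
        pos += size
        if q < 3:
            cuts.append(float(values[order[pos - 1]]))
    series = pd.Series([labels[i] for i in ids], index=pd.Index(ids, name="tract_id"))
    return QuartileAssignment(covariate="", labels=series, cut_points=tuple(cuts))


def quartile_descriptives(
    tract_records: pd.DataFrame, assignment: QuartileAssignment
) -> pd.DataFrame:
    """Count, mean, SD and median of PWMSD within each quartile."""
    df = tract_records.copy()
    df["tract_id"] = df["tract_id"].astype(str)
    lab = assignment.labels.reindex(df["tract_id"])
    if lab.isna().any():
        missing = df.loc[lab.isna().to_numpy(), "tract_id"].tolist()
        raise ValueError(f"assignment does not cover tract(s) {missing}")
    df["quartile"] = lab.to_numpy()
    rows = []
    for q in QUARTILE_LABELS:
        v = df.loc[df["quartile"] == q, "pwmsd_km"].to_numpy(dtype=float)
        if len(v) == 0:
            raise ValueError(f"quartile {q} is empty")
        rows.append(
            {
                "quartile": q,
                "count": int(len(v)),
                "mean_km": float(v.mean()),
                "sd_km": float(v.std(ddof=1)) if len(v) > 1 else math.nan,
                "median_km": float(np.median(v)),
            }
        )
    return pd.DataFrame(rows)


def to_percent_difference(
    beta: float, se: float, z: float = Z_95
) -> tuple[float, float, float]:
    """Convert a ln-scale coefficient to a percent difference with its CI.

    point = (e^beta − 1)·100; CI endpoints transform beta ∓ z·se the same way.
    """
    if not (math.isfinite(beta) and math.isfinite(se)):
        raise ValueError("beta and se must be finite")
    if se < 0:
        raise ValueError("se must be non-negative")
    pct = (math.exp(beta) - 1.0) * 100.0
    lo = (math.exp(beta - z * se) - 1.0) * 100.0
    hi = (math.exp(beta + z * se) - 1.0) * 100.0
    return pct, lo, hi


def fit_quartile_glm(
    tract_records: pd.DataFrame,
    assignment: QuartileAssignment,
    adjust_for: str | tuple[str, ...] | None = None,
    hc_type: str = "HC3",
    covariate_name: str | None = None,
) -> QuartileModelResult:
    """OLS of ln(PWMSD) on Q2–Q4 indicators with sandwich standard errors.

    The Gaussian-identity GLM coincides with OLS, so the fit is ordinary least
    squares; the coefficient covariance is the heteroskedasticity-consistent
    sandwich (X'X)⁻¹ X' diag(w_i e_i²) X (X'X)⁻¹ of the requested HC type.
    p-values and CIs use the normal (z) reference.
    """
    if hc_type not in HC_TYPES:
        raise ValueError(f"hc_type must be one of {HC_TYPES}")
    if adjust_for is None:
        adjust = ()
    elif isinstance(adjust_for, str):
        adjust = (adjust_for,)
    else:
        adjust = tuple(adjust_for)

    df = tract_records.copy()
    df["tract_id"] = df["tract_id"].astype(str)
    lab = assignment.labels.reindex(df["tract_id"])
    if lab.isna().any():
        raise ValueError("quartile assignment does not cover all records")
    df["quartile"] = lab.to_numpy()
    if (df["pwmsd_km"] <= 0).any():
        raise ValueError("pwmsd_km must be strictly positive (apply the zero floor)")

    y = np.log(df["pwmsd_km"].to_numpy(dtype=float))
    X = pd.DataFrame({"const": 1.0}, index=df.index)
    for q in QUARTILE_LABELS[1:]:
        col = (df["quartile"] == q).astype(float)
        if col.sum() == 0:
            raise ValueError(f"degenerate design: quartile {q} is empty")
        X[q] = col
    for a in adjust:
        if a not in df.columns:
            raise ValueError(f"adjustment covariate {a!r} absent from records")
        X[a] = df[a].astype(float)

    res = sm.OLS(y, X).fit(cov_type=hc_type, use_t=False)

    name = covariate_name or assignment.covariate or "covariate"
    rows = []
    for term in list(QUARTILE_LABELS[1:]) + list(adjust):
        beta = float(res.params[term])
        se = float(res.bse[term])
        pct, lo, hi = to_percent_difference(beta, se)
        if se > 0:
            p = 2.0 * float(stats.norm.sf(abs(beta / se)))
        else:  # zero residual variance: degenerate but defined
            p = 0.0 if beta != 0 else 1.0
        rows.append(
            {
                "covariate": name,
                "level": term,
                "beta": beta,
                "robust_se": se,
                "pct_diff": pct,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": p,
            }
        )
    return QuartileModelResult(
        covariate=name,
        hc_type=hc_type,
        n=int(len(df)),
        intercept=float(res.params["const"]),
        adjust_for=adjust,
        rows=rows,
    )


def binned_trends(
    tract_records: pd.DataFrame,
    bin_variable: str,
    bin_width: float,
    strata: str = "all",
) -> pd.DataFrame:
    """Mean PWMSD (and % white) within fixed-width bins of a tract covariate.

    Bins are left-closed, right-open, anchored at zero.  ``strata`` selects
    all tracts, the urban stratum (population density at or above its 75th
    percentile across the input) or the rural stratum (below it).  The 25th
    and 75th percentiles of the bin variable are attached as
    ``DataFrame.attrs['p25'] / ['p75']``.
    """
    if bin_variable not in tract_records.columns:
        raise ValueError(f"bin variable {bin_variable!r} absent from records")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if strata not in ("all", "urban", "rural"):
        raise ValueError("strata must be 'all', 'urban' or 'rural'")

    df = tract_records.copy()
    v = df[bin_variable].to_numpy(dtype=float)
    if not np.isfinite(v).all():
        raise ValueError(f"non-finite values in {bin_variable!r}")
    p25, p75 = np.percentile(v, [25, 75])

    if strata != "all":
        if "pop_density" not in df.columns:
            raise ValueError("strata splits require a 'pop_density' column")
        cut = df["pop_density"].quantile(0.75)
        df = df[df["pop_density"] >= cut] if strata == "urban" else df[df["pop_density"] < cut]

    idx = np.floor(df[bin_variable].to_numpy(dtype=float) / bin_width).astype(int)
    df = df.assign(_bin=idx)
    rows = []
    for b, grp in df.groupby("_bin", sort=True):
        rows.append(
            {
                "bin_lo": float(b * bin_width),
                "bin_hi": float((b + 1) * bin_width),
                "n_tracts": int(len(grp)),
                "mean_pwmsd_km": float(grp["pwmsd_km"].mean()),
                "mean_pct_white": float(grp["pct_white"].mean())
                if "pct_white" in grp.columns
                else math.nan,
                "stratum": strata,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["bin_lo", "bin_hi", "n_tracts", "mean_pwmsd_km", "mean_pct_white", "stratum"],
    )
    out.attrs["p25"] = float(p25)
    out.attrs["p75"] = float(p75)
    return out


class QuartileDisparityModel:
    """Quartile disparity model for a set of tract records.

    Parameters
    ----------
    data : DataFrame with ``tract_id, pwmsd_km, population`` plus the
        covariate columns to analyse.
    covariates : covariate columns to quartile and model separately
        (default: % poverty, % higher education, % Black/AA, % Hispanic).
    adjust_for : optional extra regression covariate(s), e.g. ``pop_density``.
    hc_type : sandwich covariance flavour, one of HC0/HC1/HC3.

    Examples
    --------
    >>> model = QuartileDisparityModel.from_dataframe(records)
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        data: pd.DataFrame,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        adjust_for: str | tuple[str, ...] | None = None,
        hc_type: str = "HC3",
    ):
        missing = [c for c in ("tract_id", "pwmsd_km") if c not in data.columns]
        missing += [c for c in covariates if c not in data.columns]
        if missing:
            raise ValueError(f"records missing column(s) {missing}")
        self.data = data.copy()
        self.data["tract_id"] = self.data["tract_id"].astype(str)
        self.covariates = tuple(covariates)
        self.adjust_for = adjust_for
        self.hc_type = hc_type

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "QuartileDisparityModel":
        return cls(data, **kwargs)

    def fit(self) -> "QuartileDisparityResults":
        assignments: dict[str, QuartileAssignment] = {}
        models: dict[str, QuartileModelResult] = {}
        tables: dict[str, pd.DataFrame] = {}
        for cov in self.covariates:
            asg = assign_quartiles(self.data[cov].to_numpy(), self.data["tract_id"])
            asg = QuartileAssignment(cov, asg.labels, asg.cut_points)
            assignments[cov] = asg
            tables[cov] = quartile_descriptives(self.data, asg)
            models[cov] = fit_quartile_glm(
                self.data, asg, adjust_for=self.adjust_for,
                hc_type=self.hc_type, covariate_name=cov,
            )
        return QuartileDisparityResults(self, assignments, models, tables)


class QuartileDisparityResults:
    """Fitted per-covariate quartile GLMs plus descriptive tables."""

    def __init__(self, model, assignments, models, quartile_tables):
        self.model = model
        self.assignments = assignments
        self.results = models
        self.quartile_tables = quartile_tables

    def to_frame(self) -> pd.DataFrame:
        """Stacked model rows: covariate, level, beta, robust_se, pct_diff, CI, p."""
        return pd.concat(
            [r.to_frame() for r in self.results.values()], ignore_index=True
        )

    def quartile_table(self) -> pd.DataFrame:
        """Per-covariate, per-quartile count/mean/SD/median of PWMSD."""
        frames = []
        for cov, tbl in self.quartile_tables.items():
            t = tbl.copy()
            t.insert(0, "covariate", cov)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = [
            "Quartile disparity analysis of ln(PWMSD)",
            f"  n tracts: {len(self.model.data)}   robust covariance: {self.model.hc_type}",
            f"  adjustment: {self.model.adjust_for or 'none'}",
            "",
            f"{'covariate':<16}{'level':<12}{'pct diff':>10}{'95% CI':>22}{'p':>10}",
        ]
        for cov, res in self.results.items():
            lines.append(f"{cov:<16}{'Q1':<12}{'referent':>10}")
            for row in res.rows:
                ci = f"({row['ci_low']:.1f}, {row['ci_high']:.1f})"
                p = "<0.001" if row["p_value"] < 0.001 else f"{row['p_value']:.4f}"
                lines.append(
                    f"{'':<16}{row['level']:<12}{row['pct_diff']:>9.1f}%{ci:>22}{p:>10}"
                )
        return "\n".join(lines)
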