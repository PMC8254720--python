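"""Inferential layer: mixed models, correlations, JZS Bayes factors.

``fit_lmm`` implements a Gaussian linear mixed model with a single
participant-level random intercept, estimated by profiled REML over the
variance ratio.  Fixed-term F tests are marginal (Type-III-style) Wald
tests with residual denominator degrees of freedom (n - rank(X)), which
reproduces the trial-level df bookkeeping of classical repeated-trial
analyses and collapses exactly onto ordinary least squares / classical
ANOVA when the random-intercept variance estimate hits zero.

Bayes factors follow the default JZS conventions: for correlations the
Jeffreys-Zellner-Siow integral with unit prior scale, for t tests the
JZS t Bayes factor (default Cauchy prior scale 0.707).  Both are
returned as base-10 logarithms (lgBF), with |lgBF| > 0.5 conventionally
read as substantial evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats as sps

__all__ = [
    "CorrelationResult",
    "LmmTermTest",
    "LmmResult",
    "TTestResult",
    "fit_lmm",
    "pearson_ci",
    "lgbf_correlation",
    "partial_correlation",
    "context_effects",
    "cell_means",
    "median_split",
    "two_sample_bf_t",
    "lgbf_ttest",
    "run_full_inference",
]


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with CI, p and (optionally) lgBF."""

    n: int
    r: float
    ci95: tuple[float, float]
    p: float
    lgbf: float | None = None

    def to_dict(self) -> dict:
        return {"n": self.n, "r": self.r, "ci95": list(self.ci95),
                "p": self.p, "lgbf": self.lgbf}


def pearson_ci(
    x: Sequence[float], y: Sequence[float], ci: float = 0.95,
    with_lgbf: bool = False,
) -> CorrelationResult:
    """Pearson correlation with two-sided t-based p and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    # Fisher z interval
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zc = sps.norm.ppf(0.5 + ci / 2.0)
        lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    else:
        lo, hi = r, r
    lgbf = lgbf_correlation(r, n) if with_lgbf else None
    return CorrelationResult(n=n, r=r, ci95=(float(lo), float(hi)), p=p, lgbf=lgbf)


def _jzs_corr_lgbf(r: float, n: int) -> float:
    """Base-10 log JZS Bayes factor for a correlation, by quadrature.

    BF10 = sqrt(n/2)/Gamma(1/2) * Int_0^inf (1+g)^((n-2)/2)
           * (1 + (1-r^2) g)^(-(n-1)/2) * g^(-3/2) * exp(-n/(2g)) dg

    Integrated in u = log(g) with the peak log-magnitude factored out, so
    very strong correlations (huge Bayes factors) stay representable.
    """
    r2 = min(r * r, 1.0)
    if r2 >= 1.0 - 1e-14:
        return np.inf  # degenerate: perfect correlation

    log1mr2 = np.log(1.0 - r2)

    def log_h(u):
        u = np.asarray(u, dtype=float)
        return ((n - 2) / 2.0 * np.logaddexp(0.0, u)
                - (n - 1) / 2.0 * np.logaddexp(0.0, u + log1mr2)
                - 0.5 * u - n / 2.0 * np.exp(np.minimum(-u, 700.0)))

    lo, hi = -60.0, 400.0
    grid = np.linspace(lo, hi, 4001)
    peak = float(np.max(log_h(grid)))

    val, err = integrate.quad(lambda u: np.exp(log_h(u) - peak),
                              lo, hi, limit=400)
    if not np.isfinite(val) or val <= 0 or (err > 1e-6 * abs(val) and err > 1e-12):
        raise RuntimeError(f"Bayes-factor quadrature failed (value {val}, err {err})")
    log10 = np.log(10.0)
    return float(
        (peak + np.log(val)) / log10
        + np.log10(np.sqrt(n / 2.0) / special.gamma(0.5))
    )


def lgbf_correlation(r: float, n: int) -> float:
    """Base-10 log of the JZS correlation Bayes factor H1/H0.

    Symmetric in the sign of r; +inf at |r| = 1.  Raises on integration
    failure rather than falling back silently.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError("r must lie in [-1, 1]")
    return _jzs_corr_lgbf(float(r), int(n))


def partial_correlation(
    x: Sequence[float], y: Sequence[float], z: Sequence[float] | np.ndarray,
    with_lgbf: bool = False,
) -> CorrelationResult:
    """Correlation of x and y after regressing both on covariate(s) z.

    z may be a vector or an (n, k) matrix; an intercept is always
    included in the nuisance regression.  p/CI are inherited from the
    plain Pearson machinery applied to the residuals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(z), axis=1)
    x, y, z = x[ok], y[ok], z[ok]
    design = np.column_stack([np.ones(len(x)), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # a variable that is (numerically) a deterministic function of z leaves
    # only float noise behind; its partial correlation is exactly zero
    for orig, resid in ((x, rx), (y, ry)):
        if np.std(resid) <= 1e-10 * (np.std(orig) + np.finfo(float).tiny):
            n = len(x)
            if n < 3:
                raise ValueError("need at least 3 complete pairs")
            lgbf = lgbf_correlation(0.0, n) if with_lgbf else None
            se = 1.0 / np.sqrt(n - 3) if n > 3 else np.inf
            zc = sps.norm.ppf(0.975)
            ci = (float(np.tanh(-zc * se)), float(np.tanh(zc * se)))
            return CorrelationResult(n=n, r=0.0, ci95=ci, p=1.0, lgbf=lgbf)
    return pearson_ci(rx, ry, with_lgbf=with_lgbf)


# ---------------------------------------------------------------------------
# JZS t-test Bayes factor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    lgbf: float

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p, "lgbf": self.lgbf}


def lgbf_ttest(t: float, n1: int, n2: int | None = None,
               r_scale: float = 0.707) -> float:
    """Base-10 log JZS Bayes factor for a one- or two-sample t statistic.

    The effect-size prior is Cauchy(0, r_scale); the default 0.707
    matches the common JZS convention for t tests.
    """
    if n2 is None:
        n_eff, nu = float(n1), n1 - 1
    else:
        n_eff, nu = n1 * n2 / (n1 + n2), n1 + n2 - 2
    if nu < 1:
        raise ValueError("not enough observations")
    r2 = r_scale**2

    def integrand(g: float) -> float:
        return ((1.0 + n_eff * g) ** -0.5
                * (1.0 + t**2 / ((1.0 + n_eff * g) * nu)) ** (-(nu + 1) / 2.0)
                * (r2 / 2.0) ** 0.5 / special.gamma(0.5)
                * g ** (-1.5) * np.exp(-r2 / (2.0 * g)))

    marginal1, err = integrate.quad(integrand, 0.0, np.inf, limit=400)
    if not np.isfinite(marginal1) or marginal1 <= 0:
        raise RuntimeError("Bayes-factor quadrature failed")
    marginal0 = (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return float(np.log10(marginal1 / marginal0))


def two_sample_bf_t(
    group_a: Sequence[float], group_b: Sequence[float], r_scale: float = 0.707
) -> TTestResult:
    """Pooled-variance two-sample t test with its JZS lgBF."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        t = 0.0
    else:
        t = float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p, lgbf=lgbf_ttest(t, n1, n2, r_scale))


# ---------------------------------------------------------------------------
# linear mixed model (random intercept, profiled REML)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LmmTermTest:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float

    def to_dict(self) -> dict:
        return {"F": self.F, "df_num": self.df_num,
                "df_den": self.df_den, "p": self.p}


@dataclass
class LmmResult:
    """REML fit of a random-intercept LMM with per-term Wald F tests."""

    terms: dict[str, LmmTermTest]
    beta: np.ndarray
    column_names: list[str]
    sigma2: float  # residual variance
    tau2: float  # random-intercept variance
    n_obs: int
    rank: int

    def to_dict(self) -> dict:
        return {
            "terms": {k: v.to_dict() for k, v in self.terms.items()},
            "sigma2": self.sigma2,
            "tau2": self.tau2,
            "n_obs": self.n_obs,
        }


def _sum_code(values: pd.Series, name: str) -> tuple[np.ndarray, list[str], list]:
    """Deviation (sum-to-zero) coding; k levels -> k-1 columns."""
    levels = sorted(pd.unique(values))
    k = len(levels)
    if k < 2:
        raise ValueError(f"factor '{name}' has a single level: {levels}")
    codes = pd.Categorical(values, categories=levels).codes
    cols = np.zeros((len(values), k - 1))
    for j in range(k - 1):
        cols[:, j] = (codes == j).astype(float) - (codes == k - 1).astype(float)
    names = [f"{name}[{levels[j]}]" for j in range(k - 1)]
    return cols, names, levels


def _build_design(
    data: pd.DataFrame, fixed: Sequence[str], categorical: Sequence[str]
) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Design matrix with an intercept, main effects and ':' interactions."""
    base_cols: dict[str, np.ndarray] = {}
    for term in fixed:
        for var in term.split(":"):
            if var in base_cols:
                continue
            if var in categorical:
                cols, _, _ = _sum_code(data[var], var)
            else:
                vals = np.asarray(data[var], dtype=float)[:, None]
                if np.all(vals == vals[0]):
                    raise ValueError(f"covariate '{var}' is constant")
                cols = vals
            base_cols[var] = cols

    blocks = [np.ones((len(data), 1))]
    names = ["Intercept"]
    spans: dict[str, slice] = {}
    pos = 1
    for term in fixed:
        parts = term.split(":")
        cols = base_cols[parts[0]]
        for var in parts[1:]:
            other = base_cols[var]
            cols = np.concatenate(
                [cols[:, [i]] * other for i in range(cols.shape[1])], axis=1
            )
        blocks.append(cols)
        spans[term] = slice(pos, pos + cols.shape[1])
        names.extend(f"{term}.{j}" for j in range(cols.shape[1]))
        pos += cols.shape[1]
    X = np.concatenate(blocks, axis=1)
    return X, names, spans


def _reml_profile(y: np.ndarray, X: np.ndarray, group_codes: np.ndarray):
    """Profiled REML pieces as functions of lambda = tau2 / sigma2."""
    n, p = X.shape
    n_groups = group_codes.max() + 1
    k_i = np.bincount(group_codes, minlength=n_groups).astype(float)
    # per-group column sums of X and y
    Sx = np.zeros((n_groups, p))
    np.add.at(Sx, group_codes, X)
    Sy = np.bincount(group_codes, weights=y, minlength=n_groups)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def pieces(lam: float):
        w = lam / (1.0 + k_i * lam)  # shrinkage weight per group
        XtVX = XtX - (Sx * w[:, None]).T @ Sx
        XtVy = Xty - Sx.T @ (w * Sy)
        ytVy = yty - float((w * Sy) @ Sy)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - float(beta @ XtVy)
        return beta, rss, XtVX, w

    def neg2_reml(lam: float) -> float:
        _, rss, XtVX, _ = pieces(lam)
        sigma2 = rss / (n - p)
        sign, logdet = np.linalg.slogdet(XtVX)
        logdetV = float(np.sum(np.log1p(k_i * lam)))
        return logdetV + (n - p) * np.log(sigma2) + logdet

    return pieces, neg2_reml


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    groups: str = "participant_id",
    categorical: Sequence[str] = ("size_level", "location"),
) -> LmmResult:
    """Fit a random-intercept LMM and test each fixed term.

    Parameters
    ----------
    data
        Trial-level table; rows with non-finite response are dropped.
    response
        Column to model.
    fixed
        Term list, e.g. ``["size_level", "location", "size_level:location"]``;
        ``:`` builds interactions.  Columns named in ``categorical`` get
        sum-to-zero coding, others enter numerically.
    groups
        Column defining the random-intercept grouping (participants).

    Returns per-term marginal Wald F tests with denominator df
    ``n - rank(X)``.
    """
    cols = {response, groups}
    for term in fixed:
        cols.update(term.split(":"))
    df = data.loc[:, sorted(cols)].copy()
    df = df[np.isfinite(np.asarray(df[response], dtype=float))]
    if df[groups].nunique() < 2:
        raise ValueError("need at least 2 participants")
    y = np.asarray(df[response], dtype=float)
    X, names, spans = _build_design(df, fixed, categorical)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(
            f"singular fixed-effect design for terms {list(fixed)}; "
            "check for collinear or degenerate factors"
        )
    group_codes = pd.Categorical(df[groups]).codes.astype(int)
    pieces, neg2_reml = _reml_profile(y, X, group_codes)

    # profile REML over lambda >= 0; compare the boundary explicitly
    res = optimize.minimize_scalar(
        lambda u: neg2_reml(np.exp(u)), bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam_hat = float(np.exp(res.x))
    if neg2_reml(0.0) <= res.fun:
        lam_hat = 0.0
    beta, rss, XtVX, _ = pieces(lam_hat)
    sigma2 = rss / (n - p)
    tau2 = lam_hat * sigma2
    cov = sigma2 * np.linalg.inv(XtVX)

    df_den = n - p
    terms: dict[str, LmmTermTest] = {}
    for term, span in spans.items():
        b = beta[span]
        c = cov[span, span]
        q = len(b)
        F = float(b @ np.linalg.solve(c, b) / q)
        pval = float(sps.f.sf(F, q, df_den))
        terms[term] = LmmTermTest(name=term, F=F, df_num=q, df_den=df_den, p=pval)
    return LmmResult(terms=terms, beta=beta, column_names=names,
                     sigma2=float(sigma2), tau2=float(tau2),
                     n_obs=n, rank=int(rank))


# ---------------------------------------------------------------------------
# per-participant summaries
# ---------------------------------------------------------------------------

def cell_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean pupil response and report per participant x size x location.

    Only valid trials enter; cells with no valid trial are absent (at
    most 10 cells per participant).
    """
    valid = trials[trials["valid"].astype(bool)]
    grouped = (
        valid.groupby(["participant_id", "size_level", "location"], sort=True)
        .agg(
            pupil_response_mm=("pupil_response_mm", "mean"),
            report_mm=("report_mm", "mean"),
            n_trials=("pupil_response_mm", "size"),
        )
        .reset_index()
    )
    return grouped


_EFFECT_CHANNELS = {
    "pupil": "pupil_response_mm",
    "report": "report_mm",
    "gaze_x": "gaze_x_deg",
    "gaze_y": "gaze_y_deg",
}


def context_effects(
    trials: pd.DataFrame, participants: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-participant far-minus-near effects (pooled and per size level).

    Valid trials only.  A participant with no valid trial in one of the
    two locations gets NaN effects (they are dropped from correlations
    downstream, with a log entry by the pipeline).  Also returns the
    participant's mean baseline pupil.
    """
    valid = trials[trials["valid"].astype(bool)]
    rows = []
    for pid, grp in valid.groupby("participant_id", sort=True):
        far = grp[grp["location"] == "far"]
        near = grp[grp["location"] == "near"]
        row: dict = {"participant_id": pid,
                     "n_valid": len(grp),
                     "baseline_pupil_mm": grp["baseline_pupil_mm"].mean()}
        for label, col in _EFFECT_CHANNELS.items():
            if len(far) and len(near):
                row[f"{label}_far_minus_near"] = far[col].mean() - near[col].mean()
            else:
                row[f"{label}_far_minus_near"] = np.nan
        for size in sorted(valid["size_level"].unique()):
            f = far[far["size_level"] == size]
            n_ = near[near["size_level"] == size]
            for label in ("pupil", "report"):
                col = _EFFECT_CHANNELS[label]
                key = f"{label}_far_minus_near_size{size}"
                row[key] = (f[col].mean() - n_[col].mean()
                            if len(f) and len(n_) else np.nan)
        rows.append(row)
    effects = pd.DataFrame(rows)
    if participants is not None:
        effects = effects.merge(participants, on="participant_id", how="left")
    return effects


def median_split(
    effects: pd.DataFrame, value_col: str, aq_col: str = "aq"
) -> dict:
    """Mean effect with 95 % CI in low- vs high-AQ halves.

    High = AQ strictly above the sample median; ties go to the low
    group.  The CI is the t-based interval of the group mean; each group
    needs at least 2 participants.
    """
    df = effects[[value_col, aq_col]].dropna()
    median = float(df[aq_col].median())
    out = {"aq_median": median}
    for name, mask in (("low", df[aq_col] <= median), ("high", df[aq_col] > median)):
        vals = df.loc[mask, value_col].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"{name}-AQ group has fewer than 2 participants")
        m = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        tc = sps.t.ppf(0.975, len(vals) - 1)
        lo, hi = m - tc * sem, m + tc * sem
        out[name] = {"n": int(len(vals)), "mean": m, "ci95": [float(lo), float(hi)],
                     "ci_excludes_zero": bool(lo > 0 or hi < 0)}
    return out


# ---------------------------------------------------------------------------
# full inference bundle
# ---------------------------------------------------------------------------

def _corr_entry(x, y, with_lgbf=True) -> dict:
    try:
        return pearson_ci(x, y, with_lgbf=with_lgbf).to_dict()
    except ValueError as exc:
        return {"error": str(exc)}


def run_full_inference(
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    stimulus_heights: Sequence[float] | None = None,
    jzs_t_scale: float = 0.707,
) -> dict:
    """Run the complete inferential battery on a preprocessed trial table.

    Parameters
    ----------
    trials
        Trial summaries (one row per non-first trial) with validity flags;
        only valid trials enter any analysis, and the same trial set is
        used for every response variable.
    participants
        One row per participant: participant_id, aq, gender.
    stimulus_heights
        Heights (deg) per size level, used as the numeric covariate when
        partialling physical size out of the pupil-vs-report correlation.

    Returns a JSON-serializable nested dict.
    """
    if stimulus_heights is None:
        from .design import StimulusSet
        stimulus_heights = StimulusSet().heights_deg
    heights = np.asarray(stimulus_heights, dtype=float)

    valid = trials[trials["valid"].astype(bool)].copy()
    merged = valid.merge(participants[["participant_id", "aq"]],
                         on="participant_id", how="inner")

    bundle: dict = {"n_participants": int(participants["participant_id"].nunique()),
                    "n_valid_trials": int(len(valid))}

    # --- trial-level mixed models --------------------------------------
    lmm: dict = {}
    for resp, key in (("report_mm", "report"), ("pupil_response_mm", "pupil"),
                      ("baseline_pupil_mm", "baseline"),
                      ("gaze_x_deg", "gaze_x"), ("gaze_y_deg", "gaze_y")):
        lmm[f"{key}_size_location"] = fit_lmm(
            merged, resp, ["size_level", "location", "size_level:location"]
        ).to_dict()
    for resp, key in (("pupil_response_mm", "pupil"), ("report_mm", "report")):
        lmm[f"{key}_aq_location"] = fit_lmm(
            merged, resp, ["aq", "location", "aq:location"]
        ).to_dict()
    bundle["lmm"] = lmm

    # --- per-participant effects and AQ correlations -------------------
    effects = context_effects(trials, participants)
    dropped = effects[effects["pupil_far_minus_near"].isna()]
    bundle["participants_without_effects"] = dropped["participant_id"].tolist()
    eff = effects.dropna(subset=["pupil_far_minus_near", "report_far_minus_near",
                                 "aq"])

    corr: dict = {
        "pupil_effect_vs_aq": _corr_entry(eff["pupil_far_minus_near"], eff["aq"]),
        "report_effect_vs_aq": _corr_entry(eff["report_far_minus_near"], eff["aq"]),
        "baseline_vs_aq": _corr_entry(eff["baseline_pupil_mm"], eff["aq"]),
        "gaze_x_effect_vs_aq": _corr_entry(eff["gaze_x_far_minus_near"], eff["aq"]),
        "gaze_y_effect_vs_aq": _corr_entry(eff["gaze_y_far_minus_near"], eff["aq"]),
        "pupil_effect_vs_gaze_x_effect": _corr_entry(
            eff["pupil_far_minus_near"], eff["gaze_x_far_minus_near"]),
        "pupil_effect_vs_gaze_y_effect": _corr_entry(
            eff["pupil_far_minus_near"], eff["gaze_y_far_minus_near"]),
    }
    per_size: dict = {}
    for size in range(1, 6):
        col = f"pupil_far_minus_near_size{size}"
        if col in eff:
            sub = eff.dropna(subset=[col])
            per_size[f"size{size}"] = _corr_entry(sub[col], sub["aq"])
    corr["pupil_effect_vs_aq_per_size"] = per_size
    bundle["correlations"] = corr

    # --- pupil vs report across participant x cell points --------------
    cells = cell_means(trials)
    cells["height_deg"] = heights[cells["size_level"].to_numpy() - 1]
    bundle["cells_per_participant_max"] = int(
        cells.groupby("participant_id").size().max()
    )
    bundle["pupil_vs_report"] = {
        "plain": _corr_entry(cells["pupil_response_mm"], cells["report_mm"]),
        "size_partialled": partial_correlation(
            cells["pupil_response_mm"], cells["report_mm"],
            cells["height_deg"], with_lgbf=True,
        ).to_dict(),
    }

    # --- median split ---------------------------------------------------
    bundle["median_split"] = {
        "pupil": median_split(eff, "pupil_far_minus_near"),
        "report": median_split(eff, "report_far_minus_near"),
    }

    # --- gender control -------------------------------------------------
    if "gender" in eff.columns:
        gender = eff
    else:
        gender = eff.merge(participants[["participant_id", "gender"]],
                           on="participant_id", how="left")
    g = {}
    for label in ("report_far_minus_near", "pupil_far_minus_near"):
        females = gender.loc[gender["gender"] == "F", label]
        males = gender.loc[gender["gender"] == "M", label]
        try:
            g[label] = two_sample_bf_t(females, males, r_scale=jzs_t_scale).to_dict()
        except ValueError as exc:
            g[label] = {"error": str(exc)}
    bundle["gender"] = g

    # --- leave-one-out robustness of the headline correlation ----------
    vals = eff["pupil_far_minus_near"].to_numpy()
    if len(vals) >= 4:
        extreme = int(np.argmax(np.abs(vals - np.median(vals))))
        keep = np.ones(len(vals), dtype=bool)
        keep[extreme] = False
        bundle["pupil_effect_vs_aq_drop_extreme"] = _corr_entry(
            vals[keep], eff["aq"].to_numpy()[keep]
        )
        bundle["dropped_participant"] = str(eff["participant_id"].iloc[extreme])

    bundle["effects_table"] = effects.to_dict(orient="list")
    bundle["cell_means"] = cells.to_dict(orient="list")
    return bundle
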