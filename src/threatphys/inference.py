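"""Statistical models for trial- and condition-wise response estimates.

Trialwise measures (SEBR, PSR, SCR) are analyzed in linear mixed-effects
models with fixed effects for drug group, a CS contrast, time (trial number,
categorical) and their interactions, plus a random participant intercept:

    response ~ drug * cs * time + (1 | participant)

Fixed-effect F tests use Satterthwaite-approximated denominator degrees of
freedom.  Parameter estimation is delegated to statsmodels' MixedLM (REML);
the F-test layer on top — Woodbury-based GLS covariance of the fixed
effects, delta-method Satterthwaite df from the observed REML information —
is implemented here, since statsmodels does not provide it.

Two CS contrasts are reported, following the convention of testing
discrimination and reminder specificity separately: (i) both CS⁺ pooled
vs CS⁻, fitted on all analyzed trials; (ii) CSr⁺ vs CSn⁺, fitted on CS⁺
trials only (hence the smaller denominator df).

Condition-wise heart period is tested in a mixed-design repeated-measures
ANOVA with fixed effects against pooled error variance.  Control measures
use independent-samples t tests without multiplicity correction.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM


class DfMethod(enum.Enum):
    SATTERTHWAITE = "satterthwaite"
    RESIDUAL = "residual"


class TimeCoding(enum.Enum):
    ACROSS_CS = "across_cs"    # trial number across CS types (retention)
    WITHIN_CS = "within_cs"    # nonreinforced trial counter per CS (relearning)


@dataclass
class ModelSpec:
    response: str = "amplitude"
    include_time: bool = True
    time_coding: TimeCoding = TimeCoding.ACROSS_CS
    covariates: list[str] = field(default_factory=list)
    df_method: DfMethod = DfMethod.SATTERTHWAITE
    participant_col: str = "participant"
    group_col: str = "group"
    cs_col: str = "cs"
    trial_col: str = "trial"


# ---------------------------------------------------------------------------
# contrast coding

CS_MINUS, CSR, CSN = "CS-", "CSr+", "CSn+"


class RankDeficientDesign(ValueError):
    """Fixed-effect design cannot be estimated on these data."""


def build_contrasts(table: pd.DataFrame, cs_col: str = "cs") -> pd.DataFrame:
    """Add the two orthogonal CS contrast columns.

    ``cs_plus_vs_minus``: +1/2 for either CS⁺, −1 for CS⁻ (pooled CS⁺ mean
    against CS⁻); ``csr_vs_csn``: +1 CSr⁺, −1 CSn⁺, 0 CS⁻.  On balanced
    data the columns are orthogonal.
    """
    out = table.copy()
    cs = out[cs_col]
    out["cs_plus_vs_minus"] = np.select(
        [cs == CSR, cs == CSN, cs == CS_MINUS], [0.5, 0.5, -1.0], np.nan)
    out["csr_vs_csn"] = np.select(
        [cs == CSR, cs == CSN, cs == CS_MINUS], [1.0, -1.0, 0.0], np.nan)
    return out


def add_within_cs_trial(table: pd.DataFrame, participant_col: str = "participant",
                        cs_col: str = "cs", trial_col: str = "trial",
                        out_col: str = "trial_within_cs") -> pd.DataFrame:
    """Time index for relearning models: rank of a trial among the analyzed
    (e.g. nonreinforced) trials of the same CS within a participant."""
    out = table.copy()
    out[out_col] = (out.groupby([participant_col, cs_col])[trial_col]
                    .rank(method="first").astype(int))
    return out


def _sum_code(values: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding; returns (n, k-1) matrix."""
    levels = sorted(values.unique())
    k = len(levels)
    out = np.zeros((len(values), k - 1))
    for j, lev in enumerate(levels[:-1]):
        out[:, j] = (values == lev).astype(float)
    out[(values == levels[-1]).to_numpy()] = -1.0
    return out, levels


# ---------------------------------------------------------------------------
# random-intercept REML machinery (Woodbury forms)

class _RandomInterceptML:
    """Sufficient statistics and REML quantities for y = Xβ + b_i + ε."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        self.stats = []
        for g in pd.unique(groups):
            m = groups == g
            Xi, yi = X[m], y[m]
            self.stats.append((Xi.T @ Xi, Xi.sum(axis=0), Xi.T @ yi,
                               float(yi.sum()), float(yi @ yi), int(m.sum())))

    def _gls_parts(self, sigma2: float, tau2: float):
        lam = tau2 / sigma2
        XtVX = np.zeros((self.p, self.p))
        XtVy = np.zeros(self.p)
        ytVy = 0.0
        logdet = 0.0
        for XtX, Xt1, Xty, yt1, yty, ni in self.stats:
            c = lam / (1.0 + lam * ni)
            XtVX += XtX - c * np.outer(Xt1, Xt1)
            XtVy += Xty - c * Xt1 * yt1
            ytVy += yty - c * yt1 * yt1
            logdet += ni * np.log(sigma2) + np.log1p(lam * ni)
        return XtVX / sigma2, XtVy / sigma2, ytVy / sigma2, logdet

    def reml_loglike(self, sigma2: float, tau2: float) -> float:
        XtVX, XtVy, ytVy, logdet = self._gls_parts(sigma2, tau2)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - 2 * beta @ XtVy + beta @ XtVX @ beta
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        return -0.5 * (logdet + logdet_xvx + rss)

    def cov_beta(self, sigma2: float, tau2: float) -> np.ndarray:
        XtVX, *_ = self._gls_parts(sigma2, tau2)
        return np.linalg.inv(XtVX)

    def theta_cov(self, sigma2: float, tau2: float) -> np.ndarray:
        """Asymptotic covariance of (σ², τ²) from the observed REML
        information (central finite differences)."""
        h = np.array([max(sigma2, 1e-8) * 1e-4, max(tau2, 1e-8) * 1e-4])
        th = np.array([sigma2, tau2])

        def f(t):
            return self.reml_loglike(max(t[0], 1e-12), max(t[1], 0.0))

        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                H[i, j] = H[j, i] = (
                    f(th + ei + ej) - f(th + ei - ej)
                    - f(th - ei + ej) + f(th - ei - ej)
                ) / (4 * h[i] * h[j])
        info = -H
        try:
            return np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return np.full((2, 2), np.nan)


def _satterthwaite_df(ml: _RandomInterceptML, sigma2: float, tau2: float,
                      contrasts: np.ndarray) -> np.ndarray:
    """Satterthwaite df for each 1-df contrast row via the delta method."""
    A = ml.theta_cov(sigma2, tau2)
    if not np.all(np.isfinite(A)):
        return np.full(len(contrasts), np.nan)
    h = np.array([max(sigma2, 1e-8) * 1e-3, max(tau2, 1e-8) * 1e-3])
    C0 = ml.cov_beta(sigma2, tau2)
    Cs = []
    for i, sign in ((0, 1), (0, -1), (1, 1), (1, -1)):
        th = [sigma2, tau2]
        th[i] += sign * h[i]
        Cs.append(ml.cov_beta(max(th[0], 1e-12), max(th[1], 0.0)))
    dfs = np.empty(len(contrasts))
    for r, ell in enumerate(contrasts):
        g0 = float(ell @ C0 @ ell)
        grad = np.array([
            (ell @ Cs[0] @ ell - ell @ Cs[1] @ ell) / (2 * h[0]),
            (ell @ Cs[2] @ ell - ell @ Cs[3] @ ell) / (2 * h[1]),
        ])
        denom = float(grad @ A @ grad)
        dfs[r] = 2 * g0 ** 2 / denom if denom > 0 else np.nan
    return dfs


# ---------------------------------------------------------------------------
# LME fitting and F tests

@dataclass
class _Term:
    name: str
    cols: list[int]


def _build_design(df: pd.DataFrame, spec: ModelSpec, cs_contrast_col: str):
    """Sum-coded design with named terms for drug * cs * time (+ covariates)."""
    n = len(df)
    drug = df[spec.group_col]
    drug_levels = sorted(drug.unique())
    if len(drug_levels) != 2:
        raise ValueError("need exactly two groups")
    d = np.where(drug == drug_levels[0], -0.5, 0.5)
    c = df[cs_contrast_col].to_numpy(float)

    blocks: list[np.ndarray] = [np.ones((n, 1))]
    terms: list[_Term] = []
    pos = 1

    def add(name, M):
        nonlocal pos
        blocks.append(M)
        terms.append(_Term(name, list(range(pos, pos + M.shape[1]))))
        pos += M.shape[1]

    add("drug", d[:, None])
    add("cs", c[:, None])
    if spec.include_time:
        T, _ = _sum_code(df[spec.trial_col])
        add("time", T)
    add("drug:cs", (d * c)[:, None])
    if spec.include_time:
        add("drug:time", T * d[:, None])
        add("cs:time", T * c[:, None])
        add("drug:cs:time", T * (d * c)[:, None])
    for cov in spec.covariates:
        v = df[cov].to_numpy(float)
        add(cov, (v - v.mean())[:, None])
    return np.hstack(blocks), terms


def fit_lme(table: pd.DataFrame, spec: ModelSpec | None = None,
            cs_contrast: str = "cs_plus_vs_minus") -> pd.DataFrame:
    """Fit the trialwise mixed model and return the fixed-effect F table.

    Rows with a missing response or contrast value are dropped (trial-level
    exclusions are unproblematic for this model).  Returns a table with
    columns ``effect, F, df_num, df_den, p``.
    """
    spec = spec or ModelSpec()
    df = table.copy()
    if cs_contrast not in df:
        df = build_contrasts(df, spec.cs_col)
    df = df.dropna(subset=[spec.response, cs_contrast])
    df = df[np.isfinite(df[spec.response])]
    if df[spec.participant_col].nunique() < 4:
        raise ValueError("need at least 2 participants per group")

    X, terms = _build_design(df, spec, cs_contrast)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesign(
            f"design is rank-deficient ({X.shape[1]} columns, "
            f"rank {np.linalg.matrix_rank(X)}); too few participants or "
            "trials for the requested fixed-effect structure")
    y = df[spec.response].to_numpy(float)
    groups = df[spec.participant_col].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups)
        try:
            fit = model.fit(reml=True, method="lbfgs")
            converged = bool(fit.converged)
        except Exception:
            fit = model.fit(reml=True, method="powell")
            converged = bool(fit.converged)
    sigma2 = float(fit.scale)
    tau2 = float(np.atleast_2d(fit.cov_re)[0, 0])
    beta = np.asarray(fit.fe_params)

    ml = _RandomInterceptML(X, y, groups)
    C = ml.cov_beta(sigma2, tau2)
    n, p = X.shape
    resid_df = n - p

    rows = []
    for term in terms:
        L = np.zeros((len(term.cols), p))
        for r, j in enumerate(term.cols):
            L[r, j] = 1.0
        q = len(term.cols)
        M = L @ C @ L.T
        Lb = L @ beta
        F = float(Lb @ np.linalg.solve(M, Lb) / q)
        df_den = float(resid_df)
        if spec.df_method is DfMethod.SATTERTHWAITE and tau2 > 0:
            # orthonormalize the contrast rows in the metric of M
            vals, vecs = np.linalg.eigh(M)
            keep = vals > vals.max() * 1e-10
            Lt = (vecs[:, keep] / np.sqrt(vals[keep])).T @ L
            nus = _satterthwaite_df(ml, sigma2, tau2, Lt)
            if np.all(np.isfinite(nus)):
                if q == 1:
                    df_den = float(nus[0])
                else:
                    good = nus > 2
                    if good.all():
                        E = float(np.sum(nus / (nus - 2)))
                        df_den = 2 * E / (E - q) if E > q else float(resid_df)
        pval = float(stats.f.sf(F, q, df_den))
        rows.append(dict(effect=term.name, F=F, df_num=q,
                         df_den=df_den, p=pval))
    out = pd.DataFrame(rows)
    out.attrs["converged"] = converged
    out.attrs["sigma2"] = sigma2
    out.attrs["tau2"] = tau2
    if not converged:
        warnings.warn("mixed model did not converge; diagnostics in attrs",
                      RuntimeWarning, stacklevel=2)
    return out


def effect_tables_both_contrasts(table: pd.DataFrame,
                                 spec: ModelSpec | None = None) -> pd.DataFrame:
    """The standard report: CS⁺-vs-CS⁻ model on all trials, CSr⁺-vs-CSn⁺
    model on CS⁺ trials only, stacked into one effect table."""
    spec = spec or ModelSpec()
    t = build_contrasts(table, spec.cs_col)
    a = fit_lme(t, spec, "cs_plus_vs_minus")
    a["effect"] = a["effect"].str.replace("cs", "CS+ vs CS-", regex=False)
    plus = t[t[spec.cs_col] != CS_MINUS]
    b = fit_lme(plus, spec, "csr_vs_csn")
    b["effect"] = b["effect"].str.replace("cs", "CSr+ vs CSn+", regex=False)
    b = b[b["effect"].str.contains("CSr")]
    return pd.concat([a, b], ignore_index=True)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (conditionwise measures)

def fit_rm_anova(cond_table: pd.DataFrame, value_col: str = "amplitude",
                 participant_col: str = "participant", cs_col: str = "cs",
                 group_col: str | None = "group") -> pd.DataFrame:
    """Mixed-design ANOVA on condition-wise amplitudes.

    Within-subject CS contrasts (pooled CS⁺ vs CS⁻; CSr⁺ vs CSn⁺) and their
    group interactions are tested against the pooled within-subject error
    (df (n−g)(k−1)); the between-group effect against the subject error
    (df n−g).  With a single group, pass ``group_col=None``.
    """
    wide = cond_table.pivot_table(index=participant_col, columns=cs_col,
                                  values=value_col)
    conds = list(wide.columns)
    k = len(conds)
    n = len(wide)
    Y = wide.to_numpy(float)
    if group_col is not None:
        gmap = cond_table.drop_duplicates(participant_col).set_index(
            participant_col)[group_col]
        glab = gmap.loc[wide.index].to_numpy()
        groups = sorted(pd.unique(glab))
    else:
        glab = np.array(["all"] * n)
        groups = ["all"]
    g = len(groups)

    # orthonormal within-subject contrasts
    if set(conds) == {CS_MINUS, CSR, CSN}:
        raw = {
            "CS+ vs CS-": np.array([{CS_MINUS: -1.0, CSR: 0.5, CSN: 0.5}[c]
                                    for c in conds]),
            "CSr+ vs CSn+": np.array([{CS_MINUS: 0.0, CSR: 1.0, CSN: -1.0}[c]
                                      for c in conds]),
        }
    else:
        helm = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, :k - 1]
        raw = {f"c{j+1}": helm[:, j] for j in range(k - 1)}
    C = {name: v / np.linalg.norm(v) for name, v in raw.items()}

    # pooled within-subject error: residual variation of all contrast scores
    # after removing group means, summed over an orthonormal basis
    basis = np.linalg.qr(np.column_stack(list(C.values())))[0]
    err_ss = 0.0
    for j in range(basis.shape[1]):
        s = Y @ basis[:, j]
        for grp in groups:
            m = glab == grp
            err_ss += float(np.sum((s[m] - s[m].mean()) ** 2))
    err_df = (n - g) * (k - 1)

    rows = []
    # between-group effect on the subject means
    subj_mean = Y.mean(axis=1)
    gm = subj_mean.mean()
    ss_grp = sum(np.sum(glab == grp) * (subj_mean[glab == grp].mean() - gm) ** 2
                 for grp in groups)
    ss_subj = sum(np.sum((subj_mean[glab == grp]
                          - subj_mean[glab == grp].mean()) ** 2)
                  for grp in groups)
    if g > 1:
        F = (ss_grp / (g - 1)) / (ss_subj / (n - g))
        rows.append(dict(effect="group", F=float(F), df_num=g - 1,
                         df_den=n - g,
                         p=float(stats.f.sf(F, g - 1, n - g))))

    for name, c in C.items():
        s = Y @ c
        grp_means = np.array([s[glab == grp].mean() for grp in groups])
        grp_ns = np.array([np.sum(glab == grp) for grp in groups])
        # contrast main effect: unweighted mean of group means vs 0
        grand_u = float(grp_means.mean())
        w = float(np.sum(1.0 / (g ** 2 * grp_ns)))
        F_main = (grand_u ** 2 / w) / (err_ss / err_df)
        rows.append(dict(effect=name, F=float(F_main), df_num=1, df_den=err_df,
                         p=float(stats.f.sf(F_main, 1, err_df))))
        if g > 1:
            grand_w = float(np.sum(grp_ns * grp_means) / n)
            ss_int = float(np.sum(grp_ns * (grp_means - grand_w) ** 2))
            F_int = (ss_int / (g - 1)) / (err_ss / err_df)
            rows.append(dict(effect=f"group x {name}", F=float(F_int),
                             df_num=g - 1, df_den=err_df,
                             p=float(stats.f.sf(F_int, g - 1, err_df))))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons and clearance

def compare_groups(values: np.ndarray, labels: np.ndarray,
                   paired: bool = False) -> tuple[float, float, float]:
    """Two-sample (or paired) t test; returns ``(t, df, p)``."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levs = pd.unique(labels)
    if len(levs) != 2:
        raise ValueError("need exactly two groups")
    a, b = values[labels == levs[0]], values[labels == levs[1]]
    if paired:
        res = stats.ttest_rel(a, b)
        df = len(a) - 1
    else:
        res = stats.ttest_ind(a, b)
        df = len(a) + len(b) - 2
    t = float(res.statistic)
    if np.isnan(t) and np.var(a) == 0 and np.var(b) == 0:
        # degenerate zero-variance case: identical groups are simply equal
        t = 0.0 if np.mean(a) == np.mean(b) else np.inf
        return t, float(df), 1.0 if t == 0.0 else 0.0
    return t, float(df), float(res.pvalue)


def clearance_fraction(half_life_h: float, elapsed_h: float) -> float:
    """Fraction of a drug eliminated after ``elapsed_h`` hours.

    First-order kinetics: 1 − 2^(−elapsed/half-life).  E.g. a 16 h half-life
    drug is >99.9% cleared one week (168 h) after ingestion.
    """
    if half_life_h <= 0:
        raise ValueError("half-life must be positive")
    if elapsed_h < 0:
        raise ValueError("elapsed time must be nonnegative")
    return 1.0 - 2.0 ** (-elapsed_h / half_life_h)
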