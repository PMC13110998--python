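"""Phase-level inference: mixed models, contrasts, and repeatability.

The unit of analysis is one animal x session x phase summary metric. For
each variable a linear mixed model is fitted by restricted maximum
likelihood with phase as a fixed effect and animal as a random intercept;
both sessions enter as repeated rows per animal. The overall phase effect
is an F-test with Satterthwaite-approximated (fractional) denominator
degrees of freedom, post-hoc all-pairwise phase contrasts are computed on
the estimated marginal means with Tukey-family multiplicity adjustment,
and between-session repeatability is the two-way random-effects,
absolute-agreement, single-rater intraclass correlation ICC(2,1).

Model: y = X beta + Z u + e, with u ~ N(0, sigma_a^2 I) per animal and
e ~ N(0, sigma_e^2 I). The REML criterion is profiled over the variance
ratio theta = sigma_a^2/sigma_e^2 (bounded, non-negative); Satterthwaite
degrees of freedom use the delta method: for a contrast l,
df = 2 f^2 / (g' A g) with f = l' C l, g = df/d(variance components), and
A the asymptotic covariance of the REML variance estimates (2 x inverse
Hessian of the REML deviance). On balanced complete data this reproduces
the classical repeated-measures ANOVA F and integer df exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import PHASES

__all__ = [
    "LMMFit",
    "ModelResult",
    "Contrast",
    "ICCResult",
    "DiagnosticBundle",
    "fit_phase_lmm",
    "posthoc_contrasts",
    "residual_diagnostics",
    "session_icc",
    "icc_agreement",
    "simulate_phase_response",
    "fit_all_variables",
    "report_text",
]

_THETA_MAX = 1e6


# ---------------------------------------------------------------------------
# REML machinery (random intercept per group)
# ---------------------------------------------------------------------------

def _group_stats(X: np.ndarray, y: np.ndarray, codes: np.ndarray):
    """Per-group sufficient statistics for the block-diagonal V inverse."""
    groups = []
    for g in np.unique(codes):
        m = codes == g
        Xg, yg = X[m], y[m]
        groups.append((int(m.sum()), Xg.T @ Xg, Xg.sum(axis=0),
                       Xg.T @ yg, float(yg @ yg), float(yg.sum())))
    return groups


def _profiled_quantities(theta: float, groups, n: int, p: int):
    """(logdet V, X'V^-1 X, X'V^-1 y, r'V^-1 r) for V = I + theta ZZ'."""
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for n_g, XtX, Xs, Xty, yy, ys in groups:
        c = theta / (1.0 + theta * n_g)
        XtVX += XtX - c * np.outer(Xs, Xs)
        XtVy += Xty - c * ys * Xs
        ytVy += yy - c * ys * ys
        logdet += np.log1p(theta * n_g)
    beta = np.linalg.solve(XtVX, XtVy)
    rVr = max(ytVy - beta @ XtVy, 1e-300)
    return logdet, XtVX, XtVy, rVr, beta


def _profiled_deviance(theta: float, groups, n: int, p: int) -> float:
    logdet, XtVX, _, rVr, _ = _profiled_quantities(theta, groups, n, p)
    sign, logdet_xx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    return logdet + logdet_xx + (n - p) * np.log(rVr)


def _full_deviance(sigma_a2: float, sigma_e2: float, groups, n: int, p: int
                   ) -> float:
    """REML deviance (-2 log restricted likelihood up to an additive
    constant) as a function of the two variance components."""
    theta = sigma_a2 / sigma_e2
    logdet, XtVX, _, rVr, _ = _profiled_quantities(theta, groups, n, p)
    sign, logdet_xx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    return ((n - p) * np.log(sigma_e2) + logdet + logdet_xx
            + rVr / sigma_e2)


def _beta_cov(sigma_a2: float, sigma_e2: float, groups, p: int) -> np.ndarray:
    theta = sigma_a2 / sigma_e2
    _, XtVX, _, _, _ = _profiled_quantities(theta, groups, 0, p)
    return sigma_e2 * np.linalg.inv(XtVX)


@dataclass
class LMMFit:
    """Internal REML fit state shared by tests, contrasts and diagnostics."""

    variable: str
    levels: tuple[str, ...]          # phase levels present, protocol order
    beta: np.ndarray                 # estimated marginal means per level
    cov_beta: np.ndarray
    sigma2_subject: float
    sigma2_resid: float
    singular: bool                   # subject variance at the boundary
    n_obs: int
    n_subjects: int
    vc_cov: np.ndarray               # asymptotic cov of (sigma_a^2, sigma_e^2)
    #: gradients of the beta covariance w.r.t. (sigma_a^2, sigma_e^2):
    #: dC/ds_i = C X'S^-1 G_i S^-1 X C with G_1 = ZZ', G_2 = I
    grad_cov_beta: tuple[np.ndarray, np.ndarray] | None = field(
        repr=False, default=None)
    _X: np.ndarray | None = field(repr=False, default=None)
    _y: np.ndarray | None = field(repr=False, default=None)
    _codes: np.ndarray | None = field(repr=False, default=None)

    @property
    def p(self) -> int:
        return self._X.shape[1]

    def contrast_variance(self, ell: np.ndarray) -> float:
        return float(ell @ self.cov_beta @ ell)

    def satterthwaite_df(self, ell: np.ndarray) -> float:
        """Delta-method Satterthwaite df for one contrast: 2 f^2 / (g'Ag)."""
        f0 = self.contrast_variance(ell)
        if self.singular or self.grad_cov_beta is None:
            return float(self.n_obs - self.p)
        g = np.array([float(ell @ Bi @ ell) for Bi in self.grad_cov_beta])
        denom = float(g @ self.vc_cov @ g)
        if denom <= 0:
            return float(self.n_obs - self.p)
        df = 2.0 * f0 * f0 / denom
        return float(np.clip(df, 1.0, 1e7))


@dataclass
class Contrast:
    phase_a: str
    phase_b: str
    estimate: float     # EMM(phase_a) - EMM(phase_b)
    se: float
    t_stat: float
    df: float
    p_unadjusted: float
    p_adjusted: float   # Tukey family over all pairwise comparisons


@dataclass
class ModelResult:
    variable: str
    f_stat: float
    df_num: int
    df_den: float       # Satterthwaite, fractional
    p_value: float
    sigma2_subject: float
    sigma2_resid: float
    singular: bool
    fit: LMMFit
    contrasts: list[Contrast] = field(default_factory=list)


@dataclass
class ICCResult:
    variable: str
    icc: float
    ci_low: float
    ci_high: float
    model: str
    n_pairs: int
    n_dropped: int


@dataclass
class DiagnosticBundle:
    fitted: np.ndarray
    residuals: np.ndarray            # conditional (subject effects removed)
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    shapiro_w: float
    shapiro_p: float
    normality_ok: bool


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _method_of_moments_theta(X: np.ndarray, y: np.ndarray,
                             codes: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    group_means = np.array([r[codes == g].mean() for g in np.unique(codes)])
    n_bar = len(y) / len(group_means)
    s2_w = float(r.var(ddof=X.shape[1])) if len(y) > X.shape[1] else float(r.var())
    s2_b = max(float(group_means.var(ddof=1)) - s2_w / n_bar, 0.0) \
        if len(group_means) > 1 else 0.0
    if s2_w <= 0:
        return 1e-4
    return max(s2_b / s2_w, 1e-4)


def fit_phase_lmm(table: pd.DataFrame, variable: str,
                  include_session: bool = False) -> ModelResult:
    """REML mixed-model fit of ``variable ~ phase + (1 | animal)``.

    Both sessions are pooled as repeated rows per animal. The design matrix
    uses a cell-means coding, so the fixed-effect coefficients are the
    estimated marginal means per phase; with ``include_session`` a centred
    session term is added (EMMs then average over sessions). Missing
    animal x session x phase rows are simply absent — the likelihood
    handles the imbalance, nothing is imputed. A fit with the subject
    variance at the zero boundary is flagged ``singular``, not fatal.
    """
    df = table.dropna(subset=[variable]).copy()
    levels = tuple(ph for ph in PHASES if ph in set(df["phase"]))
    if len(levels) < 2:
        raise ValueError("need at least 2 phases present")
    subjects = sorted(df["animal"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    y = df[variable].to_numpy(dtype=float)
    if np.ptp(y) < 1e-12:
        raise ValueError(f"degenerate fit: response {variable!r} is constant")
    phase_idx = {ph: i for i, ph in enumerate(levels)}
    X = np.zeros((len(df), len(levels)))
    X[np.arange(len(df)), df["phase"].map(phase_idx)] = 1.0
    if include_session:
        X = np.column_stack([X, df["session"].to_numpy(dtype=float)
                             - df["session"].mean()])
    codes = df["animal"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough observations to fit the model")
    groups = _group_stats(X, y, codes)

    theta0 = _method_of_moments_theta(X, y, codes)
    # bounded profile optimisation; bracket grown around the moment start
    hi = max(100.0 * theta0, 100.0)
    res = optimize.minimize_scalar(
        _profiled_deviance, args=(groups, n, p), bounds=(0.0, min(hi, _THETA_MAX)),
        method="bounded", options={"xatol": 1e-10})
    theta = float(res.x)
    # re-optimise on an expanded bracket if we ran into the ceiling
    while theta > 0.98 * hi and hi < _THETA_MAX:
        hi = min(hi * 100.0, _THETA_MAX)
        res = optimize.minimize_scalar(
            _profiled_deviance, args=(groups, n, p), bounds=(0.0, hi),
            method="bounded", options={"xatol": 1e-10})
        theta = float(res.x)
    logdet, XtVX, XtVy, rVr, beta = _profiled_quantities(theta, groups, n, p)
    sigma_e2 = rVr / (n - p)
    sigma_a2 = theta * sigma_e2
    singular = theta < 1e-6

    C = sigma_e2 * np.linalg.inv(XtVX)
    if singular:
        vc_cov = np.full((2, 2), np.nan)
        grad_cov_beta = None
    else:
        vc_cov, grad_cov_beta = _satterthwaite_pieces(
            sigma_a2, sigma_e2, X, y, codes, C)
    fit = LMMFit(variable=variable, levels=levels, beta=beta, cov_beta=C,
                 sigma2_subject=sigma_a2, sigma2_resid=sigma_e2,
                 singular=singular, n_obs=n, n_subjects=len(subjects),
                 vc_cov=vc_cov, grad_cov_beta=grad_cov_beta,
                 _X=X, _y=y, _codes=codes)

    f_stat, df_num, df_den, p_value = _overall_f(fit)
    return ModelResult(variable=variable, f_stat=f_stat, df_num=df_num,
                       df_den=df_den, p_value=p_value,
                       sigma2_subject=sigma_a2, sigma2_resid=sigma_e2,
                       singular=singular, fit=fit)


def _satterthwaite_pieces(sigma_a2: float, sigma_e2: float, X: np.ndarray,
                          y: np.ndarray, codes: np.ndarray, C: np.ndarray,
                          ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Analytic ingredients of the delta-method Satterthwaite df.

    Returns the asymptotic covariance of (sigma_a^2, sigma_e^2) — twice
    the inverse observed Hessian of the REML deviance — and the gradient
    matrices dC/d(sigma_i^2) of the fixed-effect covariance. Closed forms
    for Sigma = sigma_e^2 I + sigma_a^2 ZZ':

        dD/ds_i   = tr(P G_i) - y'P G_i P y
        d2D/ds_i ds_j = -tr(P G_i P G_j) + 2 y'P G_i P G_j P y
        dC/ds_i   = C X'S^-1 G_i S^-1 X C

    with G_1 = ZZ', G_2 = I, S = Sigma and P the REML projection
    S^-1 - S^-1 X (X'S^-1 X)^-1 X'S^-1. n is small here, so the dense
    n x n forms are cheapest and exact."""
    n = len(y)
    n_groups = int(codes.max()) + 1
    Z = np.zeros((n, n_groups))
    Z[np.arange(n), codes] = 1.0
    Sigma = sigma_e2 * np.eye(n) + sigma_a2 * (Z @ Z.T)
    Sinv = np.linalg.inv(Sigma)
    SinvX = Sinv @ X
    XtSX_inv = np.linalg.inv(X.T @ SinvX)
    P = Sinv - SinvX @ XtSX_inv @ SinvX.T
    G1 = Z @ Z.T
    Py = P @ y
    H = np.zeros((2, 2))
    PG = (P @ G1, P)                 # P G_1, P G_2 (G_2 = I)
    GPy = (G1 @ Py, Py)
    for i in range(2):
        for j in range(i, 2):
            tr = float(np.trace(PG[i] @ PG[j]))
            quad = float(GPy[i] @ P @ GPy[j])
            H[i, j] = H[j, i] = -tr + 2.0 * quad
    try:
        vc_cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vc_cov = 2.0 * np.linalg.pinv(H)
    B1 = C @ (SinvX.T @ G1 @ SinvX) @ C
    B2 = C @ (SinvX.T @ SinvX) @ C
    return vc_cov, (B1, B2)


def _overall_f(fit: LMMFit) -> tuple[float, int, float, float]:
    """Overall phase F-test with multi-df Satterthwaite denominator.

    The joint test is decomposed along the eigenvectors of the contrast
    covariance; each 1-df component gets a delta-method Satterthwaite df
    and the components are pooled into a single denominator df."""
    k = len(fit.levels)
    q = k - 1
    L = np.zeros((q, fit.p))
    for i in range(q):
        L[i, 0] = 1.0
        L[i, i + 1] = -1.0
    M = L @ fit.cov_beta @ L.T
    Lb = L @ fit.beta
    f_stat = float(Lb @ np.linalg.solve(M, Lb)) / q
    if fit.singular:
        df_den = float(fit.n_obs - fit.p)
    else:
        eigval, eigvec = np.linalg.eigh(M)
        nus = []
        for i in range(q):
            ell = eigvec[:, i] @ L
            nus.append(fit.satterthwaite_df(ell))
        nus = np.array(nus)
        usable = nus > 2.0
        if usable.any():
            E = float(np.sum(nus[usable] / (nus[usable] - 2.0)))
            df_den = 2.0 * E / (E - q) if E > q else float(fit.n_obs - fit.p)
        else:
            df_den = float(fit.n_obs - fit.p)
    p_value = float(stats.f.sf(f_stat, q, df_den))
    return f_stat, q, df_den, p_value


def posthoc_contrasts(model: ModelResult) -> list[Contrast]:
    """All pairwise phase contrasts on the estimated marginal means.

    Estimates are EMM(earlier phase) - EMM(later phase) in protocol order;
    each contrast carries its own Satterthwaite df and a Tukey-family
    adjusted p-value (studentised range over the phase levels present)."""
    fit = model.fit
    k = len(fit.levels)
    out: list[Contrast] = []
    for i, j in itertools.combinations(range(k), 2):
        ell = np.zeros(fit.p)
        ell[i], ell[j] = 1.0, -1.0
        est = float(ell @ fit.beta)
        var = fit.contrast_variance(ell)
        se = float(np.sqrt(var))
        t = est / se
        df = fit.satterthwaite_df(ell)
        p_un = float(2.0 * stats.t.sf(abs(t), df))
        p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        p_adj = min(max(p_adj, p_un), 1.0)
        out.append(Contrast(phase_a=fit.levels[i], phase_b=fit.levels[j],
                            estimate=est, se=se, t_stat=t, df=df,
                            p_unadjusted=p_un, p_adjusted=p_adj))
    model.contrasts = out
    return out


def residual_diagnostics(model: ModelResult) -> DiagnosticBundle:
    """QQ and residual-vs-fitted data plus a Shapiro-Wilk screen.

    Residuals are conditional (predicted subject effects removed); the
    model-checking here is plot-first, the Shapiro-Wilk p-value is only a
    numeric screen for gross non-normality."""
    fit = model.fit
    if fit.n_obs < 3:
        raise ValueError("need at least 3 observations for diagnostics")
    X, y, codes = fit._X, fit._y, fit._codes
    r_marg = y - X @ fit.beta
    theta = fit.sigma2_subject / fit.sigma2_resid
    u = np.zeros_like(r_marg)
    for g in np.unique(codes):
        m = codes == g
        n_g = m.sum()
        shrink = theta * n_g / (1.0 + theta * n_g)
        u[m] = shrink * r_marg[m].mean()
    resid = r_marg - u
    fitted = X @ fit.beta + u
    (osm, osr), _ = stats.probplot(resid, dist="norm")
    w, p = stats.shapiro(resid)
    return DiagnosticBundle(fitted=fitted, residuals=resid,
                            qq_theoretical=osm, qq_sample=osr,
                            shapiro_w=float(w), shapiro_p=float(p),
                            normality_ok=bool(p >= 0.05))


# ---------------------------------------------------------------------------
# Repeatability (ICC)
# ---------------------------------------------------------------------------

def icc_agreement(matrix: np.ndarray, alpha: float = 0.05
                  ) -> tuple[float, float, float]:
    """ICC(2,1) with its F-based confidence interval on an n x k matrix.

    Two-way random effects, absolute agreement, single rater
    (Shrout-Fleiss / McGraw-Wong). Rows are targets (animal x phase
    pairs), columns the repeated sessions."""
    Y = np.asarray(matrix, dtype=float)
    n, k = Y.shape
    if n < 3 or k < 2:
        raise ValueError("ICC needs at least 3 rows and 2 columns")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((Y - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise ValueError("degenerate ICC: no variance between targets")
    icc = (msr - mse) / denom

    if mse <= 0 and msc <= 0:       # exact agreement: CI collapses
        return float(icc), float(icc), float(icc)
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return float(icc), float(icc), float(icc)
    v = ((a * msc + b * mse) ** 2
         / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_l * mse)
             / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_u * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    return float(icc), float(lower), float(upper)


def session_icc(table: pd.DataFrame, variable: str) -> ICCResult:
    """Between-session repeatability of one variable.

    Animal x phase cells with both sessions present form the paired
    matrix; incomplete pairs are dropped and counted, never imputed."""
    wide = (table.pivot_table(index=["animal", "phase"], columns="session",
                              values=variable, aggfunc="first")
            .reindex(columns=[1, 2]))
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if len(complete) < 3:
        raise ValueError(
            f"need >= 3 complete session pairs, have {len(complete)}")
    icc, lo, hi = icc_agreement(complete.to_numpy())
    return ICCResult(variable=variable, icc=icc, ci_low=lo, ci_high=hi,
                     model="ICC(2,1) two-way random, absolute agreement, single rater",
                     n_pairs=len(complete), n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Simulation helper and reporting
# ---------------------------------------------------------------------------

def simulate_phase_response(phase_means: dict[str, float], sigma_a: float,
                            sigma_e: float, n_subjects: int, n_sessions: int,
                            rng: np.random.Generator,
                            variable: str = "y") -> pd.DataFrame:
    """Phase-observation table drawn from the mixed model itself:
    subject intercepts N(0, sigma_a^2), residuals N(0, sigma_e^2)."""
    phases = list(phase_means)
    u = rng.normal(0.0, sigma_a, n_subjects)
    rows = []
    for si in range(n_sessions):
        for ai in range(n_subjects):
            for ph in phases:
                rows.append({
                    "animal": f"A{ai + 1}", "session": si + 1, "phase": ph,
                    variable: phase_means[ph] + u[ai]
                    + rng.normal(0.0, sigma_e)})
    return pd.DataFrame(rows)


def fit_all_variables(table: pd.DataFrame,
                      variables: tuple[str, ...] = (
                          "cov_rl", "cov_vd", "roi_r", "tiv", "miv",
                          "eeli", "tidal_rate", "ti"),
                      ) -> tuple[list[ModelResult], list[ICCResult]]:
    models = []
    iccs = []
    for var in variables:
        model = fit_phase_lmm(table, var)
        posthoc_contrasts(model)
        models.append(model)
        try:
            iccs.append(session_icc(table, var))
        except ValueError:
            pass
    return models, iccs


def report_text(models: list[ModelResult], iccs: list[ICCResult]) -> str:
    """Plain-text report in the field's conventional style."""
    lines = ["Phase effect (linear mixed model, Satterthwaite F):", ""]
    for m in models:
        flag = "  [singular: zero subject variance]" if m.singular else ""
        lines.append(
            f"  {m.variable:>10}: F({m.df_num}, {m.df_den:.2f}) = "
            f"{m.f_stat:.2f}, p = {m.p_value:.3g}{flag}")
        sig = [c for c in m.contrasts if c.p_adjusted < 0.05]
        for c in sig:
            lines.append(
                f"      {c.phase_a} vs {c.phase_b}: beta = {c.estimate:.2f}, "
                f"SE = {c.se:.2f}; t({c.df:.2f}) = {c.t_stat:.2f}, "
                f"p = {c.p_adjusted:.3g} (Tukey-adjusted)")
    lines += ["", "Between-session repeatability, ICC(2,1):", ""]
    for r in iccs:
        lines.append(
            f"  {r.variable:>10}: ICC = {r.icc:.3f} "
            f"(95% CI {r.ci_low:.3f} to {r.ci_high:.3f}; "
            f"{r.n_pairs} pairs, {r.n_dropped} dropped)")
    return "\n".join(lines) + "\n"
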