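"""Statistical layer: normality-gated paired comparisons, Pearson
correlations, generalized linear mixed-effects models, and the beta-matched
trial-subgroup control.

Reaction times are right-skewed, so the RT models use an inverse-Gaussian
response with an identity link; fixed slopes are shared across hemispheres
and a random intercept varies by hemisphere.  No installed package fits that
model, so the marginal likelihood is maximized here directly with a Laplace
approximation over the random intercept (the same approximation lme4 uses by
default).  Gaussian-response models delegate to statsmodels' linear mixed
model (ML, so AIC is comparable across fixed-effect structures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sstats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "paired_compare",
    "correlate",
    "GlmeSpec",
    "GlmeResult",
    "fit_glme",
    "match_beta_trials",
    "MODEL_REGISTRY",
    "PairedResult",
]


# ---------------------------------------------------------------------------
# paired comparisons and correlation

@dataclass
class PairedResult:
    test: str  # "paired_t" or "wilcoxon"
    statistic: float
    p_raw: float
    p_corrected: float
    normal: bool
    n: int


def paired_compare(x, y, n_comparisons: int = 1) -> PairedResult:
    """Paired t-test or Wilcoxon signed-rank, gated by an Anderson-Darling
    normality test of the differences (5 % level), Bonferroni-corrected."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    import warnings as _warnings

    with _warnings.catch_warnings():
        # the 5 % critical-value gate is the intended decision rule
        _warnings.simplefilter("ignore", FutureWarning)
        ad = sstats.anderson(d, dist="norm")
    crit_5pct = ad.critical_values[list(ad.significance_level).index(5.0)]
    normal = bool(ad.statistic < crit_5pct)
    if normal:
        stat, p = sstats.ttest_rel(x, y)
        test = "paired_t"
    else:
        if np.allclose(d, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sstats.wilcoxon(x, y)
        test = "wilcoxon"
    return PairedResult(
        test=test,
        statistic=float(stat),
        p_raw=float(p),
        p_corrected=float(min(p * n_comparisons, 1.0)),
        normal=normal,
        n=int(x.size),
    )


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# mixed models

@dataclass
class GlmeSpec:
    """One mixed-model specification: response ~ 1 + predictors + (1 | group)."""

    name: str
    response: str
    predictors: list[str]
    distribution: str = "inverse_gaussian"  # or "normal"
    grouping: str = "hemisphere"

    def __post_init__(self) -> None:
        if self.distribution not in ("inverse_gaussian", "normal"):
            raise ValueError(f"unsupported distribution {self.distribution!r}")

    @property
    def formula(self) -> str:
        terms = " + ".join(["1"] + self.predictors + [f"(1|{self.grouping})"])
        return f"{self.response} ~ {terms}"


@dataclass
class GlmeResult:
    spec: GlmeSpec
    coefficients: pd.DataFrame  # term, estimate, se, z, p
    aic: float
    r2: float
    loglik: float
    scale_params: dict = field(default_factory=dict)
    fitted: np.ndarray | None = None

    def coef(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "p"])


def _design(table: pd.DataFrame, spec: GlmeSpec):
    cols = [spec.response, *spec.predictors, spec.grouping]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"trial table lacks columns {missing}")
    df = table[cols].dropna()
    y = df[spec.response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in spec.predictors])
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in model variables")
    groups = df[spec.grouping].to_numpy()
    terms = ["intercept", *spec.predictors]
    # diagnose rank deficiency by naming the first dependent column
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise ValueError(f"singular fit: predictor {terms[j]!r} is collinear")
        raise ValueError("singular design matrix")
    return y, X, groups, terms


def _ig_loglik_obs(y: np.ndarray, mu: np.ndarray, lam: float) -> np.ndarray:
    return 0.5 * np.log(lam / (2 * np.pi * y**3)) - lam * (y - mu) ** 2 / (2 * mu**2 * y)


def _ig_group_laplace(y, eta, lam, sig2) -> float:
    """Laplace-approximated marginal log-likelihood of one group."""
    b = 0.0
    penalty = 0.0
    for _ in range(50):
        mu = eta + b
        bad = mu <= 1e-4
        if bad.any():
            mu = np.maximum(mu, 1e-4)
        score = np.sum(lam * (y - mu) / mu**3) - b / sig2
        info = np.sum(lam / mu**3) + 1.0 / sig2
        step = score / info
        step = np.clip(step, -0.1, 0.1)
        b += step
        if abs(step) < 1e-10:
            break
    mu = eta + b
    if (mu <= 1e-4).any():
        penalty = 1e4 * float(np.sum(np.maximum(1e-4 - mu, 0)) ** 2 + 1.0)
        mu = np.maximum(mu, 1e-4)
    h = float(np.sum(_ig_loglik_obs(y, mu, lam))) - b**2 / (2 * sig2) \
        - 0.5 * np.log(2 * np.pi * sig2)
    info = np.sum(lam / mu**3) + 1.0 / sig2
    return h + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(info) - penalty


def _ig_blups(y, X, groups, beta, lam, sig2):
    out = {}
    for g in np.unique(groups):
        m = groups == g
        eta = X[m] @ beta
        b = 0.0
        for _ in range(50):
            mu = np.maximum(eta + b, 1e-4)
            score = np.sum(lam * (y[m] - mu) / mu**3) - b / sig2
            info = np.sum(lam / mu**3) + 1.0 / sig2
            step = np.clip(score / info, -0.1, 0.1)
            b += step
            if abs(step) < 1e-10:
                break
        out[g] = b
    return out


def _fit_ig_mixed(y, X, groups, terms) -> GlmeResult:
    uniq = np.unique(groups)
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    lam0 = max(np.mean(y) ** 3 / max(np.var(resid), 1e-8), 1e-3)
    gm = np.array([resid[groups == g].mean() for g in uniq])
    sig0 = max(float(np.std(gm)), 1e-3)
    theta0 = np.r_[beta0, np.log(lam0), np.log(sig0)]

    idx = {g: np.flatnonzero(groups == g) for g in uniq}

    def nll(theta):
        beta = theta[:-2]
        lam = np.exp(np.clip(theta[-2], -20, 30))
        sig2 = np.exp(2 * np.clip(theta[-1], -15, 10))
        eta = X @ beta
        tot = 0.0
        for g in uniq:
            m = idx[g]
            tot += _ig_group_laplace(y[m], eta[m], lam, sig2)
        return -tot

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9})
    res = optimize.minimize(nll, res.x, method="BFGS",
                            options={"maxiter": 200, "gtol": 1e-6})
    theta = res.x
    beta = theta[:-2]
    lam = float(np.exp(theta[-2]))
    sig_b = float(np.exp(theta[-1]))
    ll = -float(nll(theta))

    hess = approx_hess(theta, nll)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        # boundary fits (e.g. zero group variance, degenerate dispersion)
        # leave flat directions; the fixed-effect block is still informative
        cov = np.linalg.pinv(hess)
    se = np.sqrt(np.maximum(np.diag(cov)[: len(beta)], 0))
    z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.nan)
    p = 2 * sstats.norm.sf(np.abs(z))

    blups = _ig_blups(y, X, groups, beta, lam, sig_b**2)
    fitted = X @ beta + np.array([blups[g] for g in groups])
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0
    k = len(theta)
    coefs = pd.DataFrame(dict(term=terms, estimate=beta, se=se, z=z, p=p))
    return GlmeResult(
        spec=None,  # filled by caller
        coefficients=coefs,
        aic=float(2 * k - 2 * ll),
        r2=r2,
        loglik=ll,
        scale_params={"lambda": lam, "sigma_b": sig_b},
        fitted=fitted,
    )


def _fit_gaussian_mixed(y, X, groups, terms) -> GlmeResult:
    import warnings

    model = MixedLM(y, X, groups=groups)
    with warnings.catch_warnings():
        # a boundary fit (zero random-effect variance) is a legitimate outcome
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False, method="lbfgs")
    beta = np.asarray(fit.fe_params)
    se = np.asarray(fit.bse_fe)
    z = beta / se
    p = 2 * sstats.norm.sf(np.abs(z))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = np.asarray(fit.fittedvalues)
    except (ValueError, np.linalg.LinAlgError):
        fitted = X @ beta  # singular RE covariance: no BLUPs to add
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0
    k = len(beta) + 2  # + residual variance + random-intercept variance
    ll = float(fit.llf)
    coefs = pd.DataFrame(dict(term=terms, estimate=beta, se=se, z=z, p=p))
    return GlmeResult(
        spec=None,
        coefficients=coefs,
        aic=float(2 * k - 2 * ll),
        r2=r2,
        loglik=ll,
        scale_params={
            "sigma_e": float(np.sqrt(fit.scale)),
            "sigma_b": float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0))),
        },
        fitted=fitted,
    )


def fit_glme(table: pd.DataFrame, spec: GlmeSpec) -> GlmeResult:
    """Fit ``response ~ 1 + predictors + (1 | group)`` by maximum likelihood."""
    y, X, groups, terms = _design(table, spec)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 grouping levels for a random intercept")
    if spec.distribution == "inverse_gaussian":
        if (y <= 0).any():
            raise ValueError("inverse-Gaussian response must be positive")
        result = _fit_ig_mixed(y, X, groups, terms)
    else:
        result = _fit_gaussian_mixed(y, X, groups, terms)
    result.spec = spec
    return result


# ---------------------------------------------------------------------------
# beta-matched subgroup control

def match_beta_trials(
    beta_training,
    beta_no_training,
    fraction: float = 0.75,
    balance_tol_sd: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-neighbour matching on normalized beta power.

    Keeps ``fraction`` of the smaller condition group, pairing each kept
    Training trial with its closest No-Training trial without replacement.
    Asserts the matched group means differ by less than ``balance_tol_sd``
    pooled standard deviations; raises a diagnostic error otherwise.
    Returns (training_indices, no_training_indices).
    """
    a = np.asarray(beta_training, dtype=float)
    b = np.asarray(beta_no_training, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both condition groups must be nonempty")
    n_keep = int(np.floor(fraction * min(a.size, b.size)))
    if n_keep < 1:
        raise ValueError("too few trials to match")
    dist = np.abs(a[:, None] - b[None, :])
    order = np.argsort(dist, axis=None, kind="stable")
    used_a = np.zeros(a.size, bool)
    used_b = np.zeros(b.size, bool)
    ia, ib = [], []
    for flat in order:
        i, j = divmod(int(flat), b.size)
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        ia.append(i)
        ib.append(j)
        if len(ia) == n_keep:
            break
    ia = np.array(ia)
    ib = np.array(ib)
    pooled_sd = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2) if min(a.size, b.size) > 1 else 0.0
    gap = abs(a[ia].mean() - b[ib].mean())
    if pooled_sd > 0 and gap >= balance_tol_sd * pooled_sd:
        raise ValueError(
            f"matching failed balance check: matched means differ by "
            f"{gap:.4g} (> {balance_tol_sd} x pooled SD {pooled_sd:.4g}); "
            "the beta distributions are too dissimilar"
        )
    return ia, ib


# ---------------------------------------------------------------------------
# model registry (trial-table column conventions, see pipeline)

def _rt(name, preds):
    return GlmeSpec(name=name, response="rt", predictors=preds)


MODEL_REGISTRY: dict[str, GlmeSpec] = {
    # reaction-time family (inverse Gaussian, identity link)
    "m1": _rt("m1", ["torn"]),
    "m2": _rt("m2", ["beta_pre_db"]),
    "m3": _rt("m3", ["dur1_pre"]),
    "m4": _rt("m4", ["dur2_pre"]),
    "m5": _rt("m5", ["num_pre"]),
    "m6": _rt("m6", ["torn", "beta_pre_db", "gamma_pre_db", "alpha_pre_db"]),
    "m7": _rt("m7", ["beta_eeg_pre_db"]),
    "m8": _rt("m8", ["torn", "beta_eeg_pre_db", "alpha_eeg_pre_db"]),
    "m9": _rt("m9", ["torn", "beta_pre_db", "gamma_pre_db", "beta_eeg_pre_db"]),
    # tremor (normal response; the response is already a normalized percent change)
    "tremor": GlmeSpec("tremor", "tremor_pct", ["torn", "beta_pre_db", "theta_pre_db"],
                       distribution="normal"),
    # carry-over: 2 s pre-cue measures predicted by the 4 s feedback-phase measures
    "carry_beta": GlmeSpec("carry_beta", "beta_pre_pct", ["beta_fb_pct"], distribution="normal"),
    "carry_dur1": GlmeSpec("carry_dur1", "dur1_pre", ["dur1_fb"], distribution="normal"),
    "carry_gamma": GlmeSpec("carry_gamma", "gamma_pre_pct", ["gamma_fb_pct"], distribution="normal"),
    # carry-over: same pre-cue measures predicted by the condition
    "carry_beta_cond": GlmeSpec("carry_beta_cond", "beta_pre_pct", ["torn"], distribution="normal"),
    "carry_dur1_cond": GlmeSpec("carry_dur1_cond", "dur1_pre", ["torn"], distribution="normal"),
    "carry_gamma_cond": GlmeSpec("carry_gamma_cond", "gamma_pre_pct", ["torn"], distribution="normal"),
}

#: models that require two recording days (fit on per-day tables)
DAY_MODEL_REGISTRY: dict[str, GlmeSpec] = {
    "day_ball": GlmeSpec("day_ball", "final_y_diff", ["day"], distribution="normal"),
    "day_beta": GlmeSpec("day_beta", "beta_fb_pct_diff", ["day"], distribution="normal"),
    "day_dur1": GlmeSpec("day_dur1", "dur1_fb_diff", ["day"], distribution="normal"),
    "day_tremor": GlmeSpec("day_tremor", "tremor_pct",
                           ["torn", "day", "beta_pre_db", "theta_pre_db"],
                           distribution="normal"),
}
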