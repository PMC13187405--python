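"""Assumption-gated agreement analysis between model and reference biomarkers.

Each biomarker's paired values pass through a distributional gate
(Shapiro-Wilk normality on the differences, Levene homogeneity across the
two methods). The gate selects the parametric path — two-way single-
measurement ICC with an F-based CI, mean/1.96-SD Bland-Altman limits, OLS
regression with R^2 — or the non-parametric path — bootstrap mixed-effects
ICC, percentile Bland-Altman, Gaussian-process regression. Spearman's rho is
always reported, and p-values are BH-adjusted across the analysis batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .seg_eval import bh_adjust
from .volume_io import logger


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired values must be two 1D arrays of equal length")
    return a, b


# ---------------------------------------------------------------------------
# Assumption gate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateOutcome:
    shapiro_p: float
    levene_p: float
    parametric: bool
    degenerate: bool = False


def gate_assumptions(reference, model, alpha: float = 0.05) -> GateOutcome:
    """Shapiro-Wilk on the differences and Levene across the two methods.

    The parametric flag requires both screens to pass at ``alpha``. Constant
    differences leave Shapiro-Wilk undefined; the non-parametric path is
    taken with a warning.
    """
    a, b = _paired(reference, model)
    if a.size < 4:
        raise ValueError(f"insufficient pairs: n={a.size} < 4")
    diff = b - a
    if np.ptp(diff) == 0.0:
        logger.warning("gate: constant differences; Shapiro-Wilk undefined, "
                       "taking the non-parametric path")
        return GateOutcome(float("nan"), float("nan"), parametric=False, degenerate=True)
    shapiro_p = float(stats.shapiro(diff).pvalue)
    levene_p = float(stats.levene(a, b, center="mean").pvalue)
    return GateOutcome(shapiro_p, levene_p,
                       parametric=(shapiro_p >= alpha and levene_p >= alpha))


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    method: str  # parametric_two_way_single | bootstrap_mixed_effects
    definition: str  # consistency | absolute_agreement


def _two_way_mean_squares(a: np.ndarray, b: np.ndarray):
    data = np.stack([a, b], axis=1)  # n subjects x k=2 raters
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse


def icc(reference, model, definition: str = "consistency",
        method: str = "parametric", n_boot: int = 10000,
        seed: int | None = 0, alpha: float = 0.05) -> ICCResult:
    """Two-rating ICC between a reference and a model measurement.

    ``parametric`` computes the two-way single-measurement ICC from the
    mean-squares decomposition: the consistency form ICC(3,1)
    (MSR-MSE)/(MSR+(k-1)MSE) with an F-based CI, or the absolute-agreement
    form ICC(2,1) including the rater variance term. ``bootstrap`` estimates
    the random-intercept variance ratio sigma2_subject/(sigma2_subject +
    sigma2_error) by one-way ANOVA method-of-moments, with a percentile CI
    from subject-level resamples.
    """
    a, b = _paired(reference, model)
    if a.size < 5:
        raise ValueError(f"need at least 5 pairs for ICC, got {a.size}")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        raise ValueError("zero total variance; ICC undefined")

    if method == "parametric":
        n, k, msr, msc, mse = _two_way_mean_squares(a, b)
        if definition == "consistency":
            value = (msr - mse) / (msr + (k - 1) * mse)
            f = msr / mse if mse > 0 else np.inf
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + (k - 1))
            hi = (fu - 1) / (fu + (k - 1))
        elif definition == "absolute_agreement":
            value = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
            # Satterthwaite df then F-bounds (two-way random, single measurement)
            fj = msc / mse if mse > 0 else np.inf
            term = n * (1 + (k - 1) * value) - k * value
            v_num = (k - 1) * (n - 1) * (k * value * fj + term) ** 2
            v_den = ((n - 1) * (k * value * fj) ** 2 + term**2)
            v = v_num / v_den
            f_lower = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_upper = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f_lower * mse)
                  / (f_lower * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi = (n * (f_upper * msr - mse)
                  / (k * msc + (k * n - k - n) * mse + n * f_upper * msr))
        else:
            raise ValueError("definition must be 'consistency' or 'absolute_agreement'")
        return ICCResult(float(value), float(lo), float(hi),
                         "parametric_two_way_single", definition)

    if method != "bootstrap":
        raise ValueError("method must be 'parametric' or 'bootstrap'")

    def _vr(aa: np.ndarray, bb: np.ndarray) -> float:
        data = np.stack([aa, bb], axis=1)
        n, k = data.shape
        row_means = data.mean(axis=1)
        msb = k * np.sum((row_means - data.mean()) ** 2) / (n - 1)
        msw = np.sum((data - row_means[:, None]) ** 2) / (n * (k - 1))
        return (msb - msw) / (msb + (k - 1) * msw)

    point = _vr(a, b)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _vr(a[idx[i]], b[idx[i]])
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return ICCResult(float(point), float(lo), float(hi),
                     "bootstrap_mixed_effects", "variance_ratio")


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    method: str  # parametric | percentile


def bland_altman(reference, model, parametric: bool = True) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of model - reference differences.

    Parametric: mean difference +/- 1.96 SD. Percentile: median difference
    with 2.5th/97.5th percentile limits.
    """
    a, b = _paired(reference, model)
    if a.size < 4:
        raise ValueError(f"insufficient pairs: n={a.size} < 4")
    diff = b - a
    if parametric:
        bias = float(np.mean(diff))
        spread = 1.96 * float(np.std(diff, ddof=1))
        return BlandAltmanResult(bias, bias - spread, bias + spread, "parametric")
    bias = float(np.median(diff))
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return BlandAltmanResult(bias, float(lo), float(hi), "percentile")


# ---------------------------------------------------------------------------
# Regression + Spearman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    method: str  # OLS | GP | spearman_only
    slope: float | None
    intercept: float | None
    r2: float | None
    gp_mean: np.ndarray | None
    gp_band: tuple[np.ndarray, np.ndarray] | None
    spearman_rho: float
    spearman_p: float


def regression_agreement(reference, model, parametric: bool = True) -> RegressionResult:
    """Regress model values on reference values (reference on the x axis).

    Parametric: ordinary least squares with R^2. Non-parametric: Gaussian
    process regression (RBF + White kernel on standardized inputs) with a 95%
    pointwise predictive band; a failed GP fit degrades to Spearman-only with
    a warning. Spearman's rho is always reported.
    """
    a, b = _paired(reference, model)
    rho, rho_p = stats.spearmanr(a, b)
    if parametric:
        slope, intercept, r, p, se = stats.linregress(a, b)
        return RegressionResult("OLS", float(slope), float(intercept), float(r**2),
                                None, None, float(rho), float(rho_p))
    try:
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, WhiteKernel

        mu_a, sd_a = a.mean(), a.std() or 1.0
        mu_b, sd_b = b.mean(), b.std() or 1.0
        xs = ((a - mu_a) / sd_a)[:, None]
        ys = (b - mu_b) / sd_b
        gp = GaussianProcessRegressor(
            kernel=RBF(1.0) + WhiteKernel(0.1), normalize_y=False, random_state=0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(xs, ys)
            mean_s, sd_s = gp.predict(xs, return_std=True)
        mean = mean_s * sd_b + mu_b
        half = 1.96 * sd_s * sd_b
        return RegressionResult("GP", None, None, None, mean,
                                (mean - half, mean + half), float(rho), float(rho_p))
    except Exception as exc:  # pragma: no cover - GP failure path
        logger.warning("GP regression failed (%s); reporting Spearman only", exc)
        return RegressionResult("spearman_only", None, None, None, None, None,
                                float(rho), float(rho_p))


# ---------------------------------------------------------------------------
# Batch suite
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    biomarker: str
    gate: GateOutcome
    icc: ICCResult
    bland_altman: BlandAltmanResult
    regression: RegressionResult
    spearman_rho: float
    spearman_p: float
    p_fdr: float = field(default=float("nan"))


def agreement_suite(batch: dict[str, tuple[np.ndarray, np.ndarray]],
                    icc_definition: str = "consistency",
                    n_boot: int = 10000, seed: int = 0) -> list[AgreementResult]:
    """Run the full gated analysis per biomarker and BH-adjust across the batch.

    ``batch`` maps biomarker name -> (reference values, model values). The
    Spearman p-values are the association p-values adjusted across the batch.
    """
    results = []
    for name, (ref, mod) in batch.items():
        gate = gate_assumptions(ref, mod)
        if gate.parametric:
            icc_res = icc(ref, mod, definition=icc_definition, method="parametric")
        else:
            icc_res = icc(ref, mod, method="bootstrap", n_boot=n_boot, seed=seed)
        ba = bland_altman(ref, mod, parametric=gate.parametric)
        reg = regression_agreement(ref, mod, parametric=gate.parametric)
        results.append(AgreementResult(name, gate, icc_res, ba, reg,
                                       reg.spearman_rho, reg.spearman_p))
    p_adj = bh_adjust([r.spearman_p for r in results])
    return [AgreementResult(r.biomarker, r.gate, r.icc, r.bland_altman, r.regression,
                            r.spearman_rho, r.spearman_p, float(p))
            for r, p in zip(results, p_adj)]
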