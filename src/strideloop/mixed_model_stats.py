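"""Mixed-effects ANOVA, pairwise contrasts and the FDR-adjusted threshold.

Each per-stride metric is analyzed with linear mixed-effects models with a
random intercept per individual, fitted by maximum likelihood (so AIC and
likelihood-ratio comparisons across fixed-effect structures are valid).
Five nested candidate models are compared:

1. ``y ~ 1 + (1 | ind)``
2. ``y ~ 1 + treatment + (1 | ind)``
3. ``y ~ 1 + stride_id + (1 | ind)``
4. ``y ~ 1 + stride_id + treatment + (1 | ind)``
5. ``y ~ 1 + stride_id * treatment + (1 | ind)``

The full interaction model (5) is used for inference on every metric, with
the AIC table and the 4-vs-5 likelihood-ratio test logged alongside.
Fixed effects use sum-to-zero coding so the term-wise Wald F-tests are
type-III-style (treatment df = 1, stride category df = 4, interaction
df = 4 for the 2 x 5 design).  Denominator degrees of freedom follow the
between-within rule: the between-individual term (treatment) is tested
against n_individuals - 2, all within-individual terms against the
residual df.

Pairwise contrasts are population-level differences of model cell means
(free of the individual random intercepts): treatment cohort overall, and
each obstacle category versus level within each cohort — nine contrasts
per metric.  Significance across all metrics uses a single
Benjamini-Hochberg threshold over the pooled fixed-effect and posthoc
p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats
import statsmodels.formula.api as smf

from .recordings_io import ValidationError

logger = logging.getLogger("strideloop")

MODEL_FORMULAS = {
    1: "{y} ~ 1",
    2: "{y} ~ C(treatment, Sum)",
    3: "{y} ~ C(stride_id, Sum)",
    4: "{y} ~ C(stride_id, Sum) + C(treatment, Sum)",
    5: "{y} ~ C(stride_id, Sum) * C(treatment, Sum)",
}

OBSTACLE_CATEGORIES = ("S-1", "S0", "S+1", "S+2")


@dataclass
class CandidateFits:
    response: str
    aic: dict                 # model id -> AIC (ML)
    loglik: dict              # model id -> log-likelihood
    lrt_45_stat: float
    lrt_45_p: float
    best_model: int
    fit5: object              # statsmodels MixedLMResults of model 5

    @property
    def selection_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": list(self.aic),
            "loglik": [self.loglik[m] for m in self.aic],
            "AIC": [self.aic[m] for m in self.aic],
        })


@dataclass
class ContrastResult:
    """Per-metric inference: F-tests, pairwise contrasts, significance."""

    response: str
    anova: pd.DataFrame       # term, F, df_num, df_den, p
    contrasts: pd.DataFrame   # contrast, estimate, ci_halfwidth, p, ...
    aic_table: pd.DataFrame
    lrt_45_p: float
    fdr_threshold: float | None = None

    def flag(self, threshold: float) -> None:
        self.fdr_threshold = threshold
        self.anova["significant"] = self.anova["p"] <= threshold
        self.contrasts["significant"] = self.contrasts["p"] <= threshold


def _fit_mixed(formula: str, data: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["ind"])
        try:
            res = model.fit(reml=False, maxiter=500, disp=False)
            if not np.isfinite(res.llf) or not np.all(np.isfinite(np.asarray(res.cov_params()))):
                raise ValueError("degenerate fit")
        except Exception:
            # documented fallback for singular fits: a derivative-free
            # optimizer on the same (random-intercept) structure
            res = model.fit(reml=False, method="powell", maxiter=2000, disp=False)
    return res


def model_aic(res) -> float:
    """AIC under ML: fixed effects + random-intercept variance + residual."""
    k = res.model.k_fe + 2
    return float(-2.0 * res.llf + 2.0 * k)


def fit_candidates(table: pd.DataFrame, response: str) -> CandidateFits:
    """Fit the five candidate models and select by AIC.

    Model 5 is fitted and returned for inference regardless of which model
    wins, with the selection table logged; the 4-vs-5 likelihood-ratio test
    confirms (or not) the interaction term.
    """
    data = _prepare(table, response)
    if data["ind"].nunique() < 2:
        raise ValidationError("need >= 2 individuals")
    if data["stride_id"].nunique() < 2:
        raise ValidationError("need >= 2 stride categories")
    fits = {}
    for mid, tmpl in MODEL_FORMULAS.items():
        fits[mid] = _fit_mixed(tmpl.format(y=response), data)
    aic = {m: model_aic(r) for m, r in fits.items()}
    llf = {m: float(r.llf) for m, r in fits.items()}
    lrt = 2.0 * (llf[5] - llf[4])
    lrt_p = float(stats.chi2.sf(max(lrt, 0.0), df=4))
    best = min(aic, key=aic.get)
    logger.info("%s: AIC %s; best model %d; LRT(4 vs 5) p=%.3g",
                response, {m: round(a, 2) for m, a in aic.items()}, best, lrt_p)
    return CandidateFits(response=response, aic=aic, loglik=llf,
                         lrt_45_stat=float(lrt), lrt_45_p=lrt_p,
                         best_model=best, fit5=fits[5])


def fit_model5(table: pd.DataFrame, response: str):
    """Fit only the inference model (full interaction, random intercept)."""
    data = _prepare(table, response)
    return _fit_mixed(MODEL_FORMULAS[5].format(y=response), data)


def _prepare(table: pd.DataFrame, response: str) -> pd.DataFrame:
    cols = {"ind", "treatment", "stride_id"}
    missing = cols - set(table.columns)
    if missing:
        # accept stride-table naming
        renames = {"bird_id": "ind", "cohort": "treatment", "category": "stride_id"}
        table = table.rename(columns={k: v for k, v in renames.items() if k in table.columns})
        missing = cols - set(table.columns)
        if missing:
            raise ValidationError(f"missing grouping columns: {sorted(missing)}")
    if response not in table.columns:
        raise ValidationError(f"response column {response!r} not present")
    data = table[["ind", "treatment", "stride_id", response]].dropna()
    return data.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Wald F-tests on model 5

def _fe_cov(res):
    k = res.model.k_fe
    return np.asarray(res.cov_params())[:k, :k], np.asarray(res.fe_params)


def _term_slices(res) -> dict:
    di = res.model.data.design_info
    out = {}
    for name, sl in di.term_name_slices.items():
        if name == "Intercept":
            continue
        has_t = "treatment" in name
        has_s = "stride_id" in name
        if has_t and has_s:
            out["interaction"] = sl
        elif has_t:
            out["treatment"] = sl
        elif has_s:
            out["stride_id"] = sl
    return out


def anova_F(res, n_individuals: int | None = None) -> pd.DataFrame:
    """Type-III-style Wald F-tests of the model-5 fixed-effect terms."""
    V, beta = _fe_cov(res)
    slices = _term_slices(res)
    if "interaction" not in slices:
        raise ValidationError("anova_F expects the full interaction model (model 5)")
    n_ind = n_individuals or len(res.model.group_labels)
    nobs = int(res.model.nobs) if hasattr(res.model, "nobs") else res.model.endog.shape[0]
    df_resid = nobs - res.model.k_fe
    rows = []
    for term in ("treatment", "stride_id", "interaction"):
        sl = slices[term]
        b = beta[sl]
        if b.size == 0:
            raise ValidationError(
                f"term {term!r} has no coefficients (factor with a single level)")
        v = V[sl.start:sl.stop, sl.start:sl.stop]
        q = b.size
        try:
            w = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            raise ValidationError(f"rank-deficient term {term!r}: aliased coefficients")
        F = w / q
        df_den = (n_ind - 2) if term == "treatment" else df_resid
        p = float(stats.f.sf(F, q, df_den))
        rows.append({"term": term, "F": F, "df_num": q, "df_den": df_den, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise contrasts

def _cell_rows(res, cells: pd.DataFrame) -> np.ndarray:
    di = res.model.data.design_info
    (X,) = build_design_matrices([di], cells)
    return np.asarray(X)


def pairwise_contrasts(res, data: pd.DataFrame | None = None,
                       n_individuals: int | None = None) -> pd.DataFrame:
    """Population-level pairwise mean differences +/- 95% CI.

    One treatment contrast (reinnervated - intact, averaged over stride
    categories) and, within each cohort, each obstacle category versus
    level — nine contrasts.  Estimates are linear contrasts of the model-5
    cell means, i.e. the individual random intercepts drop out.  Contrasts
    touching an empty design cell are reported as missing.
    """
    V, beta = _fe_cov(res)
    cats = ["L", *OBSTACLE_CATEGORIES]
    cohorts = ["intact", "reinnervated"]
    cells = pd.DataFrame([(t, c) for t in cohorts for c in cats],
                         columns=["treatment", "stride_id"])
    X = _cell_rows(res, cells)
    row = {(t, c): X[i] for i, (t, c) in enumerate(zip(cells["treatment"], cells["stride_id"]))}

    observed = None
    if data is not None:
        d = data.rename(columns={"cohort": "treatment", "category": "stride_id"})
        observed = set(zip(d["treatment"], d["stride_id"]))

    n_ind = n_individuals or len(res.model.group_labels)
    nobs = res.model.endog.shape[0]
    df_resid = nobs - res.model.k_fe

    def one(name, vec, df):
        est = float(vec @ beta)
        se = float(np.sqrt(vec @ V @ vec))
        tcrit = stats.t.ppf(0.975, df)
        tval = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2 * stats.t.sf(abs(tval), df)) if se > 0 else 0.0
        return {"contrast": name, "estimate": est, "se": se,
                "ci_halfwidth": float(tcrit * se), "df": df, "p": p}

    rows = []
    treat_vec = np.mean([row[("reinnervated", c)] - row[("intact", c)] for c in cats], axis=0)
    rows.append(one("treatment: reinnervated-intact", treat_vec, n_ind - 2))
    for cohort in cohorts:
        for cat in OBSTACLE_CATEGORIES:
            name = f"{cohort}: {cat}-L"
            if observed is not None and (
                    (cohort, cat) not in observed or (cohort, "L") not in observed):
                logger.info("contrast %s skipped: empty cell", name)
                rows.append({"contrast": name, "estimate": np.nan, "se": np.nan,
                             "ci_halfwidth": np.nan, "df": np.nan, "p": np.nan})
                continue
            rows.append(one(name, row[(cohort, cat)] - row[(cohort, "L")], df_resid))
    return pd.DataFrame(rows)


def remove_individual_effect(table: pd.DataFrame, res, response: str) -> pd.Series:
    """Response with the estimated (BLUP) individual intercepts subtracted.

    Utility mirroring the stated posthoc procedure; the reported contrasts
    are equivalent population-level model contrasts.
    """
    data = _prepare(table, response)
    blups = {g: float(re.iloc[0]) for g, re in res.random_effects.items()}
    return data[response] - data["ind"].map(blups)


# ---------------------------------------------------------------------------
# FDR

def fdr_threshold(pvalues, q: float = 0.05) -> float:
    """Benjamini-Hochberg adjusted significance threshold.

    The largest sorted p-value p_(i) with p_(i) <= (i/m) * q over the
    pooled vector; 0 if none qualifies.
    """
    p = np.asarray(pvalues, float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not 0 < q < 1:
        raise ValidationError("p-values must lie in [0,1] and q in (0,1)")
    ps = np.sort(p)
    m = ps.size
    crit = (np.arange(1, m + 1) / m) * q
    ok = ps <= crit
    return float(ps[np.flatnonzero(ok)[-1]]) if ok.any() else 0.0


# ---------------------------------------------------------------------------
# driver

def analyze_metrics(table: pd.DataFrame, responses, q: float = 0.05,
                    drop_outliers: bool = True):
    """Full statistics layer over a stride table.

    Fits the candidate models per metric, runs the model-5 ANOVA and the
    nine pairwise contrasts, pools every p-value (fixed-effect F-tests and
    posthoc contrasts across all metrics) into one Benjamini-Hochberg
    threshold, and flags significance.  Returns ``(results, threshold)``
    where ``results`` maps metric -> ContrastResult.
    """
    if drop_outliers and "outlier" in table.columns:
        table = table[~table["outlier"].astype(bool)]
    probe = _prepare(table, responses[0])
    if probe["treatment"].nunique() < 2:
        raise ValidationError(
            "need both treatment cohorts (intact and reinnervated) for the "
            "2 x 5 fixed-effect design")
    results: dict[str, ContrastResult] = {}
    for resp in responses:
        data = _prepare(table, resp)
        y = data[resp].to_numpy()
        if y.size == 0 or np.var(y) <= 1e-12 * (1.0 + np.mean(y) ** 2):
            logger.warning("%s: (near-)constant response, no inference possible; skipped",
                           resp)
            continue
        try:
            cand = fit_candidates(table, resp)
            an = anova_F(cand.fit5, n_individuals=data["ind"].nunique())
            con = pairwise_contrasts(cand.fit5, data=data,
                                     n_individuals=data["ind"].nunique())
        except (np.linalg.LinAlgError, ValidationError, ValueError) as exc:
            logger.warning("%s: model fit failed (%s); metric skipped", resp, exc)
            continue
        results[resp] = ContrastResult(response=resp, anova=an, contrasts=con,
                                       aic_table=cand.selection_table,
                                       lrt_45_p=cand.lrt_45_p)
    if not results:
        raise ValidationError("no metric could be analyzed")
    pooled = np.concatenate([
        np.concatenate([r.anova["p"].to_numpy(), r.contrasts["p"].to_numpy()])
        for r in results.values()])
    thr = fdr_threshold(pooled, q=q)
    for r in results.values():
        r.flag(thr)
    logger.info("FDR-adjusted threshold over %d tests: p <= %.4g",
                np.isfinite(pooled).sum(), thr)
    return results, thr
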