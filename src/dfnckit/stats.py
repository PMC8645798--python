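"""Longitudinal statistics for dynamic-state summary metrics.

Outcomes (per-state mean dwell time, number of transitions, per-pair
temporal SD) from a two-visit design are modelled with Gaussian linear
mixed models carrying a random intercept per subject, with centered age
and sex as fixed effects.  Dwell times are Box-Cox transformed first
(they are right-skewed).  Quadratic-age and age-by-sex terms are screened
with likelihood-ratio tests under full maximum likelihood, sex-stratified
fits are produced when the interaction is supported, p-values are
FDR-corrected per term family, and population prediction bands come from
a subject-level (clustered) bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "make_outcome_table",
    "outcome_table_from_metrics",
    "descriptive_tests",
    "TransformSpec",
    "boxcox_fit",
    "LMEFit",
    "fit_lme",
    "ModelComparison",
    "lr_compare",
    "SuiteResults",
    "model_suite",
    "edgewise_sd_models",
    "BootstrapCurve",
    "bootstrap_curves",
]

#: Default summary-metric outcome family (five dwell times + transitions).
DEFAULT_OUTCOMES = tuple(f"mdt_state{k}" for k in range(1, 6)) + ("n_transitions",)

_TERM_COLUMNS = {
    "age": "age_c",
    "sex": "female",
    "age2": "age_c2",
    "age_sex": "age_c_female",
}


def make_outcome_table(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize a long outcome table.

    Expects columns subject_id, visit, age, sex ('M'/'F'), outcome, value
    (optional maternal_education).  Adds ``age_c`` (age centered to the
    visit-1 mean), ``female`` and the derived model columns.
    """
    df = records.copy()
    required = {"subject_id", "visit", "age", "sex", "outcome", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    if df.duplicated(["subject_id", "visit", "outcome"]).any():
        raise ValueError("duplicate (subject, visit, outcome) rows")
    mean_age_v1 = df.loc[df["visit"] == df["visit"].min(), "age"].mean()
    df["age_c"] = df["age"] - mean_age_v1
    df["female"] = (df["sex"] == "F").astype(float)
    df["age_c2"] = df["age_c"] ** 2
    df["age_c_female"] = df["age_c"] * df["female"]
    df.attrs["mean_age_visit1"] = float(mean_age_v1)
    return df


def outcome_table_from_metrics(sessions_meta, metrics, k: int) -> pd.DataFrame:
    """Build the long outcome table from per-session state metrics.

    ``sessions_meta`` is an iterable of (subject_id, visit, age, sex);
    ``metrics`` the matching iterable of SessionStateMetrics.
    """
    rows = []
    for (sid, visit, age, sex), m in zip(sessions_meta, metrics):
        for s in range(k):
            rows.append((sid, visit, age, sex, f"mdt_state{s + 1}", float(m.mdt[s])))
        rows.append((sid, visit, age, sex, "n_transitions", float(m.nt)))
    df = pd.DataFrame(
        rows, columns=["subject_id", "visit", "age", "sex", "outcome", "value"]
    )
    return make_outcome_table(df)


# ---------------------------------------------------------------------------
# descriptive nonparametric comparisons


def descriptive_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon comparisons of each outcome: signed-rank between visits on
    paired subjects, rank-sum between sexes within each visit.

    The rank-sum statistic reported is the rank sum of the first group in
    label order (W = U + n1(n1+1)/2).  Signed-rank uses the exact null for
    up to 25 nonzero pairs and the continuity-corrected normal
    approximation beyond.
    """
    out = []
    visits = sorted(table["visit"].unique())
    for outcome, g in table.groupby("outcome"):
        if len(visits) >= 2:
            wide = g.pivot_table(index="subject_id", columns="visit", values="value")
            paired = wide.dropna()
            if len(paired) == 0:
                warnings.warn(f"{outcome}: no paired subjects; signed-rank skipped")
            else:
                d = paired[visits[1]] - paired[visits[0]]
                nz = int((d != 0).sum())
                if nz == 0:
                    out.append((outcome, "visit_signed_rank", np.nan, 1.0, len(paired)))
                else:
                    method = "exact" if nz <= 25 else "approx"
                    res = sps.wilcoxon(
                        paired[visits[1]], paired[visits[0]],
                        zero_method="wilcox", method=method, correction=True,
                    )
                    out.append((outcome, "visit_signed_rank", float(res.statistic),
                                float(res.pvalue), len(paired)))
        for v in visits:
            gv = g[g["visit"] == v]
            groups = sorted(gv["sex"].unique())
            if len(groups) != 2:
                continue
            x = gv.loc[gv["sex"] == groups[0], "value"]
            y = gv.loc[gv["sex"] == groups[1], "value"]
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            w = float(res.statistic) + len(x) * (len(x) + 1) / 2  # rank sum of group 1
            out.append((outcome, f"sex_rank_sum_visit{v}", w, float(res.pvalue),
                        len(x) + len(y)))
    return pd.DataFrame(out, columns=["outcome", "comparison", "statistic", "p_value", "n"])


# ---------------------------------------------------------------------------
# Box-Cox


@dataclass
class TransformSpec:
    """Fitted Box-Cox transform with an offset guaranteeing positivity."""

    lambda_bc: float
    offset: float
    loglik: float

    def transform(self, y):
        y = np.asarray(y, dtype=float) + self.offset
        if np.any(y <= 0):
            raise ValueError("values must be positive after offset")
        if self.lambda_bc == 0:
            return np.log(y)
        return (y**self.lambda_bc - 1.0) / self.lambda_bc

    def inverse(self, t):
        t = np.asarray(t, dtype=float)
        if self.lambda_bc == 0:
            y = np.exp(t)
        else:
            base = self.lambda_bc * t + 1.0
            y = np.clip(base, 1e-12, None) ** (1.0 / self.lambda_bc)
        return y - self.offset


def boxcox_fit(y, lam_grid=None) -> tuple[TransformSpec, np.ndarray]:
    """Profile-likelihood Box-Cox fit on a grid of exponents [-2, 2].

    If min(y) <= 0 an offset of 1 - min(y) is applied first.  Returns the
    fitted transform and the transformed values.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2 or np.ptp(y) == 0:
        raise ValueError("Box-Cox exponent is unidentifiable for constant data")
    offset = 0.0 if y.min() > 0 else 1.0 - y.min()
    if lam_grid is None:
        lam_grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)
    lls = np.array([sps.boxcox_llf(l, y + offset) for l in lam_grid])
    best = int(np.argmax(lls))
    spec = TransformSpec(lambda_bc=float(lam_grid[best]), offset=offset,
                         loglik=float(lls[best]))
    return spec, spec.transform(y)


# ---------------------------------------------------------------------------
# mixed models


@dataclass
class LMEFit:
    """Random-intercept linear mixed model fit for one outcome.

    Coefficients are reported from the restricted-likelihood (REML) fit;
    ``llf_ml`` is the full-maximum-likelihood log-likelihood used in
    likelihood-ratio comparisons.
    """

    outcome: str
    terms: tuple
    result: object  # REML MixedLMResults
    formula: str
    data: pd.DataFrame = field(repr=False)
    _result_ml: object = field(default=None, repr=False)

    @property
    def result_ml(self):
        """Full-ML refit, computed on first use (for LR comparisons)."""
        if self._result_ml is None:
            self._result_ml = _fit_mixedlm(self.formula, self.data, reml=False)
        return self._result_ml

    @property
    def llf_ml(self) -> float:
        return float(self.result_ml.llf)

    @property
    def n_fixed(self) -> int:
        return len(self.terms) + 1  # + intercept

    def fixed_table(self) -> pd.DataFrame:
        res = self.result
        ci = res.conf_int()
        rows = []
        for term in self.terms:
            col = _TERM_COLUMNS[term]
            rows.append(
                dict(
                    term=term,
                    estimate=float(res.params[col]),
                    ci_low=float(ci.loc[col, 0]),
                    ci_high=float(ci.loc[col, 1]),
                    p_value=float(res.pvalues[col]),
                )
            )
        return pd.DataFrame(rows)

    @property
    def aic(self) -> float:
        # AIC/BIC from the ML fit (parameter count: fixed + variance components)
        k = self.n_fixed + 2
        return float(2 * k - 2 * self.llf_ml)

    @property
    def bic(self) -> float:
        k = self.n_fixed + 2
        return float(k * np.log(len(self.data)) - 2 * self.llf_ml)

    def predict(self, age_c, female) -> np.ndarray:
        """Population-level (random effects at zero) predictions."""
        age_c = np.asarray(age_c, dtype=float)
        female = np.broadcast_to(np.asarray(female, dtype=float), age_c.shape)
        X = pd.DataFrame({"age_c": age_c, "female": female})
        X["age_c2"] = X["age_c"] ** 2
        X["age_c_female"] = X["age_c"] * X["female"]
        p = self.result.params
        yhat = np.full(len(X), float(p["Intercept"]))
        for term in self.terms:
            col = _TERM_COLUMNS[term]
            yhat = yhat + float(p[col]) * X[col].to_numpy()
        return yhat


def _fit_mixedlm(formula: str, df: pd.DataFrame, reml: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = MixedLM.from_formula(formula, groups="subject_id", data=df)
        last_exc = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                return model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError, OverflowError) as exc:
                last_exc = exc
        raise RuntimeError(f"mixed-model fit failed for {formula!r}: {last_exc}")


def fit_lme(
    table: pd.DataFrame,
    outcome: str,
    fixed_terms: tuple = ("age", "sex"),
    values: np.ndarray | None = None,
) -> LMEFit:
    """Fit a random-intercept model for one outcome.

    ``fixed_terms`` draws from {'age', 'sex', 'age2', 'age_sex'}; ``values``
    optionally overrides the outcome column (e.g., Box-Cox transformed).
    """
    df = table.loc[table["outcome"] == outcome].copy()
    if df.empty:
        raise ValueError(f"no rows for outcome {outcome!r}")
    if values is not None:
        df["value"] = np.asarray(values, dtype=float)
    n_rep = df.groupby("subject_id").size()
    if (n_rep > 1).sum() < 2:
        warnings.warn(
            f"{outcome}: fewer than 2 subjects with repeated measures; "
            "random-intercept variance is weakly identified"
        )
    cols = [_TERM_COLUMNS[t] for t in fixed_terms]
    X = df[cols].to_numpy()
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(df)), X]))
    if rank < len(cols) + 1:
        raise ValueError(f"singular fixed-effect design for terms {fixed_terms}")
    formula = "value ~ " + " + ".join(cols)
    res = _fit_mixedlm(formula, df, reml=True)
    return LMEFit(outcome=outcome, terms=tuple(fixed_terms), result=res,
                  formula=formula, data=df)


@dataclass
class ModelComparison:
    lr_stat: float
    df_diff: int
    p_value: float
    preferred: str  # "base" or "extended"


def lr_compare(base: LMEFit, extended: LMEFit, alpha: float = 0.05) -> ModelComparison:
    """Likelihood-ratio test of nested mixed models under full ML."""
    if not set(base.terms) < set(extended.terms):
        raise ValueError("models are not nested")
    if len(base.data) != len(extended.data):
        raise ValueError("models were fit to different data")
    df_diff = extended.n_fixed - base.n_fixed
    lr = 2.0 * (extended.llf_ml - base.llf_ml)
    if lr < -1e-8:
        warnings.warn(f"negative LR statistic ({lr:.3g}); clipping to 0")
    lr = max(lr, 0.0)
    p = float(sps.chi2.sf(lr, df_diff))
    return ModelComparison(lr_stat=float(lr), df_diff=df_diff, p_value=p,
                           preferred="extended" if p < alpha else "base")


# ---------------------------------------------------------------------------
# the full modelling suite


@dataclass
class SuiteResults:
    """Step-wise modelling results for the summary-metric outcomes."""

    base_table: pd.DataFrame  # per outcome: age & sex rows, AIC/BIC, FDR
    interaction_table: pd.DataFrame  # age, sex, age x sex rows
    stratified_table: pd.DataFrame  # per-sex age slopes where interaction held
    lr_tests: pd.DataFrame
    fits: dict  # outcome -> {"base": LMEFit, ...}
    transforms: dict  # outcome -> TransformSpec or None
    sensitivity_table: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = ["Age- and sex-associations with state summary metrics",
                 "(random-intercept linear mixed models; dwell times Box-Cox transformed)",
                 ""]
        with pd.option_context("display.width", 120, "display.float_format",
                               lambda v: f"{v: .4f}"):
            lines.append(self.base_table.to_string(index=False))
            if len(self.stratified_table):
                lines += ["", "Sex-stratified age slopes (interaction-supported outcomes):",
                          self.stratified_table.to_string(index=False)]
        return "\n".join(lines)


def _fdr(p):
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def model_suite(
    table: pd.DataFrame,
    outcomes=DEFAULT_OUTCOMES,
    alpha: float = 0.05,
    boxcox: bool = True,
    maternal_education: bool = False,
) -> SuiteResults:
    """Run the step-wise longitudinal analysis over the outcome family.

    Per outcome: Box-Cox transform dwell times (transitions stay raw), fit
    the base age+sex model, LR-test the quadratic-age and age-by-sex
    extensions, fit sex-stratified models when the interaction LR test
    passes, and FDR-correct the base-model p-values across outcomes
    (age terms and sex terms as separate families).
    """
    fits, transforms = {}, {}
    base_rows, int_rows, strat_rows, lr_rows, sens_rows = [], [], [], [], []
    for outcome in outcomes:
        y = table.loc[table["outcome"] == outcome, "value"].to_numpy()
        if y.size == 0:
            raise ValueError(f"outcome {outcome!r} absent from table")
        spec = None
        values = None
        if boxcox and outcome.startswith("mdt"):
            spec, values = boxcox_fit(y)
        transforms[outcome] = spec

        base = fit_lme(table, outcome, ("age", "sex"), values=values)
        quad = fit_lme(table, outcome, ("age", "sex", "age2"), values=values)
        inter = fit_lme(table, outcome, ("age", "sex", "age_sex"), values=values)
        fits[outcome] = {"base": base, "quadratic": quad, "interaction": inter}

        cmp_quad = lr_compare(base, quad, alpha)
        cmp_int = lr_compare(base, inter, alpha)
        lr_rows.append((outcome, "age2", cmp_quad.lr_stat, cmp_quad.df_diff,
                        cmp_quad.p_value, cmp_quad.preferred))
        lr_rows.append((outcome, "age_sex", cmp_int.lr_stat, cmp_int.df_diff,
                        cmp_int.p_value, cmp_int.preferred))

        for row in base.fixed_table().itertuples(index=False):
            base_rows.append((outcome,) + tuple(row) + (base.aic, base.bic))
        for row in inter.fixed_table().itertuples(index=False):
            int_rows.append((outcome,) + tuple(row) + (inter.aic, inter.bic))

        if cmp_int.p_value < alpha:
            for sex, female in (("M", 0.0), ("F", 1.0)):
                sub = table[(table["outcome"] == outcome) & (table["female"] == female)]
                vals = None
                if spec is not None:
                    vals = spec.transform(sub["value"].to_numpy())
                sfit = fit_lme(sub, outcome, ("age",), values=vals)
                r = sfit.fixed_table().iloc[0]
                strat_rows.append((outcome, sex, r["estimate"], r["ci_low"],
                                   r["ci_high"], r["p_value"]))
        if maternal_education and "maternal_education" in table.columns:
            df = table.loc[table["outcome"] == outcome].copy()
            if values is not None:
                df["value"] = values
            me = pd.get_dummies(df["maternal_education"], prefix="me",
                                drop_first=True, dtype=float)
            df = pd.concat([df, me], axis=1)
            formula = "value ~ age_c + female + " + " + ".join(me.columns)
            res = _fit_mixedlm(formula, df, reml=True)
            ci = res.conf_int()
            sens_rows.append((outcome, "age", float(res.params["age_c"]),
                              float(ci.loc["age_c", 0]), float(ci.loc["age_c", 1]),
                              float(res.pvalues["age_c"])))
            sens_rows.append((outcome, "sex", float(res.params["female"]),
                              float(ci.loc["female", 0]), float(ci.loc["female", 1]),
                              float(res.pvalues["female"])))

    cols = ["outcome", "term", "estimate", "ci_low", "ci_high", "p_value", "AIC", "BIC"]
    base_table = pd.DataFrame(base_rows, columns=cols)
    interaction_table = pd.DataFrame(int_rows, columns=cols)
    # FDR per term family across the outcome set
    for term_family in ("age", "sex"):
        mask = base_table["term"] == term_family
        base_table.loc[mask, "p_fdr"] = _fdr(base_table.loc[mask, "p_value"])
    stratified_table = pd.DataFrame(
        strat_rows, columns=["outcome", "sex", "estimate", "ci_low", "ci_high", "p_value"]
    )
    lr_tests = pd.DataFrame(
        lr_rows, columns=["outcome", "term", "lr_stat", "df_diff", "p_value", "preferred"]
    )
    sensitivity = (
        pd.DataFrame(sens_rows, columns=["outcome", "term", "estimate", "ci_low",
                                         "ci_high", "p_value"])
        if sens_rows else None
    )
    return SuiteResults(
        base_table=base_table,
        interaction_table=interaction_table,
        stratified_table=stratified_table,
        lr_tests=lr_tests,
        fits=fits,
        transforms=transforms,
        sensitivity_table=sensitivity,
    )


def edgewise_sd_models(pair_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-pair age models of temporal connectivity SD with BH-FDR.

    ``pair_table`` is long with columns subject_id, visit, age_c, female,
    pair, value.  One random-intercept model (value ~ age + sex) per pair;
    Benjamini-Hochberg across all pairs on the age p-values.
    """
    rows = []
    for pair, df in pair_table.groupby("pair"):
        res = _fit_mixedlm("value ~ age_c + female", df, reml=True)
        ci = res.conf_int()
        rows.append((pair, float(res.params["age_c"]), float(ci.loc["age_c", 0]),
                     float(ci.loc["age_c", 1]), float(res.pvalues["age_c"])))
    out = pd.DataFrame(rows, columns=["pair", "estimate", "ci_low", "ci_high", "p_value"])
    out["p_fdr"] = _fdr(out["p_value"])
    out["significant"] = out["p_fdr"] < alpha
    return out


@dataclass
class BootstrapCurve:
    outcome: str
    age_grid: np.ndarray
    curves: dict  # sex -> dict(fit, lo, hi) on the original outcome scale
    n_boot: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex, c in self.curves.items():
            for a, f, lo, hi in zip(self.age_grid, c["fit"], c["lo"], c["hi"]):
                rows.append((self.outcome, sex, a, f, lo, hi))
        return pd.DataFrame(rows, columns=["outcome", "sex", "age", "fit", "lo", "hi"])


def bootstrap_curves(
    table: pd.DataFrame,
    outcome: str,
    transform: TransformSpec | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    age_grid: np.ndarray | None = None,
) -> BootstrapCurve:
    """Subject-level bootstrap prediction bands for one outcome.

    Subjects are resampled with replacement (keeping all their sessions),
    the base age+sex model is refit, and population predictions on an age
    grid are back-transformed to the original scale.  Bands are the
    2.5/97.5 percentiles across resamples.
    """
    df = table.loc[table["outcome"] == outcome]
    if df.empty:
        raise ValueError(f"no rows for outcome {outcome!r}")
    mean_age_v1 = table.attrs.get("mean_age_visit1", df["age"].mean())
    if age_grid is None:
        age_grid = np.linspace(df["age"].min(), df["age"].max(), 25)
    grid_c = np.asarray(age_grid) - mean_age_v1

    def predict(fit: LMEFit, female: float) -> np.ndarray:
        yhat = fit.predict(grid_c, female)
        return transform.inverse(yhat) if transform is not None else yhat

    values = transform.transform(df["value"].to_numpy()) if transform is not None else None
    full = fit_lme(df, outcome, ("age", "sex"), values=values)
    point = {sex: predict(full, f) for sex, f in (("M", 0.0), ("F", 1.0))}

    rng = np.random.default_rng(seed)
    subjects = df["subject_id"].unique()
    boots = {"M": [], "F": []}
    for _ in range(n_boot):
        chosen = rng.choice(subjects, size=len(subjects), replace=True)
        parts = []
        for i, s in enumerate(chosen):
            part = df[df["subject_id"] == s].copy()
            part["subject_id"] = f"bs{i}"  # duplicated subjects act as distinct
            parts.append(part)
        bs = pd.concat(parts, ignore_index=True)
        if bs["subject_id"].nunique() < 2:
            continue
        vals = transform.transform(bs["value"].to_numpy()) if transform is not None else None
        try:
            fit = fit_lme(bs, outcome, ("age", "sex"), values=vals)
        except (ValueError, np.linalg.LinAlgError):
            continue
        for sex, f in (("M", 0.0), ("F", 1.0)):
            boots[sex].append(predict(fit, f))
    curves = {}
    for sex in ("M", "F"):
        arr = np.asarray(boots[sex])
        curves[sex] = dict(
            fit=point[sex],
            lo=np.percentile(arr, 2.5, axis=0),
            hi=np.percentile(arr, 97.5, axis=0),
            boot_mean=arr.mean(axis=0),
        )
    return BootstrapCurve(outcome=outcome, age_grid=np.asarray(age_grid),
                          curves=curves, n_boot=n_boot)
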