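"""Regional statistics: trimming, linear mixed-effects models, AIC
selection, marginal effects, and the significance rule.

Voxel-wise measure values are the dependent variable; subjects contribute
random intercepts (optionally subject-by-region variance components).
Continuous covariates and the dependent variable are z-scored before
fitting, so fixed-effect coefficients are standardized; binary sex enters
as a male indicator (reference female) and region as treatment-coded
categories (reference genu).  Models compared by AIC are fitted by maximum
likelihood (not REML).  An association is flagged only when the 95% CI
excludes zero AND p < 0.005.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

SIGNIFICANCE_P = 0.005


def trim_quantiles(values, lo=0.01, hi=0.99):
    """Drop values strictly below the ``lo`` and strictly above the ``hi``
    empirical quantile (linear-interpolation definition).

    Fewer than 10 values are returned untrimmed with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        warnings.warn("fewer than 10 values: returned untrimmed", stacklevel=2)
        return values.copy()
    ql, qh = np.quantile(values, [lo, hi])
    return values[(values >= ql) & (values <= qh)]


def trim_table(table: pd.DataFrame, value_col="value",
               by=("measure", "region"), lo=0.01, hi=0.99) -> pd.DataFrame:
    """Quantile-trim a long voxel table within each group."""
    grp = table.groupby(list(by), observed=True)[value_col]
    ql = grp.transform(lambda v: v.quantile(lo) if v.size >= 10 else -np.inf)
    qh = grp.transform(lambda v: v.quantile(hi) if v.size >= 10 else np.inf)
    keep = (table[value_col] >= ql) & (table[value_col] <= qh)
    return table[keep].reset_index(drop=True)


@dataclass
class ModelSpec:
    """Mixed-model specification.

    ``fixed`` lists fixed-effect terms over subject/voxel columns; the
    tokens ``sex`` (male indicator, reference female) and ``region``
    (treatment-coded, reference genu) are translated internally.
    ``random`` may contain ``"subject"`` (random intercept) and
    ``"subject_region"`` (subject-by-region variance component).
    """

    dv: str = "value"
    fixed: tuple = ("age", "sex")
    random: tuple = ("subject",)
    zscore: tuple = ("age", "PDSA", "PDSG", "PDSS", "BMI", "hit_rt", "d_prime")

    def formula(self) -> str:
        terms = [t.replace("sex", "male") for t in self.fixed]
        terms = [t.replace("region", "C(region, Treatment('G'))") for t in terms]
        return "dv ~ " + " + ".join(terms) if terms else "dv ~ 1"

    def n_fixed_terms(self) -> int:
        return len(self.fixed)


@dataclass
class MixedModelResult:
    """Standardized fixed effects with CIs and p-values, plus AIC."""

    spec: ModelSpec
    fe_params: pd.Series
    conf_int: pd.DataFrame          # columns lo, hi
    pvalues: pd.Series
    aic: float
    llf: float
    n_params: int
    n_obs: int
    converged: bool
    vc_names: tuple = ()
    design_info: object = field(default=None, repr=False)
    data: pd.DataFrame = field(default=None, repr=False)
    sm_result: object = field(default=None, repr=False)

    def term_index(self, term: str) -> str:
        """Resolve a user-facing term name (e.g. ``sex``, ``sex:PDSA``,
        ``region[S]``) to the fitted coefficient name."""
        cand = term.replace("sex", "male")
        for name in self.fe_params.index:
            clean = (name.replace("C(region, Treatment('G'))[T.", "region[")
                     .replace("]", "]"))
            if clean == cand or name == cand:
                return name
            if set(cand.split(":")) == set(clean.split(":")):
                return name
        raise KeyError(f"term {term!r} not in model: {list(self.fe_params.index)}")


def _prepare(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = table.copy()
    if "subject" not in df.columns:
        raise ValueError("table must have a 'subject' column")
    if df["subject"].nunique() < 2:
        raise ValueError("mixed model needs >= 2 subjects (random intercept "
                         "unidentifiable otherwise)")
    if "sex" in df.columns and "male" not in df.columns:
        df["male"] = (df["sex"] == "M").astype(float)
    df["dv"] = df[spec.dv].astype(float)
    for col in set(spec.zscore) | {"dv"}:
        if col in ("dv",):
            x = df["dv"]
            sd = x.std(ddof=0)
            df["dv"] = (x - x.mean()) / (sd if sd > 0 else 1.0)
        elif col in df.columns:
            x = df[col].astype(float)
            sd = x.std(ddof=0)
            df[col] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return df


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec) -> MixedModelResult:
    """Maximum-likelihood linear mixed model on a long voxel table.

    Falls back to a simplified random structure (dropping the
    subject-by-region component) if the requested structure is singular or
    fails to converge, with a logged warning.
    """
    df = _prepare(table, spec)
    formula = spec.formula()
    want_vc = ("subject_region" in spec.random
               and "region" in df.columns and df["region"].nunique() > 1)
    vc = {"subj_region": "0 + C(region)"} if want_vc else None

    def _fit(vc_formula, method):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = smf.mixedlm(formula, df, groups=df["subject"],
                                re_formula="1", vc_formula=vc_formula)
            if method is None:
                return model, model.fit(reml=False, maxiter=500)
            return model, model.fit(reml=False, method=method, maxiter=2000)

    attempts = [(vc, "powell"), (vc, None)] if vc is not None else []
    attempts += [(None, "powell"), (None, None)]
    model = res = None
    for vc_try, method in attempts:
        model, res = _fit(vc_try, method)
        if res.converged:
            vc = vc_try
            break
    else:
        vc = attempts[-1][0]
        logger.warning("mixed model did not fully converge; "
                       "reporting last attempt")
    if want_vc and vc is None:
        logger.warning("subject-by-region component singular or "
                       "non-convergent; fitted with random intercept only")

    k_fe = model.k_fe
    fe = res.params.iloc[:k_fe]
    ci = res.conf_int().iloc[:k_fe]
    ci.columns = ["lo", "hi"]
    pv = res.pvalues.iloc[:k_fe]
    n_params = len(res.params) + 1          # + residual variance
    aic = -2.0 * res.llf + 2.0 * n_params
    return MixedModelResult(
        spec=spec,
        fe_params=fe,
        conf_int=ci,
        pvalues=pv,
        aic=float(aic),
        llf=float(res.llf),
        n_params=int(n_params),
        n_obs=int(model.nobs),
        converged=bool(res.converged),
        vc_names=("subj_region",) if vc else (),
        design_info=model.data.design_info,
        data=df,
        sm_result=res,
    )


def select_model(results) -> MixedModelResult:
    """Lowest-AIC model among ML fits of the same rows; ties break toward
    fewer parameters."""
    results = list(results)
    if not results:
        raise ValueError("no candidate models")
    n_obs = {r.n_obs for r in results}
    if len(n_obs) != 1:
        raise ValueError("candidates fitted on different row sets; "
                         "AICs not comparable")
    return min(results, key=lambda r: (round(r.aic, 9), r.n_params))


def marginal_effects(result: MixedModelResult, grid_spec: dict | None = None,
                     z=1.959963984540054) -> pd.DataFrame:
    """Fixed-effects predictions on a covariate grid with delta-method CIs.

    ``grid_spec`` maps predictor columns (model working scale, i.e.
    z-scored continuous values, 0/1 ``male``) to value lists; remaining
    numeric covariates sit at their sample means and categoricals at their
    first observed level.  With ``grid_spec=None``, predicts at the
    observed covariates.
    """
    df = result.data
    if grid_spec:
        for name in grid_spec:
            col = name.replace("sex", "male")
            if col not in df.columns:
                raise ValueError(f"grid variable {name!r} not in model data")
        keys = [k.replace("sex", "male") for k in grid_spec]
        mesh = np.meshgrid(*[np.asarray(v) for v in grid_spec.values()],
                           indexing="ij")
        grid = pd.DataFrame({k: m.ravel() for k, m in zip(keys, mesh)})
        for col in df.columns:
            if col in grid.columns or col == "dv":
                continue
            if pd.api.types.is_numeric_dtype(df[col]):
                grid[col] = df[col].mean()
            else:
                grid[col] = df[col].iloc[0]
        new = grid
    else:
        new = df
    (X,) = patsy.build_design_matrices([result.design_info], new)
    X = np.asarray(X)
    beta = result.fe_params.to_numpy()
    pred = X @ beta
    cov = np.asarray(result.sm_result.cov_params())[: len(beta), : len(beta)]
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    out = new.copy().reset_index(drop=True)
    out["predicted"] = pred
    out["se"] = se
    out["ci_lo"] = pred - z * se
    out["ci_hi"] = pred + z * se
    return out


def significance_flag(result: MixedModelResult, term: str) -> bool:
    """True iff the term's 95% CI excludes zero and p < 0.005."""
    name = result.term_index(term)
    lo, hi = result.conf_int.loc[name, ["lo", "hi"]]
    p = result.pvalues.loc[name]
    return bool(((lo > 0) or (hi < 0)) and (p < SIGNIFICANCE_P))


def coefficient_table(result: MixedModelResult) -> pd.DataFrame:
    """Tidy standardized-coefficient report."""
    out = pd.DataFrame({
        "beta": result.fe_params,
        "ci_lo": result.conf_int["lo"],
        "ci_hi": result.conf_int["hi"],
        "p": result.pvalues,
    })
    out["significant"] = [(r.ci_lo > 0 or r.ci_hi < 0) and r.p < SIGNIFICANCE_P
                          for r in out.itertuples()]
    return out
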