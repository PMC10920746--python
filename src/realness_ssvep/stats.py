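"""Statistical models: linear vs quadratic realness effects and confounds.

The central question is whether EEG response amplitude varies with face
realness linearly or quadratically (U-shaped, the uncanny-valley
signature).  Both hypotheses are cast as linear mixed models with a
subject random intercept,

    amplitude ~ 1 + realness + (1 | subject)
    amplitude ~ 1 + realness + realness^2 + (1 | subject)

fit by full maximum likelihood (not REML: the fixed effects differ between
the models, so REML likelihoods would not be comparable).  The models are
compared by a likelihood-ratio test (chi-square with 1 df) and by AIC/BIC,
where the parameter count includes the fixed effects plus the random-
intercept variance and the residual variance.  Confound-adjusted variants
add a covariate (e.g. stimulus eye size) to both models.

Condition means are displayed with 95% within-subject confidence
intervals: subject-mean centering (plus grand-mean restoration) removes
between-subject offsets, and the Morey factor sqrt(M/(M-1)) corrects the
resulting variance underestimate for M conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ModelComparison", "compare_models", "within_subject_ci",
           "partial_correlation", "stimulus_correlations",
           "confound_balance_tests"]


@dataclass
class ModelComparison:
    """Paired linear/quadratic mixed-model fits and their LRT."""

    response: str
    unit: str
    linear: dict        # {"aic", "bic", "llf", "params"}
    quadratic: dict
    chi2: float
    df: int
    p: float
    n_obs: int
    confound: str | None = None
    degenerate: bool = False

    def to_rows(self) -> pd.DataFrame:
        """Table-style output: one row per model (L/Q) with fit indices."""
        rows = []
        for tag, fit in (("L", self.linear), ("Q", self.quadratic)):
            rows.append(dict(response=self.response, unit=self.unit,
                             model=tag, aic=fit["aic"], bic=fit["bic"],
                             loglik=fit["llf"], lrt_chi2=self.chi2,
                             lrt_p=self.p, confound=self.confound or ""))
        return pd.DataFrame(rows)


def _fit_mixed(df: pd.DataFrame, formula: str, response: str):
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups=df["subject"])
        res, llf = None, np.inf
        # lbfgs can report a spurious infinite likelihood when the
        # random-intercept variance hits the boundary; fall back then
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=False, method=[method])
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(cand.llf):
                res, llf = cand, float(cand.llf)
                break
    if res is None:
        raise RuntimeError(
            f"mixed model {formula!r} failed to produce a finite likelihood")
    # k = fixed effects + random-intercept variance + residual variance
    k = res.k_fe + 2
    n = len(df)
    return dict(aic=2 * k - 2 * llf, bic=k * np.log(n) - 2 * llf, llf=llf,
                k=k, params=dict(res.fe_params))


def compare_models(amps: pd.DataFrame, response: str = "amplitude",
                   unit: str = "", confound: str | None = None,
                   aggregate: bool = True) -> ModelComparison:
    """Linear vs quadratic mixed-model comparison of a realness effect.

    ``amps`` is a long table with columns ``subject``, ``realness`` (1..6),
    the response, and optionally the confound covariate.  With
    ``aggregate=True`` (default) observations are first averaged within
    subject x realness (x confound) across sessions and trials; otherwise
    the model is fit at the trial level.
    """
    cols = ["subject", "realness", response]
    if confound is not None:
        cols.append(confound)
    df = amps[cols].dropna().copy()
    if df["subject"].nunique() < 2:
        raise ValueError("mixed model needs at least two subjects")
    if aggregate:
        keys = ["subject", "realness"]
        df = df.groupby(keys, as_index=False, observed=True).mean()
    df["realness"] = df["realness"].astype(float)

    base = f"{response} ~ realness"
    if confound is not None:
        base += f" + {confound}"
    quad = base + " + I(realness**2)"

    if np.allclose(df[response].std(ddof=0), 0.0):
        flat = dict(aic=np.nan, bic=np.nan, llf=np.nan, k=np.nan, params={})
        return ModelComparison(response, unit, flat, dict(flat), 0.0, 1, 1.0,
                               len(df), confound, degenerate=True)

    try:
        lin_fit = _fit_mixed(df, base, response)
        quad_fit = _fit_mixed(df, quad, response)
    except (np.linalg.LinAlgError, ValueError) as err:
        raise RuntimeError(f"mixed-model fit failed: {err}") from err

    chi2 = max(0.0, 2.0 * (quad_fit["llf"] - lin_fit["llf"]))
    p = float(sps.chi2.sf(chi2, df=1))
    return ModelComparison(response, unit, lin_fit, quad_fit, chi2, 1, p,
                           len(df), confound)


def within_subject_ci(amps: pd.DataFrame, value: str = "amplitude",
                      within: str = "realness", subject: str = "subject",
                      confidence: float = 0.95) -> pd.DataFrame:
    """Condition means with within-subject confidence intervals.

    Requires a balanced subject x condition table (observations are
    averaged within cell first).  Returns one row per condition with
    ``mean``, ``ci_halfwidth``, ``sem`` and ``n_subjects``.
    """
    cell = (amps.groupby([subject, within], observed=True)[value]
            .mean().unstack(within))
    if cell.isna().any().any():
        raise ValueError("unbalanced table: every subject needs every condition")
    n_subj, n_cond = cell.shape
    if n_subj < 2 or n_cond < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = cell.to_numpy().mean()
    adjusted = cell.sub(cell.mean(axis=1), axis=0) + grand
    morey = np.sqrt(n_cond / (n_cond - 1.0))
    sem = adjusted.std(axis=0, ddof=1) / np.sqrt(n_subj) * morey
    tcrit = sps.t.ppf(0.5 + confidence / 2.0, df=n_subj - 1)
    out = pd.DataFrame({
        within: cell.columns,
        "mean": cell.mean(axis=0).to_numpy(),
        "sem": sem.to_numpy(),
        "ci_halfwidth": (tcrit * sem).to_numpy(),
    })
    out["n_subjects"] = n_subj
    out.attrs["method"] = "subject-mean centering + Morey correction"
    return out


def partial_correlation(x, y, covar) -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing both on covar.

    Returns (r, p) with the p-value from a t distribution on n - 3 degrees
    of freedom.  If either residual is (numerically) constant — e.g. the
    covariate equals one of the variables — the partial correlation is 0
    by convention and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.column_stack([np.ones_like(x), np.asarray(covar, dtype=float)])
    rx = x - c @ np.linalg.lstsq(c, x, rcond=None)[0]
    ry = y - c @ np.linalg.lstsq(c, y, rcond=None)[0]
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if rx.std() < 1e-10 * scale or ry.std() < 1e-10 * scale:
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    dof = n - 3
    if dof <= 0 or abs(r) >= 1.0:
        return r, 0.0 if abs(r) >= 1.0 else 1.0
    t = r * np.sqrt(dof / (1.0 - r ** 2))
    return r, float(2.0 * sps.t.sf(abs(t), dof))


def _pearson_row(df, x, y):
    sub = df[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError(f"fewer than 3 complete pairs for ({x}, {y})")
    if sub[x].std(ddof=0) == 0 or sub[y].std(ddof=0) == 0:
        r, p = np.nan, np.nan
    else:
        r, p = sps.pearsonr(sub[x], sub[y])
    return dict(kind="pearson", x=x, y=y, covariate="", r=float(r),
                p=float(p), n=len(sub))


def stimulus_correlations(stim: pd.DataFrame, amps: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Correlations among stimulus attributes, ratings and EEG amplitudes.

    Always reports r(eye_size, realism) and r(sclera_size, realism).  When
    an amplitude table is given it is averaged per image and merged on
    ``image_id``, adding r(amplitude, realism) and the partial correlation
    of amplitude with realness controlling for eye size.
    """
    rows = [_pearson_row(stim, "eye_size", "realism"),
            _pearson_row(stim, "sclera_size", "realism")]
    if amps is not None:
        per_image = (amps.groupby("image_id", as_index=False, observed=True)
                     ["amplitude"].mean())
        merged = stim.merge(per_image, on="image_id", how="inner")
        if len(merged) < 3:
            raise ValueError("fewer than 3 images with amplitude data")
        rows.append(_pearson_row(merged, "amplitude", "realism"))
        r, p = partial_correlation(merged["amplitude"], merged["realness"],
                                   merged["eye_size"])
        rows.append(dict(kind="partial", x="amplitude", y="realness",
                         covariate="eye_size", r=r, p=p, n=len(merged)))
    return pd.DataFrame(rows)


def confound_balance_tests(stim: pd.DataFrame, pair=(5, 6),
                           variables=("eye_size", "luminosity")) -> pd.DataFrame:
    """Paired t-tests of stimulus attributes between two realness levels.

    Images are paired by (gender, emotion); with the full design this
    gives six pairs and 5 degrees of freedom.  A zero within-pair
    difference yields t = 0, p = 1.
    """
    a, b = pair
    left = stim[stim["realness"] == a].set_index(["gender", "emotion"])
    right = stim[stim["realness"] == b].set_index(["gender", "emotion"])
    if len(left) != len(right) or not left.index.sort_values().equals(
            right.index.sort_values()):
        raise ValueError(f"levels {a} and {b} are not fully paired by "
                         "gender x emotion")
    right = right.loc[left.index]
    rows = []
    for var in variables:
        diff = left[var].to_numpy() - right[var].to_numpy()
        if np.allclose(diff.std(ddof=1), 0.0):
            t, p = (0.0, 1.0) if np.allclose(diff, 0.0) else (np.inf, 0.0)
        else:
            t, p = sps.ttest_rel(left[var], right[var])
        rows.append(dict(variable=var, level_a=a, level_b=b, t=float(t),
                         df=len(diff) - 1, p=float(p)))
    return pd.DataFrame(rows)
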