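"""Ordination and cross-pair summary statistics.

PCA of aligned shapes (eigenvalues on the same 1/n divisor as the
disparity module, so they sum to total Procrustes variance), correlation
of PC1 with the first PLS axis, t-test contrasts of eigenvalue
dispersions across pairs, and the disparity~integration regressions with
a form (wild/domestic) interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .covariation import PLSResult
from .gpa_symmetry import ShapeArrays


class StatsError(ValueError):
    pass


@dataclass
class OrdinationResult:
    pc_scores: np.ndarray  # n x k, axes to >= 95% cumulative variance
    eigenvalues: np.ndarray  # all eigenvalues (1/n divisor)
    variance_fraction: np.ndarray
    n_retained: int


def pca(shapes: ShapeArrays | np.ndarray, retain: float = 0.95) -> OrdinationResult:
    """PCA of flattened aligned coordinates.

    Eigenvalues use the 1/n divisor so they sum to the total Procrustes
    variance; scores are returned for the axes reaching ``retain``
    cumulative variance.
    """
    data = shapes.flat() if isinstance(shapes, ShapeArrays) else np.asarray(shapes, float)
    if data.ndim == 3:
        data = data.reshape(data.shape[0], -1)
    n = data.shape[0]
    if n < 3:
        raise StatsError("need at least 3 specimens for PCA")
    centred = data - data.mean(axis=0)
    # SVD route: all non-trivial eigenvalues without forming the 3p x 3p matrix
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    eig = s**2 / n
    frac = eig / eig.sum()
    cum = np.cumsum(frac)
    k = int(np.searchsorted(cum, retain) + 1)
    scores = centred @ vt[:k].T
    return OrdinationResult(
        pc_scores=scores, eigenvalues=eig, variance_fraction=frac, n_retained=k
    )


def pc1_pls1_correlation(
    ordination: OrdinationResult, pls: PLSResult, block: str = "NC"
) -> tuple[float, float]:
    """|Pearson r| between PC1 scores and first-axis PLS scores.

    Both axes have arbitrary sign, so the absolute correlation is
    reported.  ``block`` selects whose PLS scores are used ("NC" or "MD").
    Returns ``(abs_r, p_value)`` from the standard correlation test.
    """
    pc1 = ordination.pc_scores[:, 0]
    scores = pls.x_scores if block == "NC" else pls.y_scores
    if len(pc1) != len(scores):
        raise StatsError(
            f"score length mismatch: {len(pc1)} PC scores vs {len(scores)} PLS scores"
        )
    r, p = stats.pearsonr(pc1, scores)
    return float(abs(r)), float(p)


def dispersion_ttests(dispersion: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test contrasts of eigenvalue dispersion across pairs.

    ``dispersion`` must have columns pair, form ("wild"/"domestic"),
    module ("NC"/"MD"), value.  Four contrasts: NC vs MD overall (paired
    over pair x form), NC vs MD within each form (paired over pairs), and
    wild vs domestic within each module.
    """
    required = {"pair", "form", "module", "value"}
    if not required.issubset(dispersion.columns):
        raise StatsError(f"dispersion table needs columns {sorted(required)}")

    def paired(sub: pd.DataFrame, split_col: str, a: str, b: str, index_cols: list[str]):
        wide = sub.pivot_table(index=index_cols, columns=split_col, values="value")
        if a not in wide or b not in wide or len(wide) < 2:
            raise StatsError("fewer than 2 pairs for a contrast")
        xa, xb = wide[a].to_numpy(), wide[b].to_numpy()
        d = xa - xb
        if np.allclose(d.std(ddof=1), 0):
            if np.allclose(d, 0):
                return 0.0, len(d) - 1, 1.0
            raise StatsError("zero variance of non-zero differences; t undefined")
        t, p = stats.ttest_rel(xa, xb)
        return float(t), len(d) - 1, float(p)

    rows = []
    t, df, p = paired(dispersion, "module", "NC", "MD", ["pair", "form"])
    rows.append({"contrast": "NC vs MD (all forms)", "t": t, "df": df, "p": p})
    for form in ("wild", "domestic"):
        sub = dispersion[dispersion["form"] == form]
        t, df, p = paired(sub, "module", "NC", "MD", ["pair"])
        rows.append({"contrast": f"NC vs MD ({form})", "t": t, "df": df, "p": p})
    for module in ("NC", "MD"):
        sub = dispersion[dispersion["module"] == module]
        t, df, p = paired(sub, "form", "wild", "domestic", ["pair"])
        rows.append({"contrast": f"wild vs domestic ({module})", "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def variance_ratio_ftest(a: np.ndarray, b: np.ndarray) -> tuple[float, int, int, float]:
    """F test of equality of variances between two samples.

    Returns ``(F, df1, df2, p)`` with F = var(a)/var(b) (ddof=1) and a
    two-sided p-value.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise StatsError("zero variance in denominator sample")
    f = va / vb
    df1, df2 = len(a) - 1, len(b) - 1
    p = 2 * min(stats.f.cdf(f, df1, df2), stats.f.sf(f, df1, df2))
    return float(f), df1, df2, float(min(p, 1.0))


def disparity_integration_regression(
    disparity: np.ndarray,
    integration: np.ndarray,
    form: np.ndarray | list[str],
) -> dict:
    """OLS of integration on disparity with a form interaction.

    Fits ``integration ~ disparity * form`` and reports the per-form
    slopes, the interaction F test (full vs common-slope model) with its
    degrees of freedom, the model p-value, and the variance-ratio F test
    between the forms' disparity values.
    """
    df = pd.DataFrame(
        {
            "disparity": np.asarray(disparity, float),
            "integration": np.asarray(integration, float),
            "form": list(form),
        }
    )
    forms = sorted(df["form"].unique())
    if len(forms) != 2:
        raise StatsError(f"exactly two forms required, got {forms}")
    if (df.groupby("form").size() < 2).any():
        raise StatsError("each form needs at least 2 observations")
    full = smf.ols("integration ~ disparity * form", data=df).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise StatsError("rank-deficient design")
    reduced = smf.ols("integration ~ disparity + form", data=df).fit()
    anova = sm.stats.anova_lm(reduced, full)
    f_inter = float(anova["F"].iloc[1])
    p_inter = float(anova["Pr(>F)"].iloc[1])
    df_num = int(anova["df_diff"].iloc[1])
    df_den = int(full.df_resid)

    slopes = {}
    for fo in forms:
        sub = df[df["form"] == fo]
        fit = smf.ols("integration ~ disparity", data=sub).fit()
        slopes[fo] = float(fit.params["disparity"])

    a = df.loc[df["form"] == forms[0], "disparity"].to_numpy()
    b = df.loc[df["form"] == forms[1], "disparity"].to_numpy()
    f_var, vdf1, vdf2, p_var = variance_ratio_ftest(a, b)

    return {
        "slopes": slopes,
        "interaction_F": f_inter,
        "interaction_df": (df_num, df_den),
        "interaction_p": p_inter,
        "model_p": float(full.f_pvalue),
        "variance_ratio_F": f_var,
        "variance_ratio_df": (vdf1, vdf2),
        "variance_ratio_p": p_var,
    }
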