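"""Allometry: shape-on-size regression with residual randomization.

Shape (all 3p Procrustes coordinates jointly) is regressed on the natural
log of centroid size.  Significance uses the residual randomization
permutation procedure (RRPP): residuals of the reduced (intercept-only)
model are shuffled among specimens, added back to the reduced-model fit,
and the model sum of squares is recomputed; the observed fit counts as one
member of the permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .gpa_symmetry import ShapeArrays


class AllometryError(ValueError):
    pass


@dataclass
class AllometryResult:
    """Procrustes ANOVA of shape on log centroid size."""

    coefficients: np.ndarray  # (3p,) shape change per unit log size
    intercept: np.ndarray  # (3p,) fitted shape at mean log size removed
    r_squared: float
    ss_model: float
    ss_resid: float
    ss_total: float
    f_statistic: float
    effect_size_z: float
    p_value: float
    perm_distribution: np.ndarray
    residuals: np.ndarray  # (n, p, 3)
    shapes: ShapeArrays
    log_size: np.ndarray


def _model_ss(y_centred: np.ndarray, x_centred: np.ndarray) -> float:
    """SS explained by a single centred regressor over all columns."""
    sxx = float(x_centred @ x_centred)
    cross = x_centred @ y_centred  # (3p,)
    return float(cross @ cross) / sxx


def procrustes_anova(
    shapes: ShapeArrays, n_perm: int = 1000, seed: int | None = 0
) -> AllometryResult:
    """Multivariate regression of Procrustes shape on log centroid size.

    ``n_perm`` is the total number of permutation iterations, the observed
    arrangement counted among them (so p >= 1/n_perm).
    """
    if n_perm < 1:
        raise AllometryError("n_perm must be >= 1")
    n = shapes.n_specimens
    if n < 4:
        raise AllometryError("need at least 4 specimens")
    y = shapes.flat()
    x = np.log(shapes.centroid_size)
    xc = x - x.mean()
    if np.allclose(xc, 0.0):
        raise AllometryError("log centroid size is constant; allometry undefined")
    yc = y - y.mean(axis=0)

    sxx = float(xc @ xc)
    beta = (xc @ yc) / sxx  # (3p,)
    ss_total = float(np.sum(yc**2))
    ss_model = _model_ss(yc, xc)
    ss_resid = ss_total - ss_model
    fitted = np.outer(xc, beta)
    residuals_flat = yc - fitted
    df_model, df_resid = 1, n - 2
    f_stat = (ss_model / df_model) / (ss_resid / df_resid)

    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    perm[0] = ss_model
    # permuting reduced-model (intercept-only) residuals == permuting rows of yc
    for b in range(1, n_perm):
        perm[b] = _model_ss(yc, xc[rng.permutation(n)])
    p_value = float(np.mean(perm >= ss_model))
    sd = perm.std(ddof=1)
    z = (ss_model - perm.mean()) / sd if sd > 0 else np.inf

    return AllometryResult(
        coefficients=beta,
        intercept=y.mean(axis=0),
        r_squared=ss_model / ss_total,
        ss_model=ss_model,
        ss_resid=ss_resid,
        ss_total=ss_total,
        f_statistic=f_stat,
        effect_size_z=float(z),
        p_value=p_value,
        perm_distribution=perm,
        residuals=residuals_flat.reshape(shapes.aligned.shape),
        shapes=shapes,
        log_size=x,
    )


def allometry_residuals(result: AllometryResult, recentre: bool = True) -> ShapeArrays:
    """Package allometry-corrected shapes for downstream modules.

    With ``recentre`` (default) the grand-mean shape is added back so the
    residual coordinates remain interpretable as shapes; either way the
    residuals carry zero linear relationship with log size.
    """
    resid = result.residuals.copy()
    if recentre:
        resid = resid + result.intercept.reshape(1, *resid.shape[1:])
    return replace(
        result.shapes,
        aligned=resid,
        consensus=resid.mean(axis=0),
    )


def _group_slopes(
    y: np.ndarray, x: np.ndarray, labels: np.ndarray
) -> dict[str, np.ndarray]:
    slopes = {}
    for g in np.unique(labels):
        sel = labels == g
        xg = x[sel] - x[sel].mean()
        yg = y[sel] - y[sel].mean(axis=0)
        slopes[g] = (xg @ yg) / float(xg @ xg)
    return slopes


def vector_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two shape-change vectors."""
    cosine = float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def compare_allometric_vectors(
    shapes: ShapeArrays,
    labels: list[str] | np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Angle between per-group allometric vectors, RRPP significance.

    The null model is a common slope for both groups: its residuals are
    permuted among specimens, per-group slopes refitted and the angle
    recomputed.  p is the proportion of permuted angles >= observed, with
    the observed arrangement counted.
    """
    if labels is None:
        labels = shapes.group
    if labels is None:
        raise AllometryError("group labels required")
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise AllometryError(f"exactly two groups required, got {list(groups)}")
    for g in groups:
        if np.sum(labels == g) < 4:
            raise AllometryError(f"group '{g}' has fewer than 4 specimens")
    y = shapes.flat()
    x = np.log(shapes.centroid_size)

    slopes = _group_slopes(y, x, labels)
    observed = vector_angle(slopes[groups[0]], slopes[groups[1]])

    # common-slope null model (pooled regression, per-group intercepts)
    n = len(labels)
    fitted = np.empty_like(y)
    xc_all = np.empty(n)
    for g in groups:
        sel = labels == g
        xc_all[sel] = x[sel] - x[sel].mean()
    yc = y.copy()
    for g in groups:
        sel = labels == g
        yc[sel] -= y[sel].mean(axis=0)
    common_beta = (xc_all @ yc) / float(xc_all @ xc_all)
    fitted = np.outer(xc_all, common_beta)
    resid = yc - fitted

    rng = np.random.default_rng(seed)
    count = 1  # observed
    for _ in range(n_perm - 1):
        y_star = fitted + resid[rng.permutation(n)]
        s = _group_slopes(y_star, x, labels)
        if vector_angle(s[groups[0]], s[groups[1]]) >= observed:
            count += 1
    return observed, count / n_perm


def centroid_size_ttest(
    shapes: ShapeArrays, labels: list[str] | np.ndarray | None = None
) -> tuple[float, float, float]:
    """Welch two-sample t-test on log centroid size between the two groups.

    Returns ``(t, df, p)``.
    """
    if labels is None:
        labels = shapes.group
    if labels is None:
        raise AllometryError("group labels required")
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise AllometryError(f"exactly two groups required, got {list(groups)}")
    a = np.log(shapes.centroid_size[labels == groups[0]])
    b = np.log(shapes.centroid_size[labels == groups[1]])
    if len(a) < 2 or len(b) < 2:
        raise AllometryError("each group needs at least 2 specimens")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise AllometryError("zero size variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
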