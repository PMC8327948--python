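"""Covariation statistics: covariance ratio, two-block PLS, eigenvalue dispersion.

Three complementary measures of how landmark modules covary:

* **Covariance ratio (CR)** — between-module covariation relative to
  within-module covariation, with within-block variable diagonals
  excluded.  CR < 1 indicates modular structure (more covariation within
  than between modules); the test permutes landmark labels (x, y, z of a
  landmark move together) and is significant in the LEFT tail.

* **Two-block PLS** — singular value decomposition of the between-block
  covariance matrix; r-PLS is the correlation of the first pair of
  projected scores, measuring between-module integration.  The test
  permutes specimens of one block and is significant in the RIGHT tail.
  The effect size z standardizes the observed r against the permutation
  distribution, making integration comparable across analyses.

* **Relative eigenvalue standard deviation** — dispersion of the
  eigenvalues of a module's correlation matrix, scaled to [0, 1]; a
  trait-count-independent measure of within-module integration.

None of these statistics inverts a covariance matrix, so all remain
well defined on the rank-deficient data typical after Procrustes
superimposition (n << 3p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gpa_symmetry import ShapeArrays
from .io_landmarks import ModuleMap


class CovariationError(ValueError):
    pass


@dataclass
class ModularityResult:
    cr_observed: float
    perm_distribution: np.ndarray
    p_value: float
    effect_size_z: float


@dataclass
class PLSResult:
    r_pls: float
    singular_values: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray
    p_value: float
    effect_size_z: float
    perm_distribution: np.ndarray
    label: str = ""


@dataclass
class DispersionResult:
    rel_eig_sd: float
    module: str
    n_variables: int
    landmark_corrected: bool = True


def _as_matrix(shapes: ShapeArrays | np.ndarray) -> np.ndarray:
    if isinstance(shapes, ShapeArrays):
        return shapes.flat()
    x = np.asarray(shapes, dtype=float)
    if x.ndim == 3:
        x = x.reshape(x.shape[0], -1)
    return x


def _landmark_block_norms(data: np.ndarray, p: int) -> np.ndarray:
    """p x p matrix of squared Frobenius norms of the 3x3 covariance blocks,
    with the variable diagonal zeroed inside each landmark's own block."""
    n = data.shape[0]
    centred = data - data.mean(axis=0)
    s = (centred.T @ centred) / (n - 1)
    # squared block norms via reshaping (p, 3, p, 3)
    s4 = s.reshape(p, 3, p, 3)
    m = np.einsum("iajb,iajb->ij", s4, s4)
    diag_sq = np.einsum("iaia,iaia->i", s4, s4)
    m[np.diag_indices(p)] -= diag_sq
    return m


def _cr_from_blocks(m: np.ndarray, labels: np.ndarray) -> float:
    a = labels == "NC"
    b = ~a
    between = float(m[np.ix_(a, b)].sum())
    within_a = float(m[np.ix_(a, a)].sum())
    within_b = float(m[np.ix_(b, b)].sum())
    if within_a <= 0 or within_b <= 0:
        raise CovariationError("zero within-module off-diagonal covariance; CR undefined")
    return float(np.sqrt(between / np.sqrt(within_a * within_b)))


def covariance_ratio(
    shapes: ShapeArrays | np.ndarray, module_map: ModuleMap
) -> float:
    """Covariance ratio between the NC and MD landmark partitions.

    From the full coordinate covariance matrix S partitioned into
    within-module blocks S11, S22 and between-module block S12:

        CR = sqrt( ||S12||_F^2 / ( ||S11*||_F * ||S22*||_F ) )

    where * zeroes each within-module block's variable diagonal.
    """
    data = _as_matrix(shapes)
    p = len(module_map.assignment)
    if data.shape[1] != 3 * p:
        raise CovariationError(
            f"data has {data.shape[1]} variables, module map implies {3 * p}"
        )
    if data.shape[0] < 3:
        raise CovariationError("need at least 3 specimens")
    if module_map.n_nc < 2 or module_map.n_md < 2:
        raise CovariationError("each module needs at least 2 landmarks")
    m = _landmark_block_norms(data, p)
    return _cr_from_blocks(m, module_map.as_labels())


def modularity_test(
    shapes: ShapeArrays | np.ndarray,
    module_map: ModuleMap,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> ModularityResult:
    """CR modularity test against a landmark-relabelling null.

    Landmarks (coordinate triplets intact) are randomly reassigned to
    modules of the observed sizes; p is the proportion of permuted CR
    values <= observed, the observed counted among ``n_perm`` iterations.
    """
    if n_perm < 1:
        raise CovariationError("n_perm must be >= 1")
    data = _as_matrix(shapes)
    p = len(module_map.assignment)
    labels = module_map.as_labels()
    m = _landmark_block_norms(data, p)
    observed = _cr_from_blocks(m, labels)

    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    perm[0] = observed
    for b in range(1, n_perm):
        perm[b] = _cr_from_blocks(m, labels[rng.permutation(p)])
    p_value = float(np.mean(perm <= observed))
    sd = perm.std(ddof=1)
    z = (observed - perm.mean()) / sd if sd > 0 else -np.inf
    return ModularityResult(
        cr_observed=observed, perm_distribution=perm, p_value=p_value,
        effect_size_z=float(z),
    )


def _pls_first_axis(xc: np.ndarray, yc: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """First singular pair of the between-block covariance and score correlation."""
    s12 = xc.T @ yc / (xc.shape[0] - 1)
    u, sing, vt = np.linalg.svd(s12, full_matrices=False)
    xs = xc @ u[:, 0]
    ys = yc @ vt[0]
    denom = xs.std() * ys.std()
    r = float(np.corrcoef(xs, ys)[0, 1]) if denom > 0 else 0.0
    return r, sing, u, vt.T


def two_block_pls(
    shapes: ShapeArrays | np.ndarray,
    module_map: ModuleMap,
    n_perm: int = 1000,
    seed: int | None = 0,
    label: str = "",
) -> PLSResult:
    """Two-block partial least squares (singular warps) between modules.

    The between-block covariance matrix of the centred NC and MD
    coordinate blocks is decomposed by SVD; r-PLS is the Pearson
    correlation of the first-axis scores.  The null permutes specimen
    rows of one block relative to the other; p is right-tailed with the
    observed arrangement counted among ``n_perm`` iterations.
    """
    if n_perm < 1:
        raise CovariationError("n_perm must be >= 1")
    data = _as_matrix(shapes)
    n = data.shape[0]
    if n < 3:
        raise CovariationError("need at least 3 specimens")
    p = len(module_map.assignment)
    if data.shape[1] != 3 * p:
        raise CovariationError("module map does not match data dimensionality")
    cols = np.arange(3 * p).reshape(p, 3)
    x = data[:, cols[module_map.indices("NC")].ravel()]
    y = data[:, cols[module_map.indices("MD")].ravel()]
    if np.allclose(x.std(axis=0), 0) or np.allclose(y.std(axis=0), 0):
        raise CovariationError("a block has no variance")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)

    r_obs, sing, u, v = _pls_first_axis(xc, yc)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    perm[0] = r_obs
    for b in range(1, n_perm):
        r_b, _, _, _ = _pls_first_axis(xc, yc[rng.permutation(n)])
        perm[b] = r_b
    p_value = float(np.mean(perm >= r_obs))
    sd = perm.std(ddof=1)
    z = (r_obs - perm.mean()) / sd if sd > 0 else np.inf
    return PLSResult(
        r_pls=r_obs,
        singular_values=sing,
        x_scores=xc @ u[:, 0],
        y_scores=yc @ v[:, 0],
        left_vectors=u,
        right_vectors=v,
        p_value=p_value,
        effect_size_z=float(z),
        perm_distribution=perm,
        label=label,
    )


def compare_pls_effects(
    results: list[PLSResult],
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise two-sample z-tests between PLS effect sizes.

    Each analysis's effect size is already a standardized deviate of its
    permutation distribution (unit standard error by construction), so the
    pairwise statistic is (z_i - z_j)/sqrt(2) with a two-sided normal p.

    Returns ``(z_diff, p_values)`` as k x k arrays.
    """
    k = len(results)
    if k < 2:
        raise CovariationError("need at least 2 PLS results to compare")
    for r in results:
        if r.perm_distribution.std(ddof=1) == 0:
            raise CovariationError(
                f"degenerate permutation distribution for '{r.label}'"
            )
    z = np.array([r.effect_size_z for r in results])
    z_diff = (z[:, None] - z[None, :]) / np.sqrt(2.0)
    p = 2.0 * stats.norm.sf(np.abs(z_diff))
    np.fill_diagonal(p, 1.0)
    return z_diff, p


def relative_eigenvalue_sd(corr: np.ndarray) -> float:
    """Relative standard deviation of a correlation matrix's eigenvalues.

    popSD(eigenvalues) / sqrt(N - 1), where popSD uses the 1/N divisor.
    Equals 0 for the identity matrix and 1 for the all-ones (rank one)
    matrix; for an exchangeable matrix with off-diagonal rho it equals rho.
    """
    eig = np.linalg.eigvalsh(corr)
    n_var = corr.shape[0]
    return float(np.sqrt(np.mean((eig - eig.mean()) ** 2)) / np.sqrt(n_var - 1))


def eigenvalue_dispersion(
    shapes: ShapeArrays | np.ndarray,
    module_map: ModuleMap,
    which: str,
) -> DispersionResult:
    """Within-module integration as relative eigenvalue dispersion.

    The correlation matrix of the module's 3*p_module coordinate
    variables is built and its eigenvalue dispersion computed; the
    relative normalization makes values comparable between modules with
    different landmark counts.
    """
    data = _as_matrix(shapes)
    if data.shape[0] < 3:
        raise CovariationError("need at least 3 specimens")
    p = len(module_map.assignment)
    cols = np.arange(3 * p).reshape(p, 3)
    idx = module_map.indices(which)
    if len(idx) < 2:
        raise CovariationError(f"module {which} needs at least 2 landmarks")
    block = data[:, cols[idx].ravel()]
    sd = block.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        j = dead[0]
        raise CovariationError(
            f"zero-variance variable: landmark {idx[j // 3] + 1} axis {'xyz'[j % 3]}"
        )
    corr = np.corrcoef(block, rowvar=False)
    return DispersionResult(
        rel_eig_sd=relative_eigenvalue_sd(corr),
        module=which,
        n_variables=block.shape[1],
    )
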