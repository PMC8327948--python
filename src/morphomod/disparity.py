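"""Morphological disparity as Procrustes variance, with permutation contrasts.

Procrustes variance of a group is the trace of its coordinate covariance
matrix with the 1/n divisor — equivalently the mean squared deviation of
specimens from the group mean shape summed over all coordinates.  Group
differences are tested by permuting group-mean-centred residual vectors
among specimens and recomputing the absolute disparity difference.

For cross-module comparisons, each module's disparity is divided by its
landmark count to remove the trivial dependence on module size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gpa_symmetry import ShapeArrays, subset_module
from .io_landmarks import ModuleMap


class DisparityError(ValueError):
    pass


@dataclass
class DisparityResult:
    proc_var: dict[str, float]
    proc_var_per_landmark: dict[str, float]
    pairwise_diffs: dict[tuple[str, str], float] = field(default_factory=dict)
    p_values: dict[tuple[str, str], float] = field(default_factory=dict)
    module: str | None = None
    n_landmarks: int = 0


def _labels(shapes: ShapeArrays, labels) -> np.ndarray:
    if labels is None:
        labels = shapes.group
    if labels is None:
        raise DisparityError("group labels required")
    labels = np.asarray(labels)
    if len(labels) != shapes.n_specimens:
        raise DisparityError("labels length does not match specimens")
    return labels


def procrustes_variance(
    shapes: ShapeArrays, labels=None
) -> dict[str, float]:
    """Per-group Procrustes variance (trace of covariance, 1/n divisor)."""
    labels = _labels(shapes, labels)
    data = shapes.flat()
    out: dict[str, float] = {}
    for g in np.unique(labels):
        sel = labels == g
        if sel.sum() < 2:
            raise DisparityError(f"group '{g}' has fewer than 2 specimens")
        centred = data[sel] - data[sel].mean(axis=0)
        out[str(g)] = float(np.sum(centred**2) / sel.sum())
    return out


def disparity_test(
    shapes: ShapeArrays,
    labels=None,
    n_perm: int = 1000,
    seed: int | None = 0,
    module: str | None = None,
    n_landmarks: int | None = None,
) -> DisparityResult:
    """Permutation test of |disparity difference| between groups.

    The null permutes group-mean-centred residual vectors among
    specimens; p is the proportion of permuted |differences| >= observed,
    the observed arrangement counted among ``n_perm`` iterations.
    """
    if n_perm < 1:
        raise DisparityError("n_perm must be >= 1")
    labels = _labels(shapes, labels)
    groups = [str(g) for g in np.unique(labels)]
    if len(groups) < 2:
        raise DisparityError("at least two distinct groups required")
    pv = procrustes_variance(shapes, labels)
    p_lm = n_landmarks if n_landmarks is not None else shapes.n_landmarks

    data = shapes.flat()
    sq = np.empty(len(labels))  # squared residual norm per specimen
    for g in groups:
        sel = labels == g
        centred = data[sel] - data[sel].mean(axis=0)
        sq[sel] = np.sum(centred**2, axis=1)
    group_masks = {g: labels == g for g in groups}
    counts = {g: int(m.sum()) for g, m in group_masks.items()}

    rng = np.random.default_rng(seed)
    result = DisparityResult(
        proc_var=pv,
        proc_var_per_landmark={g: v / p_lm for g, v in pv.items()},
        module=module,
        n_landmarks=p_lm,
    )
    for a_i in range(len(groups)):
        for b_i in range(a_i + 1, len(groups)):
            ga, gb = groups[a_i], groups[b_i]
            observed = abs(pv[ga] - pv[gb])
            count = 1
            for _ in range(n_perm - 1):
                shuffled = sq[rng.permutation(len(sq))]
                diff = abs(
                    shuffled[group_masks[ga]].sum() / counts[ga]
                    - shuffled[group_masks[gb]].sum() / counts[gb]
                )
                if diff >= observed:
                    count += 1
            result.pairwise_diffs[(ga, gb)] = observed
            result.p_values[(ga, gb)] = count / n_perm
    return result


def module_disparity(
    shapes: ShapeArrays,
    module_map: ModuleMap,
    labels=None,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> dict[str, DisparityResult]:
    """Per-module, per-group disparity with wild/domestic permutation tests.

    Modules are subsets of the joint superimposition; landmark-corrected
    values (disparity / landmark count) support NC-vs-MD comparison.
    """
    labels = _labels(shapes, labels)
    out: dict[str, DisparityResult] = {}
    ss = np.random.SeedSequence(seed).spawn(2)
    for sub_seed, which in zip(ss, ("NC", "MD")):
        sub = subset_module(shapes, module_map, which)
        out[which] = disparity_test(
            sub,
            labels,
            n_perm=n_perm,
            seed=sub_seed.generate_state(1)[0] % (2**31),
            module=which,
            n_landmarks=sub.n_landmarks,
        )
    return out
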