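"""Generalized Procrustes superimposition and object-symmetry decomposition.

The superimposition follows the classic iterative scheme: configurations
are centred, scaled to unit centroid size, and rotated onto a running
consensus by orthogonal Procrustes rotation (determinant +1 only) until
the consensus stabilises.  For bilaterally symmetric structures the
symmetric component of shape is extracted by jointly superimposing each
configuration with its mirrored, relabelled copy and averaging the two;
the residual from that average is the asymmetric component.

Module subsetting deliberately does NOT re-superimpose: modules are
analysed in the coordinate system of the joint fit, so statistics on
different modules remain comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io_landmarks import LandmarkDataset, ModuleMap, SymmetryPairing


class GPAError(RuntimeError):
    """Raised when superimposition cannot proceed."""


@dataclass
class ShapeArrays:
    """Procrustes-aligned shapes plus centroid sizes.

    ``aligned`` is ``(n, p, 3)`` with every configuration centred at the
    origin and scaled to unit centroid size; ``centroid_size`` holds the
    pre-scaling sizes.  ``symmetric`` flags whether the coordinates are
    the symmetric component of shape.
    """

    aligned: np.ndarray
    centroid_size: np.ndarray
    consensus: np.ndarray
    symmetric: bool = False
    group: list[str] | None = None
    specimen_ids: list[str] | None = None
    pair_id: str = "pair"

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """Specimens x (3p) matrix of flattened coordinates."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark deviations from the centroid."""
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[0] < 3:
        raise GPAError(f"configuration must be (p>=3, d), got {config.shape}")
    if not np.all(np.isfinite(config)):
        raise GPAError("non-finite coordinates")
    centred = config - config.mean(axis=0)
    size = float(np.sqrt(np.sum(centred**2)))
    if size <= 0.0:
        raise GPAError("degenerate configuration: all landmarks coincide")
    return size


def _optimal_rotation(
    source: np.ndarray, target: np.ndarray, check_reflection: bool = False
) -> np.ndarray:
    """Rotation R (det +1) minimising ||source @ R - target||_F.

    With ``check_reflection``, raises when allowing a reflection would fit
    dramatically better — the signature of a left/right digitising
    inconsistency, which should be fixed in the data, not silently
    reflected away.  Two merely different shapes never trigger it.
    """
    u, s, vt = np.linalg.svd(source.T @ target)
    d = np.linalg.det(u @ vt)
    if d < 0:
        if check_reflection:
            ssq = np.sum(source**2) + np.sum(target**2)
            ss_rotation = ssq - 2.0 * (s[:-1].sum() - s[-1])
            ss_reflection = ssq - 2.0 * s.sum()
            if ss_reflection < 0.1 * ss_rotation:
                raise GPAError(
                    "optimal superimposition requires a reflection; check "
                    "left/right digitising consistency"
                )
        u[:, -1] *= -1.0
    return u @ vt


def gpa(
    dataset: LandmarkDataset | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> ShapeArrays:
    """Generalized Procrustes Analysis of a set of configurations.

    Each configuration is centred, scaled to unit centroid size and
    iteratively rotated onto the consensus until the root-mean-square
    change of the consensus falls below ``tol``.
    """
    if isinstance(dataset, LandmarkDataset):
        coords = dataset.coords
        group = list(dataset.group)
        ids = list(dataset.specimen_ids)
        pair_id = dataset.pair_id
    else:
        coords = np.asarray(dataset, dtype=float)
        group = None
        ids = None
        pair_id = "pair"
    n = coords.shape[0]
    if n < 2:
        raise GPAError("need at least 2 configurations")

    sizes = np.array([centroid_size(c) for c in coords])
    aligned = (coords - coords.mean(axis=1, keepdims=True)) / sizes[:, None, None]

    consensus = aligned[0].copy()
    consensus /= np.sqrt(np.sum(consensus**2))
    for _ in range(max_iter):
        for i in range(n):
            aligned[i] = aligned[i] @ _optimal_rotation(
                aligned[i], consensus, check_reflection=True
            )
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus**2))
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise GPAError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})"
        )
    # final rotation pass so every specimen is aligned to the converged consensus
    for i in range(n):
        aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
    return ShapeArrays(
        aligned=aligned,
        centroid_size=sizes,
        consensus=aligned.mean(axis=0),
        symmetric=False,
        group=group,
        specimen_ids=ids,
        pair_id=pair_id,
    )


def mirror_relabel(
    coords: np.ndarray, pairing: SymmetryPairing, axis: int = 1
) -> np.ndarray:
    """Reflect configurations across the symmetry-normal axis and swap
    paired landmark labels.  A perfectly symmetric configuration maps to
    itself (up to rigid motion)."""
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    pairing.validate(coords.shape[1])
    mirrored = coords.copy()
    mirrored[..., axis] *= -1.0
    out = mirrored.copy()
    for left, right in pairing.pairs:
        out[:, left], out[:, right] = mirrored[:, right].copy(), mirrored[:, left].copy()
    return out[0] if single else out


def symmetric_component(
    shapes: ShapeArrays,
    pairing: SymmetryPairing,
    axis: int = 1,
    midline_tol: float = 0.1,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[ShapeArrays, np.ndarray]:
    """Extract the symmetric component of shape for object symmetry.

    Each aligned configuration and its mirrored, relabelled copy are
    superimposed jointly (one GPA over ``2n`` configurations); the
    per-specimen average of the two copies is the symmetric component and
    the half-difference is returned as the asymmetric deviations.

    Returns ``(symmetric_shapes, asymmetry)`` where ``asymmetry`` is the
    ``(n, p, 3)`` array of original-minus-symmetric deviations.
    """
    n = shapes.n_specimens
    pairing.validate(shapes.n_landmarks)
    mirrored = mirror_relabel(shapes.aligned, pairing, axis=axis)
    joint = gpa(np.concatenate([shapes.aligned, mirrored], axis=0), tol=tol, max_iter=max_iter)
    orig, mirr = joint.aligned[:n], joint.aligned[n:]
    sym = 0.5 * (orig + mirr)
    asym = orig - sym

    if pairing.midline:
        # off-plane drift of a midline landmark shows up as its asymmetric
        # deviation; the check is orientation-free
        drift = np.sqrt(np.mean(asym[:, pairing.midline] ** 2))
        scale = np.sqrt(np.mean(sym**2))
        if drift > midline_tol * scale:
            warnings.warn(
                f"midline landmarks drift off the symmetry plane "
                f"(asymmetric RMS {drift:.3g} vs shape RMS {scale:.3g})",
                stacklevel=2,
            )
    result = ShapeArrays(
        aligned=sym,
        centroid_size=shapes.centroid_size.copy(),
        consensus=sym.mean(axis=0),
        symmetric=True,
        group=shapes.group,
        specimen_ids=shapes.specimen_ids,
        pair_id=shapes.pair_id,
    )
    return result, asym


def subset_module(shapes: ShapeArrays, module_map: ModuleMap, which: str) -> ShapeArrays:
    """Select one module's landmarks from the joint fit, without refitting.

    Coordinates are taken as-is from the shared superimposition and
    centroid sizes are carried over unchanged, so module statistics live
    in a common coordinate system.
    """
    idx = module_map.indices(which)
    if len(module_map.assignment) != shapes.n_landmarks:
        raise GPAError("module map does not match the number of landmarks")
    if not idx:
        raise GPAError(f"module {which} selects no landmarks")
    sub = shapes.aligned[:, idx, :]
    return replace(shapes, aligned=sub, consensus=sub.mean(axis=0))


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations
    (both centred and scaled to unit centroid size, optimal rotation)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = (a - a.mean(axis=0)) / centroid_size(a)
    b = (b - b.mean(axis=0)) / centroid_size(b)
    rot = _optimal_rotation(a, b)
    return float(np.sqrt(np.sum((a @ rot - b) ** 2)))
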