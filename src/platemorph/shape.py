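"""Outline resampling to a fixed landmark scheme and Procrustes mean shapes.

Digitized plate outlines carry a variable number of vertices (roughly
600–1100 per plate), so each outline is resampled to 200 ordered landmarks:
two fixed anatomical landmarks at the lower and upper medial corners plus
198 semilandmarks along the outline between them.  Populations of landmark
sets are superimposed by generalized Procrustes analysis (translation,
unit-centroid-size scaling, rotation; reflections excluded) and summarized
by their consensus configuration.  Semilandmarks can optionally be slid
along their local outline tangent toward the consensus (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import polygon_area

__all__ = [
    "LandmarkSet",
    "MeanShape",
    "resample_outline",
    "centroid_size",
    "procrustes_distance",
    "gpa_align",
    "slide_semilandmarks",
    "population_mean_shapes",
]


@dataclass
class LandmarkSet:
    """Ordered landmark configuration for one plate outline.

    ``points[0]`` is the lower medial corner and ``points[upper_index]`` the
    upper medial corner; all other rows are semilandmarks in outline
    traversal order.
    """

    points: np.ndarray  # (n_landmarks, 2)
    upper_index: int
    specimen_id: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if not (0 < self.upper_index < len(self.points)):
            raise ValueError("upper corner index out of range")


@dataclass
class MeanShape:
    """GPA consensus configuration: centered, unit centroid size."""

    points: np.ndarray
    upper_index: int
    population_id: str | None = None
    n_shapes: int = 0

    def validate(self, tol: float = 1e-9) -> None:
        c = self.points.mean(axis=0)
        if np.linalg.norm(c) > tol:
            raise ValueError("mean shape centroid differs from origin")
        if abs(centroid_size(self.points) - 1.0) > tol:
            raise ValueError("mean shape centroid size differs from 1")


def _ensure_ccw(outline: np.ndarray) -> np.ndarray:
    v = np.asarray(outline, dtype=float)
    x, y = v[:, 0], v[:, 1]
    signed2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return v if signed2 > 0 else v[::-1]


def _segment_arclengths(seg: np.ndarray) -> np.ndarray:
    d = np.diff(seg, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])


def _interp_along(seg: np.ndarray, targets: np.ndarray) -> np.ndarray:
    s = _segment_arclengths(seg)
    xs = np.interp(targets, s, seg[:, 0])
    ys = np.interp(targets, s, seg[:, 1])
    return np.column_stack([xs, ys])


def resample_outline(
    outline,
    corner_indices: tuple[int, int],
    n_between: int = 198,
    mode: str = "arc_length",
    seed: int | None = None,
) -> LandmarkSet:
    """Resample an outline to ``2 + n_between`` ordered landmarks.

    The two corner vertices are retained exactly.  ``arc_length`` places
    semilandmarks at equal arc-length spacing within each corner-to-corner
    outline segment, allocating them proportionally to segment length;
    ``random`` draws existing vertices uniformly without replacement
    (seed-reproducible), keeping traversal order.
    """
    v = np.asarray(outline, dtype=float)
    lower, upper = corner_indices
    if lower == upper:
        raise ValueError("corner indices must differ")
    if not (0 <= lower < len(v)) or not (0 <= upper < len(v)):
        raise ValueError("corner index out of range")
    if polygon_area(v) <= 0:
        raise ValueError("degenerate outline")

    ccw = _ensure_ccw(v)
    if ccw is not v and not np.array_equal(ccw, v):
        # reversing flips vertex indices
        lower = len(v) - 1 - lower
        upper = len(v) - 1 - upper
        v = ccw
    v = np.roll(v, -lower, axis=0)
    upper = (upper - lower) % len(v)

    seg1 = v[: upper + 1]  # lower corner .. upper corner
    seg2 = np.vstack([v[upper:], v[:1]])  # upper corner .. back to lower

    if mode == "arc_length":
        L1 = _segment_arclengths(seg1)[-1]
        L2 = _segment_arclengths(seg2)[-1]
        n1 = int(round(n_between * L1 / (L1 + L2)))
        n1 = min(max(n1, 0), n_between)
        n2 = n_between - n1
        t1 = L1 * (np.arange(1, n1 + 1)) / (n1 + 1)
        t2 = L2 * (np.arange(1, n2 + 1)) / (n2 + 1)
        pts = np.vstack(
            [v[:1], _interp_along(seg1, t1), v[upper : upper + 1], _interp_along(seg2, t2)]
        )
        return LandmarkSet(points=pts, upper_index=n1 + 1)
    if mode == "random":
        candidates = [i for i in range(1, len(v)) if i != upper]
        if len(candidates) < n_between:
            raise ValueError(
                f"outline has too few vertices ({len(v)}) for {n_between} semilandmarks"
            )
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(candidates, size=n_between, replace=False))
        idx = np.concatenate([[0], chosen[chosen < upper], [upper], chosen[chosen > upper]])
        pts = v[idx]
        return LandmarkSet(points=pts, upper_index=int(np.count_nonzero(chosen < upper)) + 1)
    raise ValueError(f"unknown resampling mode {mode!r}")


def centroid_size(points) -> float:
    p = np.asarray(points, dtype=float)
    c = p.mean(axis=0)
    return float(np.sqrt(((p - c) ** 2).sum()))


def _center_scale(points: np.ndarray) -> np.ndarray:
    p = points - points.mean(axis=0)
    s = np.sqrt((p**2).sum())
    if s == 0:
        raise ValueError("degenerate shape: zero centroid size")
    return p / s


def _optimal_rotation(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (no reflection) minimizing ||X R - target||_F."""
    U, _, Vt = np.linalg.svd(X.T @ target)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


def procrustes_distance(a, b) -> float:
    """Full Procrustes distance between two configurations.

    Both shapes are centered and scaled to unit centroid size, the second is
    rotated onto the first (reflections excluded), and the residual
    root-sum-of-squares is returned.
    """
    A = _center_scale(np.asarray(a, dtype=float))
    B = _center_scale(np.asarray(b, dtype=float))
    R = _optimal_rotation(B, A)
    return float(np.sqrt(((B @ R - A) ** 2).sum()))


def gpa_align(
    shapes,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[list[np.ndarray], MeanShape]:
    """Generalized Procrustes alignment and consensus of >=2 landmark sets.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated onto the running consensus (reflections excluded);
    the consensus is the renormalized mean, iterated until it moves by less
    than ``tol`` (Frobenius norm) or ``max_iter`` iterations.
    """
    arrays = [s.points if isinstance(s, LandmarkSet) else np.asarray(s, float) for s in shapes]
    if len(arrays) < 2:
        raise ValueError("GPA needs >=2 shapes")
    k = arrays[0].shape
    if any(a.shape != k for a in arrays):
        raise ValueError("all shapes need matching landmark counts")
    X = [_center_scale(a) for a in arrays]
    consensus = X[0].copy()
    for _ in range(max_iter):
        X = [x @ _optimal_rotation(x, consensus) for x in X]
        new = _center_scale(np.mean(X, axis=0))
        new = new @ _optimal_rotation(new, consensus)  # fix rotational drift
        if np.linalg.norm(new - consensus) < tol:
            consensus = new
            break
        consensus = new
    upper = shapes[0].upper_index if isinstance(shapes[0], LandmarkSet) else 0
    mean = MeanShape(points=consensus, upper_index=upper, n_shapes=len(arrays))
    return X, mean


def slide_semilandmarks(
    aligned: list[np.ndarray],
    consensus: MeanShape | np.ndarray,
    fixed_indices: tuple[int, ...] | None = None,
) -> list[np.ndarray]:
    """One Gauss–Seidel pass of tangent sliding toward the consensus.

    Each semilandmark moves along its local outline tangent (estimated from
    its cyclic neighbors) to the point nearest the corresponding consensus
    landmark; fixed landmarks (the two corners by default) never move.  The
    per-landmark projection cannot increase the summed squared distance to
    the consensus.
    """
    C = consensus.points if isinstance(consensus, MeanShape) else np.asarray(consensus, float)
    if fixed_indices is None:
        upper = consensus.upper_index if isinstance(consensus, MeanShape) else 0
        fixed_indices = (0, upper)
    fixed = set(fixed_indices)
    out = []
    for shape in aligned:
        P = np.asarray(shape, dtype=float).copy()
        n = len(P)
        for i in range(n):
            if i in fixed:
                continue
            t = P[(i + 1) % n] - P[(i - 1) % n]
            norm = np.linalg.norm(t)
            if norm == 0:
                continue
            t /= norm
            P[i] = P[i] + t * np.dot(t, C[i] - P[i])
        out.append(P)
    return out


def population_mean_shapes(
    landmark_sets_by_population: dict,
    min_n: int = 4,
    slide: bool = False,
) -> dict[str, MeanShape]:
    """GPA consensus shape per population with at least ``min_n`` females.

    With ``slide=True`` one tangent-sliding pass is interleaved after each
    of a small number of GPA refits.
    """
    out: dict[str, MeanShape] = {}
    for pid, sets in landmark_sets_by_population.items():
        if len(sets) < min_n:
            continue
        if len(sets) == 1:
            only = sets[0]
            pts = _center_scale(only.points)
            out[pid] = MeanShape(pts, only.upper_index, population_id=pid, n_shapes=1)
            continue
        aligned, mean = gpa_align(sets)
        if slide:
            for _ in range(3):
                aligned = slide_semilandmarks(aligned, mean)
                aligned, mean = gpa_align(aligned if not isinstance(aligned[0], LandmarkSet) else aligned)
                mean.upper_index = sets[0].upper_index
        mean.population_id = pid
        out[pid] = mean
    return out
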