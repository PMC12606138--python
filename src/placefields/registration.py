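"""Longitudinal cell registration from spatial footprints.

The field of view of the moving session is aligned to the reference session
by maximising an intensity-normalised correlation criterion over a rigid
(translation + rotation) motion model; cells are then matched greedily by
normalised cross-correlation (NCC) of their footprints, best pair first,
until no pair above the threshold remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation

from .synth import FootprintStack


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the FOV centre followed by a (dy, dx) shift.

    Maps a moving-frame point p to ``R(θ)(p − c) + c + t`` in the reference
    frame, with c the image centre.
    """

    rotation_deg: float
    shift: tuple[float, float]
    centre: tuple[float, float]

    def _R(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def apply_to_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(self.centre)
        return (pts - c) @ self._R().T + c + np.asarray(self.shift)

    def apply_to_image(self, img: np.ndarray, order: int = 1) -> np.ndarray:
        """Warp a moving-frame image into the reference frame."""
        Rinv = self._R().T
        c = np.asarray(self.centre)
        t = np.asarray(self.shift)
        offset = c - Rinv @ (c + t)
        return affine_transform(img, Rinv, offset=offset, order=order, mode="constant", cval=0.0)

    def inverse(self) -> "RigidTransform":
        Rinv = self._R().T
        t = np.asarray(self.shift)
        return RigidTransform(
            rotation_deg=-self.rotation_deg,
            shift=tuple((-Rinv @ t).tolist()),
            centre=self.centre,
        )


def _ecc(a: np.ndarray, b: np.ndarray) -> float:
    """Enhanced correlation coefficient: zero-mean normalised correlation."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def align_fov(
    image_moving: np.ndarray,
    image_reference: np.ndarray,
    max_rotation_deg: float = 10.0,
    rotation_step_deg: float = 1.0,
    refine: bool = True,
) -> RigidTransform:
    """Rigid transform aligning the moving field of view to the reference.

    Coarse search: for each rotation on a grid, the best translation is
    found by phase cross-correlation; the candidate with the highest
    correlation seeds a Nelder-Mead refinement of (θ, dy, dx) maximising the
    enhanced correlation coefficient. Falls back to the identity transform
    with a warning if no candidate improves on it.
    """
    mov = np.asarray(image_moving, dtype=float)
    ref = np.asarray(image_reference, dtype=float)
    if mov.shape != ref.shape:
        raise ValueError("images must share shape")
    if np.ptp(mov) == 0 or np.ptp(ref) == 0:
        raise ValueError("images must be non-constant")
    centre = ((mov.shape[0] - 1) / 2.0, (mov.shape[1] - 1) / 2.0)

    def score(params) -> float:
        th, dy, dx = params
        T = RigidTransform(th, (dy, dx), centre)
        return _ecc(T.apply_to_image(mov), ref)

    best = (0.0, 0.0, 0.0)
    best_score = score(best)
    for th in np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, rotation_step_deg):
        rotated = RigidTransform(th, (0.0, 0.0), centre).apply_to_image(mov)
        shift, _, _ = phase_cross_correlation(ref, rotated, upsample_factor=10)
        cand = (float(th), float(shift[0]), float(shift[1]))
        s = score(cand)
        if s > best_score:
            best, best_score = cand, s

    if refine:
        res = minimize(
            lambda p: -score(p),
            x0=np.asarray(best),
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": 400},
        )
        if res.success or -res.fun >= best_score:
            best, best_score = tuple(res.x), -res.fun

    if best_score <= _ecc(mov, ref) - 1e-12 and best != (0.0, 0.0, 0.0):
        warnings.warn("FOV alignment did not improve on identity; using identity")
        return RigidTransform(0.0, (0.0, 0.0), centre)
    return RigidTransform(best[0], (best[1], best[2]), centre)


# ---------------------------------------------------------------------------
# footprint matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Greedy NCC matching outcome; pairs in acceptance (descending NCC) order."""

    pairs: list = field(default_factory=list)  # (idA, idB, ncc)
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)
    transform: RigidTransform | None = None


def footprint_ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean NCC of two footprints over their union support.

    Restricting to the union of the supports avoids the shared empty
    background dominating the correlation on large fields of view. Disjoint
    positive footprints score ≤ 0; a footprint against itself scores 1.
    """
    support = (a > 0) | (b > 0)
    if not support.any():
        return 0.0
    return _ecc(a[support], b[support])


def match_cells_ncc(
    stack_a: FootprintStack,
    stack_b: FootprintStack,
    threshold: float = 0.5,
    transform: RigidTransform | None = None,
) -> MatchResult:
    """One-to-one greedy matching of footprints across sessions.

    The globally best remaining pair is accepted and both cells removed,
    repeating while the best NCC exceeds ``threshold``. Equal-NCC ties break
    to the lexicographically lowest (idA, idB) pair, making the result
    independent of input ordering.
    """
    na, nb = len(stack_a.cell_ids), len(stack_b.cell_ids)
    result = MatchResult(transform=transform)
    if na == 0 or nb == 0:
        result.unmatched_a = list(stack_a.cell_ids)
        result.unmatched_b = list(stack_b.cell_ids)
        return result

    order_a = np.argsort(np.asarray(stack_a.cell_ids, dtype=object))
    order_b = np.argsort(np.asarray(stack_b.cell_ids, dtype=object))
    ncc = np.full((na, nb), -np.inf)
    for i in order_a:
        for j in order_b:
            ncc[i, j] = footprint_ncc(stack_a.images[i], stack_b.images[j])

    alive_a = np.ones(na, dtype=bool)
    alive_b = np.ones(nb, dtype=bool)
    while alive_a.any() and alive_b.any():
        sub = np.where(np.outer(alive_a, alive_b), ncc, -np.inf)
        best = sub.max()
        if not best > threshold:
            break
        cand = np.argwhere(sub == best)
        ids = sorted(
            (stack_a.cell_ids[i], stack_b.cell_ids[j], i, j) for i, j in cand
        )
        _, _, i, j = ids[0]
        result.pairs.append((stack_a.cell_ids[i], stack_b.cell_ids[j], float(best)))
        alive_a[i] = False
        alive_b[j] = False
    result.unmatched_a = [stack_a.cell_ids[i] for i in np.flatnonzero(alive_a)]
    result.unmatched_b = [stack_b.cell_ids[j] for j in np.flatnonzero(alive_b)]
    return result


def register_sessions(
    stack_a: FootprintStack,
    stack_b: FootprintStack,
    threshold: float = 0.5,
    max_rotation_deg: float = 10.0,
) -> MatchResult:
    """Align session B's field of view to session A's and match cells."""
    T = align_fov(stack_b.fov, stack_a.fov, max_rotation_deg=max_rotation_deg)
    warped = FootprintStack(
        np.stack([T.apply_to_image(img) for img in stack_b.images]),
        list(stack_b.cell_ids),
    )
    return match_cells_ncc(stack_a, warped, threshold=threshold, transform=T)
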