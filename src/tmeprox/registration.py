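"""Landmark-based 2-D registration of serial sections.

Consecutive 4-um sections are stained for different markers; to co-analyze
two markers the sections must be brought into one coordinate frame
("Z-stacked").  Registration here is landmark-based: matched fiducial pairs
are supplied (by the user or by the synthetic generator) and a rigid,
similarity or full affine transform is fit by least squares.  The rigid and
similarity fits are solved in closed form via orthogonal Procrustes with
reflections disallowed; the affine fit is a linear least-squares solve.

The achieved root-mean-square residual (microns) is returned alongside the
transform.  When it exceeds the 20-um proximity radius a warning is issued,
since radius-based proximity counts across such a pair of sections are no
longer reliable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from tmeprox.core_io import CellTable

#: residual above which cross-section proximity becomes unreliable (microns)
RESIDUAL_WARNING_UM = 20.0

_MIN_DET = 1e-12


class RegistrationError(ValueError):
    pass


@dataclass(frozen=True)
class AffineTransform2D:
    """2x3 affine map (x, y) -> (x', y') in microns.

    ``matrix`` is ``[[a, b, tx], [c, d, ty]]`` applied as
    ``x' = a x + b y + tx``, ``y' = c x + d y + ty``.
    """

    matrix: tuple

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (2, 3):
            raise ValueError("matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) <= _MIN_DET:
            raise ValueError("linear part is singular")
        object.__setattr__(self, "matrix", tuple(map(tuple, m)))

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)))

    @classmethod
    def from_rigid(cls, angle_rad: float, tx: float, ty: float) -> "AffineTransform2D":
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        return cls(((c, -s, tx), (s, c, ty)))

    @property
    def _m(self) -> np.ndarray:
        return np.asarray(self.matrix, float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        m = self._m
        return pts @ m[:, :2].T + m[:, 2]

    def inverse(self) -> "AffineTransform2D":
        m = self._m
        a_inv = np.linalg.inv(m[:, :2])
        t_inv = -a_inv @ m[:, 2]
        return AffineTransform2D(tuple(map(tuple, np.column_stack([a_inv, t_inv]))))

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return the transform equivalent to applying ``other`` first, then
        ``self``."""
        a, b = self._m, other._m
        lin = a[:, :2] @ b[:, :2]
        tr = a[:, :2] @ b[:, 2] + a[:, 2]
        return AffineTransform2D(tuple(map(tuple, np.column_stack([lin, tr]))))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.matrix}, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform2D":
        with open(path) as fh:
            return cls(json.load(fh)["matrix"])


@dataclass(frozen=True)
class RegistrationResult:
    transform: AffineTransform2D
    rmse_um: float
    model: str


def fit_affine(
    moving_landmarks: np.ndarray,
    fixed_landmarks: np.ndarray,
    model: str = "rigid",
) -> RegistrationResult:
    """Least-squares landmark registration mapping moving -> fixed.

    Parameters
    ----------
    moving_landmarks, fixed_landmarks
        (n, 2) matched point arrays in microns; the i-th rows correspond.
    model
        ``rigid`` (rotation + translation, closed-form Procrustes,
        reflection disallowed), ``similarity`` (adds isotropic scale) or
        ``affine`` (full 6-dof linear least squares).

    Requires >= 2 non-collinear pairs for rigid/similarity, >= 3 for affine.
    """
    mov = np.atleast_2d(np.asarray(moving_landmarks, float))
    fix = np.atleast_2d(np.asarray(fixed_landmarks, float))
    if mov.shape != fix.shape or mov.ndim != 2 or mov.shape[1] != 2:
        raise RegistrationError("landmark arrays must be matched (n, 2)")
    n = len(mov)
    min_n = 3 if model == "affine" else 2
    if n < min_n:
        raise RegistrationError(f"{model} fit needs >= {min_n} landmark pairs, got {n}")

    mu_m, mu_f = mov.mean(axis=0), fix.mean(axis=0)
    mc, fc = mov - mu_m, fix - mu_f

    if model == "affine":
        # x' = A x + t solved as one linear system per output coordinate
        design = np.column_stack([mov, np.ones(n)])
        if np.linalg.matrix_rank(design) < 3:
            raise RegistrationError("landmarks are collinear; affine fit is degenerate")
        coef, *_ = np.linalg.lstsq(design, fix, rcond=None)
        matrix = np.column_stack([coef[:2].T, coef[2]])
    elif model in ("rigid", "similarity"):
        if np.linalg.matrix_rank(mc, tol=1e-9 * max(1.0, np.abs(mc).max())) < 2 and n > 2:
            raise RegistrationError("landmarks are collinear; rotation is ill-determined")
        h = mc.T @ fc
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        if d < 0 and s[-1] <= 1e-9 * max(s[0], 1.0):
            # rank-deficient cross-covariance (e.g. two landmarks): the
            # smallest singular direction is free, no reflection is needed
            d = 1.0
        if d < 0:
            raise RegistrationError(
                "landmark correspondence requires a reflection, which the "
                f"{model} model disallows; use model='affine'"
            )
        rot = vt.T @ np.diag([1.0, d]) @ u.T
        if model == "similarity":
            denom = (mc**2).sum()
            if denom == 0:
                raise RegistrationError("moving landmarks are coincident")
            scale = (s * np.array([1.0, d])).sum() / denom
        else:
            scale = 1.0
        lin = scale * rot
        tr = mu_f - lin @ mu_m
        matrix = np.column_stack([lin, tr])
    else:
        raise ValueError(f"unknown model {model!r}")

    transform = AffineTransform2D(tuple(map(tuple, matrix)))
    resid = transform.apply(mov) - fix
    rmse = float(np.sqrt((resid**2).sum(axis=1).mean()))
    if rmse > RESIDUAL_WARNING_UM:
        warnings.warn(
            f"registration RMSE {rmse:.1f} um exceeds the {RESIDUAL_WARNING_UM:.0f} um "
            "proximity radius; cross-section proximity counts are unreliable",
            stacklevel=2,
        )
    return RegistrationResult(transform, rmse, model)


def apply_transform(cells: CellTable, transform: AffineTransform2D) -> CellTable:
    """Map cell coordinates through ``transform``; all other columns are
    untouched and row order is preserved."""
    out = cells.copy()
    if len(out):
        new_xy = transform.apply(out.xy)
        out.data = out.data.copy()
        out.data["x_um"] = new_xy[:, 0]
        out.data["y_um"] = new_xy[:, 1]
    return out
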