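"""Lesion placement and gradient-domain blending.

The paste step chooses the candidate superpixel whose mean colour is closest
(Euclidean distance) to the lesion's, centres the lesion on that superpixel's
centroid, and composites it.  Compositing modes:

``hard``
    plain pixel replacement inside the lesion support (no blending);
``import``
    Poisson image editing — solve the discrete Poisson equation on the
    support Omega with the lesion's gradient field as guidance and Dirichlet
    boundary equal to the background, so the pasted region inherits the
    background's illumination while keeping the lesion's structure;
``gradient_mix``
    guidance field is the convex combination ``alpha * grad L + (1 - alpha)
    * grad B`` (alpha = 1 reduces to import, alpha = 0 returns the
    background);
``pixel_mix``
    solve import mode first, then mix per pixel: ``alpha * P + (1 - alpha)
    * B`` inside Omega.

Since the two guidance fields are gradients of images, their convex
combination is itself the gradient of the blended image; the solver
therefore always works from a single full-frame guidance image.  The linear
system is the 5-point Laplacian over Omega, symmetric positive definite;
it is solved by a sparse direct factorisation (or conjugate gradients for
very large supports) and the residual is verified against ``solver_tol``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sparse
import scipy.sparse.linalg as sla

from .image import BinaryMask, RgbImage
from .lesions import LesionInstance

__all__ = [
    "BlendMode",
    "BlendParams",
    "Placement",
    "SolverError",
    "match_superpixel",
    "place_lesion",
    "hard_paste",
    "poisson_blend",
]

#: Unknown-count threshold above which CG replaces the direct factorisation.
_DIRECT_SOLVE_LIMIT = 80_000


class SolverError(RuntimeError):
    """The Poisson solve failed to reach the requested residual."""


class BlendMode(str, enum.Enum):
    HARD = "hard"
    IMPORT = "import"
    GRADIENT_MIX = "gradient_mix"
    PIXEL_MIX = "pixel_mix"


@dataclass(frozen=True)
class BlendParams:
    """Blend mode, its mixing weight, and solver tolerances.

    ``sum_gradients`` switches the guidance field to the literal sum of the
    background and lesion gradients instead of the standard import field; it
    exists for comparison only (a self-copy no longer reproduces the image
    under the summed field) and is off by default.
    """

    alpha: float = 0.8
    mode: BlendMode = BlendMode.GRADIENT_MIX
    solver_tol: float = 1e-6
    max_solver_iter: int = 10_000
    sum_gradients: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True, eq=False)
class Placement:
    """Where a lesion lands in the target frame.

    ``offset`` is the (row, col) of the patch's top-left corner; ``omega``
    is the full-frame support of the pasted lesion mask.
    """

    superpixel_id: int
    offset: tuple[int, int]
    omega: BinaryMask


def match_superpixel(les: LesionInstance, stats) -> int:
    """Index of the superpixel whose mean colour is nearest the lesion's.

    Ties break to the lowest id (``argmin`` semantics).
    """
    if len(stats) == 0:
        raise ValueError("no superpixels to match against")
    d = np.linalg.norm(stats.mean_colour - les.mean_colour[None, :], axis=1)
    return int(np.argmin(d))


def place_lesion(
    les: LesionInstance,
    target: RgbImage,
    stats,
    superpixel_id: int,
) -> Placement:
    """Centre the lesion mask on the chosen superpixel's centroid.

    The integer offset is the rounded alignment of the lesion-mask centroid
    with the superpixel centroid, shifted minimally so the patch keeps a
    one-pixel background margin on every side (required by the Poisson
    boundary condition).
    """
    h, w = target.shape
    ph, pw = les.patch.shape
    if ph > h - 2 or pw > w - 2:
        raise ValueError(
            f"lesion patch {ph}x{pw} cannot fit inside frame {h}x{w} with a 1-px margin"
        )
    rr, cc = np.nonzero(les.mask.values)
    mask_centroid = np.array([rr.mean(), cc.mean()])
    sp_centroid = stats.centroid[superpixel_id]
    r0 = int(np.rint(sp_centroid[0] - mask_centroid[0]))
    c0 = int(np.rint(sp_centroid[1] - mask_centroid[1]))
    r0 = min(max(r0, 1), h - 1 - ph)
    c0 = min(max(c0, 1), w - 1 - pw)
    omega = np.zeros((h, w), dtype=bool)
    omega[r0 : r0 + ph, c0 : c0 + pw] = les.mask.values
    return Placement(int(superpixel_id), (r0, c0), BinaryMask(omega))


def hard_paste(target: RgbImage, les: LesionInstance, pl: Placement) -> RgbImage:
    """Replace pixels under the lesion support; leave all others untouched."""
    r0, c0 = pl.offset
    ph, pw = les.patch.shape
    pixels = target.pixels.copy()
    sub = pixels[r0 : r0 + ph, c0 : c0 + pw]
    sub[les.mask.values] = les.patch.pixels[les.mask.values]
    return RgbImage(pixels)


def _guidance_image(
    target: RgbImage, les: LesionInstance, pl: Placement
) -> tuple[np.ndarray, np.ndarray]:
    """Full-frame lesion guidance image and its validity region.

    Inside the placed patch rectangle the image carries the lesion patch;
    guidance edges with an endpoint outside that rectangle have no lesion
    value and fall back to the background's own gradient (so a constant
    lesion on a constant background stays constant).
    """
    r0, c0 = pl.offset
    ph, pw = les.patch.shape
    g = target.pixels.copy()
    g[r0 : r0 + ph, c0 : c0 + pw] = les.patch.pixels
    in_rect = np.zeros(target.shape, dtype=bool)
    in_rect[r0 : r0 + ph, c0 : c0 + pw] = True
    return g, in_rect


def poisson_blend(
    target: RgbImage,
    les: LesionInstance,
    pl: Placement,
    params: BlendParams,
) -> RgbImage:
    """Blend a placed lesion into the target per ``params`` (see module doc)."""
    if params.mode == BlendMode.HARD:
        return hard_paste(target, les, pl)
    omega = pl.omega.values
    if not omega.any():
        raise ValueError("empty lesion support")
    if omega[0, :].any() or omega[-1, :].any() or omega[:, 0].any() or omega[:, -1].any():
        raise ValueError("lesion support touches the frame edge")

    b = target.pixels
    g_lesion, in_rect = _guidance_image(target, les, pl)
    if params.sum_gradients:
        g_lesion = g_lesion + b  # literal summed-gradient field (compat only)

    if params.mode == BlendMode.GRADIENT_MIX:
        guide = params.alpha * g_lesion + (1.0 - params.alpha) * b
        out = _solve_poisson(b, guide, in_rect, omega, params)
    elif params.mode == BlendMode.IMPORT:
        out = _solve_poisson(b, g_lesion, in_rect, omega, params)
    elif params.mode == BlendMode.PIXEL_MIX:
        imported = _solve_poisson(b, g_lesion, in_rect, omega, params)
        out = b.copy()
        out[omega] = params.alpha * imported[omega] + (1.0 - params.alpha) * b[omega]
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown blend mode {params.mode}")
    return RgbImage(np.clip(out, 0.0, 1.0))


def _solve_poisson(
    background: np.ndarray,
    guide: np.ndarray,
    guide_valid: np.ndarray,
    omega: np.ndarray,
    params: BlendParams,
) -> np.ndarray:
    """Solve ``laplacian(I) = div(v)`` on Omega, ``I = background`` on the
    boundary, per colour channel.  The guidance field ``v`` along an edge is
    the difference of ``guide`` when both endpoints lie inside
    ``guide_valid`` (the placed patch rectangle) and of ``background``
    otherwise.  Returns a full-frame array equal to the background outside
    Omega."""
    h, w = omega.shape
    idx = np.full((h, w), -1, dtype=np.int64)
    pr, pc = np.nonzero(omega)
    n = pr.size
    idx[pr, pc] = np.arange(n)

    rows: list[np.ndarray] = [np.arange(n)]
    cols: list[np.ndarray] = [np.arange(n)]
    vals: list[np.ndarray] = [np.full(n, 4.0)]
    # Right-hand side: sum over edges of the guidance difference, plus
    # background values of neighbours outside Omega (Dirichlet boundary).
    rhs = np.zeros((n, 3))
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        qr, qc = pr + dr, pc + dc  # in-bounds: omega is strictly interior
        use_guide = guide_valid[pr, pc] & guide_valid[qr, qc]
        diff = np.where(
            use_guide[:, None],
            guide[pr, pc, :] - guide[qr, qc, :],
            background[pr, pc, :] - background[qr, qc, :],
        )
        rhs += diff
        nb = idx[qr, qc]
        inside = nb >= 0
        rows.append(np.arange(n)[inside])
        cols.append(nb[inside])
        vals.append(np.full(int(inside.sum()), -1.0))
        rhs[~inside] += background[qr[~inside], qc[~inside], :]

    mat = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    sol = np.empty((n, 3))
    if n <= _DIRECT_SOLVE_LIMIT:
        lu = sla.splu(mat)
        for ch in range(3):
            sol[:, ch] = lu.solve(rhs[:, ch])
    else:
        for ch in range(3):
            x, info = sla.cg(
                mat, rhs[:, ch], rtol=0.0, atol=params.solver_tol / 10.0,
                maxiter=params.max_solver_iter,
            )
            if info != 0:
                raise SolverError(f"conjugate gradients did not converge (info={info})")
            sol[:, ch] = x

    residual = np.abs(mat @ sol - rhs).max()
    if residual > params.solver_tol:
        raise SolverError(f"solver residual {residual:.3e} exceeds {params.solver_tol:.3e}")

    out = background.copy()
    out[pr, pc, :] = sol
    return out
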