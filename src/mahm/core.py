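"""Per-pixel matrix analysis of hybrid MRI data.

Each pixel of a hybrid acquisition carries an M x N matrix A of signal
intensities over the TE x b grid.  Because the signal is approximately
exponential in both TE and b, the analysis linearizes A entrywise with a
natural logarithm and forms the symmetric positive-semidefinite Gram matrix

    H = lnA (lnA)^T        if M <= N   ("te-major", K = M)
    H = (lnA)^T lnA        otherwise   ("b-major",  K = N)

whose eigenvalues summarize the joint TE/b signal structure without any
curve fitting.  For mono-exponential (single-compartment) signal,
ln a_ij = ln A0 - TE_i/T2 - b_j D separates into a row term plus a column
term, so lnA has rank <= 2 and the third eigenvalue of H vanishes; tissue
heterogeneity (multiple water compartments) makes lambda3 > 0.  The scalar
ratio lambda_r = (lambda1/lambda2)/lambda3 condenses this into a single
per-pixel statistic.

Raw eigenvalues are scale-sensitive — multiplying all signals by a constant
shifts lnA by a constant matrix and changes the eigenvalues — so they cannot
be compared across scans with different gains; lambda_r provides a degree of
normalization when the TE/b grid is shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from mahm.grid import AcquisitionGrid, HybridStack

__all__ = [
    "HybridSymmetric",
    "EigenResult",
    "EigenMapSet",
    "log_transform",
    "build_hybrid",
    "eig_sym",
    "eig2x2_exact",
    "eig2x2_approx",
    "eigvec2x2",
    "lambda_ratio",
    "harmonize_grid",
    "compute_eigenmaps",
    "default_harmonization_subsets",
]

#: Relative tolerance on negative eigenvalues of the (PSD by construction)
#: hybrid matrix; anything within -PSD_TOL * lambda1 is clamped to zero.
PSD_TOL = 1e-10

#: lambda2 or lambda3 below EPS_RATIO * lambda1 makes lambda_r unreliable;
#: such pixels are capped and flagged.
EPS_RATIO = 1e-12

#: Cap used when no finite in-mask lambda_r exists to set a data-driven cap.
FALLBACK_CAP = 1e12


@dataclass(frozen=True)
class HybridSymmetric:
    """The K x K symmetric hybrid matrix of one pixel (units: squared
    log-signal), together with the product order that produced it."""

    h: np.ndarray
    orientation: str  # "te-major" (lnA lnA^T) or "b-major" ((lnA)^T lnA)

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError(f"hybrid matrix must be square, got {h.shape}")
        object.__setattr__(self, "h", h)

    @property
    def k(self) -> int:
        return self.h.shape[0]

    @property
    def trace(self) -> float:
        return float(np.trace(self.h))

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.h))


@dataclass(frozen=True)
class EigenResult:
    """Sorted eigendecomposition of a hybrid matrix.

    ``eigenvalues`` are descending; ``eigenvectors[:, i]`` pairs with
    ``eigenvalues[i]`` and carries a deterministic sign (largest-magnitude
    component positive).  ``lambda_r`` is present for K >= 3.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    lambda_r: Optional[float] = None
    lambda_r_capped: bool = False

    @property
    def k(self) -> int:
        return len(self.eigenvalues)


def log_transform(values: np.ndarray, floor: float):
    """Entrywise natural log of a pixel matrix with a positive floor.

    Magnitude MRI data can contain zero or (after preprocessing) negative
    intensities at high TE / high b, where the log is undefined; such
    entries are replaced by ``floor`` before taking the log.

    Returns ``(lnA, floored)`` where ``floored`` records whether any entry
    was floored, or ``None`` if every entry is non-positive (background
    pixel, no usable signal).
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        raise ValueError(f"non-finite signal at matrix indices {bad.tolist()}")
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    if np.all(values <= 0):
        return None
    floored = bool(np.any(values < floor))
    return np.log(np.maximum(values, floor)), floored


def build_hybrid(lnA: np.ndarray) -> HybridSymmetric:
    """Form the symmetric hybrid matrix from a log-signal matrix.

    Uses whichever product order yields the smaller matrix; a square input
    defaults to the TE-major order ``lnA (lnA)^T``.  Either way the result
    is a K x K Gram matrix (K = min(M, N)), hence symmetric and positive
    semidefinite, and its nonzero eigenvalues are the squared singular
    values of lnA regardless of orientation.
    """
    lnA = np.asarray(lnA, dtype=float)
    if lnA.ndim != 2:
        raise ValueError(f"expected a 2-D log matrix, got shape {lnA.shape}")
    if not np.all(np.isfinite(lnA)):
        bad = np.argwhere(~np.isfinite(lnA))
        raise ValueError(f"non-finite log-signal at matrix indices {bad.tolist()}")
    m, n = lnA.shape
    if m <= n:
        return HybridSymmetric(lnA @ lnA.T, "te-major")
    return HybridSymmetric(lnA.T @ lnA, "b-major")


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so each column's largest-|.| component is
    positive (ties broken by the earliest index)."""
    idx = np.argmax(np.abs(vecs), axis=-2)
    lead = np.take_along_axis(vecs, idx[..., None, :], axis=-2)
    return vecs * np.where(lead < 0, -1.0, 1.0)


def eig_sym(
    h: HybridSymmetric,
    *,
    lambda_r_cap: float = FALLBACK_CAP,
    sym_tol: float = 1e-8,
) -> EigenResult:
    """Full eigendecomposition of a hybrid matrix.

    Eigenvalues come out descending; tiny negative values (round-off on a
    PSD Gram matrix) are clamped to zero.  For K >= 3 the lambda_r ratio is
    attached, capped at ``lambda_r_cap`` when lambda2 or lambda3 is
    numerically zero.
    """
    mat = h.h
    scale = np.max(np.abs(mat))
    if scale > 0 and np.max(np.abs(mat - mat.T)) > sym_tol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    w, v = w[::-1], v[:, ::-1]
    lam1 = w[0]
    if lam1 > 0:
        if w[-1] < -PSD_TOL * lam1 * 100:
            raise ValueError(
                f"eigenvalue {w[-1]:g} violates positive semidefiniteness"
            )
        w = np.where(w < 0, 0.0, w)
    v = _fix_signs(v)
    lr: Optional[float] = None
    capped = False
    if len(w) >= 3 and lam1 > 0:
        lr, capped = lambda_ratio_values(w, cap=lambda_r_cap)
    return EigenResult(w, v, lr, capped)


def eig2x2_exact(h: HybridSymmetric) -> tuple[float, float]:
    """Closed-form eigenvalues of a 2 x 2 symmetric matrix.

    lambda_{1,2} = (tr(H) +/- sqrt(tr(H)^2 - 4 det(H))) / 2.
    """
    if h.k != 2:
        raise ValueError(f"expected a 2x2 matrix, got K={h.k}")
    tr, det = h.trace, h.det
    disc = tr * tr - 4.0 * det
    if disc < 0:
        if disc < -1e-12 * max(tr * tr, 1.0):
            raise ValueError(f"negative discriminant {disc:g} for symmetric input")
        disc = 0.0
    root = np.sqrt(disc)
    return (0.5 * (tr + root), 0.5 * (tr - root))


def eig2x2_approx(h: HybridSymmetric) -> tuple[float, float]:
    """First-order eigenvalue approximation for a 2 x 2 hybrid matrix:

        lambda1 ~ tr(H) - det(H)/tr(H),   lambda2 ~ det(H)/tr(H).

    Expanding the exact square root in det(H)/tr(H)^2 shows the relative
    error is O(det/tr^2); the approximation is accurate when
    det(H) << tr(H)^2, which holds for hybrid data because lambda1
    dominates the spectrum.
    """
    if h.k != 2:
        raise ValueError(f"expected a 2x2 matrix, got K={h.k}")
    tr = h.trace
    if tr == 0:
        raise ValueError("trace is zero; approximation undefined")
    det = h.det
    return (tr - det / tr, det / tr)


def eigvec2x2(h: HybridSymmetric, lam: float) -> np.ndarray:
    """Unnormalized eigenvector of a 2 x 2 symmetric matrix for ``lam``.

    Uses (H12, lam - H11); falls back to (lam - H22, H21) when the
    off-diagonal vanishes, and to a canonical axis vector for diagonal H.
    """
    if h.k != 2:
        raise ValueError(f"expected a 2x2 matrix, got K={h.k}")
    h11, h12 = h.h[0, 0], h.h[0, 1]
    h21, h22 = h.h[1, 0], h.h[1, 1]
    if abs(h12) >= 1e-12:
        return np.array([h12, lam - h11])
    if abs(h21) >= 1e-12:
        return np.array([lam - h22, h21])
    # diagonal H: eigenvectors are the coordinate axes
    if abs(lam - h11) <= abs(lam - h22):
        return np.array([1.0, 0.0])
    return np.array([0.0, 1.0])


def lambda_ratio_values(
    eigenvalues: Sequence[float], cap: float = FALLBACK_CAP
) -> tuple[float, bool]:
    """lambda_r = (lambda1/lambda2)/lambda3 from a descending eigenvalue
    triple (extra eigenvalues beyond the third are ignored).

    Returns ``(value, capped)``; the ratio is unbounded as lambda3 -> 0
    (rank-2 pixels), so degenerate denominators yield ``cap`` with the
    flag set.
    """
    w = np.asarray(eigenvalues, dtype=float)
    if len(w) < 3:
        raise ValueError(f"need at least 3 eigenvalues, got {len(w)}")
    lam1, lam2, lam3 = w[0], w[1], w[2]
    if lam1 <= 0:
        raise ValueError("lambda1 must be positive")
    if lam2 <= EPS_RATIO * lam1 or lam3 <= EPS_RATIO * lam1:
        return float(cap), True
    value = (lam1 / lam2) / lam3
    if value > cap:
        return float(cap), True
    return float(value), False


def lambda_ratio(eig: EigenResult, cap: float = FALLBACK_CAP) -> tuple[float, bool]:
    """lambda_r of an :class:`EigenResult` (K >= 3 required)."""
    return lambda_ratio_values(eig.eigenvalues, cap=cap)


def default_harmonization_subsets(
    grid: AcquisitionGrid, target_m: int, target_n: int
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Default TE/b subsets for harmonizing a grid down to target sizes.

    Echo times are dropped largest-first and b-values smallest-nonzero-first:
    the extreme long-TE and the low-b images carry the least diffusion/T2
    contrast per unit noise, and the surviving values stay closest to a
    native 3 x 3 protocol.
    """
    tes = list(grid.tes)
    while len(tes) > target_m:
        tes.remove(max(tes))
    bs = list(grid.bvalues)
    while len(bs) > target_n:
        nonzero = [b for b in bs if b > 0]
        bs.remove(min(nonzero) if nonzero else max(bs))
    return tuple(tes), tuple(bs)


def harmonize_grid(
    stack: HybridStack,
    target_m: int,
    target_n: int,
    keep_tes: Optional[Sequence[float]] = None,
    keep_bs: Optional[Sequence[float]] = None,
) -> HybridStack:
    """Reduce a stack to ``target_m`` TEs x ``target_n`` b-values.

    Mixed protocols must be cut down to a shared grid (typically 3 x 3)
    before eigenvalues can be compared across cases.  Explicit subsets
    override the default heuristic of
    :func:`default_harmonization_subsets`.
    """
    grid = stack.grid
    if target_m > grid.m or target_n > grid.n:
        raise ValueError(
            f"target grid {target_m}x{target_n} exceeds current {grid.m}x{grid.n}"
        )
    def_tes, def_bs = default_harmonization_subsets(grid, target_m, target_n)
    tes = tuple(keep_tes) if keep_tes is not None else def_tes
    bs = tuple(keep_bs) if keep_bs is not None else def_bs
    if len(tes) != target_m or len(bs) != target_n:
        raise ValueError(
            f"explicit subsets have sizes {len(tes)}x{len(bs)}, "
            f"expected {target_m}x{target_n}"
        )
    return stack.subset(tes, bs)


@dataclass
class EigenMapSet:
    """Per-pixel eigen-analysis results over a volume.

    ``eigenvalues`` has shape ``spatial + (K,)`` (descending),
    ``eigenvectors`` has shape ``spatial + (K, K)`` with column i paired
    with eigenvalue i, ``lambda_r`` and ``capped`` are spatial maps.
    Pixels outside ``valid`` hold NaN, never zero.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    lambda_r: np.ndarray
    capped: np.ndarray
    valid: np.ndarray
    floored: np.ndarray
    orientation: str
    cap: float
    grid: AcquisitionGrid

    @property
    def k(self) -> int:
        return self.eigenvalues.shape[-1]


def _slice_floor(signal: np.ndarray, rel_floor: float) -> np.ndarray:
    """Per-z-slice log floor: rel_floor x median positive signal."""
    X, Y, Z = signal.shape[:3]
    floors = np.empty(Z)
    for z in range(Z):
        vals = signal[:, :, z]
        pos = vals[vals > 0]
        floors[z] = rel_floor * (np.median(pos) if pos.size else 1.0)
    return floors


def compute_eigenmaps(
    stack: HybridStack,
    mask: Optional[np.ndarray] = None,
    *,
    rel_floor: float = 1e-6,
    cap: Optional[float] = None,
    cap_percentile: float = 99.0,
    cap_factor: float = 10.0,
) -> EigenMapSet:
    """Run the full per-pixel matrix analysis over a volume.

    Per pixel: log-transform (floored at ``rel_floor`` x the slice median
    positive signal) -> hybrid Gram matrix -> eigendecomposition ->
    lambda_r.  Pixels whose matrices are entirely non-positive are marked
    invalid and propagate as NaN.

    The lambda_r cap defaults to ``cap_factor`` x the ``cap_percentile``-th
    percentile of the finite in-mask ratios (the ratio diverges on rank-2
    pixels); pass ``cap`` to fix it explicitly.
    """
    signal = stack.signal
    X, Y, Z, M, N = signal.shape
    if mask is None:
        mask = np.any(signal > 0, axis=(3, 4))
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (X, Y, Z):
        raise ValueError(f"mask shape {mask.shape} != spatial shape {(X, Y, Z)}")
    if not mask.any():
        raise ValueError("mask selects no pixels")

    K = min(M, N)
    orientation = "te-major" if M <= N else "b-major"
    floors = _slice_floor(signal, rel_floor)

    idx = np.argwhere(mask)
    pix = signal[mask]  # (P, M, N)
    pix_floor = floors[idx[:, 2]]
    valid_pix = np.any(pix > 0, axis=(1, 2))

    lnA = np.log(np.maximum(pix, pix_floor[:, None, None]))
    floored_pix = np.any(pix < pix_floor[:, None, None], axis=(1, 2))
    if orientation == "te-major":
        H = np.einsum("pij,pkj->pik", lnA, lnA)
    else:
        H = np.einsum("pji,pjk->pik", lnA, lnA)

    w, v = np.linalg.eigh(H)
    w, v = w[:, ::-1], v[:, :, ::-1]
    lam1 = w[:, 0]
    w = np.where(w < 0, 0.0, w)
    v = _fix_signs(v)

    lam_r = np.full(len(pix), np.nan)
    capped_pix = np.zeros(len(pix), dtype=bool)
    if K >= 3:
        l1, l2, l3 = w[:, 0], w[:, 1], w[:, 2]
        degen = (l2 <= EPS_RATIO * np.maximum(l1, 0)) | (
            l3 <= EPS_RATIO * np.maximum(l1, 0)
        ) | (l1 <= 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (l1 / l2) / l3
        finite = ~degen & valid_pix & np.isfinite(raw)
        if cap is None:
            if finite.any():
                cap = cap_factor * float(
                    np.percentile(raw[finite], cap_percentile)
                )
            else:
                cap = FALLBACK_CAP
        lam_r = np.where(degen, cap, np.minimum(raw, cap))
        capped_pix = degen | (raw > cap)
    else:
        cap = cap if cap is not None else FALLBACK_CAP

    def scatter(values, fill=np.nan, dtype=float, extra=()):
        out = np.full((X, Y, Z) + extra, fill, dtype=dtype)
        out[mask] = values
        return out

    valid = np.zeros((X, Y, Z), dtype=bool)
    valid[mask] = valid_pix
    w = np.where(valid_pix[:, None], w, np.nan)
    v = np.where(valid_pix[:, None, None], v, np.nan)
    lam_r = np.where(valid_pix, lam_r, np.nan)

    return EigenMapSet(
        eigenvalues=scatter(w, extra=(K,)),
        eigenvectors=scatter(v, extra=(K, K)),
        lambda_r=scatter(lam_r),
        capped=scatter(capped_pix & valid_pix, fill=False, dtype=bool),
        valid=valid,
        floored=scatter(floored_pix & valid_pix, fill=False, dtype=bool),
        orientation=orientation,
        cap=float(cap),
        grid=stack.grid,
    )
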