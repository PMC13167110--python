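"""Miniscope-to-confocal co-registration by similarity transform.

Both modalities image the same field of view through the implanted GRIN lens,
so a four-parameter similarity transform (x/y translation, rotation, global
scale) suffices.  Dark blood vessels are the registration landmarks: images are
denoised, background-flattened, and black-hat filtered to turn vessels into
bright ridges, then a coarse exhaustive grid search over transform parameters
is refined by finite-difference gradient ascent on the Pearson correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import black_tophat, footprint_rectangle

from .stacks import ROIMask

__all__ = [
    "PreprocessParams",
    "CALCIUM_PREPROCESS",
    "CONFOCAL_PREPROCESS",
    "SimilarityTransform",
    "SearchGrid",
    "preprocess_image",
    "correlation_score",
    "coarse_search",
    "refine_transform",
    "apply_transform",
    "apply_transform_mask",
    "ImageRegistration",
    "RegistrationResult",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Vessel-enhancement parameters: denoise sigma, background sigma, black-hat window (px)."""

    sigma_denoise: float
    sigma_background: float
    blackhat_window: int

    def __post_init__(self):
        if not self.sigma_denoise < self.sigma_background:
            raise ValueError("sigma_denoise must be smaller than sigma_background")
        if self.blackhat_window < 3 or self.blackhat_window % 2 == 0:
            raise ValueError("blackhat_window must be odd and >= 3")


#: Reference parameters for the time-averaged miniscope (calcium) image.
CALCIUM_PREPROCESS = PreprocessParams(1.0, 50.0, 11)
#: Reference parameters for the confocal vessel-contrast channel.
CONFOCAL_PREPROCESS = PreprocessParams(2.0, 100.0, 21)


def preprocess_image(image: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Denoise, flatten background, and black-hat filter an image.

    Gaussian denoise (small sigma) -> subtract large-sigma Gaussian background
    -> morphological black-hat with a square window, which converts dark
    vessel-like features into bright ridges.  Output is nonnegative.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if image.max() == image.min():
        raise ValueError("constant image has no registerable features")
    denoised = ndimage.gaussian_filter(image, params.sigma_denoise)
    background = ndimage.gaussian_filter(denoised, params.sigma_background)
    flattened = denoised - background
    fp = footprint_rectangle((params.blackhat_window, params.blackhat_window))
    return np.clip(black_tophat(flattened, fp), 0.0, None)


@dataclass(frozen=True)
class SimilarityTransform:
    """Similarity transform: scale then rotate about the image centre, then translate.

    ``tx``/``ty`` are pixel shifts along image x (columns) and y (rows);
    ``rotation`` is in degrees, counter-clockwise in (x, y); ``scale`` is the
    global magnification mapping moving (miniscope) coordinates into fixed
    (confocal) coordinates.
    """

    tx: float = 0.0
    ty: float = 0.0
    rotation: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def params(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.rotation, self.scale])

    @classmethod
    def from_params(cls, p) -> "SimilarityTransform":
        return cls(float(p[0]), float(p[1]), float(p[2]), float(p[3]))

    def matrix(self, shape) -> tuple[np.ndarray, np.ndarray]:
        """Forward map in (row, col) index space: q = A p + b."""
        theta = np.deg2rad(self.rotation)
        c, s = np.cos(theta), np.sin(theta)
        # CCW rotation in (x, y) with y pointing down row-wise
        a_mat = self.scale * np.array([[c, s], [-s, c]])
        centre = (np.asarray(shape, dtype=float) - 1.0) / 2.0
        b_vec = centre - a_mat @ centre + np.array([self.ty, self.tx])
        return a_mat, b_vec

    def inverse(self) -> "SimilarityTransform":
        """Inverse transform about the same centre: t o t.inverse() = identity."""
        theta = np.deg2rad(self.rotation)
        c, s = np.cos(theta), np.sin(theta)
        a_mat = self.scale * np.array([[c, s], [-s, c]])
        t_inv = -np.linalg.solve(a_mat, np.array([self.ty, self.tx]))
        return SimilarityTransform(
            float(t_inv[1]), float(t_inv[0]), -self.rotation, 1.0 / self.scale
        )

    def apply_points(self, rows, cols, shape) -> tuple[np.ndarray, np.ndarray]:
        a_mat, b_vec = self.matrix(shape)
        pts = np.stack([np.asarray(rows, float), np.asarray(cols, float)])
        out = a_mat @ pts + b_vec[:, None]
        return out[0], out[1]


def apply_transform(
    target: np.ndarray,
    t: SimilarityTransform,
    mode: str = "bilinear",
    output_shape=None,
    cval: float = 0.0,
) -> np.ndarray:
    """Warp an image (or label image) into the transformed frame.

    ``bilinear`` for intensity images, ``nearest`` for masks/labels.  Pixels
    mapping outside the input are filled with ``cval``.
    """
    order = {"bilinear": 1, "nearest": 0}[mode]
    target = np.asarray(target)
    shape = tuple(output_shape) if output_shape is not None else target.shape
    a_mat, b_vec = t.matrix(shape)
    a_inv = np.linalg.inv(a_mat)
    return ndimage.affine_transform(
        target.astype(float),
        a_inv,
        offset=-a_inv @ b_vec,
        output_shape=shape,
        order=order,
        cval=cval,
        prefilter=False,
    )


def apply_transform_mask(
    mask: ROIMask, t: SimilarityTransform, shape
) -> ROIMask | None:
    """Map an ROI mask into the fixed frame (nearest-neighbour resampling)."""
    img = mask.to_label_image(shape)
    warped = apply_transform(img, t, mode="nearest", output_shape=shape)
    rows, cols = np.nonzero(warped > 0)
    if rows.size == 0:
        return None
    return ROIMask(rows, cols, mask.roi_id)


def correlation_score(
    fixed: np.ndarray,
    moving: np.ndarray,
    t: SimilarityTransform,
    min_overlap: float = 0.25,
) -> float:
    """Pearson correlation between ``fixed`` and ``moving`` warped by ``t``.

    Computed over the valid-overlap region only; candidates whose warped image
    covers less than ``min_overlap`` of the fixed image score ``-inf``.
    Invariant to affine intensity rescaling of either image.
    """
    warped = apply_transform(moving, t, output_shape=fixed.shape, cval=np.nan)
    valid = np.isfinite(warped)
    if valid.sum() < min_overlap * fixed.size:
        return -np.inf
    a = np.asarray(fixed, float)[valid]
    b = warped[valid]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _axis(extent: float, step: float) -> np.ndarray:
    n = int(round(2 * extent / step))
    return -extent + step * np.arange(n + 1)


@dataclass(frozen=True)
class SearchGrid:
    """Coarse-search parameter grid for the similarity transform.

    Defaults follow the reference protocol: translations +-60 px in 5 px
    steps, rotation +-15 deg in 5 deg steps, scale 1.8-2.0 in 0.05 steps (the
    scale interval encodes the miniscope/confocal pixel-size ratio and should
    be widened for other optics).
    """

    translation_extent: float = 60.0
    translation_step: float = 5.0
    rotation_extent: float = 15.0
    rotation_step: float = 5.0
    scale_range: tuple[float, float] = (1.8, 2.0)
    scale_step: float = 0.05
    learning_rate: float = 0.5

    def __post_init__(self):
        if min(self.translation_step, self.rotation_step, self.scale_step) <= 0:
            raise ValueError("grid steps must be positive")
        if self.scale_range[1] < self.scale_range[0]:
            raise ValueError("scale range is empty")

    def tx_values(self) -> np.ndarray:
        return _axis(self.translation_extent, self.translation_step)

    def rotation_values(self) -> np.ndarray:
        return _axis(self.rotation_extent, self.rotation_step)

    def scale_values(self) -> np.ndarray:
        lo, hi = self.scale_range
        n = int(round((hi - lo) / self.scale_step))
        return lo + self.scale_step * np.arange(n + 1)

    @property
    def n_nodes(self) -> int:
        return (
            len(self.tx_values()) ** 2
            * len(self.rotation_values())
            * len(self.scale_values())
        )

    def nodes(self):
        """Lexicographic (tx, ty, rotation, scale) node order."""
        for tx, ty, rot, sc in itertools.product(
            self.tx_values(),
            self.tx_values(),
            self.rotation_values(),
            self.scale_values(),
        ):
            yield SimilarityTransform(float(tx), float(ty), float(rot), float(sc))


def coarse_search(
    fixed: np.ndarray, moving: np.ndarray, grid: SearchGrid
) -> tuple[SimilarityTransform, float]:
    """Exhaustive grid search maximizing correlation; first-best tie-break."""
    best_t, best_score = None, -np.inf
    for t in grid.nodes():
        score = correlation_score(fixed, moving, t)
        if score > best_score:
            best_t, best_score = t, score
    if best_t is None or not np.isfinite(best_score):
        raise RuntimeError("all coarse-search candidates rejected for overlap")
    return best_t, best_score


#: Central-difference probe steps for (tx, ty, rotation, scale).
_FD_STEPS = np.array([0.5, 0.5, 0.25, 0.005])


def refine_transform(
    fixed: np.ndarray,
    moving: np.ndarray,
    t0: SimilarityTransform,
    learning_rate: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[SimilarityTransform, float]:
    """Refine a transform by finite-difference gradient ascent on correlation.

    Gradients use central differences with steps (0.5 px, 0.5 px, 0.25 deg,
    0.005); the step along the gradient is backtracked when it fails to
    improve, and the probe steps shrink when the gradient direction stalls.
    The returned score is never below ``correlation_score(fixed, moving, t0)``.
    """

    def f(p):
        return correlation_score(fixed, moving, SimilarityTransform.from_params(p))

    p = t0.params()
    best_p, best_f = p.copy(), f(p)
    if np.isnan(best_f):
        warnings.warn("refinement objective is NaN at t0; returning t0")
        return t0, best_f
    h = _FD_STEPS.copy()
    h_min = _FD_STEPS / 8.0
    cur_f = best_f
    for _ in range(max_iter):
        grad = np.zeros(4)
        for i in range(4):
            e = np.zeros(4)
            e[i] = h[i]
            grad[i] = (f(p + e) - f(p - e)) / 2.0
        if np.any(np.isnan(grad)):
            warnings.warn("refinement diverged (NaN score); returning best-so-far")
            break
        gmax = np.max(np.abs(grad))
        improved = False
        if gmax > 0:
            direction = grad / gmax
            step = learning_rate
            while step >= learning_rate / 16.0:
                cand = p + step * h * direction
                fc = f(cand)
                if fc > cur_f + tol:
                    p, cur_f, improved = cand, fc, True
                    break
                step /= 2.0
        if cur_f > best_f:
            best_p, best_f = p.copy(), cur_f
        if not improved:
            if np.all(h <= h_min):
                break
            h = np.maximum(h / 2.0, h_min)
    if cur_f > best_f:
        best_p, best_f = p.copy(), cur_f
    # coordinate-wise polish: the correlation surface couples rotation and
    # scale to the translations, which can stall the joint gradient step
    h = _FD_STEPS.copy()
    while np.any(h >= _FD_STEPS / 16.0):
        moved = False
        for i in range(4):
            for sign in (1.0, -1.0):
                cand = best_p.copy()
                cand[i] += sign * h[i]
                fc = f(cand)
                if fc > best_f + tol:
                    best_p, best_f, moved = cand, fc, True
        if not moved:
            h /= 2.0
            if np.all(h < _FD_STEPS / 16.0):
                break
    return SimilarityTransform.from_params(best_p), float(best_f)


@dataclass
class RegistrationResult:
    """Fitted registration: refined transform, score, and the coarse candidate."""

    transform: SimilarityTransform
    score: float
    coarse_transform: SimilarityTransform
    coarse_score: float
    convention: str = "scale->rotate->translate about image centre; moving->fixed"

    def summary(self) -> str:
        t = self.transform
        lines = [
            "Similarity registration",
            "=" * 52,
            f"  tx        {t.tx:10.3f} px",
            f"  ty        {t.ty:10.3f} px",
            f"  rotation  {t.rotation:10.3f} deg",
            f"  scale     {t.scale:10.4f}",
            f"  correlation (refined) {self.score:8.4f}",
            f"  correlation (coarse)  {self.coarse_score:8.4f}",
            f"  convention: {self.convention}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        t = self.transform
        return {
            "tx": t.tx,
            "ty": t.ty,
            "rotation_deg": t.rotation,
            "scale": t.scale,
            "score": self.score,
            "convention": self.convention,
        }


class ImageRegistration:
    """Model object: co-register a moving (miniscope) onto a fixed (confocal) image.

    Parameters
    ----------
    fixed, moving
        Raw 2-D images.  ``fixed`` is the confocal vessel-contrast reference,
        ``moving`` the time-averaged miniscope image.
    search
        :class:`SearchGrid` for the coarse pass.
    fixed_params, moving_params
        Vessel-enhancement preprocessing; pass ``None`` to use the images as
        given (already preprocessed).
    """

    def __init__(
        self,
        fixed: np.ndarray,
        moving: np.ndarray,
        search: SearchGrid | None = None,
        fixed_params: PreprocessParams | None = CONFOCAL_PREPROCESS,
        moving_params: PreprocessParams | None = CALCIUM_PREPROCESS,
    ):
        self.search = search or SearchGrid()
        self.fixed = (
            preprocess_image(fixed, fixed_params) if fixed_params else np.asarray(fixed, float)
        )
        self.moving = (
            preprocess_image(moving, moving_params)
            if moving_params
            else np.asarray(moving, float)
        )

    def fit(self, max_iter: int = 200, tol: float = 1e-6) -> RegistrationResult:
        coarse_t, coarse_score = coarse_search(self.fixed, self.moving, self.search)
        refined_t, refined_score = refine_transform(
            self.fixed,
            self.moving,
            coarse_t,
            learning_rate=self.search.learning_rate,
            max_iter=max_iter,
            tol=tol,
        )
        return RegistrationResult(refined_t, refined_score, coarse_t, coarse_score)
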