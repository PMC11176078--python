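"""Image-level fish localization and tail-angle quantification.

The chain mirrors a low-magnification single-fish tracking rig: a static
background model, coarse darkest-pixel detection on the blurred difference
image, extraction of a 144x144 px patch, subpixel centroid refinement
(star-centroiding style: blur, invert, median-subtract, threshold, center of
mass), and a quadratic tail fit whose tangent angle is read out at a fixed
arc-length from the tail base.

Conventions: 0-based pixel indices, x rightward, y downward, origin at the
top-left; mm = px * pixel_size.  Tail angles are signed degrees, positive
when the tail is bent toward the fish's right (the side obtained by rotating
the nostril->trunk axis by -90 deg in image coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

__all__ = [
    "NoFishError",
    "LowContrastError",
    "BackgroundModel",
    "compute_background",
    "locate_fish_coarse",
    "extract_patch",
    "refine_centroid_subpixel",
    "track_stack",
    "tail_angle",
    "PATCH_SIZE",
]

PATCH_SIZE = 144          # px; 12 x 12 mm at 83 um/px


class NoFishError(ValueError):
    """The difference image carries no signal (frame equals background)."""


class LowContrastError(ValueError):
    """The patch contains no blob mass above the detection threshold."""


@dataclass
class BackgroundModel:
    image: np.ndarray
    n_samples: int = 100


def compute_background(stack: np.ndarray, n_samples: int = 100
                       ) -> BackgroundModel:
    """Pixelwise mean of ``n_samples`` equidistantly sampled frames.

    Frame indices follow ``floor(k * N / n_samples)`` for k = 0..n_samples-1,
    which is deterministic and never exceeds the last frame.
    """
    n = len(stack)
    if n < n_samples:
        raise ValueError(f"need at least {n_samples} frames, got {n}")
    idx = (np.arange(n_samples) * n) // n_samples
    image = np.mean([np.asarray(stack[i], dtype=float) for i in idx], axis=0)
    return BackgroundModel(image=image, n_samples=n_samples)


def locate_fish_coarse(frame: np.ndarray, background: BackgroundModel,
                       sigma_um: float = 250.0, pixel_size_um: float = 83.0
                       ) -> np.ndarray:
    """Darkest pixel of the Gaussian-blurred difference image, as (x, y).

    Ties break to the first occurrence in row-major order.  Raises
    :class:`NoFishError` when the difference image is constant.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != background.image.shape:
        raise ValueError("frame and background shapes differ")
    diff = frame - background.image
    blurred = gaussian_filter(diff, sigma=sigma_um / pixel_size_um,
                              truncate=4.0)
    if np.ptp(blurred) == 0:
        raise NoFishError("difference image is constant; no fish detected")
    row, col = np.unravel_index(np.argmin(blurred), blurred.shape)
    return np.array([col, row])


def extract_patch(frame: np.ndarray, center_px, size: int = PATCH_SIZE,
                  background: BackgroundModel | None = None,
                  fill_value: float | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Crop a ``size`` x ``size`` patch around ``center_px`` and rescale 0-255.

    Out-of-frame pixels are filled with the mean background level (or
    ``fill_value``).  A constant patch maps to all zeros.  Returns
    ``(patch, origin)`` where ``origin`` is the (x, y) frame coordinate of
    patch pixel (0, 0).
    """
    frame = np.asarray(frame, dtype=float)
    cx, cy = int(round(center_px[0])), int(round(center_px[1]))
    half = size // 2
    if fill_value is None:
        fill_value = float(background.image.mean()) if background is not None \
            else float(np.median(frame))
    patch = np.full((size, size), fill_value)
    x0, y0 = cx - half, cy - half
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1 = min(x0 + size, frame.shape[1])
    sy1 = min(y0 + size, frame.shape[0])
    if sx1 > sx0 and sy1 > sy0:
        patch[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = frame[sy0:sy1, sx0:sx1]
    lo, hi = patch.min(), patch.max()
    patch = np.zeros_like(patch) if hi == lo \
        else (patch - lo) * (255.0 / (hi - lo))
    return patch, np.array([x0, y0])


def refine_centroid_subpixel(patch: np.ndarray, blur_sigma_px: float = 1.0,
                             threshold_frac: float = 0.2) -> np.ndarray:
    """Subpixel (x, y) of the dark blob in a rescaled patch.

    Blur (sigma 1 px) -> invert -> subtract the median -> zero values below
    ``threshold_frac`` of the peak -> intensity-weighted center of mass.
    """
    patch = np.asarray(patch, dtype=float)
    inv = patch.max() - gaussian_filter(patch, sigma=blur_sigma_px,
                                        truncate=4.0)
    inv = inv - np.median(inv)
    peak = inv.max()
    if peak <= 0:
        raise LowContrastError("no blob mass above the patch median")
    inv[inv < threshold_frac * peak] = 0.0
    mass = inv.sum()
    if mass <= 0:
        raise LowContrastError("blob mass below detection threshold")
    yy, xx = np.mgrid[0:patch.shape[0], 0:patch.shape[1]]
    return np.array([(inv * xx).sum() / mass, (inv * yy).sum() / mass])


def track_stack(stack: np.ndarray, pixel_size_um: float = 83.0,
                n_background_samples: int = 100, sigma_um: float = 250.0,
                patch_size: int = PATCH_SIZE,
                search_window_px: int | None = None) -> np.ndarray:
    """Localize the fish head in every frame of a stack.

    Runs background modeling, coarse detection, patch extraction and subpixel
    refinement per frame and returns (n, 2) positions in mm.

    ``search_window_px`` enables the recurrent acceleration: the coarse
    search is restricted to a window around the previous frame's position and
    falls back to the full frame if no signal is found there.  Results are
    identical to the full search whenever the fish moves less than half the
    window per frame.
    """
    background = compute_background(stack, n_background_samples)
    positions = np.empty((len(stack), 2))
    prev: np.ndarray | None = None
    for i, frame in enumerate(stack):
        frame = np.asarray(frame, dtype=float)
        if search_window_px is not None and prev is not None:
            coarse = _locate_windowed(frame, background, prev,
                                      search_window_px, sigma_um,
                                      pixel_size_um)
        else:
            coarse = locate_fish_coarse(frame, background, sigma_um,
                                        pixel_size_um)
        patch, origin = extract_patch(frame, coarse, patch_size, background)
        com = refine_centroid_subpixel(patch)
        positions[i] = origin + com
        prev = coarse
    return positions * (pixel_size_um / 1000.0)


def _locate_windowed(frame, background, prev, window, sigma_um,
                     pixel_size_um):
    """Coarse search restricted to a window around the previous position."""
    h, w = frame.shape
    x0 = max(int(prev[0]) - window, 0)
    x1 = min(int(prev[0]) + window + 1, w)
    y0 = max(int(prev[1]) - window, 0)
    y1 = min(int(prev[1]) + window + 1, h)
    sub_bg = BackgroundModel(background.image[y0:y1, x0:x1],
                             background.n_samples)
    try:
        pos = locate_fish_coarse(frame[y0:y1, x0:x1], sub_bg, sigma_um,
                                 pixel_size_um)
    except NoFishError:
        return locate_fish_coarse(frame, background, sigma_um, pixel_size_um)
    return pos + np.array([x0, y0])


# ---------------------------------------------------------------------------
# tail angle
# ---------------------------------------------------------------------------

def tail_angle(nostril_mm, trunk_mm, tail_points_mm,
               eval_dist_mm: float = 1.0, arc_length: bool = True) -> float:
    """Signed tail angle (degrees) from a quadratic fit to the tail points.

    A quadratic ``y = a x^2 + b x + c`` is least-squares fitted to the trunk
    point and the six tail points in the body-axis frame (origin at the
    trunk, x along the nostril->trunk axis, y toward the fish's right).  The
    angle is the arctangent of the fitted curve's tangent at ``eval_dist_mm``
    from the tail base, measured relative to the body-nostril axis; by
    default the evaluation position is arc length along the fitted curve
    (``arc_length=False`` uses the x-projection instead).

    Positive angles mean the tail is bent toward the fish's right; the value
    is odd under mirror reflection of the pose and invariant under rigid
    rotation.
    """
    nostril = np.asarray(nostril_mm, dtype=float)
    trunk = np.asarray(trunk_mm, dtype=float)
    tail = np.atleast_2d(np.asarray(tail_points_mm, dtype=float))
    axis = trunk - nostril
    norm = np.hypot(*axis)
    if norm == 0:
        raise ValueError("nostril and trunk coincide; body axis undefined")
    e1 = axis / norm
    e2 = np.array([e1[1], -e1[0]])       # fish's right

    pts = np.vstack([trunk[None, :], tail]) - trunk
    xb = pts @ e1
    yb = pts @ e2
    if np.ptp(xb) < 1e-9:
        raise ValueError("degenerate pose: tail points have no axial spread")
    a, b, c = np.polyfit(xb, yb, 2)

    if arc_length:
        def arclen(x):
            # closed form of int_0^x sqrt(1 + (2 a s + b)^2) ds
            def F(u):
                return 0.5 * (u * np.sqrt(1 + u * u) + np.arcsinh(u))
            if a == 0:
                return x * np.sqrt(1 + b * b)
            return (F(2 * a * x + b) - F(b)) / (2 * a)

        hi = eval_dist_mm
        while arclen(hi) < eval_dist_mm:
            hi *= 2.0
        x_eval = brentq(lambda x: arclen(x) - eval_dist_mm, 0.0, hi)
    else:
        x_eval = eval_dist_mm
    slope = 2.0 * a * x_eval + b
    return float(np.degrees(np.arctan(slope)))


def tail_angle_series(pose: "pd.DataFrame", eval_dist_mm: float = 1.0,
                      arc_length: bool = True) -> np.ndarray:
    """Vector of tail angles recomputed from the pose-table body points."""
    import pandas as pd  # noqa: F401  (type reference only)

    nostril = pose[["nostril_x_mm", "nostril_y_mm"]].to_numpy()
    trunk = pose[["trunk_x_mm", "trunk_y_mm"]].to_numpy()
    tails = np.stack([pose[[f"tail{j}_x_mm", f"tail{j}_y_mm"]].to_numpy()
                      for j in range(1, 7)], axis=1)
    out = np.empty(len(pose))
    for i in range(len(pose)):
        out[i] = tail_angle(nostril[i], trunk[i], tails[i],
                            eval_dist_mm=eval_dist_mm, arc_length=arc_length)
    return out
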