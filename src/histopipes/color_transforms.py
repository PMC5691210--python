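"""Color conditioning stages: dichromacy simulation, stain deconvolution,
grayscale conversion, Gaussian blur and linear contrast enhancement.

The two dichromacy simulations modulate blue/brown contrast in bright-field
histology: the deuteranope (red-green blind) transform dilutes the difference
between hematoxylin blue and DAB brown so the *total* cell population can be
selected as one class, while the tritanope (blue-yellow blind) transform
re-expresses the same pair as a red-axis difference that survives stain
deconvolution of the DAB channel.

Stain deconvolution follows the Beer-Lambert model: each stain absorbs light
with a characteristic unit optical-density vector ``v`` in RGB, a pixel with
stain concentrations ``c_k`` transmits ``I = 255 * 10**(-(sum_k c_k v_k))``,
and concentrations are recovered by inverting the 3x3 stain matrix in OD
space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "StainMatrix",
    "STAIN_PRESETS",
    "simulate_deuteranope",
    "simulate_tritanope",
    "color_deconvolve",
    "to_gray8",
    "gaussian_blur",
    "enhance_contrast",
]


# ---------------------------------------------------------------------------
# stain matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StainMatrix:
    """Three unit optical-density absorption vectors, one row per stain."""

    name: str
    vectors: np.ndarray  # 3x3, rows are stains, columns R,G,B

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(
                f"stain vectors of {self.name!r} must have unit norm, got {norms}"
            )
        if abs(np.linalg.det(v)) < 1e-8:
            raise ValueError(f"stain matrix {self.name!r} is singular")
        object.__setattr__(self, "vectors", v)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.vectors)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _third_vector(a, b) -> np.ndarray:
    return _unit(np.cross(_unit(a), _unit(b)))


_HEMATOXYLIN = _unit([0.650, 0.704, 0.286])
_EOSIN = _unit([0.072, 0.990, 0.105])
_DAB = _unit([0.268, 0.570, 0.776])
_FEULGEN = _unit([0.464, 0.830, 0.308])
_LIGHT_GREEN = _unit([0.147, 0.772, 0.618])

#: Named stain-vector presets (the customary deconvolution constants for
#: "H&E DAB" and "Feulgen light green"; third Feulgen vector is the
#: normalized cross product of the first two).
STAIN_PRESETS: dict[str, StainMatrix] = {
    "h_e_dab": StainMatrix(
        "h_e_dab", np.stack([_HEMATOXYLIN, _EOSIN, _DAB])
    ),
    "feulgen_light_green": StainMatrix(
        "feulgen_light_green",
        np.stack([_FEULGEN, _LIGHT_GREEN, _third_vector(_FEULGEN, _LIGHT_GREEN)]),
    ),
}


def get_stain_matrix(spec) -> StainMatrix:
    """Resolve a preset name, a 3x3 array, or a StainMatrix instance."""
    if isinstance(spec, StainMatrix):
        return spec
    if isinstance(spec, str):
        try:
            return STAIN_PRESETS[spec]
        except KeyError:
            raise KeyError(
                f"unknown stain preset {spec!r}; available: {sorted(STAIN_PRESETS)}"
            ) from None
    return StainMatrix("custom", np.asarray(spec, dtype=float))


# ---------------------------------------------------------------------------
# sRGB <-> linear <-> LMS machinery
# ---------------------------------------------------------------------------

# Hunt-Pointer-Estevez cone fundamentals (D65-normalized) applied to linear
# sRGB, with the monochromatic anchor responses used by the Brettel
# two-half-plane construction.
_RGB2LMS = np.array(
    [
        [0.3904725, 0.54990437, 0.00890159],
        [0.07092586, 0.96310739, 0.00135809],
        [0.02314268, 0.12801221, 0.93605194],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_ANCHOR_485 = np.array([0.1284, 0.2237, 0.3636])
_ANCHOR_660 = np.array([0.0914, 0.007009, 0.0])
_WHITE_LMS = _RGB2LMS @ np.ones(3)

# Vienot single-plane deuteranopia projection expressed directly in linear
# sRGB. Rows 1 and 2 are identical, so the matrix is algebraically idempotent
# and red/green collapse onto a shared luminance while blue is preserved.
_DEUTAN_LIN = np.array(
    [
        [0.29031, 0.70969, 0.0],
        [0.29031, 0.70969, 0.0],
        [-0.02197, 0.02197, 1.0],
    ]
)


def _srgb_to_linear(c8: np.ndarray) -> np.ndarray:
    c = c8.astype(float) / 255.0
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _linear_to_srgb8(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, 0.0, 1.0)
    s = np.where(c <= 0.0031308, c * 12.92, 1.055 * c ** (1 / 2.4) - 0.055)
    return np.clip(np.floor(s * 255.0 + 0.5), 0, 255).astype(np.uint8)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    return image


def simulate_deuteranope(image: np.ndarray) -> np.ndarray:
    """Simulate deuteranope (M-cone deficient) vision of an RGB image.

    Single-plane projection in linear sRGB; neutrals are fixed points and the
    transform is idempotent.
    """
    lin = _srgb_to_linear(_check_rgb(image))
    out = lin @ _DEUTAN_LIN.T
    return _linear_to_srgb8(out)


def _plane_projector(anchor: np.ndarray) -> np.ndarray:
    """Linear-RGB matrix projecting along the S-cone axis onto the plane
    spanned by the white axis and *anchor* (in LMS)."""
    n = np.cross(_WHITE_LMS, anchor)
    p_lms = np.array(
        [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [-n[0] / n[2], -n[1] / n[2], 0.0]]
    )
    return _LMS2RGB @ p_lms @ _RGB2LMS


_P485 = _plane_projector(_ANCHOR_485)
_P660 = _plane_projector(_ANCHOR_660)


def _plane_basis(anchor: np.ndarray) -> np.ndarray:
    """Orthonormal 3x2 basis of the confusion plane in linear RGB."""
    e = np.ones(3) / np.sqrt(3.0)
    a = _LMS2RGB @ anchor
    a = a - (a @ e) * e
    return np.stack([e, a / np.linalg.norm(a)], axis=1)


_U485 = _plane_basis(_ANCHOR_485)
_U660 = _plane_basis(_ANCHOR_660)


def _project_gamut_polygon(U: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Euclidean projection of in-plane points q (N,3) onto plane ∩ [0,1]^3.

    The intersection is a convex polygon in the plane's 2-D coordinates; the
    closest point is found by active-set enumeration (6 edges, 15 vertex
    pairs). Euclidean projection onto a convex set is nonexpansive, which is
    what keeps the 8-bit transform idempotent at the gamut boundary.
    """
    A = np.vstack([U, -U])  # feasible iff A @ z <= b
    b = np.concatenate([np.ones(3), np.zeros(3)])
    z = q @ U  # (N,2) isometric plane coordinates
    n = len(z)
    # candidate 1: projections onto each of the 6 edge lines
    cand = np.zeros((n, 6 + 15, 2))
    ok = np.zeros((n, 6 + 15), dtype=bool)
    for i in range(6):
        ai = A[i]
        zi = z - np.outer((z @ ai - b[i]) / (ai @ ai), ai)
        cand[:, i] = zi
        ok[:, i] = np.all(zi @ A.T <= b + 1e-9, axis=1)
    # candidate 2: the (fixed) feasible vertices of the polygon
    k = 6
    for i in range(6):
        for j in range(i + 1, 6):
            M = np.vstack([A[i], A[j]])
            if abs(np.linalg.det(M)) >= 1e-12:
                zv = np.linalg.solve(M, np.array([b[i], b[j]]))
                if np.all(A @ zv <= b + 1e-9):
                    cand[:, k] = zv
                    ok[:, k] = True
            k += 1
    d2 = np.sum((cand - z[:, None, :]) ** 2, axis=2)
    d2[~ok] = np.inf
    best = cand[np.arange(n), np.argmin(d2, axis=1)]
    return best @ U.T


def simulate_tritanope(image: np.ndarray) -> np.ndarray:
    """Simulate tritanope (S-cone deficient) vision of an RGB image.

    Brettel-style two-half-plane projection with 485 nm / 660 nm anchors; the
    half-plane is chosen by the pixel's L/M ratio relative to white, and
    out-of-gamut projections are resolved by exact projection onto the
    confusion-plane/gamut intersection.
    """
    rgb = _check_rgb(image)
    h, w, _ = rgb.shape
    # work on unique colors: 8-bit images repeat colors heavily
    colors, inverse = np.unique(rgb.reshape(-1, 3), axis=0, return_inverse=True)
    flat = _srgb_to_linear(colors)
    lms = flat @ _RGB2LMS.T
    yellow = lms[:, 0] * _WHITE_LMS[1] - lms[:, 1] * _WHITE_LMS[0] >= 0
    out = np.empty_like(flat)
    for mask, P, U in ((yellow, _P660, _U660), (~yellow, _P485, _U485)):
        if not mask.any():
            continue
        q = flat[mask] @ P.T
        oob = np.any((q < -1e-12) | (q > 1 + 1e-12), axis=1)
        if oob.any():
            q[oob] = _project_gamut_polygon(U, q[oob])
        out[mask] = q
    out8 = _linear_to_srgb8(out)
    return out8[inverse].reshape(h, w, 3)


# ---------------------------------------------------------------------------
# stain deconvolution
# ---------------------------------------------------------------------------

def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Beer-Lambert optical density.

    8-bit input is floored at intensity 1 before the log (the standard guard
    against infinite density); continuous input only guards against exact
    zero, so float synthesis/deconvolution round trips are lossless.
    """
    arr = np.asarray(image)
    floor = 1.0 if np.issubdtype(arr.dtype, np.integer) else 1e-9
    rgb = np.maximum(arr.astype(float), floor)
    return -np.log10(rgb / 255.0)


def od_to_rgb8(od: np.ndarray) -> np.ndarray:
    """Render optical densities back to 8-bit transmitted intensities."""
    return np.clip(np.floor(255.0 * 10.0 ** (-np.asarray(od, float)) + 0.5), 0, 255).astype(np.uint8)


def deconvolve_concentrations(image: np.ndarray, stains) -> np.ndarray:
    """Per-pixel stain concentrations (HxWx3 float, clamped at >= 0)."""
    sm = get_stain_matrix(stains)
    od = rgb_to_od(_check_rgb(image))
    conc = od @ sm.inverse  # od = conc @ vectors  =>  conc = od @ inv
    return np.maximum(conc, 0.0)


def color_deconvolve(image: np.ndarray, stains) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Separate an RGB image into three per-stain 8-bit channels.

    Each channel is rendered back as a transmitted intensity
    ``round(255 * 10**(-c))``, so stain-dense pixels are dark on a light
    background, matching the bright-field convention.
    """
    conc = deconvolve_concentrations(image, stains)
    return tuple(od_to_rgb8(conc[..., k]) for k in range(3))


def synthesize_stains(
    concentrations: np.ndarray, stains, quantize: bool = True
) -> np.ndarray:
    """Forward Beer-Lambert rendering of an HxWx3 concentration field.

    ``quantize=False`` returns continuous float intensities, the exact
    inverse domain of :func:`deconvolve_concentrations`.
    """
    sm = get_stain_matrix(stains)
    od = np.asarray(concentrations, dtype=float) @ sm.vectors
    trans = 255.0 * 10.0 ** (-od)
    if not quantize:
        return trans
    return np.clip(np.floor(trans + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# grayscale, blur, contrast
# ---------------------------------------------------------------------------

def to_gray8(image: np.ndarray) -> np.ndarray:
    """Unweighted-mean RGB -> 8-bit grayscale, rounding half up."""
    rgb = _check_rgb(image).astype(np.float64)
    mean = rgb.sum(axis=2) / 3.0
    return np.clip(np.floor(mean + 0.5), 0, 255).astype(np.uint8)


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """2-D Gaussian smoothing with reflective boundaries; sigma 0 is identity.

    Integer input comes back as rounded 8-bit, float input stays float.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    arr = np.asarray(image)
    if sigma == 0:
        return arr.copy()
    blurred = ndi.gaussian_filter(arr.astype(float), sigma=sigma, mode="reflect")
    if np.issubdtype(arr.dtype, np.integer):
        return np.clip(np.floor(blurred + 0.5), 0, 255).astype(np.uint8)
    return blurred


def enhance_contrast(image: np.ndarray, saturated_fraction: float) -> np.ndarray:
    """Linear stretch clipping ``saturated_fraction`` of pixels symmetrically.

    The saturated_fraction/2 and 1 - saturated_fraction/2 intensity quantiles
    map to 0 and 255; values outside clip. A constant image is returned
    unchanged (no stretch is defined).
    """
    if not 0 <= saturated_fraction < 1:
        raise ValueError(
            f"saturated_fraction must be in [0, 1), got {saturated_fraction}"
        )
    arr = np.asarray(image)
    lo = float(np.quantile(arr, saturated_fraction / 2.0))
    hi = float(np.quantile(arr, 1.0 - saturated_fraction / 2.0))
    if hi <= lo:
        return arr.copy()
    stretched = (arr.astype(float) - lo) * (255.0 / (hi - lo))
    out = np.clip(np.floor(stretched + 0.5), 0, 255)
    if np.issubdtype(arr.dtype, np.integer):
        return out.astype(np.uint8)
    return out
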