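"""Histogram auto-thresholding on 8-bit images.

Ten methods are provided — the union of the method lists the four pipelines
expose (DAB+: Huang, RenyiEntropy/Li, Otsu, Shanbhag, Yen; H&E: Moments,
MaxEntropy, Otsu, Triangle/Intermodes, Yen; colony: Huang, Li/MaxEntropy,
Otsu, Triangle, Yen; PLA: Huang, Intermodes, Otsu, RenyiEntropy). Each method
consumes a 256-bin histogram and returns an integer cut ``t``: the background
class is bins ``0..t`` and the foreground class ``t+1..255``; which class is
*selected* is a downstream polarity choice, not the method's.

All methods are deterministic and break criterion ties toward the lowest
threshold index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSpec",
    "ConstantImageError",
    "histogram",
    "auto_threshold",
    "apply_threshold",
    "threshold_montage",
    "THRESHOLD_METHODS",
]

_EPS = 1e-12
_LEVELS = np.arange(256, dtype=float)


class ConstantImageError(ValueError):
    """Raised when a histogram has fewer than two occupied bins."""


def histogram(image: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of an 8-bit grayscale image."""
    arr = np.asarray(image)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("histogram expects 8-bit values in [0, 255]")
    return np.bincount(arr.astype(np.int64).ravel(), minlength=256)[:256]


def _norm(hist: np.ndarray) -> np.ndarray:
    hist = np.asarray(hist, dtype=float)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    if np.count_nonzero(hist) < 2:
        raise ConstantImageError(
            "constant image: histogram has a single occupied bin"
        )
    return hist / total


def _argbest(values: np.ndarray, candidates: np.ndarray, maximize: bool) -> int:
    vals = values[candidates]
    best = np.nanmax(vals) if maximize else np.nanmin(vals)
    # lowest-index tie break; ties are compared with a tiny tolerance so
    # float-path noise over criterion plateaus (runs of empty bins) cannot
    # shift the winner
    tol = 1e-9 * max(1.0, abs(float(best)))
    return int(candidates[np.nonzero(np.abs(vals - best) <= tol)[0][0]])


def _split_candidates(p: np.ndarray) -> np.ndarray:
    """Thresholds t for which both classes 0..t and t+1..255 are non-empty."""
    w0 = np.cumsum(p)[:-1]
    return np.nonzero((w0 > _EPS) & (w0 < 1 - _EPS))[0]


# ---------------------------------------------------------------------------
# the ten methods (vectorized; the test-suite oracles are loop-based)
# ---------------------------------------------------------------------------

def _otsu(p: np.ndarray) -> int:
    w0 = np.cumsum(p)
    mu = np.cumsum(p * _LEVELS)
    mu_t = mu[-1]
    t = np.arange(255)
    w0t, w1t = w0[t], 1.0 - w0[t]
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = np.where(
            (w0t > _EPS) & (w1t > _EPS),
            (mu_t * w0t - mu[t]) ** 2 / (w0t * w1t),
            -np.inf,
        )
    full = np.full(256, -np.inf)
    full[:255] = crit
    return _argbest(full, _split_candidates(p), maximize=True)


def _huang(p: np.ndarray) -> int:
    nz = np.nonzero(p)[0]
    first, last = nz[0], nz[-1]
    c = float(last - first)
    w0 = np.cumsum(p)
    a0 = np.cumsum(p * _LEVELS)
    crit = np.full(256, np.inf)
    for t in range(first, last):
        w_b, w_f = w0[t], 1.0 - w0[t]
        if w_b <= _EPS or w_f <= _EPS:
            continue
        mu0 = a0[t] / w_b
        mu1 = (a0[-1] - a0[t]) / w_f
        g = _LEVELS
        u = np.where(
            g <= t,
            1.0 / (1.0 + np.abs(g - mu0) / c),
            1.0 / (1.0 + np.abs(g - mu1) / c),
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        s[~np.isfinite(s)] = 0.0
        crit[t] = float(np.sum(p * s))
    return _argbest(crit, _split_candidates(p), maximize=False)


def _li(p: np.ndarray) -> int:
    """Global minimization of Li & Tam's cross entropy."""
    w0 = np.cumsum(p)
    a0 = np.cumsum(p * _LEVELS)
    t = np.arange(255)
    w_b, w_f = w0[t], 1.0 - w0[t]
    a_b, a_f = a0[t], a0[-1] - a0[t]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_b = np.where(w_b > _EPS, a_b / w_b, 0.0)
        mu_f = np.where(w_f > _EPS, a_f / w_f, 0.0)
        term_b = np.where(a_b > _EPS, a_b * np.log(mu_b), 0.0)
        term_f = np.where(a_f > _EPS, a_f * np.log(mu_f), 0.0)
    crit = np.full(256, np.inf)
    crit[:255] = -(term_b + term_f)
    return _argbest(crit, _split_candidates(p), maximize=False)


def _yen(p: np.ndarray) -> int:
    p1 = np.cumsum(p)
    s1 = np.cumsum(p * p)
    s_tot = s1[-1]
    t = np.arange(255)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = -np.log(np.maximum(s1[t], _EPS) * np.maximum(s_tot - s1[t], _EPS)) + 2.0 * np.log(
            np.maximum(p1[t], _EPS) * np.maximum(1.0 - p1[t], _EPS)
        )
    full = np.full(256, -np.inf)
    full[:255] = crit
    return _argbest(full, _split_candidates(p), maximize=True)


def _renyi(p: np.ndarray, alpha: float = 0.5) -> int:
    """Two-class Renyi entropy sum at alpha = 0.5."""
    p1 = np.cumsum(p)
    r1 = np.cumsum(p ** alpha)
    r_tot = r1[-1]
    coef = 1.0 / (1.0 - alpha)
    crit = np.full(256, -np.inf)
    for t in range(255):
        w_b, w_f = p1[t], 1.0 - p1[t]
        if w_b <= _EPS or w_f <= _EPS:
            continue
        h_b = coef * np.log(r1[t] / w_b ** alpha)
        h_f = coef * np.log((r_tot - r1[t]) / w_f ** alpha)
        crit[t] = h_b + h_f
    return _argbest(crit, _split_candidates(p), maximize=True)


def _max_entropy(p: np.ndarray) -> int:
    """Kapur-Sahoo-Wong entropy maximization."""
    p1 = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > _EPS, p * np.log(p), 0.0)
    c1 = np.cumsum(plogp)
    crit = np.full(256, -np.inf)
    for t in range(255):
        w_b, w_f = p1[t], 1.0 - p1[t]
        if w_b <= _EPS or w_f <= _EPS:
            continue
        h_b = np.log(w_b) - c1[t] / w_b
        h_f = np.log(w_f) - (c1[-1] - c1[t]) / w_f
        crit[t] = h_b + h_f
    return _argbest(crit, _split_candidates(p), maximize=True)


def _shanbhag(p: np.ndarray) -> int:
    """Shanbhag's fuzzy information measure: minimize |H_b - H_f|."""
    p1 = np.cumsum(p)
    q = 1.0 - p1  # q[t] = mass strictly above t
    crit = np.full(256, np.inf)
    for t in range(255):
        w_b, w_f = p1[t], q[t]
        if w_b <= _EPS or w_f <= _EPS:
            continue
        term_b = 0.5 / w_b
        g = np.arange(1, t + 1)
        ent_b = 0.0
        if g.size:
            ent_b = -term_b * float(
                np.sum(p[g] * np.log(1.0 - term_b * p1[g - 1]))
            )
        term_f = 0.5 / w_f
        g = np.arange(t + 1, 255)
        ent_f = 0.0
        if g.size:
            ent_f = -term_f * float(
                np.sum(p[g] * np.log(1.0 - term_f * q[g]))
            )
        crit[t] = abs(ent_b - ent_f)
    return _argbest(crit, _split_candidates(p), maximize=False)


def _moments(p: np.ndarray) -> int:
    """Tsai moment-preserving threshold."""
    m1 = float(np.sum(p * _LEVELS))
    m2 = float(np.sum(p * _LEVELS ** 2))
    m3 = float(np.sum(p * _LEVELS ** 3))
    cd = m2 - m1 * m1
    if cd <= _EPS:
        raise ConstantImageError("constant image: zero histogram variance")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    disc = max(disc, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)  # fraction of pixels below threshold
    cum = np.cumsum(p)
    idx = np.nonzero(cum >= p0 - _EPS)[0]
    return int(idx[0]) if idx.size else 254


def _triangle(p: np.ndarray) -> int:
    """Geometric triangle method.

    A line is drawn from the histogram peak to the far end of the longer
    tail; the threshold is the bin between them at maximal perpendicular
    distance below the line.
    """
    nz = np.nonzero(p)[0]
    first, last = int(nz[0]), int(nz[-1])
    peak = int(np.argmax(p))
    right = (last - peak) >= (peak - first)
    end = last if right else first
    if end == peak:
        # degenerate: all mass at the peak side; fall back to midpoint
        return (first + last) // 2
    lo, hi = (peak, end) if right else (end, peak)
    g = np.arange(lo, hi + 1)
    # distance from (g, p[g]) to the segment (peak, p[peak]) -> (end, p[end])
    dx, dy = float(end - peak), float(p[end] - p[peak])
    dist = np.abs(dy * (g - peak) - dx * (p[g] - p[peak]))
    best = int(g[np.argmax(dist)])  # np.argmax: first (lowest) index on ties
    return best


def _intermodes(p: np.ndarray, max_iter: int = 10_000) -> int:
    """Iterated 3-bin mean smoothing until bimodal; t = mean of the two modes."""
    h = np.asarray(p, dtype=float).copy()
    padded_mean = lambda x: (
        np.concatenate([[0.0], x[:-1]]) + x + np.concatenate([x[1:], [0.0]])
    ) / 3.0
    for _ in range(max_iter):
        interior = h[1:-1]
        modes = np.nonzero((interior > h[:-2]) & (interior > h[2:]))[0] + 1
        if h[0] > h[1]:
            modes = np.concatenate([[0], modes])
        if h[-1] > h[-2]:
            modes = np.concatenate([modes, [255]])
        if len(modes) == 2:
            return int((modes[0] + modes[1]) // 2)
        h = padded_mean(h)
    raise ValueError("Intermodes: histogram not bimodal after 10000 smoothing passes")


THRESHOLD_METHODS = {
    "Otsu": _otsu,
    "Huang": _huang,
    "Li": _li,
    "Yen": _yen,
    "RenyiEntropy": _renyi,
    "MaxEntropy": _max_entropy,
    "Shanbhag": _shanbhag,
    "Moments": _moments,
    "Triangle": _triangle,
    "Intermodes": _intermodes,
}


#: procedural methods operating on raw counts (their float tie-breaking is
#: not invariant under histogram normalization)
_RAW_COUNT_METHODS = {"Triangle", "Intermodes"}


def auto_threshold(hist: np.ndarray, method: str) -> int:
    """Compute a threshold from a 256-bin histogram with the named method."""
    if method not in THRESHOLD_METHODS:
        raise KeyError(
            f"unknown threshold method {method!r}; available: {sorted(THRESHOLD_METHODS)}"
        )
    p = _norm(hist)  # validates shape and non-degeneracy
    if method in _RAW_COUNT_METHODS:
        arg = np.asarray(hist, dtype=float)
    else:
        arg = p
    t = THRESHOLD_METHODS[method](arg)
    return int(np.clip(t, 0, 255))


# ---------------------------------------------------------------------------
# applying thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSpec:
    """How a pipeline branch turns a gray image into a binary mask.

    mode 'manual' uses ``value`` directly; mode 'auto' computes ``method`` on
    the image histogram. Polarity 'dark' selects pixels <= t (stained or
    absorbing material on a light background), 'bright' selects pixels > t
    (fluorescence on a dark background).
    """

    mode: str = "auto"
    method: str = "Otsu"
    value: int = 128
    polarity: str = "dark"

    def __post_init__(self) -> None:
        if self.mode not in ("manual", "auto"):
            raise ValueError(f"mode must be 'manual' or 'auto', got {self.mode!r}")
        if self.polarity not in ("dark", "bright"):
            raise ValueError(f"polarity must be 'dark' or 'bright', got {self.polarity!r}")
        if self.mode == "manual" and not 0 <= int(self.value) <= 255:
            raise ValueError(f"manual threshold must be in [0, 255], got {self.value}")
        if self.mode == "auto" and self.method not in THRESHOLD_METHODS:
            raise KeyError(f"unknown threshold method {self.method!r}")

    @classmethod
    def parse(cls, text: str, polarity: str = "dark") -> "ThresholdSpec":
        """Parse 'auto:<Method>' or 'manual:<0-255>' CLI syntax."""
        kind, _, rest = text.partition(":")
        if kind == "auto":
            return cls(mode="auto", method=rest or "Otsu", polarity=polarity)
        if kind == "manual":
            return cls(mode="manual", value=int(rest), polarity=polarity)
        raise ValueError(f"cannot parse threshold spec {text!r}")


def resolve_threshold(image: np.ndarray, spec: ThresholdSpec) -> int:
    if spec.mode == "manual":
        return int(spec.value)
    return auto_threshold(histogram(image), spec.method)


def apply_threshold(image: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """Binarize an 8-bit image; dark polarity selects pixels <= t."""
    arr = np.asarray(image)
    t = resolve_threshold(arr, spec)
    if spec.polarity == "dark":
        return arr <= t
    return arr > t


# ---------------------------------------------------------------------------
# optimization montage
# ---------------------------------------------------------------------------

def threshold_montage(
    images: list[np.ndarray],
    methods: list[str],
    labels: list[str] | None = None,
    polarity: str = "dark",
    pad: int = 4,
):
    """Tile per-method binary masks for visual threshold inspection.

    Returns ``(montage_rgb, rows)`` where rows are ``(image, method, t)``
    records (t is None for constant tiles). One montage row per input image,
    one column per method, each tile labeled with the method name and t.
    """
    from PIL import Image, ImageDraw

    if not 1 <= len(images) <= 5:
        raise ValueError("threshold montage expects 1-5 test images")
    labels = labels or [f"image_{i}" for i in range(len(images))]
    tile_h = max(im.shape[0] for im in images) + 14
    tile_w = max(im.shape[1] for im in images)
    rows = []
    montage = np.full(
        (len(images) * (tile_h + pad) - pad, len(methods) * (tile_w + pad) - pad, 3),
        64,
        dtype=np.uint8,
    )
    for i, (img, name) in enumerate(zip(images, labels)):
        for j, method in enumerate(methods):
            try:
                t = auto_threshold(histogram(img), method)
                mask = apply_threshold(
                    img, ThresholdSpec(mode="manual", value=t, polarity=polarity)
                )
                tile = (mask * 255).astype(np.uint8)
                caption = f"{method} t={t}"
            except (ConstantImageError, ValueError):
                t, tile = None, np.zeros(img.shape, dtype=np.uint8)
                caption = f"{method} constant image"
            rows.append({"image": name, "method": method, "threshold": t})
            canvas = Image.new("RGB", (tile_w, tile_h), (0, 0, 0))
            canvas.paste(Image.fromarray(tile).convert("RGB"), (0, 14))
            ImageDraw.Draw(canvas).text((2, 1), caption, fill=(255, 255, 0))
            y, x = i * (tile_h + pad), j * (tile_w + pad)
            montage[y : y + tile_h, x : x + tile_w] = np.asarray(canvas)
    return montage, rows
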