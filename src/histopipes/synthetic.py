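"""Synthetic image generators with exact ground truth.

Every generator draws from a single seeded pseudo-random stream and returns
both the rendered image(s) and a GroundTruth record consistent with the
rendering, so the full pipeline stack can be validated without any external
data. Bright-field images are exact Beer-Lambert products of the package's
own stain matrices; fluorescence triples are hard-edged ellipse masks plus
Gaussian point spread foci; colony wells are dark colonies under a radial
vignette.

What these fixtures emulate — and what they do not: real tissue has textured
chromatin, stain gradients within cells, overlapping and touching nuclei and
out-of-focus light, none of which are modelled here. Recovery results on
these images therefore validate the algorithmic chain (color separation,
thresholding, morphology, measurement), not staining-robustness on real
cohorts, which the pipelines address through their per-cohort optimization
step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .color_transforms import STAIN_PRESETS, synthesize_stains
from .imgio import ChannelSet

__all__ = ["GroundTruth", "make_ihc", "make_pla", "make_colony", "make_he"]


@dataclass
class GroundTruth:
    """Exact per-image truth emitted alongside each synthetic render."""

    seed: int
    records: list[dict] = field(default_factory=list)
    positive_fraction_count: float | None = None
    positive_fraction_area: float | None = None
    foci_counts: dict[str, int] | None = None
    noise_sigma: float = 0.0
    illumination: dict | None = None
    extras: dict = field(default_factory=dict)


def _ellipse_mask(shape, cy, cx, a, b, theta):
    """Boolean mask of a rotated ellipse (a, b are semi-axes in px)."""
    h, w = shape
    y, x = np.mgrid[:h, :w]
    ct, st = np.cos(theta), np.sin(theta)
    xr = (x - cx) * ct + (y - cy) * st
    yr = -(x - cx) * st + (y - cy) * ct
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _place_centers(rng, n, shape, radii, margin, max_tries_per=200):
    """Dart-throwing placement of non-overlapping circles; may return fewer
    centers than requested when packing is infeasible."""
    h, w = shape
    centers, kept_r = [], []
    for r in radii[:n]:
        for _ in range(max_tries_per):
            cy = rng.uniform(r + margin, h - r - margin)
            cx = rng.uniform(r + margin, w - r - margin)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 >= (r + orr + margin) ** 2
                for (oy, ox), orr in zip(centers, kept_r)
            ):
                centers.append((cy, cx))
                kept_r.append(r)
                break
    return centers, kept_r


# ---------------------------------------------------------------------------
# DAB+ IHC
# ---------------------------------------------------------------------------

def make_ihc(
    n_cells: int = 100,
    positive_fraction: float = 0.3,
    od_range: tuple[float, float] = (0.7, 1.0),
    noise_sigma: float = 5.0,
    gradient_amplitude: float = 20.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
) -> tuple[np.ndarray, GroundTruth]:
    """White-background bright-field field of hematoxylin/DAB stained cells.

    ``positive_fraction`` of the cells additionally carry DAB at a
    concentration drawn from ``od_range``; all cells carry hematoxylin. An
    optional linear illumination ramp (``gradient_amplitude`` intensity
    levels across the width) and Gaussian pixel noise are applied after
    Beer-Lambert rendering.
    """
    if not 0 <= positive_fraction <= 1:
        raise ValueError("positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    axes_a = rng.uniform(8, 13, n_cells)
    axes_b = rng.uniform(6, 9, n_cells)
    thetas = rng.uniform(0, np.pi, n_cells)
    centers, _ = _place_centers(rng, n_cells, shape, axes_a + 2.0, margin=3.0)
    n_placed = len(centers)
    n_pos = int(round(n_placed * positive_fraction))
    pos_idx = set(rng.choice(n_placed, size=n_pos, replace=False).tolist())

    conc = np.zeros((h, w, 3))  # hematoxylin, eosin, DAB concentrations
    cell_mask = np.zeros((h, w), bool)
    dab_mask = np.zeros((h, w), bool)
    records = []
    for i, (cy, cx) in enumerate(centers):
        m = _ellipse_mask(shape, cy, cx, axes_a[i], axes_b[i], thetas[i])
        c_h = rng.uniform(*od_range)
        c_d = rng.uniform(*od_range) if i in pos_idx else 0.0
        conc[m, 0] = c_h
        conc[m, 2] = c_d
        cell_mask |= m
        if c_d > 0:
            dab_mask |= m
        records.append(
            {
                "center": (cx, cy),
                "axes": (float(axes_a[i]), float(axes_b[i])),
                "theta": float(thetas[i]),
                "positive": i in pos_idx,
                "hematoxylin": c_h,
                "dab": c_d,
                "area_px": int(m.sum()),
            }
        )

    img = synthesize_stains(conc, STAIN_PRESETS["h_e_dab"]).astype(float)
    if gradient_amplitude:
        # illumination is multiplicative in transmitted light: the ramp is
        # calibrated so a white-background pixel loses gradient_amplitude
        # levels at the darkest edge
        ramp = 1.0 - (gradient_amplitude / 255.0) * (np.arange(w) / max(w - 1, 1))
        img *= ramp[None, :, None]
    if noise_sigma:
        img += rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        seed=seed,
        records=records,
        positive_fraction_count=(n_pos / n_placed if n_placed else None),
        positive_fraction_area=(
            float(dab_mask.sum()) / float(cell_mask.sum()) if cell_mask.any() else None
        ),
        noise_sigma=noise_sigma,
        illumination={"gradient_amplitude": gradient_amplitude},
        extras={
            "n_placed": n_placed,
            "n_positive": n_pos,
            "cell_area_px": int(cell_mask.sum()),
            "dab_area_px": int(dab_mask.sum()),
        },
    )
    return img, truth


# ---------------------------------------------------------------------------
# PLA fluorescence triples
# ---------------------------------------------------------------------------

def make_pla(
    n_nuclei: int = 10,
    foci_per_nucleus: int = 4,
    foci_per_cytoplasm: int = 2,
    psf_sigma: float = 2.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (448, 448),
    base_name: str = "synthetic_pla_",
) -> tuple[ChannelSet, GroundTruth]:
    """Dark-background fluorescence triple: nuclei, cytoplasm, foci.

    Nuclei are bright ellipses, each inside a larger dim cytoplasm ellipse;
    foci are Gaussian spots of amplitude 200 on jittered rings in ellipse
    coordinates — well inside the nucleus (nuclear foci, ring factor 0.55)
    or inside the cytoplasm clear of the nucleus (cytoplasmic foci, ring
    factor 1.4 of the nuclear axes, cytoplasm extends to 1.8) — so every
    requested focus is placed with spacing that keeps maxima-based counting
    exact on noise-free renders.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    axes_a = rng.uniform(16, 20, n_nuclei)
    axes_b = rng.uniform(12, 15, n_nuclei)
    thetas = rng.uniform(0, np.pi, n_nuclei)
    cyto_scale = 1.8
    centers, _ = _place_centers(
        rng, n_nuclei, shape, axes_a * cyto_scale + 2.0, margin=4.0
    )

    nuclei_img = np.full(shape, 8.0)
    cyto_img = np.full(shape, 8.0)
    foci_img = np.full(shape, 5.0)
    y, x = np.mgrid[:h, :w]
    records = []
    foci_points: list[tuple[float, float, str]] = []

    def ring_points(cy, cx, a, b, theta, factor, count):
        """Evenly spaced points on an ellipse-coordinate ring, random phase."""
        if count <= 0:
            return []
        phase = rng.uniform(0, 2 * np.pi)
        pts = []
        ct, st = np.cos(theta), np.sin(theta)
        for k in range(count):
            ang = phase + 2 * np.pi * k / count
            ex, ey = factor * a * np.cos(ang), factor * b * np.sin(ang)
            pts.append((cy + ex * st + ey * ct, cx + ex * ct - ey * st))
        return pts

    for i, (cy, cx) in enumerate(centers):
        nuc = _ellipse_mask(shape, cy, cx, axes_a[i], axes_b[i], thetas[i])
        cyt = _ellipse_mask(
            shape, cy, cx, axes_a[i] * cyto_scale, axes_b[i] * cyto_scale, thetas[i]
        )
        nuclei_img[nuc] = 180.0
        cyto_img[cyt] = 90.0
        if foci_per_nucleus == 1:
            nuclear_pts = [(cy, cx)]
        else:
            nuclear_pts = ring_points(
                cy, cx, axes_a[i], axes_b[i], thetas[i], 0.55, foci_per_nucleus
            )
        cyto_pts = ring_points(
            cy, cx, axes_a[i], axes_b[i], thetas[i], 1.4, foci_per_cytoplasm
        )
        foci_points.extend((px, py, "nuclear") for py, px in nuclear_pts)
        foci_points.extend((px, py, "cytoplasmic") for py, px in cyto_pts)
        records.append(
            {
                "center": (cx, cy),
                "axes": (float(axes_a[i]), float(axes_b[i])),
                "theta": float(thetas[i]),
            }
        )

    for px, py, _ in foci_points:
        foci_img += 200.0 * np.exp(
            -((y - py) ** 2 + (x - px) ** 2) / (2.0 * psf_sigma**2)
        )
    if noise_sigma:
        nuclei_img += rng.normal(0, noise_sigma, shape)
        cyto_img += rng.normal(0, noise_sigma, shape)
        foci_img += rng.normal(0, noise_sigma, shape)

    to8 = lambda a: np.clip(np.floor(a + 0.5), 0, 255).astype(np.uint8)
    channels = ChannelSet(
        base_name=base_name,
        foci=to8(foci_img),
        nuclei=to8(nuclei_img),
        cytoplasm=to8(cyto_img),
    )
    n_nuc = sum(1 for *_, kind in foci_points if kind == "nuclear")
    n_cyt = sum(1 for *_, kind in foci_points if kind == "cytoplasmic")
    truth = GroundTruth(
        seed=seed,
        records=records,
        foci_counts={"nuclear": n_nuc, "cytoplasmic": n_cyt, "total": n_nuc + n_cyt},
        noise_sigma=noise_sigma,
        extras={
            "n_nuclei": len(centers),
            "foci": [(px, py, kind) for px, py, kind in foci_points],
            "psf_sigma": psf_sigma,
        },
    )
    return channels, truth


# ---------------------------------------------------------------------------
# 3D colony wells
# ---------------------------------------------------------------------------

def _star_polygon(cy, cx, r_outer, r_inner, n_points, phase):
    ang = phase + np.arange(2 * n_points) * np.pi / n_points
    radii = np.where(np.arange(2 * n_points) % 2 == 0, r_outer, r_inner)
    return np.stack([cy + radii * np.sin(ang), cx + radii * np.cos(ang)], axis=1)


def _polygon_mask(shape, verts):
    from skimage.draw import polygon

    rr, cc = polygon(verts[:, 0], verts[:, 1], shape)
    m = np.zeros(shape, bool)
    m[rr, cc] = True
    return m


def _polygon_circularity(verts):
    y, x = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    per = np.sum(np.linalg.norm(np.diff(np.vstack([verts, verts[:1]]), axis=0), axis=1))
    return 4.0 * np.pi * area / (per * per)


def make_colony(
    n_round: int = 8,
    n_invasive: int = 4,
    vignette_amplitude: float = 60.0,
    seed: int = 0,
    shape: tuple[int, int] = (384, 384),
    background: float = 235.0,
    depth: float = 60.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Bright-field colony well: dark colonies under a radial vignette.

    Round colonies are discs (true circularity 1); invasive colonies are
    7-point star polygons with analytically lower circularity. The vignette
    subtracts up to ``vignette_amplitude`` levels toward the corners, chosen
    so that at amplitude ~60 the corner background overlaps the colony
    intensity range and a global threshold cannot be correct everywhere —
    the regime where shading correction becomes necessary.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    n = n_round + n_invasive
    radii = rng.uniform(9, 15, n)
    centers, kept_r = _place_centers(rng, n, shape, radii + 4.0, margin=10.0)
    img = np.full(shape, background)
    records = []
    for i, (cy, cx) in enumerate(centers):
        invasive = i >= n_round
        if invasive:
            verts = _star_polygon(cy, cx, kept_r[i], 0.42 * kept_r[i], 7, rng.uniform(0, np.pi))
            m = _polygon_mask(shape, verts)
            circ = _polygon_circularity(verts)
        else:
            yy, xx = np.mgrid[:h, :w]
            m = (yy - cy) ** 2 + (xx - cx) ** 2 <= kept_r[i] ** 2
            circ = 1.0
        img[m] = background - depth
        records.append(
            {
                "center": (cx, cy),
                "radius": float(kept_r[i]),
                "shape_class": "invasive" if invasive else "round",
                "true_circularity": float(circ),
                "area_px": int(m.sum()),
            }
        )
    if vignette_amplitude:
        yy, xx = np.mgrid[:h, :w]
        r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
        img -= vignette_amplitude * (r2 / 2.0)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        seed=seed,
        records=records,
        illumination={"vignette_amplitude": vignette_amplitude},
        extras={"n_round": sum(1 for r in records if r["shape_class"] == "round"),
                "n_invasive": sum(1 for r in records if r["shape_class"] == "invasive")},
    )
    return img, truth


# ---------------------------------------------------------------------------
# H&E low-power fields
# ---------------------------------------------------------------------------

def make_he(
    tissue_fraction: float = 0.4,
    dense_fraction_of_tissue: float = 0.25,
    seed: int = 0,
    shape: tuple[int, int] = (384, 384),
) -> tuple[np.ndarray, GroundTruth]:
    """Eosin-pink tissue blob on white with hematoxylin-dense nests inside.

    Pixel-exact truth by construction: the tissue mask is the top
    ``tissue_fraction`` quantile of a smoothed random field (one connected
    blob-like region), and dense nests are exactly
    ``round(dense_fraction_of_tissue * tissue_px)`` pixels chosen by a
    second, finer field inside the tissue.
    """
    if not (0 <= tissue_fraction <= 1 and 0 <= dense_fraction_of_tissue <= 1):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    n_tissue = int(round(tissue_fraction * h * w))
    conc = np.zeros((h, w, 3))
    tissue = np.zeros(shape, bool)
    dense = np.zeros(shape, bool)
    if n_tissue > 0:
        yy, xx = np.mgrid[:h, :w]
        bump = -(((yy - h / 2) / h) ** 2 + ((xx - w / 2) / w) ** 2)
        field = ndi.gaussian_filter(rng.normal(0, 1, shape), 40) + 1.2 * bump
        cutoff = np.partition(field.ravel(), -n_tissue)[-n_tissue]
        tissue = field >= cutoff
        # guard against quantile ties producing a few extra pixels
        if tissue.sum() != n_tissue:
            idx = np.argsort(field.ravel())[::-1][:n_tissue]
            tissue = np.zeros(h * w, bool)
            tissue[idx] = True
            tissue = tissue.reshape(shape)
        n_dense = int(round(dense_fraction_of_tissue * n_tissue))
        if n_dense > 0:
            nest_field = ndi.gaussian_filter(rng.normal(0, 1, shape), 9)
            vals = np.where(tissue, nest_field, -np.inf).ravel()
            idx = np.argsort(vals)[::-1][:n_dense]
            dense = np.zeros(h * w, bool)
            dense[idx] = True
            dense = dense.reshape(shape)
        conc[tissue, 0] = 0.25   # light hematoxylin wash over all tissue
        conc[tissue, 1] = 0.55   # eosin
        conc[dense, 0] = 1.1     # hematoxylin-dense nests
    img = synthesize_stains(conc, STAIN_PRESETS["h_e_dab"])
    truth = GroundTruth(
        seed=seed,
        extras={
            "tissue_px": int(tissue.sum()),
            "dense_px": int(dense.sum()),
            "tissue_fraction": float(tissue.sum()) / (h * w),
            "dense_fraction_of_tissue": (
                float(dense.sum()) / float(tissue.sum()) if tissue.any() else 0.0
            ),
        },
    )
    return img, truth
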