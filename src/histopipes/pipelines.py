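"""The four end-to-end pipelines (DAB+ IHC basic/enhanced, PLA, H&E, 3D
colony), the threshold-optimization mode, and the batch runner.

A batch run is frozen to one PipelineParams: parameters are optimized once
on 3-5 test images, written to a config file, and then applied unchanged to
every image in the cohort — per-image adaptation is deliberately impossible,
which is the unbiasedness contract of batch analysis.

Bright-field branches condition the RGB input (optional dichromacy filter,
stain deconvolution, Gaussian blur, 8-bit), threshold it (select-dark: stain
renders dark on a light background), clean the mask (fill holes, watershed,
edge exclusion, size filter — in that fixed order, each switchable) and run
particle analysis. Fluorescence branches threshold select-bright, and foci
come from prominence-based maxima detection instead of thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binary_morphology as morph
from .autothreshold import (
    ConstantImageError,
    ThresholdSpec,
    apply_threshold,
    resolve_threshold,
    threshold_montage,
)
from .color_transforms import (
    color_deconvolve,
    enhance_contrast,
    gaussian_blur,
    simulate_deuteranope,
    simulate_tritanope,
    to_gray8,
)
from .illumination import ShadingParams
from .imgio import (
    ChannelSet,
    group_channels,
    list_images,
    read_image,
    render_overlay,
    write_image,
    write_summary,
)
from .particle_analysis import (
    ParticleSummary,
    analyze_particles,
    assign_foci,
    find_maxima,
    percent_positive,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BranchParams",
    "PipelineParams",
    "BatchResult",
    "PIPELINE_METHOD_SETS",
    "run_dab",
    "run_pla",
    "run_he",
    "run_colony",
    "optimize",
    "run_batch",
]

#: Auto-threshold methods each pipeline exposes (per-branch where they differ).
PIPELINE_METHOD_SETS = {
    "dab": ["Huang", "RenyiEntropy", "Li", "Otsu", "Shanbhag", "Yen"],
    "pla": ["Huang", "Intermodes", "Otsu", "RenyiEntropy"],
    "he": ["Moments", "MaxEntropy", "Otsu", "Triangle", "Yen"],
    "he_dense": ["Moments", "MaxEntropy", "Otsu", "Triangle", "Intermodes", "Yen"],
    "colony": ["Huang", "Li", "MaxEntropy", "Otsu", "Triangle", "Yen"],
}

_OVERLAY_COLORS = {
    "total": (255, 0, 0),
    "dab": (0, 255, 0),
    "tissue": (255, 0, 0),
    "dense": (0, 255, 0),
    "colony": (255, 0, 0),
    "nuclei": (255, 0, 0),
    "cytoplasm": (0, 0, 255),
    "foci": (0, 255, 0),
}


@dataclass
class BranchParams:
    """Per-branch conditioning and mask-cleanup settings."""

    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    blur_sigma: float = 2.0
    fill_holes: bool = True
    watershed: bool = False
    exclude_edges: bool = False
    min_size: float = 0.0
    max_size: float = float("inf")
    # robust intensity range (0.5th..99.5th percentile) below which the
    # branch is considered featureless and selects nothing: auto methods
    # must always cut somewhere, and on an empty field that cut would
    # otherwise select noise
    min_contrast: float = 8.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["threshold"] = asdict(self.threshold)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BranchParams":
        d = dict(d)
        thr = d.pop("threshold", {})
        max_size = d.pop("max_size", float("inf"))
        if max_size is None:
            max_size = float("inf")
        return cls(threshold=ThresholdSpec(**thr), max_size=float(max_size), **d)


@dataclass
class PipelineParams:
    """The complete frozen parameter set of one batch run."""

    pipeline: str
    variant: str = "enhanced"            # dab only: basic | enhanced
    branches: dict[str, BranchParams] = field(default_factory=dict)
    scale: float = 1.0                   # physical units per pixel
    unit: str = "pixel"
    noise_tolerance: float = 50.0        # PLA find-maxima prominence
    enhance_fraction: float = 0.0035     # PLA enhance-contrast saturation
    suffix_map: dict = field(
        default_factory=lambda: {"foci": "Ch00", "nuclei": "Ch01", "cytoplasm": "Ch02"}
    )
    shading: ShadingParams = field(default_factory=ShadingParams)
    total_stain: str = "feulgen_light_green"
    total_channel: int = 0
    dab_stain: str = "h_e_dab"
    dab_channel: int = 2
    dense_channel: int = 0               # hematoxylin channel of h_e_dab

    def __post_init__(self) -> None:
        if self.pipeline not in ("dab", "pla", "he", "colony"):
            raise ValueError(f"unknown pipeline {self.pipeline!r}")
        if self.variant not in ("basic", "enhanced"):
            raise ValueError(f"variant must be basic|enhanced, got {self.variant!r}")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    # -- defaults ----------------------------------------------------------
    @classmethod
    def defaults(cls, pipeline: str, variant: str = "enhanced") -> "PipelineParams":
        dark = lambda m: ThresholdSpec(mode="auto", method=m, polarity="dark")
        bright = lambda m: ThresholdSpec(mode="auto", method=m, polarity="bright")
        if pipeline == "dab":
            if variant == "enhanced":
                # after the tritanope filter the DAB channel carries three
                # classes (background / hematoxylin / DAB+); the frozen
                # manual cut from the optimization montage separates the two
                # stain classes, which no global auto method resolves
                dab_branch = BranchParams(
                    threshold=ThresholdSpec(mode="manual", value=40, polarity="dark"),
                    blur_sigma=0.0,
                    min_size=40.0,
                )
            else:
                dab_branch = BranchParams(threshold=dark("Otsu"), min_size=40.0)
            return cls(
                pipeline="dab",
                variant=variant,
                branches={
                    "total": BranchParams(threshold=dark("Otsu"), min_size=40.0),
                    "dab": dab_branch,
                },
            )
        if pipeline == "pla":
            return cls(
                pipeline="pla",
                branches={
                    "nuclei": BranchParams(
                        threshold=bright("Otsu"), blur_sigma=1.0,
                        fill_holes=True, watershed=True, min_size=120.0,
                    ),
                    "cytoplasm": BranchParams(
                        threshold=bright("Otsu"), blur_sigma=1.0,
                        fill_holes=True, min_size=120.0,
                    ),
                },
            )
        if pipeline == "he":
            return cls(
                pipeline="he",
                branches={
                    "tissue": BranchParams(threshold=dark("Otsu"), blur_sigma=2.0,
                                           min_size=200.0),
                    "dense": BranchParams(threshold=dark("Otsu"), blur_sigma=2.0,
                                          min_size=50.0),
                },
            )
        if pipeline == "colony":
            return cls(
                pipeline="colony",
                branches={
                    "colony": BranchParams(threshold=dark("Otsu"), blur_sigma=1.0,
                                           fill_holes=True, min_size=30.0),
                },
                shading=ShadingParams(method="subtract_background", radius=40.0,
                                      light_background=True),
            )
        raise ValueError(f"unknown pipeline {pipeline!r}")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "pipeline": self.pipeline,
            "variant": self.variant,
            "scale": self.scale,
            "unit": self.unit,
            "noise_tolerance": self.noise_tolerance,
            "enhance_fraction": self.enhance_fraction,
            "suffix_map": dict(self.suffix_map),
            "shading": asdict(self.shading),
            "total_stain": self.total_stain,
            "total_channel": self.total_channel,
            "dab_stain": self.dab_stain,
            "dab_channel": self.dab_channel,
            "dense_channel": self.dense_channel,
            "branches": {k: b.to_dict() for k, b in self.branches.items()},
        }
        # YAML-friendly infinity
        for b in d["branches"].values():
            if b["max_size"] == float("inf"):
                b["max_size"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        d = dict(d)
        branches = {
            k: BranchParams.from_dict(v) for k, v in d.pop("branches", {}).items()
        }
        shading = ShadingParams(**d.pop("shading", {}))
        return cls(branches=branches, shading=shading, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class BatchResult:
    table: pd.DataFrame
    overlay_paths: list[Path]
    log: list[str]
    n_failed: int

    @property
    def ok(self) -> bool:
        return self.n_failed == 0


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _binary_chain(gray8: np.ndarray, branch: BranchParams, scale: float):
    """Threshold + the fixed-order cleanup chain; returns (mask, t).

    A constant image (blank slide / empty channel) has no threshold; it
    yields an empty selection rather than an error.
    """
    arr = np.asarray(gray8)
    if branch.threshold.mode == "auto" and branch.min_contrast > 0:
        lo, hi = np.percentile(arr, [0.5, 99.5])
        if hi - lo < branch.min_contrast:
            return np.zeros(arr.shape, dtype=bool), None
    try:
        t = resolve_threshold(gray8, branch.threshold)
    except ConstantImageError:
        return np.zeros(np.asarray(gray8).shape, dtype=bool), None
    mask = apply_threshold(
        gray8,
        ThresholdSpec(mode="manual", value=t, polarity=branch.threshold.polarity),
    )
    if branch.fill_holes:
        mask = morph.fill_holes(mask)
    if branch.watershed:
        mask = morph.watershed_split(mask)
    if branch.exclude_edges:
        mask = morph.exclude_edges(mask)
    if branch.min_size > 0 or np.isfinite(branch.max_size):
        mask = morph.size_filter(mask, branch.min_size, branch.max_size, scale)
    return mask, t


def _condition_dab_branch(
    image: np.ndarray, params: PipelineParams, which: str
) -> np.ndarray:
    """RGB -> conditioned 8-bit gray for the total or DAB selection branch."""
    if which == "total":
        rgb = simulate_deuteranope(image) if params.variant == "enhanced" else image
        chan = color_deconvolve(rgb, params.total_stain)[params.total_channel]
    else:
        rgb = simulate_tritanope(image) if params.variant == "enhanced" else image
        chan = color_deconvolve(rgb, params.dab_stain)[params.dab_channel]
    sigma = params.branches[which].blur_sigma
    return gaussian_blur(chan, sigma)


def _summary_columns(prefix: str, s: ParticleSummary) -> dict:
    return {
        f"{prefix}_count": s.count,
        f"{prefix}_total_area": s.total_area,
        f"{prefix}_average_size": s.average_size,
        f"{prefix}_percent_area": s.percent_area,
        f"{prefix}_mean_intensity": s.mean_intensity,
    }


# ---------------------------------------------------------------------------
# the four pipelines
# ---------------------------------------------------------------------------

def run_dab(image: np.ndarray, params: PipelineParams):
    """DAB+ IHC: parallel total-cell and DAB+ selections plus their ratio.

    Returns ``(row, overlays, particles)`` where overlays maps layer name to
    an RGB image (total contours red, DAB+ green in the combined overlay).
    """
    if params.pipeline != "dab":
        raise ValueError("params.pipeline must be 'dab'")
    results, masks, thresholds = {}, {}, {}
    for which in ("total", "dab"):
        gray = _condition_dab_branch(image, params, which)
        mask, t = _binary_chain(gray, params.branches[which], params.scale)
        records, summary = analyze_particles(mask, intensity=gray, scale=params.scale)
        results[which] = (records, summary)
        masks[which] = mask
        thresholds[which] = t
    ratio = percent_positive(results["total"][1], results["dab"][1])
    row = {
        "pipeline": "dab",
        "variant": params.variant,
        **_summary_columns("total", results["total"][1]),
        **_summary_columns("dab", results["dab"][1]),
        **ratio,
        "total_threshold": thresholds["total"],
        "dab_threshold": thresholds["dab"],
    }
    overlay = render_overlay(
        image,
        [(masks["total"], _OVERLAY_COLORS["total"]), (masks["dab"], _OVERLAY_COLORS["dab"])],
    )
    particles = {k: v[0] for k, v in results.items()}
    return row, {"selection": overlay}, particles


def run_pla(channels: ChannelSet, params: PipelineParams):
    """PLA: nuclei/cytoplasm masks plus maxima-detected foci per compartment."""
    if params.pipeline != "pla":
        raise ValueError("params.pipeline must be 'pla'")
    if channels.nuclei is None:
        raise ValueError(f"channel set {channels.base_name!r} has no nuclei channel")

    def fluor_mask(chan: np.ndarray, branch: BranchParams):
        g = enhance_contrast(chan, params.enhance_fraction)
        g = gaussian_blur(g, branch.blur_sigma)
        return _binary_chain(g, branch, params.scale)

    nuc_mask, t_n = fluor_mask(channels.nuclei, params.branches["nuclei"])
    cyto_mask = None
    if channels.cytoplasm is not None:
        cyto_mask, _ = fluor_mask(channels.cytoplasm, params.branches["cytoplasm"])
    foci = find_maxima(channels.foci, params.noise_tolerance)
    counts = assign_foci(foci, nuc_mask, cyto_mask)
    _, nuc_summary = analyze_particles(nuc_mask, intensity=channels.nuclei,
                                       scale=params.scale)
    row = {
        "pipeline": "pla",
        "nuclei_count": nuc_summary.count,
        "foci_nuclear": counts["nuclear"],
        "foci_cytoplasmic": counts["cytoplasmic"],
        "foci_total": counts["total"],
        "foci_unassigned": counts["unassigned"],
        "foci_per_nucleus": (
            counts["total"] / nuc_summary.count if nuc_summary.count else None
        ),
        "nuclei_threshold": t_n,
        "noise_tolerance": params.noise_tolerance,
    }
    overlays = {
        "nuclei": render_overlay(channels.nuclei, [(nuc_mask, _OVERLAY_COLORS["nuclei"])]),
        "foci": render_overlay(channels.foci, [(foci.points, _OVERLAY_COLORS["foci"])]),
    }
    if cyto_mask is not None:
        overlays["cytoplasm"] = render_overlay(
            channels.cytoplasm, [(cyto_mask, _OVERLAY_COLORS["cytoplasm"])]
        )
    return row, overlays, {"foci": foci, "nuclei_mask": nuc_mask, "cytoplasm_mask": cyto_mask}


def run_he(image: np.ndarray, params: PipelineParams):
    """H&E: whole-tissue selection vs hematoxylin-dense nests within it."""
    if params.pipeline != "he":
        raise ValueError("params.pipeline must be 'he'")
    # total tissue: deuteranope + Feulgen-light-green channel, as in the
    # enhanced DAB total branch
    tis_gray = gaussian_blur(
        color_deconvolve(simulate_deuteranope(image), params.total_stain)[params.total_channel],
        params.branches["tissue"].blur_sigma,
    )
    tis_mask, t_t = _binary_chain(tis_gray, params.branches["tissue"], params.scale)
    # dense nests: tritanope + hematoxylin channel of H&E-DAB
    dense_gray = gaussian_blur(
        color_deconvolve(simulate_tritanope(image), params.dab_stain)[params.dense_channel],
        params.branches["dense"].blur_sigma,
    )
    dense_mask, t_d = _binary_chain(dense_gray, params.branches["dense"], params.scale)
    dense_mask &= tis_mask  # dense regions are tissue by definition
    _, tis_summary = analyze_particles(tis_mask, intensity=tis_gray, scale=params.scale)
    _, dense_summary = analyze_particles(dense_mask, intensity=dense_gray, scale=params.scale)
    dense_of_tissue = (
        100.0 * dense_summary.total_area / tis_summary.total_area
        if tis_summary.total_area > 0 else None
    )
    row = {
        "pipeline": "he",
        **_summary_columns("tissue", tis_summary),
        **_summary_columns("dense", dense_summary),
        "dense_percent_of_tissue": dense_of_tissue,
        "tissue_threshold": t_t,
        "dense_threshold": t_d,
    }
    overlay = render_overlay(
        image,
        [(tis_mask, _OVERLAY_COLORS["tissue"]), (dense_mask, _OVERLAY_COLORS["dense"])],
    )
    return row, {"selection": overlay}, {"tissue_mask": tis_mask, "dense_mask": dense_mask}


def run_colony(image: np.ndarray, params: PipelineParams):
    """3D colony wells: count, mean size, mean circularity after shading
    correction."""
    if params.pipeline != "colony":
        raise ValueError("params.pipeline must be 'colony'")
    gray = to_gray8(image) if image.ndim == 3 else np.asarray(image)
    corrected = params.shading.apply(gray)
    branch = params.branches["colony"]
    conditioned = gaussian_blur(corrected, branch.blur_sigma)
    mask, t = _binary_chain(conditioned, branch, params.scale)
    records, summary = analyze_particles(mask, intensity=conditioned, scale=params.scale)
    mean_circ = float(np.mean([r.circularity for r in records])) if records else None
    row = {
        "pipeline": "colony",
        **_summary_columns("colony", summary),
        "mean_circularity": mean_circ,
        "colony_threshold": t,
        "shading_method": params.shading.method,
    }
    overlay = render_overlay(gray, [(mask, _OVERLAY_COLORS["colony"])])
    return row, {"selection": overlay}, {"records": records, "mask": mask}


_RUNNERS = {"dab": run_dab, "pla": run_pla, "he": run_he, "colony": run_colony}


# ---------------------------------------------------------------------------
# optimization mode
# ---------------------------------------------------------------------------

def _conditioned_branches(image, params: PipelineParams) -> dict[str, np.ndarray]:
    """The per-branch conditioned gray images that thresholding would see."""
    p = params
    if p.pipeline == "dab":
        return {w: _condition_dab_branch(image, p, w) for w in ("total", "dab")}
    if p.pipeline == "he":
        return {
            "tissue": gaussian_blur(
                color_deconvolve(simulate_deuteranope(image), p.total_stain)[p.total_channel],
                p.branches["tissue"].blur_sigma,
            ),
            "dense": gaussian_blur(
                color_deconvolve(simulate_tritanope(image), p.dab_stain)[p.dense_channel],
                p.branches["dense"].blur_sigma,
            ),
        }
    if p.pipeline == "colony":
        gray = to_gray8(image) if image.ndim == 3 else image
        return {"colony": gaussian_blur(p.shading.apply(gray), p.branches["colony"].blur_sigma)}
    raise ValueError("optimize mode supports dab, he and colony image folders")


def optimize(
    image_paths: list,
    params: PipelineParams,
    out_dir,
) -> dict:
    """Threshold-inspection montages plus a ready-to-edit config file.

    For each branch of the pipeline, every registered method is applied to
    the conditioned test images and tiled into a labeled montage; the trial
    parameters are echoed to ``config.yaml`` so a batch run can re-ingest
    them unchanged.
    """
    if not image_paths:
        raise ValueError("optimize mode needs 1-5 test images")
    if len(image_paths) > 5:
        logger.warning("optimize mode uses at most 5 test images; using the first 5")
        image_paths = image_paths[:5]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = [read_image(p) for p in image_paths]
    labels = [Path(p).stem for p in image_paths]
    written: dict[str, list] = {"montages": [], "tables": []}
    branch_names = list(params.branches)
    for branch in branch_names:
        conditioned = [_conditioned_branches(im, params)[branch] for im in images]
        methods = PIPELINE_METHOD_SETS[
            "he_dense" if (params.pipeline, branch) == ("he", "dense") else params.pipeline
        ]
        polarity = params.branches[branch].threshold.polarity
        montage, rows = threshold_montage(conditioned, methods, labels, polarity)
        mpath = out_dir / f"montage_{branch}.png"
        write_image(mpath, montage)
        tpath = out_dir / f"thresholds_{branch}.csv"
        write_summary(pd.DataFrame(rows), tpath)
        written["montages"].append(mpath)
        written["tables"].append(tpath)
    cfg = out_dir / "config.yaml"
    params.to_yaml(cfg)
    written["config"] = cfg
    return written


# ---------------------------------------------------------------------------
# batch runner
# ---------------------------------------------------------------------------

def run_batch(
    directory,
    params: PipelineParams,
    out_dir=None,
    write_overlays: bool = True,
) -> BatchResult:
    """Process every image (or channel set) in a folder with frozen params.

    Per-image failures are logged and skipped, never fatal; the summary CSV
    and the run log land in ``out_dir`` (default: the input folder), and
    overlays beside their inputs. Two runs on identical input produce
    byte-identical summaries.
    """
    directory = Path(directory)
    out_dir = Path(out_dir) if out_dir is not None else directory
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"pipeline={params.pipeline}", "params:"]
    log.extend(
        f"  {line}" for line in yaml.safe_dump(params.to_dict(), sort_keys=True).splitlines()
    )
    rows, overlay_paths = [], []
    n_failed = 0

    if params.pipeline == "pla":
        units = group_channels(directory, params.suffix_map)
        if not units:
            raise FileNotFoundError(f"no complete channel sets in {directory}")
        def iterate():
            for cs in units:
                yield cs.base_name, cs
    else:
        paths = list_images(directory)
        if not paths:
            raise FileNotFoundError(f"no readable images in {directory}")
        def iterate():
            for p in paths:
                yield p.name, p

    runner = _RUNNERS[params.pipeline]
    for name, item in iterate():
        try:
            if params.pipeline == "pla":
                row, overlays, _ = runner(item, params)
                stem = item.base_name.rstrip("_") or "set"
            else:
                image = read_image(item)
                row, overlays, _ = runner(image, params)
                stem = Path(item).stem
            row = {"image": name, **row}
            rows.append(row)
            if write_overlays:
                for layer, overlay in overlays.items():
                    opath = out_dir / f"{stem}_overlay_{layer}.png"
                    write_image(opath, overlay)
                    overlay_paths.append(opath)
            log.append(f"ok: {name}")
        except (ConstantImageError, OSError, ValueError) as exc:
            n_failed += 1
            log.append(f"skip: {name}: {exc}")
            logger.warning("skipping %s: %s", name, exc)
    if not rows:
        raise RuntimeError(f"no image in {directory} could be processed")
    table = pd.DataFrame(rows)
    write_summary(table, out_dir / "summary.csv")
    log.append(f"processed={len(rows)} failed={n_failed}")
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return BatchResult(table=table, overlay_paths=overlay_paths, log=log, n_failed=n_failed)
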