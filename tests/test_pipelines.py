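"""End-to-end pipelines, optimize mode, batch runner."""

import numpy as np
import pytest

from histopipes.autothreshold import ThresholdSpec
from histopipes.illumination import ShadingParams
from histopipes.imgio import write_image
from histopipes.pipelines import (
    PipelineParams,
    optimize,
    run_batch,
    run_colony,
    run_dab,
    run_he,
    run_pla,
)
from histopipes.synthetic import make_colony, make_he, make_ihc, make_pla


class TestParams:
    def test_yaml_roundtrip(self, tmp_path):
        p = PipelineParams.defaults("dab")
        p.branches["dab"].max_size = float("inf")
        path = tmp_path / "config.yaml"
        p.to_yaml(path)
        q = PipelineParams.from_yaml(path)
        assert q.to_dict() == p.to_dict()
        assert q.branches["dab"].max_size == float("inf")

    def test_invalid_pipeline_rejected(self):
        with pytest.raises(ValueError):
            PipelineParams(pipeline="wat")

    def test_every_pipeline_has_defaults(self):
        for name in ("dab", "pla", "he", "colony"):
            p = PipelineParams.defaults(name)
            assert p.pipeline == name and p.branches


class TestRunDab:
    def test_recovers_truth_on_easy_image(self):
        img, truth = make_ihc(
            n_cells=40, positive_fraction=0.5, noise_sigma=0.0,
            gradient_amplitude=0.0, seed=11, shape=(384, 384),
        )
        for variant in ("basic", "enhanced"):
            row, overlays, _ = run_dab(img, PipelineParams.defaults("dab", variant))
            assert row["total_count"] == truth.extras["n_placed"]
            assert abs(row["dab_count"] - truth.extras["n_positive"]) <= 1
            assert abs(
                row["percent_positive_area"] - 100 * truth.positive_fraction_area
            ) <= 3
            assert overlays["selection"].shape == img.shape

    def test_blank_image_zero_counts_missing_ratio(self):
        blank = np.full((96, 96, 3), 255, np.uint8)
        row, _, _ = run_dab(blank, PipelineParams.defaults("dab"))
        assert row["total_count"] == 0
        assert row["percent_positive_area"] is None

    def test_wrong_pipeline_params_rejected(self):
        with pytest.raises(ValueError):
            run_dab(np.zeros((4, 4, 3), np.uint8), PipelineParams.defaults("pla"))


class TestRunPla:
    def test_exact_counts_noise_free(self):
        channels, truth = make_pla(seed=3)
        row, overlays, _ = run_pla(channels, PipelineParams.defaults("pla"))
        assert row["foci_nuclear"] == truth.foci_counts["nuclear"]
        assert row["foci_cytoplasmic"] == truth.foci_counts["cytoplasmic"]
        assert row["foci_total"] == truth.foci_counts["total"]
        assert row["nuclei_count"] == truth.extras["n_nuclei"]
        assert set(overlays) == {"nuclei", "foci", "cytoplasm"}

    def test_zero_foci_channel(self):
        channels, _ = make_pla(foci_per_nucleus=0, foci_per_cytoplasm=0, seed=3)
        row, _, _ = run_pla(channels, PipelineParams.defaults("pla"))
        assert (row["foci_nuclear"], row["foci_cytoplasmic"], row["foci_total"]) == (0, 0, 0)

    def test_foci_monotone_in_noise_tolerance(self):
        channels, _ = make_pla(seed=4, noise_sigma=3.0)
        counts = []
        for tol in (10, 50, 100, 250):
            p = PipelineParams.defaults("pla")
            p.noise_tolerance = tol
            row, _, _ = run_pla(channels, p)
            counts.append(row["foci_total"] + row["foci_unassigned"])
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRunHe:
    def test_recovers_area_fractions(self):
        img, truth = make_he(0.4, 0.25, seed=2)
        row, _, masks = run_he(img, PipelineParams.defaults("he"))
        assert abs(row["tissue_percent_area"] - 40.0) <= 3
        assert abs(row["dense_percent_of_tissue"] - 25.0) <= 4
        # containment is enforced
        assert not (masks["dense_mask"] & ~masks["tissue_mask"]).any()

    def test_blank_slide_zero_tissue(self):
        img, _ = make_he(0.0, 0.0, seed=2, shape=(128, 128))
        row, _, _ = run_he(img, PipelineParams.defaults("he"))
        assert row["tissue_count"] == 0 and row["dense_percent_of_tissue"] is None


class TestRunColony:
    def test_counts_with_shading_correction(self):
        img, truth = make_colony(n_round=8, n_invasive=4, vignette_amplitude=60, seed=1)
        row, _, parts = run_colony(img, PipelineParams.defaults("colony"))
        assert row["colony_count"] == 12

    def test_empty_well(self):
        img, _ = make_colony(n_round=0, n_invasive=0, vignette_amplitude=30, seed=1)
        row, _, _ = run_colony(img, PipelineParams.defaults("colony"))
        assert row["colony_count"] == 0

    def test_round_wells_high_circularity(self):
        img, _ = make_colony(n_round=12, n_invasive=0, vignette_amplitude=40, seed=6)
        row, _, _ = run_colony(img, PipelineParams.defaults("colony"))
        assert row["colony_count"] == 12
        assert row["mean_circularity"] >= 0.85

    def test_invasive_colonies_score_below_round(self):
        img, _ = make_colony(n_round=6, n_invasive=6, vignette_amplitude=40, seed=7)
        _, _, parts = run_colony(img, PipelineParams.defaults("colony"))
        circs = sorted(r.circularity for r in parts["records"])
        assert len(circs) == 12
        assert np.mean(circs[:6]) < np.mean(circs[6:]) - 0.2

    def test_nlc_route_with_edge_exclusion(self):
        img, _ = make_colony(n_round=8, n_invasive=4, vignette_amplitude=60, seed=2)
        p = PipelineParams.defaults("colony")
        p.shading = ShadingParams(method="normalize_local_contrast", block_radius=40, stddevs=3)
        p.branches["colony"].threshold = ThresholdSpec(mode="auto", method="MaxEntropy", polarity="dark")
        p.branches["colony"].exclude_edges = True
        row, _, _ = run_colony(img, p)
        assert row["colony_count"] == 12


class TestOptimize:
    def test_montages_table_and_config_roundtrip(self, tmp_path):
        img_dir = tmp_path / "imgs"
        img_dir.mkdir()
        for seed in (1, 2, 3):
            img, _ = make_ihc(n_cells=15, seed=seed, shape=(160, 160))
            write_image(img_dir / f"test_{seed}.png", img)
        out = tmp_path / "opt"
        params = PipelineParams.defaults("dab")
        written = optimize(sorted(img_dir.iterdir()), params, out)
        assert len(written["montages"]) == 2  # total and DAB branches
        for m in written["montages"]:
            assert m.exists()
        # the emitted config re-ingests to identical parameters
        q = PipelineParams.from_yaml(written["config"])
        assert q.to_dict() == params.to_dict()

    def test_zero_images_usage_error(self, tmp_path):
        with pytest.raises(ValueError):
            optimize([], PipelineParams.defaults("dab"), tmp_path)


class TestRunBatch:
    def _ihc_folder(self, folder, n=4):
        folder.mkdir(exist_ok=True)
        for seed in range(n):
            img, _ = make_ihc(n_cells=12, seed=seed, shape=(128, 128))
            write_image(folder / f"img_{seed}.png", img)

    def test_one_row_per_image_and_overlays(self, tmp_path):
        self._ihc_folder(tmp_path / "batch")
        res = run_batch(tmp_path / "batch", PipelineParams.defaults("dab", "basic"))
        assert len(res.table) == 4
        assert res.ok
        assert (tmp_path / "batch" / "summary.csv").exists()
        assert len(res.overlay_paths) == 4

    def test_byte_identical_across_runs(self, tmp_path):
        self._ihc_folder(tmp_path / "batch")
        p = PipelineParams.defaults("dab", "basic")
        run_batch(tmp_path / "batch", p, tmp_path / "out1")
        run_batch(tmp_path / "batch", p, tmp_path / "out2")
        a = (tmp_path / "out1" / "summary.csv").read_bytes()
        b = (tmp_path / "out2" / "summary.csv").read_bytes()
        assert a == b

    def test_corrupt_file_skipped_and_logged(self, tmp_path):
        folder = tmp_path / "batch"
        self._ihc_folder(folder, n=3)
        (folder / "broken.png").write_bytes(b"\x89PNG garbage")
        res = run_batch(folder, PipelineParams.defaults("dab", "basic"))
        assert len(res.table) == 3
        assert res.n_failed == 1 and not res.ok
        assert any("skip: broken.png" in line for line in res.log)

    def test_empty_directory_raises(self, tmp_path):
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(FileNotFoundError):
            run_batch(empty, PipelineParams.defaults("dab"))

    def test_pla_batch_groups_channel_sets(self, tmp_path):
        folder = tmp_path / "pla"
        folder.mkdir()
        for seed in (1, 2):
            channels, _ = make_pla(n_nuclei=3, seed=seed, shape=(192, 192),
                                   base_name=f"set{seed}_")
            write_image(folder / f"set{seed}_Ch00.tif", channels.foci)
            write_image(folder / f"set{seed}_Ch01.tif", channels.nuclei)
            write_image(folder / f"set{seed}_Ch02.tif", channels.cytoplasm)
        res = run_batch(folder, PipelineParams.defaults("pla"))
        assert len(res.table) == 2
        assert set(res.table["image"]) == {"set1_", "set2_"}
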