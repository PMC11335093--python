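import datetime as dt
import itertools
import sys

import numpy as np
import pytest
from shapely.geometry import box

from plotpheno.extraction import (
    BiomassSpec,
    ExternalFeatureSpec,
    ExternalSpec,
    ExtractionStrategy,
    FormulaSpec,
    HeightSpec,
    SourceImage,
    compute_biomass,
    extract_height,
    extract_plot,
    run_external_feature,
    zonal_stat,
)
from plotpheno.formula_engine import parse_formula, registry
from plotpheno.geodata_io import BandMap, GeoTransform, RasterGrid, clip_plot
from plotpheno.roi_manager import PlotROI

DATE = dt.date(2026, 6, 1)


def single_band(values, nodata=None):
    values = np.asarray(values, dtype=float)
    transform = GeoTransform(0.0, float(values.shape[0]), 1.0, 1.0)
    return RasterGrid(values[np.newaxis], transform, nodata=nodata)


class TestZonalStat:
    def test_constant_mean(self):
        value, n = zonal_stat(single_band(np.full((3, 3), 5.0)))
        assert value == 5.0 and n == 9

    def test_enumerated_pixels(self):
        clip = single_band(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert zonal_stat(clip, "mean")[0] == 2.5
        assert zonal_stat(clip, "max")[0] == 4.0
        assert zonal_stat(clip, "min")[0] == 1.0
        assert zonal_stat(clip, "sum")[0] == 10.0
        assert zonal_stat(clip, "median")[0] == 2.5
        assert zonal_stat(clip, "count")[0] == 4.0
        assert zonal_stat(clip, "std")[0] == pytest.approx(np.sqrt(1.25))

    def test_all_nodata_missing(self):
        clip = single_band(np.full((2, 2), -9.0), nodata=-9.0)
        value, n = zonal_stat(clip)
        assert np.isnan(value) and n == 0

    def test_unknown_statistic(self):
        with pytest.raises(ValueError, match="unknown statistic"):
            zonal_stat(single_band(np.ones((2, 2))), "mode")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_masked_grid(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 10, (6, 6))
        mask = rng.uniform(size=(6, 6)) < 0.3
        values[mask] = -1.0
        clip = single_band(values, nodata=-1.0)
        kept = values[~mask]
        expected = {"mean": kept.mean(), "median": np.median(kept),
                    "min": kept.min(), "max": kept.max(),
                    "std": kept.std(), "sum": kept.sum(),
                    "count": float(kept.size)}
        for statistic, want in expected.items():
            got, n = zonal_stat(clip, statistic)
            assert got == pytest.approx(want, rel=1e-12)
            assert n == kept.size


class TestHeight:
    def roi(self):
        return PlotROI("P1", box(1.0, 1.0, 3.0, 3.0))

    def test_scalar_ground_hand_arithmetic(self):
        dsm = single_band(np.full((4, 4), 1.8))
        value, n = extract_height(dsm, self.roi(), ground=0.6)
        assert value == pytest.approx(1.2)
        assert n == 4

    def test_dtm_equal_dsm_is_zero(self):
        surface = single_band(np.random.default_rng(0).uniform(5, 9, (4, 4)))
        terrain = RasterGrid(surface.values.copy(), surface.transform)
        value, _ = extract_height(surface, self.roi(), ground=terrain)
        assert value == pytest.approx(0.0)

    def test_nodata_holes_bruteforce(self):
        values = np.full((4, 4), 2.0)
        values[1, 1] = -9.0  # inside the ROI
        dsm = single_band(values, nodata=-9.0)
        value, n = extract_height(dsm, self.roi(), ground=0.5)
        assert n == 3
        assert value == pytest.approx(1.5)

    def test_missing_ground_errors(self):
        dsm = single_band(np.ones((4, 4)))
        with pytest.raises(ValueError, match="soil reference"):
            extract_height(dsm, self.roi(), ground=None)


class TestBiomass:
    def test_hand_arithmetic(self):
        formula = parse_formula("biomass", "0.5*height")
        assert compute_biomass(formula, {"height": 1.2}) == pytest.approx(0.6)

    def test_undefined_trait_missing(self, caplog):
        formula = parse_formula("biomass", "0.5*lai")
        assert np.isnan(compute_biomass(formula, {"height": 1.2}))
        assert "lai" in caplog.text

    def test_identity(self):
        formula = parse_formula("b", "height")
        assert compute_biomass(formula, {"height": 0.77}) == 0.77


class TestExternal:
    def script(self, tmp_path, body):
        path = tmp_path / "feature.py"
        path.write_text(body)
        return ExternalFeatureSpec(sys.executable, str(path), timeout=30)

    def test_echo_stub(self, tmp_path):
        spec = self.script(tmp_path, "print(2.5)\n")
        assert run_external_feature(spec, "img.tif", "P1") == 2.5

    def test_nonzero_exit_missing(self, tmp_path, caplog):
        spec = self.script(tmp_path, "import sys; sys.exit(1)\n")
        assert np.isnan(run_external_feature(spec, "img.tif", "P1"))
        assert "exit 1" in caplog.text

    def test_last_line_protocol(self, tmp_path):
        spec = self.script(tmp_path, "print('header')\nprint(3.75)\n")
        assert run_external_feature(spec, "img.tif", "P1") == 3.75

    def test_non_numeric_output_missing(self, tmp_path, caplog):
        spec = self.script(tmp_path, "print('done')\n")
        assert np.isnan(run_external_feature(spec, "img.tif", "P1"))
        assert "not numeric" in caplog.text

    def test_arguments_passed(self, tmp_path):
        spec = self.script(
            tmp_path,
            "import sys\n"
            "assert sys.argv[1:] == ['img.tif', 'P9', 'x'], sys.argv\n"
            "print(1.0)\n")
        spec = ExternalFeatureSpec(spec.interpreter, spec.script,
                                   extra_args=("x",), timeout=30)
        assert run_external_feature(spec, "img.tif", "P9") == 1.0

    def test_missing_script_is_config_error(self):
        spec = ExternalFeatureSpec(sys.executable, "/nonexistent.py")
        with pytest.raises(FileNotFoundError):
            spec.validate()

    def test_bad_timeout(self):
        with pytest.raises(ValueError):
            ExternalFeatureSpec(sys.executable, "s.py", timeout=0)


class TestStrategy:
    def test_duplicate_names(self):
        ndvi = registry.expand("NDVI")
        with pytest.raises(ValueError, match="duplicate"):
            ExtractionStrategy([FormulaSpec("a", ndvi), FormulaSpec("a", ndvi)])

    def test_biomass_forward_reference(self):
        with pytest.raises(ValueError, match="not defined earlier"):
            ExtractionStrategy([
                BiomassSpec("biomass", parse_formula("biomass", "0.5*height")),
                HeightSpec("height", ground=0.0),
            ])

    def test_biomass_after_height_ok(self):
        ExtractionStrategy([
            HeightSpec("height", ground=0.0),
            BiomassSpec("biomass", parse_formula("biomass", "0.5*height")),
        ])


def field_images(rho=None, height=1.2, ground=20.0):
    """One 6x6 plot with uniform reflectance; returns (images, roi, rho)."""
    rho = rho or {"r": 0.1, "g": 0.15, "b": 0.05, "re": 0.3, "nir": 0.5}
    transform = GeoTransform(0.0, 6.0, 1.0, 1.0)
    ms = np.stack([np.full((6, 6), rho[k]) for k in ("r", "g", "b", "re", "nir")])
    rgb = ms[:3].copy()
    dsm = np.full((1, 6, 6), ground + height)
    images = {
        "ms": SourceImage(RasterGrid(ms, transform), BandMap.ms()),
        "rgb": SourceImage(RasterGrid(rgb, transform), BandMap.rgb()),
        "dsm": SourceImage(RasterGrid(dsm, transform)),
    }
    return images, PlotROI("P1", box(1.0, 1.0, 5.0, 5.0)), rho


class TestExtractPlot:
    def test_closed_form_oracle(self):
        images, roi, rho = field_images()
        strategy = ExtractionStrategy([
            FormulaSpec("NDVI", registry.expand("NDVI"), source="ms"),
            FormulaSpec("EXG", registry.expand("EXG"), source="rgb"),
            HeightSpec("height", ground=20.0),
        ])
        record = extract_plot(images, roi, strategy, DATE)
        ndvi = (rho["nir"] - rho["r"]) / (rho["nir"] + rho["r"])
        exg = (rho["g"] * 2 - rho["r"] - rho["b"]) / (rho["r"] + rho["g"] + rho["b"])
        assert record.values["NDVI"] == pytest.approx(ndvi, abs=1e-12)
        assert record.values["EXG"] == pytest.approx(exg, abs=1e-12)
        assert record.values["height"] == pytest.approx(1.2, abs=1e-12)
        assert record.pixel_counts["NDVI"] == 16

    def test_empty_strategy(self):
        images, roi, _ = field_images()
        record = extract_plot(images, roi, ExtractionStrategy([]), DATE)
        assert record.plot_id == "P1" and record.date == DATE
        assert record.values == {}

    def test_external_stub_in_strategy(self, tmp_path):
        images, roi, _ = field_images()
        script = tmp_path / "stub.py"
        script.write_text("print(2.5)\n")
        strategy = ExtractionStrategy([
            ExternalSpec("lrs", ExternalFeatureSpec(sys.executable, str(script)),
                         source="rgb"),
        ])
        record = extract_plot(images, roi, strategy, DATE, workdir=tmp_path)
        assert record.values["lrs"] == 2.5
        assert (tmp_path / "P1.tif").exists()  # clip retained

    def test_missing_role_enumerates_blocked(self):
        images, roi, _ = field_images()
        del images["dsm"]
        strategy = ExtractionStrategy([
            FormulaSpec("NDVI", registry.expand("NDVI"), source="ms"),
            HeightSpec("height", ground=20.0),
        ])
        with pytest.raises(ValueError, match="height"):
            extract_plot(images, roi, strategy, DATE)

    def test_formula_order_independence(self):
        images, roi, _ = field_images()
        specs = [
            FormulaSpec("NDVI", registry.expand("NDVI"), source="ms"),
            FormulaSpec("EXG", registry.expand("EXG"), source="rgb"),
            FormulaSpec("GNDVI", registry.expand("GNDVI"), source="ms"),
        ]
        baseline = extract_plot(images, roi, ExtractionStrategy(specs), DATE)
        for permutation in itertools.permutations(specs):
            record = extract_plot(images, roi,
                                  ExtractionStrategy(list(permutation)), DATE)
            assert record.values == baseline.values

    def test_band_mean_equals_pixel_on_uniform_plot(self):
        images, roi, _ = field_images()
        per_pixel = FormulaSpec("NDVI", registry.expand("NDVI"), source="ms")
        band_mean = FormulaSpec("NDVI", registry.expand("NDVI"), source="ms",
                                aggregate="band_mean")
        a = extract_plot(images, roi, ExtractionStrategy([per_pixel]), DATE)
        b = extract_plot(images, roi, ExtractionStrategy([band_mean]), DATE)
        assert a.values["NDVI"] == pytest.approx(b.values["NDVI"], abs=1e-12)

    def test_band_mean_differs_on_nonuniform_plot(self):
        # nonlinear formula: mean-of-index != index-of-means in general
        images, roi, _ = field_images()
        ms = images["ms"].raster
        rng = np.random.default_rng(1)
        ms.values[:] = rng.uniform(0.05, 0.6, ms.values.shape)
        per_pixel = FormulaSpec("NDVI", registry.expand("NDVI"), source="ms")
        band_mean = FormulaSpec("NDVI", registry.expand("NDVI"), source="ms",
                                aggregate="band_mean")
        a = extract_plot(images, roi, ExtractionStrategy([per_pixel]), DATE)
        b = extract_plot(images, roi, ExtractionStrategy([band_mean]), DATE)
        assert a.values["NDVI"] != pytest.approx(b.values["NDVI"], abs=1e-6)
        # oracle for band-mean-first: formula applied to the band means
        clip = clip_plot(ms, roi)
        means = {k: float(np.nanmean(clip.band_masked(i)))
                 for k, i in BandMap.ms().bindings.items()
                 if k in ("nir", "r")}
        expected = (means["nir"] - means["r"]) / (means["nir"] + means["r"])
        assert b.values["NDVI"] == pytest.approx(expected, abs=1e-12)


class TestNoiseConvergence:
    def test_delta_method_bound(self):
        """Per-pixel-then-mean NDVI error shrinks with pixel noise."""
        rho = {"r": 0.1, "g": 0.15, "b": 0.05, "re": 0.3, "nir": 0.5}
        truth = (rho["nir"] - rho["r"]) / (rho["nir"] + rho["r"])
        rng = np.random.default_rng(42)
        transform = GeoTransform(0.0, 20.0, 1.0, 1.0)
        roi = PlotROI("P1", box(0.0, 0.0, 20.0, 20.0))
        n_pixels = 400
        for sigma in (0.0, 0.005, 0.02):
            bands = np.stack([
                np.full((20, 20), rho[k]) + rng.normal(0, sigma, (20, 20))
                for k in ("r", "g", "b", "re", "nir")])
            images = {"ms": SourceImage(RasterGrid(bands, transform),
                                        BandMap.ms())}
            spec = FormulaSpec("NDVI", registry.expand("NDVI"), source="ms")
            record = extract_plot(images, roi, ExtractionStrategy([spec]), DATE)
            if sigma == 0.0:
                assert record.values["NDVI"] == pytest.approx(truth, abs=1e-12)
            else:
                # delta method: sd(NDVI) ≈ |∂f| * sigma per pixel; the mean
                # over n pixels shrinks by sqrt(n)
                s = rho["nir"] + rho["r"]
                grad = np.hypot(2 * rho["r"] / s**2, 2 * rho["nir"] / s**2)
                bound = 3 * grad * sigma / np.sqrt(n_pixels)
                assert abs(record.values["NDVI"] - truth) < bound
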