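import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsiduct import (
    PhantomConfig,
    default_spectral_model,
    generate_cohort,
    generate_mask,
    generate_patient,
    iter_cohort,
    load_cohort,
)
from hsiduct.phantom import SpectralClassModel, manifest_digest


class TestDefaultSpectralModel:
    def test_endmembers_in_open_unit_interval(self, spectral_model):
        for em in spectral_model.endmembers.values():
            assert np.all(em > 0.0) and np.all(em < 1.0)

    def test_smoothness(self, spectral_model):
        for em in spectral_model.endmembers.values():
            assert np.max(np.abs(np.diff(em))) < 0.1

    def test_pure_function(self):
        a, b = default_spectral_model(), default_spectral_model()
        for key in a.endmembers:
            assert np.array_equal(a.endmembers[key], b.endmembers[key])

    def test_stained_separation_peaks_nearest_550(self, spectral_model, default_grid):
        # exhaustive scan, independent of the model's own calibration check
        diff = np.abs(
            spectral_model.endmember("normal", "stained")
            - spectral_model.endmember("cancer", "stained")
        )
        score = diff / spectral_model.pixel_noise_sd
        best = int(np.argmax(score))
        nearest_550 = int(np.argmin(np.abs(default_grid - 550.0)))
        assert best == nearest_550
        assert default_grid[best] == 551.0

    def test_stained_exceeds_unstained_at_reference(self, spectral_model, default_grid):
        b = int(np.argmin(np.abs(default_grid - 550.0)))
        sep = lambda s: abs(
            spectral_model.endmember("normal", s)[b]
            - spectral_model.endmember("cancer", s)[b]
        )
        assert sep("stained") > sep("unstained")

    def test_miscalibrated_model_rejected(self, default_grid):
        flat = np.full(31, 0.5)
        with pytest.raises(ValueError, match="550"):
            SpectralClassModel(
                wavelengths=default_grid,
                endmembers={
                    ("normal", "stained"): flat,
                    # separation peaks at band 0, not near 550 nm
                    ("cancer", "stained"): flat - np.linspace(0.2, 0.01, 31),
                    ("normal", "unstained"): flat,
                    ("cancer", "unstained"): flat - 0.01,
                },
            )


class TestPhantomConfig:
    def test_defaults_match_sensor(self):
        cfg = PhantomConfig()
        assert (cfg.rows, cfg.cols, cfg.bands) == (443, 313, 31)
        assert (cfg.wavelength_min, cfg.wavelength_max) == (461.0, 641.0)
        assert cfg.n_patients == 10

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_patients": 0},
            {"rows": -1},
            {"wavelength_min": 700.0},
            {"cancer_area_fraction": 0.02},
            {"cancer_area_fraction": 0.95},
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            PhantomConfig(**kwargs)

    def test_text_round_trip(self):
        cfg = PhantomConfig(n_patients=4, rows=50, seed=9)
        assert PhantomConfig.from_text(cfg.to_text()) == cfg


class TestGenerateMask:
    def test_normal_all_zero(self, rng):
        mask = generate_mask("normal", 40, 30, 0.3, rng)
        assert not mask.labels.any()

    def test_same_seed_identical(self):
        a = generate_mask("dcis", 60, 50, 0.3, np.random.default_rng(5))
        b = generate_mask("dcis", 60, 50, 0.3, np.random.default_rng(5))
        assert np.array_equal(a.labels, b.labels)

    def test_dcis_fraction_within_half_relative(self):
        # target 0.3 at full sensor size, 20 seeds
        for seed in range(20):
            mask = generate_mask("dcis", 443, 313, 0.3, np.random.default_rng(seed))
            assert 0.15 <= mask.cancer_fraction() <= 0.45

    def test_infeasible_fraction(self, rng):
        with pytest.raises(ValueError, match="0.9"):
            generate_mask("dcis", 40, 40, 0.95, rng)

    def test_unknown_slide_class(self, rng):
        with pytest.raises(ValueError):
            generate_mask("weird", 10, 10, 0.3, rng)


class TestGeneratePatient:
    def test_degenerate_noise_exact_cancer_endmember(self, default_grid):
        cfg = PhantomConfig(
            n_patients=1, rows=48, cols=40, cancer_area_fraction=0.3,
            pixel_noise_sd=0.0, patient_gain_sd=0.0, patient_tilt_sd=0.0, seed=3,
        )
        model = default_spectral_model(
            default_grid, pixel_noise_sd=0.0, patient_gain_sd=0.0, patient_tilt_sd=0.0
        )
        slides = generate_patient(cfg, model, "p", np.random.default_rng(3))
        for lc in slides:
            if lc.slide_class != "dcis":
                continue
            expected = model.endmember("cancer", lc.staining).astype(np.float32)
            cancer = lc.mask.labels.astype(bool)
            assert np.array_equal(
                lc.cube.data[cancer], np.tile(expected, (cancer.sum(), 1))
            )

    def test_default_dims(self, spectral_model):
        cfg = PhantomConfig(seed=1)
        slides = generate_patient(cfg, spectral_model, "p", np.random.default_rng(1))
        assert len(slides) == 4
        for lc in slides:
            assert lc.cube.data.shape == (443, 313, 31)
            assert lc.cube.wavelengths[0] == 461.0
            assert lc.cube.wavelengths[-1] == 641.0

    def test_cancer_mean_within_3se(self, small_cohort):
        for lc in small_cohort:
            if lc.slide_class != "dcis":
                continue
            gain = float(lc.cube.metadata["patient gain"])
            tilt = float(lc.cube.metadata["patient tilt"])
            model = default_spectral_model()
            wl = lc.cube.wavelengths
            expected = (
                gain * (1 + tilt * (wl - 551.0)) * model.endmember("cancer", lc.staining)
            )
            cancer = lc.mask.labels.astype(bool)
            n = cancer.sum()
            se = 0.02 / np.sqrt(n)  # pixel noise SD / sqrt(n)
            observed = lc.cube.data[cancer].mean(axis=0)
            # 4 SE: ~190 simultaneous per-band comparisons make a plain 3-SE
            # bound flaky; float32 storage adds a negligible 1e-5 slack
            assert np.all(np.abs(observed - expected) < 4 * se + 1e-5)

    def test_label_fidelity_zero_noise(self, default_grid):
        cfg = PhantomConfig(
            n_patients=1, rows=48, cols=40, cancer_area_fraction=0.3,
            pixel_noise_sd=0.0, seed=11,
        )
        model = default_spectral_model(default_grid, pixel_noise_sd=0.0)
        slides = generate_patient(cfg, model, "p", np.random.default_rng(11))
        for lc in slides:
            if lc.staining != "stained":
                continue
            normal_em = model.endmember("normal", "stained")
            cancer_em = model.endmember("cancer", "stained")
            px = lc.cube.data.reshape(-1, 31).astype(float)
            d_normal = np.linalg.norm(px - normal_em, axis=1)
            d_cancer = np.linalg.norm(px - cancer_em, axis=1)
            predicted = (d_cancer < d_normal).astype(np.uint8)
            assert np.array_equal(predicted, lc.mask.labels.ravel())

    def test_gain_tilt_shared_across_slides(self, small_cohort):
        by_patient = {}
        for lc in small_cohort:
            by_patient.setdefault(lc.patient_id, set()).add(
                (lc.cube.metadata["patient gain"], lc.cube.metadata["patient tilt"])
            )
        for pid, pairs in by_patient.items():
            assert len(pairs) == 1, pid


class TestCohort:
    def test_cohort_size(self, small_cohort, small_phantom_config):
        assert len(small_cohort) == small_phantom_config.n_patients * 4
        patients = {lc.patient_id for lc in small_cohort}
        assert len(patients) == small_phantom_config.n_patients

    def test_iter_cohort_deterministic(self, small_phantom_config, small_cohort):
        again = list(iter_cohort(small_phantom_config))
        for a, b in zip(small_cohort, again):
            assert np.array_equal(a.cube.data, b.cube.data)
            assert np.array_equal(a.mask.labels, b.mask.labels)

    def test_on_disk_layout_and_determinism(self, tmp_path):
        cfg = PhantomConfig(n_patients=2, rows=40, cols=36, seed=5)
        m1 = generate_cohort(cfg, str(tmp_path / "a"))
        m2 = generate_cohort(cfg, str(tmp_path / "b"))
        rows1 = open(m1).read().splitlines()
        assert len(rows1) == 1 + cfg.n_patients * 4  # header + one row per cube
        assert open(m1).read() == open(m2).read()
        assert manifest_digest(str(tmp_path / "a")) == manifest_digest(str(tmp_path / "b"))

    def test_load_cohort_round_trip(self, tmp_path):
        cfg = PhantomConfig(n_patients=1, rows=32, cols=30, seed=2)
        generate_cohort(cfg, str(tmp_path / "c"))
        loaded = load_cohort(str(tmp_path / "c"))
        original = list(iter_cohort(cfg))
        assert len(loaded) == 4
        key = lambda lc: (lc.patient_id, lc.slide_class, lc.staining)
        for a, b in zip(sorted(loaded, key=key), sorted(original, key=key)):
            assert np.array_equal(a.cube.data, b.cube.data)
            assert np.array_equal(a.mask.labels, b.mask.labels)
            assert key(a) == key(b)

    def test_normal_slides_all_zero_masks(self, small_cohort):
        for lc in small_cohort:
            if lc.slide_class == "normal":
                assert not lc.mask.labels.any()

    def test_dcis_fraction_near_target(self, small_cohort, small_phantom_config):
        target = small_phantom_config.cancer_area_fraction
        for lc in small_cohort:
            if lc.slide_class == "dcis":
                assert 0.5 * target <= lc.mask.cancer_fraction() <= 1.5 * target


@settings(max_examples=10, deadline=None)
@given(
    n_patients=st.integers(1, 3),
    rows=st.integers(36, 64),
    cols=st.integers(36, 64),
    bands=st.integers(4, 12),
    fraction=st.floats(0.2, 0.5),
    seed=st.integers(0, 10_000),
)
def test_cohort_conforms_to_arbitrary_config(n_patients, rows, cols, bands, fraction, seed):
    cfg = PhantomConfig(
        n_patients=n_patients, rows=rows, cols=cols, bands=bands,
        cancer_area_fraction=fraction, seed=seed,
    )
    cohort = list(iter_cohort(cfg))
    assert len(cohort) == n_patients * 4
    for lc in cohort:
        assert lc.cube.data.shape == (rows, cols, bands)
        assert lc.mask.shape == (rows, cols)
        assert len(lc.cube.wavelengths) == bands
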