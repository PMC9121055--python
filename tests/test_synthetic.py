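"""Ground-truth structure and reproducibility of the synthetic generator."""

import numpy as np
import pytest
from scipy.special import erf

from linacvsm import classify, phsp_io, synthetic
from linacvsm.phsp_io import Species

WINDOW_3SIGMA_FRACTION = erf(3 / np.sqrt(2)) ** 2  # 0.994608 for two axes


def test_degenerate_mixture_is_all_primary_photons():
    cfg = synthetic.SourceTruthConfig(charged_fraction=0.0,
                                      primary_photon_fraction=1.0,
                                      primary_jitter=0.0, seed=1)
    arr = synthetic.generate_synthetic_phsp(cfg, 50_000)
    assert np.all(arr["type"] == int(Species.PHOTON))
    x0, y0 = classify.reverse_transport_to_focal(
        arr["x"], arr["y"], arr["u"], arr["v"], cfg.scoring_plane_z)
    # reverse-transported origins are the Gaussian focal spot
    assert abs(x0.mean()) < 4 * cfg.sigma_x / np.sqrt(len(arr))
    assert x0.std() == pytest.approx(cfg.sigma_x, rel=0.02)
    assert y0.std() == pytest.approx(cfg.sigma_y, rel=0.02)


def test_origin_mean_converges_at_clt_rate():
    cfg = synthetic.SourceTruthConfig(charged_fraction=0.0,
                                      primary_photon_fraction=1.0,
                                      primary_jitter=0.0, seed=2)
    n = 1_000_000
    arr = synthetic.generate_synthetic_phsp(cfg, n)
    x0, _ = classify.reverse_transport_to_focal(
        arr["x"], arr["y"], arr["u"], arr["v"], cfg.scoring_plane_z)
    assert abs(x0.mean()) < 3 * cfg.sigma_x / np.sqrt(n)


def test_exact_three_sigma_window_captures_closed_form_fraction():
    """Per-axis independence gives erf(3/sqrt(2))^2 = 0.994608 in-window."""
    cfg = synthetic.SourceTruthConfig(charged_fraction=0.0,
                                      primary_photon_fraction=1.0,
                                      primary_jitter=0.0, seed=3)
    n = 1_000_000
    arr = synthetic.generate_synthetic_phsp(cfg, n)
    x0, y0 = classify.reverse_transport_to_focal(
        arr["x"], arr["y"], arr["u"], arr["v"], cfg.scoring_plane_z)
    inside = ((np.abs(x0) <= 3 * cfg.sigma_x)
              & (np.abs(y0) <= 3 * cfg.sigma_y)).mean()
    p = WINDOW_3SIGMA_FRACTION
    assert inside == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / n))


def test_same_seed_gives_byte_identical_files(tmp_path):
    cfg = synthetic.SourceTruthConfig()
    for name in ("a", "b"):
        synthetic.write_synthetic_phsp(cfg, 30_000, tmp_path / name, seed=99)
    assert ((tmp_path / "a.IAEAphsp").read_bytes()
            == (tmp_path / "b.IAEAphsp").read_bytes())
    other = tmp_path / "c"
    synthetic.write_synthetic_phsp(cfg, 30_000, other, seed=100)
    assert ((tmp_path / "a.IAEAphsp").read_bytes()
            != (tmp_path / "c.IAEAphsp").read_bytes())


def test_generated_particles_satisfy_phase_space_invariants():
    cfg = synthetic.SourceTruthConfig(seed=4)
    arr = synthetic.generate_synthetic_phsp(cfg, 200_000)
    u = arr["u"].astype(np.float64)
    v = arr["v"].astype(np.float64)
    assert np.all(arr["energy"] > 0)
    assert np.all(arr["energy"] <= cfg.e_max)
    assert np.all(u * u + v * v < 1.0)
    assert np.all(np.abs(arr["x"]) <= cfg.field_half_width)
    assert np.all(np.abs(arr["y"]) <= cfg.field_half_width)
    # charged contamination near the configured sub-percent level
    ch = (arr["type"] != int(Species.PHOTON)).mean()
    assert ch == pytest.approx(cfg.charged_fraction, abs=5e-4)


def test_radial_softening_lowers_mean_energy_off_axis():
    cfg = synthetic.SourceTruthConfig(charged_fraction=0.0, seed=5)
    arr = synthetic.generate_synthetic_phsp(cfg, 500_000)
    r = np.hypot(arr["x"], arr["y"])
    inner = arr["energy"][r < 1.5].mean()
    outer = arr["energy"][r > 4.5].mean()
    assert outer < inner


def test_truth_expectations_match_classifier_on_mixture():
    """Quadrature oracle for the scatter leakage into the fitted window."""
    cfg = synthetic.SourceTruthConfig(primary_photon_fraction=0.9,
                                      charged_fraction=0.0,
                                      primary_jitter=0.0, scatter_jitter=0.0,
                                      seed=6)
    n = 1_000_000
    arr = synthetic.generate_synthetic_phsp(cfg, n)
    x0, y0 = classify.reverse_transport_to_focal(
        arr["x"], arr["y"], arr["u"], arr["v"], cfg.scoring_plane_z)
    fit = classify.fit_focal_gaussian(x0, y0)
    measured = classify.primary_fraction(arr, fit, cfg.scoring_plane_z)
    expected = synthetic.truth_expectations(cfg, fit=fit)
    p = expected.classified_primary_fraction
    assert measured == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / n))


def test_truth_expectations_pure_primary_closed_form():
    cfg = synthetic.SourceTruthConfig(primary_photon_fraction=1.0,
                                      charged_fraction=0.0,
                                      primary_jitter=0.0)
    exp = synthetic.truth_expectations(cfg)
    assert exp.classified_primary_fraction == pytest.approx(
        WINDOW_3SIGMA_FRACTION, abs=1e-6)
    assert exp.sigma_x == pytest.approx(cfg.sigma_x)


def test_invalid_arguments_rejected():
    with pytest.raises(ValueError):
        synthetic.generate_synthetic_phsp(synthetic.SourceTruthConfig(), 0)
    with pytest.raises(ValueError):
        synthetic.SourceTruthConfig(primary_photon_fraction=1.5)
    with pytest.raises(ValueError):
        synthetic.SourceTruthConfig(sigma_x=-0.1)


def test_written_file_reads_back_through_phsp_io(tmp_path):
    cfg = synthetic.SourceTruthConfig(seed=8)
    header = synthetic.write_synthetic_phsp(cfg, 25_000, tmp_path / "s")
    assert header.record_count == 25_000
    arr = phsp_io.read_phsp_array(tmp_path / "s")
    assert len(arr) == 25_000
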