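"""Logistic detection model: arithmetic, inversion, fitting, records."""

import math

import numpy as np
import pandas as pd
import pytest

from tcrseek import (
    PUBLISHED_COEFFICIENTS,
    DetectionModelCoefficients,
    build_detection_records,
    fit_detection_model,
    fraction_to_tpm,
    min_depth_for_detection,
    predict_detection,
    til_to_tcr_fraction,
)
from tcrseek.extractor import ClonotypeTable


class TestPublishedArithmetic:
    def test_tumor_scenario_linear_predictor(self):
        lp = PUBLISHED_COEFFICIENTS.linear_predictor(10, 7e7, 50, 45)
        assert lp == pytest.approx(0.37, abs=1e-9)
        p = predict_detection(PUBLISHED_COEFFICIENTS, 10, 7e7, 50, 45)
        assert p == pytest.approx(1 / (1 + math.exp(-0.37)), abs=1e-12)
        assert p > 0.5

    def test_tpm_odds_ratio(self):
        assert PUBLISHED_COEFFICIENTS.odds_ratios()["log10_tpm"] == pytest.approx(
            7.242, abs=0.01
        )

    def test_zero_coefficients_give_half(self):
        zero = DetectionModelCoefficients(0, 0, 0, 0, 0)
        assert predict_detection(zero, 5, 1e6, 50, 45) == pytest.approx(0.5)

    def test_required_depth_tumor_scenario(self):
        exact, rounded = min_depth_for_detection(
            PUBLISHED_COEFFICIENTS, tpm=10, read_length=50, cdr3_length=45
        )
        # algebra: (5.38 - 1.98 - 2.0 + 1.8) / 0.51 x 1e7
        assert exact == pytest.approx((5.38 - 1.98 - 2.0 + 1.8) / 0.51 * 1e7)
        assert rounded == 7e7

    def test_depth_probability_inverse(self):
        for target in (0.3, 0.5, 0.9):
            exact, _ = min_depth_for_detection(
                PUBLISHED_COEFFICIENTS, 10, 50, 45, target_p=target
            )
            lp = PUBLISHED_COEFFICIENTS.linear_predictor(10, exact, 50, 45)
            assert lp == pytest.approx(math.log(target / (1 - target)), abs=1e-9)

    def test_monotonicities(self):
        f = lambda tpm, depth, c: predict_detection(
            PUBLISHED_COEFFICIENTS, tpm, depth, 50, c
        )
        assert f(20, 1e7, 45) > f(10, 1e7, 45)
        assert f(10, 2e7, 45) > f(10, 1e7, 45)
        assert f(10, 1e7, 48) < f(10, 1e7, 45)
        d_hi, _ = min_depth_for_detection(PUBLISHED_COEFFICIENTS, 100, 50, 45)
        d_lo, _ = min_depth_for_detection(PUBLISHED_COEFFICIENTS, 10, 50, 45)
        assert d_hi < d_lo

    def test_input_validation(self):
        with pytest.raises(ValueError):
            predict_detection(PUBLISHED_COEFFICIENTS, 0, 1e7, 50, 45)
        bad = DetectionModelCoefficients(0, 1, -0.1, 0, 0)
        with pytest.raises(ValueError):
            min_depth_for_detection(bad, 10, 50, 45)


class TestTranscriptFraction:
    def test_pure_lymphocytes(self):
        assert til_to_tcr_fraction(100) == pytest.approx(5e-4)

    def test_two_percent_til(self):
        assert til_to_tcr_fraction(2) == pytest.approx(1e-5)

    def test_one_in_two_thousand(self):
        assert 1 / til_to_tcr_fraction(100) == pytest.approx(2000)

    def test_tpm_conversion(self):
        assert fraction_to_tpm(1.5e-4) == pytest.approx(150)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            til_to_tcr_fraction(101)
        with pytest.raises(ValueError):
            til_to_tcr_fraction(10, lymphocyte_fraction=0)


def simulate_records(seed, n=50_000, coeffs=PUBLISHED_COEFFICIENTS):
    """Bernoulli detection records drawn from the logistic model itself,
    with covariates spanning realistic benchmark ranges."""
    rng = np.random.default_rng(seed)
    log10tpm = rng.uniform(-1, 4, n)
    depth = 10 ** rng.uniform(4, 8, n)
    read_length = rng.choice([50, 76, 101], n)
    cdr3 = rng.choice(np.arange(30, 61, 3), n).astype(float)
    lp = (
        coeffs.intercept
        + coeffs.b_log10_tpm * log10tpm
        + coeffs.b_depth_per_1e7 * depth / 1e7
        + coeffs.b_read_length * read_length
        + coeffs.b_cdr3_length * cdr3
    )
    detected = rng.random(n) < 1 / (1 + np.exp(-lp))
    return pd.DataFrame(
        {
            "transcript_id": [f"t{i}" for i in range(n)],
            "tpm": 10.0 ** log10tpm,
            "depth": depth,
            "read_length": read_length,
            "cdr3_length": cdr3,
            "detected": detected,
        }
    )


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_parameter_recovery(seed):
    """Refitting on 50,000 self-simulated records recovers every published
    coefficient within 10 %."""
    records = simulate_records(seed)
    coeffs, performance = fit_detection_model(records, split_seed=seed)
    truth = PUBLISHED_COEFFICIENTS
    for name in (
        "intercept", "b_log10_tpm", "b_depth_per_1e7", "b_read_length",
        "b_cdr3_length",
    ):
        est, true = getattr(coeffs, name), getattr(truth, name)
        assert abs(est - true) / abs(true) < 0.10, name
    assert 0 < performance["validation_sensitivity"] <= 1
    assert 0 < performance["validation_specificity"] <= 1


def test_fit_deterministic():
    records = simulate_records(7, n=5000)
    a, _ = fit_detection_model(records, split_seed=3)
    b, _ = fit_detection_model(records, split_seed=3)
    assert a == b


def test_fit_rejects_degenerate_outcomes():
    records = simulate_records(0, n=500)
    records["detected"] = True
    with pytest.raises(ValueError):
        fit_detection_model(records)


def test_build_detection_records(ref, beta_repertoire):
    transcripts = beta_repertoire[:4]
    abundance = pd.DataFrame(
        {
            "transcript_id": [t.name for t in transcripts],
            "tpm": [10.0, 0.0, 5.0, 2.0],
            "is_tcr": True,
        }
    )
    detected_nt = transcripts[0].cdr3_nt
    extracted = ClonotypeTable(
        df=pd.DataFrame(
            [{
                "chain": "beta", "cdr3_nt": detected_nt,
                "cdr3_aa": transcripts[0].cdr3_aa, "v_name": "v", "j_name": "j",
                "read_count": 2, "has_stop": False,
            }]
        )
    )
    short_read_length = len(transcripts[2].cdr3_nt)  # read not longer than CDR3
    records, excluded = build_detection_records(
        transcripts, abundance, extracted, depth=1000,
        read_length=short_read_length,
    )
    # transcript 1 (tpm=0) and transcript 2 (cdr3 == read length) are excluded
    assert set(excluded.transcript_id) >= {transcripts[1].name, transcripts[2].name}
    # detected is exactly the membership test against the extracted nt set
    for r in records.itertuples():
        t = next(t for t in transcripts if t.name == r.transcript_id)
        assert r.detected == (t.cdr3_nt == detected_nt)
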