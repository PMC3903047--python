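import math

import numpy as np
import pandas as pd
import pytest

import sixmeth as sm
from sixmeth.seqfeatures import SixmerDecomposition
from conftest import random_codon_cds


def decomp(gene_id, counts):
    return SixmerDecomposition(gene_id, counts, sum(counts.values()))


def brute_force_aggregate(decomps, values):
    """Oracle: accumulate over the flat per-occurrence list."""
    flat: dict[str, list[float]] = {}
    for d in decomps:
        if d.gene_id not in values or math.isnan(values[d.gene_id]):
            continue
        for sixmer, count in d.counts.items():
            flat.setdefault(sixmer, []).extend([values[d.gene_id]] * count)
    mean = {s: sum(v) / len(v) for s, v in flat.items()}
    sd = {s: (sum((x - mean[s]) ** 2 for x in v) / len(v)) ** 0.5
          for s, v in flat.items()}
    return mean, sd


def test_sixmer_space_is_4096_unique_types():
    types = sm.all_sixmers()
    assert len(types) == 4 ** 6 == sm.N_SIXMER_TYPES
    assert len(set(types)) == 4096


def test_single_contributor_gets_gene_value():
    d = decomp("g", {"ATGGCT": 2, "GCTAAA": 1})
    occ = sm.build_occurrence_frame([d])
    out = sm.aggregate_by_sixmer(occ, pd.Series({"g": 0.7}), "V")
    assert (out["V"] == 0.7).all()
    assert (out["SD_V"] == 0.0).all()


def test_weighted_mean_example():
    # values 0 and 1, occurring 1x and 3x -> (0*1 + 1*3)/4 = 0.75
    occ = sm.build_occurrence_frame([
        decomp("a", {"ATGGCT": 1}), decomp("b", {"ATGGCT": 3})])
    out = sm.aggregate_by_sixmer(occ, pd.Series({"a": 0.0, "b": 1.0}), "V")
    assert out.loc["ATGGCT", "V"] == 0.75
    assert out.loc["ATGGCT", "OCC_TOTAL"] == 4


def test_missing_value_genes_are_skipped():
    occ = sm.build_occurrence_frame([
        decomp("a", {"ATGGCT": 1}), decomp("b", {"ATGGCT": 3})])
    out = sm.aggregate_by_sixmer(occ, pd.Series({"a": 0.5, "b": np.nan}), "V")
    assert out.loc["ATGGCT", "V"] == 0.5
    assert out.loc["ATGGCT", "OCC_TOTAL"] == 1


def test_aggregation_matches_per_occurrence_oracle():
    rng = np.random.default_rng(5)
    for _ in range(5):
        genes = [sm.GeneModel(f"g{i}", random_codon_cds(rng, rng.integers(3, 15)))
                 for i in range(20)]
        decomps = [sm.extract_sixmers(g) for g in genes]
        values = {g.gene_id: float(rng.normal()) for g in genes}
        got = sm.aggregate_by_sixmer(
            sm.build_occurrence_frame(decomps), pd.Series(values), "V")
        mean, sd = brute_force_aggregate(decomps, values)
        for sixmer in mean:
            assert got.loc[sixmer, "V"] == pytest.approx(mean[sixmer], abs=1e-12)
            assert got.loc[sixmer, "SD_V"] == pytest.approx(sd[sixmer], abs=1e-12)


def test_weighted_mean_stays_in_convex_hull():
    rng = np.random.default_rng(6)
    genes = [sm.GeneModel(f"g{i}", random_codon_cds(rng, 20)) for i in range(15)]
    values = pd.Series({g.gene_id: float(rng.uniform(-2, 3)) for g in genes})
    out = sm.aggregate_by_sixmer(
        sm.build_occurrence_frame([sm.extract_sixmers(g) for g in genes]),
        values, "V")
    assert (out["V"] >= values.min() - 1e-12).all()
    assert (out["V"] <= values.max() + 1e-12).all()


def test_dispersion_screen_retains_expression_features_only():
    # ten genes share one sixmer; expression features constant across genes,
    # compositional features alternating -> per-sixmer SD 0 vs ~0.5 / ~1.0
    decomps = [decomp(f"g{i}", {"ATGGCT": 1}) for i in range(10)]
    table = pd.DataFrame({
        "GE_STD": 0.05, "GE_CV": 0.9,
        "GC3": [i % 2 for i in range(10)],
        "GEN_SIG": [2.0 * (i % 2) for i in range(10)],
    }, index=[f"g{i}" for i in range(10)])
    _, disp = sm.aggregate_feature_table(
        sm.build_occurrence_frame(decomps), table)
    assert sm.dispersion_screen(disp) == ["GE_STD", "GE_CV"]


def test_dispersion_screen_cutoff_comparison():
    disp = pd.DataFrame({"flat": [0.0, 0.0], "wide": [0.5, 0.6]},
                        index=["AAAAAA", "CCCCCC"])
    assert sm.dispersion_screen(disp) == ["flat"]


def test_linear_fit_recovers_planted_published_constants():
    x = pd.Series(np.linspace(0.4, 1.2, 200))
    y = -1.66 * x + 1.7567
    fit = sm.fit_linear_sixmer_model(x, y)
    assert fit.slope == pytest.approx(-1.66, rel=1e-12)
    assert fit.intercept == pytest.approx(1.7567, rel=1e-12)
    assert fit.r == pytest.approx(-1.0, abs=1e-12)


def test_linear_fit_constant_y():
    x = pd.Series([0.1, 0.5, 0.9, 1.3])
    fit = sm.fit_linear_sixmer_model(x, pd.Series([2.0] * 4))
    assert fit.slope == pytest.approx(0.0, abs=1e-14)
    assert fit.intercept == pytest.approx(2.0, rel=1e-14)


def test_linear_fit_noisy_slope_within_sampling_error():
    rng = np.random.default_rng(7)
    x = rng.uniform(0, 1, 4096)
    y = 2.0 * x + rng.normal(0, 0.01, 4096)
    fit = sm.fit_linear_sixmer_model(pd.Series(x), pd.Series(y))
    assert fit.slope == pytest.approx(2.0, abs=0.01)


def test_linear_fit_zero_variance_errors():
    with pytest.raises(ValueError, match="zero variance"):
        sm.fit_linear_sixmer_model(pd.Series([1.0, 1.0, 1.0]),
                                   pd.Series([1.0, 2.0, 3.0]))


def test_reconstruction_examples():
    table = pd.Series({"ATGGCT": 0.3, "GCTAAA": 0.6})
    # 9-nt gene with both sixmers once: (0.3 + 0.6) / 9 = 0.1
    met, cov = sm.reconstruct_gene_met(
        decomp("g", {"ATGGCT": 1, "GCTAAA": 1}), 9, table)
    assert met == pytest.approx(0.1)
    assert cov == 1.0
    # all table values zero -> positivity filter gives 0
    met0, _ = sm.reconstruct_gene_met(
        decomp("g", {"ATGGCT": 2}), 9, pd.Series({"ATGGCT": 0.0}))
    assert met0 == 0.0


def test_reconstruction_homogeneous_closed_form():
    rng = np.random.default_rng(8)
    gene = sm.GeneModel("g", random_codon_cds(rng, 40))
    d = sm.extract_sixmers(gene)
    table = pd.Series(0.42, index=list(d.counts))
    met, cov = sm.reconstruct_gene_met(d, gene.length_nt, table)
    assert met == pytest.approx(0.42 * (40 - 1) / (3 * 40), rel=1e-12)
    assert cov == 1.0


def test_reconstruction_ignores_absent_and_nonpositive_sixmers():
    rng = np.random.default_rng(9)
    gene = sm.GeneModel("g", random_codon_cds(rng, 30))
    d = sm.extract_sixmers(gene)
    table = pd.Series(rng.uniform(-0.5, 1.0, len(d.counts)),
                      index=list(d.counts))
    met_full, _ = sm.reconstruct_gene_met(d, gene.length_nt, table)
    met_trim, cov = sm.reconstruct_gene_met(
        d, gene.length_nt, table[table > 0])
    assert met_trim == pytest.approx(met_full, rel=1e-12)
    assert cov <= 1.0


def test_reconstruction_rejects_nonpositive_length():
    with pytest.raises(ValueError):
        sm.reconstruct_gene_met(decomp("g", {"ATGGCT": 1}), 0,
                                pd.Series({"ATGGCT": 1.0}))


def test_exponential_fit_exact_recovery_any_window():
    rng = np.random.default_rng(10)
    x = np.sort(rng.uniform(0, 0.3, 400))
    y = 6e-4 * np.exp(21.33 * x)
    for window in (1, 7, 51):
        amp, rate, r2, sse = sm.fit_exponential_calibration(x, y, window=window)
        assert amp == pytest.approx(6e-4, rel=1e-9)
        assert rate == pytest.approx(21.33, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert sse == pytest.approx(0.0, abs=1e-12)


def test_exponential_fit_constant_series_gives_zero_rate():
    x = np.linspace(0, 1, 200)
    amp, rate, _, _ = sm.fit_exponential_calibration(
        x, np.full(200, 0.05), window=21)
    assert rate == pytest.approx(0.0, abs=1e-12)
    assert amp == pytest.approx(0.05, rel=1e-12)


def test_exponential_fit_noisy_recovery():
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 0.3, 2000)
    y = 0.002 * np.exp(10.0 * x) * np.exp(rng.normal(0, 0.05, 2000))
    amp, rate, _, _ = sm.fit_exponential_calibration(x, y, window=51)
    assert amp == pytest.approx(0.002, rel=0.10)
    assert rate == pytest.approx(10.0, abs=0.5)


def test_exponential_fit_rejects_bad_window_and_empty_positive_set():
    x = np.linspace(0, 1, 50)
    y = np.exp(x)
    with pytest.raises(ValueError):
        sm.fit_exponential_calibration(x, y, window=4)
    with pytest.raises(ValueError):
        sm.fit_exponential_calibration(x, np.zeros(50), window=5)


def test_published_preset_and_degenerate_prediction():
    model = sm.published_model()
    assert model.sixmer_met(0.0) == 1.7567
    assert model.calibrate(0.0) == 6e-4
    flat = sm.CalibrationModel(slope=0.0, intercept=0.5, amplitude=0.01,
                               rate=0.0, smoothing_window=1)
    table = pd.Series({"ATGGCT": 0.9, "GCTAAA": 1.1})
    pred, met_prime, cov = sm.predict_gene_methylation(
        decomp("g", {"ATGGCT": 1, "GCTAAA": 2}), 12, table, flat)
    assert pred == 0.01
    assert met_prime == pytest.approx(0.5 * 3 / 12)
    assert cov == 1.0


def test_prediction_decreases_when_cv_shifts_up():
    # negative slope and positive rate: higher expression CV -> less methylation
    model = sm.CalibrationModel(slope=-1.66, intercept=1.7567,
                                amplitude=6e-4, rate=21.33)
    assert model.slope < 0
    d = decomp("g", {"ATGGCT": 2, "GCTAAA": 1})
    table = pd.Series({"ATGGCT": 0.7, "GCTAAA": 0.8})
    base = sm.predict_gene_methylation(d, 12, table, model)[0]
    shifted = sm.predict_gene_methylation(d, 12, table + 0.05, model)[0]
    assert shifted < base


def test_prediction_requires_table_overlap():
    model = sm.published_model()
    with pytest.raises(ValueError, match="no sixmer"):
        sm.predict_gene_methylation(
            decomp("g", {"ATGGCT": 1}), 9, pd.Series({"CCCCCC": 1.0}), model)


def test_model_yaml_roundtrip_is_bit_exact(tmp_path):
    model = sm.CalibrationModel(
        slope=-1.6600000000000001, intercept=1.7567, amplitude=6.0e-4,
        rate=21.33, smoothing_window=101, r2=0.83, sse=82.0, linear_r=-0.95)
    path = tmp_path / "model.yaml"
    model.save(path)
    loaded = sm.CalibrationModel.load(path)
    assert loaded == model


def test_model_rejects_even_window():
    with pytest.raises(ValueError):
        sm.CalibrationModel(slope=1, intercept=0, amplitude=1, rate=1,
                            smoothing_window=10)
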