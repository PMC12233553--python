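"""Wavelet feature extraction checked against independent oracles.

The transform oracle is a direct filter-and-downsample cascade built from
the analytic Daubechies 4-tap coefficients with half-sample symmetric
extension; the statistics oracle recomputes every band statistic from its
defining formula with no shared code path.
"""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from fwave.features import (
    BANDS,
    DEMOGRAPHIC_COLUMNS,
    SESSION_FEATURE_COLUMNS,
    STAT_NAMES,
    STIM_FEATURE_NAMES,
    TableTransform,
    WaveletDecomposition,
    aggregate_session,
    annotations_to_table,
    band_statistics,
    dwt_decompose,
    extract_stimulation_features,
    sessions_to_table,
)
from fwave.preprocessing import preprocess, split_m_f
from fwave.synthetic import WaveformParams, generate_waveform
from fwave.types import NERVE_ORDER, Nerve

# ----------------------------------------------------------------------
# independent transform oracle: analytic db2 filters, direct convolution
# ----------------------------------------------------------------------

_S3 = np.sqrt(3.0)
ORACLE_DEC_LO = np.array([1 - _S3, 3 - _S3, 3 + _S3, 1 + _S3]) / (4 * np.sqrt(2.0))
ORACLE_DEC_HI = np.array([-ORACLE_DEC_LO[3], ORACLE_DEC_LO[2], -ORACLE_DEC_LO[1], ORACLE_DEC_LO[0]])


def oracle_dwt_level(x):
    """One analysis level: half-sample symmetric extension by L-1, full
    convolution with the analytic filters, downsample by 2."""
    L = 4
    ext = np.concatenate([x[:L - 1][::-1], x, x[-(L - 1):][::-1]])
    out_len = (len(x) + L - 1) // 2
    a = np.convolve(ext, ORACLE_DEC_LO)[L::2][:out_len]
    d = np.convolve(ext, ORACLE_DEC_HI)[L::2][:out_len]
    return a, d


def oracle_cascade(x, levels=4):
    details = []
    a = np.asarray(x, dtype=float)
    for _ in range(levels):
        a, d = oracle_dwt_level(a)
        details.append(d)
    return [a] + details[::-1]  # cA4, cD4, cD3, cD2, cD1


class TestDwtDecompose:
    def test_matches_oracle_cascade_on_random_traces(self, rng):
        for _ in range(20):
            n = int(rng.integers(100, 3000))
            x = rng.normal(size=n)
            decomp = dwt_decompose(x)
            expected = oracle_cascade(x)
            for band, exp in zip(BANDS, expected):
                got = decomp.bands[band]
                assert got.shape == exp.shape
                np.testing.assert_allclose(got, exp, atol=1e-10)

    def test_all_zero_input(self):
        decomp = dwt_decompose(np.zeros(2975))
        for band in BANDS:
            assert np.all(decomp.bands[band] == 0)
            assert decomp.band_powers[band] == 0

    def test_constant_input_details_vanish(self):
        # db2 has two vanishing moments: constants live in the approximation
        decomp = dwt_decompose(np.full(1024, 3.7))
        for band in BANDS[1:]:
            core = decomp.bands[band][3:-3]
            assert np.max(np.abs(core)) < 1e-10
        assert decomp.band_powers["cA4"] > 0

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="16"):
            dwt_decompose(np.zeros(10))


# ----------------------------------------------------------------------
# independent statistics oracle
# ----------------------------------------------------------------------

def _pct(x, q):
    xs = np.sort(np.asarray(x, dtype=float))
    pos = q / 100.0 * (len(xs) - 1)
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def _crossings(x, mu):
    signs = []
    for v in x:
        d = v - mu
        if d > 0:
            signs.append(1)
        elif d < 0:
            signs.append(-1)
        else:
            signs.append(signs[-1] if signs else 0)
    # leading zeros inherit the first nonzero sign
    first = next((s for s in signs if s != 0), 0)
    signs = [first if s == 0 else s for s in signs]
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


def direct_stats(bands, name):
    x = np.asarray(bands[name], dtype=float)
    n = len(x)
    mu = float(np.sum(x)) / n
    var = float(np.sum((x - mu) ** 2)) / n
    sd = var ** 0.5
    powers = {b: float(np.sum(np.asarray(v) ** 2)) for b, v in bands.items()}
    total = sum(powers.values())
    r = powers[name] / total if total > 0 else 0.0
    return {
        "mean": mu,
        "var": var,
        "rms": (float(np.sum(x ** 2)) / n) ** 0.5,
        "p5": _pct(x, 5),
        "p95": _pct(x, 95),
        "skew": float(np.sum((x - mu) ** 3)) / n / sd ** 3 if sd > 0 else 0.0,
        "kurt": float(np.sum((x - mu) ** 4)) / n / sd ** 4 - 3.0 if sd > 0 else 0.0,
        "crossings": float(_crossings(x, mu)),
        "relpow": r,
        "entropy": -r * np.log(r) if r > 0 else 0.0,
    }


class TestBandStatistics:
    def test_matches_direct_formulas_on_100_random_traces(self, rng):
        for _ in range(100):
            x = rng.normal(scale=rng.uniform(0.1, 5.0), size=int(rng.integers(64, 600)))
            decomp = dwt_decompose(x)
            for band in BANDS:
                got = band_statistics(decomp, band)
                expected = direct_stats(decomp.bands, band)
                for stat in STAT_NAMES:
                    assert got[stat] == pytest.approx(expected[stat], abs=1e-9), (band, stat)

    def test_relative_powers_sum_to_one(self, rng):
        for _ in range(20):
            decomp = dwt_decompose(rng.normal(size=500))
            total = sum(band_statistics(decomp, b)["relpow"] for b in BANDS)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_constant_band(self):
        decomp = WaveletDecomposition(bands={
            "cA4": np.array([1.0, 1.0, 1.0, 1.0]), "cD4": np.array([0.5, -0.5]),
            "cD3": np.zeros(4), "cD2": np.zeros(8), "cD1": np.zeros(16)})
        s = band_statistics(decomp, "cA4")
        assert s["mean"] == 1.0 and s["var"] == 0.0 and s["rms"] == 1.0
        assert s["p5"] == 1.0 and s["p95"] == 1.0 and s["crossings"] == 0.0

    def test_alternating_band_crossings(self):
        decomp = WaveletDecomposition(bands={
            "cA4": np.array([-1.0, 1.0, -1.0, 1.0]), "cD4": np.zeros(2),
            "cD3": np.zeros(4), "cD2": np.zeros(8), "cD1": np.zeros(16)})
        s = band_statistics(decomp, "cA4")
        assert s["mean"] == 0.0 and s["var"] == 1.0 and s["crossings"] == 3.0

    def test_point_mass_power_entropy(self):
        decomp = WaveletDecomposition(bands={
            "cA4": np.array([2.0, -2.0]), "cD4": np.zeros(2),
            "cD3": np.zeros(4), "cD2": np.zeros(8), "cD1": np.zeros(16)})
        assert band_statistics(decomp, "cA4")["relpow"] == 1.0
        assert band_statistics(decomp, "cA4")["entropy"] == 0.0
        assert band_statistics(decomp, "cD1")["relpow"] == 0.0
        assert band_statistics(decomp, "cD1")["entropy"] == 0.0

    def test_rms_literal_form(self, rng):
        x = rng.normal(size=256)
        decomp = dwt_decompose(x)
        true_rms = band_statistics(decomp, "cA4")["rms"]
        literal = band_statistics(decomp, "cA4", rms_literal=True)["rms"]
        assert literal == pytest.approx(true_rms ** 2, rel=1e-12)


class TestStimulationFeatures:
    def test_length_is_52(self, rng):
        feats = extract_stimulation_features(rng.normal(size=2975), 0.2, 40.0)
        assert feats.shape == (52,)
        assert len(STIM_FEATURE_NAMES) == 52

    def test_zero_waveform(self):
        feats = extract_stimulation_features(np.zeros(2975), 0.2, 40.0)
        named = dict(zip(STIM_FEATURE_NAMES, feats))
        assert all(named[f"{b}_{s}"] == 0.0 for b in BANDS for s in STAT_NAMES)
        assert named["stim_duration"] == 0.2 and named["stim_amplitude"] == 40.0

    def test_deterministic(self, rng):
        x = rng.normal(size=2975)
        a = extract_stimulation_features(x, 0.2, 40.0)
        b = extract_stimulation_features(x.copy(), 0.2, 40.0)
        np.testing.assert_array_equal(a, b)

    def test_m_features_invariant_to_f_parameters(self):
        base = dict(nerve=Nerve.ULNAR, m_onset_latency=3.5, m_amplitude=8.0,
                    m_duration=9.0, f_present=True, f_amplitude=0.9, noise_sd=0.0)
        segments = []
        for f_lat in (26.0, 40.0):
            wf, _ = generate_waveform(WaveformParams(f_onset_latency=f_lat, **base), 0)
            pair = split_m_f(preprocess(wf))
            segments.append((pair.m_segment.samples, pair.f_segment.samples))
        m_a = extract_stimulation_features(segments[0][0], 0.2, 40.0)
        m_b = extract_stimulation_features(segments[1][0], 0.2, 40.0)
        np.testing.assert_array_equal(m_a, m_b)
        f_a = extract_stimulation_features(segments[0][1], 0.2, 40.0)
        f_b = extract_stimulation_features(segments[1][1], 0.2, 40.0)
        assert not np.array_equal(f_a, f_b)


class TestAggregateSession:
    DEMO = {"age": 60.0, "sex": "male", "bmi": 25.0, "source": "natus"}

    def test_identical_stimulations_zero_sd(self, rng):
        v = rng.normal(size=52)
        out = aggregate_session({Nerve.ULNAR: np.tile(v, (5, 1))}, self.DEMO)
        means = out[[f"ulnar_{f}_mean" for f in STIM_FEATURE_NAMES]].to_numpy(dtype=float)
        sds = out[[f"ulnar_{f}_sd" for f in STIM_FEATURE_NAMES]].to_numpy(dtype=float)
        np.testing.assert_allclose(means, v, atol=1e-12)
        np.testing.assert_allclose(sds, np.zeros(52), atol=1e-12)

    def test_four_nerve_session_has_420_values(self, rng):
        per_nerve = {n: rng.normal(size=(6, 52)) for n in NERVE_ORDER}
        out = aggregate_session(per_nerve, self.DEMO)
        assert len(out) == 420
        assert len(SESSION_FEATURE_COLUMNS) == 420
        assert out.notna().sum() == 420

    def test_two_nerve_session_missingness(self, rng):
        per_nerve = {Nerve.FIBULAR: rng.normal(size=(5, 52)), Nerve.TIBIAL: rng.normal(size=(5, 52))}
        out = aggregate_session(per_nerve, self.DEMO)
        numeric = out.drop(list(DEMOGRAPHIC_COLUMNS))
        assert numeric.notna().sum() == 208
        assert numeric.isna().sum() == 208

    def test_permutation_invariant(self, rng):
        feats = rng.normal(size=(7, 52))
        a = aggregate_session({Nerve.ULNAR: feats}, self.DEMO)
        b = aggregate_session({Nerve.ULNAR: feats[::-1]}, self.DEMO)
        numeric_cols = [c for c in a.index if c not in DEMOGRAPHIC_COLUMNS]
        np.testing.assert_allclose(a[numeric_cols].to_numpy(dtype=float),
                                   b[numeric_cols].to_numpy(dtype=float), atol=1e-12)

    def test_single_stimulation_warns_sd_zero(self, rng):
        with pytest.warns(UserWarning, match="single stimulation"):
            out = aggregate_session({Nerve.ULNAR: rng.normal(size=(1, 52))}, self.DEMO)
        assert out["ulnar_cA4_mean_sd"] == 0.0


class TestAnnotationFeatures:
    def test_fixture_table_contracts(self, fixture_sessions):
        table = annotations_to_table(fixture_sessions)
        assert len(table) == len(fixture_sessions)
        # latency mean equals arithmetic mean of per-stim latencies
        s = fixture_sessions[0]
        nerve = s.nerves[0]
        lats = [a.m_neg_peak[0] for a in s.annotations[nerve]]
        col = f"{nerve.value}_m_neg_peak_latency_mean"
        assert table.iloc[0][col] == pytest.approx(np.mean(lats), abs=1e-12)

    def test_absent_f_waves_are_missing(self):
        from fwave.synthetic import PRESETS, generate_session
        preset = dataclasses.replace(PRESETS["control"], f_persistence=0.0)
        s = generate_session(preset, dict(age=60, sex="male", bmi=25),
                             dict(nerves=["ulnar"], stimulations_per_nerve=5), 0)
        table = annotations_to_table([s])
        assert np.isnan(table.iloc[0]["ulnar_f_onset_latency_mean"])
        assert not np.isnan(table.iloc[0]["ulnar_m_onset_latency_mean"])


class TestTableTransform:
    def make_table(self, rng, n=40, missing=False):
        table = pd.DataFrame({
            "a": rng.normal(5.0, 2.0, size=n),
            "b": rng.normal(size=n),
            "sex": rng.choice(["male", "female"], size=n),
            "source": rng.choice(["natus", "cadwell"], size=n),
        })
        if missing:
            table.loc[0, "a"] = np.nan
        return table

    def test_no_missing_imputation_is_identity(self, rng):
        table = self.make_table(rng)
        tf = TableTransform(n_neighbors=10).fit(table)
        out = tf.transform(table)
        # invert the scaling: recovered values equal the originals
        recovered = out[["a", "b"]].to_numpy() * tf.scaler_.scale_ + tf.scaler_.mean_
        np.testing.assert_allclose(recovered, table[["a", "b"]].to_numpy(), atol=1e-9)

    def test_standardization_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        a = (a - a.mean()) / a.std() * 2.0 + 5.0  # exact mean 5, SD 2
        table = pd.DataFrame({"a": a, "sex": ["male"] * 30, "source": ["natus"] * 30})
        tf = TableTransform(n_neighbors=10).fit(table)
        probe = table.iloc[[0]].copy()
        probe.loc[probe.index[0], "a"] = 9.0
        assert tf.transform(probe)["a"].iloc[0] == pytest.approx(2.0, abs=1e-9)

    def test_knn_imputation_matches_brute_force(self, rng):
        n = 60
        X = rng.normal(size=(n, 4))
        cols = ["c0", "c1", "c2", "c3"]
        table = pd.DataFrame(X, columns=cols)
        table["sex"] = "male"
        table["source"] = "natus"
        masked = table.copy()
        masked.loc[0, "c2"] = np.nan
        tf = TableTransform(n_neighbors=10).fit(masked)
        imputed = tf.imputer_.transform(masked[cols].to_numpy())[0, 2]
        # brute force: 10 nearest complete rows by euclidean distance on the
        # observed coordinates, mean of their c2 values
        others = X[1:]
        d = np.sqrt(((others[:, [0, 1, 3]] - X[0, [0, 1, 3]]) ** 2).sum(axis=1))
        nearest = np.argsort(d)[:10]
        assert imputed == pytest.approx(others[nearest, 2].mean(), abs=1e-9)

    def test_too_few_rows_rejected(self, rng):
        table = self.make_table(rng, n=8)
        with pytest.raises(ValueError, match="n_neighbors"):
            TableTransform(n_neighbors=10).fit(table)

    def test_missing_columns_reported(self, rng):
        table = self.make_table(rng)
        tf = TableTransform(n_neighbors=10).fit(table)
        with pytest.raises(ValueError, match="missing columns"):
            tf.transform(table.drop(columns=["b"]))


class TestSessionTable:
    def test_fixture_table_shape_and_missingness(self, fixture_sessions):
        table = sessions_to_table(fixture_sessions)
        assert table.shape == (12, 421)  # 420 features + label
        two_nerve = table.drop(columns=["label"]).isna().sum(axis=1)
        assert (two_nerve > 0).any()  # missing-nerve sessions present

    def test_no_wave_variant_is_demographics_only(self, fixture_sessions):
        table = sessions_to_table(fixture_sessions, variant="no_wave")
        assert list(table.columns) == list(DEMOGRAPHIC_COLUMNS) + ["label"]
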