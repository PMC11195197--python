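import json
import math

import numpy as np
import pytest
from scipy import stats

from fbekit.adjacency import find_pairs, scan_peak
from fbekit.motif import FBE_PATTERNS, match_positions, scan_all
from fbekit.peak_stats import pooled_t_test
from fbekit.synthetic import (
    UNIFORM_COMPOSITION,
    UTR_COMPOSITION,
    PeakSimSpec,
    PlantPlan,
    ProfileShape,
    default_plans,
    expected_match_probability,
    gen_background,
    gen_emsa,
    gen_fret,
    gen_itc,
    gen_peakset,
    gen_profiles,
    plant_pair,
    realize_element,
)


class TestGenBackground:
    def test_zero_length(self):
        assert gen_background(0) == ""

    def test_determinism(self):
        assert gen_background(500, seed=42) == gen_background(500, seed=42)
        assert gen_background(500, seed=42) != gen_background(500, seed=43)

    def test_uniform_base_frequencies(self):
        seq = gen_background(40_000, seed=1)
        for base in "ACGU":
            freq = seq.count(base) / len(seq)
            sd = math.sqrt(0.25 * 0.75 / 40_000)
            assert abs(freq - 0.25) < 3 * sd

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            gen_background(10, {"A": 0.5, "C": 0.5, "G": 0.5, "U": -0.5})


class TestRealizeElement:
    @pytest.mark.parametrize("name", list(FBE_PATTERNS))
    def test_realizations_match_their_class(self, name):
        for seed in range(20):
            elem = realize_element(name, seed)
            assert len(elem) == FBE_PATTERNS[name].length
            assert match_positions(elem, FBE_PATTERNS[name])

    def test_fbea_core_is_a_valid_canonical_draw(self):
        from fbekit.reference_data import GLD1_FBEA_CORE

        assert match_positions(GLD1_FBEA_CORE, FBE_PATTERNS["FBE9"])

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            realize_element("FBE7")


class TestPlantPair:
    def test_reproduces_gld1_core_geometry(self, gld1_rna):
        from fbekit.reference_data import GLD1_FBEA_CORE, GLD1_FBEASTAR_CORE

        bg = gen_background(29, {"A": 1.0, "C": 0.0, "G": 0.0, "U": 0.0})
        seq, (s5, s3) = plant_pair(bg, GLD1_FBEA_CORE, GLD1_FBEASTAR_CORE, 5, 4)
        assert (s5, s3) == (4, 18)
        pairs = find_pairs(scan_all(seq))
        assert len(pairs) == 1 and pairs[0].gap == 5
        # planted region matches the natural arrangement
        assert seq[4:13] == gld1_rna[4:13] and seq[18:28] == gld1_rna[18:28]

    def test_geometry_violation_rejected(self):
        with pytest.raises(ValueError, match="nt"):
            plant_pair("ACGU" * 5, "UGUGCCAUA", "UGUGCCAUA", gap=5, offset=0)


class TestExpectedMatchProbability:
    def test_ugu_anchor_closed_form(self):
        from fbekit.motif import ConsensusPattern

        p = expected_match_probability(ConsensusPattern("anchor", "UGU"))
        assert p == pytest.approx((1 / 4) ** 3)

    def test_canonical_element_closed_form(self):
        # (1/4)^3 * (1/2) * 1 * 1 * (1/4) * (1/4) * 1 = 2^-11
        p = expected_match_probability(FBE_PATTERNS["FBE9"])
        assert p == pytest.approx(2**-11)

    def test_monte_carlo_agreement(self):
        # 10^6 random 9-mers, vectorized: empirical match rate of the
        # canonical pattern within a 99% binomial band of 2^-11
        n = 1_000_000
        rng = np.random.default_rng(9)
        mat = rng.integers(0, 4, size=(n, 9))  # 0=A 1=C 2=G 3=U
        code = {"A": 0, "C": 1, "G": 2, "U": 3}
        ok = np.ones(n, bool)
        for j, sym in enumerate(FBE_PATTERNS["FBE9"].symbols):
            allowed = [code[b] for b in {"R": "AG", "Y": "CU", "n": "ACGU"}.get(sym, sym)]
            ok &= np.isin(mat[:, j], allowed)
        p_hat = ok.mean()
        p = 2**-11
        assert abs(p_hat - p) < 2.576 * math.sqrt(p * (1 - p) / n)

    def test_composition_weighting(self):
        from fbekit.motif import ConsensusPattern

        p = expected_match_probability(ConsensusPattern("anchor", "UGU"), UTR_COMPOSITION)
        assert p == pytest.approx(0.4 * 0.15 * 0.4)


class TestGenPeakset:
    def test_empty_spec(self):
        peaks, truth = gen_peakset(PeakSimSpec(n_peaks=0), seed=0)
        assert peaks == [] and truth.planted == {}

    def test_determinism_and_sidecar(self):
        spec = PeakSimSpec(n_peaks=20, planted=default_plans(5, seed=0))
        p1, t1 = gen_peakset(spec, seed=3)
        p2, t2 = gen_peakset(spec, seed=3)
        assert [x.sequence for x in p1] == [x.sequence for x in p2]
        assert t1.to_json() == t2.to_json()
        payload = json.loads(t1.to_json())
        assert payload["kind"] == "peakset" and len(payload["planted"]) == 5

    def test_planted_coordinates_rescanned_exactly(self):
        spec = PeakSimSpec(
            n_peaks=40, planted=default_plans(40, gaps=tuple(range(1, 21)), seed=1)
        )
        peaks, truth = gen_peakset(spec, seed=5)
        for peak in peaks:
            rec = truth.planted[peak.peak_id]
            _, pairs = scan_peak(peak)
            assert any(
                p.upstream.start == rec["start_5p"]
                and p.downstream.start == rec["start_3p"]
                and p.gap == rec["gap"]
                for p in pairs
            ), f"{peak.peak_id}: planted pair not re-detected"

    def test_scan_summary_equals_oracle_rescan(self):
        # 50 planted + 50 background peaks: peaks with pairs = planted
        # count plus brute-force-verified background coincidences
        from conftest import regex_scan

        spec = PeakSimSpec(n_peaks=100, planted=default_plans(50, seed=2))
        peaks, truth = gen_peakset(spec, seed=6)
        flagged = {p.peak_id for p, prs in map(scan_peak, peaks) if prs}
        oracle_flagged = set()
        for peak in peaks:
            matches = [
                m
                for pat in FBE_PATTERNS.values()
                for m in regex_scan(peak.sequence, pat, peak.peak_id)
            ]
            if find_pairs(matches):
                oracle_flagged.add(peak.peak_id)
        assert flagged == oracle_flagged
        assert set(truth.planted) <= flagged

    def test_null_multiplier_gives_uniform_pvalues(self):
        # multiplier 1: planted vs background heights indistinguishable;
        # p-values over 100 seeds are uniform (KS test)
        pvals = []
        for seed in range(100):
            spec = PeakSimSpec(
                n_peaks=100,
                planted=default_plans(50, seed=seed),
                adjacent_multiplier=1.0,
            )
            peaks, truth = gen_peakset(spec, seed=seed)
            planted = [p.height_wt for p in peaks if p.peak_id in truth.planted]
            background = [p.height_wt for p in peaks if p.peak_id not in truth.planted]
            pvals.append(pooled_t_test(planted, background).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_at_reference_effect_size(self):
        # multiplier 4, 500 planted vs 500 background, logsd 1: the pooled
        # t-test rejects at alpha=0.001 in >= 99% of 100 seeds
        rejections = 0
        for seed in range(100):
            spec = PeakSimSpec(
                n_peaks=1000,
                planted=default_plans(500, seed=seed),
                adjacent_multiplier=4.0,
            )
            peaks, truth = gen_peakset(spec, seed=seed)
            planted = [p.height_wt for p in peaks if p.peak_id in truth.planted]
            background = [p.height_wt for p in peaks if p.peak_id not in truth.planted]
            if pooled_t_test(planted, background).p_value < 0.001:
                rejections += 1
        assert rejections >= 99

    def test_false_positive_rate_matches_analytic(self):
        # element-free background: per-pattern match counts over 1,000
        # sequences within a 99% band of (L - m + 1) * p
        n_seqs, length = 1000, 150
        rng = np.random.default_rng(12)
        seqs = [
            "".join(rng.choice(list("ACGU"), length)) for _ in range(n_seqs)
        ]
        for pattern in FBE_PATTERNS.values():
            p = expected_match_probability(pattern, UNIFORM_COMPOSITION)
            offsets = length - pattern.length + 1
            expected = n_seqs * offsets * p
            sd = math.sqrt(n_seqs * offsets * p * (1 - p))
            observed = sum(len(match_positions(s, pattern)) for s in seqs)
            assert abs(observed - expected) < 2.576 * sd, pattern.name


class TestMeasurementGenerators:
    def test_itc_zero_noise_equals_forward_model(self):
        from fbekit.binding import BindingParams, one_site_heats, standard_schedule

        params = BindingParams(0.5, 1.1e-6, -61.9)
        series, truth = gen_itc(params)
        assert np.allclose(series.heats, one_site_heats(params, standard_schedule()))
        assert truth.params["kd"] == 1.1e-6

    def test_emsa_zero_noise_equals_forward_model(self):
        from fbekit.binding import one_site_specific

        curve, _ = gen_emsa(0.9, 131e-9)
        expected = one_site_specific(0.9, 131e-9, np.array(curve.protein_concs))
        assert np.allclose(curve.fraction_bound, expected)

    def test_fret_zero_noise_exact(self):
        from fbekit.binding import fret_efficiency

        rows, _ = gen_fret(0.25, total_intensity=400.0)
        for i564, i668 in rows:
            assert (i564, i668) == (300.0, 100.0)
            assert fret_efficiency(i564, i668) == 0.25

    def test_profiles_zero_noise_equals_shape(self):
        shape = ProfileShape()
        profs, _ = gen_profiles({"wt": shape}, n_gonads=2, noise_sd=0.0, seed=0)
        expected = shape.evaluate(np.asarray(profs[0].positions))
        assert np.allclose(profs[0].intensities, expected)

    @pytest.mark.parametrize(
        "call",
        [
            lambda: gen_itc(None, noise_frac=-0.1),
            lambda: gen_emsa(1.0, 1e-7, noise_sd=-1.0),
            lambda: gen_fret(0.5, noise_sd=-1.0),
            lambda: gen_profiles({"wt": ProfileShape()}, noise_sd=-1.0),
        ],
    )
    def test_negative_noise_rejected(self, call):
        with pytest.raises(ValueError):
            call()

    def test_generators_are_pure_in_seed(self):
        from fbekit.binding import BindingParams

        params = BindingParams(0.5, 1e-6, -60.0)
        s1, _ = gen_itc(params, noise_frac=0.02, seed=7)
        s2, _ = gen_itc(params, noise_frac=0.02, seed=7)
        assert s1.heats == s2.heats
        c1, _ = gen_emsa(1.0, 4e-7, noise_sd=0.05, seed=7)
        c2, _ = gen_emsa(1.0, 4e-7, noise_sd=0.05, seed=7)
        assert c1.fraction_bound == c2.fraction_bound
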