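"""The NAC statistic: normalization, dosage ratio, calibration, gain call."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from her2cn import (
    Cohort,
    DegenerateInputError,
    Her2Class,
    NacCopyNumberModel,
    NacThreshold,
    SampleCoverage,
    SimulationConfig,
    calibrate_threshold,
    classify_nac,
    erbb2_tp53_ratio,
    gene_nac,
    normalized_amplicon_coverage,
    simulate_cohort,
)


def make_sample(counts, sid="s", cohort=Cohort.tumor):
    return SampleCoverage(sid, cohort, counts)


def panel_sample(panel, erbb2_counts, tp53_counts, **kw):
    counts = dict(
        zip([a.amplicon_id for a in panel.amplicons_for("ERBB2")], erbb2_counts)
    )
    counts.update(
        zip([a.amplicon_id for a in panel.amplicons_for("TP53")], tp53_counts)
    )
    return make_sample(counts, **kw)


count_dicts = st.dictionaries(
    st.text(alphabet="abcdefgh", min_size=1, max_size=2),
    st.integers(min_value=0, max_value=10_000),
    min_size=2,
    max_size=8,
).filter(lambda d: sum(d.values()) > 0)


class TestNormalization:
    def test_uniform_counts_normalize_to_one(self):
        nac = normalized_amplicon_coverage(make_sample({"a": 100, "b": 100, "c": 100}))
        assert nac == {"a": 1.0, "b": 1.0, "c": 1.0}

    def test_hand_arithmetic(self):
        nac = normalized_amplicon_coverage(make_sample({"a": 100, "b": 200, "c": 300}))
        assert nac == {"a": 0.5, "b": 1.0, "c": 1.5}

    @settings(derandomize=True, max_examples=200)
    @given(counts=count_dicts)
    def test_mean_nac_is_one(self, counts):
        nac = normalized_amplicon_coverage(make_sample(counts))
        assert np.mean(list(nac.values())) == pytest.approx(1.0, abs=1e-12)

    def test_zero_coverage_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalized_amplicon_coverage(make_sample({}))


class TestGeneNac:
    def test_unweighted_mean(self, panel):
        nac = {a.amplicon_id: v
               for a, v in zip(panel.amplicons_for("ERBB2"), (0.4, 0.5, 0.6))}
        assert gene_nac(nac, panel, "ERBB2") == pytest.approx(0.5)

    def test_single_amplicon_gene_is_identity(self):
        from her2cn import default_panel

        p = default_panel(n_background=1)
        assert gene_nac({"BG1_amp1": 0.77}, p, "BG1") == 0.77

    def test_order_invariance(self, panel):
        ids = [a.amplicon_id for a in panel.amplicons_for("TP53")]
        vals = [0.1, 0.9, 0.4, 0.4, 0.7, 1.3, 0.2, 0.6]
        a = gene_nac(dict(zip(ids, vals)), panel, "TP53")
        b = gene_nac(dict(zip(reversed(ids), vals)), panel, "TP53")
        assert a == pytest.approx(b)

    def test_unknown_gene_raises(self, panel):
        with pytest.raises(KeyError):
            gene_nac({}, panel, "EGFR")


class TestDosageRatio:
    def test_symmetric_input_gives_one(self, panel):
        s = panel_sample(panel, [100] * 3, [100] * 8)
        assert erbb2_tp53_ratio(s, panel) == pytest.approx(1.0)

    def test_hand_arithmetic_ratio_two(self, panel):
        s = panel_sample(panel, [100] * 3, [50] * 8)
        assert erbb2_tp53_ratio(s, panel) == pytest.approx(2.0)

    def test_noiseless_dosage_gives_half_copy_number(self, panel):
        # expected counts at cn 12, purity 1: ERBB2 amplicons carry 6x the
        # diploid depth -> ratio 12/2 = 6 exactly
        s = panel_sample(panel, [6000] * 3, [1000] * 8)
        assert erbb2_tp53_ratio(s, panel) == pytest.approx(6.0)

    def test_zero_tp53_coverage_rejected(self, panel):
        s = panel_sample(panel, [100] * 3, [0] * 8)
        with pytest.raises(DegenerateInputError, match="TP53"):
            erbb2_tp53_ratio(s, panel)

    @settings(derandomize=True, max_examples=100)
    @given(
        erbb2=st.lists(st.integers(1, 5000), min_size=3, max_size=3),
        tp53=st.lists(st.integers(1, 5000), min_size=8, max_size=8),
        scale=st.integers(2, 50),
    )
    def test_scale_invariance(self, erbb2, tp53, scale, panel):
        s1 = panel_sample(panel, erbb2, tp53)
        s2 = panel_sample(panel, [c * scale for c in erbb2], [c * scale for c in tp53])
        r1, r2 = erbb2_tp53_ratio(s1, panel), erbb2_tp53_ratio(s2, panel)
        assert r1 == pytest.approx(r2, rel=1e-12)
        n1 = normalized_amplicon_coverage(s1)
        n2 = normalized_amplicon_coverage(s2)
        assert n1 == pytest.approx(n2, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        erbb2=st.lists(st.integers(1, 5000), min_size=3, max_size=3),
        tp53=st.lists(st.integers(1, 5000), min_size=8, max_size=8),
    )
    def test_normalize_then_average_equals_direct_count_ratio(self, erbb2, tp53, panel):
        # the stated order of operations (normalize -> gene means -> ratio)
        # is algebraically a plain ratio of the genes' mean raw counts
        s = panel_sample(panel, erbb2, tp53)
        direct = (sum(erbb2) / 3) / (sum(tp53) / 8)
        assert erbb2_tp53_ratio(s, panel) == pytest.approx(direct, rel=1e-12)

    def test_ratio_strictly_increasing_in_erbb2_count(self, panel):
        base = panel_sample(panel, [100, 100, 100], [100] * 8)
        bumped = panel_sample(panel, [101, 100, 100], [100] * 8)
        assert erbb2_tp53_ratio(bumped, panel) > erbb2_tp53_ratio(base, panel)


class TestCalibration:
    def _controls_with_ratios(self, panel, ratios):
        return [
            panel_sample(panel, [int(round(100 * r))] * 3, [100] * 8,
                         sid=f"c{i}", cohort=Cohort.control)
            for i, r in enumerate(ratios)
        ]

    def test_identical_controls_give_zero_sd(self, panel):
        t = calibrate_threshold(self._controls_with_ratios(panel, [0.8, 0.8, 0.8]), panel)
        assert t.value == pytest.approx(0.8)
        assert t.control_sd == pytest.approx(0.0)

    def test_hand_arithmetic_with_sample_sd(self, panel):
        # ratios 0.9, 1.0, 1.1: mean 1.0, sample SD 0.1 -> threshold 1.2
        t = calibrate_threshold(self._controls_with_ratios(panel, [0.9, 1.0, 1.1]), panel)
        assert t.value == pytest.approx(1.2)
        assert (t.control_n, t.control_mean) == (3, pytest.approx(1.0))
        assert t.control_sd == pytest.approx(0.1)

    def test_fewer_than_two_controls_rejected(self, panel):
        with pytest.raises(ValueError, match="2 controls"):
            calibrate_threshold(self._controls_with_ratios(panel, [1.0]), panel)

    def test_simulated_diploid_recovery_matches_analytic_threshold(self, panel):
        # flat efficiencies: control ratios center on 1 with analytic spread
        # sd ~= sqrt((1/3 + 1/8) * (1/depth + dispersion))
        depth, d = 2000.0, 0.05
        sigma = np.sqrt((1 / 3 + 1 / 8) * (1 / depth + d))
        thresholds = []
        for seed in range(200):
            cfg = SimulationConfig(
                seed=seed, n_tumors=0, n_controls=12, mean_depth_control=depth,
                dispersion=d, efficiency_sd=0.0,
            )
            samples, _ = simulate_cohort(cfg, panel)
            thresholds.append(calibrate_threshold(samples, panel).value)
        assert np.mean(thresholds) == pytest.approx(1.0 + 2 * sigma, rel=0.05)


class TestGainCall:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.88, Her2Class.negative),   # below the published cutoff
            (1.12, Her2Class.negative),   # amplified case the assay misses
            (2.44, Her2Class.positive),
            (1.18, Her2Class.negative),   # boundary: strictly-greater rule
        ],
    )
    def test_published_cutoff_calls(self, ratio, expected):
        assert classify_nac(ratio, 1.18) is expected

    def test_never_equivocal(self):
        for r in np.linspace(0.0, 10.0, 101):
            assert classify_nac(r, 1.18) is not Her2Class.equivocal


class TestModelResults:
    def test_fit_calibrates_from_controls(self, panel):
        cfg = SimulationConfig(seed=21, n_tumors=10, n_controls=12)
        samples, _ = simulate_cohort(cfg, panel)
        res = NacCopyNumberModel(samples, panel).fit()
        t = res.threshold
        assert t.control_n == 12
        assert t.value == pytest.approx(t.control_mean + 2 * t.control_sd)
        assert len(res.frame) == 22
        assert set(res.frame["her2_class"]) <= {"negative", "positive"}

    def test_fixed_threshold_skips_controls(self, panel):
        s = panel_sample(panel, [300] * 3, [100] * 8)
        res = NacCopyNumberModel([s], panel, threshold=1.18).fit()
        assert res.threshold.control_n is None
        assert res.calls["s"] is Her2Class.positive

    def test_summary_reports_calibration_provenance(self, panel):
        cfg = SimulationConfig(seed=21, n_tumors=4, n_controls=12)
        samples, _ = simulate_cohort(cfg, panel)
        text = NacCopyNumberModel(samples, panel).fit().summary()
        assert "mean + 2*SD over 12 controls" in text
        assert "3 ERBB2, 8 TP53" in text

    def test_missing_controls_without_threshold_raises(self, panel):
        s = panel_sample(panel, [300] * 3, [100] * 8)
        with pytest.raises(ValueError, match="controls"):
            NacCopyNumberModel([s], panel).fit()

    def test_from_files_roundtrip(self, panel, tmp_path):
        from her2cn import write_coverage_matrix
        from her2cn.datamodel import write_panel

        cfg = SimulationConfig(seed=2, n_tumors=3, n_controls=4)
        samples, _ = simulate_cohort(cfg, panel)
        write_coverage_matrix(samples, tmp_path / "cov.tsv")
        write_panel(panel, tmp_path / "panel.tsv")
        controls = [s.sample_id for s in samples if s.cohort is Cohort.control]
        model = NacCopyNumberModel.from_files(
            tmp_path / "cov.tsv", tmp_path / "panel.tsv", control_ids=controls
        )
        res = model.fit()
        direct = NacCopyNumberModel(samples, panel).fit()
        assert res.threshold.value == pytest.approx(direct.threshold.value)
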