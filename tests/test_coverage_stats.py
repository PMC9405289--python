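"""Double-normalized exon coverage and the downstream-coverage criterion."""

import numpy as np
import pytest
from scipy import stats

from fusiontriage import (
    CohortBaseline,
    ExonCoverageProfile,
    SimulationConfig,
    asymmetry_ttest,
    cohort_pattern,
    downstream_criterion,
    exon_counts,
    moiety_expression,
    normalize,
    simulate_coverage,
    split_at_junction,
)
from fusiontriage.coverage_stats import (
    NORM_DEPTH,
    NORM_GENE,
    read_counts_table,
    read_sample_manifest,
    write_counts_table,
)
from fusiontriage.fusion_annotation import FusionCall


class TestNormalize:
    def test_depth_mode_is_reads_per_kb_per_million(self):
        vals = normalize([100, 100], [1000, 1000], depth=1_000_000)
        assert vals == pytest.approx([100.0, 100.0])
        # 50 reads on a 500 nt exon at 10M depth: 50/0.5/10 = 10
        assert normalize([50], [500], depth=10_000_000) == pytest.approx([10.0])

    def test_gene_mode_uniform_counts_equal_lengths_all_equal(self):
        vals = normalize([7, 7, 7], [120, 120, 120], norm_mode=NORM_GENE)
        assert np.allclose(vals, vals[0])

    def test_gene_mode_zero_gene_is_all_zeros(self):
        vals = normalize([0, 0, 0], [100, 100, 100], norm_mode=NORM_GENE)
        assert np.all(vals == 0)

    def test_gene_mode_length_weighted_sum_is_one(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 500, size=12)
        lengths = rng.integers(50, 400, size=12)
        vals = normalize(counts, lengths, norm_mode=NORM_GENE)
        assert np.sum(vals * lengths) == pytest.approx(1.0)

    def test_scale_equivariance(self):
        counts = np.array([10, 40, 25])
        lengths = np.array([100, 200, 150])
        d = normalize(counts, lengths, depth=5e6)
        d2 = normalize(2 * counts, lengths, depth=5e6)
        assert np.allclose(d2, 2 * d)
        g = normalize(counts, lengths, norm_mode=NORM_GENE)
        g2 = normalize(2 * counts, lengths, norm_mode=NORM_GENE)
        assert np.allclose(g2, g)

    def test_depth_required_and_positive(self):
        with pytest.raises(ValueError, match="depth"):
            normalize([1], [100], depth=0)
        with pytest.raises(ValueError, match="depth"):
            normalize([1], [100])


class TestSplit:
    def test_twenty_exons_junction_twelve(self):
        up, down = split_at_junction(np.arange(20), 12)
        assert len(up) == 11 and len(down) == 9

    def test_junction_at_two_leaves_one_upstream(self):
        up, down = split_at_junction([1.0, 2.0, 3.0], 2)
        assert list(up) == [1.0] and list(down) == [2.0, 3.0]

    def test_junction_at_one_gives_nd_asymmetry(self):
        up, down = split_at_junction([1.0, 2.0, 3.0], 1)
        res = asymmetry_ttest(up, down)
        assert res.criterion_met == "ND" and res.reason == "no upstream exons"

    def test_out_of_range_junction_rejected(self):
        with pytest.raises(ValueError, match="junction"):
            split_at_junction([1.0, 2.0], 5)


class TestAsymmetryTtest:
    def test_equal_distributions_give_half_p(self):
        res = asymmetry_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)
        assert res.criterion_met == "no"

    def test_matches_hand_computed_welch_formula(self):
        rng = np.random.default_rng(5)
        up = 1.0 + 0.1 * rng.standard_normal(10)
        down = 10.0 + 1.0 * rng.standard_normal(10)
        res = asymmetry_ttest(up, down)
        vu, vd = up.var(ddof=1), down.var(ddof=1)
        nu, nd = len(up), len(down)
        se2 = vd / nd + vu / nu
        t = (down.mean() - up.mean()) / np.sqrt(se2)
        df = se2**2 / ((vd / nd) ** 2 / (nd - 1) + (vu / nu) ** 2 / (nu - 1))
        p = stats.t.sf(t, df)
        assert res.t_statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)
        assert p < 0.001 and res.criterion_met == "yes"
        assert res.direction == "downstream_greater"

    def test_downstream_lower_never_fires(self):
        rng = np.random.default_rng(6)
        up = 10.0 + rng.standard_normal(10)
        down = 1.0 + 0.1 * rng.standard_normal(10)
        res = asymmetry_ttest(up, down)
        assert res.direction == "upstream_greater"
        assert res.criterion_met == "no"

    def test_single_exon_side_is_insufficient(self):
        res = asymmetry_ttest([1.0], [5.0, 6.0, 7.0])
        assert res.criterion_met == "no" and res.reason == "insufficient exons"

    def test_constant_sides_do_not_fire(self):
        res = asymmetry_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.criterion_met == "no"
        assert "zero variance" in res.reason


def _profiles(seed=9, fold=10.0, cv=0.1, n_exons=20, k=11, n_controls=20,
              mode=NORM_GENE):
    cfg = SimulationConfig(
        n_exons=n_exons, junction_exon=k, fold_change=fold, noise_cv=cv,
        n_controls=n_controls, seed=seed,
    )
    return simulate_coverage(cfg, norm_mode=mode)


class TestCohort:
    def test_baseline_matches_independent_computation(self):
        fusion, controls = _profiles()
        base = CohortBaseline.from_profiles(controls)
        mat = np.vstack([p.values for p in controls])
        n = len(controls)
        assert np.allclose(base.mean, mat.mean(axis=0))
        assert np.allclose(base.p95, np.quantile(mat, 0.95, axis=0))
        half = stats.t.ppf(0.975, n - 1) * mat.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.allclose(base.ci_high - base.mean, half)
        assert np.all(base.ci_low <= base.mean) and np.all(base.mean <= base.ci_high)

    @staticmethod
    def _hand_cohort(seed=17, n_exons=20, n_controls=20):
        # controls ~ N(100, 10) counts per exon; unit lengths/depth factors
        # make depth-mode values equal counts
        rng = np.random.default_rng(seed)
        lengths = np.full(n_exons, 1000)
        controls = [
            ExonCoverageProfile(
                f"C{i}", "TX", rng.normal(100, 10, n_exons), lengths, 1_000_000
            )
            for i in range(n_controls)
        ]
        return controls, lengths

    def test_fusion_sample_with_strong_downstream_signal_fires(self):
        # upstream exons at the control mean, downstream at 10x: the
        # canonical promoter-swap signature
        controls, lengths = self._hand_cohort()
        base = CohortBaseline.from_profiles(controls)
        counts = np.full(20, 100.0)
        counts[10:] = 1000.0
        fusion = ExonCoverageProfile("F", "TX", counts, lengths, 1_000_000)
        assert cohort_pattern(fusion, base, 11) is True

    def test_gene_mode_deflates_upstream_share_under_strong_signal(self):
        # normalizing by total gene counts shrinks the fusion sample's
        # upstream share, so the strict upstream-within-CI condition fails
        # for a highly expressed partner; the t-test arm covers this case
        fusion, controls = _profiles(fold=10.0, mode=NORM_GENE)
        base = CohortBaseline.from_profiles(controls)
        assert cohort_pattern(fusion, base, 11) is False

    def test_cohort_mean_profile_does_not_fire(self):
        _, controls = _profiles(fold=1.0)
        base = CohortBaseline.from_profiles(controls)
        mean_profile = ExonCoverageProfile(
            "MEAN", controls[0].transcript_id,
            np.rint(np.vstack([p.counts for p in controls]).mean(axis=0)),
            controls[0].lengths, controls[0].depth, NORM_GENE,
        )
        assert cohort_pattern(mean_profile, base, 11) is False

    def test_unexpressed_gene_with_downstream_only_expression_fires(self):
        # the silent-partner pattern: controls do not express the gene at
        # all; the fusion sample expresses only the retained downstream exons
        lengths = np.full(10, 150)
        controls = [
            ExonCoverageProfile(f"C{i}", "TX", np.zeros(10), lengths, 1_000_000, NORM_GENE)
            for i in range(10)
        ]
        counts = np.zeros(10)
        counts[4:] = 50
        fusion = ExonCoverageProfile("F", "TX", counts, lengths, 1_000_000, NORM_GENE)
        base = CohortBaseline.from_profiles(controls)
        assert cohort_pattern(fusion, base, 5) is True

    def test_transcript_mismatch_rejected(self):
        fusion, controls = _profiles()
        base = CohortBaseline.from_profiles(controls)
        other = ExonCoverageProfile(
            "F", "OTHER", fusion.counts, fusion.lengths, fusion.depth, NORM_GENE
        )
        with pytest.raises(ValueError, match="does not match"):
            cohort_pattern(other, base, 11)

    def test_fraction_relaxes_strict_aggregation(self):
        controls, lengths = self._hand_cohort()
        base = CohortBaseline.from_profiles(controls)
        counts = np.full(20, 100.0)
        counts[10:] = 1000.0
        counts[-1] = 0.0  # one dropped downstream exon breaks the strict rule
        damaged = ExonCoverageProfile("F", "TX", counts, lengths, 1_000_000)
        assert cohort_pattern(damaged, base, 11) is False
        assert cohort_pattern(damaged, base, 11, fraction=0.8) is True


class TestDownstreamCriterion:
    @pytest.mark.parametrize("side,expected", [("5'", "ND"), ("none", "ND")])
    def test_not_defined_off_three_prime(self, side, expected):
        assert downstream_criterion(None, None, side) == expected

    def test_and_or_semantics(self):
        met = asymmetry_ttest([1.0, 1.1, 0.9], [10.0, 11.0, 9.0])
        not_met = asymmetry_ttest([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert downstream_criterion(not_met, True, "3'") == "yes"
        assert downstream_criterion(met, False, "3'") == "yes"
        assert downstream_criterion(not_met, False, "3'") == "no"
        assert downstream_criterion(not_met, False, "both") == "no"


class TestMoietyExpression:
    def _call(self, exon5=2, exon3=3):
        return FusionCall("S", "A", "T5", 0, exon5, "B", "T3", 0, exon3)

    def test_hand_computed_means(self):
        p5 = ExonCoverageProfile("S", "T5", [100, 200, 999], [1000] * 3, 1_000_000)
        p3 = ExonCoverageProfile("S", "T3", [5, 5, 300, 500], [1000] * 4, 1_000_000)
        m5, m3 = moiety_expression(self._call(), p5, p3)
        assert m5 == pytest.approx((100 + 200) / 2)  # retained exons 1..2
        assert m3 == pytest.approx((300 + 500) / 2)  # retained exons 3..4

    def test_identical_profiles_give_equal_means(self):
        p = ExonCoverageProfile("S", "T", [10, 10, 10, 10], [100] * 4, 1_000_000)
        m5, m3 = moiety_expression(self._call(exon5=4, exon3=1), p, p)
        assert m5 == pytest.approx(m3)

    def test_gene_mode_profiles_rejected(self):
        p = ExonCoverageProfile("S", "T", [1, 2], [100, 100], norm_mode=NORM_GENE)
        with pytest.raises(ValueError, match="depth-normalized"):
            moiety_expression(self._call(), p, p)


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr2\tLN:2000\n"


def _sam_line(qname, pos, cigar):
    return f"{qname}\t0\tchr2\t{pos}\t60\t{cigar}\t*\t0\t0\t{'A'*50}\t*\n"


class TestExonCounts:
    def test_empty_alignment_gives_zeros(self, toy_annotation, tmp_path):
        sam = tmp_path / "empty.sam"
        sam.write_text(SAM_HEADER)
        counts = exon_counts(sam, toy_annotation.get("RET-1"))
        assert list(counts) == [0, 0]

    def test_overlap_rule_matches_brute_force(self, toy_annotation, tmp_path):
        model = toy_annotation.get("RET-1")  # exon1 [1300,1450), exon2 [1000,1150)
        reads = [
            ("inside_e2", 1011, "50M"),        # [1010,1060) -> exon 2 only
            ("inside_e2b", 1090, "50M"),       # [1089,1139) -> exon 2 only
            ("inside_e1", 1301, "50M"),        # [1300,1350) -> exon 1 only
            ("edge_out", 1151, "50M"),         # [1150,1200) intron -> neither
            ("spliced", 1101, "25M175N25M"),   # spans both exons -> both
        ]
        sam = tmp_path / "reads.sam"
        sam.write_text(SAM_HEADER + "".join(_sam_line(*r) for r in reads))
        counts = exon_counts(sam, model)
        # brute force: overlap of [start,end) alignment spans with each exon
        spans = [(1010, 1060), (1089, 1139), (1300, 1350), (1150, 1200), (1100, 1325)]
        expected = [
            sum(s < e.end and e.start < t for s, t in spans) for e in model.exons
        ]
        assert list(counts) == expected == [2, 3]

    def test_missing_chromosome_names_it(self, toy_annotation, tmp_path):
        sam = tmp_path / "wrong.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:2000\n")
        with pytest.raises(ValueError, match="chr2"):
            exon_counts(sam, toy_annotation.get("RET-1"))


class TestTables:
    def test_counts_round_trip(self, tmp_path):
        rows = [("S1", "T1", 1, 10), ("S1", "T1", 2, 20), ("S2", "T1", 1, 5), ("S2", "T1", 2, 0)]
        path = tmp_path / "counts.tsv"
        write_counts_table(rows, path)
        table = read_counts_table(path)
        assert list(table[("S1", "T1")]) == [10, 20]
        assert list(table[("S2", "T1")]) == [5, 0]

    def test_non_contiguous_exons_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\ttranscript_id\texon_index\tcount\nS\tT\t1\t3\nS\tT\t3\t4\n")
        with pytest.raises(ValueError, match="non-contiguous"):
            read_counts_table(path)

    def test_manifest(self, tmp_path):
        path = tmp_path / "manifest.tsv"
        path.write_text("sample_id\tdepth\nS1\t30000000\n")
        assert read_sample_manifest(path) == {"S1": 30_000_000}
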