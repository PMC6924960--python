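import numpy as np
import pandas as pd
import pytest

from clipscore.annotation import TranscriptModel, Transcriptome
from clipscore.scoring import (
    RegressionFit,
    aggregate_and_classify,
    compute_cds_rpkm,
    compute_clip_scores,
    fit_abundance_regression,
    replicate_correlation,
    score_pipeline,
    windowed_abundance,
)
from clipscore.simulate import SimConfig, simulate_experiment, simulate_uniform_coverage
from clipscore.tables import AbundanceTable, TagCountTable


def _counts(rows):
    return TagCountTable(pd.DataFrame(
        rows, columns=["transcript_id", "replicate", "cre_pos", "cre_neg"]))


def _abundance(pairs, condition="wt", replicate="rep1"):
    return AbundanceTable(pd.DataFrame(
        [(t, condition, replicate, r) for t, r in pairs],
        columns=["transcript_id", "condition", "replicate", "rpkm"]))


class TestCdsRpkm:
    def test_hand_example(self):
        txome = Transcriptome([TranscriptModel("t1", "g1", 2500, 100, 2100),
                               TranscriptModel("bulk", "g0", 1000, 0, 1000)])
        counts = _counts([("t1", "rep1", 20, 0), ("bulk", "rep1", 2_000_000 - 20, 0)])
        rpkm = compute_cds_rpkm(counts, txome, "rep1")
        # (20 - 0) * 1e9 / (2000 * 2e6) = 5.0
        assert rpkm["t1"] == pytest.approx(5.0)

    def test_sentinel_background_exceeds_signal(self):
        txome = Transcriptome([TranscriptModel("t1", "g1", 2500, 100, 2100),
                               TranscriptModel("bulk", "g0", 1000, 0, 1000)])
        counts = _counts([("t1", "rep1", 3, 5), ("bulk", "rep1", 1000, 10)])
        assert compute_cds_rpkm(counts, txome, "rep1")["t1"] == 1.0

    def test_sentinel_no_reads_either_library(self):
        txome = Transcriptome([TranscriptModel("t1", "g1", 2500, 100, 2100),
                               TranscriptModel("bulk", "g0", 1000, 0, 1000)])
        counts = _counts([("t1", "rep1", 0, 0), ("bulk", "rep1", 1000, 10)])
        assert compute_cds_rpkm(counts, txome, "rep1")["t1"] == 1.0

    def test_background_deeper_than_signal_errors(self):
        txome = Transcriptome([TranscriptModel("t1", "g1", 2500, 100, 2100)])
        counts = _counts([("t1", "rep1", 10, 50)])
        with pytest.raises(ValueError, match="background"):
            compute_cds_rpkm(counts, txome, "rep1")


class TestAbundanceRegression:
    def test_collinear_points_recovered_exactly(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        clip = pd.Series(2.0 ** (2 * np.log2(x) + 1), index=[f"t{i}" for i in range(5)])
        ab = _abundance(list(zip(clip.index, x)))
        fit = fit_abundance_regression(clip, ab, "rep1")
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self, ols):
        rng = np.random.default_rng(0)
        x = rng.lognormal(1, 1, 50)
        y = rng.lognormal(0, 1, 50)
        ids = [f"t{i}" for i in range(50)]
        fit = fit_abundance_regression(pd.Series(y, index=ids), _abundance(list(zip(ids, x))), "rep1")
        slope, intercept = ols(np.log2(x), np.log2(y))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.n_fit == 50

    def test_too_few_points_error(self):
        ids = ["t0", "t1"]
        with pytest.raises(ValueError, match="regression needs|transcripts"):
            fit_abundance_regression(pd.Series([1.0, 2.0], index=ids),
                                     _abundance([(i, 1.0) for i in ids]), "rep1")

    def test_fit_filter_requires_tags(self):
        """Only transcripts with >=1 Cre-positive tag enter the fit."""
        ids = [f"t{i}" for i in range(6)]
        txome = Transcriptome([TranscriptModel(i, i, 1000, 0, 1000) for i in ids])
        counts = _counts([(i, "rep1", (10 * (k + 1) if k < 4 else 0), 0)
                          for k, i in enumerate(ids)])
        rpkm = compute_cds_rpkm(counts, txome, "rep1")
        ab = _abundance([(i, 2.0 ** k) for k, i in enumerate(ids)])
        fit = fit_abundance_regression(rpkm, ab, "rep1", counts=counts)
        assert fit.n_fit == 4

    def test_mean_residual_zero_over_fit_subset(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(1, 1, 200)
        y = rng.lognormal(0, 1, 200)
        ids = [f"t{i}" for i in range(200)]
        ab = _abundance(list(zip(ids, x)))
        clip = pd.Series(y, index=ids)
        fit = fit_abundance_regression(clip, ab, "rep1")
        scores = compute_clip_scores(clip, fit, ab)
        assert abs(scores.mean()) < 1e-9


class TestClipScores:
    def test_point_on_line_scores_zero_and_doubling_scores_one(self):
        fit = RegressionFit("rep1", 1.5, 0.5, 0.9, 10)
        ab = _abundance([("t1", 4.0), ("t2", 4.0)])
        fitted = 2.0 ** (1.5 * 2 + 0.5)
        scores = compute_clip_scores(pd.Series([fitted, 2 * fitted], index=["t1", "t2"]), fit, ab)
        assert scores["t1"] == pytest.approx(0.0, abs=1e-12)
        assert scores["t2"] == pytest.approx(1.0, abs=1e-12)

    def test_sentinel_rpkm_with_unit_fit(self):
        fit = RegressionFit("rep1", 1.0, 0.0, 0.9, 10)
        scores = compute_clip_scores(pd.Series([1.0], index=["t1"]), fit, _abundance([("t1", 8.0)]))
        assert scores["t1"] == pytest.approx(-3.0)

    def test_nonpositive_abundance_gives_missing(self):
        fit = RegressionFit("rep1", 1.0, 0.0, 0.9, 10)
        scores = compute_clip_scores(pd.Series([4.0, 4.0], index=["t1", "t2"]),
                                     fit, _abundance([("t1", 0.0), ("t2", 2.0)]))
        assert np.isnan(scores["t1"]) and np.isfinite(scores["t2"])


class TestClassification:
    def _classify(self, *triplets):
        df = pd.DataFrame(list(triplets), columns=["rep1", "rep2", "rep3"],
                          index=[f"t{i}" for i in range(len(triplets))])
        return aggregate_and_classify(df)

    def test_spec_rule_examples(self):
        out = self._classify((2.5, 2.1, 3.0), (3.5, 1.5, 0.5), (0.2, 0.4, 0.6), (-1.0, 0.1, 0.2))
        assert list(out.target_class) == ["stringent", "high", "low", "non_target"]
        assert out.mean_clip_score.iloc[1] == pytest.approx(np.mean([3.5, 1.5, 0.5]))

    def test_stringent_requires_all_replicates(self):
        out = self._classify((2.5, 2.5, 1.9))
        assert out.target_class.iloc[0] == "high"  # mean 2.3 >= 1 but not all >= 2

    def test_missing_replicate_forces_non_target(self):
        out = self._classify((2.5, np.nan, 3.0))
        assert out.target_class.iloc[0] == "non_target"
        assert bool(out.missing_replicate.iloc[0])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_and_classify(pd.DataFrame())


class TestPipelineProperties:
    def test_depth_invariance(self, small_sim):
        """Scaling one replicate's counts and totals leaves its scores
        unchanged up to the refit (residuals identical to 1e-9)."""
        table, _ = score_pipeline(small_sim.clip, small_sim.abundance, small_sim.txome)
        df = small_sim.clip.df.copy()
        sel = df.replicate == "rep1"
        df.loc[sel, ["cre_pos", "cre_neg"]] = df.loc[sel, ["cre_pos", "cre_neg"]] * 7
        scaled, _ = score_pipeline(TagCountTable(df), small_sim.abundance, small_sim.txome)
        a = table["clip_score_rep1"]
        b = scaled["clip_score_rep1"]
        mask = a.notna() & b.notna()
        assert np.allclose(a[mask], b[mask], atol=1e-9)

    def test_monotone_in_cre_pos_count(self):
        """At fixed abundance and fit, the score strictly increases with the
        Cre-positive count above the sentinel regime."""
        txome = Transcriptome([TranscriptModel(f"t{i}", f"g{i}", 1000, 0, 1000)
                               for i in range(5)])
        fit = RegressionFit("rep1", 1.0, 0.0, 0.9, 10)
        ab = _abundance([(f"t{i}", 4.0) for i in range(5)])
        scores = []
        for pos in (2, 5, 20, 100):
            counts = _counts([("t0", "rep1", pos, 1)]
                             + [(f"t{i}", "rep1", 1000, 0) for i in range(1, 5)])
            rpkm = compute_cds_rpkm(counts, txome, "rep1")
            scores.append(compute_clip_scores(rpkm, fit, ab)["t0"])
        assert np.all(np.diff(scores) > 0)

    def test_every_transcript_classified_once(self, small_sim):
        table, _ = score_pipeline(small_sim.clip, small_sim.abundance, small_sim.txome)
        assert len(table) == len(small_sim.txome)
        assert table.target_class.isin(["stringent", "high", "low", "non_target"]).all()


class TestWindowedAbundance:
    def test_uniform_coverage_windowed_close_to_full(self, small_sim):
        sub = Transcriptome([tx for tx in small_sim.txome if tx.length >= 2000][:80])
        tags = simulate_uniform_coverage(sub, 400, 30, seed=9)
        tags["library"] = "trap"
        win = windowed_abundance(tags, sub, window_nt=1000, anchor="start")
        full_like = tags.groupby("transcript_id").size()
        lengths = pd.Series({t.transcript_id: t.length for t in sub})
        full_rpkm = full_like * 1e9 / (lengths * len(tags))
        ratio = win.mean_rpkm("wt").loc[full_rpkm.index] / full_rpkm
        assert abs(np.log2(ratio).mean()) < 0.1

    def test_reads_outside_window_score_zero(self, toy_txome):
        tags = pd.DataFrame([("tx2", 1500, 1530, "rep1", "trap")],
                            columns=["transcript_id", "start", "end", "replicate_id", "library"])
        win = windowed_abundance(tags, toy_txome, window_nt=1000, anchor="start")
        assert win.mean_rpkm("wt")["tx2"] == 0.0
        win_end = windowed_abundance(tags, toy_txome, window_nt=1000, anchor="end")
        assert win_end.mean_rpkm("wt")["tx2"] > 0

    def test_short_transcript_uses_own_length(self, toy_txome):
        # tx3 is 500 nt; one read in it -> denominator is 500, not 1000
        tags = pd.DataFrame([("tx3", 100, 130, "rep1", "trap")],
                            columns=["transcript_id", "start", "end", "replicate_id", "library"])
        win = windowed_abundance(tags, toy_txome, window_nt=1000, anchor="start")
        assert win.mean_rpkm("wt")["tx3"] == pytest.approx(1 * 1e9 / (500 * 1))


class TestReplicateCorrelation:
    def test_diagonal_unity_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(50, 300)
        rows = [(f"t{i}", "rep1", int(c), 0) for i, c in enumerate(base)]
        rows += [(f"t{i}", "rep2", int(2 * c), 0) for i, c in enumerate(base)]
        r2 = replicate_correlation(_counts(rows))
        assert np.allclose(np.diag(r2), 1.0)
        assert r2.loc["rep1", "rep2"] == pytest.approx(1.0, abs=1e-12)
        assert r2.equals(r2.T)

    def test_independent_counts_near_zero(self):
        rng = np.random.default_rng(5)
        rows = []
        for rep in ("rep1", "rep2"):
            for i, c in enumerate(rng.poisson(30, 1000)):
                rows.append((f"t{i}", rep, int(c), 0))
        r2 = replicate_correlation(_counts(rows))
        assert r2.loc["rep1", "rep2"] < 0.05
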