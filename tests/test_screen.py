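import numpy as np
import pandas as pd
import pytest

from peakscreen.guides import GuideRecord
from peakscreen.io import GeneAnnotation, GenomicInterval
from peakscreen.screen import (
    CountMatrix,
    SpacerLocator,
    aggregate_peaks,
    bh_adjust,
    classify_tss_proximity,
    count_spacers,
    empirical_p,
    guide_log2fc,
    guide_significance,
    normalize_counts,
    replicate_correlation,
    tss_distance_guides,
    tss_distance_peaks,
)

from oracles import bh_stepup


def _cm(data, pdna="pdna"):
    df = pd.DataFrame(data)
    df.index.name = "guide_id"
    return CountMatrix.from_frame(df, pdna_column=pdna)


def _lib(n_target=4, n_ctl=3, peak="p1"):
    lib = []
    for i in range(n_target):
        lib.append(
            GuideRecord(f"t{i}", f"{'ACGT'[i % 4] * 20}", "AGG", None, ".", None,
                        "peak", peak_id=peak, motif_ids=(f"{peak}.1",))
        )
    for i in range(n_ctl):
        lib.append(
            GuideRecord(f"c{i}", "G" * 20, "NNN", None, ".", None, "nontargeting_control")
        )
    return lib


class TestCountSpacers:
    def _library(self):
        return [
            GuideRecord("g1", "A" * 20, "AGG", None, ".", None, "peak", "p1", ("p1.1",)),
            GuideRecord("g2", "C" * 20, "AGG", None, ".", None, "peak", "p1", ("p1.1",)),
            GuideRecord("dupA", "T" * 20, "AGG", None, ".", None, "peak", "p2", ("p2.1",)),
            GuideRecord("dupB", "T" * 20, "AGG", None, ".", None, "peak", "p3", ("p3.1",)),
        ]

    def test_anchor_assignment(self):
        lib = self._library()
        loc = SpacerLocator(anchor="ACCG")
        reads = ["TTACCG" + "A" * 20 + "GT", "TTACCG" + "C" * 20 + "GT"]
        counts, rep = count_spacers(reads, lib, loc)
        assert counts["g1"] == 1 and counts["g2"] == 1
        assert rep == {"total": 2, "assigned": 2, "unassigned": 0, "ambiguous": 0}

    def test_mismatched_spacer_unassigned(self):
        lib = self._library()
        loc = SpacerLocator(anchor="ACCG")
        reads = ["TTACCG" + "A" * 19 + "G" + "GT"]
        counts, rep = count_spacers(reads, lib, loc)
        assert rep["unassigned"] == 1 and counts.sum() == 0

    def test_missing_anchor_unassigned(self):
        lib = self._library()
        counts, rep = count_spacers(["T" * 40], lib, SpacerLocator(anchor="ACCG"))
        assert rep["unassigned"] == 1

    def test_ambiguous_spacer_binned_not_split(self):
        lib = self._library()
        reads = ["ACCG" + "T" * 20]
        counts, rep = count_spacers(reads, lib, SpacerLocator(anchor="ACCG"))
        assert rep["ambiguous"] == 1
        assert counts["dupA"] == 0 and counts["dupB"] == 0

    def test_fixed_offset_locator(self):
        lib = self._library()
        reads = ["NN" + "A" * 20 + "TTTT"]
        counts, _ = count_spacers(reads, lib, SpacerLocator(offset=2))
        assert counts["g1"] == 1

    def test_conservation(self, rng):
        """assigned + unassigned + ambiguous always equals total reads."""
        lib = self._library()
        reads = []
        for _ in range(500):
            kind = rng.integers(4)
            if kind == 0:
                reads.append("ACCG" + "A" * 20)
            elif kind == 1:
                reads.append("ACCG" + "T" * 20)
            elif kind == 2:
                reads.append("ACCG" + "".join(rng.choice(list("ACGT"), size=20)))
            else:
                reads.append("".join(rng.choice(list("ACGT"), size=30)))
        counts, rep = count_spacers(reads, lib, SpacerLocator(anchor="ACCG"))
        assert rep["assigned"] + rep["unassigned"] + rep["ambiguous"] == rep["total"] == 500
        assert counts.sum() == rep["assigned"]

    def test_malformed_fastq_names_record(self, tmp_path):
        p = tmp_path / "bad.fq"
        p.write_text("@r1\nACGT\n+\nII\n")  # quality length mismatch
        with pytest.raises(ValueError, match="record #1"):
            count_spacers(p, self._library(), SpacerLocator(offset=0))

    def test_locator_requires_exactly_one_mode(self):
        with pytest.raises(ValueError):
            SpacerLocator()
        with pytest.raises(ValueError):
            SpacerLocator(offset=1, anchor="A")


class TestNormalization:
    def test_identical_columns_equal_factors(self):
        col = list(range(1, 201))
        cm = _cm({"pdna": col, "s_r1": col, "s_r2": col})
        factors, norm = normalize_counts(cm)
        assert np.allclose(factors, factors.iloc[0])
        assert np.allclose(norm["pdna"], norm["s_r1"])

    def test_scale_equivariance(self):
        col = np.arange(1, 201)
        cm = _cm({"pdna": col, "s_r1": 2 * col})
        factors, _ = normalize_counts(cm)
        assert factors["s_r1"] / factors["pdna"] == pytest.approx(2.0)

    def test_median_of_ratios_near_one(self, rng):
        mat = rng.negative_binomial(10, 10 / (10 + 300), size=(2000, 3)) + 1
        cm = _cm({"pdna": mat[:, 0], "s_r1": mat[:, 1], "s_r2": mat[:, 2]})
        _, norm = normalize_counts(cm)
        log_ref = np.log(norm).mean(axis=1)
        med = np.exp(np.log(norm).sub(log_ref, axis=0).median(axis=0))
        assert np.allclose(med, 1.0, atol=0.01)

    def test_fallback_to_total_when_few_common(self):
        # mostly zeros: median-ratio not computable over < 100 common guides
        data = {"pdna": [10] * 10 + [0] * 90, "s_r1": [0] * 10 + [20] * 90}
        cm = _cm(data)
        factors, _ = normalize_counts(cm)
        totals = cm.counts.sum(axis=0)
        assert np.allclose(factors, totals / totals.mean())

    def test_all_zero_sample_rejected(self):
        cm = _cm({"pdna": [1, 2], "s_r1": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(cm)


class TestLog2FC:
    def test_equal_counts_give_zero(self):
        col = list(range(10, 210))
        cm = _cm({"pdna": col, "s_r1": col})
        lfc = guide_log2fc(cm)
        assert np.allclose(lfc["lfc_s_r1"], 0.0)

    def test_fourfold_gives_two(self):
        # identical marginals per column so size factors are 1
        base = np.array([25] * 100)
        cm = _cm({"pdna": base, "s_r1": base * 4})
        lfc = guide_log2fc(cm, method="total")
        # total-count scaling removes the global factor; spike a single guide instead
        cm2 = _cm({"pdna": [25] + [100] * 199, "s_r1": [100] + [100] * 199})
        lfc2 = guide_log2fc(cm2, pseudocount=1e-9, method="total")
        sf = (100 + 199 * 100) / (25 + 199 * 100)
        expected = np.log2((100 / sf) / 25)
        assert lfc2["lfc_s_r1"].iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_pseudocount_shrinks_low_counts_only(self):
        # equal column totals so size factors are 1
        cm = _cm({"pdna": [2, 10_000], "s_r1": [8, 9_994]})
        small = guide_log2fc(cm, pseudocount=0.5, method="total")
        large = guide_log2fc(cm, pseudocount=1.0, method="total")
        assert abs(large["lfc_s_r1"].iloc[0]) < abs(small["lfc_s_r1"].iloc[0])
        assert large["lfc_s_r1"].iloc[1] == pytest.approx(
            small["lfc_s_r1"].iloc[1], abs=1e-3
        )

    def test_zero_pseudocount_with_zeros_rejected(self):
        cm = _cm({"pdna": [0, 5], "s_r1": [1, 5]})
        with pytest.raises(ValueError, match="pseudocount"):
            guide_log2fc(cm, pseudocount=0.0)

    def test_mean_lfc_is_replicate_mean(self):
        cm = _cm({"pdna": [10] * 150, "s_r1": [20] * 150, "s_r2": [40] * 150})
        lfc = guide_log2fc(cm)
        expected = (lfc["lfc_s_r1"] + lfc["lfc_s_r2"]) / 2
        assert np.allclose(lfc["mean_lfc"], expected)


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        col = list(range(10, 110))
        cm = _cm({"pdna": [50] * 100, "s_r1": col, "s_r2": col})
        corr = replicate_correlation(guide_log2fc(cm))
        assert corr["r"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        lfc = pd.DataFrame({"lfc_a": [1.0, 2.0, 3.0], "lfc_b": [-1.0, -2.0, -3.0]})
        corr = replicate_correlation(lfc)
        assert corr["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_flagged_not_nan(self):
        lfc = pd.DataFrame({"lfc_a": [1.0, 1.0, 1.0], "lfc_b": [1.0, 2.0, 3.0]})
        corr = replicate_correlation(lfc)
        assert corr["defined"].iloc[0] == False  # noqa: E712
        assert corr["r"].iloc[0] is None

    def test_independent_replicates_near_zero(self, rng):
        """Null simulation: independent replicate noise gives |r| < 0.1."""
        n_small = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            lfc = pd.DataFrame(
                {"lfc_a": r.normal(size=1000), "lfc_b": r.normal(size=1000)}
            )
            if abs(replicate_correlation(lfc)["r"].iloc[0]) < 0.1:
                n_small += 1
        assert n_small >= 19

    def test_spearman_option(self):
        lfc = pd.DataFrame({"lfc_a": [1.0, 2.0, 3.0], "lfc_b": [10.0, 200.0, 30000.0]})
        corr = replicate_correlation(lfc, method="spearman")
        assert corr["r"].iloc[0] == pytest.approx(1.0)


class TestSignificance:
    def test_smoothing_formula(self):
        """A guide more extreme than all 999 controls gets p = 1/1000."""
        null = np.linspace(-1, 1, 999)
        p = empirical_p(np.array([5.0]), null)
        assert p[0] == pytest.approx(1.0 / 1000)

    def test_central_observation_near_one(self):
        null = np.linspace(-1, 1, 999)
        p = empirical_p(np.array([0.0]), null)
        assert p[0] > 0.99

    def test_bh_textbook_example(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_bh_matches_stepup_oracle(self, rng):
        for _ in range(20):
            p = rng.random(size=int(rng.integers(1, 400)))
            assert np.allclose(bh_adjust(p), bh_stepup(p))

    def test_fdr_at_least_p(self, rng):
        lfc = pd.DataFrame({"mean_lfc": rng.normal(size=300)})
        lfc.index = [f"t{i}" for i in range(200)] + [f"c{i}" for i in range(100)]
        out = guide_significance(lfc, [f"c{i}" for i in range(100)])
        mask = out["empirical_p"].notna()
        assert (out.loc[mask, "fdr"] >= out.loc[mask, "empirical_p"] - 1e-12).all()

    def test_empty_null_rejected(self):
        lfc = pd.DataFrame({"mean_lfc": [0.0]}, index=["t0"])
        with pytest.raises(ValueError, match="null"):
            guide_significance(lfc, [])


class TestAggregatePeaks:
    def _stats(self, vals, n_ctl=200, rng=None):
        rng = rng or np.random.default_rng(0)
        lib = []
        rows = {}
        for i, v in enumerate(vals):
            gid = f"t{i}"
            lib.append(GuideRecord(gid, "A" * 20, "AGG", None, ".", None, "peak",
                                   peak_id="p1", motif_ids=("p1.1",)))
            rows[gid] = v
        ctl_ids = []
        for i in range(n_ctl):
            gid = f"c{i}"
            ctl_ids.append(gid)
            lib.append(GuideRecord(gid, "C" * 20, "NNN", None, ".", None,
                                   "nontargeting_control"))
            rows[gid] = rng.normal(0, 0.3)
        lfc = pd.DataFrame({"mean_lfc": pd.Series(rows)})
        return lfc, lib, ctl_ids

    def test_median_is_exact(self):
        lfc, lib, ctl = self._stats([-1.0, 0.0, 3.0])
        pk = aggregate_peaks(lfc, lib, ctl, n_perm=500, rng_seed=1)
        assert pk.loc["p1", "median_lfc"] == 0.0
        assert pk.loc["p1", "n_guides"] == 3

    def test_null_peak_p_near_one(self):
        lfc, lib, ctl = self._stats([0.0, 0.0, 0.0, 0.0])
        pk = aggregate_peaks(lfc, lib, ctl, n_perm=2000, rng_seed=1)
        assert pk.loc["p1", "empirical_p"] > 0.9

    def test_p_values_in_unit_interval(self, rng):
        lfc, lib, ctl = self._stats(list(rng.normal(size=8)))
        pk = aggregate_peaks(lfc, lib, ctl, n_perm=100, rng_seed=2)
        assert ((pk["empirical_p"] > 0) & (pk["empirical_p"] <= 1)).all()

    def test_planted_peak_detected_across_seeds(self):
        """Peak at +2 lfc with 4 guides against sd-0.3 controls reaches
        FDR < 0.05 in >= 95% of seeds."""
        n_called = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            vals = list(2.0 + r.normal(0, 0.3, size=4))
            lfc, lib, ctl = self._stats(vals, rng=r)
            pk = aggregate_peaks(lfc, lib, ctl, n_perm=2000, rng_seed=seed)
            if pk.loc["p1", "fdr"] < 0.05:
                n_called += 1
        assert n_called >= 19

    def test_reproducible_under_seed(self, rng):
        lfc, lib, ctl = self._stats(list(rng.normal(size=5)))
        a = aggregate_peaks(lfc, lib, ctl, n_perm=300, rng_seed=7)
        b = aggregate_peaks(lfc, lib, ctl, n_perm=300, rng_seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_perm_p_stability_in_n_perm(self):
        """Doubling n_perm moves p by roughly n_perm^-1/2, not more."""
        lfc, lib, ctl = self._stats([0.45, 0.5, 0.55, 0.5])
        p1 = aggregate_peaks(lfc, lib, ctl, n_perm=4000, rng_seed=1).loc["p1", "empirical_p"]
        p2 = aggregate_peaks(lfc, lib, ctl, n_perm=8000, rng_seed=2).loc["p1", "empirical_p"]
        assert abs(p1 - p2) < 10 / np.sqrt(4000)


class TestTssDistance:
    def _genes(self):
        return [
            GeneAnnotation("g1", GenomicInterval("c1", 400, 900, "+", "g1"), True),
            GeneAnnotation("g2", GenomicInterval("c1", 1500, 1900, "-", "g2"), True),
        ]

    def _guide(self, cut):
        return GuideRecord(
            f"g@{cut}", "A" * 20, "AGG",
            GenomicInterval("c1", cut - 16, cut + 4, "+"), "+", cut, "peak", "p1", ("p1.1",)
        )

    def test_zero_at_tss(self):
        d = tss_distance_guides([self._guide(400)], self._genes())
        assert d["g@400"] == 0

    def test_nearest_wins(self):
        # TSSs at 400 (+ gene) and 1899 (- gene); cut at 1000
        d = tss_distance_guides([self._guide(1000)], self._genes())
        assert d["g@1000"] == 600

    def test_contig_without_genes_flagged(self):
        g = GuideRecord("x", "A" * 20, "AGG",
                        GenomicInterval("c9", 100, 120, "+"), "+", 116, "peak", "p", ("p.1",))
        d = tss_distance_guides([g], self._genes())
        assert d["x"] is None

    def test_empty_gene_table_rejected(self):
        with pytest.raises(ValueError):
            tss_distance_guides([self._guide(500)], [])

    def test_peak_distance_from_midpoint(self):
        peaks = [GenomicInterval("c1", 300, 500, ".", "pk")]  # midpoint 400
        d = tss_distance_peaks(peaks, self._genes())
        assert d["pk"] == 0

    def test_10kb_boundary_is_proximal(self):
        assert classify_tss_proximity(10_000) == "proximal"
        assert classify_tss_proximity(10_001) == "distal"
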