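"""Normalization, fold change, ranking, hit calling and competitive assays."""

import numpy as np
import pandas as pd
import pytest

from splicescreen import (
    Arm,
    CountMatrix,
    FoldChangeTable,
    HitParams,
    SampleMeta,
    ShrnaLibrary,
    ShrnaRecord,
    Timepoint,
    analyze_screen,
    call_hits,
    called_genes,
    competitive_ratio,
    fold_change,
    fold_change_table,
    mean_log2fc,
    normalize_counts,
    rank_percentiles,
    replicate_correlation,
)
from conftest import make_guides


def library_from_spec(gene_sizes, n_controls=0):
    """Build a library with the given gene -> n_hairpins map."""
    n = sum(gene_sizes.values()) + n_controls
    guides = iter(make_guides(n, seed=abs(hash(tuple(sorted(gene_sizes)))) % 2**31))
    records = []
    for gene, size in gene_sizes.items():
        for j in range(size):
            records.append(ShrnaRecord(f"{gene}_sh{j+1}", gene, next(guides)))
    for k in range(n_controls):
        records.append(ShrnaRecord(f"SCR{k+1}", "", next(guides), is_control=True))
    return ShrnaLibrary(records)


class TestNormalizeCounts:
    def test_simple_frequencies(self, small_library):
        ids = small_library.hairpin_ids[:3]
        counts = pd.DataFrame({"s": [10, 30, 60] + [0] * 6},
                              index=small_library.hairpin_ids)
        cm = CountMatrix(counts, [SampleMeta("s", Arm.AML, 1, Timepoint.INPUT)],
                         small_library)
        # pseudocount 0 on a sample without zeros in the cells of interest
        freqs = normalize_counts(cm, pseudocount=0.0)
        assert freqs["s"].loc[ids].tolist() == [0.1, 0.3, 0.6]

    def test_all_zero_with_pseudocount(self, small_library):
        counts = pd.DataFrame({"s": [0] * 9}, index=small_library.hairpin_ids)
        cm = CountMatrix(counts, [SampleMeta("s", Arm.AML, 1, Timepoint.INPUT)],
                         small_library)
        freqs = normalize_counts(cm, pseudocount=0.5)
        assert np.allclose(freqs["s"], 1 / 9)
        with pytest.raises(ValueError):
            normalize_counts(cm, pseudocount=0.0)

    def test_columns_sum_to_one(self, small_counts):
        freqs = normalize_counts(small_counts, 0.5)
        assert np.allclose(freqs.sum(axis=0), 1.0, atol=1e-9)


class TestFoldChange:
    def make_freqs(self, library, fin, fout):
        return pd.DataFrame({"in": fin, "out": fout}, index=library.hairpin_ids)

    def test_single_control_normalization(self):
        lib = library_from_spec({"G1": 1}, n_controls=1)
        # hairpin in 0.01 -> 0.04 (raw 4), control raw ratio 2 -> fc 2, log2fc 1
        freqs = self.make_freqs(lib, [0.01, 0.10], [0.04, 0.20])
        t = fold_change(freqs, "in", "out", lib)
        assert t.loc["G1_sh1", "fc"] == pytest.approx(2.0)
        assert t.loc["G1_sh1", "log2fc"] == pytest.approx(1.0)

    def test_sole_control_self_normalizes(self):
        lib = library_from_spec({"G1": 1}, n_controls=1)
        freqs = self.make_freqs(lib, [0.01, 0.10], [0.04, 0.20])
        t = fold_change(freqs, "in", "out", lib)
        assert t.loc["SCR1", "fc"] == pytest.approx(1.0)
        assert t.loc["SCR1", "log2fc"] == pytest.approx(0.0)

    def test_median_of_three_controls(self):
        """Controls with raw ratios {0.5, 1, 4}: median 1, so fc == raw."""
        lib = library_from_spec({"G1": 5}, n_controls=3)
        fin = [0.1] * 5 + [0.1, 0.1, 0.025]
        fout = [0.12, 0.08, 0.2, 0.05, 0.1] + [0.05, 0.1, 0.1]
        freqs = self.make_freqs(lib, fin, fout)
        t = fold_change(freqs, "in", "out", lib, control_summary="median")
        assert np.allclose(t["fc"], t["raw"])

    def test_no_controls_instructs_none(self):
        lib = library_from_spec({"G1": 2})
        freqs = self.make_freqs(lib, [0.5, 0.5], [0.5, 0.5])
        with pytest.raises(ValueError, match="control_summary='none'"):
            fold_change(freqs, "in", "out", lib)
        t = fold_change(freqs, "in", "out", lib, control_summary="none")
        assert np.allclose(t["fc"], 1.0)

    def test_scale_invariance_of_hit_calls(self, small_counts):
        """Scaling one sample's raw counts leaves fold changes unchanged (pc=0)."""
        params = HitParams(pseudocount=0.0)
        aml = small_counts.for_arm(Arm.AML)
        counter = small_counts.for_arm(Arm.COUNTER)
        base = analyze_screen(aml, counter, params)
        scaled = aml.counts.copy()
        scaled.iloc[:, 0] *= 7
        aml2 = CountMatrix(scaled, aml.samples, aml.library)
        redo = analyze_screen(aml2, counter, params)
        pd.testing.assert_series_equal(
            base[0].summary["mean_log2fc"], redo[0].summary["mean_log2fc"]
        )
        pd.testing.assert_frame_equal(base[2], redo[2])


class TestMeanAndCorrelation:
    def test_mean_of_two_replicates(self):
        t1 = pd.DataFrame({"log2fc": [1.0, 0.0]}, index=["a", "b"])
        t2 = pd.DataFrame({"log2fc": [3.0, 2.0]}, index=["a", "b"])
        m = mean_log2fc([t1, t2])
        assert m.tolist() == [2.0, 1.0]

    def test_single_replicate_identity(self):
        t1 = pd.DataFrame({"log2fc": [1.5, -0.5]}, index=["a", "b"])
        assert mean_log2fc([t1]).tolist() == [1.5, -0.5]

    def test_mismatched_hairpins_rejected(self):
        t1 = pd.DataFrame({"log2fc": [1.0]}, index=["a"])
        t2 = pd.DataFrame({"log2fc": [1.0]}, index=["b"])
        with pytest.raises(ValueError):
            mean_log2fc([t1, t2])

    def test_pearson_extremes(self):
        v = pd.Series([1.0, 2.0, 5.0])
        assert replicate_correlation(v, v) == pytest.approx(1.0)
        assert replicate_correlation(v, -v) == pytest.approx(-1.0)

    def test_pearson_hand_computed(self):
        # r = 5 / sqrt(2 * 38/3) = 0.99340 for (1,2,3) vs (2,4,7)
        r = replicate_correlation(pd.Series([1.0, 2, 3]), pd.Series([2.0, 4, 7]))
        assert r == pytest.approx(0.9934, abs=5e-5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            replicate_correlation(pd.Series([1.0, 1, 1]), pd.Series([1.0, 2, 3]))


class TestRankPercentiles:
    def test_basic_ranks(self):
        m = pd.Series({"a": 2.0, "b": 0.0, "c": -1.0})
        df = rank_percentiles(m)
        assert df["enrich_rank"].tolist() == [1, 2, 3]
        assert df["deplete_rank"].tolist() == [3, 2, 1]

    def test_top_percentile(self):
        m = pd.Series({f"h{i:02d}": -float(i) for i in range(10)})
        df = rank_percentiles(m)
        assert df.loc["h00", "enrich_pctile"] == pytest.approx(0.1)

    def test_all_tied_ranked_by_id(self):
        m = pd.Series({"c": 1.0, "a": 1.0, "b": 1.0})
        df = rank_percentiles(m)
        assert df.loc[["a", "b", "c"], "enrich_rank"].tolist() == [1, 2, 3]
        assert df.loc[["a", "b", "c"], "deplete_rank"].tolist() == [1, 2, 3]

    def test_rank_sum_invariant_untied(self):
        rng = np.random.default_rng(0)
        m = pd.Series(rng.normal(size=25), index=[f"h{i:02d}" for i in range(25)])
        df = rank_percentiles(m)
        assert ((df["enrich_rank"] + df["deplete_rank"]) == 26).all()


def brute_force_hits(aml_mean, counter_mean, library, params):
    """Verbatim reimplementation of the percentile hit rule, written
    independently of the production code path (explicit sorting, no pandas
    rank machinery)."""
    targeting = [r for r in library.records if not r.is_control]
    n = len(aml_mean)

    def top_set(mean, direction, cut):
        # sort hairpins most-extreme first; percentile of rank r is r/N
        reverse = direction == "ENRICHED"
        items = sorted(
            mean.items(), key=lambda kv: ((-kv[1]) if reverse else kv[1], kv[0])
        )
        return {h for r, (h, _v) in enumerate(items, start=1) if r / n <= cut}

    calls = {}
    for direction, cut in (("ENRICHED", params.enrich_pct), ("DEPLETED", params.deplete_pct)):
        top_a = top_set(aml_mean, direction, cut)
        top_c = top_set(counter_mean, direction, cut)
        counter_support = params.counter_min_support or params.min_support
        for gene in sorted({r.gene for r in targeting}):
            hp = [r.hairpin_id for r in targeting if r.gene == gene]
            support = sorted(h for h in hp if h in top_a)
            flag = len([h for h in hp if h in top_c]) >= counter_support
            calls[(gene, direction)] = (
                len(support) >= params.min_support and not flag,
                tuple(support),
                flag,
            )
    return calls


def assert_matches_bruteforce(aml_mean, counter_mean, library, params):
    aml_fc = FoldChangeTable.from_mean_log2fc(aml_mean, library)
    counter_fc = FoldChangeTable.from_mean_log2fc(counter_mean, library)
    hits = call_hits(aml_fc, counter_fc, library, params)
    expected = brute_force_hits(aml_mean, counter_mean, library, params)
    assert len(hits) == len(expected)
    for _, row in hits.iterrows():
        called, support, flag = expected[(row["gene"], row["direction"])]
        assert row["called"] == called, (row["gene"], row["direction"])
        assert row["counter_flag"] == flag
        assert tuple(filter(None, row["support_ids"].split(","))) == support


class TestCallHits:
    def test_default_parameters(self):
        p = HitParams()
        assert (p.enrich_pct, p.deplete_pct, p.min_support) == (0.20, 0.25, 2)

    def test_single_supporting_hairpin_not_called(self):
        lib = library_from_spec({"G1": 3, "G2": 3, "G3": 3, "G4": 1})
        rng = np.random.default_rng(1)
        base = pd.Series(rng.normal(0, 0.1, len(lib)), index=lib.hairpin_ids)
        aml = base.copy()
        aml["G4_sh1"] = 10.0  # single hairpin, far in the top percentile
        counter = base.copy()
        hits = call_hits(
            FoldChangeTable.from_mean_log2fc(aml, lib),
            FoldChangeTable.from_mean_log2fc(counter, lib),
            lib,
        )
        row = hits.query("gene == 'G4' and direction == 'ENRICHED'").iloc[0]
        assert row["n_support"] == 1 and not row["called"]

    def test_planted_genes_with_counter_confounder(self):
        """2 planted enriched genes, 1 also enriched in the counter arm:
        exactly 1 call, agreeing with the brute-force rule."""
        lib = library_from_spec({f"G{i}": 3 for i in range(1, 11)}, n_controls=5)
        rng = np.random.default_rng(42)
        aml = pd.Series(rng.normal(0, 0.3, len(lib)), index=lib.hairpin_ids)
        counter = pd.Series(rng.normal(0, 0.3, len(lib)), index=lib.hairpin_ids)
        for h in ("G1_sh1", "G1_sh2", "G1_sh3", "G2_sh1", "G2_sh2", "G2_sh3"):
            aml[h] += 5.0
        for h in ("G2_sh1", "G2_sh2", "G2_sh3"):
            counter[h] += 5.0
        aml_fc = FoldChangeTable.from_mean_log2fc(aml, lib)
        counter_fc = FoldChangeTable.from_mean_log2fc(counter, lib)
        hits = call_hits(aml_fc, counter_fc, lib)
        assert called_genes(hits, "ENRICHED") == ["G1"]
        assert_matches_bruteforce(aml, counter, lib, HitParams())

    def test_mismatched_hairpin_sets_rejected(self):
        lib = library_from_spec({"G1": 2, "G2": 2})
        m = pd.Series(np.arange(4.0), index=lib.hairpin_ids)
        with pytest.raises(ValueError):
            call_hits(
                FoldChangeTable.from_mean_log2fc(m, lib),
                FoldChangeTable.from_mean_log2fc(m.iloc[:3], lib),
                lib,
            )

    def test_monotonicity_in_thresholds(self):
        """Raising enrich_pct never removes a call; raising min_support
        never adds one."""
        lib = library_from_spec({f"G{i}": 3 for i in range(1, 13)}, n_controls=4)
        rng = np.random.default_rng(7)
        aml = pd.Series(rng.normal(size=len(lib)), index=lib.hairpin_ids)
        counter = pd.Series(rng.normal(size=len(lib)), index=lib.hairpin_ids)
        a_fc = FoldChangeTable.from_mean_log2fc(aml, lib)
        c_fc = FoldChangeTable.from_mean_log2fc(counter, lib)
        prev: set = set()
        for pct in (0.10, 0.20, 0.30, 0.40):
            # counter arm held fixed: its criterion is made unreachable
            p = HitParams(enrich_pct=pct, counter_min_support=99)
            now = set(called_genes(call_hits(a_fc, c_fc, lib, p), "ENRICHED"))
            assert prev <= now
            prev = now
        prev_support = None
        for ms in (1, 2, 3):
            p = HitParams(min_support=ms, counter_min_support=2)
            now = set(called_genes(call_hits(a_fc, c_fc, lib, p), "ENRICHED"))
            if prev_support is not None:
                assert now <= prev_support
            prev_support = now

    def test_random_instances_match_bruteforce(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            sizes = {f"G{i}": int(rng.integers(1, 5)) for i in range(rng.integers(2, 13))}
            lib = library_from_spec(sizes, n_controls=int(rng.integers(0, 4)))
            aml = pd.Series(rng.normal(size=len(lib)).round(1), index=lib.hairpin_ids)
            counter = pd.Series(rng.normal(size=len(lib)).round(1), index=lib.hairpin_ids)
            params = HitParams(
                enrich_pct=float(rng.uniform(0.05, 0.45)),
                deplete_pct=float(rng.uniform(0.05, 0.45)),
                min_support=int(rng.integers(1, 4)),
            )
            assert_matches_bruteforce(aml, counter, lib, params)


class TestCompetitiveRatio:
    def test_balanced_mixture(self):
        t = pd.Index([0, 14])
        r = competitive_ratio(pd.Series([0.5, 0.5], t), pd.Series([0.5, 0.5], t))
        assert r.tolist() == [1.0, 1.0]

    def test_twofold_enrichment(self):
        t = pd.Index([0, 14])
        r = competitive_ratio(pd.Series([0.5, 0.6667], t), pd.Series([0.5, 0.3333], t))
        assert r.iloc[1] == pytest.approx(2.0, abs=0.01)

    def test_uneven_input_hand_computed(self):
        t = pd.Index([0, 7, 14])
        r = competitive_ratio(
            pd.Series([0.4, 0.4, 0.6], t), pd.Series([0.6, 0.6, 0.4], t)
        )
        assert np.allclose(r, [1.0, 1.0, 2.25])

    def test_degenerate_fraction_rejected(self):
        t = pd.Index([0, 7])
        with pytest.raises(ValueError):
            competitive_ratio(pd.Series([0.5, 1.0], t), pd.Series([0.5, 0.5], t))


class TestControlCentering:
    def test_median_control_fc_is_one(self, small_counts):
        """Odd number of controls + median summary: the median control
        hairpin has fc exactly 1 in every replicate."""
        aml = small_counts.for_arm(Arm.AML)
        fct = fold_change_table(aml, pseudocount=0.5, control_summary="median")
        controls = aml.library.control_ids
        for rep, grp in fct.per_replicate.groupby("replicate"):
            fcs = grp.loc[controls, "fc"]
            assert np.isclose(fcs, 1.0).any()
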