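"""Hard filtering, sanitation, type classification, and concordance."""

import numpy as np
import pytest

from clonediv.simulate import SimulationConfig, simulate, write_fixture
from clonediv.variants import (FilterConfig, VariantRecord, VariantTable,
                               apply_hard_filters, brute_force_concordance,
                               call_set_concordance, classify_variant_type,
                               complete_call_sites, drop_reference_nonref,
                               limit_alts, read_variant_table,
                               record_variant_types)

from conftest import small_config
from _oracles import revcomp  # noqa: F401  (shared helper sanity)


def _rec(metrics=None, qual=500.0, genotypes=None, **kw):
    defaults = dict(contig="c1", pos=100, ref="A", alts=("T",),
                    qual=qual, metrics=metrics or {},
                    genotypes=genotypes or {"s1": (0, 1)})
    defaults.update(kw)
    return VariantRecord(**defaults)


PASSING = {"DP": 12.0, "QD": 25.0, "FS": 3.0, "MQ": 60.0,
           "MQRankSum": 0.0, "ReadPosRankSum": 0.0}


class TestHardFilters:
    def test_low_qd_fails_qd_rule(self):
        table = VariantTable(["s1"], [_rec(metrics={**PASSING, "QD": 1.5})])
        out = apply_hard_filters(table, FilterConfig())
        assert out.records[0].filters == ("QD2",)

    def test_all_metrics_absent_passes_vacuously(self, caplog):
        table = VariantTable(["s1"], [_rec(metrics={}, qual=None)])
        with caplog.at_level("WARNING"):
            out = apply_hard_filters(table, FilterConfig())
        assert out.records[0].is_pass
        assert "not evaluated" in caplog.text

    def test_ten_record_table_exact_pass_fail_vector(self):
        """Hand-evaluated PASS/FAIL against the printed threshold set."""
        specs = [
            (dict(PASSING), 500.0, ()),                      # clean
            ({**PASSING, "DP": 30.0}, 500.0, ("DP_high",)),  # DP > 20
            ({**PASSING, "DP": 2.0}, 500.0, ("DP_low",)),    # DP < 5
            (dict(PASSING), 10.0, ("LowQual",)),             # QUAL < 20
            ({**PASSING, "QD": 1.9}, 500.0, ("QD2",)),       # QD < 2.0
            ({**PASSING, "FS": 60.5}, 500.0, ("FS60",)),     # FS > 60.0
            ({**PASSING, "MQ": 39.0}, 500.0, ("MQ40",)),     # MQ < 40.0
            ({**PASSING, "MQRankSum": -13.0}, 500.0, ("MQRankSum",)),
            ({**PASSING, "ReadPosRankSum": -8.5}, 500.0, ("ReadPosRankSum",)),
            ({**PASSING, "DP": 21.0, "QD": 0.5}, 15.0,
             ("DP_high", "LowQual", "QD2")),                 # multiple failures
        ]
        table = VariantTable(
            ["s1"], [_rec(metrics=m, qual=q, pos=100 + i)
                     for i, (m, q, _) in enumerate(specs)])
        out = apply_hard_filters(table, FilterConfig())
        assert [r.filters for r in out.records] == [f for _, _, f in specs]

    def test_boundary_values_pass(self):
        # thresholds are strict inequalities: equality passes
        m = {**PASSING, "DP": 20.0, "QD": 2.0, "FS": 60.0, "MQ": 40.0,
             "MQRankSum": -12.5, "ReadPosRankSum": -8.0}
        table = VariantTable(["s1"], [_rec(metrics=m, qual=20.0)])
        assert apply_hard_filters(table, FilterConfig()).records[0].is_pass

    def test_tightening_threshold_is_monotone(self):
        rng = np.random.default_rng(0)
        records = [
            _rec(pos=i + 1, metrics={**PASSING, "QD": float(q)})
            for i, q in enumerate(rng.uniform(0, 40, size=200))
        ]
        table = VariantTable(["s1"], records)
        n_pass = []
        for thr in (1.0, 2.0, 5.0, 10.0, 20.0):
            cfg = FilterConfig()
            cfg.rules = [r if r.name != "QD2" else
                         type(r)(r.name, r.metric, r.op, thr)
                         for r in cfg.rules]
            n_pass.append(len(apply_hard_filters(table, cfg).passing()))
        assert n_pass == sorted(n_pass, reverse=True)

    def test_no_enabled_rules_rejected(self):
        cfg = FilterConfig().disable(*[r.name for r in FilterConfig().rules])
        with pytest.raises(ValueError):
            apply_hard_filters(VariantTable(["s1"], [_rec()]), cfg)


class TestSanitation:
    def _table(self, ref_gts, clone_gts):
        recs = [
            _rec(pos=i + 1,
                 genotypes={"ref": rg, "c1": cg})
            for i, (rg, cg) in enumerate(zip(ref_gts, clone_gts))
        ]
        return VariantTable(["ref", "c1"], recs)

    def test_reference_het_record_removed(self):
        t = self._table([(0, 1), (0, 0)], [(0, 1), (0, 1)])
        out, frac = drop_reference_nonref(t, "ref")
        assert len(out) == 1 and frac == 0.5

    def test_all_homref_reference_is_noop(self):
        t = self._table([(0, 0)] * 4, [(0, 1)] * 4)
        out, frac = drop_reference_nonref(t, "ref")
        assert len(out) == 4 and frac == 0.0

    def test_unknown_reference_sample_raises(self):
        with pytest.raises(KeyError):
            drop_reference_nonref(self._table([(0, 0)], [(0, 1)]), "nope")

    def test_spiked_fraction_recovered(self):
        rng = np.random.default_rng(1)
        spiked = set(rng.choice(100, size=10, replace=False))
        t = self._table(
            [(1, 1) if i in spiked else (0, 0) for i in range(100)],
            [(0, 1)] * 100)
        out, frac = drop_reference_nonref(t, "ref")
        assert len(out) == 90 and frac == pytest.approx(0.10)

    def test_complete_call_sites_drops_missing(self):
        t = self._table([(0, 0), None, (0, 0)], [(0, 1), (0, 1), None])
        assert len(complete_call_sites(t)) == 1

    def test_sanitation_predicates_commute(self):
        rng = np.random.default_rng(2)
        gts = lambda: (None if rng.random() < 0.2 else
                       tuple(sorted(rng.integers(0, 2, size=2))))
        recs = [_rec(pos=i + 1, genotypes={"ref": gts(), "c1": gts()})
                for i in range(300)]
        t = VariantTable(["ref", "c1"], recs)
        a = complete_call_sites(drop_reference_nonref(t, "ref")[0])
        b = drop_reference_nonref(complete_call_sites(t), "ref")[0]
        assert [r.pos for r in a.records] == [r.pos for r in b.records]

    def test_artifact_spikes_into_reference_are_exactly_what_gets_dropped(
            self, tmp_path):
        cfg = small_config(9, artifact_homalt_rate=0.05,
                           artifact_samples=("mother",))
        ds = simulate(cfg)
        paths = write_fixture(ds, tmp_path)
        table = read_variant_table(paths["vcf"])
        out, _ = drop_reference_nonref(table, "mother")
        small = ds.truth[ds.truth["vartype"].isin(["SNV", "INDEL"])]
        spiked = set(small.loc[small["artifact_samples"].str.contains("mother"),
                               "variant_id"])
        assert spiked  # the condition must actually exercise the filter
        kept = {r.variant_id for r in out.records}
        assert kept == set(small["variant_id"]) - spiked


class TestClassification:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("C", "T", "SNV"),
        ("CA", "C", "INDEL"),
        ("C", "CAA", "INDEL"),
        ("CAT", "GAT", "INDEL"),
        ("C", "<DEL>", "SV"),
    ])
    def test_classify_variant_type(self, ref, alt, expected):
        assert classify_variant_type(ref, alt) == expected

    def test_multiallelic_classified_per_alt(self):
        rec = _rec(alts=("T", "CAA"))
        assert record_variant_types(rec) == ("SNV", "INDEL")

    def test_limit_alts_truncates_and_masks(self):
        rec = _rec(alts=("T", "G", "C"),
                   genotypes={"s1": (0, 3), "s2": (1, 2)})
        out = limit_alts(VariantTable(["s1", "s2"], [rec]), max_alts=2)
        assert out.records[0].alts == ("T", "G")
        assert out.records[0].genotypes["s1"] is None
        assert out.records[0].genotypes["s2"] == (1, 2)


class TestConcordance:
    def test_three_set_example(self):
        part, per_set = call_set_concordance({
            "A": {"s1", "s2", "s3"}, "B": {"s2", "s3", "s4"},
            "C": {"s3", "s4", "s5"}})
        rows = {r["pattern"]: r["count"] for _, r in part.iterrows()}
        assert rows["A&B&C"] == 1
        assert rows["A"] == 1
        assert per_set.set_index("set").loc["A", "unique_count"] == 1

    def test_identical_sets(self):
        s = set(range(10))
        part, per_set = call_set_concordance({"A": s, "B": s, "C": s})
        rows = {r["pattern"]: r["count"] for _, r in part.iterrows()}
        assert rows == {"A&B&C": 10}
        assert (per_set["unique_count"] == 0).all()

    def test_partition_matches_brute_force_and_sums_to_union(self):
        rng = np.random.default_rng(3)
        sets = {name: set(rng.choice(1000, size=400, replace=False))
                for name in "ABC"}
        part, _ = call_set_concordance(sets)
        oracle = brute_force_concordance(sets)
        got = {r["pattern"]: r["count"] for _, r in part.iterrows()}
        assert got == {k: v for k, v in oracle.items() if v > 0}
        assert part["count"].sum() == len(set().union(*sets.values()))

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            call_set_concordance({})
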