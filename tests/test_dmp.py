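"""Probe filtering, M-values, delta-beta, Welch calls, composition tallies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methexpr import (
    DataError,
    DmpThresholds,
    MethylationSet,
    ProbeAnnotation,
    call_dmps,
    composition_report,
    delta_beta,
    dmp_test,
    filter_probes,
    m_values,
)
from methexpr._stats import bh_adjust

from conftest import make_sheet


def make_annotation(n, chrom="chr1", snp=None, multimap=None, gene="GENEA", region="Body"):
    ids = [f"cg{i}" for i in range(n)]
    probes = pd.DataFrame(
        {
            "chrom": [chrom] * n if isinstance(chrom, str) else chrom,
            "pos": range(100, 100 + n),
            "cpg_context": ["OpenSea"] * n,
            "snp_flag": snp if snp is not None else [False] * n,
            "multimap_flag": multimap if multimap is not None else [False] * n,
        },
        index=pd.Index(ids, name="probe_id"),
    )
    gene_map = pd.DataFrame({"probe_id": ids, "gene": gene, "region": region})
    return ProbeAnnotation(probes, gene_map)


def make_meth(beta_rows, n_tumor, n_normal, detection_p=None):
    sheet = make_sheet(n_tumor, n_normal)
    beta = pd.DataFrame(
        beta_rows,
        index=pd.Index([f"cg{i}" for i in range(len(beta_rows))], name="probe_id"),
        columns=sheet.sample_ids,
    )
    det = None
    if detection_p is not None:
        det = pd.DataFrame(detection_p, index=beta.index, columns=beta.columns)
    return MethylationSet(beta, sheet, det)


class TestFilterProbes:
    def test_hand_enumerated_removals(self, rng):
        """10 probes: 2 on chrX, 1 SNP-flagged, 1 failing detection -> 6 kept."""
        chroms = ["chrX", "chrX"] + ["chr1"] * 8
        snp = [False] * 4 + [True] + [False] * 5
        annot = make_annotation(10, chrom=chroms, snp=snp)
        det = np.full((10, 4), 0.001)
        det[7, 2] = 0.02
        meth = make_meth(rng.random((10, 4)), 2, 2, detection_p=det)
        kept = filter_probes(meth, annot, DmpThresholds())
        assert list(kept.probe_ids) == ["cg2", "cg3", "cg5", "cg6", "cg8", "cg9"]

    def test_clean_probe_retained(self, rng):
        meth = make_meth(rng.random((3, 4)), 2, 2)
        kept = filter_probes(meth, make_annotation(3), DmpThresholds())
        assert list(kept.probe_ids) == ["cg0", "cg1", "cg2"]

    def test_unannotated_probe_is_an_error(self, rng):
        meth = make_meth(rng.random((3, 4)), 2, 2)
        with pytest.raises(DataError, match="cg2"):
            filter_probes(meth, make_annotation(2), DmpThresholds())


class TestMValues:
    def test_reference_points(self):
        meth = make_meth([[0.5, 0.8, 0.0, 0.5]], 2, 2)
        m = m_values(meth).to_numpy()[0]
        assert m[0] == pytest.approx(0.0)
        assert m[1] == pytest.approx(2.0)
        eps = 1e-6
        assert m[2] == pytest.approx(np.log2(eps / (1 - eps)))
        assert np.isfinite(m).all()


class TestDeltaBeta:
    def test_identical_groups_give_zero(self):
        meth = make_meth([[0.4, 0.4, 0.4, 0.4]], 2, 2)
        assert delta_beta(meth).iloc[0] == pytest.approx(0.0)

    def test_arithmetic(self):
        meth = make_meth([[0.8, 0.8, 0.5, 0.5]], 2, 2)
        assert delta_beta(meth).iloc[0] == pytest.approx(0.3)

    def test_matches_naive_loop(self, rng):
        beta = rng.random((50, 7))
        meth = make_meth(beta, 4, 3)
        db = delta_beta(meth).to_numpy()
        expected = np.array([row[:4].mean() - row[4:].mean() for row in beta])
        np.testing.assert_allclose(db, expected, atol=1e-15)


class TestDmpTest:
    def test_constant_equal_groups_give_p_one(self):
        meth = make_meth([[0.5] * 6], 3, 3)
        res = dmp_test(meth)
        assert res["p"].iloc[0] == 1.0
        assert res["stat"].iloc[0] == 0.0

    def test_identical_group_values_give_p_one(self):
        # beta chosen so M-values are {1, 2, 3}-like in both groups
        row = [0.6, 0.7, 0.8, 0.6, 0.7, 0.8]
        res = dmp_test(make_meth([row], 3, 3))
        assert res["stat"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_highly_significant(self):
        # tumor M ~ {2.9, 3.1, 3.0}; normal M ~ {0.1, -0.1, 0.0}
        def b(m):
            return 2.0**m / (1 + 2.0**m)

        row = [b(2.9), b(3.1), b(3.0), b(0.1), b(-0.1), b(0.0)]
        res = dmp_test(make_meth([row], 3, 3))
        assert res["p"].iloc[0] < 0.001


class TestCallDmps:
    def test_impossible_threshold_empty(self, rng):
        meth = make_meth(rng.random((20, 6)), 3, 3)
        out = call_dmps(meth, make_annotation(20), DmpThresholds(min_abs_delta_beta=1.1))
        assert len(out) == 0

    def test_direction_matches_delta_beta_sign(self, default_calls):
        dmps = default_calls["dmps"]
        assert len(dmps) > 0
        assert (
            (dmps["direction"] == "hyper") == (dmps["delta_beta"] > 0)
        ).all()
        assert (dmps["delta_beta"].abs() > 0.2).all()
        assert (dmps["adj_p"] <= 0.005).all()

    def test_invariant_to_probe_and_sample_order(self, rng):
        beta = rng.random((30, 8))
        meth = make_meth(beta, 5, 3)
        annot = make_annotation(30)
        th = DmpThresholds(min_abs_delta_beta=0.05, max_adj_p=0.5)
        base = call_dmps(meth, annot, th)

        perm = rng.permutation(30)
        meth_shuffled = MethylationSet(meth.beta.iloc[perm], meth.samples)
        shuffled = call_dmps(meth_shuffled, annot, th)
        pd.testing.assert_frame_equal(base, shuffled)

        cols = meth.samples.tumor_ids[::-1] + meth.samples.normal_ids[::-1]
        sheet = meth.samples.table.set_index("sample_id").loc[cols].reset_index()
        from methexpr import SampleSheet

        meth_cols = MethylationSet(meth.beta[cols], SampleSheet(sheet))
        reordered = call_dmps(meth_cols, annot, th)
        pd.testing.assert_frame_equal(base, reordered)


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_step_up_oracle(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(n)
        running = 1.0
        for rank_from_top in range(n, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, p[i] * n / rank_from_top)
            expected[i] = running
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        p = rng.random(200)
        adj = bh_adjust(p)
        assert (adj <= 1).all() and (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestComposition:
    def test_printed_percentages(self):
        """Hyper/hypo splits of a 23022-probe DMP set: 85.4% / 14.6%."""
        n_hyper, n_hypo = 19658, 3364
        ids = [f"cg{i}" for i in range(n_hyper + n_hypo)]
        records = pd.DataFrame(
            {
                "probe_id": ids,
                "direction": ["hyper"] * n_hyper + ["hypo"] * n_hypo,
            }
        )
        annot = make_annotation(n_hyper + n_hypo)
        report = composition_report(records, annot).set_index(["stratum", "category"])
        assert report.at[("direction", "hyper"), "percent"] == 85.4
        assert report.at[("direction", "hypo"), "percent"] == 14.6

    def test_single_category_is_100(self):
        records = pd.DataFrame({"probe_id": ["cg0", "cg1"], "direction": ["hyper", "hyper"]})
        report = composition_report(records, make_annotation(2)).set_index(
            ["stratum", "category"]
        )
        assert report.at[("direction", "hyper"), "percent"] == 100.0

    def test_region_counts_per_gene_pair(self):
        """A probe in two genes' regions contributes twice to region tallies."""
        probes = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "pos": [100],
                "cpg_context": ["Island"],
                "snp_flag": [False],
                "multimap_flag": [False],
            },
            index=pd.Index(["cg0"], name="probe_id"),
        )
        gene_map = pd.DataFrame(
            {"probe_id": ["cg0", "cg0"], "gene": ["A", "B"], "region": ["TSS200", "Body"]}
        )
        annot = ProbeAnnotation(probes, gene_map)
        records = pd.DataFrame({"probe_id": ["cg0"], "direction": ["hyper"]})
        report = composition_report(records, annot).set_index(["stratum", "category"])
        assert report.at[("region", "promoter"), "count"] == 1
        assert report.at[("region", "body"), "count"] == 1
        assert report.at[("context", "island"), "count"] == 1
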