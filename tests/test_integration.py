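"""Spearman screen, region/context stratification, quadrant concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from methexpr import (
    DataError,
    IntegrationParams,
    classify_quadrant,
    correlate_dmps,
    integration_summary,
    overlap_with_degs,
    ratio_test,
    spearman,
)


def rank_then_pearson(x, y):
    """Oracle: mid-ranks by hand, then Pearson, then the t-approximation."""

    def midranks(v):
        out = np.empty(len(v))
        for i, vi in enumerate(v):
            less = sum(1 for w in v if w < vi)
            equal = sum(1 for w in v if w == vi)
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = midranks(x), midranks(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return rho, p


class TestSpearman:
    def test_perfect_antimonotone(self):
        x = np.arange(10.0)
        rho, _ = spearman(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        rho, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            n = rng.integers(5, 20)
            x, y = rng.random(n), rng.random(n)
            rho, p = spearman(x, y)
            rho_o, p_o = rank_then_pearson(x, y)
            assert rho == pytest.approx(rho_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    @given(
        st.lists(
            st.integers(min_value=-1000, max_value=1000),
            min_size=5,
            max_size=20,
            unique=True,
        ),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transforms(self, xs, transform):
        rng = np.random.default_rng(7)
        x = np.array(xs, dtype=float)
        y = rng.permutation(len(x)).astype(float)
        f = {
            "exp": lambda v: np.exp(v / 100),
            "cube": lambda v: v**3,
            "affine": lambda v: 3 * v + 11,
        }[transform]
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(f(x), y)
        assert rho1 == pytest.approx(rho2, abs=1e-9)


class TestCorrelateDmps:
    def test_sign_agreement_with_planted_couplings(self, default_sim, default_calls):
        corr = default_calls["corr"]
        truth = default_sim.truth_probes.set_index("probe_id")
        coupled = truth[truth["coupled_gene"] != ""]
        planted = {
            (p, g): s
            for p, g, s in zip(coupled.index, coupled["coupled_gene"], coupled["coupling_sign"])
        }
        hits = [
            (p, g, s)
            for p, g, s in zip(corr["probe_id"], corr["gene"], corr["sign"])
            if (p, g) in planted
        ]
        assert len(hits) >= 3
        agreement = np.mean([s == planted[(p, g)] for p, g, s in hits])
        assert agreement >= 0.95

    def test_null_emission_rate_matches_alpha(self, null_sim):
        """Screening all probes at coupling 0 emits ~alpha of tested pairs."""
        from methexpr import estimate_size_factors, filter_low_expression, filter_probes

        filtered = filter_probes(null_sim.meth, null_sim.annotation)
        expr = estimate_size_factors(filter_low_expression(null_sim.expr))
        candidates = pd.DataFrame(
            {"probe_id": filtered.probe_ids, "direction": "hyper"}
        )
        corr = correlate_dmps(candidates, filtered, expr, null_sim.annotation)
        gm = null_sim.annotation.gene_map
        pairs = gm[gm["probe_id"].isin(set(filtered.probe_ids))]
        pairs = pairs[pairs["gene"].isin(set(expr.gene_ids))]
        n_tested = len(pairs.groupby(["probe_id", "gene"]))
        rate = len(corr) / n_tested
        half_width = sps.norm.ppf(0.995) * np.sqrt(0.05 * 0.95 / n_tested)
        assert abs(rate - 0.05) <= half_width

    def test_gene_absent_from_expression_is_skipped(self, default_sim, default_calls):
        sub_expr = default_calls["expr"].subset_genes(
            list(default_calls["expr"].gene_ids[:10])
        )
        dmps = default_calls["dmps"]
        corr = correlate_dmps(dmps, default_calls["filtered"], sub_expr, default_sim.annotation)
        assert set(corr["gene"]) <= set(sub_expr.gene_ids)

    def test_invariant_to_joint_sample_permutation(self, default_sim, default_calls):
        from methexpr import MethylationSet, ExpressionSet, SampleSheet

        filtered, expr = default_calls["filtered"], default_calls["expr"]
        dmps = default_calls["dmps"].head(20)
        base = correlate_dmps(dmps, filtered, expr, default_sim.annotation)
        rng = np.random.default_rng(3)
        tumor = list(filtered.samples.tumor_ids)
        shuffled = list(rng.permutation(tumor)) + filtered.samples.normal_ids
        sheet = SampleSheet(
            filtered.samples.table.set_index("sample_id").loc[shuffled].reset_index()
        )
        meth2 = MethylationSet(filtered.beta[shuffled], sheet)
        expr2 = ExpressionSet(expr.counts[shuffled], sheet, expr.size_factors[shuffled])
        perm = correlate_dmps(dmps, meth2, expr2, default_sim.annotation)
        pd.testing.assert_frame_equal(base, perm)


class TestRatioTest:
    def test_homogeneous_table(self):
        records = pd.DataFrame(
            {
                "sign": ["negative"] * 20 + ["positive"] * 20,
                "region_class": (["body"] * 10 + ["promoter"] * 10) * 2,
            }
        )
        rn, rp, p = ratio_test(records)
        assert rn == pytest.approx(1.0)
        assert rp == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_published_scale_counts(self):
        """Counts back-solved from body:promoter ratios 1.36 / 2.5 at 1756/767."""
        records = pd.DataFrame(
            {
                "sign": ["negative"] * 1756 + ["positive"] * 767,
                "region_class": ["body"] * 1012
                + ["promoter"] * 744
                + ["body"] * 548
                + ["promoter"] * 219,
            }
        )
        rn, rp, p = ratio_test(records)
        assert round(rn, 2) == 1.36
        assert round(rp, 2) == 2.50
        assert p < 0.00001

    def test_matches_textbook_chi_square(self, rng):
        for _ in range(30):
            counts = rng.integers(5, 100, 4)
            records = pd.DataFrame(
                {
                    "sign": ["negative"] * (counts[0] + counts[1])
                    + ["positive"] * (counts[2] + counts[3]),
                    "region_class": ["body"] * counts[0]
                    + ["promoter"] * counts[1]
                    + ["body"] * counts[2]
                    + ["promoter"] * counts[3],
                }
            )
            _, _, p = ratio_test(records)
            obs = np.array(counts, dtype=float).reshape(2, 2)
            row = obs.sum(axis=1, keepdims=True)
            col = obs.sum(axis=0, keepdims=True)
            exp = row @ col / obs.sum()
            chi2 = ((obs - exp) ** 2 / exp).sum()
            p_oracle = sps.chi2.sf(chi2, 1)
            assert p == pytest.approx(p_oracle, abs=1e-12)


class TestQuadrants:
    def test_canonical_concordant_cases(self):
        assert classify_quadrant("hyper", "negative", "down") is True
        assert classify_quadrant("hypo", "negative", "up") is True

    def test_exhaustive_four_concordant_four_discordant(self):
        combos = list(
            itertools.product(["hyper", "hypo"], ["negative", "positive"], ["up", "down"])
        )
        flags = [classify_quadrant(*c) for c in combos]
        assert sum(flags) == 4
        assert len(flags) == 8

    def test_double_flip_symmetry(self):
        flip_m = {"hyper": "hypo", "hypo": "hyper"}
        flip_e = {"up": "down", "down": "up"}
        for m, s, e in itertools.product(
            ["hyper", "hypo"], ["negative", "positive"], ["up", "down"]
        ):
            assert classify_quadrant(m, s, e) == classify_quadrant(flip_m[m], s, flip_e[e])

    def test_invalid_enum_rejected(self):
        with pytest.raises(ValueError):
            classify_quadrant("hyper", "negative", "sideways")


class TestOverlap:
    def test_empty_deg_table_gives_empty_output(self, default_calls):
        out = overlap_with_degs(
            default_calls["corr"], default_calls["dmps"], pd.DataFrame(columns=["gene", "direction"])
        )
        assert len(out) == 0

    def test_join_soundness(self, default_calls):
        quad = default_calls["quadrants"]
        assert set(quad["probe_id"]) <= set(default_calls["dmps"]["probe_id"])
        assert set(quad["gene"]) <= set(default_calls["degs"]["gene"])
        pairs_corr = set(zip(default_calls["corr"]["probe_id"], default_calls["corr"]["gene"]))
        assert set(zip(quad["probe_id"], quad["gene"])) <= pairs_corr

    def test_hand_built_join(self):
        corr = pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3", "p4", "p5"],
                "gene": ["g1", "g2", "g3", "g4", "g5"],
                "rho": [-0.5, 0.5, -0.5, 0.5, -0.5],
                "p": [0.01] * 5,
                "sign": ["negative", "positive", "negative", "positive", "negative"],
                "region_class": ["promoter"] * 5,
                "context_class": ["island"] * 5,
            }
        )
        dmps = pd.DataFrame(
            {"probe_id": ["p1", "p3", "p5"], "direction": ["hyper", "hypo", "hyper"]}
        )
        degs = pd.DataFrame({"gene": ["g1", "g3"], "direction": ["down", "up"]})
        out = overlap_with_degs(corr, dmps, degs)
        assert list(zip(out["probe_id"], out["gene"])) == [("p1", "g1"), ("p3", "g3")]
        assert out["concordant"].tolist() == [True, True]

    def test_concordance_flag_matches_pure_function(self, default_calls):
        quad = default_calls["quadrants"]
        for _, row in quad.iterrows():
            assert row["concordant"] == classify_quadrant(
                row["meth_direction"], row["corr_sign"], row["expr_direction"]
            )


class TestSummary:
    def test_printed_percentage(self):
        corr = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(2523)],
                "gene": [f"g{i % 1470}" for i in range(2523)],
                "rho": [-0.5] * 1756 + [0.5] * 767,
                "sign": ["negative"] * 1756 + ["positive"] * 767,
            }
        )
        s = integration_summary(corr, pd.DataFrame(), n_tested_dmps=23022)
        assert s["pct_significant"] == 11.0
        assert s["n_positive"] == 2523 - 1756

    def test_identities(self, default_calls):
        s = integration_summary(
            default_calls["corr"],
            default_calls["quadrants"],
            n_tested_dmps=len(default_calls["dmps"]),
        )
        assert s["n_negative"] + s["n_positive"] == s["n_records"]
        quad_total = sum(v for k, v in s.items() if k.startswith("quadrant_"))
        assert quad_total == s["n_pairs"]

    def test_empty_input_all_zero(self):
        s = integration_summary(pd.DataFrame(columns=["probe_id", "gene", "rho", "sign"]),
                                pd.DataFrame(), n_tested_dmps=0)
        assert s["n_records"] == 0
        assert s["n_pairs"] == 0
        assert s["pct_significant"] == 0.0
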