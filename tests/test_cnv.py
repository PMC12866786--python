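"""Genome ordering, sliding-window smoothing and burden-comparison tests."""

import numpy as np
import pandas as pd
import pytest

import spatialmargin as sm
from spatialmargin.cnv import _moving_average_truncated
from spatialmargin.exceptions import InputError, ParameterError


def brute_force_window_mean(values, window, chroms):
    """Oracle: per-gene mean over the centered window clipped to the
    gene's chromosome."""
    left, right = window // 2, window - 1 - window // 2
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        sel = np.flatnonzero(chroms == chroms[j])
        pos = int(np.flatnonzero(sel == j)[0])
        lo, hi = max(pos - left, 0), min(pos + right, len(sel) - 1)
        out[:, j] = values[:, sel[lo: hi + 1]].mean(axis=1)
    return out


class TestOrderGenes:
    def _ann(self):
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d", "e"],
                "chromosome": ["chr2", "chr1", "chr1", "chr10", "chr2"],
                "ordinal": [5, 1, 2, 1, 1],
            }
        )

    def test_sorted_output_matches_brute_force(self):
        out, dropped = sm.order_genes(self._ann())
        assert out["gene"].tolist() == ["b", "c", "e", "a", "d"]
        assert dropped == []

    def test_already_ordered_is_identity(self):
        ann = pd.DataFrame(
            {"gene": list("abcd"), "chromosome": ["chr1"] * 4,
             "ordinal": [1, 2, 3, 4]}
        )
        out, _ = sm.order_genes(ann)
        assert out["gene"].tolist() == list("abcd")

    def test_unannotated_genes_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="lack annotation"):
            out, dropped = sm.order_genes(self._ann(), genes=["b", "zz", "a"])
        assert dropped == ["zz"]
        assert out["gene"].tolist() == ["b", "a"]

    def test_duplicate_position_tiebreak_by_gene_id(self):
        ann = pd.DataFrame(
            {"gene": ["z", "a"], "chromosome": ["chr1", "chr1"], "ordinal": [1, 1]}
        )
        with pytest.warns(UserWarning, match="duplicate"):
            out, _ = sm.order_genes(ann)
        assert out["gene"].tolist() == ["a", "z"]


class TestSmoothing:
    def test_self_reference_profile_is_zero(self, rng):
        genes = [f"g{i}" for i in range(300)]
        expr = pd.DataFrame(rng.random((1, 300)), columns=genes)
        ref = expr.iloc[0]
        cfg = sm.CNVConfig(window_genes=11)
        out = sm.smooth_cnv(expr, ref, np.repeat(["chr1", "chr2"], 150), cfg)
        assert np.allclose(out.to_numpy(), 0.0)

    @pytest.mark.parametrize("window", [3, 4, 11, 250])
    def test_matches_brute_force_everywhere(self, rng, window):
        n_genes = 700
        chroms = np.repeat(["chr1", "chr2", "chr3"], [300, 260, 140])
        vals = rng.normal(size=(5, n_genes))
        genes = [f"g{i}" for i in range(n_genes)]
        expr = pd.DataFrame(vals, columns=genes)
        ref = pd.Series(np.zeros(n_genes), index=genes)
        out = sm.smooth_cnv(expr, ref, chroms, sm.CNVConfig(window_genes=window))
        assert np.allclose(out.to_numpy(),
                           brute_force_window_mean(vals, window, chroms))

    def test_window_never_crosses_chromosomes(self, rng):
        # sentinel: chr2 constant 5.0; chr1 random. Any leakage would pull
        # chr2's smoothed values off 5.0 and chr1 ends toward 5.0.
        chroms = np.repeat(["chr1", "chr2"], [100, 80])
        vals = np.concatenate([rng.normal(size=(1, 100)),
                               np.full((1, 80), 5.0)], axis=1)
        genes = [f"g{i}" for i in range(180)]
        out = sm.smooth_cnv(
            pd.DataFrame(vals, columns=genes),
            pd.Series(np.zeros(180), index=genes),
            chroms,
            sm.CNVConfig(window_genes=51),
        )
        assert np.allclose(out.to_numpy()[0, 100:], 5.0)
        assert np.all(np.abs(out.to_numpy()[0, :100]) < 4.0)

    def test_even_window_centering_125_left_124_right(self):
        vals = np.zeros((1, 600))
        vals[0, 300] = 1.0  # unit impulse
        genes = [f"g{i}" for i in range(600)]
        out = sm.smooth_cnv(
            pd.DataFrame(vals, columns=genes),
            pd.Series(np.zeros(600), index=genes),
            np.repeat("chr1", 600),
            sm.CNVConfig(window_genes=250),
        )
        hit = np.flatnonzero(out.to_numpy()[0] > 0)
        # gene j sees the impulse iff 300 in [j-125, j+124]
        assert hit[0] == 300 - 124 and hit[-1] == 300 + 125
        assert np.allclose(out.to_numpy()[0, hit], 1.0 / 250.0)

    def test_tiny_chromosome_passthrough_warns(self, rng):
        chroms = np.array(["chr1"] * 10 + ["chr2"] * 2)
        genes = [f"g{i}" for i in range(12)]
        vals = rng.normal(size=(2, 12))
        with pytest.warns(UserWarning, match="unsmoothed"):
            out = sm.smooth_cnv(
                pd.DataFrame(vals, columns=genes),
                pd.Series(np.zeros(12), index=genes),
                chroms,
                sm.CNVConfig(window_genes=5),
            )
        assert np.allclose(out.to_numpy()[:, 10:], vals[:, 10:])

    def test_mismatched_gene_order_rejected(self):
        expr = pd.DataFrame(np.ones((1, 3)), columns=list("abc"))
        ref = pd.Series(np.zeros(3), index=list("acb"))
        with pytest.raises(InputError):
            sm.smooth_cnv(expr, ref, np.repeat("chr1", 3))

    def test_window_parameter_validation(self):
        with pytest.raises(ParameterError):
            sm.CNVConfig(window_genes=2)
        with pytest.raises(ParameterError):
            sm.CNVConfig(burden_stat="median")


class TestBurden:
    def test_zero_profile_zero_burden(self):
        prof = pd.DataFrame(np.zeros((3, 50)))
        assert np.all(sm.cnv_burden(prof) == 0.0)
        assert np.all(
            sm.cnv_burden(prof, sm.CNVConfig(burden_stat="mean_square")) == 0.0
        )

    def test_mean_square_sign_invariant_signed_mean_not(self, rng):
        prof = pd.DataFrame(rng.normal(size=(4, 60)))
        cfg = sm.CNVConfig(burden_stat="mean_square")
        assert np.allclose(sm.cnv_burden(prof, cfg), sm.cnv_burden(-prof, cfg))
        assert np.allclose(sm.cnv_burden(-prof), -sm.cnv_burden(prof))

    def test_three_groups_three_pairs(self, rng):
        g = {k: rng.normal(size=20) for k in "abc"}
        out = sm.compare_burden(g)
        assert len(out) == 3
        assert set(map(tuple, out[["group_a", "group_b"]].to_numpy())) == {
            ("a", "b"), ("a", "c"), ("b", "c")
        }

    def test_identical_groups_p_one_single_group_empty(self, rng):
        x = rng.normal(size=15)
        out = sm.compare_burden({"a": x, "b": x.copy()})
        assert out["p"].iloc[0] == 1.0
        assert sm.compare_burden({"a": x}).empty


@pytest.fixture(scope="module")
def planted():
    scene = sm.Scene(
        width_um=5000.0,
        height_um=5000.0,
        tumor_region=sm.disk(2500.0, 2500.0, 1000.0),
        cnv_blocks=(sm.CNVBlock("chr2", 50, 349, 2.0),),
        seed=5,
    )
    panel = sm.make_signature_panel(2000, 5, 4, 0.02, seed=5)
    section = sm.plant_cnv(sm.simulate_section(scene, panel), panel, scene)
    scorer = sm.CNVScorer(window_genes=250, reference_label="AT2").fit(
        section.counts_frame(), panel.annotation_frame(),
        labels=section.truth_type,
    )
    return scene, panel, section, scorer


class TestScorerPlantedRecovery:
    def test_gain_block_positive_and_above_background(self, planted):
        _, panel, section, scorer = planted
        tumor = section.truth_type == "AT2-like"
        prof = scorer.transform(section.counts_frame().loc[tumor]).to_numpy()
        order = scorer.gene_order_
        block = (
            (order["chromosome"] == "chr2")
            & order["ordinal"].between(50, 349)
        ).to_numpy()
        mean_prof = prof.mean(axis=0)
        assert mean_prof[block].mean() > 0
        assert mean_prof[block].mean() >= 3.0 * mean_prof[~block].std()

    def test_reference_spots_burden_near_zero(self, planted):
        _, _, section, scorer = planted
        ref = section.truth_type == "AT2"
        burden = sm.cnv_burden(scorer.transform(section.counts_frame().loc[ref]))
        se = burden.std() / np.sqrt(len(burden))
        assert abs(burden.mean()) <= 3.0 * se

    def test_monotone_in_gain_factor(self, planted):
        scene, panel, section, scorer = planted
        import dataclasses

        block_means = []
        order = scorer.gene_order_
        block = (
            (order["chromosome"] == "chr2") & order["ordinal"].between(50, 349)
        ).to_numpy()
        base = sm.simulate_section(
            dataclasses.replace(scene, cnv_blocks=()), panel
        )
        for f in (1.0, 1.5, 2.0):
            sc = dataclasses.replace(
                scene, cnv_blocks=(sm.CNVBlock("chr2", 50, 349, f),)
            )
            sec = sm.plant_cnv(base, panel, sc)
            tumor = sec.truth_type == "AT2-like"
            prof = scorer.transform(sec.counts_frame().loc[tumor])
            block_means.append(prof.to_numpy()[:, block].mean())
        assert block_means[0] < block_means[1] < block_means[2]

    def test_burden_comparison_significant_at_200_per_group(self, planted):
        _, _, section, scorer = planted
        rng = np.random.default_rng(6)
        ti = np.flatnonzero(section.truth_type == "AT2-like")
        ri = np.flatnonzero(section.truth_type == "AT2")
        sel = np.concatenate(
            [rng.choice(ti, 200, replace=False), rng.choice(ri, 200, replace=False)]
        )
        prof = scorer.transform(section.counts_frame().iloc[sel])
        burden = sm.cnv_burden(prof, sm.CNVConfig(burden_stat="mean_square"))
        comp = sm.compare_burden(
            {"AT2-like": burden.to_numpy()[:200], "AT2": burden.to_numpy()[200:]}
        )
        assert comp["p_adj"].iloc[0] < 0.05
        assert burden.to_numpy()[:200].mean() > burden.to_numpy()[200:].mean()
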