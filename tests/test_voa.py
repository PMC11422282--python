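import numpy as np
import pandas as pd
import pytest

from boldcvr import (
    ResponseProfile,
    WindowDesign,
    analyze_subject,
    composite_mean,
    compute_voa,
    generate_subject,
    group_compare,
    region_fdr,
)


def make_voa_table(sham, injured, composite="ctx", leaf="ctx_01"):
    """Single-leaf VOA table from per-subject counts."""
    rows = []
    for i, v in enumerate(sham):
        rows.append(("sham_%02d" % i, "sham", leaf, composite, v, 100))
    for i, v in enumerate(injured):
        rows.append(("inj_%02d" % i, "injured", leaf, composite, v, 100))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "condition", "leaf_region", "composite_region",
                 "voa", "region_size"],
    )


class TestComputeVoa:
    def test_counts_activated_voxels(self, tiny_atlas):
        activated = np.zeros(tiny_atlas.geometry.dims, dtype=bool)
        lid = tiny_atlas.label_of("ctx_01")
        vox = np.argwhere(tiny_atlas.labels == lid)[:12]
        activated[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        voa = compute_voa(activated, tiny_atlas.labels, tiny_atlas, "s", "sham")
        row = voa.set_index("leaf_region").loc["ctx_01"]
        assert row["voa"] == 12
        assert row["region_size"] == int((tiny_atlas.labels == lid).sum())

    def test_empty_map_all_zero(self, tiny_atlas):
        voa = compute_voa(
            np.zeros(tiny_atlas.geometry.dims, bool), tiny_atlas.labels,
            tiny_atlas, "s", "sham",
        )
        assert (voa["voa"] == 0).all()
        assert len(voa) == 4

    def test_conservation_over_regions(self, tiny_atlas):
        rng = np.random.default_rng(0)
        activated = rng.uniform(size=tiny_atlas.geometry.dims) < 0.3
        voa = compute_voa(activated, tiny_atlas.labels, tiny_atlas, "s", "sham")
        in_atlas = activated & (tiny_atlas.labels > 0)
        assert voa["voa"].sum() == int(in_atlas.sum())

    def test_orphan_label_rejected(self, tiny_atlas):
        labels = tiny_atlas.labels.copy()
        labels[0, 0, 0] = 55
        with pytest.raises(ValueError, match=r"\[55\]"):
            compute_voa(np.zeros(labels.shape, bool), labels, tiny_atlas,
                        "s", "sham")

    def test_phantom_truth_exact_when_noiseless(self, tiny_atlas, quiet_noise):
        prof = ResponseProfile(amplitude=3.0, onset_volume=11,
                               offset_volume=20, ramp_tau=0.0)
        series, truth = generate_subject(
            tiny_atlas, {"ctx": prof}, noise=quiet_noise, seed=0, n_volumes=30
        )
        res = analyze_subject(
            series, WindowDesign((1, 10), (11, 20), (21, 30)),
            tiny_atlas.brain_mask,
        )
        voa = compute_voa(res.activated, tiny_atlas.labels, tiny_atlas, "s",
                          "sham")
        for row in voa.itertuples():
            assert row.voa == truth.true_voa[row.leaf_region]


class TestCompositeMean:
    def test_mean_over_leaves(self):
        tbl = pd.concat(
            [
                make_voa_table([10], [0], leaf="ctx_01"),
                make_voa_table([20], [0], leaf="ctx_02"),
                make_voa_table([30], [0], leaf="ctx_03"),
            ]
        )
        means = composite_mean(tbl, "ctx")
        assert means["sham_00"] == pytest.approx(20.0)

    def test_single_leaf_composite(self):
        tbl = make_voa_table([7, 9], [5, 5])
        means = composite_mean(tbl, "ctx")
        assert means["sham_00"] == 7

    def test_unknown_composite_rejected(self):
        with pytest.raises(KeyError):
            composite_mean(make_voa_table([1], [1]), "nope")


class TestGroupCompare:
    def test_symmetric_groups_give_zero_md(self):
        gc = group_compare(make_voa_table([10, 10, 10], [10, 10, 10]), "ctx",
                           ci_method="welch")
        assert gc.mean_difference == 0.0
        assert gc.ci_low <= 0.0 <= gc.ci_high

    def test_md_arithmetic(self):
        gc = group_compare(make_voa_table([4, 6, 8], [3, 5, 7]), "ctx",
                           n_boot=200, seed=0)
        assert gc.mean_difference == pytest.approx(-1.0)

    def test_antisymmetry_of_md(self):
        tbl = make_voa_table([4, 6, 8], [1, 5, 9])
        swapped = tbl.copy()
        swapped["condition"] = swapped["condition"].map(
            {"sham": "injured", "injured": "sham"}
        )
        a = group_compare(tbl, "ctx", ci_method="welch")
        b = group_compare(swapped, "ctx", ci_method="welch")
        assert a.mean_difference == pytest.approx(-b.mean_difference)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        tbl = make_voa_table(rng.integers(5, 40, 7), rng.integers(5, 40, 7))
        gc = group_compare(tbl, "ctx", n_boot=2000, seed=1)
        assert gc.ci_low <= gc.mean_difference <= gc.ci_high

    def test_bootstrap_is_seeded(self):
        tbl = make_voa_table([4, 9, 8, 2], [3, 5, 7, 11])
        a = group_compare(tbl, "ctx", n_boot=500, seed=9)
        b = group_compare(tbl, "ctx", n_boot=500, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            group_compare(make_voa_table([5, 5], [4]), "ctx")

    def test_leaf_table_has_estimation_rows(self):
        tbl = pd.concat(
            [
                make_voa_table([1, 2, 3], [4, 5, 6], leaf="ctx_01"),
                make_voa_table([2, 2, 2], [1, 1, 1], leaf="ctx_02"),
            ]
        )
        gc = group_compare(tbl, "ctx", n_boot=200, seed=0)
        assert set(gc.leaf_table["leaf_region"]) == {"ctx_01", "ctx_02"}
        row = gc.leaf_table.set_index("leaf_region").loc["ctx_01"]
        assert row["mean_difference"] == pytest.approx(3.0)  # 5 - 2


class TestRegionFdr:
    def test_single_small_p_significant(self):
        out = region_fdr({"ctx": 0.01})
        assert bool(out["ctx"])

    def test_all_large_p_not_significant(self):
        out = region_fdr({f"r{i}": 0.5 for i in range(10)})
        assert not out.any()

    def test_matches_brute_force(self):
        from tests_oracles import bh_step_up

        rng = np.random.default_rng(1)
        p = np.concatenate([[0.001, 0.011, 0.02], rng.uniform(0, 1, 9)])
        names = [f"r{i}" for i in range(len(p))]
        got = region_fdr(dict(zip(names, p)))
        want = bh_step_up(p, 0.05)
        np.testing.assert_array_equal(got.to_numpy(), want)
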