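"""Standard-curve fitting, geNorm stability and fold-change recovery."""

import numpy as np
import pandas as pd
import pytest

from mdxquant import qpcr, synthdata


def _plate_rows(gene, cts, dilutions):
    return pd.DataFrame(
        {
            "gene": gene,
            "sample": [f"std_{i}" for i in range(len(cts))],
            "group": "standard",
            "replicate": 1,
            "ct": cts,
            "is_dilution_standard": True,
            "dilution_factor": dilutions,
        }
    )


class TestStandardCurve:
    def test_perfect_tenfold_series_slope_and_efficiency(self):
        plate = _plate_rows("g", [20.0, 23.3219, 26.6439], [1.0, 0.1, 0.01])
        curve = qpcr.fit_standard_curve(plate, "g")
        assert curve.slope == pytest.approx(-3.3219, abs=1e-3)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-3)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_efficiency_from_slope_closed_form(self):
        x = np.array([1.0, 0.1, 0.01, 0.001])
        cts = 20.0 - 3.5 * np.log10(x)
        curve = qpcr.fit_standard_curve(_plate_rows("g", cts, x), "g")
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.5) - 1, abs=1e-6)

    def test_two_points_insufficient(self):
        with pytest.raises(ValueError, match=">= 3"):
            qpcr.fit_standard_curve(_plate_rows("g", [20.0, 23.3], [1.0, 0.1]), "g")

    def test_positive_slope_flags_invalid(self):
        curve = qpcr.fit_standard_curve(
            _plate_rows("g", [26.6, 23.3, 20.0], [1.0, 0.1, 0.01]), "g"
        )
        assert not curve.valid
        with pytest.raises(ValueError, match="invalid"):
            qpcr.relative_quantity(20.0, curve)


class TestRelativeQuantity:
    curve = qpcr.StandardCurve("g", slope=-3.3219, intercept=22.0, r_squared=1.0)

    def test_ct_at_intercept_is_unity(self):
        assert qpcr.relative_quantity(22.0, self.curve) == pytest.approx(1.0)

    def test_one_slope_below_is_tenfold(self):
        assert qpcr.relative_quantity(22.0 - 3.3219, self.curve) == pytest.approx(10.0)

    def test_zero_noise_round_trip(self):
        plate = synthdata.generate_qpcr_plate(
            ["a"],
            ["wt", "mdx"],
            3,
            {"a": 0.95},
            {"a": {"wt": 1.0, "mdx": 3.0}},
            noise_sd_ct=0.0,
            seed=5,
        )
        qt = qpcr.quantity_table(plate)
        got = qt.set_index(["group", "sample"])["quantity"]
        assert np.allclose(got.xs("wt", level="group"), 1.0, rtol=0.01)
        assert np.allclose(got.xs("mdx", level="group"), 3.0, rtol=0.01)


def _qtable(quantities: dict[str, list[float]], groups=None) -> pd.DataFrame:
    genes = list(quantities)
    n = len(quantities[genes[0]])
    rows = []
    for g in genes:
        for i, q in enumerate(quantities[g]):
            rows.append(
                {
                    "gene": g,
                    "sample": f"s{i}",
                    "group": (groups or ["x"] * n)[i],
                    "quantity": q,
                    "replicate_cv": 0.0,
                    "n_replicates": 1,
                }
            )
    return pd.DataFrame(rows)


class TestGeNorm:
    def test_proportional_genes_have_zero_m(self):
        qt = _qtable({"a": [1, 2, 4, 8], "b": [3, 6, 12, 24]})
        m = qpcr.genorm_m(qt)
        assert np.allclose(m, 0.0, atol=1e-12)

    def test_matches_brute_force_definition(self, rng):
        q = {g: rng.lognormal(0, 0.5, 4).tolist() for g in ("a", "b", "c")}
        m = qpcr.genorm_m(_qtable(q))
        logq = {g: np.log2(q[g]) for g in q}
        for j in q:
            sds = [
                np.std(logq[j] - logq[k], ddof=1) for k in q if k != j
            ]
            assert m[j] == pytest.approx(np.mean(sds), rel=1e-12)

    def test_noise_on_one_gene_raises_its_m(self):
        base = np.array([1.0, 2.0, 0.5, 1.5, 3.0, 0.8])
        rng = np.random.default_rng(3)
        ms = []
        for sigma in (0.05, 0.2, 0.8):
            noisy = base * rng.lognormal(0, sigma, base.size)
            qt = _qtable(
                {"a": base.tolist(), "b": (2 * base).tolist(), "c": noisy.tolist()}
            )
            ms.append(qpcr.genorm_m(qt)["c"])
        assert ms[0] < ms[1] < ms[2]

    def test_m_invariant_to_global_gene_rescaling(self):
        qt1 = _qtable({"a": [1, 2, 3], "b": [2, 1, 5], "c": [4, 4, 1]})
        qt2 = qt1.copy()
        qt2.loc[qt2["gene"] == "b", "quantity"] *= 100.0
        assert np.allclose(qpcr.genorm_m(qt1), qpcr.genorm_m(qt2))

    def test_pairwise_variation_zero_for_proportional_added_gene(self):
        qt = _qtable(
            {"a": [1, 2, 4], "b": [2, 4, 8], "c": [0.5, 1, 2], "d": [7, 3, 9]}
        )
        v = qpcr.pairwise_variation(qt, ranking=["d", "c", "b", "a"])
        # adding the third-most-stable gene (proportional to the best two)
        # does not change the normalization factor
        assert v["V2/3"] == pytest.approx(0.0, abs=1e-12)


class TestNormalizationFoldChange:
    def test_identical_samples_unit_everything(self):
        qt = _qtable({"a": [2, 2], "b": [5, 5]}, groups=["wt", "tr"])
        norm, fold = qpcr.normalization_and_fold_change(qt, ["a"], "wt")
        assert np.allclose(norm["normalization_factor"], 1.0)
        assert np.allclose(fold["fold_change"], 1.0)

    def test_doubled_target_gene_gives_fold_two(self):
        qt = _qtable(
            {"ref": [1, 1, 1, 1], "tgt": [1, 1, 2, 2]},
            groups=["wt", "wt", "tr", "tr"],
        )
        _, fold = qpcr.normalization_and_fold_change(qt, ["ref"], "wt")
        f = fold.set_index(["gene", "group"])["fold_change"]
        assert f[("tgt", "tr")] == pytest.approx(2.0)

    def test_sample_scale_absorbed_by_normalization(self):
        # multiplying one sample's quantities by a constant is absorbed by
        # its normalization factor: normalized quantities change only by a
        # common rescaling (NF geometric mean is anchored to 1), so every
        # ratio and fold change is untouched
        qt = _qtable(
            {"ref": [1, 1], "tgt": [3, 3]}, groups=["wt", "tr"]
        )
        scaled = qt.copy()
        scaled.loc[scaled["sample"] == "s1", "quantity"] *= 10.0
        n1, f1 = qpcr.normalization_and_fold_change(qt, ["ref"], "wt")
        n2, f2 = qpcr.normalization_and_fold_change(scaled, ["ref"], "wt")
        v1 = n1.sort_values(["gene", "sample"])["normalized_quantity"].to_numpy()
        v2 = n2.sort_values(["gene", "sample"])["normalized_quantity"].to_numpy()
        assert np.allclose(v2 / v1, (v2 / v1)[0])
        assert np.allclose(
            f1.sort_values(["gene", "group"])["fold_change"],
            f2.sort_values(["gene", "group"])["fold_change"],
        )

    def test_missing_control_group_raises(self):
        qt = _qtable({"a": [1, 2]}, groups=["x", "y"])
        with pytest.raises(ValueError, match="control"):
            qpcr.normalization_and_fold_change(qt, ["a"], "wt")


class TestPlateGenerator:
    def test_delta_ct_closed_form(self):
        plate = synthdata.generate_qpcr_plate(
            ["g"],
            ["lo", "hi"],
            1,
            {"g": 1.0},
            {"g": {"lo": 1.0, "hi": 10.0}},
            noise_sd_ct=0.0,
            seed=0,
        )
        samp = plate[~plate["is_dilution_standard"]].groupby("group")["ct"].mean()
        assert samp["hi"] - samp["lo"] == pytest.approx(-1 / np.log10(2), abs=1e-9)

    def test_deterministic_under_seed(self):
        kw = dict(
            genes=["a", "b"],
            groups=["wt"],
            n_per_group=3,
            efficiencies={"a": 0.9, "b": 1.0},
            base_quantities={"a": {"wt": 1.0}, "b": {"wt": 2.0}},
            noise_sd_ct=0.3,
            seed=11,
        )
        pd.testing.assert_frame_equal(
            synthdata.generate_qpcr_plate(**kw), synthdata.generate_qpcr_plate(**kw)
        )

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            synthdata.generate_qpcr_plate(
                ["g"], ["wt"], 1, {"g": 1.5}, {"g": {"wt": 1.0}}
            )
        with pytest.raises(ValueError, match="onpositive"):
            synthdata.generate_qpcr_plate(
                ["g"], ["wt"], 1, {"g": 1.0}, {"g": {"wt": 0.0}}
            )
        with pytest.raises(ValueError):
            synthdata.generate_qpcr_plate(
                ["g"], ["wt"], 1, {"g": 1.0}, {"g": {"wt": 1.0}}, dilution_steps=2
            )
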