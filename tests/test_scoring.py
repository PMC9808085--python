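"""Per-feature scaling, weighted-mean scores and the permutation NES."""
import itertools

import numpy as np
import pandas as pd
import pytest

import omiqc as oq
from conftest import toy_matrix


class TestScalePerFeature:
    def test_hand_example(self):
        out = oq.scale_per_feature(toy_matrix([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.values()[0], [-1.0, 0.0, 1.0])
        assert out.stage == "scaled"

    def test_constant_feature_becomes_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = oq.scale_per_feature(toy_matrix([[5.0, 5.0, 5.0], [1, 2, 3]]))
        np.testing.assert_array_equal(out.values()[0], 0.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            oq.scale_per_feature(toy_matrix([[1.0]]))

    def test_normalization_contract(self):
        rng = np.random.default_rng(0)
        out = oq.scale_per_feature(toy_matrix(rng.normal(5, 3, (30, 10)))).values()
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)


class TestWmeanScore:
    def test_unit_weights_give_plain_mean(self):
        profile = pd.Series({"a": 1.0, "b": 2.0, "c": 6.0, "d": 100.0})
        sig = oq.Signature("s", {"a": 1.0, "b": 1.0, "c": 1.0})
        assert oq.wmean_score(profile, sig) == pytest.approx(3.0)

    def test_signed_weights_hand_example(self):
        profile = pd.Series({"f1": 2.0, "f2": -1.0})
        sig = oq.Signature("s", {"f1": 1.0, "f2": -2.0})
        assert oq.wmean_score(profile, sig, min_overlap=2) == pytest.approx(4.0 / 3.0)

    def test_insufficient_overlap_rejected(self):
        profile = pd.Series({"f1": 2.0, "f2": -1.0})
        sig = oq.Signature("s", {"f1": 1.0, "f2": -2.0, "f3": 1.0})
        with pytest.raises(ValueError, match="min_overlap"):
            oq.wmean_score(profile, sig, min_overlap=3)

    def test_unmeasured_features_warned(self):
        profile = pd.Series({"f1": 2.0, "f2": -1.0, "f3": 0.5})
        sig = oq.Signature("s", {"f1": 1.0, "f2": 1.0, "f3": 1.0, "f4": 9.0})
        with pytest.warns(UserWarning, match="unmeasured"):
            oq.wmean_score(profile, sig)

    def test_all_zero_overlap_weights_rejected(self):
        profile = pd.Series({"f1": 2.0, "f2": -1.0, "f3": 1.0})
        sig = oq.Signature("s", {"f1": 0.0, "f2": 0.0, "f3": 0.0, "f4": 1.0})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="zero"):
                oq.wmean_score(profile, sig)


def scaledm(values, **kw):
    return toy_matrix(values, stage="scaled", **kw)


class TestNesScores:
    def test_degenerate_null_yields_missing_nes(self):
        m = scaledm([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        sig = oq.Signature("s", {"f0": 1.0, "f1": 1.0, "f2": 1.0})
        with pytest.warns(UserWarning, match="degenerate"):
            st = oq.nes_scores(m, [sig], n_perm=100, seed=0)
        assert st.table["nes"].isna().all()

    def test_sign_flip_negates_scores(self):
        rng = np.random.default_rng(2)
        m = scaledm(rng.normal(size=(30, 4)))
        sig = oq.Signature("s", {f"f{i}": 1.0 for i in range(8)})
        neg = oq.Signature("s", {f"f{i}": -1.0 for i in range(8)})
        a = oq.nes_scores(m, [sig], n_perm=200, seed=1).table
        b = oq.nes_scores(m, [neg], n_perm=200, seed=1).table
        np.testing.assert_allclose(a["raw_score"], -b["raw_score"])
        np.testing.assert_allclose(a["nes"], -b["nes"], rtol=1e-9)

    def test_invariant_to_positive_weight_rescaling(self):
        rng = np.random.default_rng(3)
        m = scaledm(rng.normal(size=(25, 3)))
        w = {f"f{i}": rng.normal() for i in range(6)}
        sig1 = oq.Signature("s", w)
        sig2 = oq.Signature("s", {k: 7.3 * v for k, v in w.items()})
        a = oq.nes_scores(m, [sig1], n_perm=150, seed=4).table
        b = oq.nes_scores(m, [sig2], n_perm=150, seed=4).table
        np.testing.assert_allclose(a["raw_score"], b["raw_score"], rtol=1e-12)
        np.testing.assert_allclose(a["nes"], b["nes"], rtol=1e-9)

    def test_invariant_to_sample_column_order(self):
        rng = np.random.default_rng(5)
        m = scaledm(rng.normal(size=(20, 6)))
        rev = oq.OmicsMatrix(m.data[list(m.samples[::-1])], stage="scaled")
        sig = oq.Signature("s", {f"f{i}": 1.0 for i in range(5)})
        a = oq.nes_scores(m, [sig], n_perm=150, seed=6).table.set_index("sample_id")
        b = oq.nes_scores(rev, [sig], n_perm=150, seed=6).table.set_index("sample_id")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        m = scaledm(rng.normal(size=(15, 3)))
        sig = oq.Signature("s", {f"f{i}": 1.0 for i in range(4)})
        a = oq.nes_scores(m, [sig], n_perm=120, seed=9).table
        b = oq.nes_scores(m, [sig], n_perm=120, seed=9).table
        pd.testing.assert_frame_equal(a, b)

    def test_small_n_perm_rejected(self):
        m = scaledm(np.zeros((5, 2)))
        sig = oq.Signature("s", {"f0": 1.0, "f1": 1.0, "f2": 1.0})
        with pytest.raises(ValueError):
            oq.nes_scores(m, [sig], n_perm=50)

    def test_null_matches_exhaustive_enumeration(self):
        """Sampled null vs brute-force enumeration over member-value pairs."""
        x = np.array([0.3, -1.2, 2.5, 0.9, -0.4])
        m = scaledm(x[:, None] * np.ones((1, 1)), samples=["s"])
        sig = oq.Signature("s", {"f0": 1.0, "f1": 1.0})
        st = oq.nes_scores(m, [sig], n_perm=30000, seed=13, min_overlap=2).table
        pair_means = [(a + b) / 2 for a, b in itertools.combinations(x, 2)]
        assert st["null_mean"][0] == pytest.approx(np.mean(pair_means), rel=0.02)
        assert st["null_sd"][0] == pytest.approx(np.std(pair_means), rel=0.03)


class TestGroupingAndReference:
    def metadata(self):
        md = pd.DataFrame({
            "sample_id": ["s0", "s1", "s2"],
            "individual": ["I01", "I02", "I03"],
            "matrix": ["plasma", "plasma", "serum"],
            "time_h": [8.0, 8.0, 0.0],
            "temperature": ["RT", "RT", "RT"],
            "centrifugation_g": 2000})
        return oq.validate_metadata(md)

    def table(self, nes):
        return oq.ScoreTable(pd.DataFrame({
            "sample_id": ["s0", "s1", "s2"], "signature": "q",
            "raw_score": nes, "null_mean": 0.0, "null_sd": 1.0,
            "nes": nes, "n_overlap": 5}))

    def test_group_average_means_by_condition(self):
        grouped = oq.group_average(self.table([1.0, 3.0, 7.0]), self.metadata())
        plasma = grouped[grouped["matrix"] == "plasma"]
        assert plasma["mean_nes"].iloc[0] == pytest.approx(2.0)
        assert plasma["n"].iloc[0] == 2
        serum = grouped[grouped["matrix"] == "serum"]
        assert serum["mean_nes"].iloc[0] == pytest.approx(7.0)  # single sample

    def test_missing_key_rejected(self):
        with pytest.raises(ValueError, match="centrifuge"):
            oq.group_average(self.table([1, 2, 3]), self.metadata(),
                             keys=("centrifuge",))

    def test_unknown_sample_rejected(self):
        md = self.metadata().drop(index="s2")
        with pytest.raises(ValueError, match="s2"):
            oq.group_average(self.table([1, 2, 3]), md)

    def test_delta_vs_reference(self):
        out = oq.delta_vs_reference(self.table([1.0, 3.0, 7.0]), ["s0", "s1"])
        np.testing.assert_allclose(out["delta_nes"], [-1.0, 1.0, 5.0])
        with pytest.raises(ValueError):
            oq.delta_vs_reference(self.table([1, 2, 3]), ["nope"])
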