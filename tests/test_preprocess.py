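import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evmeth.preprocess import (
    PairedDesign,
    SamplePair,
    beta_to_m,
    compute_beta,
    filter_probes,
    run_pca,
    select_variable_probes,
)

from .conftest import toy_manifest


class TestComputeBeta:
    @pytest.mark.parametrize(
        "meth,unmeth,offset,expected",
        [
            (300.0, 600.0, 100.0, 0.3),
            (0.0, 0.0, 100.0, 0.0),
            (500.0, 500.0, 0.0, 0.5),
        ],
    )
    def test_known_values(self, meth, unmeth, offset, expected):
        beta = compute_beta(np.array([[meth]]), np.array([[unmeth]]), offset)
        assert beta[0, 0] == pytest.approx(expected)

    def test_shape_mismatch_and_negative_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            compute_beta(np.ones((2, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError, match="non-negative"):
            compute_beta(np.array([-1.0]), np.array([1.0]))

    @given(
        meth=st.floats(0, 1e5),
        unmeth=st.floats(0, 1e5),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_intensity_scale_invariance(self, meth, unmeth, scale):
        """Rescaling both channels and the offset leaves beta unchanged."""
        m, u = np.array([meth]), np.array([unmeth])
        b1 = compute_beta(m, u, 100.0)
        b2 = compute_beta(m * scale, u * scale, 100.0 * scale)
        assert b1[0] == pytest.approx(b2[0], abs=1e-9)
        assert 0 <= b1[0] < 1


class TestBetaToM:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert beta_to_m(np.array([beta]))[0] == pytest.approx(m)

    @pytest.mark.parametrize("eps", [0.0, 0.5, -0.1, 1.0])
    def test_bad_epsilon(self, eps):
        with pytest.raises(ValueError):
            beta_to_m(np.array([0.5]), epsilon=eps)

    def test_finite_at_extremes(self):
        m = beta_to_m(np.array([0.0, 1.0]))
        assert np.isfinite(m).all()

    @given(
        b1=st.floats(0.0, 1.0),
        b2=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone(self, b1, b2):
        eps = 1e-6
        m1, m2 = beta_to_m(np.array([b1, b2]), eps)
        c1, c2 = np.clip([b1, b2], eps, 1 - eps)
        if c1 < c2:
            assert m1 < m2
        elif c1 == c2:
            assert m1 == m2


class TestFilterProbes:
    def make_inputs(self):
        probes = [f"p{i}" for i in range(10)]
        beta = pd.DataFrame(
            np.full((10, 2), 0.5), index=probes, columns=["s1", "s2"]
        )
        rows = {p: ("1", "", "OpenSea") for p in probes}
        rows["p7"] = ("Y", "", "OpenSea")
        manifest = toy_manifest(rows)
        detp = pd.DataFrame(np.full((10, 2), 0.001), index=probes, columns=["s1", "s2"])
        detp.loc["p9", "s2"] = 0.5  # fails detection in one sample
        return beta, manifest, detp

    def test_hand_enumerated_toy(self):
        """2 SNP-listed + 1 chrY + 1 detection failure out of 10 -> 6 kept."""
        beta, manifest, detp = self.make_inputs()
        out, report = filter_probes(
            beta, manifest, snp_blacklist={"p1", "p2"}, detection_p=detp
        )
        assert len(out) == 6
        assert report.removed == {
            "detection_p": 1,
            "snp": 2,
            "sex_chromosome": 1,
            "cross_reactive": 0,
        }

    def test_sex_chromosome_removed(self):
        beta, manifest, _ = self.make_inputs()
        out, _ = filter_probes(beta, manifest)
        assert "p7" not in out.index

    def test_no_rules_is_identity(self):
        beta, manifest, _ = self.make_inputs()
        beta = beta.drop(index="p7")
        out, report = filter_probes(beta, manifest)
        pd.testing.assert_frame_equal(out, beta)
        assert report.n_survivors == report.n_input

    def test_first_rule_attribution_tally_sums(self):
        """A probe hit by several rules counts once; tally + survivors = input."""
        beta, manifest, detp = self.make_inputs()
        detp.loc["p1", "s1"] = 0.9  # p1 fails detection AND is SNP-listed
        out, report = filter_probes(
            beta, manifest, snp_blacklist={"p1"}, crossreactive_blacklist={"p7", "p3"},
            detection_p=detp,
        )
        assert sum(report.removed.values()) + report.n_survivors == report.n_input
        assert report.removed["detection_p"] == 2  # p1 attributed here, not to snp
        assert report.removed["sex_chromosome"] == 1  # p7 here, not cross-reactive
        assert report.removed["cross_reactive"] == 1

    def test_missing_manifest_probe_rejected(self):
        beta, manifest, _ = self.make_inputs()
        with pytest.raises(ValueError, match="absent from manifest"):
            filter_probes(beta, manifest.drop(index="p0"))


class TestSelectVariableProbes:
    def test_hand_computed_ratios_strict_threshold(self):
        """Rows with sd/|mean| = .1, .4, .5, .6, 2.0: only .6 and 2.0 pass 0.5."""
        ratios = [0.1, 0.4, 0.5, 0.6, 2.0]
        half = np.array(ratios) / np.sqrt(2)  # two-sample sd(ddof=1) = |x1-x2|/sqrt(2)
        m = pd.DataFrame(
            {"s1": 1 + half, "s2": 1 - half},
            index=[f"r{r}" for r in ratios],
        )
        kept = select_variable_probes(m, 0.5)
        assert set(kept) == {"r0.6", "r2.0"}

    def test_constant_row_never_kept(self):
        m = pd.DataFrame({"s1": [3.0, 1.0], "s2": [3.0, 2.0]}, index=["const", "var"])
        assert "const" not in select_variable_probes(m, 0.01)

    def test_zero_mean_rows_excluded_and_counted(self):
        m = pd.DataFrame({"s1": [1.0, -5.0], "s2": [-1.0, 5.0]}, index=["z1", "z2"])
        kept, info = select_variable_probes(m, 0.5, return_info=True)
        assert len(kept) == 0 and info["n_zero_mean_excluded"] == 2

    def test_column_permutation_invariant(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
        kept1 = select_variable_probes(m, 0.5)
        kept2 = select_variable_probes(m[list("fedcba")], 0.5)
        assert set(kept1) == set(kept2)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            select_variable_probes(pd.DataFrame({"s1": [1.0]}), 0.5)


class TestRunPca:
    def test_identical_samples_equal_scores(self, rng):
        col = rng.normal(size=20)
        m = pd.DataFrame({"s1": col, "s2": col, "s3": rng.normal(size=20)})
        scores = run_pca(m).scores
        assert np.allclose(scores.loc["s1"], scores.loc["s2"], atol=1e-8)

    def test_explained_variance_fractions(self, rng):
        m = pd.DataFrame(rng.normal(size=(40, 5)))
        evr = run_pca(m).explained_variance_ratio
        assert (evr >= 0).all() and evr.sum() <= 1 + 1e-9

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            run_pca(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestPairedDesign:
    def test_duplicate_samples_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            PairedDesign(groups=(SamplePair("a", "s1", "s1"),))

    def test_json_round_trip(self, tmp_path):
        d = PairedDesign(
            groups=(SamplePair("a", "t1", "c1"), SamplePair("b", "t2", "c2"))
        )
        d.to_json(tmp_path / "design.json")
        assert PairedDesign.from_json(tmp_path / "design.json") == d
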