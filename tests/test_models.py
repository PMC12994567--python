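"""GLM designs, EMM contrasts (validated against R emmeans) and slopes."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_repertoire
from wildtcr.diversity import diversity_table
from wildtcr.models import (
    _fit_glm,
    emm_contrasts,
    emm_means,
    emm_slopes,
    fit_diversity_model,
    fit_richness_model,
    fit_sharing_model,
    sharing_permutation_pvalues,
)
from wildtcr.repertoire_io import MouseMetadata
from wildtcr.sharing import build_pair_table, pairwise_shared


# small fixed dataset shared with the R `emmeans` oracle below
_X = [7.74, 4.39, 8.59, 6.97, 0.94, 9.76, 7.61, 7.86, 1.28, 4.5, 3.71, 9.27]
_Y = [4.355, 3.881, 4.811, 3.661, 3.966, 5.949, 6.222, 5.833, 1.492, 2.21,
      2.924, 3.904]
_G = ["a"] * 4 + ["b"] * 4 + ["c"] * 4


def _oracle_frame():
    return pd.DataFrame({"x": _X, "y": _Y, "g": _G})


class TestEmmAgainstEmmeans:
    """Frozen oracle values computed with R: glm(y ~ g + x, family=...),
    emmeans(m, "g") and pairs(..., adjust="tukey")."""

    # (family, {(a,b): (estimate, SE, t, p_tukey)})
    CASES = {
        "gaussian": {
            ("a", "b"): (-1.413360386, 0.286996409, -4.92466, 0.00293016),
            ("a", "c"): (0.969570233, 0.302305658, 3.20725, 0.02998831),
            ("b", "c"): (2.382930619, 0.297481116, 8.01036, 0.00011257),
        },
        "gamma_log": {
            ("a", "b"): (-0.291250564, 0.113103570, -2.57508, 0.07575398),
            ("a", "c"): (0.342697158, 0.119136853, 2.87650, 0.04861947),
            ("b", "c"): (0.633947722, 0.117235530, 5.40747, 0.00163305),
        },
    }
    EMMS = {
        "gaussian": {"a": 3.952737, "b": 5.366097, "c": 2.983166},
        "gamma_log": {"a": 1.3656134, "b": 1.6568640, "c": 1.0229163},
    }

    @pytest.mark.parametrize("family", ["gaussian", "gamma_log"])
    def test_emms_and_tukey_contrasts_match_R(self, family):
        model = _fit_glm(_oracle_frame(), "y", factors=["g"],
                         covariates=["x"], interactions=[],
                         family_name=family)
        emms = emm_means(model, "g").set_index("level")["emm"]
        for level, expected in self.EMMS[family].items():
            assert emms[level] == pytest.approx(expected, abs=5e-6)
        got = {(c.level_a, c.level_b): c for c in emm_contrasts(model, "g")}
        for pair, (est, se, t, p) in self.CASES[family].items():
            c = got[pair]
            assert c.estimate == pytest.approx(est, abs=5e-6)
            assert c.se == pytest.approx(se, abs=5e-6)
            assert c.statistic == pytest.approx(t, abs=5e-4)
            assert c.p_adjusted == pytest.approx(p, rel=1e-3)
            assert c.p_adjusted >= c.p_unadjusted


def _diversity_fixture(n_mice=8, seed=0):
    rng = np.random.default_rng(seed)
    reps, meta = {}, []
    for i in range(n_mice):
        mid = f"m{i}"
        meta.append(MouseMetadata(mid, "MF"[i % 2], float(5 + 5 * i),
                                  ("Nottingham", "Wirral")[i % 2 == 0
                                                           and i > 4]))
        for subset in ("CD4", "CD8"):
            for chain in ("alpha", "beta"):
                counts = rng.integers(1, 40, size=rng.integers(20, 40))
                reps[(mid, f"{subset}_{chain}")] = make_repertoire(
                    list(counts), mouse_id=mid, subset=subset, chain=chain)
    tbl = diversity_table(reps, seed=seed)
    return tbl, meta, reps


class TestModelDesigns:
    def test_richness_design_terms(self):
        tbl, meta, _ = _diversity_fixture()
        m = fit_richness_model(tbl, meta)
        assert m.family == "gamma_log"
        assert m.formula == ("richness ~ receptor_type + site + sex + age "
                             "+ age:sex")
        expected = {"Intercept", "receptor_type[T.CD4_beta]",
                    "receptor_type[T.CD8_alpha]", "receptor_type[T.CD8_beta]",
                    "site[T.Wirral]", "sex[T.M]", "age", "age:sex[T.M]"}
        assert set(m.coefficients.index) == expected

    def test_diversity_design_and_family(self):
        tbl, meta, _ = _diversity_fixture()
        m = fit_diversity_model(tbl, meta, "shannon")
        assert m.family == "gaussian"
        assert "age:sex[T.M]" in m.coefficients.index

    def test_sharing_design_terms(self):
        tbl, meta, reps = _diversity_fixture()
        pairs = pd.concat(
            [build_pair_table(pairwise_shared(reps, rt, seed=0), meta)
             for rt in ("CD4_alpha", "CD4_beta", "CD8_alpha", "CD8_beta")],
            ignore_index=True)
        m = fit_sharing_model(pairs)
        assert m.formula == (
            "shared ~ receptor_type + same_sex + age_diff + age_sum "
            "+ age_diff:receptor_type + age_sum:receptor_type")
        slopes = emm_slopes(m, "age_diff", "receptor_type")
        assert len(slopes) == 4

    def test_log_link_scale_property(self):
        """Scaling a gamma/log response by 10 shifts only the intercept,
        by ln 10."""
        tbl, meta, _ = _diversity_fixture()
        m1 = fit_richness_model(tbl, meta)
        tbl10 = tbl.copy()
        tbl10["richness"] = tbl10["richness"] * 10
        m2 = fit_richness_model(tbl10, meta)
        c1, c2 = m1.coefficients["estimate"], m2.coefficients["estimate"]
        assert c2["Intercept"] - c1["Intercept"] == pytest.approx(
            np.log(10), abs=1e-6)
        others = [t for t in c1.index if t != "Intercept"]
        assert np.allclose(c1[others], c2[others], atol=1e-6)

    def test_single_level_factor_dropped_with_warning(self):
        tbl, meta, _ = _diversity_fixture()
        tbl = tbl[tbl.receptor_type == "CD4_alpha"]
        with pytest.warns(UserWarning, match="receptor_type"):
            m = fit_richness_model(tbl, meta)
        assert not any("receptor_type" in t for t in m.coefficients.index)

    def test_zero_variance_covariate_rejected(self):
        tbl, meta, _ = _diversity_fixture()
        for mouse in meta:
            mouse.age = 7.0
        with pytest.raises(ValueError, match="age"):
            fit_diversity_model(tbl, meta, "shannon")

    def test_constant_response_rejected(self):
        tbl, meta, _ = _diversity_fixture()
        tbl = tbl.copy()
        tbl["richness"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            fit_richness_model(tbl, meta)

    def test_aliased_design_rejected(self):
        """Site perfectly confounded with sex: rank-deficient design."""
        tbl, meta, _ = _diversity_fixture()
        for mouse in meta:
            mouse.site = "NorthFarm" if mouse.sex == "M" else "SouthFarm"
        with pytest.raises(ValueError, match="aliased"):
            fit_richness_model(tbl, meta)


class TestEmmReductions:
    def test_balanced_one_factor_emms_equal_group_means(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "g": ["a"] * 6 + ["b"] * 6 + ["c"] * 6,
            "y": rng.normal(5, 1, 18),
        })
        df["x"] = 1.0 + np.tile([0, 1, 2, 3, 4, 5], 3)  # balanced covariate
        m = _fit_glm(df, "y", factors=["g"], covariates=["x"],
                     interactions=[], family_name="gaussian")
        emms = emm_means(m, "g").set_index("level")["emm"]
        means = df.groupby("g")["y"].mean()
        for g in "abc":
            assert emms[g] == pytest.approx(means[g], abs=1e-8)

    def test_four_levels_give_six_contrasts(self):
        tbl, meta, _ = _diversity_fixture()
        m = fit_diversity_model(tbl, meta, "shannon")
        contrasts = emm_contrasts(m, "receptor_type")
        assert len(contrasts) == 6
        assert all(c.p_adjusted >= c.p_unadjusted - 1e-12 for c in contrasts)

    def test_unknown_factor_rejected(self):
        tbl, meta, _ = _diversity_fixture()
        m = fit_diversity_model(tbl, meta, "shannon")
        with pytest.raises(ValueError, match="factor"):
            emm_contrasts(m, "weekday")


class TestSharingModelGuards:
    def test_single_receptor_type_rejected(self):
        pairs = pd.DataFrame({
            "mouse_a": ["a"] * 12, "mouse_b": [f"b{i}" for i in range(12)],
            "shared": range(12), "same_sex": [True] * 12,
            "age_diff": np.arange(12.0), "age_sum": np.arange(12.0) + 20,
            "receptor_type": ["CD4_alpha"] * 12,
        })
        with pytest.raises(ValueError, match="receptor types"):
            fit_sharing_model(pairs)

    def test_too_few_pairs_rejected(self):
        pairs = pd.DataFrame({
            "mouse_a": ["a"] * 4, "mouse_b": list("bcde"),
            "shared": [1, 2, 3, 4], "same_sex": [True, False] * 2,
            "age_diff": [1.0, 2, 3, 4], "age_sum": [5.0, 6, 7, 8],
            "receptor_type": ["CD4_alpha", "CD4_beta"] * 2,
        })
        with pytest.raises(ValueError, match="pairs"):
            fit_sharing_model(pairs)

    def test_permutation_pvalues_cover_null(self):
        tbl, meta, reps = _diversity_fixture()
        pairs = pd.concat(
            [build_pair_table(pairwise_shared(reps, rt, seed=0), meta)
             for rt in ("CD4_alpha", "CD4_beta")], ignore_index=True)
        out = sharing_permutation_pvalues(pairs, meta, n_perm=30, seed=0)
        assert ((out["p_permutation"] > 0) & (out["p_permutation"] <= 1)).all()
        assert any("age_diff" in t for t in out.index)
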