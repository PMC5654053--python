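"""z-score specificity, responsiveness and marker classification."""

import numpy as np
import pandas as pd
import pytest

from ernalink.expression_quant import ExpressionMatrix
from ernalink.genome_model import SampleMetadata
from ernalink.specificity import (
    condition_links,
    load_marker_genes,
    macrophage_specific,
    marker_enhancers,
    stimuli_responsive,
    zscores,
)


def _em(arr, groups=None, conditions=None):
    arr = np.asarray(arr, dtype=float)
    n = arr.shape[1]
    groups = groups or ["macrophage"] * n
    conditions = conditions or ["untreated"] * n
    samples = [
        SampleMetadata(f"s{i}", groups[i],
                       conditions[i] if groups[i] == "macrophage" else "none")
        for i in range(n)
    ]
    values = pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])],
                          columns=[s.sample_id for s in samples])
    return ExpressionMatrix(values, samples, "tpm")


class TestZscores:
    def test_arithmetic(self):
        em = _em([[2.0, 6.0, 10.0]])  # bg mean 4, sd 2 over first two... no:
        # background s0,s1: mean 4, sd(n-1) = 2.828 -> use explicit values
        em = _em([[2.0, 6.0, 10.0, 4.0]])
        res = zscores(em, ["s2", "s3"], ["s0", "s1"])
        # bg mean 4, sd = sqrt(((2-4)^2+(6-4)^2)/1) = 2.828
        assert res["f0"].z[0] == pytest.approx((10 - 4) / np.sqrt(8))
        assert res["f0"].z[1] == pytest.approx(0.0)

    def test_constant_background_conventions(self):
        em = _em([[5.0, 5.0, 9.0, 3.0]])
        res = zscores(em, ["s2", "s3"], ["s0", "s1"])
        assert np.isinf(res["f0"].z[0]) and res["f0"].z[0] > 0
        assert res["f0"].z[1] == 0.0

    def test_small_background_is_error(self):
        em = _em([[1.0, 2.0]])
        with pytest.raises(ValueError):
            zscores(em, ["s1"], ["s0"])


class TestMacrophageSpecific:
    def _zres(self, values, target, background):
        em = _em([values])
        return zscores(em, target, background)

    def test_ceiling_rule_at_twenty_targets(self):
        # 20 targets, ceil(0.1*20) = 2 needed
        vals = [0.0, 1.0, 2.0, 0.5] + [100.0, 100.0] + [1.0] * 18
        em = _em([vals])
        targets = [f"s{i}" for i in range(4, 24)]
        res = zscores(em, targets, ["s0", "s1", "s2", "s3"])
        assert macrophage_specific(res, 20, frac=0.10) == ["f0"]
        vals2 = [0.0, 1.0, 2.0, 0.5] + [100.0] + [1.0] * 19
        res2 = zscores(_em([vals2]), targets, ["s0", "s1", "s2", "s3"])
        assert macrophage_specific(res2, 20, frac=0.10) == []

    def test_threshold_is_strict(self):
        # bg (0, 2) -> mean 1, sd sqrt(2); x = 1 + 3*sqrt(2) gives z exactly 3,
        # which must not count ("z-score > 3" is strict)
        x = 1 + 3 * np.sqrt(2)
        res = zscores(_em([[0.0, 2.0, x, x]]), ["s2", "s3"], ["s0", "s1"])
        assert res["f0"].n_above == 0


class TestStimuliResponsive:
    def _matrix(self, n_above):
        bg = list(np.linspace(9.0, 11.0, 10))  # mean 10, modest sd
        sd = float(np.std(bg, ddof=1))
        hi = 10 + 10 * sd
        targets = [hi] * n_above + [10.0] * (16 - n_above)
        em = _em([bg + targets])
        stim = [f"s{i}" for i in range(10, 26)]
        unstim = [f"s{i}" for i in range(10)]
        return em, stim, unstim

    @pytest.mark.parametrize("n_above,expected", [(5, True), (4, False), (0, False)])
    def test_strictly_more_than_quarter_rule(self, n_above, expected):
        em, stim, unstim = self._matrix(n_above)
        hits = stimuli_responsive(em, stim, unstim, frac=0.25)
        assert (hits == ["f0"]) is expected


class TestConditionLinks:
    def _links(self):
        return pd.DataFrame(
            {"enhancer_id": ["e1"], "promoter_id": ["p1"], "tad_id": ["t"],
             "rho": [0.9], "p": [1e-9], "distance": [100], "q": [1e-8]}
        )

    def _tpms(self, e_vals, p_vals):
        n = len(e_vals)
        samples = [SampleMetadata(f"s{i}", "macrophage", "ifng") for i in range(n)]
        ids = [s.sample_id for s in samples]
        etpm = ExpressionMatrix(pd.DataFrame([e_vals], index=["e1"], columns=ids),
                                samples, "tpm")
        ptpm = ExpressionMatrix(pd.DataFrame([p_vals], index=["p1"], columns=ids),
                                samples, "tpm")
        return etpm, ptpm, ids

    def test_positive_in_state_kept(self):
        etpm, ptpm, ids = self._tpms([1, 2, 3, 4], [1, 3, 2, 4])
        kept = condition_links(self._links(), etpm, ptpm, ids, ["e1"], ["p1"])
        assert len(kept) == 1

    def test_negative_or_zero_dropped(self):
        etpm, ptpm, ids = self._tpms([1, 2, 3, 4], [4, 3, 2, 1])
        assert len(condition_links(self._links(), etpm, ptpm, ids, ["e1"], ["p1"])) == 0
        etpm, ptpm, ids = self._tpms([1, 2, 3, 4], [1, 2, 2, 1])
        out = condition_links(self._links(), etpm, ptpm, ids, ["e1"], ["p1"])
        rho_zero_or_neg = len(out) == 0
        assert rho_zero_or_neg

    def test_non_responsive_endpoint_dropped(self):
        etpm, ptpm, ids = self._tpms([1, 2, 3, 4], [1, 3, 2, 4])
        assert len(condition_links(self._links(), etpm, ptpm, ids, [], ["p1"])) == 0


class TestMarkerEnhancers:
    def _setup(self, responsive, linked_gene, z_high):
        n_state = 16
        samples = (
            [SampleMetadata(f"i{k}", "macrophage", "ifng") for k in range(n_state)]
            + [SampleMetadata(f"a{k}", "macrophage", "il4il13") for k in range(n_state)]
        )
        ids = [s.sample_id for s in samples]
        ifng_vals = [100.0] * n_state if z_high else [10.0] * n_state
        il4_vals = list(np.linspace(9.0, 11.0, n_state))
        etpm = ExpressionMatrix(
            pd.DataFrame([ifng_vals + il4_vals], index=["e1"], columns=ids),
            samples, "tpm",
        )
        links = pd.DataFrame({"enhancer_id": ["e1"], "gene_id": [linked_gene]})
        state_links = {"ifng": links, "il4il13": links.iloc[0:0]}
        state_samples = {"ifng": ids[:n_state], "il4il13": ids[n_state:]}
        return responsive, state_links, state_samples, etpm

    def test_full_conjunction_yields_marker(self):
        resp, sl, ss, etpm = self._setup({"ifng": ["e1"], "il4il13": []}, "Cxcl9", True)
        calls = marker_enhancers(resp, sl, {"ifng": ["Cxcl9"], "il4il13": []},
                                 etpm, ss)
        assert [(c.enhancer_id, c.state) for c in calls] == [("e1", "ifng")]
        assert calls[0].marker_gene_ids == ("Cxcl9",)

    def test_responsive_in_both_states_is_never_marker(self):
        resp, sl, ss, etpm = self._setup(
            {"ifng": ["e1"], "il4il13": ["e1"]}, "Cxcl9", True
        )
        assert marker_enhancers(resp, sl, {"ifng": ["Cxcl9"], "il4il13": []},
                                etpm, ss) == []

    def test_no_marker_gene_link_is_never_marker(self):
        resp, sl, ss, etpm = self._setup({"ifng": ["e1"], "il4il13": []}, "Foo", True)
        assert marker_enhancers(resp, sl, {"ifng": ["Cxcl9"], "il4il13": []},
                                etpm, ss) == []

    def test_z_rule_vs_other_state_required(self):
        resp, sl, ss, etpm = self._setup({"ifng": ["e1"], "il4il13": []}, "Cxcl9", False)
        assert marker_enhancers(resp, sl, {"ifng": ["Cxcl9"], "il4il13": []},
                                etpm, ss) == []


class TestCalibration:
    def test_null_normal_model_produces_no_responsive_calls(self):
        """Pure null: 10,000 features, background and 16 targets from one
        normal distribution (background panel large enough that z-scores are
        effectively exact); the z>3-in->25% rule has a per-feature rate
        around the binomial tail of P(Z>3)^5-scale, far below 1/10,000."""
        rng = np.random.default_rng(12345)
        n_feat, n_bg, n_tg = 10_000, 744, 16
        bg = rng.normal(100, 10, size=(n_feat, n_bg))
        tg = rng.normal(100, 10, size=(n_feat, n_tg))
        em = _em(np.hstack([bg, tg]))
        bg_ids = em.sample_ids[:n_bg]
        tg_ids = em.sample_ids[n_bg:]
        calls = stimuli_responsive(em, tg_ids, bg_ids, frac=0.25, threshold=3.0)
        assert calls == []

    def test_planted_shift_is_detected(self):
        """A +5 background-SD shift in every stimulated sample is called
        responsive for >= 99% of shifted features."""
        rng = np.random.default_rng(77)
        n_feat, n_bg, n_tg = 2_000, 10, 16
        bg = rng.normal(100, 10, size=(n_feat, n_bg))
        tg = rng.normal(100 + 5 * 10, 10, size=(n_feat, n_tg))
        em = _em(np.hstack([bg, tg]))
        calls = stimuli_responsive(em, em.sample_ids[n_bg:], em.sample_ids[:n_bg])
        assert len(calls) >= 0.99 * n_feat


def test_packaged_marker_panel_loads():
    panels = load_marker_genes()
    assert "Cxcl9" in panels["ifng"]
    assert "Arg1" in panels["il4il13"]
    assert set(panels) == {"ifng", "il4il13"}


def test_marker_states_disjoint_on_pipeline_run(default_result):
    ifng = {m.enhancer_id for m in default_result.markers if m.state == "ifng"}
    il4 = {m.enhancer_id for m in default_result.markers if m.state == "il4il13"}
    assert not (ifng & il4)
    assert ifng and il4  # both states produce markers on the default study
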