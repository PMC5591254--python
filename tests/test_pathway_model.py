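"""Unit and property tests for the Bayesian pathway network."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellpath import pathway_model as pm


def random_model(rng, max_genes=10):
    """A random valid model: probabilities drawn and ordered per the invariants."""
    n = int(rng.integers(1, max_genes + 1))
    genes = []
    for i in range(n):
        pua, pui = np.sort(rng.uniform(0.02, 0.98, size=2))[::-1]
        if pua == pui:
            pua = min(0.99, pui + 0.01)
        ph_up, ph_down = np.sort(rng.uniform(0.02, 0.98, size=2))[::-1]
        if ph_up == ph_down:
            ph_up = min(0.99, ph_down + 0.01)
        genes.append(
            pm.TargetGeneSpec(f"G{i}", float(pua), float(pui), float(ph_up), float(ph_down))
        )
    return pm.PathwayModel(genes=tuple(genes), tc_prior_odds=float(rng.uniform(0.1, 10)))


def random_evidence(rng, model):
    ev = {}
    for g in model.genes:
        r = rng.random()
        if r < 0.25:
            ev[g.name] = pm.MISSING
        elif r < 0.35:
            ev[g.name] = float(rng.integers(0, 2))  # hard 0/1 calls too
        else:
            ev[g.name] = float(rng.random())
    return ev


class TestDefaults:
    def test_default_composite_lr_hits_five_and_fifth_root(self):
        lr_high, lr_low = pm.composite_lr(pm.TargetGeneSpec("AXIN2"))
        assert lr_high == pytest.approx(5.0, rel=1e-12)
        assert lr_low == pytest.approx(5.0 ** (-1 / 5), rel=1e-12)

    def test_up_call_weighs_five_times_a_down_call(self):
        lr_high, lr_low = pm.composite_lr(pm.TargetGeneSpec("AXIN2"))
        assert math.log(lr_high) / abs(math.log(lr_low)) == pytest.approx(5.0, rel=1e-12)
        assert lr_high / lr_low == pytest.approx(5.0 ** (6 / 5), rel=1e-12)

    def test_default_cpt_entries_are_valid_probabilities(self):
        g = pm.TargetGeneSpec("X")
        assert 0 < g.p_high_given_down < g.p_high_given_up < 1


class TestTargetGeneSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_up_given_active": 0.0},
            {"p_up_given_active": 1.0},
            {"p_up_given_active": 0.3, "p_up_given_inactive": 0.5},
            {"p_high_given_up": 0.2, "p_high_given_down": 0.2},
        ],
    )
    def test_invalid_probabilities_rejected(self, kwargs):
        with pytest.raises(ValueError):
            pm.TargetGeneSpec("X", **kwargs)

    def test_uninformative_gene_bypass_gives_unit_lrs(self):
        # equal gene-layer CPTs cannot be built as a TargetGeneSpec; a bare
        # stand-in exercises the marginalization formula directly
        from types import SimpleNamespace

        g = SimpleNamespace(
            p_up_given_active=0.5,
            p_up_given_inactive=0.5,
            p_high_given_up=0.8,
            p_high_given_down=0.2,
        )
        assert pm.composite_lr(g) == (1.0, 1.0)

    def test_composite_probabilities_normalize(self):
        g = pm.TargetGeneSpec("X", 0.9, 0.2, 0.7, 0.1)
        a = pm._p_high_given_tc(g, True)
        b = pm._p_high_given_tc(g, False)
        lr_high, lr_low = pm.composite_lr(g)
        assert lr_high * b + lr_low * (1 - b) == pytest.approx(a + (1 - a))
        assert lr_high > 1 > lr_low


class TestBuildModel:
    def test_bundled_panel_has_34_gene_nodes(self, wnt_model):
        assert len(wnt_model.genes) == 34
        assert wnt_model.tc_prior_odds == 1.0

    def test_single_gene_panel(self):
        m = pm.build_model(["AXIN2"])
        assert len(m.genes) == 1
        assert m.tc_prior_odds == 1.0

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pm.build_model(["A", "A"])
        with pytest.raises(ValueError, match="duplicate"):
            pm.build_model(["A", " a "])  # case/whitespace-insensitive match

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            pm.build_model([])

    def test_cpt_overrides_applied(self):
        m = pm.build_model(["A", "B"], {"a": {"p_up_given_active": 0.8}})
        by_name = m.gene_index()
        assert by_name["A"].p_up_given_active == 0.8
        assert by_name["B"].p_up_given_active == pm.DEFAULT_P_UP_GIVEN_ACTIVE


class TestInference:
    def test_no_evidence_gives_prior(self, toy_model):
        res = pm.infer_log_odds(toy_model, {g: pm.MISSING for g in toy_model.gene_names})
        assert res.log_odds == 0.0
        assert res.n_genes_used == 0

    def test_hard_high_call_adds_ln5(self):
        m = pm.build_model(["A"])
        res = pm.infer_log_odds(m, {"A": 1.0})
        assert res.log_odds == pytest.approx(math.log(5), rel=1e-12)

    def test_log_odds_decomposes_over_genes(self, toy_model):
        ev = {"A": 0.9, "B": 0.2, "C": pm.MISSING}
        res = pm.infer_log_odds(toy_model, ev)
        assert res.log_odds == pytest.approx(
            math.log(toy_model.tc_prior_odds) + sum(res.per_gene_log_lr.values())
        )
        assert res.per_gene_log_lr["C"] == 0.0
        assert res.n_genes_used == 2

    def test_all_high_minus_all_low_telescopes(self, toy_model):
        hi = pm.infer_log_odds(toy_model, {g: 1.0 for g in toy_model.gene_names})
        lo = pm.infer_log_odds(toy_model, {g: 0.0 for g in toy_model.gene_names})
        expected = sum(
            math.log(lr_h / lr_l)
            for lr_h, lr_l in (pm.composite_lr(g) for g in toy_model.genes)
        )
        assert hi.log_odds - lo.log_odds == pytest.approx(expected)

    def test_unknown_gene_in_evidence_rejected(self, toy_model):
        with pytest.raises(KeyError):
            pm.infer_log_odds(toy_model, {"NOT_A_GENE": 0.5})

    def test_adding_missing_gene_is_a_no_op(self, toy_model):
        base = pm.infer_log_odds(toy_model, {"A": 0.7})
        padded = pm.infer_log_odds(toy_model, {"A": 0.7, "B": pm.MISSING})
        assert base.log_odds == padded.log_odds

    def test_monotone_in_q(self, toy_model):
        qs = np.linspace(0, 1, 21)
        vals = [pm.infer_log_odds(toy_model, {"A": float(q), "B": 0.4}).log_odds for q in qs]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_per_gene_lr_bounded_by_composite_lrs(self):
        g = pm.TargetGeneSpec("A")
        lr_high, lr_low = pm.composite_lr(g)
        m = pm.build_model(["A"])
        for q in np.linspace(0, 1, 11):
            llr = pm.infer_log_odds(m, {"A": float(q)}).log_odds
            assert math.log(lr_low) - 1e-12 <= llr <= math.log(lr_high) + 1e-12


class TestBruteforceOracle:
    def test_matches_factorized_on_examples(self, toy_model):
        for ev in [
            {"A": 1.0},
            {"A": 0.5},
            {"A": 0.9, "B": 0.2, "C": pm.MISSING},
            {g: 1.0 for g in toy_model.gene_names},
        ]:
            fact = pm.infer_log_odds(toy_model, ev).log_odds
            brute = pm.infer_log_odds_bruteforce(toy_model, ev)
            assert brute == pytest.approx(fact, abs=1e-9)

    def test_single_gene_half_evidence(self):
        m = pm.build_model(["A"], tc_prior_odds=2.0)
        assert pm.infer_log_odds_bruteforce(m, {"A": 0.5}) == pytest.approx(
            pm.infer_log_odds(m, {"A": 0.5}).log_odds, abs=1e-12
        )

    def test_random_models_agree(self):
        rng = np.random.default_rng(20170908)
        worst = 0.0
        for _ in range(200):
            model = random_model(rng)
            ev = random_evidence(rng, model)
            delta = abs(
                pm.infer_log_odds(model, ev).log_odds
                - pm.infer_log_odds_bruteforce(model, ev)
            )
            worst = max(worst, delta)
        assert worst < 1e-9

    def test_enumeration_guard(self):
        m = pm.build_model([f"G{i}" for i in range(16)])
        with pytest.raises(ValueError, match="enumeration"):
            pm.infer_log_odds_bruteforce(m, {})


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    q=st.floats(0, 1),
    pua=st.floats(0.1, 0.9),
    gap=st.floats(0.05, 0.5),
    odds=st.floats(0.1, 10),
)
def test_soft_evidence_inference_consistent_with_oracle(q, pua, gap, odds):
    """Virtual-evidence inference equals full-joint enumeration for one gene."""
    pui = max(0.01, pua - gap)
    if pui >= pua:
        pua = pui + 0.01
    gene = pm.TargetGeneSpec("G", pua, pui, 0.8, 0.15)
    model = pm.PathwayModel(genes=(gene,), tc_prior_odds=odds)
    fact = pm.infer_log_odds(model, {"G": q}).log_odds
    brute = pm.infer_log_odds_bruteforce(model, {"G": q})
    assert brute == pytest.approx(fact, abs=1e-9)


def test_panel_tsv_round_trip(tmp_path, wnt_model):
    path = tmp_path / "panel.tsv"
    pm.write_panel_tsv(wnt_model, path)
    back = pm.read_panel_tsv(path)
    assert back.gene_names == wnt_model.gene_names
    for a, b in zip(back.genes, wnt_model.genes):
        assert a == b  # bit-exact float round-trip through repr strings
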