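"""Mediation/synergy classification rules."""

import itertools

import numpy as np
import pytest

from tycausal.causality import TYResult, TYSpec
from tycausal.mediation import LABELS, MediationInput, classify, classify_decisions, scan_triples
from tycausal.synthetic import gen_mediation_chain
from tycausal.causality import ty_joint_with_submodels, ty_test


def _result(p_value: float, outcome="Y", cause="X") -> TYResult:
    spec = TYSpec(outcome=outcome, cause_blocks=((cause,),), p=1, dmax=0)
    return TYResult(
        spec=spec, chi2=1.0, df=1, p_value=p_value, reject=p_value < 0.05,
        p_used=1, dmax_used=0, restricted=(cause,),
    )


def _input(**sig) -> MediationInput:
    """Build a MediationInput from significance booleans (True = p=0.001)."""
    p = {k: (0.001 if v else 0.5) for k, v in sig.items()}
    return MediationInput(
        x="X", m="M", y="Y",
        x_to_m=_result(p["x_to_m"], outcome="M"),
        m_to_y=_result(p["m_to_y"], cause="M"),
        x_to_y=_result(p["x_to_y"]),
        joint=_result(p["joint"]),
        sub_x=_result(p["sub_x"]),
        sub_m=_result(p["sub_m"], cause="M"),
    )


class TestClassificationRules:
    def test_every_pattern_yields_exactly_one_label(self):
        """Totality: all 2^6 decision patterns produce one valid label."""
        names = ("x_to_m", "m_to_y", "x_to_y", "joint", "sub_x", "sub_m")
        for bits in itertools.product([False, True], repeat=6):
            d = dict(zip(names, bits))
            label, rationale = classify_decisions(d)
            assert label in LABELS
            assert rationale  # every verdict is justified

    def test_nothing_significant_is_no_effect(self):
        v = classify(_input(x_to_m=False, m_to_y=False, x_to_y=False,
                            joint=False, sub_x=False, sub_m=False))
        assert v.label == "no_effect"

    def test_full_mediation_when_x_submodel_vanishes(self):
        # chain significant, joint significant, only the mediator's block
        # survives in the combined model
        v = classify(_input(x_to_m=True, m_to_y=True, x_to_y=True,
                            joint=True, sub_x=False, sub_m=True))
        assert v.label == "full_mediation"

    def test_partial_mediation_when_both_submodels_hold(self):
        v = classify(_input(x_to_m=True, m_to_y=True, x_to_y=True,
                            joint=True, sub_x=True, sub_m=True))
        assert v.label == "partial_mediation"

    def test_joint_only_significance_is_synergy(self):
        v = classify(_input(x_to_m=True, m_to_y=True, x_to_y=True,
                            joint=True, sub_x=False, sub_m=False))
        assert v.label == "joint_synergy"

    def test_direct_only_when_mediator_chain_broken(self):
        # direct path and joint significant, but the mediator block is not:
        # no mediated structure, X acts directly
        v = classify(_input(x_to_m=True, m_to_y=True, x_to_y=True,
                            joint=True, sub_x=True, sub_m=False))
        assert v.label == "direct_only"

    def test_strict_alpha_borderline_p_is_not_significant(self):
        """p = 0.0566 at alpha = 0.05 counts as not significant; p-values
        are still reported so near-misses stay visible."""
        inp = MediationInput(
            x="X", m="M", y="Y",
            x_to_m=_result(0.0048, outcome="M"),
            m_to_y=_result(0.0001, cause="M"),
            x_to_y=_result(0.0122),
            joint=_result(0.0003),
            sub_x=_result(0.0566),
            sub_m=_result(0.0486, cause="M"),
        )
        v = classify(inp)
        assert v.label == "full_mediation"
        assert v.p_values["sub_x"] == pytest.approx(0.0566)

    def test_direct_only_pattern_with_insignificant_mediator_submodel(self):
        # X->M, M->Y, X->Y and joint all significant, X survives in the
        # combined model but M does not: direct effect, no mediation
        v = classify(_input(x_to_m=True, m_to_y=True, x_to_y=True,
                            joint=True, sub_x=True, sub_m=False))
        assert v.label == "direct_only"


class TestScanTriples:
    def _battery(self, panel):
        battery = {}
        for a, b in (("X", "M"), ("M", "Y"), ("X", "Y")):
            battery[f"{a}->{b}"] = ty_test(
                panel, TYSpec(outcome=b, cause_blocks=((a,),)), cap=3
            )
        trio = ty_joint_with_submodels(panel, "Y", ("X", "M"), cap=3)
        battery["X+M->Y"] = trio["joint"]
        battery["X+M->Y:X"] = trio["sub_X"]
        battery["X+M->Y:M"] = trio["sub_M"]
        return battery

    def test_empty_triple_list_gives_empty_output(self):
        assert scan_triples({}, []) == []

    def test_unresolved_reference_raises(self):
        with pytest.raises(KeyError, match="unresolved"):
            scan_triples({}, [("X", "M", "Y")])

    def test_chain_without_direct_path_is_mostly_full_mediation(self):
        labels = []
        for seed in range(30):
            panel, _ = gen_mediation_chain(0.8, 0.8, 0.0, n=150, seed=seed)
            v = scan_triples(self._battery(panel), [("X", "M", "Y")])[0]
            labels.append(v.label)
        assert labels.count("full_mediation") / len(labels) >= 0.6
        assert max(set(labels), key=labels.count) == "full_mediation"

    def test_chain_with_direct_path_is_mostly_partial_mediation(self):
        labels = []
        for seed in range(30):
            panel, _ = gen_mediation_chain(0.8, 0.8, 0.8, n=150, seed=seed)
            v = scan_triples(self._battery(panel), [("X", "M", "Y")])[0]
            labels.append(v.label)
        assert max(set(labels), key=labels.count) == "partial_mediation"

    def test_independent_series_mostly_no_effect(self):
        hits = 0
        for seed in range(20):
            panel, _ = gen_mediation_chain(0.0, 0.0, 0.0, n=150, seed=seed)
            v = scan_triples(self._battery(panel), [("X", "M", "Y")])[0]
            hits += v.label == "no_effect"
        assert hits / 20 >= 0.85

    def test_direct_only_dgp_recovers_direct_label(self):
        labels = []
        for seed in range(20):
            panel, _ = gen_mediation_chain(0.0, 0.0, 0.8, n=150, seed=seed)
            v = scan_triples(self._battery(panel), [("X", "M", "Y")])[0]
            labels.append(v.label)
        assert max(set(labels), key=labels.count) == "direct_only"
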