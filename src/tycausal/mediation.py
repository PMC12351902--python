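"""Mediation and synergy classification from causality-test outcomes.

A longitudinal adaptation of the Baron-Kenny logic: for a candidate triple
(X, M, Y) the six relevant causality tests are

* ``x_to_m``  — X -> M (does the cause drive the mediator?)
* ``m_to_y``  — M -> Y (does the mediator drive the outcome?)
* ``x_to_y``  — X -> Y (simple direct test)
* ``joint``   — X + M -> Y (joint lag restriction)
* ``sub_x``   — X's individual block within the joint model
* ``sub_m``   — M's individual block within the joint model

The verdict is a pure function of the six significance decisions, applied
in a fixed rule order; each firing is recorded so the classification is
auditable.  An indirect (mediated) path X -> M -> Y requires X to cause M,
M to cause Y, and M to stay significant in the combined outcome model:
"full" mediation when X's individual effect vanishes there, "partial" when
both remain.  A joint restriction that is significant while neither
individual block is marks a synergistic (combined) rather than mediated
influence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .causality import TYResult

__all__ = ["MediationInput", "MediationVerdict", "classify", "scan_triples", "LABELS"]

LABELS = ("no_effect", "direct_only", "partial_mediation", "full_mediation", "joint_synergy")


@dataclass(frozen=True)
class MediationInput:
    """The six causality results needed to classify one (X, M, Y) triple."""

    x: str
    m: str
    y: str
    x_to_m: TYResult
    m_to_y: TYResult
    x_to_y: TYResult
    joint: TYResult
    sub_x: TYResult
    sub_m: TYResult
    alpha: float = 0.05

    def decisions(self) -> dict[str, bool]:
        return {
            name: bool(getattr(self, name).p_value < self.alpha)
            for name in ("x_to_m", "m_to_y", "x_to_y", "joint", "sub_x", "sub_m")
        }


@dataclass(frozen=True)
class MediationVerdict:
    """Exactly one label per triple, with the rule firings that produced it."""

    x: str
    m: str
    y: str
    label: str
    rationale: tuple[str, ...]
    p_values: dict[str, float]


def classify_decisions(d: dict[str, bool]) -> tuple[str, tuple[str, ...]]:
    """Label a pattern of six boolean significance decisions.

    Total over all 2^6 patterns: every input yields exactly one label.
    Rule order is fixed; later rules only see patterns the earlier ones
    left unclaimed.
    """
    sig = {k: ("significant" if v else "not significant") for k, v in d.items()}
    rationale = []
    if not d["joint"] and not d["x_to_y"]:
        rationale.append(f"rule 1: joint {sig['joint']} and X->Y {sig['x_to_y']}")
        return "no_effect", tuple(rationale)
    if d["x_to_m"] and d["m_to_y"] and d["joint"] and d["sub_m"]:
        rationale.append(
            f"rule 2: X->M {sig['x_to_m']}, M->Y {sig['m_to_y']}, "
            f"joint {sig['joint']}, M-submodel {sig['sub_m']}"
        )
        if d["sub_x"]:
            rationale.append("rule 2a: X-submodel significant -> partial mediation")
            return "partial_mediation", tuple(rationale)
        rationale.append("rule 2b: X-submodel not significant -> full mediation")
        return "full_mediation", tuple(rationale)
    if d["joint"] and not d["sub_x"] and not d["sub_m"]:
        rationale.append(
            f"rule 3: joint {sig['joint']} while neither submodel is -> joint effect"
        )
        return "joint_synergy", tuple(rationale)
    if d["x_to_y"]:
        rationale.append(f"rule 4: X->Y {sig['x_to_y']} without a mediated structure")
        return "direct_only", tuple(rationale)
    rationale.append(
        "rule 5 (fallback): joint significant but no direct X->Y path and no "
        "complete mediation chain -> no individually attributable effect"
    )
    return "no_effect", tuple(rationale)


def classify(inp: MediationInput) -> MediationVerdict:
    """Classify one (X, M, Y) triple from its six causality results."""
    label, rationale = classify_decisions(inp.decisions())
    p_values = {
        name: float(getattr(inp, name).p_value)
        for name in ("x_to_m", "m_to_y", "x_to_y", "joint", "sub_x", "sub_m")
    }
    return MediationVerdict(
        x=inp.x, m=inp.m, y=inp.y, label=label, rationale=rationale, p_values=p_values
    )


def scan_triples(
    battery: dict[str, TYResult],
    triples,
    alpha: float = 0.05,
) -> list[MediationVerdict]:
    """Classify a list of ``(x, m, y)`` triples against a result lookup.

    ``battery`` must contain, for each triple, the keys
    ``"{x}->{m}"``, ``"{m}->{y}"``, ``"{x}->{y}"``, ``"{x}+{m}->{y}"``
    (joint), ``"{x}+{m}->{y}:{x}"`` and ``"{x}+{m}->{y}:{m}"`` (submodels).
    A missing key raises ``KeyError`` naming the unresolved reference.
    """
    verdicts = []
    for x, m, y in triples:
        keys = {
            "x_to_m": f"{x}->{m}",
            "m_to_y": f"{m}->{y}",
            "x_to_y": f"{x}->{y}",
            "joint": f"{x}+{m}->{y}",
            "sub_x": f"{x}+{m}->{y}:{x}",
            "sub_m": f"{x}+{m}->{y}:{m}",
        }
        missing = [k for k in keys.values() if k not in battery]
        if missing:
            raise KeyError(f"unresolved battery reference(s): {missing}")
        inp = MediationInput(
            x=x, m=m, y=y, alpha=alpha,
            **{role: battery[key] for role, key in keys.items()},
        )
        verdicts.append(classify(inp))
    return verdicts
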