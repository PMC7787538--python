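"""Rule DSL, MPIN-derived rules, and the forward-chaining engine.

The entailment contract is checked against sympy's SAT solver as an
independent truth-table oracle; definite-clause bases additionally
against naive least-fixpoint iteration; traces are replayed with an
independent clause-level checker.
"""
import random
import warnings

import pytest
import sympy
from sympy.logic.inference import satisfiable

from sddp.logic_inference import (
    And,
    Atom,
    Implies,
    InconsistentRuleBase,
    Not,
    Or,
    Rule,
    RuleBase,
    RuleParseError,
    conj,
    disj,
    explain,
    formula_atoms,
    format_formula,
    forward_chain,
    parse_rules,
    rules_from_mpin,
)
from sddp.pathway_model import build_mpin
from sddp.synthetic import nested_example

# ---------------------------------------------------------------------------
# oracles

def to_sympy(f):
    if isinstance(f, Atom):
        return sympy.Symbol(f.name)
    if isinstance(f, Not):
        return sympy.Not(to_sympy(f.operand))
    if isinstance(f, And):
        return sympy.And(*[to_sympy(a) for a in f.args])
    if isinstance(f, Or):
        return sympy.Or(*[to_sympy(a) for a in f.args])
    if isinstance(f, Implies):
        return sympy.Implies(to_sympy(f.antecedent), to_sympy(f.consequent))
    raise TypeError(f)


def oracle_entailed(rules, detected):
    """Truth-table/SAT entailment oracle, independent of the engine."""
    premises = sympy.And(*[to_sympy(r.formula) for r in rules],
                         *[sympy.Symbol(a) for a in detected])
    universe = set().union(*[formula_atoms(r.formula) for r in rules],
                           set(detected)) if (len(rules) or detected) else set()
    if satisfiable(premises) is False:
        return True, set(universe) - set(detected)
    inferred = {
        a for a in universe - set(detected)
        if satisfiable(sympy.And(premises, sympy.Not(sympy.Symbol(a)))) is False
    }
    return False, inferred


def fixpoint_definite(rules, detected):
    """Naive bottom-up iteration for definite-clause rule bases."""
    def conj_atoms(f):
        if isinstance(f, Atom):
            return {f.name}
        assert isinstance(f, And) and all(isinstance(a, Atom) for a in f.args)
        return {a.name for a in f.args}

    facts = set(detected)
    changed = True
    while changed:
        changed = False
        for r in rules:
            if conj_atoms(r.antecedent) <= facts:
                new = conj_atoms(r.consequent) - facts
                if new:
                    facts |= new
                    changed = True
    return facts - set(detected)


def clause_of(formula):
    """Independent single-clause reading of an engine step formula."""
    def lits(f):
        if isinstance(f, Atom):
            return [(f.name, True)]
        if isinstance(f, Not):
            assert isinstance(f.operand, Atom)
            return [(f.operand.name, False)]
        raise AssertionError(f"not a literal: {f}")

    if isinstance(formula, Implies):
        ant = (formula.antecedent.args if isinstance(formula.antecedent, And)
               else (formula.antecedent,))
        cons = (formula.consequent.args if isinstance(formula.consequent, Or)
                else (formula.consequent,))
        neg = [(a.name, False) for a in ant]
        return frozenset(neg + [l for c in cons for l in lits(c)])
    if isinstance(formula, Or):
        return frozenset(l for a in formula.args for l in lits(a))
    return frozenset(lits(formula))


def replay_step(step, trace):
    """Re-derive a step's formula mechanically from its supports."""
    if step.justification == "premise":
        assert not step.supports
        return
    supports = [trace.steps[i - 1] for i in step.supports]
    if step.justification not in {"modus ponens", "modus tollens",
                                  "hypothetical syllogism",
                                  "disjunctive syllogism", "resolution"}:
        # clause extracted from a rule: check semantic entailment by truth table
        (src,) = supports
        premise = to_sympy(src.formula)
        assert satisfiable(sympy.And(premise,
                                     sympy.Not(to_sympy(step.formula)))) is False
        return
    c1, c2 = (clause_of(s.formula) for s in supports)
    expected = clause_of(step.formula)
    resolvents = set()
    for name, pos in c1:
        if (name, not pos) in c2:
            resolvents.add(frozenset((c1 - {(name, pos)}) | (c2 - {(name, not pos)})))
    assert expected in resolvents, (
        f"step {step.number} is not a resolvent of its supports")
    if step.justification == "modus ponens":
        assert any(len(c) == 1 and next(iter(c))[1] for c in (c1, c2))


def random_rulebase(rng, n_atoms=12, max_rules=8):
    atoms = [f"A{i}" for i in range(n_atoms)]

    def side():
        k = rng.randint(1, 2)
        lits = []
        for _ in range(k):
            a = Atom(rng.choice(atoms))
            lits.append(Not(a) if rng.random() < 0.2 else a)
        return rng.choice([conj, disj])(lits)

    rules = []
    for i in range(rng.randint(1, max_rules)):
        try:
            rules.append(Rule(f"R{len(rules) + 1}", side(), side()))
        except ValueError:
            continue  # a side reduced to a contradiction-free duplicate; skip
    return RuleBase(rules)


# ---------------------------------------------------------------------------
# DSL

def test_parse_conjunctive_rule():
    rb = parse_rules("R1: MP_SMB & MP_CTM -> MP_TRXN")
    (rule,) = rb.rules
    assert rule.antecedent == And((Atom("MP_SMB"), Atom("MP_CTM")))
    assert rule.consequent == Atom("MP_TRXN")


def test_parse_empty_file():
    assert len(parse_rules("")) == 0
    assert len(parse_rules("# only a comment\n\n")) == 0


def test_parse_error_reports_line_and_caret():
    with pytest.raises(RuleParseError) as exc:
        parse_rules("R1: -> MP_X")
    assert exc.value.line_no == 1
    assert "^" in str(exc.value)


def test_unicode_operators_parse_identically():
    ascii_rb = parse_rules("R1: MP_A & !MP_B | MP_C -> MP_D")
    uni_rb = parse_rules("R1: MP_A ∧ ¬MP_B ∨ MP_C → MP_D")
    assert ascii_rb.rules[0].formula == uni_rb.rules[0].formula


def test_precedence_not_over_and_over_or():
    rb = parse_rules("R1: !MP_A & MP_B | MP_C -> MP_D")
    assert rb.rules[0].antecedent == Or((And((Not(Atom("MP_A")), Atom("MP_B"))),
                                         Atom("MP_C")))


def test_dsl_round_trip():
    text = "R1: MP_A & MP_B -> MP_C\nR2: !MP_C | MP_D -> MP_E & MP_F\n"
    rb = parse_rules(text)
    assert parse_rules(rb.to_dsl()).to_dsl() == rb.to_dsl()


def test_duplicate_rule_ids_rejected():
    with pytest.raises(ValueError):
        parse_rules("R1: MP_A -> MP_B\nR1: MP_B -> MP_C")


# ---------------------------------------------------------------------------
# MPIN -> rules

def _nested_mpin():
    network, a, b = nested_example()
    return build_mpin([a, b], network, seed=0)


def test_generalize_policy_specific_implies_general():
    rb = rules_from_mpin(_nested_mpin(), "generalize")
    assert [(r.id, r.formula) for r in rb] == [
        ("R1", Implies(Atom("MP_A"), Atom("MP_B")))]


def test_specialize_policy_reverses():
    rb = rules_from_mpin(_nested_mpin(), "specialize")
    assert rb.rules[0].formula == Implies(Atom("MP_B"), Atom("MP_A"))


def test_conjunctive_policy_adds_joint_rule():
    rb = rules_from_mpin(_nested_mpin(), "conjunctive")
    formulas = [r.formula for r in rb]
    assert Implies(Atom("MP_A"), Atom("MP_B")) in formulas
    assert Implies(Atom("MP_B"), Atom("MP_A")) in formulas  # single general


def test_unknown_policy_errors():
    with pytest.raises(ValueError):
        rules_from_mpin(_nested_mpin(), "bogus")


def test_empty_mpin_empty_rulebase():
    from sddp.pathway_model import PathwayNetwork
    rb = rules_from_mpin(PathwayNetwork(pathways=[], edges=[]))
    assert len(rb) == 0


def test_chain_of_arrows_forward_chains_up_the_hierarchy():
    # C -> B -> A arrows mean A is most general under generalize? No:
    # generalize turns each arrow general->specific into specific -> general,
    # so detecting the most specific pathway entails the whole chain.
    rb = parse_rules("R1: MP_C -> MP_B\nR2: MP_B -> MP_A")
    res = forward_chain(rb, ["MP_C"])
    assert res.inferred == {"MP_A", "MP_B"}


# ---------------------------------------------------------------------------
# forward chaining

def test_no_rules_infer_nothing():
    res = forward_chain(RuleBase([]), ["P"])
    assert res.inferred == frozenset()
    assert res.detected == {"P"}
    assert res.combined == {"P"}


def test_single_modus_ponens():
    res = forward_chain(parse_rules("R1: P -> Q"), ["P"])
    assert res.inferred == {"Q"}
    d = explain(res, "Q")
    assert len(d) == 3
    assert [s.justification for s in d.steps] == ["premise", "premise",
                                                  "modus ponens"]


def test_chained_derivation_replays():
    res = forward_chain(parse_rules("R1: P -> Q\nR2: Q -> R"), ["P"])
    assert res.inferred == {"Q", "R"}
    d = explain(res, "R")
    names = {s.justification for s in d.steps}
    assert names <= {"premise", "modus ponens", "hypothetical syllogism"}
    for step in d.steps:
        replay_step(step, d)


def test_explain_unknown_atom_errors():
    res = forward_chain(parse_rules("R1: P -> Q"), ["P"])
    with pytest.raises(ValueError):
        explain(res, "P")  # detected, not inferred
    with pytest.raises(ValueError):
        explain(res, "Z")


def test_detected_atoms_outside_rulebase_carried_through():
    res = forward_chain(parse_rules("R1: P -> Q"), ["P", "MP_NEW"])
    assert "MP_NEW" in res.combined
    assert "MP_NEW" not in res.inferred


def test_contradictory_base_flags_inconsistent_and_reports_all():
    rb = parse_rules("R1: A -> B\nR2: A -> !B")
    with pytest.warns(InconsistentRuleBase):
        res = forward_chain(rb, ["A"])
    assert res.inconsistent
    assert res.inferred == {"B"}


def test_case_analysis_beyond_horn_clauses():
    rb = parse_rules("R1: P -> A | B\nR2: A -> C\nR3: B -> C")
    res = forward_chain(rb, ["P"])
    assert res.inferred == {"C"}
    for step in explain(res, "C").steps:
        replay_step(step, explain(res, "C"))


@pytest.mark.parametrize("n_trials", [60])
def test_engine_matches_truthtable_oracle(n_trials):
    rng = random.Random(2024)
    for _ in range(n_trials):
        rb = random_rulebase(rng)
        universe = sorted(rb.atoms)
        detected = rng.sample(universe, rng.randint(0, min(3, len(universe))))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", InconsistentRuleBase)
            res = forward_chain(rb, detected)
        inconsistent, expected = oracle_entailed(rb.rules, detected)
        assert res.inconsistent == inconsistent
        assert set(res.inferred) == expected
        # soundness of every trace
        if not inconsistent:
            for atom in res.inferred:
                for step in explain(res, atom).steps:
                    replay_step(step, explain(res, atom))


def test_definite_clause_completeness_matches_fixpoint():
    rng = random.Random(77)
    atoms = [f"A{i}" for i in range(10)]
    for _ in range(40):
        rules = []
        for i in range(rng.randint(1, 10)):
            ant = conj([Atom(a) for a in rng.sample(atoms, rng.randint(1, 3))])
            cons = conj([Atom(a) for a in rng.sample(atoms, rng.randint(1, 2))])
            rules.append(Rule(f"R{i + 1}", ant, cons))
        rb = RuleBase(rules)
        detected = set(rng.sample(atoms, rng.randint(0, 4)))
        res = forward_chain(rb, detected)
        assert not res.inconsistent
        assert set(res.inferred) == fixpoint_definite(rules, detected)


def test_monotonicity_and_idempotence():
    rng = random.Random(5150)
    for _ in range(25):
        rb = random_rulebase(rng, n_atoms=8, max_rules=6)
        universe = sorted(rb.atoms)
        small = set(rng.sample(universe, rng.randint(0, 2)))
        extra = set(rng.sample(universe, rng.randint(0, 2)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", InconsistentRuleBase)
            res_small = forward_chain(rb, small)
            res_big = forward_chain(rb, small | extra)
            assert res_small.combined <= res_big.combined | res_big.detected
            # idempotence: chaining from the closure adds nothing
            res_again = forward_chain(rb, res_small.combined)
            if not res_small.inconsistent:
                assert res_again.inferred == frozenset()


def test_trace_supports_precede_steps():
    res = forward_chain(parse_rules("R1: P & Q -> R\nR2: R -> S"), ["P", "Q"])
    for step in res.trace.steps:
        assert all(s < step.number for s in step.supports)
    printable = str(explain(res, "S"))
    assert "modus ponens" in printable or "resolution" in printable
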