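"""Propositional specification rules and forward-chaining inference.

Pathway deficiencies are ground propositions; specification rules are
implications between formulas over ``∧``, ``∨`` and ``¬``.  Rules are
either generated from the MPIN hierarchy (:func:`rules_from_mpin`) or
loaded from a small rule DSL (:func:`parse_rules`).

:func:`forward_chain` computes the set of pathway atoms classically
entailed by the rules together with an individual's detected pathways,
and a numbered proof trace for every inferred atom.  The engine
saturates the clause space breadth-first with binary resolution
(complete for unit consequences by the subsumption theorem); each
resolvent is recorded as a derivation step named after the classical
inference rule it instantiates — modus ponens, modus tollens,
hypothetical syllogism, disjunctive syllogism — falling back to the
generic name "resolution".  Non-clausal rules contribute their clause
forms as steps justified by the source rule's id.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .pathway_model import PathwayNetwork

__all__ = [
    "Atom", "Not", "And", "Or", "Implies", "Formula",
    "Rule", "RuleBase", "RuleParseError",
    "DerivationStep", "Derivation", "InferenceResult", "InconsistentRuleBase",
    "parse_rules", "rules_from_mpin", "forward_chain", "explain",
    "formula_atoms", "evaluate", "format_formula", "to_clauses",
]

INFERENCE_RULE_NAMES = frozenset({
    "modus ponens", "modus tollens", "hypothetical syllogism",
    "disjunctive syllogism", "addition", "simplification",
    "conjunction", "resolution",
})


# ---------------------------------------------------------------------------
# formulas

class Formula:
    __slots__ = ()


@dataclass(frozen=True)
class Atom(Formula):
    name: str


@dataclass(frozen=True)
class Not(Formula):
    operand: Formula


@dataclass(frozen=True)
class And(Formula):
    args: tuple[Formula, ...]


@dataclass(frozen=True)
class Or(Formula):
    args: tuple[Formula, ...]


@dataclass(frozen=True)
class Implies(Formula):
    antecedent: Formula
    consequent: Formula


def conj(args: Sequence[Formula]) -> Formula:
    flat: list[Formula] = []
    for a in args:
        flat.extend(a.args) if isinstance(a, And) else flat.append(a)
    uniq = list(dict.fromkeys(flat))
    return uniq[0] if len(uniq) == 1 else And(tuple(uniq))


def disj(args: Sequence[Formula]) -> Formula:
    flat: list[Formula] = []
    for a in args:
        flat.extend(a.args) if isinstance(a, Or) else flat.append(a)
    uniq = list(dict.fromkeys(flat))
    return uniq[0] if len(uniq) == 1 else Or(tuple(uniq))


def formula_atoms(f: Formula) -> set[str]:
    if isinstance(f, Atom):
        return {f.name}
    if isinstance(f, Not):
        return formula_atoms(f.operand)
    if isinstance(f, (And, Or)):
        out: set[str] = set()
        for a in f.args:
            out |= formula_atoms(a)
        return out
    if isinstance(f, Implies):
        return formula_atoms(f.antecedent) | formula_atoms(f.consequent)
    raise TypeError(f"not a formula: {f!r}")


def evaluate(f: Formula, assignment: dict[str, bool]) -> bool:
    if isinstance(f, Atom):
        return assignment[f.name]
    if isinstance(f, Not):
        return not evaluate(f.operand, assignment)
    if isinstance(f, And):
        return all(evaluate(a, assignment) for a in f.args)
    if isinstance(f, Or):
        return any(evaluate(a, assignment) for a in f.args)
    if isinstance(f, Implies):
        return (not evaluate(f.antecedent, assignment)) or evaluate(f.consequent, assignment)
    raise TypeError(f"not a formula: {f!r}")


def format_formula(f: Formula, top: bool = True) -> str:
    if isinstance(f, Atom):
        return f.name
    if isinstance(f, Not):
        return "¬" + format_formula(f.operand, top=False)
    if isinstance(f, And):
        s = " ∧ ".join(format_formula(a, top=False) for a in f.args)
        return s if top else f"({s})"
    if isinstance(f, Or):
        s = " ∨ ".join(format_formula(a, top=False) for a in f.args)
        return s if top else f"({s})"
    if isinstance(f, Implies):
        s = (f"{format_formula(f.antecedent, top=False)} → "
             f"{format_formula(f.consequent, top=False)}")
        return s if top else f"({s})"
    raise TypeError(f"not a formula: {f!r}")


# ---------------------------------------------------------------------------
# rules

@dataclass(frozen=True)
class Rule:
    """A specification rule ``antecedent → consequent``."""

    id: str
    antecedent: Formula
    consequent: Formula

    def __post_init__(self):
        if not formula_atoms(self.antecedent) or not formula_atoms(self.consequent):
            raise ValueError(f"rule {self.id}: both sides need at least one atom")

    @property
    def formula(self) -> Implies:
        return Implies(self.antecedent, self.consequent)


class RuleBase:
    """Ordered rule collection with a derived atom universe."""

    def __init__(self, rules: Iterable[Rule] = ()):
        self.rules: list[Rule] = list(rules)
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rule ids")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    @property
    def atoms(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.rules:
            out |= formula_atoms(r.formula)
        return frozenset(out)

    def to_dsl(self) -> str:
        lines = []
        for r in self.rules:
            lines.append(f"{r.id}: {_dsl(r.antecedent)} -> {_dsl(r.consequent)}")
        return "\n".join(lines) + ("\n" if lines else "")


def _dsl(f: Formula, top: bool = True) -> str:
    if isinstance(f, Atom):
        return f.name
    if isinstance(f, Not):
        return "!" + _dsl(f.operand, top=False)
    if isinstance(f, And):
        s = " & ".join(_dsl(a, top=False) for a in f.args)
        return s if top else f"({s})"
    if isinstance(f, Or):
        s = " | ".join(_dsl(a, top=False) for a in f.args)
        return s if top else f"({s})"
    raise TypeError(f"cannot serialise {f!r} inside a rule side")


# ---------------------------------------------------------------------------
# rule DSL parser

class RuleParseError(ValueError):
    def __init__(self, message: str, line_no: int, col: int, line: str):
        caret = " " * col + "^"
        super().__init__(f"line {line_no}: {message}\n  {line}\n  {caret}")
        self.line_no = line_no
        self.col = col


_ALIASES = {"∧": "&", "∨": "|", "¬": "!", "→": "->"}
_TOKEN = re.compile(r"->|[&|!():]|[A-Za-z_][A-Za-z0-9_]*|\S")


class _LineParser:
    def __init__(self, line: str, line_no: int):
        self.line = line
        self.line_no = line_no
        self.tokens = [(m.group(), m.start()) for m in _TOKEN.finditer(line)]
        self.pos = 0

    def error(self, message: str) -> RuleParseError:
        col = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.line)
        return RuleParseError(message, self.line_no, col, self.line)

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self, expected: str | None = None) -> str:
        tok = self.peek()
        if tok is None or (expected is not None and tok != expected):
            raise self.error(f"expected {expected!r}" if expected else "unexpected end of line")
        self.pos += 1
        return tok

    def parse_rule(self) -> Rule:
        rid = self.take()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", rid):
            raise self.error("expected rule id")
        self.take(":")
        lhs = self.parse_expr()
        self.take("->")
        rhs = self.parse_expr()
        if self.peek() is not None:
            raise self.error("trailing input after rule")
        try:
            return Rule(rid, lhs, rhs)
        except ValueError as exc:
            raise RuleParseError(str(exc), self.line_no, 0, self.line) from exc

    def parse_expr(self) -> Formula:
        return self.parse_or()

    def parse_or(self) -> Formula:
        args = [self.parse_and()]
        while self.peek() == "|":
            self.take()
            args.append(self.parse_and())
        return disj(args)

    def parse_and(self) -> Formula:
        args = [self.parse_unary()]
        while self.peek() == "&":
            self.take()
            args.append(self.parse_unary())
        return conj(args)

    def parse_unary(self) -> Formula:
        tok = self.peek()
        if tok == "!":
            self.take()
            operand = self.parse_unary()
            if isinstance(operand, Not):
                return operand.operand
            return Not(operand)
        if tok == "(":
            self.take()
            inner = self.parse_expr()
            self.take(")")
            return inner
        if tok is not None and re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", tok):
            self.take()
            return Atom(tok)
        raise self.error("expected atom, '!' or '('")


def parse_rules(text: str) -> RuleBase:
    """Parse the rule DSL: one ``Ri: EXPR -> EXPR`` per line.

    Operators ``&``, ``|``, ``!`` at standard precedence (``!`` > ``&``
    > ``|``), parentheses, ``#`` comments; the unicode connectives
    ``∧ ∨ ¬ →`` are accepted as aliases.  Syntax errors name the line
    and point a caret at the offending column.
    """
    rules: list[Rule] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0]
        for alias, ascii_op in _ALIASES.items():
            line = line.replace(alias, ascii_op)
        if not line.strip():
            continue
        rules.append(_LineParser(line.rstrip(), line_no).parse_rule())
    return RuleBase(rules)


# ---------------------------------------------------------------------------
# clause machinery

Literal = tuple[str, bool]          # (atom name, positive)
Clause = frozenset  # of Literal


def _nnf(f: Formula, negate: bool = False) -> Formula:
    if isinstance(f, Atom):
        return Not(f) if negate else f
    if isinstance(f, Not):
        return _nnf(f.operand, not negate)
    if isinstance(f, And):
        parts = tuple(_nnf(a, negate) for a in f.args)
        return disj(parts) if negate else conj(parts)
    if isinstance(f, Or):
        parts = tuple(_nnf(a, negate) for a in f.args)
        return conj(parts) if negate else disj(parts)
    if isinstance(f, Implies):
        return _nnf(disj((Not(f.antecedent), f.consequent)), negate)
    raise TypeError(f"not a formula: {f!r}")


def _cnf_clauses(f: Formula) -> list[Clause]:
    f = _nnf(f)

    def rec(g: Formula) -> list[frozenset]:
        if isinstance(g, Atom):
            return [frozenset({(g.name, True)})]
        if isinstance(g, Not):
            assert isinstance(g.operand, Atom)
            return [frozenset({(g.operand.name, False)})]
        if isinstance(g, And):
            out: list[frozenset] = []
            for a in g.args:
                out.extend(rec(a))
            return out
        if isinstance(g, Or):
            parts = [rec(a) for a in g.args]
            out = [frozenset()]
            for clauses in parts:
                out = [c | d for c in out for d in clauses]
            return out
        raise TypeError(f"unexpected NNF node: {g!r}")

    seen: set[Clause] = set()
    result: list[Clause] = []
    for clause in rec(f):
        if any((name, not pos) in clause for name, pos in clause):
            continue  # tautology
        if clause not in seen:
            seen.add(clause)
            result.append(clause)
    return result


def to_clauses(f: Formula) -> list[Clause]:
    """CNF clause forms of a formula; tautologies and duplicates dropped."""
    return _cnf_clauses(f)


def _clause_key(clause: Clause) -> tuple:
    return tuple(sorted(clause))


def clause_formula(clause: Clause) -> Formula:
    """Implication-normal rendering: negatives → antecedent, positives → consequent."""
    neg = sorted(name for name, pos in clause if not pos)
    pos_ = sorted(name for name, pos in clause if pos)
    if neg and pos_:
        return Implies(conj([Atom(n) for n in neg]), disj([Atom(p) for p in pos_]))
    if pos_:
        return disj([Atom(p) for p in pos_])
    if neg:
        return disj([Not(Atom(n)) for n in neg])
    raise ValueError("empty clause has no formula rendering")


def _classify(c1: Clause, c2: Clause, pivot: Literal, result: Clause) -> str:
    """Name the classical inference rule a binary resolution step instantiates."""
    name, _ = pivot

    def shape(c: Clause) -> tuple[int, int]:
        return (sum(1 for _, p in c if not p), sum(1 for _, p in c if p))

    for unit, other in ((c1, c2), (c2, c1)):
        if len(unit) != 1:
            continue
        (lname, lpos), = unit
        o_neg, o_pos = shape(other)
        if lpos and (lname, False) in other:
            # positive unit resolving an implication's whole antecedent
            if o_neg == 1 and o_pos >= 1:
                return "modus ponens"
            if o_neg == 0:
                return "disjunctive syllogism"  # cannot happen: needs (lname, False)
        if not lpos and (lname, True) in other:
            if o_neg == 0:
                return "disjunctive syllogism"  # ¬a against a positive disjunction
            if o_pos == 1 and o_neg >= 1:
                return "modus tollens"
    n1, p1 = shape(c1)
    n2, p2 = shape(c2)
    if n1 >= 1 and p1 == 1 and n2 >= 1 and p2 == 1 and shape(result) == (
            n1 + n2 - 1, 1):
        return "hypothetical syllogism"
    return "resolution"


# ---------------------------------------------------------------------------
# derivations

@dataclass(frozen=True)
class DerivationStep:
    """One numbered step of a derivation.

    ``justification`` is "premise", a rule id (clause form of that
    rule), or a standard inference-rule name; ``supports`` are 1-based
    step numbers of the formulas the step was derived from.
    """

    number: int
    formula: Formula
    justification: str
    supports: tuple[int, ...] = ()
    rule_id: str | None = None

    def render(self) -> str:
        just = self.justification
        if self.rule_id and just == "premise":
            just = f"premise ({self.rule_id})"
        elif self.justification not in INFERENCE_RULE_NAMES and self.justification != "premise":
            just = f"clause of {self.justification}"
        if self.supports:
            src = ", ".join(str(s) for s in self.supports)
            just += f" (from step{'s' if len(self.supports) > 1 else ''} {src})"
        return f"{self.number}. {format_formula(self.formula)}    [{just}]"


@dataclass
class Derivation:
    steps: list[DerivationStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def validate(self) -> None:
        for i, step in enumerate(self.steps, start=1):
            if step.number != i:
                raise ValueError("steps must be numbered consecutively from 1")
            if any(s >= step.number or s < 1 for s in step.supports):
                raise ValueError(f"step {i}: supports must precede the step")
            if (step.supports and step.justification != "premise"
                    and step.justification not in INFERENCE_RULE_NAMES
                    and step.rule_id is None and "_" not in step.justification
                    and not step.justification):
                raise ValueError(f"step {i}: unknown justification")

    def __str__(self) -> str:
        return "\n".join(step.render() for step in self.steps)


class InconsistentRuleBase(UserWarning):
    pass


@dataclass
class InferenceResult:
    """Detected premises, inferred pathway atoms, and the proof trace."""

    detected: frozenset[str]
    inferred: frozenset[str]
    trace: Derivation
    inconsistent: bool = False
    _atom_steps: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def combined(self) -> frozenset[str]:
        return self.detected | self.inferred


# ---------------------------------------------------------------------------
# forward chaining

def forward_chain(
    rules: RuleBase,
    detected: Iterable[str],
    max_clauses: int = 200_000,
) -> InferenceResult:
    """All pathway atoms entailed by ``rules`` plus the detected premises.

    ``inferred`` is the set of atoms (outside ``detected``) true in
    every model of the rules together with the detected atoms.  The
    clause space is saturated breadth-first with binary resolution
    under forward subsumption, which is complete for unit consequences;
    a contradictory rule base derives the empty clause, is flagged
    inconsistent with a warning, and reports every atom.  Detected
    atoms absent from the rule base are carried through unchanged.
    """
    detected = frozenset(detected)
    universe = set(rules.atoms) | detected

    steps: list[DerivationStep] = []
    clause_step: dict[Clause, int] = {}

    def add_step(formula: Formula, justification: str,
                 supports: tuple[int, ...] = (), rule_id: str | None = None) -> int:
        steps.append(DerivationStep(len(steps) + 1, formula, justification,
                                    supports, rule_id))
        return len(steps)

    # premises: detected atoms, then the rules themselves
    for atom in sorted(detected):
        n = add_step(Atom(atom), "premise")
        clause_step[frozenset({(atom, True)})] = n
    for rule in rules:
        rule_step = add_step(rule.formula, "premise", rule_id=rule.id)
        clauses = sorted(to_clauses(rule.formula), key=_clause_key)
        for clause in clauses:
            if clause in clause_step:
                continue
            if len(clauses) == 1:
                # the rule formula is equivalent to its single clause
                clause_step[clause] = rule_step
            else:
                clause_step[clause] = add_step(
                    clause_formula(clause), rule.id, (rule_step,))

    # breadth-first resolution saturation with forward subsumption
    inconsistent = False
    contradiction_supports: tuple[int, int] | None = None
    frontier = sorted(clause_step, key=lambda c: clause_step[c])
    while frontier and not inconsistent:
        existing = sorted(clause_step, key=lambda c: clause_step[c])
        new_round: list[Clause] = []
        for c1 in frontier:
            for c2 in existing:
                if c1 is c2:
                    continue
                for lit in sorted(c1):
                    comp = (lit[0], not lit[1])
                    if comp not in c2:
                        continue
                    resolvent = frozenset((c1 - {lit}) | (c2 - {comp}))
                    if any((n, not p) in resolvent for n, p in resolvent):
                        continue  # tautology
                    if not resolvent:
                        inconsistent = True
                        contradiction_supports = (clause_step[c1], clause_step[c2])
                        break
                    if resolvent in clause_step:
                        continue
                    if any(kept <= resolvent for kept in clause_step):
                        continue  # forward subsumption
                    name = _classify(c1, c2, lit, resolvent)
                    clause_step[resolvent] = add_step(
                        clause_formula(resolvent), name,
                        tuple(sorted((clause_step[c1], clause_step[c2]))))
                    new_round.append(resolvent)
                    if len(clause_step) > max_clauses:
                        raise RuntimeError(
                            "resolution saturation exceeded the clause budget")
                if inconsistent:
                    break
            if inconsistent:
                break
        frontier = new_round

    trace = Derivation(steps)
    if inconsistent:
        warnings.warn("rule base together with the detected pathways is "
                      "contradictory; every atom is entailed",
                      InconsistentRuleBase)
        inferred = frozenset(universe - detected)
        atom_steps: dict[str, int] = {}
    else:
        atom_steps = {
            name: idx for clause, idx in clause_step.items()
            if len(clause) == 1 for name, pos in clause if pos
        }
        inferred = frozenset(a for a in atom_steps if a not in detected)
    return InferenceResult(detected=detected, inferred=inferred,
                           trace=trace, inconsistent=inconsistent,
                           _atom_steps=atom_steps)


def explain(result: InferenceResult, atom: str) -> Derivation:
    """Minimal renumbered derivation of one inferred atom.

    Extracts the supporting steps of the atom's first derivation from
    the full trace and renumbers them consecutively.
    """
    if atom not in result.inferred:
        raise ValueError(f"atom {atom!r} was not inferred")
    if result.inconsistent or atom not in result._atom_steps:
        raise ValueError(
            f"no direct derivation recorded for {atom!r} (inconsistent rule base)")
    target = result._atom_steps[atom]
    needed: set[int] = set()
    stack = [target]
    while stack:
        n = stack.pop()
        if n in needed:
            continue
        needed.add(n)
        stack.extend(result.trace.steps[n - 1].supports)
    ordered = sorted(needed)
    renumber = {old: new for new, old in enumerate(ordered, start=1)}
    steps = [
        DerivationStep(
            renumber[old],
            result.trace.steps[old - 1].formula,
            result.trace.steps[old - 1].justification,
            tuple(renumber[s] for s in result.trace.steps[old - 1].supports),
            result.trace.steps[old - 1].rule_id,
        )
        for old in ordered
    ]
    derivation = Derivation(steps)
    derivation.validate()
    return derivation


# ---------------------------------------------------------------------------
# MPIN → rules

RULE_POLICIES = ("generalize", "specialize", "conjunctive")


def rules_from_mpin(mpin: PathwayNetwork, policy: str = "generalize") -> RuleBase:
    """Specification rules encoding the MPIN hierarchy.

    For each arrow from a general pathway g to a more specific pathway
    s:  ``generalize`` (default) emits ``s → g`` — a deficiency in the
    specific pathway implies one in its more general relative, since
    the shared molecule lies in both; ``specialize`` emits ``g → s``;
    ``conjunctive`` emits the generalize rules plus, for every pathway
    s with incoming arrows from g1…gk, the rule ``g1 ∧ … ∧ gk → s``.
    Undirected edges emit no rule.  Rule ids run R1… in deterministic
    edge order.
    """
    if policy not in RULE_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {RULE_POLICIES}")
    arrows = []
    for e in sorted(mpin.edges, key=lambda e: (e.x, e.y)):
        if e.arrow is not None:
            arrows.append(e.arrow)  # (general, specific)

    rules: list[Rule] = []

    def next_id() -> str:
        return f"R{len(rules) + 1}"

    for general, specific in arrows:
        if policy == "specialize":
            rules.append(Rule(next_id(), Atom(general), Atom(specific)))
        else:
            rules.append(Rule(next_id(), Atom(specific), Atom(general)))
    if policy == "conjunctive":
        incoming: dict[str, list[str]] = {}
        for general, specific in arrows:
            incoming.setdefault(specific, []).append(general)
        for specific in sorted(incoming):
            generals = sorted(incoming[specific])
            rules.append(Rule(next_id(),
                              conj([Atom(g) for g in generals]),
                              Atom(specific)))
    return RuleBase(rules)
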