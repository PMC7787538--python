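"""Part-Of-Sentence Trees (POST).

A sentence is represented as an ordered rooted tree of constituents:
clauses, units and groups, with tokens at the leaves.  The tree is the
substrate for the strict relatedness rules in :mod:`sddp.text_mining` —
in particular the independent-clause boundaries and the coordinator
tokens between them.

Parsing proper is consumed, not performed: trees are loaded from
Penn-style bracketed parses produced by an external toolkit
(:func:`load_post`), or approximated from raw text by a deliberately
simple clause splitter (:func:`post_from_text`) when no parse is
available.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterator

logger = logging.getLogger(__name__)

#: The seven constituent kinds of a POST.
POST_LABELS = frozenset({
    "independent-clause",
    "adverbial-clause",
    "conjoint-clause",
    "compound-unit",
    "unit",
    "group",
    "token",
})

#: Penn-treebank-style labels mapped onto POST constituent kinds.
#: Anything not listed (and not already a POST label) collapses to "unit".
DEFAULT_LABEL_MAP = {
    "S": "independent-clause",
    "SINV": "independent-clause",
    "SQ": "independent-clause",
    "IC": "independent-clause",
    "SBAR": "adverbial-clause",
    "SBARQ": "adverbial-clause",
    "ADVCL": "adverbial-clause",
    "CONJP": "conjoint-clause",
    "UCP": "compound-unit",
    "NP": "group",
    "VP": "group",
    "PP": "group",
    "ADJP": "group",
    "ADVP": "group",
    "WHNP": "group",
    "WHADVP": "group",
    "NML": "group",
    "QP": "group",
    "PRT": "group",
}

#: Pronouns whose referent is replaced by the closest terms of the
#: preceding independent clause.
DEFAULT_PRONOUNS = frozenset({"whom", "which", "it", "who", "that"})

#: Preposition modifiers that render two independent clauses unrelated.
DEFAULT_COORDINATORS = frozenset({"whereas", "while", "but"})


class PostParseError(ValueError):
    """Malformed bracketed parse; ``offset`` is the character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass
class Constituent:
    """One node of a POST: an internal constituent or a token leaf.

    ``start``/``end`` are 0-based half-open token indices into the
    sentence.  ``antecedents`` is non-empty only on pronoun leaves after
    pronoun resolution, and holds the canonical ids of the antecedent
    terms.
    """

    label: str
    start: int
    end: int
    children: tuple["Constituent", ...] = ()
    text: str | None = None
    antecedents: tuple[str, ...] = ()

    @property
    def is_token(self) -> bool:
        return self.label == "token"

    def walk(self) -> Iterator["Constituent"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class ConstituentTree:
    """Ordered rooted tree over one sentence."""

    root: Constituent

    def leaves(self) -> list[Constituent]:
        return [c for c in self.root.walk() if c.is_token]

    def tokens(self) -> list[str]:
        return [c.text for c in self.leaves()]  # type: ignore[misc]

    def constituents(self, label: str) -> list[Constituent]:
        return [c for c in self.root.walk() if c.label == label]

    def validate(self) -> None:
        """Check span partitioning and leaf/token consistency."""
        for node in self.root.walk():
            if node.is_token:
                if node.text is None or node.end != node.start + 1 or node.children:
                    raise ValueError(f"bad token leaf at {node.start}")
                continue
            if not node.children:
                raise ValueError(f"internal node without children at {node.start}")
            pos = node.start
            for child in node.children:
                if child.start != pos:
                    raise ValueError(
                        f"children do not partition span at token {pos}")
                pos = child.end
            if pos != node.end:
                raise ValueError(f"children do not cover span ending {node.end}")
            if node.label not in POST_LABELS:
                raise ValueError(f"unknown label {node.label!r}")


_BRACKET_TOKEN = re.compile(r"[()]|[^\s()]+")


def load_post(bracketed: str, label_map: dict[str, str] | None = None) -> ConstituentTree:
    """Build a POST from a Penn-style bracketed constituency parse.

    Labels are mapped through ``label_map`` (default
    :data:`DEFAULT_LABEL_MAP`); labels that are neither mappable nor
    already POST labels collapse to ``"unit"``.  Bare words become token
    leaves.  Malformed bracketing raises :class:`PostParseError` naming
    the character offset of the offending (or outermost unclosed)
    bracket.
    """
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map

    # stack frames: [open_offset, label (None until seen), children list]
    stack: list[list] = []
    root: Constituent | None = None
    counter = 0  # running token index

    def close_frame() -> None:
        nonlocal root, counter
        offset, label, children = stack.pop()
        if not children:
            raise PostParseError("empty constituent", offset)
        if label is None:
            mapped = "unit"
        elif label in POST_LABELS:
            mapped = label
        else:
            mapped = label_map.get(label, "unit")
        node = Constituent(
            label=mapped,
            start=children[0].start,
            end=children[-1].end,
            children=tuple(children),
        )
        if stack:
            stack[-1][2].append(node)
        elif root is None:
            root = node
        else:
            raise PostParseError("multiple root constituents", offset)

    for match in _BRACKET_TOKEN.finditer(bracketed):
        tok, offset = match.group(), match.start()
        if tok == "(":
            stack.append([offset, None, []])
        elif tok == ")":
            if not stack:
                raise PostParseError("unbalanced ')'", offset)
            close_frame()
        else:
            if not stack:
                raise PostParseError("token outside brackets", offset)
            frame = stack[-1]
            if frame[1] is None and not frame[2]:
                frame[1] = tok  # first bare word after '(' is the label
            else:
                leaf = Constituent("token", counter, counter + 1, text=tok)
                counter += 1
                frame[2].append(leaf)

    if stack:
        raise PostParseError("unclosed '('", stack[0][0])
    if root is None:
        raise PostParseError("empty parse", 0)
    tree = ConstituentTree(root)
    tree.validate()
    return tree


_WORD = re.compile(r"[^\s,;:.!?]+|[,;:.!?]")


def tokenize(text: str) -> list[str]:
    """Whitespace + punctuation tokenizer; hyphenated terms stay whole."""
    return _WORD.findall(text)


def post_from_text(
    text: str,
    coordinators: frozenset[str] = DEFAULT_COORDINATORS,
    pronouns: frozenset[str] = DEFAULT_PRONOUNS,
) -> ConstituentTree:
    """Heuristic POST for raw text when no bracketed parse is supplied.

    The sentence is cut into flat independent clauses at semicolons, at
    coordinator tokens, and at a comma directly followed by a pronoun
    (relative clauses).  Coordinators and clause-separating punctuation
    sit between the clauses at root level, so the strict relatedness
    rules still see the clause boundaries they need.
    """
    tokens = tokenize(text)
    pieces: list[tuple[str, list[str]]] = []  # ("clause" | "sep", tokens)
    current: list[str] = []

    def flush() -> None:
        if current:
            pieces.append(("clause", current.copy()))
            current.clear()

    i = 0
    while i < len(tokens):
        tok = tokens[i]
        low = tok.lower()
        if low in coordinators:
            if current and current[-1] == ",":
                current.pop()
                flush()
                pieces.append(("sep", [","]))
            else:
                flush()
            pieces.append(("sep", [tok]))
        elif tok == ";":
            flush()
            pieces.append(("sep", [tok]))
        elif low in pronouns and current and current[-1] == ",":
            current.pop()
            flush()
            pieces.append(("sep", [","]))
            current.append(tok)
        else:
            current.append(tok)
        i += 1
    flush()

    pos = 0
    children: list[Constituent] = []
    for kind, toks in pieces:
        leaves = []
        for tok in toks:
            leaves.append(Constituent("token", pos, pos + 1, text=tok))
            pos += 1
        if kind == "clause":
            children.append(Constituent(
                "independent-clause", leaves[0].start, leaves[-1].end,
                children=tuple(leaves)))
        else:
            children.extend(leaves)
    if not children:
        raise PostParseError("empty sentence", 0)
    if len(children) == 1:
        root = children[0]
    else:
        root = Constituent("unit", 0, pos, children=tuple(children))
    tree = ConstituentTree(root)
    tree.validate()
    return tree


def to_bracketed(tree: ConstituentTree) -> str:
    """Serialise a POST back to bracketed form (inverse of :func:`load_post`)."""

    def rec(node: Constituent) -> str:
        if node.is_token:
            return node.text  # type: ignore[return-value]
        inner = " ".join(rec(c) for c in node.children)
        return f"({node.label} {inner})"

    return rec(tree.root)


def copy_tree(tree: ConstituentTree) -> ConstituentTree:
    def rec(node: Constituent) -> Constituent:
        return replace(node, children=tuple(rec(c) for c in node.children))

    return ConstituentTree(rec(tree.root))


def innermost_clause(tree: ConstituentTree, start: int, end: int) -> Constituent | None:
    """Innermost independent clause whose span contains [start, end)."""
    best: Constituent | None = None
    for node in tree.root.walk():
        if node.label == "independent-clause" and node.start <= start and end <= node.end:
            if best is None or (node.end - node.start) <= (best.end - best.start):
                best = node
    return best
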