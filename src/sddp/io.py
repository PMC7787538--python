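"""Readers and writers for the pipeline's plain-text formats.

TSV dialect: tab-separated, UTF-8, no quoting, ``#`` header/comment
lines.  All writers go through :func:`atomic_write`, which leaves a
``.partial`` file behind on failure instead of a truncated artifact.

MEDLINE flat files are read with Bio.Medline; everything else is small
enough to parse directly.
"""
from __future__ import annotations

import json
import logging
import os
import re
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

from .logic_inference import InferenceResult, RuleBase, parse_rules
from .pathway_model import CharacteristicTree, MPINEdge, Pathway, PathwayNetwork
from .post import ConstituentTree, load_post, post_from_text, to_bracketed
from .risk_ranking import Combination, CombinationWeights, DominanceResult
from .text_mining import PairStatistics, Publication, TermDictionary, TermEntry

logger = logging.getLogger(__name__)

__all__ = [
    "atomic_write",
    "read_dictionary", "write_dictionary",
    "read_corpus", "read_corpus_jsonl", "write_corpus_jsonl", "read_corpus_medline",
    "read_network", "write_network_sif",
    "read_pathways", "write_pathways",
    "read_rules_file", "write_rules_file",
    "read_detected", "write_detected",
    "read_weights", "write_weights",
    "write_associations", "write_mpin", "read_mpin", "write_forest_json",
    "read_ranking",
    "write_ranking", "write_inference_json", "write_json",
]


class FormatError(ValueError):
    """Malformed record; message carries file, line and field."""


@contextmanager
def atomic_write(path: str | Path) -> Iterator:
    """Write to ``<path>.partial`` and rename on success only."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    partial = path.with_name(path.name + ".partial")
    handle = open(partial, "w", encoding="utf-8", newline="\n")
    try:
        yield handle
    except BaseException:
        handle.close()
        raise
    handle.close()
    os.replace(partial, path)


def _err(path, line_no, field, message) -> FormatError:
    return FormatError(f"{path}:{line_no}: field {field!r}: {message}")


# --- term dictionaries -----------------------------------------------------

def read_dictionary(path: str | Path) -> TermDictionary:
    """4-column TSV: id, type, primary term, pipe-separated synonyms."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise _err(path, line_no, "row", "expected at least 3 columns")
            tid, ttype, primary = cols[0], cols[1], cols[2]
            synonyms = [s for s in (cols[3].split("|") if len(cols) > 3 else [])
                        if s]
            forms = tuple(dict.fromkeys([primary] + synonyms))
            try:
                entries.append(TermEntry(tid, ttype, forms))
            except ValueError as exc:
                raise _err(path, line_no, "type", str(exc)) from exc
    return TermDictionary(entries)


def write_dictionary(dictionary: TermDictionary, path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("#id\ttype\tprimary_term\tsynonyms\n")
        for tid in dictionary.ids():
            entry = dictionary[tid]
            primary, *rest = entry.surface_forms
            fh.write(f"{tid}\t{entry.type}\t{primary}\t{'|'.join(rest)}\n")


# --- corpora ---------------------------------------------------------------

_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")


def _sentences_from_text(abstract: str) -> tuple[list[str], list[ConstituentTree]]:
    raws = [s.strip() for s in _SENT_SPLIT.split(abstract) if s.strip()]
    return raws, [post_from_text(s) for s in raws]


def read_corpus_jsonl(path: str | Path) -> list[Publication]:
    """JSONL corpus: {"pmid", "abstract", "sentences": [bracketed POST]?}.

    When bracketed parses are present they are authoritative; otherwise
    the abstract is split into sentences and run through the heuristic
    clause splitter.
    """
    pubs = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise _err(path, line_no, "json", str(exc)) from exc
            if "pmid" not in rec:
                raise _err(path, line_no, "pmid", "missing")
            if rec.get("sentences"):
                trees = [load_post(s) for s in rec["sentences"]]
                raws = rec.get(
                    "raw_sentences",
                    [" ".join(load_post(s).tokens()) for s in rec["sentences"]])
            elif "abstract" in rec:
                raws, trees = _sentences_from_text(rec["abstract"])
            else:
                raise _err(path, line_no, "abstract", "missing")
            pubs.append(Publication(str(rec["pmid"]), trees, raws))
    return pubs


def write_corpus_jsonl(corpus: Iterable[Publication], path: str | Path) -> None:
    with atomic_write(path) as fh:
        for pub in corpus:
            rec = {
                "pmid": pub.pmid,
                "abstract": ". ".join(pub.raw) + ("." if pub.raw else ""),
                "sentences": [to_bracketed(t) for t in pub.sentences],
                "raw_sentences": list(pub.raw),
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_corpus_medline(path: str | Path) -> list[Publication]:
    """MEDLINE flat-file records; PMID and AB fields are used."""
    from Bio import Medline

    pubs = []
    with open(path, encoding="utf-8") as fh:
        for rec in Medline.parse(fh):
            pmid = rec.get("PMID")
            abstract = rec.get("AB", "")
            if not pmid:
                continue
            raws, trees = _sentences_from_text(abstract)
            pubs.append(Publication(str(pmid), trees, raws))
    return pubs


def read_corpus(path: str | Path) -> list[Publication]:
    """Sniff JSONL vs MEDLINE by the first non-blank line."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                first = line.strip()
                break
        else:
            return []
    if first.startswith("{"):
        return read_corpus_jsonl(path)
    return read_corpus_medline(path)


# --- molecular networks ----------------------------------------------------

def read_network(path: str | Path) -> nx.Graph:
    """SIF (``a relation b``) or 2-column TSV edge list.

    Duplicate edges are deduplicated and self-loops dropped, both with
    a warning.
    """
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) == 1:
                g.add_node(cols[0])  # SIF singleton node line
                continue
            if len(cols) == 2:
                a, b = cols
            elif len(cols) >= 3:
                a, b = cols[0], cols[2]
            else:
                raise _err(path, line_no, "edge", "expected 1-3 columns")
            if a == b:
                logger.warning("%s:%d: self-loop %r dropped", path, line_no, a)
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                logger.warning("%s:%d: duplicate edge %s-%s", path, line_no, a, b)
            g.add_edge(a, b)
    return g


def write_network_sif(network: nx.Graph, path: str | Path,
                      relation: str = "interacts") -> None:
    with atomic_write(path) as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for node in sorted(n for n in network if network.degree(n) == 0):
            fh.write(f"{node}\n")


# --- pathways --------------------------------------------------------------

def read_pathways(path: str | Path) -> list[Pathway]:
    """TSV: pathway_id, molecule_id, is_marker in {0, 1}."""
    molecules: dict[str, set[str]] = {}
    markers: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise _err(path, line_no, "row", "expected 3 columns")
            pid, mol, flag = cols
            if flag not in ("0", "1"):
                raise _err(path, line_no, "is_marker", f"must be 0 or 1, got {flag!r}")
            molecules.setdefault(pid, set()).add(mol)
            if flag == "1":
                markers.setdefault(pid, set()).add(mol)
    return [Pathway(pid, frozenset(molecules[pid]),
                    frozenset(markers.get(pid, set())))
            for pid in sorted(molecules)]


def write_pathways(pathways: Iterable[Pathway], path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("#pathway_id\tmolecule_id\tis_marker\n")
        for p in sorted(pathways, key=lambda p: p.id):
            for mol in sorted(p.molecules):
                fh.write(f"{p.id}\t{mol}\t{int(mol in p.markers)}\n")


# --- rules and detected lists ----------------------------------------------

def read_rules_file(path: str | Path) -> RuleBase:
    return parse_rules(Path(path).read_text(encoding="utf-8"))


def write_rules_file(rules: RuleBase, path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write(rules.to_dsl())


def read_detected(path: str | Path) -> list[str]:
    """One id per line, ``#`` comments allowed."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_detected(ids: Iterable[str], path: str | Path) -> None:
    with atomic_write(path) as fh:
        for tid in ids:
            fh.write(tid + "\n")


# --- weight matrices -------------------------------------------------------

def read_weights(path: str | Path) -> CombinationWeights:
    """Weight-matrix TSV: header ``#<tab>cid=MP_A+MP_B…``, one row per
    publication."""
    with open(path, encoding="utf-8") as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines or not lines[0].startswith("#"):
        raise FormatError(f"{path}:1: field 'header': expected '#' header row")
    header = lines[0].lstrip("#").split("\t")
    combos = []
    for col_no, cell in enumerate(h for h in header if h.strip()):
        if "=" not in cell:
            raise _err(path, 1, f"column {col_no}", "expected cid=MP_A+MP_B")
        cid, members = cell.split("=", 1)
        combos.append(Combination(cid.strip(),
                                  frozenset(members.strip().split("+"))))
    publications, rows = [], []
    for line_no, line in enumerate(lines[1:], 2):
        cols = line.split("\t")
        if len(cols) != len(combos) + 1:
            raise _err(path, line_no, "row",
                       f"expected {len(combos) + 1} columns, got {len(cols)}")
        publications.append(cols[0])
        try:
            rows.append([int(c) for c in cols[1:]])
        except ValueError as exc:
            raise _err(path, line_no, "weight", str(exc)) from exc
    return CombinationWeights(combos, publications, np.array(rows, dtype=int))


def write_weights(weights: CombinationWeights, path: str | Path) -> None:
    with atomic_write(path) as fh:
        header = "\t".join(
            f"{c.id}={'+'.join(sorted(c.pathways))}" for c in weights.combinations)
        fh.write("#\t" + header + "\n")
        for i, pub in enumerate(weights.publications):
            fh.write(pub + "\t" + "\t".join(map(str, weights.W[i])) + "\n")


# --- stage outputs ---------------------------------------------------------

def write_associations(results: Iterable[tuple[str, PairStatistics]],
                       path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("#marker_id\tdisease_id\tn_related\tn_docs_related\tz\n")
        for marker, stats in results:
            fh.write(f"{marker}\t{stats.pair[1]}\t{stats.n_related}\t"
                     f"{stats.n_docs_related}\t{stats.z:.4f}\n")


def write_mpin(mpin: PathwayNetwork, path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("#pathways\t" + ",".join(mpin.pathways) + "\n")
        fh.write("#x\ty\tdirection\tn_com\tx_bar\ty_bar\tshared\n")
        for e in sorted(mpin.edges, key=lambda e: (e.x, e.y)):
            fh.write(f"{e.x}\t{e.y}\t{e.direction}\t{e.n_com or '.'}\t"
                     f"{'.' if e.x_bar is None else e.x_bar}\t"
                     f"{'.' if e.y_bar is None else e.y_bar}\t"
                     f"{','.join(sorted(e.shared))}\n")


def write_mpin_graphml(mpin: PathwayNetwork, path: str | Path) -> None:
    nx.write_graphml(mpin.to_networkx(), path)


def write_forest_json(forests: dict[str, list[CharacteristicTree]],
                      path: str | Path) -> None:
    payload = {
        pid: [
            {"root": t.root,
             "parent": dict(sorted(t.parent.items())),
             "depth": dict(sorted(t.depth.items()))}
            for t in forest
        ]
        for pid, forest in sorted(forests.items())
    }
    write_json(payload, path)


def read_mpin(path: str | Path) -> PathwayNetwork:
    """Read back an MPIN edge-list TSV written by :func:`write_mpin`."""
    pathways: list[str] = []
    edges: list[MPINEdge] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#pathways\t"):
                pathways = [p for p in line.split("\t")[1].split(",") if p]
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 7:
                raise _err(path, line_no, "row", "expected 7 columns")
            x, y, direction, n_com, xb, yb, shared = cols
            if direction not in ("x->y", "y->x", "undirected"):
                raise _err(path, line_no, "direction", f"bad value {direction!r}")
            edges.append(MPINEdge(
                x, y,
                frozenset(s for s in shared.split(",") if s),
                None if n_com == "." else n_com,
                None if xb == "." else int(xb),
                None if yb == "." else int(yb),
                direction))
    if not pathways:
        pathways = sorted({e.x for e in edges} | {e.y for e in edges})
    return PathwayNetwork(pathways=pathways, edges=edges)


def read_ranking(path: str | Path) -> DominanceResult:
    """Read back a ranking TSV; the beats matrix is not persisted."""
    combos, scores, ranks = [], [], []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise _err(path, line_no, "row", "expected 3 columns")
            combos.append(cols[0])
            scores.append(int(cols[1]))
            ranks.append(int(cols[2]))
    n = len(combos)
    return DominanceResult(combos, np.zeros((n, n), dtype=int),
                           np.array(scores, dtype=int), np.array(ranks, dtype=int))


def write_ranking(result: DominanceResult, path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("#combination\tscore\trank\n")
        for i, cid in enumerate(result.combinations):
            fh.write(f"{cid}\t{int(result.scores[i])}\t{int(result.ranks[i])}\n")


def write_inference_json(result: InferenceResult, path: str | Path) -> None:
    from .logic_inference import format_formula

    payload = {
        "detected": sorted(result.detected),
        "inferred": sorted(result.inferred),
        "combined": sorted(result.combined),
        "inconsistent": result.inconsistent,
        "trace": [
            {"step": s.number,
             "formula": format_formula(s.formula),
             "justification": s.justification,
             "rule_id": s.rule_id,
             "supports": list(s.supports)}
            for s in result.trace.steps
        ],
    }
    write_json(payload, path)


def write_json(payload, path: str | Path) -> None:
    with atomic_write(path) as fh:
        json.dump(payload, fh, indent=2, ensure_ascii=False, sort_keys=False)
        fh.write("\n")
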