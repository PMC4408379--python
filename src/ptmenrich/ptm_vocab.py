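"""The PTM controlled vocabulary and its three-level DAG.

The vocabulary distinguishes *keyword-level* (KW) terms — coarse categories
such as "Phosphoprotein" that appear on Swiss-Prot KW lines — from
*feature-level* (FT) terms — specific modified residues such as
"Phosphoserine" that appear as MOD_RES/LIPID/CROSSLNK feature descriptions.
The DAG has exactly three levels: the literal root "PTM", KW terms below
it, and FT terms below their KW parents.  An FT term may have several KW
parents (a DAG, not a tree).

Feature descriptions are normalized before vocabulary lookup:
``normalize_ft_description`` strips the trailing period, truncates agent
clauses at the first semicolon, and removes the non-experimental
qualifiers "(By similarity)", "(Probable)" and "(Potential)", whose
presence marks the annotation as *putative* rather than *experimental*.
"""

from __future__ import annotations

import enum
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from ptmenrich.errors import UnnamedFeatureError, VocabularyError

__all__ = [
    "ROOT_ID",
    "ROOT_LABEL",
    "EvidenceQualifier",
    "PTMTerm",
    "PTMVocabulary",
    "PTMDag",
    "build_dag",
    "dag_to_xml",
    "xml_from_text",
    "default_vocabulary",
    "load_vocabulary",
    "read_vocabulary_tsv",
    "write_vocabulary_tsv",
    "normalize_ft_description",
    "slugify",
]

ROOT_LABEL = "PTM"
ROOT_ID = "ptm"

#: Parenthesized qualifiers whose presence marks an annotation as putative.
PUTATIVE_QUALIFIERS = ("By similarity", "Probable", "Potential")


class EvidenceQualifier(enum.Enum):
    EXPERIMENTAL = "Experimental"
    PUTATIVE = "Putative"


def slugify(label: str) -> str:
    """Stable opaque identifier for a term label."""
    slug = re.sub(r"[^a-z0-9]+", "-", label.lower()).strip("-")
    return slug or "term"


@dataclass(frozen=True)
class PTMTerm:
    """One vocabulary node: an identifier, a label, a level and its parents.

    FT-level terms carry >= 1 KW-level parent; KW-level terms have exactly
    the root as parent.
    """

    term_id: str
    label: str
    level: str  # "KW" or "FT"
    parents: tuple[str, ...]

    def __post_init__(self):
        if self.level not in ("KW", "FT"):
            raise VocabularyError(f"term {self.label!r}: invalid level {self.level!r}")


class PTMVocabulary:
    """Indexed KW/FT term lists supporting exact and case-insensitive lookup."""

    def __init__(self, terms: Iterable[PTMTerm]):
        self.terms: dict[str, PTMTerm] = {}
        self._by_label: dict[tuple[str, str], str] = {}  # (level, casefolded) -> id
        for term in terms:
            if term.term_id in self.terms:
                raise VocabularyError(f"duplicate term id {term.term_id!r}")
            key = (term.level, term.label.casefold())
            if key in self._by_label:
                raise VocabularyError(
                    f"duplicate {term.level} label {term.label!r}"
                )
            self.terms[term.term_id] = term
            self._by_label[key] = term.term_id
        self._validate()

    def _validate(self) -> None:
        offenders = []
        for term in self.terms.values():
            if term.level == "KW":
                if term.parents != (ROOT_ID,):
                    offenders.append(f"{term.label} (KW term must parent to root)")
            else:
                if not term.parents:
                    offenders.append(f"{term.label} (FT term without a KW parent)")
                for pid in term.parents:
                    parent = self.terms.get(pid)
                    if parent is None or parent.level != "KW":
                        offenders.append(
                            f"{term.label} (parent {pid!r} is not a KW term)"
                        )
        if offenders:
            raise VocabularyError("invalid vocabulary edges: " + "; ".join(offenders))

    # -- lookup -----------------------------------------------------------
    def lookup(self, level: str, label: str) -> PTMTerm | None:
        """Case-insensitive exact label lookup within a level."""
        term_id = self._by_label.get((level, label.casefold()))
        return self.terms[term_id] if term_id else None

    def kw_terms(self) -> list[PTMTerm]:
        return sorted(
            (t for t in self.terms.values() if t.level == "KW"),
            key=lambda t: t.term_id,
        )

    def ft_terms(self) -> list[PTMTerm]:
        return sorted(
            (t for t in self.terms.values() if t.level == "FT"),
            key=lambda t: t.term_id,
        )

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other) -> bool:
        return isinstance(other, PTMVocabulary) and self.terms == other.terms


def load_vocabulary(
    kw_term_list: Iterable[str],
    ft_term_list: Iterable[str],
    edge_list: Iterable[tuple[str, str]],
) -> PTMVocabulary:
    """Build a vocabulary from term labels plus (ft_label, kw_label) edges.

    Every FT term needs at least one edge into the KW level; dangling edge
    endpoints and duplicate labels raise :class:`VocabularyError` listing
    the offenders.
    """
    kw_labels = list(kw_term_list)
    ft_labels = list(ft_term_list)
    kw_ids = {label.casefold(): slugify(label) for label in kw_labels}
    offenders = []
    parents: dict[str, list[str]] = {label: [] for label in ft_labels}
    ft_index = {label.casefold(): label for label in ft_labels}
    for ft_label, kw_label in edge_list:
        canonical_ft = ft_index.get(ft_label.casefold())
        kw_id = kw_ids.get(kw_label.casefold())
        if canonical_ft is None:
            offenders.append(f"edge references unknown FT term {ft_label!r}")
        if kw_id is None:
            offenders.append(f"edge references unknown KW term {kw_label!r}")
        if canonical_ft is not None and kw_id is not None:
            if kw_id not in parents[canonical_ft]:
                parents[canonical_ft].append(kw_id)
    for label in ft_labels:
        if not parents[label]:
            offenders.append(f"FT term {label!r} has no KW parent edge")
    if offenders:
        raise VocabularyError("vocabulary definition errors: " + "; ".join(offenders))
    terms = [
        PTMTerm(slugify(label), label, "KW", (ROOT_ID,)) for label in kw_labels
    ] + [
        PTMTerm(slugify(label), label, "FT", tuple(parents[label]))
        for label in ft_labels
    ]
    return PTMVocabulary(terms)


# ---------------------------------------------------------------------------
# the DAG


@dataclass
class PTMDag:
    """Three-level rooted DAG: root "PTM" -> KW terms -> FT terms."""

    nodes: dict[str, PTMTerm] = field(default_factory=dict)

    @property
    def root_id(self) -> str:
        return ROOT_ID

    def level_of(self, term_id: str) -> int:
        if term_id == ROOT_ID:
            return 0
        return 1 if self.nodes[term_id].level == "KW" else 2

    def children(self, term_id: str) -> list[str]:
        if term_id == ROOT_ID:
            return sorted(t.term_id for t in self.nodes.values() if t.level == "KW")
        return sorted(
            t.term_id for t in self.nodes.values() if term_id in t.parents
        )

    def edge_count(self) -> int:
        return sum(len(t.parents) for t in self.nodes.values())

    def node_count(self) -> int:
        """Nodes including the root."""
        return 1 + len(self.nodes)

    def __eq__(self, other) -> bool:
        return isinstance(other, PTMDag) and self.nodes == other.nodes


def build_dag(vocab: PTMVocabulary) -> PTMDag:
    """Arrange a validated vocabulary as the rooted three-level DAG.

    Node count is ``1 + |KW| + |FT|``; an FT term with several KW parents
    appears once with one edge per parent.
    """
    return PTMDag(nodes=dict(vocab.terms))


def dag_to_xml(dag: PTMDag) -> str:
    """Serialize the DAG to XML.

    Schema: ``<ptmdag><term id=.. label=.. level=..><parent ref=../></term>
    ...</ptmdag>``.  The root node is implicit; KW terms omit parent
    elements (their only parent is the root), FT terms list each KW parent
    as a ``<parent ref=.../>`` child.
    """
    top = ET.Element("ptmdag", attrib={"root": ROOT_LABEL})
    for term in sorted(dag.nodes.values(), key=lambda t: (t.level, t.term_id)):
        el = ET.SubElement(
            top,
            "term",
            attrib={"id": term.term_id, "label": term.label, "level": term.level},
        )
        if term.level == "FT":
            for pid in term.parents:
                ET.SubElement(el, "parent", attrib={"ref": pid})
    ET.indent(top)
    return ET.tostring(top, encoding="unicode", xml_declaration=True) + "\n"


def xml_from_text(text: str) -> PTMDag:
    """Parse :func:`dag_to_xml` output back into a validated DAG.

    Schema violations (a term missing id/label/level, a dangling or
    cycle-forming parent reference) raise :class:`VocabularyError` naming
    the offending node.
    """
    try:
        top = ET.fromstring(text)
    except ET.ParseError as exc:
        raise VocabularyError(f"malformed DAG XML: {exc}") from exc
    if top.tag != "ptmdag":
        raise VocabularyError(f"expected <ptmdag> root element, got <{top.tag}>")
    raw: list[tuple[str, str, str, tuple[str, ...]]] = []
    for el in top:
        if el.tag != "term":
            raise VocabularyError(f"unexpected element <{el.tag}> in DAG XML")
        term_id, label, level = el.get("id"), el.get("label"), el.get("level")
        if not term_id or not label or level not in ("KW", "FT"):
            raise VocabularyError(
                f"term element missing id/label/level: id={term_id!r} label={label!r}"
            )
        refs = tuple(p.get("ref") or "" for p in el.findall("parent"))
        if any(not r for r in refs):
            raise VocabularyError(f"term {term_id!r} has a parent without a ref")
        raw.append((term_id, label, level, refs))
    ids = {t[0] for t in raw}
    terms = []
    for term_id, label, level, refs in raw:
        if level == "KW":
            if refs and set(refs) != {ROOT_ID}:
                raise VocabularyError(
                    f"KW term {term_id!r} may only reference the root as parent"
                )
            parents: tuple[str, ...] = (ROOT_ID,)
        else:
            if not refs:
                raise VocabularyError(f"FT term {term_id!r} has no parent reference")
            for ref in refs:
                if ref == term_id:
                    raise VocabularyError(f"term {term_id!r} references itself")
                if ref not in ids:
                    raise VocabularyError(
                        f"term {term_id!r} has dangling parent ref {ref!r}"
                    )
            parents = refs
        terms.append(PTMTerm(term_id, label, level, parents))
    try:
        vocab = PTMVocabulary(terms)
    except VocabularyError as exc:
        # e.g. an FT term used as a parent => a cycle through level 3
        raise VocabularyError(f"DAG XML violates the 3-level structure: {exc}") from exc
    return build_dag(vocab)


# ---------------------------------------------------------------------------
# FT description normalization

_QUALIFIER_RE = re.compile(
    r"\s*\((?:%s)\)" % "|".join(re.escape(q) for q in PUTATIVE_QUALIFIERS),
    flags=re.IGNORECASE,
)


def normalize_ft_description(raw_text: str) -> tuple[str, EvidenceQualifier]:
    """Clean a MOD_RES/LIPID/CROSSLNK description into a vocabulary label.

    Trailing period stripped; text truncated at the first ``;`` (agent
    clauses such as "; by PKA"); the parenthesized qualifiers "(By
    similarity)", "(Probable)" and "(Potential)" removed — their presence
    makes the annotation :attr:`EvidenceQualifier.PUTATIVE`.  Internal
    parentheses that are part of the chemical name (e.g.
    "N6-(pyridoxal phosphate)lysine") are preserved.  Idempotent.
    """
    text = raw_text.strip()
    text = text.split(";", 1)[0]
    qualifier = EvidenceQualifier.EXPERIMENTAL
    cleaned = _QUALIFIER_RE.sub("", text)
    if cleaned != text:
        qualifier = EvidenceQualifier.PUTATIVE
    cleaned = cleaned.strip()
    while cleaned.endswith("."):
        cleaned = cleaned[:-1].strip()
    # qualifier may sit after the period: "Phosphoserine. (Probable)"
    requalified = _QUALIFIER_RE.sub("", cleaned)
    if requalified != cleaned:
        qualifier = EvidenceQualifier.PUTATIVE
        cleaned = requalified.strip()
        while cleaned.endswith("."):
            cleaned = cleaned[:-1].strip()
    if not cleaned:
        raise UnnamedFeatureError(f"feature description {raw_text!r} is unnamed")
    return cleaned, qualifier


# ---------------------------------------------------------------------------
# vocabulary file format (TSV: level, label, parent_labels "|"-separated)


def write_vocabulary_tsv(vocab: PTMVocabulary) -> str:
    lines = ["level\tlabel\tparent_labels"]
    for term in vocab.kw_terms():
        lines.append(f"KW\t{term.label}\t")
    for term in vocab.ft_terms():
        parent_labels = "|".join(
            vocab.terms[pid].label for pid in term.parents
        )
        lines.append(f"FT\t{term.label}\t{parent_labels}")
    return "\n".join(lines) + "\n"


def read_vocabulary_tsv(text: str) -> PTMVocabulary:
    kw, ft, edges = [], [], []
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if lines and lines[0].lower().startswith("level\t"):
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if len(parts) < 2:
            raise VocabularyError(f"vocabulary TSV line {lineno}: need level\\tlabel")
        level, label = parts[0].strip(), parts[1].strip()
        parent_field = parts[2].strip() if len(parts) > 2 else ""
        if level == "KW":
            kw.append(label)
        elif level == "FT":
            ft.append(label)
            for parent in parent_field.split("|"):
                if parent.strip():
                    edges.append((label, parent.strip()))
        else:
            raise VocabularyError(
                f"vocabulary TSV line {lineno}: unknown level {level!r}"
            )
    return load_vocabulary(kw, ft, edges)


def default_vocabulary() -> PTMVocabulary:
    """The small vocabulary shipped with the package.

    Covers the common Swiss-Prot PTM keywords and the frequent modified-
    residue terms; real analyses should load a full vocabulary file.  Note
    that "Nucleotide-binding" is kept although it is a binding property
    rather than a covalent modification, for continuity with established
    PTM keyword dictionaries (see docs).
    """
    text = (
        resources.files("ptmenrich").joinpath("data/default_vocabulary.tsv")
        .read_text(encoding="utf-8")
    )
    return read_vocabulary_tsv(text)
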