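"""Curating the PTM database from parsed Swiss-Prot records.

A protein enters the database iff it is reviewed and carries at least one
PTM annotation: a keyword matching a KW-level vocabulary term, or a
feature with a configured key (MOD_RES, LIPID, CROSSLNK by default) whose
description normalizes to a non-empty term.  Proteins are partitioned by
organism; the per-organism protein sets are the enrichment background, so
P-values are computed against PTM-annotated proteins of the organism, not
the whole proteome.

FT descriptions that do not match the vocabulary are not dropped: they
become ad-hoc FT terms attached to a synthetic "Uncategorized" KW parent.
"""

from __future__ import annotations

import difflib
import hashlib
import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ptmenrich.errors import DatabaseError, ResolutionError, UnnamedFeatureError
from ptmenrich.ptm_vocab import (
    ROOT_ID,
    EvidenceQualifier,
    PTMTerm,
    PTMVocabulary,
    normalize_ft_description,
    slugify,
    write_vocabulary_tsv,
)
from ptmenrich.swissprot_io import ProteinRecord

__all__ = [
    "DEFAULT_FT_KEYS",
    "ALL_ORGANISMS",
    "ProteinSummary",
    "PTMDatabase",
    "VennCounts",
    "annotation_source_partition",
    "build_database",
    "evidence_dictionaries",
    "ft_key_composition",
    "resolve_proteins",
    "term_frequencies",
    "top_k",
]

DEFAULT_FT_KEYS = frozenset({"MOD_RES", "LIPID", "CROSSLNK"})

#: Sentinel organism selector meaning "union over all organisms".
ALL_ORGANISMS = "ALL"

UNCATEGORIZED_KW_ID = "uncategorized"
UNCATEGORIZED_KW_LABEL = "Uncategorized"


@dataclass(frozen=True)
class ProteinSummary:
    """The slice of a record the enrichment analyses need."""

    accession: str  # primary
    entry_name: str
    accessions: tuple[str, ...]
    organism_key: str
    source_tag: str  # "KW-only" | "FT-only" | "Both"
    terms: frozenset[str]
    ft_keys_present: frozenset[str]
    cross_refs: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class VennCounts:
    """Partition of database proteins by where their PTM annotation lives."""

    kw_only: int
    ft_only: int
    both: int

    @property
    def total(self) -> int:
        return self.kw_only + self.ft_only + self.both

    def percentages(self) -> tuple[int, int, int]:
        """(KW-only, FT-only, Both) as nearest-integer percentages of total."""
        if self.total == 0:
            return (0, 0, 0)
        return tuple(
            int(round(100.0 * part / self.total))
            for part in (self.kw_only, self.ft_only, self.both)
        )


class PTMDatabase:
    """Organism- and term-indexed sets of PTM-annotated proteins."""

    def __init__(
        self,
        proteins: Mapping[str, Mapping[str, ProteinSummary]],
        term_index: Mapping[tuple[str, str], frozenset[str]],
        term_labels: Mapping[str, str],
        term_levels: Mapping[str, str],
        evidence: Mapping[tuple[str, str], frozenset[EvidenceQualifier]],
        manifest: Mapping[str, object],
    ):
        self.proteins = {
            org: dict(sorted(part.items())) for org, part in sorted(proteins.items())
        }
        self.term_index = dict(term_index)
        self.term_labels = dict(term_labels)
        self.term_levels = dict(term_levels)
        self.evidence = dict(evidence)
        self.manifest = dict(manifest)
        self._check_invariants()
        self._aliases: dict[str, dict[str, str]] = {}
        for org, part in self.proteins.items():
            index: dict[str, str] = {}
            for acc, summary in part.items():
                for alias in (*summary.accessions, summary.entry_name):
                    index.setdefault(alias.casefold(), acc)
            self._aliases[org] = index

    def _check_invariants(self) -> None:
        seen: dict[str, str] = {}
        for org, part in self.proteins.items():
            for acc, summary in part.items():
                if acc in seen:
                    raise DatabaseError(
                        f"accession {acc} appears in organisms "
                        f"{seen[acc]!r} and {org!r}"
                    )
                seen[acc] = org
                if not summary.terms:
                    raise DatabaseError(f"protein {acc} carries no PTM term")
        for (org, term_id), accs in self.term_index.items():
            part = self.proteins.get(org, {})
            if not accs <= set(part):
                raise DatabaseError(
                    f"term index ({org!r}, {term_id!r}) escapes the organism partition"
                )

    # -- basic queries ----------------------------------------------------
    @property
    def organisms(self) -> list[str]:
        return list(self.proteins)

    def size(self, organism_key: str = ALL_ORGANISMS) -> int:
        if organism_key == ALL_ORGANISMS:
            return sum(len(p) for p in self.proteins.values())
        return len(self.partition(organism_key))

    def partition(self, organism_key: str) -> dict[str, ProteinSummary]:
        try:
            return self.proteins[organism_key]
        except KeyError:
            close = difflib.get_close_matches(organism_key, self.organisms, n=3)
            hint = f"; nearest matches: {', '.join(close)}" if close else ""
            raise DatabaseError(f"unknown organism {organism_key!r}{hint}") from None

    def term_members(self, organism_key: str, term_id: str) -> frozenset[str]:
        if organism_key == ALL_ORGANISMS:
            out: set[str] = set()
            for org in self.proteins:
                out |= self.term_index.get((org, term_id), frozenset())
            return frozenset(out)
        return self.term_index.get((organism_key, term_id), frozenset())

    def testable_terms(self, organism_key: str) -> list[str]:
        """Term ids with at least one carrier in the organism background."""
        if organism_key == ALL_ORGANISMS:
            ids = {t for (_, t), accs in self.term_index.items() if accs}
        else:
            self.partition(organism_key)
            ids = {
                t
                for (org, t), accs in self.term_index.items()
                if org == organism_key and accs
            }
        return sorted(ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PTMDatabase)
            and self.proteins == other.proteins
            and self.term_index == other.term_index
            and self.term_labels == other.term_labels
            and self.evidence == other.evidence
        )

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write a portable single-file archive (zip of text tables).

        Bit-stable: identical databases produce identical bytes.
        """
        members = {
            "manifest.json": json.dumps(self.manifest, indent=2, sort_keys=True) + "\n",
            "proteins.tsv": self._proteins_tsv(),
            "term_index.tsv": self._term_index_tsv(),
            "terms.tsv": self._terms_tsv(),
            "evidence.tsv": self._evidence_tsv(),
        }
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
            for name in sorted(members):
                info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, members[name])

    def _proteins_tsv(self) -> str:
        rows = ["accession\tentry_name\taccessions\torganism\tsource_tag\tterms\tft_keys\tcross_refs"]
        for org, part in self.proteins.items():
            for acc, s in part.items():
                rows.append(
                    "\t".join(
                        [
                            acc,
                            s.entry_name,
                            "|".join(s.accessions),
                            org,
                            s.source_tag,
                            "|".join(sorted(s.terms)),
                            "|".join(sorted(s.ft_keys_present)),
                            "|".join(f"{db}={ident}" for db, ident in s.cross_refs),
                        ]
                    )
                )
        return "\n".join(rows) + "\n"

    def _term_index_tsv(self) -> str:
        rows = ["organism\tterm_id\taccessions"]
        for (org, term_id), accs in sorted(self.term_index.items()):
            rows.append(f"{org}\t{term_id}\t{'|'.join(sorted(accs))}")
        return "\n".join(rows) + "\n"

    def _terms_tsv(self) -> str:
        rows = ["term_id\tlabel\tlevel"]
        for term_id in sorted(self.term_labels):
            rows.append(
                f"{term_id}\t{self.term_labels[term_id]}\t{self.term_levels[term_id]}"
            )
        return "\n".join(rows) + "\n"

    def _evidence_tsv(self) -> str:
        rows = ["accession\tterm_id\tqualifiers"]
        for (acc, term_id), quals in sorted(self.evidence.items()):
            names = "|".join(sorted(q.value for q in quals))
            rows.append(f"{acc}\t{term_id}\t{names}")
        return "\n".join(rows) + "\n"

    @classmethod
    def load(cls, path) -> "PTMDatabase":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json").decode("utf-8"))
            proteins_tsv = zf.read("proteins.tsv").decode("utf-8")
            index_tsv = zf.read("term_index.tsv").decode("utf-8")
            terms_tsv = zf.read("terms.tsv").decode("utf-8")
            evidence_tsv = zf.read("evidence.tsv").decode("utf-8")
        proteins: dict[str, dict[str, ProteinSummary]] = {}
        for row in proteins_tsv.splitlines()[1:]:
            acc, entry, accs, org, tag, terms, ftk, xrefs = row.split("\t")
            cross = tuple(
                tuple(pair.split("=", 1)) for pair in xrefs.split("|") if pair
            )
            proteins.setdefault(org, {})[acc] = ProteinSummary(
                accession=acc,
                entry_name=entry,
                accessions=tuple(accs.split("|")),
                organism_key=org,
                source_tag=tag,
                terms=frozenset(t for t in terms.split("|") if t),
                ft_keys_present=frozenset(k for k in ftk.split("|") if k),
                cross_refs=cross,
            )
        term_index = {}
        for row in index_tsv.splitlines()[1:]:
            org, term_id, accs = row.split("\t")
            term_index[(org, term_id)] = frozenset(a for a in accs.split("|") if a)
        term_labels, term_levels = {}, {}
        for row in terms_tsv.splitlines()[1:]:
            term_id, label, level = row.split("\t")
            term_labels[term_id] = label
            term_levels[term_id] = level
        evidence = {}
        for row in evidence_tsv.splitlines()[1:]:
            acc, term_id, quals = row.split("\t")
            evidence[(acc, term_id)] = frozenset(
                EvidenceQualifier(q) for q in quals.split("|") if q
            )
        return cls(proteins, term_index, term_labels, term_levels, evidence, manifest)


# ---------------------------------------------------------------------------
# construction


def build_database(
    records: Iterable[ProteinRecord],
    vocab: PTMVocabulary,
    ft_keys: frozenset[str] | set[str] = DEFAULT_FT_KEYS,
    dialect: str | None = None,
) -> PTMDatabase:
    """Filter records to PTM-annotated, reviewed proteins and index them.

    Inclusion rule: at least one keyword matches a KW-level vocabulary term
    (case-insensitively), or at least one feature with key in ``ft_keys``
    yields a non-empty normalized description.  Unreviewed entries are
    excluded.  Deterministic and order-independent: permuting the input
    records yields an equal database.
    """
    if vocab is None:
        raise DatabaseError("a PTM vocabulary is required to build the database")
    ft_keys = frozenset(ft_keys)
    proteins: dict[str, dict[str, ProteinSummary]] = {}
    term_index: dict[tuple[str, str], set[str]] = {}
    term_labels: dict[str, str] = {t.term_id: t.label for t in vocab.terms.values()}
    term_levels: dict[str, str] = {t.term_id: t.level for t in vocab.terms.values()}
    evidence: dict[tuple[str, str], set[EvidenceQualifier]] = {}
    n_records = 0
    for record in records:
        n_records += 1
        if not record.is_reviewed:
            continue
        kw_ids = set()
        for kw in record.keywords:
            term = vocab.lookup("KW", kw)
            if term is not None:
                kw_ids.add(term.term_id)
        ft_ids = set()
        ft_keys_present = set()
        protein_evidence: dict[str, set[EvidenceQualifier]] = {}
        for feat in record.features:
            if feat.key not in ft_keys:
                continue
            try:
                label, qualifier = normalize_ft_description(feat.description)
            except UnnamedFeatureError:
                continue
            term = vocab.lookup("FT", label)
            if term is not None:
                term_id = term.term_id
            else:
                # ad-hoc term under the synthetic "Uncategorized" KW parent
                term_id = "x-" + slugify(label)
                if term_id not in term_labels:
                    term_labels[term_id] = label
                    term_levels[term_id] = "FT"
                if UNCATEGORIZED_KW_ID not in term_labels:
                    term_labels[UNCATEGORIZED_KW_ID] = UNCATEGORIZED_KW_LABEL
                    term_levels[UNCATEGORIZED_KW_ID] = "KW"
            ft_ids.add(term_id)
            ft_keys_present.add(feat.key)
            protein_evidence.setdefault(term_id, set()).add(qualifier)
        if not kw_ids and not ft_ids:
            continue
        if kw_ids and ft_ids:
            tag = "Both"
        elif kw_ids:
            tag = "KW-only"
        else:
            tag = "FT-only"
        org = record.organism_key
        primary = record.accessions[0]
        part = proteins.setdefault(org, {})
        if primary in part:
            raise DatabaseError(
                f"duplicate primary accession {primary} in organism {org!r}"
            )
        part[primary] = ProteinSummary(
            accession=primary,
            entry_name=record.entry_name,
            accessions=tuple(record.accessions),
            organism_key=org,
            source_tag=tag,
            terms=frozenset(kw_ids | ft_ids),
            ft_keys_present=frozenset(ft_keys_present),
            cross_refs=tuple(record.cross_refs),
        )
        for term_id in kw_ids | ft_ids:
            term_index.setdefault((org, term_id), set()).add(primary)
        for term_id, quals in protein_evidence.items():
            evidence.setdefault((primary, term_id), set()).update(quals)
    vocab_hash = hashlib.sha256(
        write_vocabulary_tsv(vocab).encode("utf-8")
    ).hexdigest()
    manifest = {
        "vocabulary_sha256": vocab_hash,
        "ft_keys": sorted(ft_keys),
        "dialect": dialect,
        "n_input_records": n_records,
        "n_proteins": sum(len(p) for p in proteins.values()),
        "n_organisms": len(proteins),
    }
    return PTMDatabase(
        proteins,
        {k: frozenset(v) for k, v in term_index.items()},
        term_labels,
        term_levels,
        {k: frozenset(v) for k, v in evidence.items()},
        manifest,
    )


# ---------------------------------------------------------------------------
# curation statistics


def annotation_source_partition(db: PTMDatabase) -> VennCounts:
    """Venn partition of proteins by annotation source (KW, FT or both)."""
    kw_only = ft_only = both = 0
    for part in db.proteins.values():
        for summary in part.values():
            if summary.source_tag == "KW-only":
                kw_only += 1
            elif summary.source_tag == "FT-only":
                ft_only += 1
            else:
                both += 1
    return VennCounts(kw_only, ft_only, both)


def ft_percentages(counts: Mapping[str, int], ndigits: int = 2) -> dict[str, float]:
    """Per-key percentages of the summed per-key protein counts.

    A protein carrying two keys contributes to both counts and twice to
    the denominator (a per-annotation-class composition, not a protein
    partition).  All-zero counts report 0 throughout.
    """
    denom = sum(counts.values())
    if denom == 0:
        return {key: 0.0 for key in counts}
    return {key: round(100.0 * c / denom, ndigits) for key, c in counts.items()}


def ft_key_composition(
    db: PTMDatabase, ndigits: int = 2
) -> dict[str, tuple[int, float]]:
    """Count and percentage of proteins having each configured FT key.

    Counts proteins having >= 1 feature of the key, among proteins with
    any FT-derived annotation; a protein counts once per key.
    """
    ft_keys = sorted(db.manifest.get("ft_keys", sorted(DEFAULT_FT_KEYS)))
    counts = {key: 0 for key in ft_keys}
    for part in db.proteins.values():
        for summary in part.values():
            for key in summary.ft_keys_present:
                if key in counts:
                    counts[key] += 1
    pct = ft_percentages(counts, ndigits=ndigits)
    return {key: (counts[key], pct[key]) for key in ft_keys}


def term_frequencies(
    db: PTMDatabase, organism_key: str = ALL_ORGANISMS
) -> dict[str, int]:
    """Carrier counts per term, descending by count then ascending by label."""
    if organism_key == ALL_ORGANISMS:
        term_ids = {t for (_, t) in db.term_index}
    else:
        db.partition(organism_key)
        term_ids = {t for (org, t) in db.term_index if org == organism_key}
    items = [
        (term_id, len(db.term_members(organism_key, term_id))) for term_id in term_ids
    ]
    items = [(t, c) for t, c in items if c > 0]
    items.sort(key=lambda tc: (-tc[1], db.term_labels.get(tc[0], tc[0])))
    return dict(items)


def evidence_dictionaries(
    db: PTMDatabase,
) -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
    """(experimental, putative, total) carrier counts per FT term.

    A protein counts once per (term, qualifier); a protein with both an
    experimental and a putative occurrence of the same term contributes to
    both dictionaries but once to each.
    """
    experimental: dict[str, int] = {}
    putative: dict[str, int] = {}
    total: dict[str, int] = {}
    for (_, term_id), quals in db.evidence.items():
        if EvidenceQualifier.EXPERIMENTAL in quals:
            experimental[term_id] = experimental.get(term_id, 0) + 1
        if EvidenceQualifier.PUTATIVE in quals:
            putative[term_id] = putative.get(term_id, 0) + 1
        total[term_id] = total.get(term_id, 0) + 1
    return experimental, putative, total


def top_k(counter: Mapping[str, int], k: int, labels: Mapping[str, str] | None = None):
    """Top-k (key, count) pairs, descending by count then ascending by label."""
    name = (lambda t: labels.get(t, t)) if labels else (lambda t: t)
    return sorted(counter.items(), key=lambda tc: (-tc[1], name(tc[0])))[:k]


def resolve_proteins(
    db: PTMDatabase, organism_key: str, raw_ids: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Map user identifiers to primary accessions within one organism.

    Matching is case-insensitive against primary accessions, secondary
    accessions and entry names.  Duplicates collapse to the first
    occurrence; output order is stable.  Zero matches raise
    :class:`ResolutionError` suggesting an organism check.
    """
    cleaned = [tok.strip() for tok in raw_ids]
    cleaned = [tok for tok in cleaned if tok and not tok.startswith("#")]
    if not cleaned:
        raise ResolutionError("protein list is empty after cleaning")
    db.partition(organism_key)
    aliases = db._aliases[organism_key]
    matched: list[str] = []
    seen: set[str] = set()
    unmatched: list[str] = []
    for tok in cleaned:
        acc = aliases.get(tok.casefold())
        if acc is None:
            unmatched.append(tok)
        elif acc not in seen:
            seen.add(acc)
            matched.append(acc)
    if not matched:
        raise ResolutionError(
            f"none of {len(cleaned)} identifiers matched organism "
            f"{organism_key!r}; check the organism selection"
        )
    return matched, unmatched
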