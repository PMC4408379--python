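"""Stream parsing and writing of UniProtKB/Swiss-Prot flat-file (DAT) text.

Two feature-table dialects are supported: the *classic* layout (positions in
fixed columns on the FT line, description following on the same line and on
continuation lines) and the *modern* layout introduced by UniProt in 2019
(``begin..end`` position spans plus ``/note="..."`` qualifiers).  A stream
uses exactly one dialect; ``detect_dialect`` infers it from the first FT
lines seen and mixing dialects is an error.

Only the line codes relevant to PTM curation are structured (ID, AC, OS,
KW, FT, DR, CC); everything else, including SQ/sequence blocks, is
tolerated and skipped.  CC comments are retained verbatim and are never
mined for PTM terms.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from ptmenrich.errors import ParseError

__all__ = [
    "DatDialect",
    "FeatureAnnotation",
    "ProteinRecord",
    "detect_dialect",
    "parse_entries",
    "parse_file",
    "write_entry",
    "write_entries",
]

#: FT keys structured enough to carry a modification description.
_MAX_FT_KEY_LEN = 8

_MODERN_POS_RE = re.compile(r"^[<>?]?\d+\.\.[<>?]?\d+$|^\?\.\.|\.\.\?$")
_MODERN_SINGLE_POS_RE = re.compile(r"^[<>?]?\d+$|^\?$")


class DatDialect(enum.Enum):
    """Which flat-file feature-table layout a stream uses."""

    CLASSIC = "classic"
    MODERN = "modern"


@dataclass
class FeatureAnnotation:
    """One FT line group: a keyed, positioned annotation with description.

    ``begin``/``end`` are 1-based inclusive residue positions; ``None``
    marks an unknown or fuzzy position (``?``, ``<1``, ``>100``).  Such
    features still participate in term extraction: the curation counts
    terms, not residue coordinates.
    """

    key: str
    begin: int | None
    end: int | None
    description: str = ""

    def validate(self) -> None:
        if not self.key or not self.key.isupper() or len(self.key) > _MAX_FT_KEY_LEN:
            raise ValueError(
                f"FT key must be an uppercase token of <= {_MAX_FT_KEY_LEN} "
                f"characters, got {self.key!r}"
            )
        if self.begin is not None and self.end is not None and self.begin > self.end:
            raise ValueError(
                f"feature begin {self.begin} exceeds end {self.end} ({self.key})"
            )


@dataclass
class ProteinRecord:
    """One parsed Swiss-Prot entry (annotation fields only, no sequence)."""

    entry_name: str
    review_status: str = "Reviewed"
    accessions: list[str] = field(default_factory=list)
    organism_names: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    features: list[FeatureAnnotation] = field(default_factory=list)
    cross_refs: list[tuple[str, str]] = field(default_factory=list)
    comment_topics: list[tuple[str, str]] = field(default_factory=list)

    @property
    def organism_key(self) -> str:
        """Canonical organism string used for database keying.

        The first OS name up to the first ``(`` (which introduces common
        names), whitespace-normalized.
        """
        if not self.organism_names:
            return ""
        name = self.organism_names[0].split("(", 1)[0]
        return " ".join(name.split())

    @property
    def is_reviewed(self) -> bool:
        return self.review_status == "Reviewed"

    def validate(self) -> None:
        if not self.entry_name or any(c.isspace() for c in self.entry_name):
            raise ValueError(f"invalid entry name {self.entry_name!r}")
        if self.review_status not in ("Reviewed", "Unreviewed"):
            raise ValueError(f"invalid review status {self.review_status!r}")
        if not self.accessions:
            raise ValueError(f"entry {self.entry_name} has no accessions")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError(f"entry {self.entry_name} has duplicate accessions")
        for acc in self.accessions:
            if not acc or ";" in acc or any(c.isspace() for c in acc):
                raise ValueError(f"invalid accession token {acc!r}")
        for kw in self.keywords:
            if kw.endswith(".") or kw.endswith(";"):
                raise ValueError(f"keyword {kw!r} carries trailing punctuation")
        for feat in self.features:
            feat.validate()


# ---------------------------------------------------------------------------
# dialect detection


def _ft_line_vote(line: str) -> DatDialect | None:
    """Classify a single FT feature-start line, None if undecidable."""
    if len(line) <= 5 or line[5] == " ":
        # continuation line; only /note= is dialect-revealing
        if "/note=" in line or "/evidence=" in line:
            return DatDialect.MODERN
        return None
    body = line[5:].split()
    if len(body) < 2:
        return None
    if _MODERN_POS_RE.match(body[1]) or ".." in body[1]:
        return DatDialect.MODERN
    if len(body) >= 3 and _MODERN_SINGLE_POS_RE.match(body[1]) and _MODERN_SINGLE_POS_RE.match(body[2]):
        return DatDialect.CLASSIC
    if len(body) == 2 and _MODERN_SINGLE_POS_RE.match(body[1]):
        # a lone position token is the modern single-residue form
        return DatDialect.MODERN
    return None


def detect_dialect(lines: Iterable[str]) -> DatDialect:
    """Infer the FT dialect from a sample of lines.

    Defaults to :attr:`DatDialect.CLASSIC` when no FT line is present.
    Raises :class:`ParseError` if both dialects appear in the sample.
    """
    votes = set()
    for line in lines:
        if line.startswith("FT"):
            vote = _ft_line_vote(line.rstrip("\n"))
            if vote is not None:
                votes.add(vote)
    if len(votes) == 2:
        raise ParseError("mixed classic and modern FT dialects in one stream")
    if votes:
        return votes.pop()
    return DatDialect.CLASSIC


# ---------------------------------------------------------------------------
# parsing


def _decode(line) -> str:
    if isinstance(line, bytes):
        try:
            return line.decode("utf-8")
        except UnicodeDecodeError:
            return line.decode("latin-1")
    return line


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, str):
        yield from source.splitlines()
    else:
        for line in source:
            yield _decode(line).rstrip("\n").rstrip("\r")


def _parse_positions(tok: str) -> int | None:
    return int(tok) if tok.isdigit() else None


class _EntryParser:
    """Accumulates the lines of one entry and builds a ProteinRecord."""

    def __init__(self, dialect: DatDialect):
        self.dialect = dialect
        self.entry_name: str | None = None
        self.review_status = "Reviewed"
        self.accessions: list[str] = []
        self.os_names: list[str] = []
        self._os_pending: list[str] = []
        self._kw_parts: list[str] = []
        self.features: list[FeatureAnnotation] = []
        self.cross_refs: list[tuple[str, str]] = []
        self.comments: list[tuple[str, str]] = []
        self._in_sequence = False
        self.saw_any = False

    def feed(self, line: str, lineno: int) -> None:
        self.saw_any = True
        if line.startswith("  "):  # sequence data block
            return
        code = line[:2]
        content = line[5:] if len(line) > 5 else ""
        if code == "ID":
            self._parse_id(content, lineno)
        elif code == "AC":
            for tok in content.split(";"):
                tok = tok.strip()
                if tok:
                    self.accessions.append(tok)
        elif code == "OS":
            self._parse_os(content)
        elif code == "KW":
            self._kw_parts.append(content.strip())
        elif code == "FT":
            self._parse_ft(line, lineno)
        elif code == "DR":
            self._parse_dr(content)
        elif code == "CC":
            self._parse_cc(content)
        # DE, GN, OX, RN.., PE, SQ, etc.: tolerated, skipped

    def _parse_id(self, content: str, lineno: int) -> None:
        toks = content.split()
        if not toks:
            raise ParseError("empty ID line", line_number=lineno)
        self.entry_name = toks[0]
        if len(toks) > 1:
            status = toks[1].rstrip(";")
            if status.lower().startswith("unreviewed"):
                self.review_status = "Unreviewed"
            else:
                self.review_status = "Reviewed"

    def _parse_os(self, content: str) -> None:
        content = content.strip()
        if not content:
            return
        self._os_pending.append(content)
        if content.endswith("."):
            name = " ".join(self._os_pending)[:-1].strip()
            if name:
                self.os_names.append(name)
            self._os_pending = []

    def _parse_ft(self, line: str, lineno: int) -> None:
        vote = _ft_line_vote(line)
        if vote is not None and vote is not self.dialect:
            raise ParseError(
                f"FT line in {vote.value} dialect inside a {self.dialect.value} stream",
                line_number=lineno,
                entry_name=self.entry_name,
            )
        is_start = len(line) > 5 and line[5] != " "
        if self.dialect is DatDialect.CLASSIC:
            self._parse_ft_classic(line, is_start, lineno)
        else:
            self._parse_ft_modern(line, is_start, lineno)

    def _parse_ft_classic(self, line: str, is_start: bool, lineno: int) -> None:
        if is_start:
            m = re.match(r"^FT   (\S+)\s+(\S+)\s+(\S+)(?:\s+(.*))?$", line)
            if not m:
                raise ParseError(
                    f"unparseable classic FT line: {line!r}",
                    line_number=lineno,
                    entry_name=self.entry_name,
                )
            key, b_tok, e_tok, desc = m.group(1), m.group(2), m.group(3), m.group(4) or ""
            self.features.append(
                FeatureAnnotation(
                    key=key,
                    begin=_parse_positions(b_tok),
                    end=_parse_positions(e_tok),
                    description=desc.strip(),
                )
            )
        else:
            if not self.features:
                raise ParseError(
                    "FT continuation line without a feature",
                    line_number=lineno,
                    entry_name=self.entry_name,
                )
            extra = line[5:].strip()
            feat = self.features[-1]
            feat.description = (feat.description + " " + extra).strip()

    def _parse_ft_modern(self, line: str, is_start: bool, lineno: int) -> None:
        if is_start:
            m = re.match(r"^FT   (\S+)\s+(\S+)\s*$", line)
            if not m:
                raise ParseError(
                    f"unparseable modern FT line: {line!r}",
                    line_number=lineno,
                    entry_name=self.entry_name,
                )
            key, span = m.group(1), m.group(2)
            if ".." in span:
                b_tok, e_tok = span.split("..", 1)
            else:
                b_tok = e_tok = span
            self.features.append(
                FeatureAnnotation(
                    key=key,
                    begin=_parse_positions(b_tok),
                    end=_parse_positions(e_tok),
                    description="",
                )
            )
        else:
            if not self.features:
                raise ParseError(
                    "FT continuation line without a feature",
                    line_number=lineno,
                    entry_name=self.entry_name,
                )
            content = line[5:].strip()
            m = re.match(r'^/note="(.*)"$', content)
            if m:
                self.features[-1].description = m.group(1)
            # other qualifiers (/evidence=, /id=) are skipped

    def _parse_dr(self, content: str) -> None:
        parts = [p.strip() for p in content.split(";")]
        if len(parts) >= 2 and parts[0]:
            ident = parts[1].rstrip(".").strip()
            self.cross_refs.append((parts[0], ident))

    def _parse_cc(self, content: str) -> None:
        stripped = content.strip()
        if stripped.startswith("-!-"):
            body = stripped[3:].strip()
            topic, _, text = body.partition(":")
            self.comments.append((topic.strip(), text.strip()))
        elif self.comments and stripped:
            topic, text = self.comments[-1]
            self.comments[-1] = (topic, (text + " " + stripped).strip())
        # preamble/license CC lines before any -!- are dropped

    def finish(self, lineno: int) -> ProteinRecord:
        if self.entry_name is None:
            raise ParseError("entry terminated without an ID line", line_number=lineno)
        if self._os_pending:  # OS text that never saw its final period
            name = " ".join(self._os_pending).strip()
            if name:
                self.os_names.append(name)
        keywords = []
        if self._kw_parts:
            joined = " ".join(self._kw_parts)
            for kw in joined.split(";"):
                kw = kw.strip().rstrip(".").strip()
                if kw:
                    keywords.append(kw)
        record = ProteinRecord(
            entry_name=self.entry_name,
            review_status=self.review_status,
            accessions=self.accessions,
            organism_names=self.os_names,
            keywords=keywords,
            features=self.features,
            cross_refs=self.cross_refs,
            comment_topics=self.comments,
        )
        if not record.accessions:
            raise ParseError(
                "entry has no AC line", line_number=lineno, entry_name=self.entry_name
            )
        return record


def parse_entries(
    source, dialect: DatDialect | None = None
) -> Iterator[ProteinRecord]:
    """Yield one :class:`ProteinRecord` per ``//``-delimited flat-file entry.

    ``source`` may be a string, a file object, or any iterable of text or
    byte lines (bytes are decoded as UTF-8 with a Latin-1 fallback).  The
    parser is streaming: working state is bounded by the largest single
    entry.  The FT ``dialect`` is auto-detected from the first entry that
    carries FT lines unless given explicitly.
    """
    entry_lines: list[tuple[int, str]] = []
    last_entry_name: str | None = None
    lineno = 0
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if line.strip() == "//":
            if not any(ln.startswith("ID") for _, ln in entry_lines):
                raise ParseError(
                    "entry terminator without a preceding ID line",
                    line_number=lineno,
                )
            entry_dialect = dialect
            if entry_dialect is None:
                detected = detect_dialect(ln for _, ln in entry_lines)
                if any(ln.startswith("FT") for _, ln in entry_lines):
                    dialect = detected  # first FT-bearing entry pins the stream
                entry_dialect = detected
            parser = _EntryParser(entry_dialect)
            for ln_no, ln in entry_lines:
                parser.feed(ln, ln_no)
            record = parser.finish(lineno)
            last_entry_name = record.entry_name
            entry_lines = []
            yield record
        elif line.strip():
            entry_lines.append((lineno, line))
    if entry_lines:
        name = None
        for _, ln in entry_lines:
            if ln.startswith("ID"):
                toks = ln[5:].split()
                name = toks[0] if toks else None
                break
        raise ParseError(
            "truncated final entry (EOF before '//'); last complete entry was "
            f"{last_entry_name!r}",
            line_number=lineno,
            entry_name=name,
        )


def parse_file(path, dialect: DatDialect | None = None) -> Iterator[ProteinRecord]:
    """Parse a DAT file from disk, decoding per line."""
    with open(path, "rb") as handle:
        yield from parse_entries(handle, dialect=dialect)


# ---------------------------------------------------------------------------
# writing


def _wrap_tokens(prefix: str, tokens: Sequence[str], sep: str, width: int = 75) -> list[str]:
    lines: list[str] = []
    current = ""
    for i, tok in enumerate(tokens):
        piece = tok + (sep if i < len(tokens) - 1 else "")
        if current and len(prefix) + len(current) + 1 + len(piece) > width:
            lines.append(prefix + current)
            current = piece
        else:
            current = (current + " " + piece).strip()
    if current:
        lines.append(prefix + current)
    return lines


def _pos_token(pos: int | None) -> str:
    return "?" if pos is None else str(pos)


def write_entry(record: ProteinRecord, dialect: DatDialect = DatDialect.CLASSIC) -> str:
    """Render a record as flat-file text ending in ``//``.

    The output is parseable back to an identical record:
    ``next(parse_entries(write_entry(r)))`` equals ``r`` for every valid
    record, in both dialects.
    """
    record.validate()
    for feat in record.features:
        if "\n" in feat.description or "\r" in feat.description:
            raise ValueError(
                f"feature description contains a line terminator: {feat.description!r}"
            )
    lines: list[str] = []
    status = record.review_status
    lines.append(f"ID   {record.entry_name:<24}{status};")
    lines.extend(_wrap_tokens("AC   ", record.accessions, ";"))
    if record.accessions:
        lines[-1] += ";" if not lines[-1].endswith(";") else ""
    for name in record.organism_names:
        lines.append(f"OS   {name}.")
    for db, ident in record.cross_refs:
        lines.append(f"DR   {db}; {ident}; -.")
    for topic, text in record.comment_topics:
        lines.append(f"CC   -!- {topic}: {text}")
    if record.keywords:
        kw_lines = _wrap_tokens("KW   ", record.keywords, ";")
        kw_lines[-1] += "."
        lines.extend(kw_lines)
    for feat in record.features:
        if dialect is DatDialect.CLASSIC:
            head = f"FT   {feat.key:<8} {_pos_token(feat.begin):>6} {_pos_token(feat.end):>6}"
            if feat.description:
                head += f"       {feat.description}"
            lines.append(head)
        else:
            lines.append(
                f"FT   {feat.key:<15} {_pos_token(feat.begin)}..{_pos_token(feat.end)}"
            )
            if feat.description:
                lines.append(f'FT                   /note="{feat.description}"')
    lines.append("//")
    return "\n".join(lines) + "\n"


def write_entries(
    records: Iterable[ProteinRecord], dialect: DatDialect = DatDialect.CLASSIC
) -> str:
    """Concatenate :func:`write_entry` over many records."""
    return "".join(write_entry(r, dialect) for r in records)
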