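"""User-facing analyses: enrichment, two-list matching, frequency, export.

``enrich`` tests every term carried by at least one protein of the
organism background (the *testable* terms, T of them) with the exact
hypergeometric tail, applies the chosen multiplicity correction across
those T tests, and reports the terms hit by the query list.  ``match``
integrates two enrichment runs over the same database and organism into
one table of terms significant in either list.  ``list_frequency``
reports per-term frequencies and percentages without hypothesis testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ptmenrich.enrich_stats import (
    CorrectionMethod,
    HypergeomParams,
    bh_adjust,
    bonferroni_adjust,
    hypergeom_pvalue,
)
from ptmenrich.errors import DatabaseError, ParameterError
from ptmenrich.ptm_db import PTMDatabase, ProteinSummary, resolve_proteins

__all__ = [
    "DEFAULT_CROSSREF_MARKERS",
    "EnrichmentRow",
    "EnrichmentResult",
    "FrequencyRow",
    "FrequencyResult",
    "MatchedRow",
    "MatchedResult",
    "TermStats",
    "crossref_markers",
    "enrich",
    "export_barchart",
    "export_table",
    "list_frequency",
    "match",
    "read_table",
]

#: Cross-reference database name prefix -> marker digit rendered after the
#: accession, e.g. "P12345(2)" for a PhosphoSite-linked protein.
DEFAULT_CROSSREF_MARKERS: dict[str, int] = {
    "phossite": 1,
    "phosphosite": 2,
    "unicarbkb": 3,
}

ENRICHMENT_HEADER = [
    "ID",
    "PTM vocabulary",
    "Frequency in UniProt",
    "Percent in UniProt",
    "Frequency in list",
    "Percent in list",
    "UniProtKB accession numbers",
    "P-value",
    "Corrected P-value",
]


def crossref_markers(
    record_or_summary,
    marker_map: Mapping[str, int] | None = None,
) -> set[int]:
    """Marker digits for a protein's DR cross-references.

    Database names are matched case-insensitively by prefix against
    ``marker_map`` (default: PhosSite -> 1, PhosphoSite -> 2,
    UniCarbKB -> 3), so "PhosphoSitePlus" also maps to 2.
    """
    marker_map = DEFAULT_CROSSREF_MARKERS if marker_map is None else marker_map
    markers: set[int] = set()
    for db_name, _ in record_or_summary.cross_refs:
        lowered = db_name.casefold()
        for prefix, marker in marker_map.items():
            if lowered.startswith(prefix.casefold()):
                markers.add(marker)
    return markers


def _render_accession(summary: ProteinSummary, marker_map) -> str:
    markers = sorted(crossref_markers(summary, marker_map))
    return summary.accession + "".join(f"({m})" for m in markers)


@dataclass(frozen=True)
class TermStats:
    """Per-term test statistics kept for every testable term (even m=0)."""

    term_id: str
    K: int
    m: int
    p_value: float
    adjusted_p: float | None


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_label: str
    freq_db: int  # K
    pct_db: float  # 100*K/N
    freq_list: int  # m
    pct_list: float  # 100*m/n
    member_accessions: tuple[str, ...]  # rendered with crossref markers
    p_value: float
    adjusted_p: float | None
    significant: bool

    @property
    def decision_p(self) -> float:
        return self.p_value if self.adjusted_p is None else self.adjusted_p


@dataclass(frozen=True)
class AnalysisContext:
    organism_key: str
    population_size: int  # N
    list_size: int  # n
    unmatched_ids: tuple[str, ...]
    alpha: float
    correction: CorrectionMethod
    adjusted_alpha: float | None
    manifest: Mapping[str, object]


@dataclass(frozen=True)
class EnrichmentResult:
    rows: tuple[EnrichmentRow, ...]
    context: AnalysisContext
    term_stats: Mapping[str, TermStats] = field(default_factory=dict, repr=False)
    term_labels: Mapping[str, str] = field(default_factory=dict, repr=False)

    def significant_terms(self) -> list[str]:
        return [row.term_id for row in self.rows if row.significant]


@dataclass(frozen=True)
class MatchedRow:
    term_id: str
    term_label: str
    pct_list1: float
    pct_list2: float
    p1: float
    p2: float
    adj_p1: float | None
    adj_p2: float | None
    significant_in: str  # "list1" | "list2" | "both"


@dataclass(frozen=True)
class MatchedResult:
    rows: tuple[MatchedRow, ...]
    context1: AnalysisContext
    context2: AnalysisContext


@dataclass(frozen=True)
class FrequencyRow:
    term_id: str
    term_label: str
    freq_db: int
    pct_db: float
    freq_list: int
    pct_list: float


@dataclass(frozen=True)
class FrequencyResult:
    rows: tuple[FrequencyRow, ...]
    context: AnalysisContext


# ---------------------------------------------------------------------------
# enrichment


def _decision(p: float, adj: float | None, alpha: float) -> bool:
    return (p if adj is None else adj) <= alpha


def enrich(
    db: PTMDatabase,
    organism_key: str,
    raw_ids: Sequence[str],
    alpha: float = 0.05,
    correction: CorrectionMethod = CorrectionMethod.BONFERRONI,
    marker_map: Mapping[str, int] | None = None,
) -> EnrichmentResult:
    """Hypergeometric over-representation test of a protein list.

    The background is the organism's PTM-annotated proteins (size N).
    Rows cover the terms hit by the list (m >= 1), ordered by descending
    -log P (ties by label); statistics for every testable term, including
    misses, remain available in ``term_stats`` for matching.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    matched, unmatched = resolve_proteins(db, organism_key, raw_ids)
    matched_set = set(matched)
    N = db.size(organism_key)
    n = len(matched)
    term_ids = db.testable_terms(organism_key)
    Ks, ms, ps = [], [], []
    for term_id in term_ids:
        members = db.term_members(organism_key, term_id)
        K = len(members)
        m = len(members & matched_set)
        Ks.append(K)
        ms.append(m)
        ps.append(hypergeom_pvalue(HypergeomParams(N, K, n, m)))
    adjusted_alpha: float | None = None
    adjusted: list[float | None]
    if not term_ids:
        adjusted = []
    elif correction is CorrectionMethod.BONFERRONI:
        adj, adjusted_alpha = bonferroni_adjust(ps, alpha)
        adjusted = list(adj)
    elif correction is CorrectionMethod.BENJAMINI_HOCHBERG:
        adjusted = list(bh_adjust(ps))
    else:
        adjusted = [None] * len(ps)
    stats = {
        term_id: TermStats(term_id, K, m, p, adj)
        for term_id, K, m, p, adj in zip(term_ids, Ks, ms, ps, adjusted)
    }
    part = db.partition(organism_key)
    rows = []
    for term_id in term_ids:
        st = stats[term_id]
        if st.m == 0:
            continue
        members = sorted(db.term_members(organism_key, term_id) & matched_set)
        rendered = tuple(_render_accession(part[acc], marker_map) for acc in members)
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                term_label=db.term_labels.get(term_id, term_id),
                freq_db=st.K,
                pct_db=100.0 * st.K / N,
                freq_list=st.m,
                pct_list=100.0 * st.m / n,
                member_accessions=rendered,
                p_value=st.p_value,
                adjusted_p=st.adjusted_p,
                significant=_decision(st.p_value, st.adjusted_p, alpha),
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.term_label))
    context = AnalysisContext(
        organism_key=organism_key,
        population_size=N,
        list_size=n,
        unmatched_ids=tuple(unmatched),
        alpha=alpha,
        correction=correction,
        adjusted_alpha=adjusted_alpha,
        manifest=dict(db.manifest),
    )
    return EnrichmentResult(
        rows=tuple(rows),
        context=context,
        term_stats=stats,
        term_labels=dict(db.term_labels),
    )


# ---------------------------------------------------------------------------
# two-list integration / matching


def _comparable(c1: AnalysisContext, c2: AnalysisContext) -> bool:
    keys = ("vocabulary_sha256", "ft_keys")
    return c1.organism_key == c2.organism_key and all(
        c1.manifest.get(k) == c2.manifest.get(k) for k in keys
    )


def match(result1: EnrichmentResult, result2: EnrichmentResult) -> MatchedResult:
    """Integrate two enrichment runs: union of their significant terms.

    Both results must come from the same database build and organism
    (incomparable backgrounds raise :class:`DatabaseError`).  Each row
    carries both lists' percentages and (adjusted) P-values; a term
    untested or missed in one list shows the m=0 values for that list.
    """
    c1, c2 = result1.context, result2.context
    if not _comparable(c1, c2):
        raise DatabaseError(
            "enrichment results are incomparable: different organism or "
            "database build"
        )
    sig1 = set(result1.significant_terms())
    sig2 = set(result2.significant_terms())
    labels = {**result2.term_labels, **result1.term_labels}
    rows = []
    for term_id in sorted(sig1 | sig2, key=lambda t: labels.get(t, t)):
        st1 = result1.term_stats.get(term_id)
        st2 = result2.term_stats.get(term_id)
        pct1 = 100.0 * st1.m / c1.list_size if st1 else 0.0
        pct2 = 100.0 * st2.m / c2.list_size if st2 else 0.0
        where = "both" if term_id in sig1 and term_id in sig2 else (
            "list1" if term_id in sig1 else "list2"
        )
        rows.append(
            MatchedRow(
                term_id=term_id,
                term_label=labels.get(term_id, term_id),
                pct_list1=pct1,
                pct_list2=pct2,
                p1=st1.p_value if st1 else 1.0,
                p2=st2.p_value if st2 else 1.0,
                adj_p1=st1.adjusted_p if st1 else None,
                adj_p2=st2.adjusted_p if st2 else None,
                significant_in=where,
            )
        )
    return MatchedResult(rows=tuple(rows), context1=c1, context2=c2)


# ---------------------------------------------------------------------------
# frequency analysis


def list_frequency(
    db: PTMDatabase, organism_key: str, raw_ids: Sequence[str]
) -> FrequencyResult:
    """Per-term frequency and percentage in the organism and in the list.

    Every term carried by the organism background (K > 0) is listed, with
    the list count m possibly zero.  No hypothesis testing.
    """
    matched, unmatched = resolve_proteins(db, organism_key, raw_ids)
    matched_set = set(matched)
    N = db.size(organism_key)
    n = len(matched)
    rows = []
    for term_id in db.testable_terms(organism_key):
        members = db.term_members(organism_key, term_id)
        K = len(members)
        m = len(members & matched_set)
        rows.append(
            FrequencyRow(
                term_id=term_id,
                term_label=db.term_labels.get(term_id, term_id),
                freq_db=K,
                pct_db=100.0 * K / N,
                freq_list=m,
                pct_list=100.0 * m / n,
            )
        )
    rows.sort(key=lambda r: (-r.freq_db, r.term_label))
    context = AnalysisContext(
        organism_key=organism_key,
        population_size=N,
        list_size=n,
        unmatched_ids=tuple(unmatched),
        alpha=math.nan,
        correction=CorrectionMethod.NONE,
        adjusted_alpha=None,
        manifest=dict(db.manifest),
    )
    return FrequencyResult(rows=tuple(rows), context=context)


# ---------------------------------------------------------------------------
# export

_PCT = "{:.2f}".format


def _sci(p: float | None) -> str:
    return "NA" if p is None else "{:.3e}".format(p)


def _footer(context: AnalysisContext) -> str:
    parts = [
        f"N={context.population_size}",
        f"n={context.list_size}",
        f"alpha={context.alpha:g}",
        f"correction={context.correction.value}",
    ]
    if context.adjusted_alpha is not None:
        parts.append(f"adjusted_alpha={_sci(context.adjusted_alpha)}")
    if context.unmatched_ids:
        parts.append(f"unmatched={len(context.unmatched_ids)}")
    return "# " + "\t".join(parts)


def export_table(result, destination=None) -> str:
    """Render a result as tab-delimited text with a ``#`` footer line.

    Enrichment tables use the canonical column set (ID, PTM vocabulary,
    frequencies/percentages in UniProt and in the list, marker-annotated
    accessions, raw and corrected P-values); P-values print in scientific
    notation with 4 significant digits, percentages with 2 decimals.
    Identical results render byte-identically.  If ``destination`` is
    given the text is also written there.
    """
    if isinstance(result, EnrichmentResult):
        lines = ["\t".join(ENRICHMENT_HEADER)]
        for r in result.rows:
            lines.append(
                "\t".join(
                    [
                        r.term_id,
                        r.term_label,
                        str(r.freq_db),
                        _PCT(r.pct_db),
                        str(r.freq_list),
                        _PCT(r.pct_list),
                        " ".join(r.member_accessions),
                        _sci(r.p_value),
                        _sci(r.adjusted_p),
                    ]
                )
            )
        lines.append(_footer(result.context))
    elif isinstance(result, FrequencyResult):
        lines = ["\t".join(ENRICHMENT_HEADER[:6])]
        for r in result.rows:
            lines.append(
                "\t".join(
                    [
                        r.term_id,
                        r.term_label,
                        str(r.freq_db),
                        _PCT(r.pct_db),
                        str(r.freq_list),
                        _PCT(r.pct_list),
                    ]
                )
            )
        lines.append(_footer(result.context))
    elif isinstance(result, MatchedResult):
        lines = [
            "\t".join(
                [
                    "ID",
                    "PTM vocabulary",
                    "Percent in list 1",
                    "Percent in list 2",
                    "P-value list 1",
                    "P-value list 2",
                    "Corrected P-value list 1",
                    "Corrected P-value list 2",
                    "Significant in",
                ]
            )
        ]
        for r in result.rows:
            lines.append(
                "\t".join(
                    [
                        r.term_id,
                        r.term_label,
                        _PCT(r.pct_list1),
                        _PCT(r.pct_list2),
                        _sci(r.p1),
                        _sci(r.p2),
                        _sci(r.adj_p1),
                        _sci(r.adj_p2),
                        r.significant_in,
                    ]
                )
            )
        lines.append(_footer(result.context1))
        lines.append(_footer(result.context2))
    else:
        raise TypeError(f"cannot export {type(result).__name__}")
    text = "\n".join(lines) + "\n"
    if destination is not None:
        with open(destination, "w", encoding="utf-8") as handle:
            handle.write(text)
    return text


def read_table(source):
    """Reimport an exported table as a pandas DataFrame (footer skipped)."""
    import io

    import pandas as pd

    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source, "r", encoding="utf-8") as handle:
                text = handle.read()
        except (OSError, ValueError):
            text = source
    body = "\n".join(
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    )
    return pd.read_csv(io.StringIO(body), sep="\t")


def export_barchart(result, destination=None):
    """Bar chart of a result; returns the matplotlib Figure.

    Enrichment and frequency results plot one bar per term
    (-log10 of the decision P-value, or the list percentage); matched
    results plot two bars per term, one per list.  ``destination`` may be
    any path matplotlib can save to (.pdf/.svg for vector output).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, max(2.5, 0.4 * _n_rows(result) + 1.5)))
    if isinstance(result, EnrichmentResult):
        labels = [r.term_label for r in result.rows]
        heights = [-math.log10(max(r.decision_p, 5e-324)) for r in result.rows]
        ax.barh(labels[::-1], heights[::-1], color="#4878d0")
        ax.set_xlabel("-log10 corrected P" if result.context.correction
                      is not CorrectionMethod.NONE else "-log10 P")
        if result.context.adjusted_alpha is not None:
            ax.axvline(-math.log10(result.context.alpha), ls="--", color="grey")
    elif isinstance(result, FrequencyResult):
        labels = [r.term_label for r in result.rows]
        ax.barh(labels[::-1], [r.pct_list for r in result.rows][::-1],
                color="#4878d0")
        ax.set_xlabel("Percent in list")
    elif isinstance(result, MatchedResult):
        import numpy as np

        labels = [r.term_label for r in result.rows]
        y = np.arange(len(labels))
        h = 0.38
        ax.barh(y + h / 2, [r.pct_list1 for r in result.rows], height=h,
                label="list 1", color="#4878d0")
        ax.barh(y - h / 2, [r.pct_list2 for r in result.rows], height=h,
                label="list 2", color="#d65f5f")
        ax.set_yticks(y, labels)
        ax.invert_yaxis()
        ax.set_xlabel("Percent in list")
        ax.legend()
    else:
        raise TypeError(f"cannot plot {type(result).__name__}")
    fig.tight_layout()
    if destination is not None:
        fig.savefig(destination)
    return fig


def _n_rows(result) -> int:
    return len(result.rows)
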