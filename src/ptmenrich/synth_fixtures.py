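"""Synthetic Swiss-Prot entries and planted-enrichment lists.

Every stage of the pipeline is testable without downloading UniProt: the
generator emits flat-file-writable records with a known ground truth
(which proteins carry which terms), and ``plant_enriched_list`` draws
protein lists whose expected prevalence of a chosen term is an explicit
multiple of its background prevalence.

Annotation sampling is independent per term — there are no PTM
co-occurrence correlations, which is adequate for statistical calibration
but unrealistic for biology (see docs).  Accessions follow the UniProt
grammar (a letter followed by five alphanumerics) so identifier-resolution
code sees realistic tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ptmenrich.errors import ParameterError
from ptmenrich.ptm_vocab import PTMVocabulary, default_vocabulary, slugify
from ptmenrich.swissprot_io import DatDialect, FeatureAnnotation, ProteinRecord

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "PlantedListSpec",
    "example_spec",
    "generate_records",
    "plant_enriched_list",
]

_NON_PTM_KEYWORDS = ("Cytoplasm", "Transport", "Reference proteome")


def _ft_key_for(label: str) -> str:
    lowered = label.lower()
    if "palmitoyl" in lowered or "diacylglycerol" in lowered or "myristoyl" in lowered:
        return "LIPID"
    if "isopeptide" in lowered or "interchain" in lowered:
        return "CROSSLNK"
    return "MOD_RES"


@dataclass(frozen=True)
class FixtureSpec:
    """Ground-truth generation parameters.

    ``kw_probabilities`` / ``ft_probabilities`` map vocabulary labels to
    independent per-protein annotation probabilities.  ``putative_fraction``
    is the chance an emitted FT description carries "(By similarity)".
    The seed fixes the entire output stream: regeneration is
    byte-identical.
    """

    n_proteins: int
    kw_probabilities: Mapping[str, float]
    ft_probabilities: Mapping[str, float]
    organisms: tuple[str, ...] = ("Homo sapiens",)
    putative_fraction: float = 0.3
    unreviewed_fraction: float = 0.0
    crossref_probability: float = 0.3
    dialect: DatDialect = DatDialect.CLASSIC
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ParameterError("n_proteins must be positive")
        for name, probs in (
            ("kw_probabilities", self.kw_probabilities),
            ("ft_probabilities", self.ft_probabilities),
        ):
            for label, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ParameterError(f"{name}[{label!r}] = {p} outside [0, 1]")
        for name, frac in (
            ("putative_fraction", self.putative_fraction),
            ("unreviewed_fraction", self.unreviewed_fraction),
            ("crossref_probability", self.crossref_probability),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ParameterError(f"{name} = {frac} outside [0, 1]")


@dataclass(frozen=True)
class FixtureTruth:
    """What the generator actually emitted.

    ``background`` lists, per organism, the reviewed proteins carrying at
    least one annotation — exactly the proteins the database builder will
    keep.  ``terms`` maps (organism, term_id) to the carrier set.
    """

    background: Mapping[str, tuple[str, ...]]
    terms: Mapping[tuple[str, str], frozenset[str]]

    def prevalence(self, organism: str, term_id: str) -> float:
        universe = self.background[organism]
        carriers = self.terms.get((organism, term_id), frozenset())
        return len(carriers) / len(universe) if universe else 0.0


def example_spec(
    n_proteins: int = 2000,
    seed: int = 0,
    organisms: tuple[str, ...] = ("Homo sapiens",),
) -> FixtureSpec:
    """A 20-term study condition over the shipped vocabulary.

    Eight keyword-level and twelve feature-level terms with prevalences
    spanning 2%-50%, the range spanned by common PTM categories in curated
    proteomes (phosphorylation keywords near the top, rare residue-level
    modifications at the bottom).
    """
    kw = {
        "Phosphoprotein": 0.50,
        "Glycoprotein": 0.40,
        "Disulfide bond": 0.30,
        "Acetylation": 0.25,
        "Ubl conjugation": 0.20,
        "Methylation": 0.15,
        "Lipoprotein": 0.10,
        "Nucleotide-binding": 0.05,
    }
    ft = {
        "Phosphoserine": 0.30,
        "Phosphothreonine": 0.25,
        "N6-acetyllysine": 0.20,
        "Phosphotyrosine": 0.15,
        "N-acetylalanine": 0.12,
        "N-acetylmethionine": 0.10,
        "N6-succinyllysine": 0.08,
        "S-palmitoyl cysteine": 0.06,
        "Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)": 0.05,
        "Omega-N-methylarginine": 0.04,
        "Sulfotyrosine": 0.03,
        "4-hydroxyproline": 0.02,
    }
    return FixtureSpec(
        n_proteins=n_proteins,
        kw_probabilities=kw,
        ft_probabilities=ft,
        organisms=organisms,
        seed=seed,
    )


_ACC_FIRST = "OPQ"
_ACC_REST = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _new_accession(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        acc = _ACC_FIRST[rng.integers(len(_ACC_FIRST))] + "".join(
            _ACC_REST[i] for i in rng.integers(len(_ACC_REST), size=5)
        )
        if acc not in used:
            used.add(acc)
            return acc


def generate_records(spec: FixtureSpec) -> tuple[list[ProteinRecord], FixtureTruth]:
    """Sample records per the spec; the truth table matches them exactly."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    used_accs: set[str] = set()
    records: list[ProteinRecord] = []
    background: dict[str, list[str]] = {}
    terms: dict[tuple[str, str], set[str]] = {}
    kw_items = sorted(spec.kw_probabilities.items())
    ft_items = sorted(spec.ft_probabilities.items())
    for org_idx, organism in enumerate(spec.organisms):
        org_tag = f"ORG{org_idx}" if len(spec.organisms) > 1 else "HUMAN"
        org_bg = background.setdefault(organism, [])
        for i in range(spec.n_proteins):
            acc = _new_accession(rng, used_accs)
            reviewed = rng.random() >= spec.unreviewed_fraction
            keywords: list[str] = []
            kw_hits: list[str] = []
            for label, p in kw_items:
                if rng.random() < p:
                    keywords.append(label)
                    kw_hits.append(label)
            if rng.random() < 0.5:
                keywords.append(_NON_PTM_KEYWORDS[rng.integers(len(_NON_PTM_KEYWORDS))])
            features: list[FeatureAnnotation] = []
            ft_hits: list[str] = []
            for label, p in ft_items:
                if rng.random() < p:
                    pos = int(rng.integers(1, 500))
                    desc = label
                    if rng.random() < spec.putative_fraction:
                        desc += " (By similarity)"
                    desc += "."
                    features.append(
                        FeatureAnnotation(_ft_key_for(label), pos, pos, desc)
                    )
                    ft_hits.append(label)
            cross_refs: list[tuple[str, str]] = []
            if rng.random() < spec.crossref_probability:
                cross_refs.append(("PhosphoSite", acc))
            record = ProteinRecord(
                entry_name=f"SY{i:04d}_{org_tag}",
                review_status="Reviewed" if reviewed else "Unreviewed",
                accessions=[acc],
                organism_names=[organism],
                keywords=keywords,
                features=features,
                cross_refs=cross_refs,
            )
            records.append(record)
            if reviewed and (kw_hits or ft_hits):
                org_bg.append(acc)
                for label in kw_hits + ft_hits:
                    terms.setdefault((organism, slugify(label)), set()).add(acc)
    truth = FixtureTruth(
        background={org: tuple(accs) for org, accs in background.items()},
        terms={key: frozenset(accs) for key, accs in terms.items()},
    )
    return records, truth


@dataclass(frozen=True)
class PlantedListSpec:
    """A list with a term's prevalence boosted by ``enrichment_factor``.

    The expected list prevalence is ``min(1, factor * background
    prevalence)``; ``factor == 1`` draws a uniform background sample.
    """

    organism: str
    term_id: str
    list_size: int
    enrichment_factor: float = 1.0
    seed: int = 0


def plant_enriched_list(truth: FixtureTruth, spec: PlantedListSpec) -> list[str]:
    """Sample a protein list without replacement at the planted prevalence.

    The returned identifiers are shuffled deterministically by the seed.
    Raises :class:`ParameterError` when the requested prevalence is
    infeasible (more carriers needed than exist).
    """
    if spec.enrichment_factor < 0:
        raise ParameterError("enrichment_factor must be >= 0")
    universe = list(truth.background[spec.organism])
    if spec.list_size > len(universe):
        raise ParameterError(
            f"list size {spec.list_size} exceeds the organism background "
            f"({len(universe)} proteins)"
        )
    carriers = sorted(truth.terms.get((spec.organism, spec.term_id), frozenset()))
    if not carriers:
        raise ParameterError(
            f"term {spec.term_id!r} has zero prevalence in {spec.organism!r}"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.enrichment_factor == 1.0:
        # the null case is a genuinely uniform draw, not a quota sample
        picked = list(rng.choice(sorted(universe), size=spec.list_size, replace=False))
        return [str(acc) for acc in picked]
    prevalence = len(carriers) / len(universe)
    target = min(1.0, spec.enrichment_factor * prevalence)
    n_carry = int(round(target * spec.list_size))
    n_other = spec.list_size - n_carry
    others = sorted(set(universe) - set(carriers))
    if n_carry > len(carriers):
        raise ParameterError(
            f"infeasible prevalence: need {n_carry} carriers of "
            f"{spec.term_id!r} but only {len(carriers)} exist"
        )
    if n_other > len(others):
        raise ParameterError(
            f"infeasible list: need {n_other} non-carriers but only "
            f"{len(others)} exist"
        )
    picked = list(rng.choice(carriers, size=n_carry, replace=False)) + list(
        rng.choice(others, size=n_other, replace=False)
    )
    rng.shuffle(picked)
    return [str(acc) for acc in picked]
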