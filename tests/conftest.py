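import pytest

from ptmenrich import ptm_db, ptm_vocab
from ptmenrich.swissprot_io import FeatureAnnotation, ProteinRecord


@pytest.fixture(scope="session")
def small_vocab():
    """Three KW terms and three FT terms, one FT term with two parents."""
    return ptm_vocab.load_vocabulary(
        kw_term_list=["Phosphoprotein", "Acetylation", "Lipoprotein"],
        ft_term_list=["Phosphoserine", "N6-acetyllysine", "S-palmitoyl cysteine"],
        edge_list=[
            ("Phosphoserine", "Phosphoprotein"),
            ("N6-acetyllysine", "Acetylation"),
            ("S-palmitoyl cysteine", "Lipoprotein"),
            ("S-palmitoyl cysteine", "Acetylation"),
        ],
    )


def make_record(
    entry_name,
    accession,
    organism="Homo sapiens (Human)",
    keywords=(),
    features=(),
    cross_refs=(),
    review_status="Reviewed",
    extra_accessions=(),
):
    return ProteinRecord(
        entry_name=entry_name,
        review_status=review_status,
        accessions=[accession, *extra_accessions],
        organism_names=[organism],
        keywords=list(keywords),
        features=list(features),
        cross_refs=list(cross_refs),
    )


def mod_res(description, begin=10, end=None, key="MOD_RES"):
    return FeatureAnnotation(key, begin, end if end is not None else begin, description)


@pytest.fixture(scope="session")
def small_records():
    """Hand-built records exercising every inclusion/exclusion rule."""
    return [
        make_record("KWONLY_HUMAN", "P10001", keywords=["Phosphoprotein"]),
        make_record(
            "FTONLY_HUMAN", "P10002", features=[mod_res("Phosphoserine.")]
        ),
        make_record(
            "BOTH_HUMAN",
            "P10003",
            keywords=["Acetylation"],
            features=[mod_res("N6-acetyllysine (By similarity).")],
            cross_refs=[("PhosphoSite", "P10003")],
            extra_accessions=["Q99999"],
        ),
        make_record(
            "PLAIN_HUMAN", "P10004", keywords=["Transport"]
        ),  # no PTM annotation -> excluded
        make_record(
            "CARB_HUMAN",
            "P10005",
            features=[mod_res("O-linked glycan.", key="CARBOHYD")],
        ),  # CARBOHYD not in default ft_keys -> excluded
        make_record(
            "TREMBL_HUMAN",
            "P10006",
            keywords=["Phosphoprotein"],
            review_status="Unreviewed",
        ),  # unreviewed -> excluded
        make_record(
            "YEAST1_YEAST",
            "P20001",
            organism="Saccharomyces cerevisiae (Baker's yeast)",
            keywords=["Phosphoprotein"],
            features=[mod_res("Phosphoserine; by PKA.")],
        ),
    ]


@pytest.fixture(scope="session")
def small_db(small_records, small_vocab):
    return ptm_db.build_database(small_records, small_vocab)
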