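"""Variant parsing, filtering and knowledge-based classification."""

import pytest

from pgm_paralogs import (
    Category,
    FrequencyClass,
    MissenseVariant,
    classify_all,
    classify_variant,
    frequency_filter,
    polyphen_hook,
    summarize,
)
from pgm_paralogs.variants import parse_protein_change, read_variant_table, write_variant_table


def test_parse_hgvs_protein_change():
    assert parse_protein_change("p.Arg503Gln") == ("R", 503, "Q")
    assert parse_protein_change("p.Gly121Arg") == ("G", 121, "R")
    with pytest.raises(ValueError):
        parse_protein_change("p.Xyz10Ala")
    with pytest.raises(ValueError):
        parse_protein_change("R503Q")


def test_variant_invariants():
    with pytest.raises(ValueError):
        MissenseVariant(protein="PGM1", position=10, ref="A", alt="A")
    with pytest.raises(ValueError):
        MissenseVariant(protein="PGM1", position=0, ref="A", alt="G")


def test_variant_table_round_trip(tmp_path, bundle):
    path = tmp_path / "v.tsv"
    write_variant_table(bundle.variants, path)
    again = read_variant_table(path)
    assert again == list(bundle.variants)


def test_frequency_filter_classes():
    def v(freq):
        return MissenseVariant(protein="PGM1", position=5, ref="G", alt="R",
                               frequency=freq)

    assert frequency_filter(v(FrequencyClass.SINGLETON))
    assert frequency_filter(v(FrequencyClass.BELOW_1E4))
    assert frequency_filter(v(FrequencyClass.BETWEEN_1E4_1E3))
    assert not frequency_filter(v(FrequencyClass.ABOVE_1E3))
    assert frequency_filter(v(5e-4))
    assert not frequency_filter(v(0.01))


def test_classification_examples(bundle, pm):
    """The catalogued exemplar transfers behave as published."""
    by_label = {}
    cls = classify_all(bundle.variants, bundle.catalog, pm, bundle.regions)
    for c in cls:
        by_label[c.variant.label] = c

    # population PGM3 R496W corresponds to the PGM1 503 patient position
    c = by_label["PGM3:R496W"]
    assert c.category is Category.CORRESPONDS
    assert c.mapped_anchor == ("PGM1", 503)
    assert c.domain == 4

    # patient PGM1 R503Q is confirmed disease, domain 4
    c = by_label["PGM1:R503Q"]
    assert c.category is Category.CONFIRMED
    assert c.domain == 4

    # PGM2 metal-loop variants are category 2 (functional region), domain 2
    c = by_label["PGM2:P323L"]
    assert c.category is Category.FUNCTIONAL_REGION
    assert c.domain == 2

    # PGM1 G330S sits at a known PGM1 disease position (parenthesised entry)
    c = by_label["PGM1:G330S"]
    assert c.category is Category.AT_DISEASE_POSITION

    # PGM3 D297E patient variant is assigned to domain 3, as catalogued
    assert by_label["PGM3:D297E"].domain == 3
    # PGM2L1 C520Y anchors at the PGM3 451 patient position, domain 4
    c = by_label["PGM2L1:C520Y"]
    assert c.category is Category.CORRESPONDS
    assert c.mapped_anchor == ("PGM3", 451)
    assert c.domain == 4


def test_unmapped_nonregion_variant_unclassified(bundle, pm):
    v = MissenseVariant(protein="PGM1", position=200, ref="X", alt="R",
                        frequency=FrequencyClass.SINGLETON)
    # position 200 is outside regions and maps to no disease position; the
    # ref need not match for classification, which is positional
    v = MissenseVariant(protein="PGM1", position=200,
                        ref=bundle.msa.row("PGM1").record.residue_at(200),
                        alt="W", frequency=FrequencyClass.SINGLETON,
                        physchem_override=True)
    c = classify_variant(v, bundle.catalog, pm, bundle.regions)
    assert c.category is Category.UNCLASSIFIED


def test_category_partition(bundle, pm):
    cls = classify_all(bundle.variants, bundle.catalog, pm, bundle.regions)
    assert len(cls) == len(bundle.variants)
    for c in cls:
        assert isinstance(c.category, Category)  # exactly one category each


def test_monotonicity_in_tau_and_freq(bundle, pm):
    """Raising tau or lowering max_freq never grows the predicted set."""

    def predicted(tau, max_freq):
        # drop the expert flag so tau actually governs selection
        stripped = [
            MissenseVariant(
                protein=v.protein, position=v.position, ref=v.ref, alt=v.alt,
                frequency=v.frequency, provenance=v.provenance,
            )
            for v in bundle.variants
        ]
        cls = classify_all(stripped, bundle.catalog, pm, bundle.regions,
                           tau=tau, max_freq=max_freq)
        return {
            c.variant.label
            for c in cls
            if c.category in (Category.CORRESPONDS, Category.FUNCTIONAL_REGION,
                              Category.AT_DISEASE_POSITION)
        }

    base = predicted(60, 1e-3)
    assert predicted(110, 1e-3) <= base
    assert predicted(60, 1e-4) <= base
    assert predicted(110, 1e-4) <= predicted(110, 1e-3)


def test_polyphen_hook_filtering(bundle, pm):
    cls = classify_all(bundle.variants, bundle.catalog, pm, bundle.regions)
    # empty score table: unchanged
    assert polyphen_hook(cls, None) == cls
    target = next(c for c in cls if c.category is Category.CORRESPONDS)
    v = target.variant
    scored = polyphen_hook(cls, {(v.protein, v.position, v.ref, v.alt): 0.01})
    dropped = [c for c in scored if c.discarded]
    assert len(dropped) == 1 and dropped[0].variant == v
    before = summarize(cls, bundle.catalog).counts["category1_variants"]
    after = summarize(scored, bundle.catalog).counts["category1_variants"]
    assert after == before - 1


def test_catalog_counts(bundle):
    catalog = bundle.catalog
    assert catalog.proteins == ["PGM1", "PGM3"]
    assert catalog.contains("PGM1", 503)
    assert not catalog.contains("PGM1", 261)
    assert catalog.alts("PGM1", 263) == {"G", "Y"}


def test_variant_table_with_hgvs_change_column(tmp_path):
    path = tmp_path / "hgvs.tsv"
    path.write_text(
        "protein\tchange\tfrequency\tprovenance\n"
        "PGM1\tp.Arg503Gln\tsingleton\tpopulation\n"
        "PGM3\tp.Leu83Ser\tlt_1e-4\tpatient_confirmed\n"
    )
    variants = read_variant_table(path)
    assert variants[0].label == "PGM1:R503Q"
    assert variants[1].label == "PGM3:L83S"
    assert variants[1].provenance.value == "patient_confirmed"
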