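"""Properties of the bundled synthetic reference alignment.

The fixture must behave like the curated alignment it stands in for: native
lengths, permutation-adjusted PGM3 with native reporting, every catalogued
cross-paralog correspondence in one column, and the four active-site motifs
recoverable through region extraction.
"""

import pytest

from pgm_paralogs import extract_region, fixtures
from pgm_paralogs.records import NATIVE_LENGTHS

# correspondence groups transcribed from the curated variant table rows
TABLE_ROWS = [
    {"PGM1": 38, "PGM3": 41},
    {"PGM1": 139, "PGM3": 83},
    {"PGM1": 261, "PGM2L1": 291, "PGM3": 246},
    {"PGM1": 288, "PGM2": 322, "PGM2L1": 332},
    {"PGM2": 324, "PGM2L1": 334, "PGM5": 295},
    {"PGM1": 377, "PGM2L1": 435},
    {"PGM1": 375, "PGM2L1": 433},
    {"PGM2L1": 437, "PGM3": 372},
    {"PGM1": 380, "PGM2": 428},
    {"PGM1": 422, "PGM5": 427},
    {"PGM2L1": 520, "PGM3": 451},
    {"PGM1": 503, "PGM2": 558, "PGM3": 496, "PGM5": 508},
    {"PGM1": 508, "PGM2": 563, "PGM3": 501, "PGM5": 513},
    {"PGM1": 511, "PGM5": 516},
    {"PGM1": 515, "PGM3": 505},
    {"PGM1": 506, "PGM2L1": 571},
]


def test_native_lengths(bundle):
    for protein, length in NATIVE_LENGTHS.items():
        assert len(bundle.msa.row(protein).record) == length


def test_pgm3_row_is_adjusted_and_reports_native(bundle, pm):
    row = bundle.msa.row("PGM3")
    assert row.adjusted
    # native 115 is the first residue of the swapped-forward segment
    assert row.translator.to_adjusted(115) == 54
    # mapping reports native numbering: PGM1 139 pairs with PGM3 native 83
    assert pm.map_position("PGM1", 139, "PGM3") == 83


@pytest.mark.parametrize("row", TABLE_ROWS, ids=lambda r: "+".join(f"{k}{v}" for k, v in r.items()))
def test_catalogued_correspondences_share_a_column(pm, row):
    """Every multi-protein row of the variant catalog is one column group."""
    (p0, pos0), *rest = row.items()
    group = pm.group(p0, pos0)
    for protein, pos in rest:
        assert group.get(protein) == pos, f"{p0}:{pos0} !~ {protein}:{pos}"


MOTIF_CHECKS = [
    ("PGM1", "phosphoserine", "TASH"),
    ("PGM2", "phosphoserine", "TASH"),
    ("PGM2L1", "phosphoserine", "TASHNRKE"),
    ("PGM3", "phosphoserine", "TASH"),
    ("PGM5", "phosphoserine", "TASH"),
    ("PGM1", "metal_binding", "DGDGDR"),
    ("PGM2", "metal_binding", "DPDADR"),
    ("PGM2L1", "metal_binding", "DPDADR"),
    ("PGM5", "metal_binding", "DGDGDR"),
    ("PGM1", "sugar_binding", "GEESF"),
    ("PGM5", "sugar_binding", "GEESF"),
    ("PGM2", "sugar_binding", "FAFEE"),
    ("PGM2L1", "sugar_binding", "FAFEE"),
    ("PGM3", "sugar_binding", "YFEAN"),
]


@pytest.mark.parametrize("protein,label,motif", MOTIF_CHECKS)
def test_region_extraction_contains_motifs(bundle, pm, regions_by_label, protein, label, motif):
    record = bundle.msa.row(protein).record
    sub, positions = extract_region(record, regions_by_label[label], pm)
    assert motif in sub
    assert len(sub) == len(positions)


def test_catalytic_serine_column_shared(bundle, pm, regions_by_label):
    """The catalytic serine of all five paralogs occupies one column."""
    # PGM1 S117; PGM3 native S64
    group = pm.group("PGM1", 117)
    assert group["PGM3"] == 64
    assert set(group) == {"PGM1", "PGM2", "PGM2L1", "PGM3", "PGM5"}
    for protein, pos in group.items():
        assert bundle.msa.row(protein).record.residue_at(pos) == "S"
        assert regions_by_label["phosphoserine"].contains(pm, protein, pos)


def test_variant_refs_match_fixture_sequences(bundle):
    for v in bundle.variants:
        rec = bundle.msa.row(v.protein).record
        assert rec.residue_at(v.position) == v.ref, v.label


def test_sister_pairs_have_highest_identities(bundle):
    from pgm_paralogs import identity_matrix

    idm = identity_matrix(bundle.msa).identity
    offdiag = idm.where(~(idm == 100.0)).stack()
    assert idm.loc["PGM1", "PGM5"] > idm.loc["PGM1", "PGM3"]
    assert idm.loc["PGM2", "PGM2L1"] > idm.loc["PGM2", "PGM3"]
    top_two = set(offdiag.sort_values(ascending=False).index[:4])
    assert ("PGM1", "PGM5") in top_two and ("PGM2", "PGM2L1") in top_two


def test_fixture_is_deterministic(bundle, tmp_path):
    first = bundle.msa.row("PGM1").gapped
    fixtures.reference_alignment.cache_clear()
    again = fixtures.reference_alignment().row("PGM1").gapped
    assert first == again
    # exported bundle round-trips through the aligned-FASTA reader
    paths = fixtures.write_bundle(tmp_path)
    from pgm_paralogs.pipeline import read_reference_alignment

    msa2 = read_reference_alignment(paths["alignment"])
    assert [r.gapped for r in msa2.rows] == [r.gapped for r in bundle.msa.rows]
    assert msa2.row("PGM3").record.residues == bundle.msa.row("PGM3").record.residues


def test_shipped_data_files_match_generated_bundle(bundle, tmp_path):
    """The exported data/ copies are byte-identical to the generators."""
    from importlib import resources

    fresh = fixtures.write_bundle(tmp_path)
    data_dir = resources.files("pgm_paralogs") / "data"
    for path in fresh.values():
        shipped = data_dir / path.name
        assert shipped.is_file(), f"missing shipped fixture {path.name}"
        assert shipped.read_text() == path.read_text(), path.name
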