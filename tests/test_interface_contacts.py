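"""Chain pairing, heavy-atom contact extraction, aggregation, regions, Vernier."""

import math

import pytest

from pairedab.errors import DataError, EmptyResultError
from pairedab.interface_contacts import (
    ContactFrequencyTable,
    ContactMap,
    PositionContactStats,
    aggregate_contact_stats,
    extract_contacts,
    imgt_region_of,
    load_vernier_positions,
    pair_chains_by_cys104,
    region_pair_summary,
    residue_contacts,
    select_key_positions,
    vernier_overlap,
)
from pairedab.io_formats import AnnotatedStructure, Atom, Residue, StructChain


def _chain(chain_id, chain_type, residue_specs):
    """residue_specs: {imgt_pos: [(name, element, x, y, z), ...]}"""
    residues = {
        pos: Residue(amino_acid="C" if pos == "104" else "A",
                     atoms=[Atom(*a) for a in atoms])
        for pos, atoms in residue_specs.items()
    }
    return StructChain(chain_id=chain_id, chain_type=chain_type, residues=residues)


def _cys_chain(chain_id, chain_type, ca_xyz):
    return _chain(chain_id, chain_type, {"104": [("CA", "C", *ca_xyz)]})


def test_pair_chains_within_20A():
    s = AnnotatedStructure("t", [
        _cys_chain("H", "H", (0, 0, 0)), _cys_chain("L", "L", (10, 0, 0))])
    pairs = pair_chains_by_cys104(s)
    assert [(h.chain_id, l.chain_id) for h, l in pairs] == [("H", "L")]


def test_no_pairing_beyond_20A():
    s = AnnotatedStructure("t", [
        _cys_chain("H", "H", (0, 0, 0)), _cys_chain("L", "L", (25, 0, 0))])
    assert pair_chains_by_cys104(s) == []


def test_greedy_nearest_first_matching():
    """H1L1=8, H1L2=12, H2L2=9 (H2L1 out of range) -> (H1,L1), (H2,L2)."""
    s = AnnotatedStructure("t", [
        _cys_chain("H1", "H", (0, 0, 0)),
        _cys_chain("H2", "H", (0, 21, 0)),
        _cys_chain("L1", "L", (8, 0, 0)),
        _cys_chain("L2", "L", (0, 12, 0)),
    ])
    assert math.dist((0, 21, 0), (0, 12, 0)) == pytest.approx(9)
    pairs = pair_chains_by_cys104(s)
    assert [(h.chain_id, l.chain_id) for h, l in pairs] == [("H1", "L1"), ("H2", "L2")]


def test_chain_missing_cys104_is_skipped_not_fatal():
    s = AnnotatedStructure("t", [
        _chain("H", "H", {"50": [("CA", "C", 0, 0, 0)]}),
        _cys_chain("L", "L", (5, 0, 0))])
    assert pair_chains_by_cys104(s) == []


# ---------------------------------------------------------------------------
# residue contacts
# ---------------------------------------------------------------------------

def test_contact_at_4p40_present_and_4p60_absent():
    h = _chain("H", "H", {"50": [("CB", "C", 0, 0, 0)], "60": [("CB", "C", 30, 0, 0)]})
    l = _chain("L", "L", {"40": [("CB", "C", 4.40, 0, 0)], "44": [("CB", "C", 34.60, 0, 0)]})
    cmap = residue_contacts(h, l)
    assert ("50", "40") in cmap.contacts
    assert ("60", "44") not in cmap.contacts


def test_cutoff_is_inclusive():
    h = _chain("H", "H", {"50": [("CB", "C", 0, 0, 0)]})
    l = _chain("L", "L", {"40": [("CB", "C", 4.5, 0, 0)]})
    assert ("50", "40") in residue_contacts(h, l).contacts


def test_hydrogen_only_proximity_is_not_a_contact():
    h = _chain("H", "H", {"50": [("CB", "C", 0, 0, 0), ("HB1", "H", 3.0, 0, 0)]})
    l = _chain("L", "L", {"40": [("HD1", "H", 4.0, 0, 0), ("CB", "C", 8.0, 0, 0)]})
    # closest heavy-atom pair is CB-CB at 8.0; all sub-4.5 pairs involve hydrogens
    assert residue_contacts(h, l).contacts == frozenset()


def test_contact_symmetry_under_chain_swap():
    h = _chain("H", "H", {"50": [("CB", "C", 0, 0, 0)], "105": [("CB", "C", 10, 0, 0)]})
    l = _chain("L", "L", {"40": [("CB", "C", 3, 0, 0)], "44": [("CB", "C", 11, 0, 0)]})
    fwd = residue_contacts(h, l).contacts
    rev = residue_contacts(l, h).contacts
    assert {(b, a) for a, b in fwd} == rev


def _brute_force_contacts(h_chain, l_chain, cutoff=4.5):
    """Independent oracle: loop over every heavy-atom pair."""
    contacts = set()
    for hp, hres in h_chain.residues.items():
        for lp, lres in l_chain.residues.items():
            for ha in hres.atoms:
                if ha.is_hydrogen:
                    continue
                for la in lres.atoms:
                    if la.is_hydrogen:
                        continue
                    if math.dist(ha.coord, la.coord) <= cutoff:
                        contacts.add((hp, lp))
    return contacts


def test_kernel_matches_brute_force_oracle_on_synthetic_structures():
    from pairedab.synthetic_data import StructureConfig, simulate_interface_structures

    structures, designed = simulate_interface_structures(
        StructureConfig(n_structures=3, seed=21))
    for s in structures:
        h = s.chain("H")
        l = s.chain("L")
        cmap = residue_contacts(h, l, structure_id=s.structure_id)
        assert cmap.contacts == frozenset(_brute_force_contacts(h, l))
        assert cmap.contacts == designed


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_aggregate_ratio_counts_occurrences():
    """Position present in 4 structures, contacting in 1 -> ratio 0.25."""
    from pairedab.synthetic_data import StructureConfig, simulate_interface_structures

    structures, _ = simulate_interface_structures(StructureConfig(n_structures=4, seed=2))
    maps = [m for s in structures for m in extract_contacts(s)]
    # replace 3 of the maps with empty contact sets: position 105 contacts once
    maps = [maps[0]] + [
        ContactMap(m.structure_id, m.pair, frozenset()) for m in maps[1:]]
    freqs, matrix = aggregate_contact_stats(maps, structures)
    st = freqs.by_chain["H"]["105"]
    assert (st.n_contact, st.n_occurrence) == (1, 4)
    assert st.ratio == pytest.approx(0.25)


def test_positions_never_present_are_absent_from_table():
    h = _chain("H", "H", {"50": [("CB", "C", 0, 0, 0)], "104": [("CA", "C", 1, 0, 0)]})
    l = _chain("L", "L", {"40": [("CB", "C", 4, 0, 0)], "104": [("CA", "C", 5, 0, 0)]})
    s = AnnotatedStructure("t", [h, l])
    maps = [residue_contacts(h, l, structure_id="t")]
    freqs, _ = aggregate_contact_stats(maps, [s])
    assert set(freqs.by_chain["H"]) == {"50", "104"}
    assert "2" not in freqs.by_chain["H"]


def test_pair_count_matrix_equals_design_indicator_times_n():
    from pairedab.synthetic_data import StructureConfig, simulate_interface_structures

    n = 5
    structures, designed = simulate_interface_structures(
        StructureConfig(n_structures=n, seed=8))
    maps = [m for s in structures for m in extract_contacts(s)]
    freqs, matrix = aggregate_contact_stats(maps, structures)
    assert int(matrix.values.sum()) == sum(len(m.contacts) for m in maps)
    for h, l in designed:
        assert matrix.loc[h, l] == n


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "position, region",
    [("1", "FWR1"), ("26", "FWR1"), ("27", "CDR1"), ("38", "CDR1"), ("39", "FWR2"),
     ("40", "FWR2"), ("55", "FWR2"), ("56", "CDR2"), ("65", "CDR2"), ("66", "FWR3"),
     ("104", "FWR3"), ("105", "CDR3"), ("111A", "CDR3"), ("117", "CDR3"),
     ("118", "FWR4"), ("128", "FWR4")],
)
def test_imgt_region_delimitation(position, region):
    assert imgt_region_of(position, "H") == region
    assert imgt_region_of(position, "L") == region


@pytest.mark.parametrize("position", ["0", "129"])
def test_out_of_range_position_rejected(position):
    with pytest.raises(DataError):
        imgt_region_of(position, "H")


def test_designed_cdr3_fwr2_pattern_in_region_summary():
    from pairedab.synthetic_data import StructureConfig, simulate_interface_structures

    structures, _ = simulate_interface_structures(StructureConfig(n_structures=2, seed=3))
    maps = [m for s in structures for m in extract_contacts(s)]
    summary = region_pair_summary(maps)
    # default design: H-CDR3 <-> L-FWR2 (two pairs) and H-FWR2 <-> L-CDR3 (one)
    assert summary.loc["CDR3", "FWR2"] == 2 * 2
    assert summary.loc["FWR2", "CDR3"] == 1 * 2
    assert summary.values.sum() == 3 * 2


# ---------------------------------------------------------------------------
# key positions and Vernier overlap
# ---------------------------------------------------------------------------

def _freq_table(ratios):
    t = ContactFrequencyTable()
    for pos, (contact, occ) in ratios.items():
        t.by_chain["H"][pos] = PositionContactStats(contact, occ)
    return t


def test_key_selection_by_ratio_threshold():
    t = _freq_table({"105": (18, 20), "40": (6, 20), "2": (1, 20)})  # ratios .9/.3/.05
    keys = select_key_positions(t, min_ratio=0.25, min_occurrence=1)
    assert keys["H"] == {"105", "40"}


def test_min_ratio_zero_selects_all_contacting_and_above_max_none():
    t = _freq_table({"105": (18, 20), "40": (6, 20)})
    assert select_key_positions(t, min_ratio=0.0, min_occurrence=1)["H"] == {"105", "40"}
    assert select_key_positions(t, min_ratio=0.95, min_occurrence=1)["H"] == set()


def test_min_occurrence_filters_rare_positions():
    t = _freq_table({"105": (2, 2), "40": (10, 10)})
    keys = select_key_positions(t, min_ratio=0.5, min_occurrence=5)
    assert keys["H"] == {"40"}


@pytest.mark.parametrize(
    "key, vernier, jaccard",
    [({"1", "2"}, {"1", "2"}, 1.0),
     ({"1", "2"}, {"3", "4"}, 0.0),
     ({"1", "2", "3"}, {"3", "4"}, 0.25)],
)
def test_vernier_overlap_set_algebra(key, vernier, jaccard):
    o = vernier_overlap(key, vernier)
    assert o["jaccard"] == pytest.approx(jaccard)
    assert o["intersection"] == key & vernier
    assert o["key_only"] == key - vernier


def test_vernier_overlap_empty_union_signalled():
    with pytest.raises(EmptyResultError):
        vernier_overlap(set(), set())


def test_shipped_vernier_positions_load():
    v = load_vernier_positions()
    assert v["H"] and v["L"]
    assert all(1 <= int(p) <= 128 for p in v["H"] | v["L"])
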