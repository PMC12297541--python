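"""Map VH/VL interface contacts on toy structures with designed ground truth.

Builds 10 two-chain structures whose cross-chain contacts are placed by
construction (CDR3 of each chain touching FWR2 of the other), pairs chains
through the IMGT-104 cysteines, extracts 4.5-Angstrom heavy-atom contacts,
and summarizes contact frequencies, regions, and the Vernier-zone overlap.
"""

from pairedab import (
    StructureConfig,
    aggregate_contact_stats,
    extract_contacts,
    load_vernier_positions,
    region_pair_summary,
    select_key_positions,
    simulate_interface_structures,
    vernier_overlap,
)

structures, designed = simulate_interface_structures(StructureConfig(n_structures=10, seed=3))
print(f"designed contacts (H position, L position): {sorted(designed)}")

maps = [m for s in structures for m in extract_contacts(s)]
print(f"extracted {sum(len(m.contacts) for m in maps)} contacts over {len(maps)} chain pairs")

freqs, matrix = aggregate_contact_stats(maps, structures)
print("\ncontact ratio per position (contacts / occurrences):")
print(freqs.to_frame()[lambda d: d.n_contact > 0].to_string(index=False))

print("\ncontacts by IMGT region (rows = heavy, cols = light):")
regions = region_pair_summary(maps)
print(regions.loc[regions.sum(axis=1) > 0, regions.sum(axis=0) > 0])
print("-> the designed CDR3 <-> FWR2 cross-chain pattern")

keys = select_key_positions(freqs, min_ratio=0.5, min_occurrence=5)
vernier = load_vernier_positions()
for ct in ("H", "L"):
    o = vernier_overlap(keys[ct], vernier[ct])
    print(f"\n{ct} chain: key interface residues {sorted(keys[ct])}")
    print(f"  overlap with Vernier zone: {sorted(o['intersection'])} (Jaccard {o['jaccard']:.2f})")
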