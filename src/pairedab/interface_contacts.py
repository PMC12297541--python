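"""VH/VL interface analysis: chain pairing, heavy-atom contacts, key residues.

An antibody Fv packs a heavy and a light variable domain against each other;
the residues at that interface determine how (and whether) a given H/L pair
assembles. This module

* pairs H and L chains inside a structure through the conserved IMGT-104
  cysteines (Calpha-Calpha distance <= 20 Angstrom, the disulfide-anchored core);
* extracts contacting residue pairs: any two non-hydrogen atoms across the
  chains within 4.5 Angstrom (inclusive);
* aggregates per-IMGT-position contact frequencies over many structures
  (how often a position is in contact out of the times it occurs);
* maps IMGT positions to FWR/CDR regions and summarizes contacts by region
  (e.g. the recurring CDR3 <-> FWR2 cross-chain pattern);
* selects "key interface residues" by occurrence/ratio thresholds and
  compares them to the classic Vernier-zone framework positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DataError, EmptyResultError
from .io_formats import AnnotatedStructure, StructChain, imgt_integer

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 4.5  # Angstrom, inclusive, heavy atoms only
CYS104_MAX_DIST = 20.0  # Angstrom, Calpha-Calpha at IMGT 104

#: IMGT region delimitation over positions 1-128 (inclusive bounds)
IMGT_REGIONS = (
    ("FWR1", 1, 26),
    ("CDR1", 27, 38),
    ("FWR2", 39, 55),
    ("CDR2", 56, 65),
    ("FWR3", 66, 104),
    ("CDR3", 105, 117),
    ("FWR4", 118, 128),
)


@dataclass(frozen=True)
class ContactMap:
    """Contacting IMGT position pairs for one paired H/L chain couple."""

    structure_id: str
    pair: tuple[str, str]  # (H chain id, L chain id)
    contacts: frozenset[tuple[str, str]]  # (H IMGT id, L IMGT id)


@dataclass
class PositionContactStats:
    n_contact: int
    n_occurrence: int

    @property
    def ratio(self) -> float:
        return self.n_contact / self.n_occurrence


@dataclass
class ContactFrequencyTable:
    """Per chain type, per IMGT position: contact count out of occurrences."""

    by_chain: dict[str, dict[str, PositionContactStats]] = field(
        default_factory=lambda: {"H": {}, "L": {}}
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain_type": ct,
                "imgt_position": pos,
                "n_contact": st.n_contact,
                "n_occurrence": st.n_occurrence,
                "ratio": st.ratio,
            }
            for ct, positions in self.by_chain.items()
            for pos, st in sorted(positions.items(), key=lambda kv: imgt_integer(kv[0]))
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chain pairing and contact extraction
# ---------------------------------------------------------------------------

def _cys104_ca(chain: StructChain) -> np.ndarray | None:
    res = chain.residues.get("104")
    if res is None:
        logger.warning("chain %s has no residue at IMGT 104; skipped", chain.chain_id)
        return None
    ca = res.atom("CA")
    if ca is None:
        logger.warning("chain %s residue 104 has no Calpha; skipped", chain.chain_id)
        return None
    if res.amino_acid != "C":
        logger.warning(
            "chain %s residue at IMGT 104 is %s, not Cys; using it anyway",
            chain.chain_id,
            res.amino_acid,
        )
    return np.array(ca.coord)


def pair_chains_by_cys104(
    structure: AnnotatedStructure, max_dist: float = CYS104_MAX_DIST
) -> list[tuple[StructChain, StructChain]]:
    """Pair H and L chains whose IMGT-104 Calpha atoms lie within ``max_dist``.

    Greedy nearest-first matching, each chain used at most once (resolves
    multi-Fab asymmetric units deterministically). Chains lacking position
    104 or its Calpha are skipped with a warning.
    """
    heavies = [(c, _cys104_ca(c)) for c in structure.chains if c.chain_type == "H"]
    lights = [(c, _cys104_ca(c)) for c in structure.chains if c.chain_type == "L"]
    candidates = []
    for h, hca in heavies:
        if hca is None:
            continue
        for l, lca in lights:
            if lca is None:
                continue
            d = float(np.linalg.norm(hca - lca))
            if d <= max_dist:
                candidates.append((d, h, l))
    candidates.sort(key=lambda t: (t[0], t[1].chain_id, t[2].chain_id))
    used: set[str] = set()
    pairs = []
    for d, h, l in candidates:
        if h.chain_id in used or l.chain_id in used:
            continue
        used.update((h.chain_id, l.chain_id))
        pairs.append((h, l))
    return pairs


def _heavy_atom_table(chain: StructChain) -> tuple[np.ndarray, list[str]]:
    """Coordinates of all non-hydrogen atoms with their residue's IMGT id."""
    coords = []
    positions = []
    for pos, res in chain.residues.items():
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            coords.append(atom.coord)
            positions.append(pos)
    if not coords:
        return np.empty((0, 3)), []
    return np.asarray(coords, dtype=float), positions


def residue_contacts(
    h_chain: StructChain,
    l_chain: StructChain,
    cutoff: float = CONTACT_CUTOFF,
    structure_id: str = "",
) -> ContactMap:
    """Cross-chain residue contacts at a heavy-atom distance cutoff.

    A residue pair (i on H, j on L) is a contact iff some non-hydrogen atom
    of i lies within ``cutoff`` (inclusive) of some non-hydrogen atom of j.
    """
    if not h_chain.residues or not l_chain.residues:
        raise DataError("both chains must carry at least one residue")
    h_xyz, h_pos = _heavy_atom_table(h_chain)
    l_xyz, l_pos = _heavy_atom_table(l_chain)
    contacts: set[tuple[str, str]] = set()
    if len(h_xyz) and len(l_xyz):
        dist = cdist(h_xyz, l_xyz)
        for i, j in zip(*np.nonzero(dist <= cutoff)):
            contacts.add((h_pos[i], l_pos[j]))
    return ContactMap(
        structure_id=structure_id,
        pair=(h_chain.chain_id, l_chain.chain_id),
        contacts=frozenset(contacts),
    )


def extract_contacts(
    structure: AnnotatedStructure,
    cutoff: float = CONTACT_CUTOFF,
    max_cys_dist: float = CYS104_MAX_DIST,
) -> list[ContactMap]:
    """Pair chains via Cys-104 and extract a ContactMap per paired couple."""
    return [
        residue_contacts(h, l, cutoff=cutoff, structure_id=structure.structure_id)
        for h, l in pair_chains_by_cys104(structure, max_dist=max_cys_dist)
    ]


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_contact_stats(
    maps: list[ContactMap], structures: list[AnnotatedStructure]
) -> tuple[ContactFrequencyTable, pd.DataFrame]:
    """Aggregate contact maps into per-position frequencies and a pair-count matrix.

    ``n_occurrence`` counts one instance per paired chain per structure (a
    position present in two Fabs of one file counts twice); ``n_contact``
    counts the instances where the position appears in at least one contact.
    The pair-count matrix sums (H position, L position) contact occurrences
    across all maps.
    """
    by_id = {s.structure_id: s for s in structures}
    freq = ContactFrequencyTable()
    pair_counts: dict[tuple[str, str], int] = {}
    for cmap in maps:
        structure = by_id.get(cmap.structure_id)
        if structure is None:
            raise DataError(f"contact map references unknown structure {cmap.structure_id!r}")
        chains = {cid: structure.chain(cid) for cid in cmap.pair}
        contacting = {"H": {h for h, _ in cmap.contacts}, "L": {l for _, l in cmap.contacts}}
        for ct, cid in zip(("H", "L"), cmap.pair):
            chain = chains[cid]
            if chain.chain_type != ct:
                raise DataError(
                    f"chain {cid} of {cmap.structure_id} is type {chain.chain_type}, expected {ct}"
                )
            for pos in chain.residues:
                st = freq.by_chain[ct].setdefault(pos, PositionContactStats(0, 0))
                st.n_occurrence += 1
                if pos in contacting[ct]:
                    st.n_contact += 1
        for hl in cmap.contacts:
            pair_counts[hl] = pair_counts.get(hl, 0) + 1
    h_ids = sorted({h for h, _ in pair_counts}, key=imgt_integer)
    l_ids = sorted({l for _, l in pair_counts}, key=imgt_integer)
    matrix = pd.DataFrame(0, index=h_ids, columns=l_ids, dtype=int)
    for (h, l), n in pair_counts.items():
        matrix.loc[h, l] = n
    return freq, matrix


def imgt_region_of(position: str | int, chain_type: str = "H") -> str:
    """IMGT FWR/CDR region of a position (insertions inherit their integer's region)."""
    if chain_type not in ("H", "L"):
        raise DataError("chain_type must be H or L")
    n = imgt_integer(str(position))
    for region, lo, hi in IMGT_REGIONS:
        if lo <= n <= hi:
            return region
    raise DataError(f"IMGT position {position} outside 1..128")


def region_pair_summary(maps: list[ContactMap]) -> pd.DataFrame:
    """Contact occurrences cross-tabulated by (H region, L region)."""
    regions = [r for r, _, _ in IMGT_REGIONS]
    matrix = pd.DataFrame(0, index=regions, columns=regions, dtype=int)
    for cmap in maps:
        for h, l in cmap.contacts:
            matrix.loc[imgt_region_of(h, "H"), imgt_region_of(l, "L")] += 1
    return matrix


def select_key_positions(
    freqs: ContactFrequencyTable, min_ratio: float = 0.5, min_occurrence: int = 1
) -> dict[str, set[str]]:
    """Positions qualifying as key interface residues, per chain type.

    A position qualifies when it occurs at least ``min_occurrence`` times and
    is in contact in at least a ``min_ratio`` fraction of its occurrences.
    """
    if not any(freqs.by_chain.values()):
        raise EmptyResultError("empty contact frequency table")
    return {
        ct: {
            pos
            for pos, st in positions.items()
            if st.n_occurrence >= min_occurrence and st.ratio >= min_ratio
        }
        for ct, positions in freqs.by_chain.items()
    }


# ---------------------------------------------------------------------------
# Vernier comparison
# ---------------------------------------------------------------------------

def load_vernier_positions() -> dict[str, set[str]]:
    """Vernier-zone framework positions (Foote & Winter) in IMGT numbering.

    Loaded from the editable package data file ``data/vernier_imgt.tsv``; the
    Kabat-to-IMGT translation shipped there is approximate for loop-adjacent
    positions (see the file header) and meant to be replaced by users with
    their preferred lookup.
    """
    out: dict[str, set[str]] = {"H": set(), "L": set()}
    text = resources.files("pairedab").joinpath("data/vernier_imgt.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chain_type, imgt_pos, _kabat = line.split("\t")
        if chain_type == "chain_type":
            continue
        out[chain_type].add(imgt_pos)
    return out


def vernier_overlap(key_set: set[str], vernier_set: set[str]) -> dict:
    """Set overlap between key interface residues and Vernier positions."""
    union = key_set | vernier_set
    if not union:
        raise EmptyResultError("both position sets are empty; Jaccard undefined")
    inter = key_set & vernier_set
    return {
        "intersection": inter,
        "key_only": key_set - vernier_set,
        "vernier_only": vernier_set - key_set,
        "jaccard": len(inter) / len(union),
    }
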