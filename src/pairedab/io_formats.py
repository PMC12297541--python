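"""Readers, writers and domain containers for paired-repertoire and structure data.

The pipeline exchanges three plain-text formats:

* AIRR-style rearrangement TSV, one row per assembled chain, curated at read
  time to one heavy + one light chain per cell (highest mean assembly
  coverage wins, as in the source database's curation).
* PDB files for antibody Fv structures, accompanied by a 5-column numbering
  map TSV assigning IMGT positions to author residue numbers (IMGT numbering
  itself is delegated to external tools such as ANARCI/RIOT).
* RFC-4180 CSV for all result tables (written with pandas).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    DataError,
    EmptyResultError,
    GeneLabelError,
    SchemaError,
)

logger = logging.getLogger(__name__)

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: symbols allowed at an IMGT position: 20 canonical amino acids plus X (unknown)
AA_SYMBOLS = CANONICAL_AA | {"X"}
STOP_SYMBOL = "*"
GAP_CHARS = frozenset(".-")

#: mandatory columns of the paired AIRR dialect ("barcode" is accepted for cell_id)
AIRR_COLUMNS = (
    "study_id",
    "cell_id",
    "locus",
    "productive",
    "v_call",
    "j_call",
    "c_call",
    "consensus_coverage",
    "sequence",
    "sequence_aa",
    "sequence_alignment_aa",
)

_IMGT_POS_RE = re.compile(r"^(\d+)([A-Z]?)$")
_GENE_RE = re.compile(r"^(IGH|IGK|IGL)([VDJC]?)")

AA_3LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}
AA_1LETTER = {v: k for k, v in AA_3LETTER.items()}


def imgt_sort_key(position: str) -> tuple[int, str]:
    """Sort key for IMGT position ids: integer part, then insertion letter."""
    m = _IMGT_POS_RE.match(position)
    if not m:
        raise DataError(f"invalid IMGT position id: {position!r}")
    return int(m.group(1)), m.group(2)


def imgt_integer(position: str) -> int:
    """Integer part of an IMGT position id ('111A' -> 111)."""
    return imgt_sort_key(position)[0]


# ---------------------------------------------------------------------------
# gene labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLabel:
    """A parsed immunoglobulin gene call such as ``IGHV3-23*01``.

    ``subgroup`` is the token before the first hyphen (``IGHV3``); ``gene``
    carries the hyphenated gene name when present; ``allele`` the two-digit
    designation after ``*``.
    """

    raw: str
    locus: str
    subgroup: str
    gene: str | None
    allele: str | None
    segment: str

    def serialize(self) -> str:
        """Canonical ``gene*allele`` text (reproduces ``raw`` for single calls)."""
        base = self.gene if self.gene is not None else self.subgroup
        return f"{base}*{self.allele}" if self.allele is not None else base


def parse_gene_label(raw: str) -> GeneLabel:
    """Parse a V/D/J/C gene call into locus, subgroup, gene and allele.

    Multi-gene ambiguous calls (comma-separated) resolve to the first listed
    call. The segment is read from the fourth character when it is one of
    V/D/J; anything else (IGKC, IGHM, IGHG1 ...) is treated as a constant
    gene. Note this means the heavy-chain delta constant gene ``IGHD`` is
    reported as segment ``D``; callers working with c_calls should rely on
    the locus and subgroup fields instead.
    """
    if not raw:
        raise GeneLabelError("empty gene call")
    first = raw.split(",")[0].strip()
    m = _GENE_RE.match(first)
    if not m:
        raise GeneLabelError(f"gene call {first!r} does not start with IGH/IGK/IGL")
    locus = m.group(1)
    segment = m.group(2) if m.group(2) in ("V", "D", "J") else "C"
    body, _, allele = first.partition("*")
    subgroup, hyphen, _ = body.partition("-")
    gene = body if hyphen else None
    return GeneLabel(
        raw=first,
        locus=locus,
        subgroup=subgroup,
        gene=gene,
        allele=allele or None,
        segment=segment,
    )


# ---------------------------------------------------------------------------
# paired records
# ---------------------------------------------------------------------------

@dataclass
class ChainAnnotation:
    """Curated annotations for one assembled chain of a cell."""

    locus: str
    v_call: GeneLabel | None
    j_call: GeneLabel | None
    c_call: GeneLabel | None
    productive: bool
    coverage: float
    sequence_nt: str
    sequence_aa: str
    imgt_positions: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.productive and STOP_SYMBOL in self.sequence_aa:
            raise DataError("productive chain contains a stop symbol")
        for pos, aa in self.imgt_positions.items():
            imgt_sort_key(pos)
            if aa not in AA_SYMBOLS:
                raise DataError(f"invalid amino-acid symbol {aa!r} at IMGT {pos}")


@dataclass
class PairedRecord:
    """One cell's heavy + light chain pair with study provenance."""

    study_id: str
    cell_id: str
    heavy: ChainAnnotation
    light: ChainAnnotation
    organism: str = "human"

    def validate(self) -> None:
        if self.heavy.locus != "IGH":
            raise DataError(f"heavy chain locus {self.heavy.locus!r} != IGH")
        if self.light.locus not in ("IGK", "IGL"):
            raise DataError(f"light chain locus {self.light.locus!r} not IGK/IGL")
        if not (self.heavy.productive and self.light.productive):
            raise DataError("paired record contains a non-productive chain")


@dataclass
class PairedDataset:
    """A curated collection of paired records; (study_id, cell_id) is unique."""

    records: list[PairedRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.study_id, rec.cell_id)
            if key in seen:
                raise DataError(f"duplicate (study, cell) key {key}")
            seen.add(key)
            rec.validate()


# ---------------------------------------------------------------------------
# IMGT-gapped alignment strings
# ---------------------------------------------------------------------------

def gapped_to_positions(alignment_aa: str) -> dict[str, str]:
    """Decode an IMGT-gapped amino-acid alignment into a position -> symbol map.

    Column *i* (1-based) of the gapped string is IMGT position *i*; gap
    characters ('.' or '-') mean the position is absent.
    """
    out: dict[str, str] = {}
    for i, aa in enumerate(alignment_aa.strip(), start=1):
        if aa in GAP_CHARS:
            continue
        out[str(i)] = aa
    return out


def positions_to_gapped(positions: Mapping[str, str], length: int = 128) -> str:
    """Encode integer IMGT positions as a gapped string ('.' for absences).

    Insertion-lettered positions (e.g. '111A') cannot be represented in the
    plain 128-column layout and raise.
    """
    chars = ["."] * length
    for pos, aa in positions.items():
        n, letter = imgt_sort_key(pos)
        if letter:
            raise DataError(f"insertion position {pos} not representable in gapped string")
        if not 1 <= n <= length:
            raise DataError(f"IMGT position {pos} outside 1..{length}")
        chars[n - 1] = aa
    return "".join(chars)


# ---------------------------------------------------------------------------
# paired AIRR TSV
# ---------------------------------------------------------------------------

def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("t", "true", "1", "yes")


def _maybe_gene(text: str) -> GeneLabel | None:
    text = text.strip()
    return parse_gene_label(text) if text else None


def read_paired_airr(path: str | Path, min_fields: Iterable[str] = AIRR_COLUMNS) -> PairedDataset:
    """Read a paired AIRR-style TSV and curate it to one H+L pair per cell.

    Non-productive rows are dropped; among a cell's surviving rows of one
    chain class the highest-coverage row is kept (ties broken by
    lexicographically smallest nucleotide sequence); cells lacking either a
    heavy or a light survivor are dropped entirely.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        columns = {name: i for i, name in enumerate(header)}
        if "barcode" in columns and "cell_id" not in columns:
            columns["cell_id"] = columns["barcode"]
        missing = [c for c in min_fields if c not in columns]
        if missing:
            raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")

        # (study, cell) -> {"H": [rows], "L": [rows]}
        cells: dict[tuple[str, str], dict[str, list[dict]]] = {}
        order: list[tuple[str, str]] = []
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            row = {name: fields[idx] for name, idx in columns.items() if idx < len(fields)}
            if not _parse_bool(row.get("productive", "")):
                continue
            locus = row["locus"].strip()
            chain_class = "H" if locus == "IGH" else "L"
            key = (row["study_id"], row["cell_id"])
            if key not in cells:
                cells[key] = {"H": [], "L": []}
                order.append(key)
            cells[key][chain_class].append(row)

    records: list[PairedRecord] = []
    for key in order:
        groups = cells[key]
        if not groups["H"] or not groups["L"]:
            continue
        chosen = {}
        for cls in ("H", "L"):
            chosen[cls] = max(
                groups[cls],
                key=lambda r: (float(r["consensus_coverage"]), _NegStr(r["sequence"])),
            )
        records.append(
            PairedRecord(
                study_id=key[0],
                cell_id=key[1],
                heavy=_row_to_chain(chosen["H"]),
                light=_row_to_chain(chosen["L"]),
                organism=groups["H"][0].get("organism", "human") or "human",
            )
        )
    if not records:
        raise EmptyResultError(f"no cells with a productive heavy+light pair in {path}")
    dataset = PairedDataset(records=records, provenance=f"read from {path.name}")
    dataset.validate()
    return dataset


class _NegStr:
    """Reverses string comparison so max() prefers the lexicographically smaller."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s


def _row_to_chain(row: dict) -> ChainAnnotation:
    chain = ChainAnnotation(
        locus=row["locus"].strip(),
        v_call=_maybe_gene(row.get("v_call", "")),
        j_call=_maybe_gene(row.get("j_call", "")),
        c_call=_maybe_gene(row.get("c_call", "")),
        productive=True,
        coverage=float(row["consensus_coverage"]),
        sequence_nt=row["sequence"].strip(),
        sequence_aa=row["sequence_aa"].strip(),
        imgt_positions=gapped_to_positions(row.get("sequence_alignment_aa", "")),
    )
    chain.validate()
    return chain


def write_paired_airr(dataset: PairedDataset, path: str | Path) -> Path:
    """Write a PairedDataset as a paired AIRR TSV (two rows per record)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(AIRR_COLUMNS + ("organism",)) + "\n")
        for rec in dataset:
            for chain in (rec.heavy, rec.light):
                fh.write(
                    "\t".join(
                        (
                            rec.study_id,
                            rec.cell_id,
                            chain.locus,
                            "T" if chain.productive else "F",
                            chain.v_call.serialize() if chain.v_call else "",
                            chain.j_call.serialize() if chain.j_call else "",
                            chain.c_call.serialize() if chain.c_call else "",
                            repr(chain.coverage),
                            chain.sequence_nt,
                            chain.sequence_aa,
                            positions_to_gapped(chain.imgt_positions),
                            rec.organism,
                        )
                    )
                    + "\n"
                )
    return path


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    amino_acid: str
    atoms: list[Atom]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructChain:
    chain_id: str
    chain_type: str  # "H" or "L"
    residues: dict[str, Residue]  # IMGT position id -> residue


@dataclass
class AnnotatedStructure:
    structure_id: str
    chains: list[StructChain]

    def chain(self, chain_id: str) -> StructChain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


def read_numbering_map(path: str | Path) -> dict[tuple[str, int, str], tuple[str, str]]:
    """Read a numbering map TSV: chain, resnum, icode, chain_type, imgt_position.

    An icode of '-' (or empty) means no insertion code. Returns a mapping
    (chain id, author resnum, icode) -> (chain_type, IMGT position id).
    """
    mapping: dict[tuple[str, int, str], tuple[str, str]] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["chain", "resnum", "icode", "chain_type", "imgt_position"]
        if header != required:
            raise SchemaError(f"numbering map header must be {required}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            chain, resnum, icode, chain_type, imgt_pos = line.rstrip("\n").split("\t")
            icode = "" if icode in ("-", "") else icode
            imgt_sort_key(imgt_pos)
            if chain_type not in ("H", "L"):
                raise DataError(f"chain_type must be H or L, got {chain_type!r}")
            mapping[(chain, int(resnum), icode)] = (chain_type, imgt_pos)
    return mapping


def write_numbering_map(
    mapping: Mapping[tuple[str, int, str], tuple[str, str]], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("chain\tresnum\ticode\tchain_type\timgt_position\n")
        for (chain, resnum, icode), (chain_type, imgt_pos) in mapping.items():
            fh.write(f"{chain}\t{resnum}\t{icode or '-'}\t{chain_type}\t{imgt_pos}\n")
    return path


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def read_structure(pdb_path: str | Path, numbering_map: str | Path) -> AnnotatedStructure:
    """Read a PDB file plus its residue -> IMGT numbering map.

    Residues without a map entry (waters, ligands, unnumbered residues) are
    excluded. For disordered atoms only the highest-occupancy altloc is
    retained. Atoms with a blank element column get their element inferred
    from the atom-name convention (logged).
    """
    from Bio.PDB import PDBParser

    pdb_path = Path(pdb_path)
    mapping = read_numbering_map(numbering_map)
    parser = PDBParser(QUIET=True)
    model = parser.get_structure(pdb_path.stem, str(pdb_path))[0]

    chains: dict[str, StructChain] = {}
    seen_keys: set[tuple[str, int, str]] = set()
    for chain in model:
        for residue in chain:
            het, resnum, icode = residue.id
            key = (chain.id, resnum, icode.strip())
            if key not in mapping:
                continue
            seen_keys.add(key)
            chain_type, imgt_pos = mapping[key]
            atoms: list[Atom] = []
            for atom in residue:
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0)
                element = (atom.element or "").strip()
                if not element:
                    element = _infer_element(atom.get_name())
                    logger.info(
                        "inferred element %r for atom %s in %s", element, atom.get_name(), pdb_path.name
                    )
                x, y, z = (float(v) for v in atom.get_coord())
                atoms.append(Atom(name=atom.get_name(), element=element, x=x, y=y, z=z))
            resname = residue.get_resname().strip()
            sc = chains.setdefault(chain.id, StructChain(chain.id, chain_type, {}))
            sc.residues[imgt_pos] = Residue(
                amino_acid=AA_1LETTER.get(resname, "X"), atoms=atoms
            )

    missing = sorted(set(mapping) - seen_keys)
    if missing:
        names = ", ".join(f"{c}/{n}{i}" for c, n, i in missing)
        raise DataError(f"numbering map references absent residues: {names}")
    if not chains:
        raise EmptyResultError(f"no mapped chains in {pdb_path}")
    return AnnotatedStructure(structure_id=pdb_path.stem, chains=list(chains.values()))


def write_structure_pdb(structure: AnnotatedStructure, path: str | Path) -> Path:
    """Write an AnnotatedStructure as a minimal (deterministic) PDB file.

    Residues are numbered sequentially per chain in IMGT order; use
    :func:`structure_numbering_map` for the matching sidecar map.
    """
    path = Path(path)
    serial = 1
    with path.open("w") as fh:
        for chain in structure.chains:
            resseq = 0
            for pos in sorted(chain.residues, key=imgt_sort_key):
                resseq += 1
                res = chain.residues[pos]
                resname = AA_3LETTER.get(res.amino_acid, "UNK")
                for atom in res.atoms:
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    fh.write(
                        f"ATOM  {serial:>5d} {name}{'':1s}{resname:>3s} {chain.chain_id:1s}"
                        f"{resseq:>4d}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
                    )
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")
    return path


def structure_numbering_map(
    structure: AnnotatedStructure,
) -> dict[tuple[str, int, str], tuple[str, str]]:
    """Numbering map matching :func:`write_structure_pdb`'s residue numbering."""
    mapping: dict[tuple[str, int, str], tuple[str, str]] = {}
    for chain in structure.chains:
        for resseq, pos in enumerate(sorted(chain.residues, key=imgt_sort_key), start=1):
            mapping[(chain.chain_id, resseq, "")] = (chain.chain_type, pos)
    return mapping
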