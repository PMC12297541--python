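"""Synthetic paired repertoires, incidence structures and toy Fv structures.

Every downstream statistic in this package is exercised against data with
*known* ground truth, generated here:

* :func:`simulate_paired_repertoire` draws heavy/light germline pairs from a
  renormalized ``enrichment x (product of marginals)`` joint — the minimal
  alternative hypothesis to "pairing follows usage frequencies" — together
  with per-IMGT-position amino acids (optionally coupled across chains),
  random nucleotide backfill, and cross-study clone sharing for incidence
  counting. Defaults emulate a human repertoire: IGHV3-dominated heavy
  usage, a 60:40 kappa:lambda split, IGHJ4-dominated heavy J usage.
* :func:`simulate_incidence` produces study -> key-set structures where each
  of ``true_richness`` clones is detected independently per study.
* :func:`simulate_interface_structures` builds toy two-chain 3D structures
  whose cross-chain contacts are placed by construction: designed pairs at
  3.6-4.2 Angstrom, everything else beyond 6, with jitter bounded so no
  classification against the 4.5 / 20 Angstrom thresholds can flip.

Each generator uses its own RNG stream derived from the config seed plus a
fixed stream id, so adding a generator never shifts existing draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .io_formats import (
    AnnotatedStructure,
    Atom,
    ChainAnnotation,
    PairedDataset,
    PairedRecord,
    Residue,
    StructChain,
    imgt_sort_key,
    parse_gene_label,
)

_STREAM_REPERTOIRE = 1
_STREAM_INCIDENCE = 2
_STREAM_STRUCTURE = 3

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_HEAVY_V_USAGE = {
    "IGHV1": 0.14, "IGHV2": 0.04, "IGHV3": 0.40, "IGHV4": 0.22,
    "IGHV5": 0.07, "IGHV6": 0.06, "IGHV7": 0.07,
}
DEFAULT_LIGHT_V_USAGE = {
    "IGK": {"IGKV1": 0.35, "IGKV2": 0.15, "IGKV3": 0.30, "IGKV4": 0.12, "IGKV5": 0.08},
    "IGL": {"IGLV1": 0.30, "IGLV2": 0.30, "IGLV3": 0.25, "IGLV6": 0.10, "IGLV7": 0.05},
}
DEFAULT_J_USAGE = {
    "IGH": {"IGHJ1": 0.02, "IGHJ2": 0.05, "IGHJ3": 0.10, "IGHJ4": 0.50,
            "IGHJ5": 0.13, "IGHJ6": 0.20},
    "IGK": {"IGKJ1": 0.30, "IGKJ2": 0.25, "IGKJ3": 0.20, "IGKJ4": 0.15, "IGKJ5": 0.10},
    "IGL": {"IGLJ1": 0.15, "IGLJ2": 0.35, "IGLJ3": 0.35, "IGLJ7": 0.15},
}
DEFAULT_C_USAGE = {
    "IGH": {"IGHM": 0.60, "IGHG1": 0.25, "IGHA1": 0.15},
    "IGK": {"IGKC": 1.0},
    "IGL": {"IGLC2": 0.45, "IGLC1": 0.30, "IGLC3": 0.25},
}

#: default per-position amino-acid profiles: conserved cysteines at 23/104,
#: concentrated framework positions, broader CDR3 positions.
DEFAULT_POSITION_PROFILES = {
    ("H", "23"): {"C": 1.0},
    ("H", "40"): {"A": 0.55, "G": 0.25, "S": 0.20},
    ("H", "42"): {"W": 0.90, "F": 0.10},
    ("H", "44"): {"G": 0.60, "R": 0.25, "S": 0.15},
    ("H", "104"): {"C": 1.0},
    ("H", "105"): {"A": 0.40, "T": 0.25, "V": 0.20, "G": 0.15},
    ("H", "106"): {"R": 0.45, "K": 0.25, "S": 0.15, "T": 0.15},
    ("H", "107"): {"D": 0.30, "G": 0.25, "E": 0.20, "S": 0.15, "Y": 0.10},
    ("H", "118"): {"W": 0.95, "F": 0.05},
    ("L", "23"): {"C": 1.0},
    ("L", "40"): {"P": 0.60, "S": 0.25, "A": 0.15},
    ("L", "44"): {"P": 0.70, "L": 0.20, "V": 0.10},
    ("L", "87"): {"Y": 0.55, "F": 0.30, "H": 0.15},
    ("L", "104"): {"C": 1.0},
    ("L", "105"): {"Q": 0.50, "S": 0.20, "A": 0.20, "G": 0.10},
    ("L", "106"): {"Q": 0.45, "S": 0.30, "A": 0.25},
    ("L", "116"): {"P": 0.40, "L": 0.30, "R": 0.20, "W": 0.10},
    ("L", "118"): {"F": 0.85, "L": 0.15},
}


def _check_probs(name: str, probs: dict[str, float]) -> None:
    if not probs:
        raise ConfigError(f"{name}: empty probability vector")
    total = sum(probs.values())
    if any(p < 0 or not math.isfinite(p) for p in probs.values()):
        raise ConfigError(f"{name}: probabilities must be finite and non-negative")
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {total}, not 1")


@dataclass
class RepertoireConfig:
    """Stated world for the paired-repertoire generator (defaults = human-like)."""

    heavy_v_usage: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HEAVY_V_USAGE))
    light_v_usage: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LIGHT_V_USAGE.items()})
    j_usage: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_J_USAGE.items()})
    kappa_fraction: float = 0.60  # established human kappa:lambda consensus 60:40
    enrichment: dict[tuple[str, str], float] = field(default_factory=dict)
    n_cells: int = 10_000
    n_studies: int = 2
    share_prob: float = 0.001
    position_profiles: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_POSITION_PROFILES.items()})
    coupling: list[tuple[str, str, dict[tuple[str, str], float]]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        _check_probs("heavy_v_usage", self.heavy_v_usage)
        for locus, usage in self.light_v_usage.items():
            _check_probs(f"light_v_usage[{locus}]", usage)
        for locus, usage in self.j_usage.items():
            _check_probs(f"j_usage[{locus}]", usage)
        if not 0.0 <= self.kappa_fraction <= 1.0:
            raise ConfigError("kappa_fraction must be in [0, 1]")
        for pair, factor in self.enrichment.items():
            if not math.isfinite(factor) or factor < 0:
                raise ConfigError(f"enrichment factor for {pair} must be finite and >= 0")
        if self.n_cells <= 0:
            raise ConfigError("n_cells must be positive")
        if self.n_studies <= 0:
            raise ConfigError("n_studies must be positive")
        if not 0.0 <= self.share_prob <= 1.0:
            raise ConfigError("share_prob must be a probability")
        for key, profile in self.position_profiles.items():
            _check_probs(f"position_profiles[{key}]", profile)
        for h_pos, l_pos, joint in self.coupling:
            _check_probs(f"coupling[({h_pos},{l_pos})]", {str(k): v for k, v in joint.items()})


def pair_probabilities(config: RepertoireConfig):
    """Renormalized joint (heavy subgroup, light subgroup) distribution.

    Light subgroups pool kappa and lambda, weighted by ``kappa_fraction``.
    The joint is ``enrichment[(h, l)] * p_h * p_l`` renormalized to sum 1.
    Returns (heavy labels, light labels, light locus per label, prob matrix).
    """
    config.validate()
    h_labels = sorted(config.heavy_v_usage)
    l_labels: list[str] = []
    l_locus: list[str] = []
    l_probs: list[float] = []
    locus_weight = {"IGK": config.kappa_fraction, "IGL": 1.0 - config.kappa_fraction}
    for locus in ("IGK", "IGL"):
        for sub in sorted(config.light_v_usage.get(locus, {})):
            l_labels.append(sub)
            l_locus.append(locus)
            l_probs.append(locus_weight[locus] * config.light_v_usage[locus][sub])
    h_probs = np.array([config.heavy_v_usage[h] for h in h_labels])
    joint = np.outer(h_probs, np.array(l_probs))
    for (h, l), factor in config.enrichment.items():
        if h in h_labels and l in l_labels:
            joint[h_labels.index(h), l_labels.index(l)] *= factor
    total = joint.sum()
    if total <= 0:
        raise ConfigError("pair distribution has zero mass after enrichment")
    return h_labels, l_labels, l_locus, joint / total


def _random_strings(rng: np.random.Generator, n: int, length: int, alphabet: np.ndarray):
    idx = rng.integers(0, len(alphabet), size=(n, length))
    codes = alphabet[idx]
    return [bytes(row).decode("ascii") for row in codes]


def _draw_symbols(rng: np.random.Generator, profile: dict[str, float], n: int) -> np.ndarray:
    symbols = sorted(profile)
    p = np.array([profile[s] for s in symbols])
    return np.array(symbols, dtype=object)[rng.choice(len(symbols), size=n, p=p)]


def simulate_paired_repertoire(config: RepertoireConfig) -> PairedDataset:
    """Draw a paired repertoire from the configured stated world.

    Deterministic for a fixed ``config.seed``. Clones are re-emitted into a
    different study (same sequences, a new cell id) with ``share_prob``,
    feeding the incidence-based richness machinery.
    """
    h_labels, l_labels, l_locus, joint = pair_probabilities(config)
    rng = np.random.default_rng([config.seed, _STREAM_REPERTOIRE])
    n = config.n_cells

    flat = joint.ravel()
    pair_idx = rng.choice(flat.size, size=n, p=flat)
    h_idx, l_idx = np.unravel_index(pair_idx, joint.shape)
    studies = rng.integers(0, config.n_studies, size=n)

    # gene calls, drawn per locus
    h_j = _draw_symbols(rng, config.j_usage["IGH"], n)
    h_c = _draw_symbols(rng, DEFAULT_C_USAGE["IGH"], n)
    locus_arr = np.array([l_locus[i] for i in l_idx], dtype=object)
    l_j = np.empty(n, dtype=object)
    l_c = np.empty(n, dtype=object)
    for locus in ("IGK", "IGL"):
        mask = locus_arr == locus
        m = int(mask.sum())
        if m:
            l_j[mask] = _draw_symbols(rng, config.j_usage[locus], m)
            l_c[mask] = _draw_symbols(rng, DEFAULT_C_USAGE[locus], m)

    # per-position amino acids (independent draws, then coupling overrides)
    positions = {
        "H": sorted((p for ct, p in config.position_profiles if ct == "H"), key=imgt_sort_key),
        "L": sorted((p for ct, p in config.position_profiles if ct == "L"), key=imgt_sort_key),
    }
    symbols = {
        (ct, pos): _draw_symbols(rng, config.position_profiles[(ct, pos)], n)
        for ct in ("H", "L")
        for pos in positions[ct]
    }
    for h_pos, l_pos, joint_profile in config.coupling:
        pairs = sorted(joint_profile)
        p = np.array([joint_profile[k] for k in pairs])
        drawn = rng.choice(len(pairs), size=n, p=p)
        symbols[("H", h_pos)] = np.array([pairs[i][0] for i in drawn], dtype=object)
        symbols[("L", l_pos)] = np.array([pairs[i][1] for i in drawn], dtype=object)
    for h_pos, l_pos, _ in config.coupling:
        if h_pos not in positions["H"]:
            positions["H"] = sorted(positions["H"] + [h_pos], key=imgt_sort_key)
        if l_pos not in positions["L"]:
            positions["L"] = sorted(positions["L"] + [l_pos], key=imgt_sort_key)

    junction = {
        ct: _random_strings(rng, n, 10, np.frombuffer(_AA20.encode(), dtype=np.uint8))
        for ct in ("H", "L")
    }
    backfill = {ct: _random_strings(rng, n, 48, _NT) for ct in ("H", "L")}
    coverage = np.round(rng.uniform(10.0, 100.0, size=(n, 2)), 2)

    gene_cache: dict[str, object] = {}

    def _gene(label: str):
        if label not in gene_cache:
            gene_cache[label] = parse_gene_label(label)
        return gene_cache[label]

    records: list[PairedRecord] = []
    for i in range(n):
        h_sub, l_sub = h_labels[h_idx[i]], l_labels[l_idx[i]]
        locus = l_locus[l_idx[i]]
        chains = {}
        for ct, (loc, v_sub, j_lab, c_lab, cov) in {
            "H": ("IGH", h_sub, h_j[i], h_c[i], coverage[i, 0]),
            "L": (locus, l_sub, l_j[i], l_c[i], coverage[i, 1]),
        }.items():
            imgt = {pos: str(symbols[(ct, pos)][i]) for pos in positions[ct]}
            seq_aa = "".join(imgt[p] for p in positions[ct]) + junction[ct][i]
            chains[ct] = ChainAnnotation(
                locus=loc,
                v_call=_gene(f"{v_sub}-1*01" if "-" not in v_sub else f"{v_sub}*01"),
                j_call=_gene(f"{j_lab}*01"),
                c_call=_gene(c_lab),
                productive=True,
                coverage=float(cov),
                sequence_nt=backfill[ct][i],
                sequence_aa=seq_aa,
                imgt_positions=imgt,
            )
        records.append(
            PairedRecord(
                study_id=f"study{studies[i]:02d}",
                cell_id=f"cell{i:07d}",
                heavy=chains["H"],
                light=chains["L"],
            )
        )

    if config.n_studies > 1 and config.share_prob > 0:
        share_mask = rng.random(n) < config.share_prob
        offsets = rng.integers(1, config.n_studies, size=n)
        for i in np.nonzero(share_mask)[0]:
            src = records[i]
            new_study = (studies[i] + offsets[i]) % config.n_studies
            records.append(
                replace(src, study_id=f"study{new_study:02d}", cell_id=f"cell{i:07d}s")
            )

    return PairedDataset(records=records, provenance=f"simulated, seed={config.seed}")


def simulate_incidence(
    true_richness: int, n_studies: int, detect_prob: float, seed: int = 0
) -> dict[str, set[str]]:
    """Independent per-study detection of ``true_richness`` distinct clones.

    Each clone is present in each study independently with ``detect_prob``;
    returns a study -> set-of-keys mapping for the incidence counter.
    """
    if true_richness <= 0:
        raise ConfigError("true_richness must be positive")
    if not 0.0 < detect_prob <= 1.0:
        raise ConfigError("detect_prob must be in (0, 1]")
    if n_studies <= 0:
        raise ConfigError("n_studies must be positive")
    rng = np.random.default_rng([seed, _STREAM_INCIDENCE])
    keys = np.array([f"sp{i:06d}" for i in range(true_richness)], dtype=object)
    out: dict[str, set[str]] = {}
    for s in range(n_studies):
        mask = rng.random(true_richness) < detect_prob
        out[f"study{s:02d}"] = set(keys[mask])
    return out


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

_RESIDUE_SPACING = 8.0  # Angstrom between consecutive residues along a chain
_CHAIN_SEPARATION = 50.0  # baseline z-offset between the H and L chains
_DESIGNED_RANGE = (3.6, 4.2)  # designed contact min-distance band
_CONTACT_MARGIN = 0.3  # distance to the 4.5 Angstrom classification boundary
# worst-case displacement of one atom pair: two atoms, each moved by up to
# 3 sigma in each of 3 coordinates -> 2 * 3 * sqrt(3) * sigma
_JITTER_FACTOR = 2 * 3 * math.sqrt(3.0)


@dataclass
class StructureConfig:
    """Stated world for the toy-structure generator."""

    designed_contacts: set[tuple[str, str]] = field(
        default_factory=lambda: {("105", "40"), ("106", "44"), ("40", "107")})
    cys104_separation: float = 16.0
    n_structures: int = 10
    jitter_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.cys104_separation <= 6.5:
            raise ConfigError("cys104_separation must exceed 6.5 Angstrom")
        if self.n_structures <= 0:
            raise ConfigError("n_structures must be positive")
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be non-negative")
        if self.jitter_sd * _JITTER_FACTOR > _CONTACT_MARGIN:
            raise ConfigError(
                f"jitter_sd={self.jitter_sd} can move atom pairs across the 4.5 Angstrom "
                f"boundary (margin {_CONTACT_MARGIN} Angstrom)"
            )
        if abs(self.cys104_separation - 20.0) <= self.jitter_sd * _JITTER_FACTOR:
            raise ConfigError("cys104_separation too close to the 20 Angstrom pairing threshold")
        l_moved = [l for _, l in self.designed_contacts]
        if len(l_moved) != len(set(l_moved)):
            raise ConfigError("each light position may appear in at most one designed contact")
        if "104" in l_moved:
            raise ConfigError("light position 104 is reserved for the Cys104 anchor")
        for h, l in self.designed_contacts:
            for pos in (h, l):
                n, _ = imgt_sort_key(pos)
                if not 1 <= n <= 128:
                    raise ConfigError(f"designed contact position {pos} outside IMGT 1..128")


def _toy_residue(aa: str, base: np.ndarray) -> Residue:
    atoms = [
        Atom("CA", "C", *(base + np.array([0.0, 0.0, 0.0]))),
        Atom("CB", "C", *(base + np.array([0.0, 1.5, 0.0]))),
    ]
    if aa == "C":
        atoms.append(Atom("SG", "S", *(base + np.array([0.0, 2.8, 0.0]))))
    return Residue(amino_acid=aa, atoms=atoms)


def simulate_interface_structures(
    config: StructureConfig,
) -> tuple[list[AnnotatedStructure], frozenset[tuple[str, str]]]:
    """Toy two-chain structures with contacts placed by construction.

    Both chains carry IMGT positions 1..128 (Cys at 104, Ala elsewhere).
    Designed (H, L) contact pairs get minimum heavy-atom distances in the
    3.6-4.2 Angstrom band; all other cross-chain residue pairs stay beyond
    6 Angstrom; the two Cys-104 Calpha atoms sit ``cys104_separation``
    apart. Gaussian jitter (clipped at 3 sigma) is bounded by validation so
    the 4.5 / 20 Angstrom classifications cannot flip. Returns the
    structures plus the designed contact set (the ground-truth contact map
    shared by every structure).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_STRUCTURE])
    all_positions = [str(i) for i in range(1, 129)]
    x_of = {pos: i * _RESIDUE_SPACING for i, pos in enumerate(all_positions)}
    designed = sorted(config.designed_contacts)

    structures: list[AnnotatedStructure] = []
    for s in range(config.n_structures):
        bases: dict[tuple[str, str], np.ndarray] = {}
        for pos in all_positions:
            bases[("H", pos)] = np.array([x_of[pos], 0.0, 0.0])
            bases[("L", pos)] = np.array([x_of[pos], 0.0, _CHAIN_SEPARATION])
        bases[("L", "104")] = bases[("H", "104")] + np.array(
            [0.0, 0.0, config.cys104_separation])
        for h_pos, l_pos in designed:
            d = rng.uniform(*_DESIGNED_RANGE)
            bases[("L", l_pos)] = bases[("H", h_pos)] + np.array([0.0, 0.0, d])

        chains = []
        for ct in ("H", "L"):
            residues = {}
            for pos in all_positions:
                aa = "C" if pos in ("23", "104") else "A"
                res = _toy_residue(aa, bases[(ct, pos)])
                if config.jitter_sd > 0:
                    for atom in res.atoms:
                        noise = np.clip(
                            rng.normal(0.0, config.jitter_sd, size=3),
                            -3 * config.jitter_sd,
                            3 * config.jitter_sd,
                        )
                        atom.x += float(noise[0])
                        atom.y += float(noise[1])
                        atom.z += float(noise[2])
                residues[pos] = res
            chains.append(StructChain(chain_id=ct, chain_type=ct, residues=residues))
        structures.append(AnnotatedStructure(structure_id=f"toy{s:03d}", chains=chains))
    return structures, frozenset(config.designed_contacts)
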