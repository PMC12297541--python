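"""End-to-end orchestration: simulate -> analyze -> report, from one config.

``run_pipeline`` executes the enabled stages in dependency order, writes all
result tables as CSV under the configured output directory, and records a
JSON run manifest (parameter echo, seeds, SHA-256 digests of every written
file). Identical config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aa_profiles as aap
from . import interface_contacts as ic
from . import pairing_stats as ps
from . import richness as rich
from .errors import ConfigError, EmptyResultError, TestNotApplicableError
from .io_formats import (
    read_paired_airr,
    read_structure,
    structure_numbering_map,
    write_numbering_map,
    write_paired_airr,
    write_structure_pdb,
)
from .synthetic_data import (
    RepertoireConfig,
    StructureConfig,
    simulate_interface_structures,
    simulate_paired_repertoire,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "richness", "pairing", "contacts", "aa_profiles")


@dataclass
class PipelineConfig:
    """One config object driving a full run; see field defaults for units."""

    out_dir: Path = Path("pairedab_run")
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # inputs: either simulation configs or paths to existing data
    repertoire: RepertoireConfig | None = None
    structures: StructureConfig | None = None
    airr_path: Path | None = None
    pdb_dir: Path | None = None
    # analysis parameters
    key_mode: str = "nucleotide"
    min_pair_count: int = 5
    alpha: float = 0.05
    contact_cutoff: float = ic.CONTACT_CUTOFF
    cys104_max_dist: float = ic.CYS104_MAX_DIST
    key_min_ratio: float = 0.5
    key_min_occurrence: int = 1
    pair_null_mode: str = "analytic"

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages:
            if self.airr_path is not None and not Path(self.airr_path).exists():
                raise ConfigError(f"airr_path {self.airr_path} does not exist")
            if self.pdb_dir is not None and not Path(self.pdb_dir).exists():
                raise ConfigError(f"pdb_dir {self.pdb_dir} does not exist")
        if self.pair_null_mode not in ("analytic", "permutation"):
            raise ConfigError("pair_null_mode must be 'analytic' or 'permutation'")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("repertoire", "structures"):
        if key in raw and raw[key] is not None:
            cls = RepertoireConfig if key == "repertoire" else StructureConfig
            section = dict(raw[key])
            if key == "repertoire" and "enrichment" in section:
                section["enrichment"] = {tuple(k.split(":")): v
                                         for k, v in section["enrichment"].items()}
            if key == "structures" and "designed_contacts" in section:
                section["designed_contacts"] = {
                    tuple(str(p) for p in pair) for pair in section["designed_contacts"]}
            raw[key] = cls(**section)
    if "out_dir" in raw:
        raw["out_dir"] = Path(raw["out_dir"])
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return sorted((_jsonable(v) for v in obj), key=str) if isinstance(obj, (set, frozenset)) \
            else [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return the run manifest (also written to disk).

    A stage failure aborts the run but still writes a manifest recording the
    stages completed so far.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": _jsonable(config),
        "stages_completed": [],
        "outputs": {},
    }

    def _write_csv(frame: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        frame.to_csv(path, **kwargs)
        manifest["outputs"][name] = _sha256(path)

    dataset = None
    structures: list = []
    key_positions = None
    try:
        if "simulate" in config.stages:
            rep_cfg = config.repertoire or RepertoireConfig(seed=config.seed)
            str_cfg = config.structures or StructureConfig(seed=config.seed)
            dataset = simulate_paired_repertoire(rep_cfg)
            airr = out / "repertoire.tsv"
            write_paired_airr(dataset, airr)
            manifest["outputs"]["repertoire.tsv"] = _sha256(airr)
            structures, designed = simulate_interface_structures(str_cfg)
            struct_dir = out / "structures"
            struct_dir.mkdir(exist_ok=True)
            for s in structures:
                pdb = write_structure_pdb(s, struct_dir / f"{s.structure_id}.pdb")
                nmap = write_numbering_map(
                    structure_numbering_map(s), struct_dir / f"{s.structure_id}.map.tsv")
                manifest["outputs"][f"structures/{pdb.name}"] = _sha256(pdb)
                manifest["outputs"][f"structures/{nmap.name}"] = _sha256(nmap)
            manifest["designed_contacts"] = sorted(map(list, designed))
            manifest["stages_completed"].append("simulate")
        else:
            if config.airr_path is not None:
                dataset = read_paired_airr(config.airr_path)
            if config.pdb_dir is not None:
                for pdb in sorted(Path(config.pdb_dir).glob("*.pdb")):
                    structures.append(read_structure(pdb, pdb.with_suffix(".map.tsv")))

        if "richness" in config.stages:
            if dataset is None:
                raise ConfigError("richness stage needs a dataset (simulate or airr_path)")
            summary = rich.incidence_counts(dataset, key_mode=config.key_mode)
            est = rich.chao2(summary)
            _write_csv(
                pd.DataFrame(
                    [{
                        "s_observed": summary.s_observed, "q1": summary.q1, "q2": summary.q2,
                        "n_studies": summary.n_studies, "estimate": est.estimate,
                        "corrected": est.corrected, "key_mode": summary.key_mode,
                    }]
                ),
                "richness.csv", index=False,
            )
            manifest["stages_completed"].append("richness")

        if "pairing" in config.stages:
            if dataset is None:
                raise ConfigError("pairing stage needs a dataset (simulate or airr_path)")
            for locus, tag in (("IGK", "kappa"), ("IGL", "lambda")):
                try:
                    table = ps.pairing_counts(
                        dataset, min_pair_count=config.min_pair_count, light_locus=locus)
                except EmptyResultError:
                    logger.warning("no usable %s pairs; skipping", tag)
                    continue
                _write_csv(table.to_frame(), f"pairing_counts_{tag}.csv")
                try:
                    stat, df, p = ps.global_independence_test(table)
                    _write_csv(
                        pd.DataFrame([{"statistic": stat, "df": df, "p": p}]),
                        f"global_test_{tag}.csv", index=False)
                except TestNotApplicableError as exc:
                    logger.warning("global test (%s) not applicable: %s", tag, exc)
                results = ps.per_pair_enrichment(table, alpha=config.alpha)
                _write_csv(ps.results_to_frame(results), f"pair_tests_{tag}.csv", index=False)
                pref = ps.preferential_pairs(results)
                indicator = table.to_frame().copy() * 0
                for h, l in pref:
                    indicator.loc[h, l] = 1
                _write_csv(indicator, f"preferential_pairs_{tag}.csv")
            # inter-chain V-J pairing: same machinery, J-gene selectors
            for hf, lf, tag in (("v_subgroup", "j_subgroup", "hv_lj"),
                                ("j_subgroup", "v_subgroup", "hj_lv")):
                table = ps.pairing_counts(
                    dataset, heavy_feature=hf, light_feature=lf,
                    min_pair_count=config.min_pair_count, light_locus="both")
                _write_csv(table.to_frame(), f"pairing_counts_{tag}.csv")
            for name, frame in ps.summarize_repertoire(dataset).items():
                _write_csv(frame, f"summary_{name}.csv")
            manifest["stages_completed"].append("pairing")

        if "contacts" in config.stages:
            if not structures:
                raise ConfigError("contacts stage needs structures (simulate or pdb_dir)")
            maps = [m for s in structures for m in ic.extract_contacts(
                s, cutoff=config.contact_cutoff, max_cys_dist=config.cys104_max_dist)]
            contact_rows = pd.DataFrame(
                [{"structure_id": m.structure_id, "h_chain": m.pair[0], "l_chain": m.pair[1],
                  "h_position": h, "l_position": l}
                 for m in maps for h, l in sorted(m.contacts)])
            _write_csv(contact_rows, "contact_maps.csv", index=False)
            freqs, matrix = ic.aggregate_contact_stats(maps, structures)
            _write_csv(freqs.to_frame(), "contact_frequencies.csv", index=False)
            _write_csv(matrix, "pair_count_matrix.csv")
            _write_csv(ic.region_pair_summary(maps), "region_pairs.csv")
            key_positions = ic.select_key_positions(
                freqs, min_ratio=config.key_min_ratio, min_occurrence=config.key_min_occurrence)
            vernier = ic.load_vernier_positions()
            overlap_rows = []
            for ct in ("H", "L"):
                o = ic.vernier_overlap(key_positions[ct], vernier[ct])
                overlap_rows.append({
                    "chain_type": ct,
                    "intersection": ";".join(sorted(o["intersection"])),
                    "key_only": ";".join(sorted(o["key_only"])),
                    "vernier_only": ";".join(sorted(o["vernier_only"])),
                    "jaccard": o["jaccard"],
                })
            _write_csv(pd.DataFrame(overlap_rows), "vernier_overlap.csv", index=False)
            manifest["stages_completed"].append("contacts")

        if "aa_profiles" in config.stages:
            if dataset is None:
                raise ConfigError("aa_profiles stage needs a dataset")
            if key_positions:
                positions = {
                    ct: sorted(p for p in key_positions[ct]
                               if _observed(dataset, ct, p))
                    for ct in ("H", "L")}
            else:
                positions = {"H": ["40", "105", "106", "107"], "L": ["40", "44", "105", "116"]}
            dist_rows = []
            for ct in ("H", "L"):
                for pos in positions[ct]:
                    d = aap.position_aa_distribution(dataset, ct, pos)
                    for aa, frac in sorted(d.proportions.items()):
                        dist_rows.append({"chain_type": ct, "imgt_position": pos,
                                          "aa": aa, "proportion": frac, "n": d.n})
            _write_csv(pd.DataFrame(dist_rows), "aa_distributions.csv", index=False)
            tvd_rows = []
            for hp in positions["H"]:
                for lp in positions["L"]:
                    try:
                        obs = aap.joint_pair_distribution(dataset, hp, lp)
                    except EmptyResultError:
                        continue
                    ref = aap.random_pairing_reference(
                        dataset, hp, lp, mode=config.pair_null_mode, seed=config.seed)
                    tvd_rows.append({"h_position": hp, "l_position": lp,
                                     "tvd_vs_random_pairing": aap.pair_tvd(obs, ref),
                                     "n": obs.n, "null_mode": config.pair_null_mode})
            _write_csv(pd.DataFrame(tvd_rows), "pair_tvd_matrix.csv", index=False)
            manifest["stages_completed"].append("aa_profiles")
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _observed(dataset, chain_type: str, position: str) -> bool:
    try:
        aap.position_aa_distribution(dataset, chain_type, position)
        return True
    except EmptyResultError:
        return False
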