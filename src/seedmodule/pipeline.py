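"""End-to-end orchestration of the network workflow from one YAML config.

Stages: consolidate the interaction files into one interactome; build the
PH seed network; build (or load a prebuilt) fibrosis network; expand the
union of heritable factors and miR targets into the query network;
partition it against the two reference networks; run the two enrichment
rounds. Every stage logs its filter counts, and a machine-readable
``report.json`` collects every statistic the stages produce. Identical
config and inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as smio
from .expansion import expand_network, network_stats
from .genesets import seed_overlap_report
from .interactome import consolidate
from .partition import build_query_network, partition, partition_report
from .enrichment import two_round_enrichment, write_results_tsv

logger = logging.getLogger("seedmodule")

MANDATORY_ROLES = ("ph", "heritable_pah", "mir_targets")


class ConfigError(ValueError):
    """Configuration invalid; ``errors`` lists every failure found."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    interactome_files: list[tuple[str, str, str]]  # (path, source_label, format)
    seed_files: dict[str, str]                     # role -> path
    gmt_path: str
    outdir: str
    universe: str = "interactome"                  # or "file:<path>"
    fibrosis_network: str | None = None            # prebuilt GraphML substitute
    max_chain: int | None = None
    min_set: int = 5
    max_set: int = 500
    strict: bool = False

    def to_dict(self) -> dict:
        return {
            "interactome_files": [list(t) for t in self.interactome_files],
            "seed_files": dict(sorted(self.seed_files.items())),
            "gmt_path": self.gmt_path,
            "outdir": self.outdir,
            "universe": self.universe,
            "fibrosis_network": self.fibrosis_network,
            "max_chain": self.max_chain,
            "min_set": self.min_set,
            "max_set": self.max_set,
            "strict": self.strict,
        }

    def config_hash(self) -> str:
        # hash the analytic inputs only, not the output location
        fields = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        canon = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _as_config(raw: dict, base: Path) -> tuple[RunConfig | None, list[str]]:
    errors: list[str] = []

    def resolve(p: str) -> str:
        path = Path(p)
        return str(path if path.is_absolute() else base / path)

    files: list[tuple[str, str, str]] = []
    for i, entry in enumerate(raw.get("interactome", []) or []):
        if not isinstance(entry, dict) or "path" not in entry:
            errors.append(f"interactome[{i}]: needs a 'path'")
            continue
        path = resolve(str(entry["path"]))
        fmt = str(entry.get("format", "tsv"))
        if fmt not in ("tsv", "mitab"):
            errors.append(f"interactome[{i}]: unknown format {fmt!r}")
        if not Path(path).exists():
            errors.append(f"interactome[{i}]: missing file {path}")
        files.append((path, str(entry.get("source", Path(path).stem)), fmt))
    if not files:
        errors.append("no interactome files configured")

    seeds_raw = raw.get("seeds", {}) or {}
    seed_files: dict[str, str] = {}
    for role, path in seeds_raw.items():
        rpath = resolve(str(path))
        if not Path(rpath).exists():
            errors.append(f"seeds.{role}: missing file {rpath}")
        seed_files[str(role)] = rpath
    for role in MANDATORY_ROLES:
        if role not in seed_files:
            errors.append(f"seeds: mandatory role {role!r} is missing")

    fibrosis_network = raw.get("fibrosis_network")
    if fibrosis_network is not None:
        fibrosis_network = resolve(str(fibrosis_network))
        if not Path(fibrosis_network).exists():
            errors.append(f"fibrosis_network: missing file {fibrosis_network}")
    if fibrosis_network is None and "fibrosis" not in seed_files:
        errors.append("either seeds.fibrosis or fibrosis_network is required")

    gmt_path = raw.get("gmt")
    if gmt_path is None:
        errors.append("gmt: required")
        gmt_path = ""
    else:
        gmt_path = resolve(str(gmt_path))
        if not Path(gmt_path).exists():
            errors.append(f"gmt: missing file {gmt_path}")

    universe = str(raw.get("universe", "interactome"))
    if universe != "interactome":
        if not universe.startswith("file:"):
            errors.append("universe must be 'interactome' or 'file:<path>'")
        else:
            upath = resolve(universe[5:])
            if not Path(upath).exists():
                errors.append(f"universe: missing file {upath}")
            universe = f"file:{upath}"

    expansion = raw.get("expansion", {}) or {}
    max_chain = expansion.get("max_chain")
    if max_chain is not None:
        try:
            max_chain = int(max_chain)
            if max_chain < 1:
                errors.append("expansion.max_chain must be >= 1")
        except (TypeError, ValueError):
            errors.append("expansion.max_chain must be an integer")
            max_chain = None

    enrichment = raw.get("enrichment", {}) or {}
    min_set = enrichment.get("min_set", 5)
    max_set = enrichment.get("max_set", 500)
    try:
        min_set, max_set = int(min_set), int(max_set)
        if not 1 <= min_set <= max_set:
            errors.append("enrichment: need 1 <= min_set <= max_set")
    except (TypeError, ValueError):
        errors.append("enrichment.min_set/max_set must be integers")
        min_set, max_set = 5, 500

    outdir = resolve(str(raw.get("outdir", "seedmodule_out")))

    if errors:
        return None, errors
    return RunConfig(
        interactome_files=files,
        seed_files=seed_files,
        gmt_path=gmt_path,
        outdir=outdir,
        universe=universe,
        fibrosis_network=fibrosis_network,
        max_chain=max_chain,
        min_set=min_set,
        max_set=max_set,
        strict=bool(raw.get("strict", False)),
    ), []


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, collecting all failures."""
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
    except OSError as exc:
        raise ConfigError([f"cannot read config: {exc}"]) from exc
    except yaml.YAMLError as exc:
        raise ConfigError([f"invalid YAML: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])
    config, errors = _as_config(raw, path.parent)
    if errors:
        raise ConfigError(errors)
    return config


def run_all(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report: dict = {"config_hash": chash, "stages": {}}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    # --- consolidate -------------------------------------------------------
    name = stage("consolidate")
    try:
        parts, load_reports = [], []
        for path, label, fmt in config.interactome_files:
            inter, lrep = smio.read_edge_list(path, label, fmt,
                                              strict=config.strict)
            parts.append(inter)
            load_reports.append(lrep.to_dict())
            logger.info("  %s: %d edges kept, %d skipped", label,
                        lrep.edges_kept, lrep.lines_skipped)
        ci = consolidate(parts)
        smio.write_interactome(ci, outdir / "ci.graphml", config_hash=chash)
        report["stages"][name] = {
            "load_reports": load_reports,
            "ci_nodes": ci.n_nodes,
            "ci_edges": ci.n_edges,
        }
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    # --- reference networks -------------------------------------------------
    name = stage("ph_network")
    try:
        ph_seeds = smio.read_seed_list(config.seed_files["ph"], name="ph")
        ph_net = expand_network(ci, ph_seeds, max_chain=config.max_chain)
        smio.write_network(ph_net, outdir / "ph_network.graphml",
                           config_hash=chash)
        report["stages"][name] = {
            **network_stats(ph_net),
            "n_seeds_input": len(ph_seeds.genes),
            "n_seeds_unmapped": len(ph_seeds.unmapped),
            "excluded_seeds": sorted(ph_net.excluded_seeds),
        }
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    name = stage("fibrosis_network")
    try:
        if config.fibrosis_network:
            fib_net = smio.read_network(config.fibrosis_network)
            smio.write_network(fib_net, outdir / "fib_network.graphml",
                               config_hash=chash)
            report["stages"][name] = {**network_stats(fib_net), "prebuilt": True}
        else:
            fib_seeds = smio.read_seed_list(config.seed_files["fibrosis"],
                                            name="fibrosis")
            fib_net = expand_network(ci, fib_seeds, max_chain=config.max_chain)
            smio.write_network(fib_net, outdir / "fib_network.graphml",
                               config_hash=chash)
            report["stages"][name] = {
                **network_stats(fib_net),
                "n_seeds_input": len(fib_seeds.genes),
                "n_seeds_unmapped": len(fib_seeds.unmapped),
                "prebuilt": False,
            }
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    # --- query network ------------------------------------------------------
    name = stage("query_network")
    try:
        heritable = smio.read_seed_list(config.seed_files["heritable_pah"],
                                        name="heritable_pah")
        mir = smio.read_seed_list(config.seed_files["mir_targets"],
                                  name="mir_targets")
        query_net = build_query_network(ci, heritable, mir)
        smio.write_network(query_net, outdir / "query_network.graphml",
                           config_hash=chash)
        a, b, common = seed_overlap_report(heritable, mir)
        report["stages"][name] = {
            **network_stats(query_net),
            "n_heritable_input": a,
            "n_mir_targets_input": b,
            "n_common_heritable_mir": common,
            "excluded_seeds": sorted(query_net.excluded_seeds),
        }
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    # --- partition ----------------------------------------------------------
    name = stage("partition")
    try:
        partitioned = partition(query_net, ph_net.nodes, fib_net.nodes)
        smio.write_network(query_net, outdir / "partitioned.graphml",
                           config_hash=chash)
        report["stages"][name] = partition_report(partitioned)
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    # --- enrichment ---------------------------------------------------------
    name = stage("enrichment")
    try:
        collection = smio.read_gmt(config.gmt_path, strict=config.strict)
        if config.universe == "interactome":
            universe = ci.nodes
        else:
            universe = smio.read_seed_list(config.universe[5:],
                                           name="universe").genes
        round1, round2 = two_round_enrichment(
            partitioned, collection, universe,
            min_set=config.min_set, max_set=config.max_set)
        write_results_tsv(round1, outdir / "round1.tsv")
        stage_report = {
            "universe_size": len(universe),
            "n_sets_tested_round1": len(round1),
            "top_set_round1": round1[0].set_name,
            "top_p_adj_round1": round1[0].p_adjusted,
        }
        if round2 is not None:
            write_results_tsv(round2, outdir / "round2.tsv")
            stage_report.update({
                "n_sets_tested_round2": len(round2),
                "top_set_round2": round2[0].set_name,
                "top_p_adj_round2": round2[0].p_adjusted,
            })
        else:
            stage_report["round2_skipped"] = True
        report["stages"][name] = stage_report
    except Exception as exc:
        raise StageError(name, str(exc)) from exc

    smio.write_json_report(report, outdir / "report.json")
    return report
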