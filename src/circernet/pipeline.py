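"""End-to-end orchestration: simulate (or load) -> DE -> filter cascade ->
network assembly -> export, with a machine-readable run manifest.

The manifest records the per-stage counts of the inference funnel
(junctions in -> after abundance filter -> DE features per layer -> edges
after each filter -> triples) so every run is auditable; each stage's
output can only shrink relative to its input.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cernet import (
    CeRNANetwork,
    ThresholdConfig,
    abundance_filter,
    assemble_network,
    de_threshold_filter,
    filter_mirna_mrna_predictions,
    inverse_modulation_filter,
    merge_circ_mirna_predictions,
    network_summary,
    rank_hubs,
)
from .destats import DesignInfo, log_cpm, two_group_de
from .simdata import (
    SimParams,
    evaluate_recovery,
    simulate_counts,
    simulate_ground_truth,
    simulate_mirna_de,
    simulate_prediction_tables,
)
from .tabio import (
    FormatError,
    Layer,
    read_bsj_matrix,
    read_circ_mir_table,
    read_de_table,
    read_mir_mrna_table,
    write_circ_mir_table,
    write_count_matrix,
    write_de_table,
    write_mir_mrna_table,
    write_network,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "infer_network"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``sim`` is set (inputs are generated) or the input paths are set
    (inputs are loaded from disk).  ``seed`` drives every stochastic step.
    """

    outdir: Path
    seed: int = 0
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    sim: SimParams | None = None
    mrna_counts: Path | None = None
    mrna_meta: Path | None = None
    circ_counts: Path | None = None
    circ_meta: Path | None = None
    mirna_de: Path | None = None
    circ_mir_tables: tuple[Path, ...] = ()
    mir_mrna_table: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "seed" not in raw:
            raise FormatError(f"{path}: config must set an explicit seed")
        kwargs: dict = {"outdir": Path(raw.get("outdir", "circernet_out")),
                        "seed": int(raw["seed"])}
        if "thresholds" in raw:
            kwargs["thresholds"] = ThresholdConfig(**raw["thresholds"])
        if "sim" in raw:
            sim = dict(raw["sim"])
            sim.setdefault("seed", kwargs["seed"])
            kwargs["sim"] = SimParams(**sim)
        for key in ("mrna_counts", "mrna_meta", "circ_counts", "circ_meta",
                    "mirna_de", "mir_mrna_table"):
            if key in raw:
                kwargs[key] = Path(raw[key])
        if "circ_mir_tables" in raw:
            kwargs["circ_mir_tables"] = tuple(Path(p)
                                              for p in raw["circ_mir_tables"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (where outputs land is excluded)."""
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj
        payload = enc(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PipelineResult:
    network: CeRNANetwork
    manifest: dict
    outdir: Path


def infer_network(mrna_de_table, mirna_de_table, circ_de_table,
                  circ_mir_tables, mir_mrna_edges, cfg: ThresholdConfig,
                  circ_universe=None) -> tuple[CeRNANetwork, dict]:
    """The inference cascade from DE tables + prediction tables to a network.

    Returns the assembled network and the stage-count dictionary for the
    manifest (DE features per layer, edges surviving each filter, triples,
    concordant and non-DE drop counters).
    """
    signed = {
        Layer.MRNA: de_threshold_filter(mrna_de_table, cfg),
        Layer.MIRNA: de_threshold_filter(mirna_de_table, cfg),
        Layer.CIRCRNA: de_threshold_filter(circ_de_table, cfg),
    }
    merged = merge_circ_mirna_predictions(circ_mir_tables,
                                          circ_universe=circ_universe)
    cm_inverse = inverse_modulation_filter(merged.edges,
                                           signed[Layer.CIRCRNA],
                                           signed[Layer.MIRNA])
    mm_provenance = filter_mirna_mrna_predictions(mir_mrna_edges, cfg)
    mm_inverse = inverse_modulation_filter(mm_provenance,
                                           signed[Layer.MIRNA],
                                           signed[Layer.MRNA])
    network = assemble_network(cm_inverse.retained, mm_inverse.retained,
                               signed)
    counts = {
        "de_mrna": len(signed[Layer.MRNA]),
        "de_mirna": len(signed[Layer.MIRNA]),
        "de_circ": len(signed[Layer.CIRCRNA]),
        "circ_mir_merged": len(merged.edges),
        "circ_mir_no_match": list(merged.no_match_circs),
        "circ_mir_after_inverse": len(cm_inverse.retained),
        "circ_mir_concordant_dropped": cm_inverse.concordant_count,
        "circ_mir_nonde_dropped": cm_inverse.dropped_non_de_count,
        "mir_mrna_input": len(list(mir_mrna_edges)),
        "mir_mrna_after_provenance": len(mm_provenance),
        "mir_mrna_after_inverse": len(mm_inverse.retained),
        "mir_mrna_concordant_dropped": mm_inverse.concordant_count,
        "mir_mrna_nonde_dropped": mm_inverse.dropped_non_de_count,
        "triples": len(network),
    }
    return network, counts


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full workflow and write artifacts + manifest to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.thresholds
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    stage = "setup"
    try:
        ground_truth = None
        if config.sim is not None:
            stage = "simulate"
            params = dataclasses.replace(config.sim, seed=config.seed)
            ground_truth = simulate_ground_truth(params)
            matrices = simulate_counts(ground_truth, params)
            mrna_counts = matrices[Layer.MRNA]
            circ_counts = matrices[Layer.CIRCRNA]
            mirna_de_table = simulate_mirna_de(ground_truth, params)
            cm_edges, mm_edges = simulate_prediction_tables(ground_truth,
                                                            params)
            circ_mir_tables = [cm_edges]
            write_count_matrix(mrna_counts, outdir / "mrna_counts.tsv",
                               outdir / "mrna_meta.tsv")
            write_count_matrix(circ_counts, outdir / "circ_counts.tsv",
                               outdir / "circ_meta.tsv")
            write_de_table(mirna_de_table, outdir / "mirna_de.tsv")
            write_circ_mir_table(cm_edges,
                                 outdir / "circ_mir_predictions.tsv")
            write_mir_mrna_table(mm_edges,
                                 outdir / "mir_mrna_predictions.tsv")
        else:
            stage = "load"
            for name in ("mrna_counts", "mrna_meta", "circ_counts",
                         "circ_meta", "mirna_de", "mir_mrna_table"):
                p = getattr(config, name)
                if p is None:
                    raise FormatError(f"config is missing input path {name!r}")
                if not Path(p).exists():
                    raise FormatError(f"input file not found: {p}")
            if not config.circ_mir_tables:
                raise FormatError("config lists no circ_mir prediction table")
            for p in config.circ_mir_tables:
                if not Path(p).exists():
                    raise FormatError(f"input file not found: {p}")
            mrna_counts = read_bsj_matrix(config.mrna_counts,
                                          config.mrna_meta)
            circ_counts = read_bsj_matrix(config.circ_counts,
                                          config.circ_meta)
            mirna_de_table = read_de_table(config.mirna_de, Layer.MIRNA)
            circ_mir_tables = [
                read_circ_mir_table(p, source=Path(p).stem)
                for p in config.circ_mir_tables]
            mm_edges = read_mir_mrna_table(config.mir_mrna_table)

        stage = "bsj_abundance_filter"
        circ_kept, bsj_report = abundance_filter(circ_counts, cfg)
        manifest["stages"]["bsj_junctions_in"] = bsj_report.n_in
        manifest["stages"]["bsj_junctions_kept"] = bsj_report.n_out

        stage = "differential_expression"
        mrna_de_table = two_group_de(log_cpm(mrna_counts),
                                     DesignInfo.from_matrix(mrna_counts),
                                     mrna_counts.feature_ids, Layer.MRNA)
        circ_de_table = two_group_de(log_cpm(circ_kept),
                                     DesignInfo.from_matrix(circ_kept),
                                     circ_kept.feature_ids, Layer.CIRCRNA)
        write_de_table(mrna_de_table, outdir / "mrna_de.tsv")
        write_de_table(circ_de_table, outdir / "circ_de.tsv")

        stage = "network_inference"
        network, counts = infer_network(
            mrna_de_table, mirna_de_table, circ_de_table, circ_mir_tables,
            mm_edges, cfg, circ_universe=circ_kept.feature_ids)
        manifest["stages"].update(counts)

        stage = "export"
        write_network(network, outdir / "network.edges.tsv", "edge_tsv")
        write_network(network, outdir / "network.sif", "sif")
        write_network(network, outdir / "network.graphml", "graphml")
        summary = network_summary(network)
        import pandas as pd

        pd.DataFrame(summary.to_rows()).to_csv(outdir / "summary.tsv",
                                               sep="\t", index=False)
        manifest["summary"] = {
            "total_interactions": summary.total_interactions,
            "n_circs": summary.n_circs,
            "n_mirnas": summary.n_mirnas,
            "n_mrnas": summary.n_mrnas,
            "hubs": rank_hubs(network),
        }

        if ground_truth is not None:
            stage = "recovery"
            report = evaluate_recovery(network, ground_truth)
            manifest["recovery"] = report.to_dict()
            (outdir / "recovery.json").write_text(
                json.dumps(report.to_dict(), indent=2), encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                          encoding="utf-8")
    return PipelineResult(network=network, manifest=manifest, outdir=outdir)
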