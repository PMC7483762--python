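"""End-to-end orchestration: simulate (or load) -> differential -> lipids ->
enrichment -> concordance -> report bundle on disk.

A single YAML/JSON config drives every stage; all outputs are TSV/JSON files
stamped with the seed and a hash of the resolved configuration so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import concordance, differential, enrichment, lipidomics, synthetic
from .matrix import AnalyteMatrix, DRUG

log = logging.getLogger("omiconcord")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    ``inputs`` may map layer names to ``{"matrix": ..., "samples": ...}``
    paths plus an optional ``"gene_sets"`` GMT path; when empty, the
    experiment is simulated from ``simulation`` (kwargs of
    :class:`~omiconcord.synthetic.SimulationConfig`).
    """

    outdir: str = "omiconcord_out"
    seed: int = 0
    alpha: float = 0.05
    up_thr: float = 150.0
    down_thr: float = 50.0
    pufa_db_threshold: int = 2
    impute_shift_sd: float = 1.8
    impute_width_sd: float = 0.3
    matching_mode: str = "same_time"
    simulation: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.up_thr <= 0 or self.down_thr <= 0:
            raise ValueError("thresholds must be positive")
        if self.down_thr >= self.up_thr:
            raise ValueError("down threshold must be below the up threshold")
        if self.matching_mode not in ("same_time", "any_time"):
            raise ValueError(f"unknown matching mode {self.matching_mode!r}")
        for layer, paths in self.inputs.items():
            if layer == "gene_sets":
                paths = {"gene_sets": paths}
            for role, p in paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"input {role} for {layer!r}: {p}")
        # constructing the simulation config runs its own invariant checks
        synthetic.SimulationConfig(**self.simulation, seed=self.seed)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_or_simulate(config: PipelineConfig):
    if config.inputs:
        layers = {}
        for layer, paths in config.inputs.items():
            if layer == "gene_sets":
                continue
            layers[layer] = AnalyteMatrix.from_tsv(paths["matrix"], paths["samples"])
        gmt = config.inputs.get("gene_sets")
        gene_sets = (
            enrichment.GeneSetCollection.from_gmt(gmt).terms if gmt else {}
        )
        return synthetic.SimulationResult(
            layers, gene_sets, pd.DataFrame(), synthetic.SimulationConfig(**config.simulation)
        )
    sim_config = synthetic.SimulationConfig(**config.simulation, seed=config.seed)
    return synthetic.generate_experiment(sim_config)


def _lipid_stage(result, config: PipelineConfig, outdir: Path) -> dict:
    """PC composition and PUFA fraction per (cell line, treatment, time) of
    the lipid layer, against unit internal standards (within-class shares are
    standard-invariant)."""
    matrix = result.layers.get("lipid")
    if matrix is None:
        return {}
    rows = []
    meta = matrix.samples
    for (line, treatment, t), ids in meta.groupby(
        ["cell_line", "treatment", "timepoint_h"]
    ).groups.items():
        means = matrix.values[list(ids)].mean(axis=1)
        quants = []
        for label, intensity in means.items():
            try:
                sp = lipidomics.parse_species_label(label)
            except ValueError:
                continue
            if pd.isna(intensity):
                continue
            quants.append(lipidomics.SpeciesQuant(sp, float(intensity), 1.0))
        if not any(q.species.lipid_class == "PC" for q in quants):
            continue
        pufa = lipidomics.pufa_fraction(quants, config.pufa_db_threshold)
        rows.append((line, treatment, t, pufa, len(quants)))
    table = pd.DataFrame(
        rows, columns=["cell_line", "treatment", "timepoint_h", "pufa_pct_of_pc", "n_species"]
    )
    table.to_csv(outdir / "lipid_pufa_fraction.tsv", sep="\t", index=False)
    return {"lipid_pufa": table}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order and write the report bundle.

    Raises on validation errors before any stage runs; any stage failure
    propagates after being logged (downstream stages are not attempted).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}
    timings: dict[str, float] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                out = fn()
            except Exception:
                log.exception("stage %s failed; downstream stages skipped", name)
                raise
            timings[name] = round(time.perf_counter() - t0, 3)
            return out
        return wrap

    result = stage("simulate")(lambda: _load_or_simulate(config))
    if not config.inputs:
        synthetic.write_experiment(result, outdir / "experiment")

    def _differential():
        calls = {}
        for layer, matrix in result.layers.items():
            if matrix.values.isna().any().any():
                matrix = differential.impute_missing(
                    matrix, config.impute_shift_sd, config.impute_width_sd,
                    seed=config.seed,
                )
            table = differential.differential_table(matrix, alpha=config.alpha)
            table.to_csv(outdir / f"calls_{layer}.tsv", sep="\t", index=False)
            calls[layer] = table
        return calls

    calls = stage("differential")(_differential)

    def _class_summary():
        lipid_calls = calls.get("lipid")
        if lipid_calls is None or lipid_calls.empty:
            return None
        class_map = {}
        for label in lipid_calls["analyte"].unique():
            try:
                class_map[label] = lipidomics.parse_species_label(label).lipid_class
            except ValueError:
                pass
        summary = differential.aggregate_class_summary(lipid_calls, class_map)
        summary.to_csv(outdir / "lipid_class_summary.tsv", sep="\t", index=False)
        return summary

    class_summary = stage("class_summary")(_class_summary)
    lipid_out = stage("lipids")(lambda: _lipid_stage(result, config, outdir))

    def _enrichment():
        layer = result.config.process_layer
        if layer not in calls or not result.gene_sets:
            return None
        table = calls[layer]
        population = set(result.layers[layer].values.index)
        collection = enrichment.GeneSetCollection(result.gene_sets, population)
        charts = {}
        for t in sorted(table["timepoint_h"].unique()):
            at_t = table[table["timepoint_h"] == t]
            ids = set(at_t.loc[at_t["direction"] != differential.UNCHANGED, "analyte"])
            if not ids:
                continue
            chart = enrichment.annotation_chart(ids, collection, config.alpha)
            chart.to_csv(outdir / f"enrichment_{t}h.tsv", sep="\t", index=False)
            charts[t] = chart
        return charts

    charts = stage("enrichment")(_enrichment)

    def _concordance():
        layer = result.config.process_layer
        if layer not in calls or not result.gene_sets:
            return None
        table = calls[layer]
        line_a, line_b = sorted(table["cell_line"].unique())[:2]
        calls_a = table[table["cell_line"] == line_a]
        calls_b = table[table["cell_line"] == line_b]
        phospho = calls.get("phospho")
        kwargs = {}
        if phospho is not None and not phospho.empty:
            # pseudo-pathways over the phospho layer to exercise the pathway
            # status/overlap stage on simulated data
            ids = sorted(phospho["analyte"].unique())
            pathway_map = {
                f"pathway_{i//10 + 1:02d}": set(ids[i : i + 10])
                for i in range(0, len(ids), 10)
            }
            t_last = max(phospho["timepoint_h"].unique())
            sub = phospho[phospho["timepoint_h"] == t_last]
            kwargs = {
                "phospho_pcts_a": sub[sub["cell_line"] == line_a],
                "phospho_pcts_b": sub[sub["cell_line"] == line_b],
                "pathway_map": pathway_map,
                "up_thr": config.up_thr,
                "down_thr": config.down_thr,
            }
        report = concordance.concordance_report(
            calls_a, calls_b, result.gene_sets, mode=config.matching_mode, **kwargs
        )
        report["process_scores"].to_csv(outdir / "process_scores.tsv", sep="\t", index=False)
        report["protein_scores"].to_csv(outdir / "protein_scores.tsv", sep="\t", index=False)
        for t, ranking in report["rankings"].items():
            ranking.to_csv(outdir / f"ranking_{t}h.tsv", sep="\t", index=False)
        if "overlap" in report:
            with open(outdir / "pathway_overlap.json", "w") as fh:
                json.dump(
                    {**stamp, **report["overlap"]._asdict()}, fh, indent=2, sort_keys=True
                )
        return report

    report = stage("concordance")(_concordance)

    with open(outdir / "run_info.json", "w") as fh:
        json.dump({**stamp, "timings_s": timings}, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", timings)
    return {
        "result": result,
        "calls": calls,
        "class_summary": class_summary,
        "lipids": lipid_out,
        "enrichment": charts,
        "concordance": report,
        "stamp": stamp,
    }
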