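"""Synthetic two-cell-line drug-response experiments with known ground truth.

Emulates the design of a FASN-inhibitor study in two ovarian-cancer cell
lines: for each omics layer (protein, phospho, metabolite, lipid) an
analyte-by-sample intensity matrix over
``cell line x {vehicle, drug} x timepoint x replicate``, with

* log-normal replicate noise at a configurable coefficient of variation
  (default 0.20, inside the 10-33% reproducibility band typical of the
  targeted assays being emulated),
* treatment effects planted into annotated processes — *primary* processes
  respond with the same sign at the same time in both cell lines (the
  signature of a causal drug mechanism), *secondary* processes respond with
  independently drawn sign and time per cell line (a reactive, cell-context
  dependent response), *null* processes and unannotated analytes carry no
  effect,
* optional left-censored missingness: the probability of a dropout follows a
  logistic curve in minus log-intensity, calibrated so the overall missing
  fraction matches ``missing_rate``.

Identical configuration and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import DRUG, VEHICLE, AnalyteMatrix

ROLES = ("primary", "secondary", "null")

#: lipid classes used to label analytes of the lipid layer as sum-composition
#: species (e.g. "PC 34:1") so the lipidomics module can consume them
_LIPID_LAYER_CLASSES = ("PC", "LPC", "PE", "PS", "PI", "PG", "SM", "DAG", "TAG")


@dataclass(frozen=True)
class ProcessSpec:
    """A planted biological process: name, member count and causal role."""

    name: str
    n_members: int
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.n_members < 1:
            raise ValueError("process needs at least one member")


def default_processes() -> list[ProcessSpec]:
    return [
        ProcessSpec("apoptosis", 20, "primary"),
        ProcessSpec("fatty_acid_metabolism", 20, "primary"),
        ProcessSpec("glycolysis", 20, "secondary"),
        ProcessSpec("oxphos", 20, "secondary"),
    ]


@dataclass
class SimulationConfig:
    """Parameters of a simulated two-cell-line drug-response experiment.

    ``effect_log2`` is the magnitude of the planted treatment effect on the
    log2 scale (1.0 = two-fold); ``noise_cv`` the replicate coefficient of
    variation of the multiplicative log-normal noise; ``missing_rate`` the
    target overall fraction of left-censored dropouts.
    """

    n_analytes_per_layer: dict[str, int] = field(
        default_factory=lambda: {
            "protein": 400,
            "phospho": 150,
            "metabolite": 180,
            "lipid": 60,
        }
    )
    processes: list[ProcessSpec] = field(default_factory=default_processes)
    process_layer: str = "protein"
    effect_log2: float = 1.0
    noise_cv: float = 0.20
    n_replicates: int = 3
    timepoints_h: list[float] = field(default_factory=lambda: [8, 24])
    cell_lines: list[str] = field(default_factory=lambda: ["SKOV3", "OVCAR3"])
    missing_rate: float = 0.0
    baseline_mean_log2: float = 20.0
    baseline_sd_log2: float = 1.5
    missing_steepness_log2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not (0 <= self.noise_cv <= 0.5):
            raise ValueError("noise_cv must lie in [0, 0.5]")
        if not (0 <= self.missing_rate < 0.5):
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if len(self.cell_lines) != 2:
            raise ValueError("exactly two cell lines are required")
        procs = [p if isinstance(p, ProcessSpec) else ProcessSpec(*p) for p in self.processes]
        self.processes = procs
        if self.process_layer not in self.n_analytes_per_layer:
            raise ValueError(f"process_layer {self.process_layer!r} not a layer")
        n_members = sum(p.n_members for p in procs)
        if n_members > self.n_analytes_per_layer[self.process_layer]:
            raise ValueError(
                "process member counts exceed the analyte count of layer "
                f"{self.process_layer!r} ({n_members} > "
                f"{self.n_analytes_per_layer[self.process_layer]})"
            )
        if len({p.name for p in procs}) != len(procs):
            raise ValueError("duplicate process names")


@dataclass
class SimulationResult:
    """Layers, process annotation and planted ground truth of one experiment."""

    layers: dict[str, AnalyteMatrix]
    gene_sets: dict[str, set[str]]
    ground_truth: pd.DataFrame  # analyte, process, role, cell_line, timepoint_h, effect_log2
    config: SimulationConfig


def _noise_sd_log2(cv: float) -> float:
    """Log2-scale SD of a log-normal with coefficient of variation ``cv``."""
    if cv == 0:
        return 0.0
    return float(np.sqrt(np.log1p(cv**2)) / np.log(2))


def _lipid_species_labels(n: int, rng: np.random.Generator) -> list[str]:
    """Sum-composition labels for the lipid layer, covering 0-6 double bonds."""
    labels: list[str] = []
    seen: set[str] = set()
    i = 0
    while len(labels) < n:
        cls = _LIPID_LAYER_CLASSES[i % len(_LIPID_LAYER_CLASSES)]
        carbons = int(rng.integers(14, 23)) * 2  # 28-44, even
        dbs = int(rng.integers(0, 7))
        label = f"{cls} {carbons}:{dbs}"
        i += 1
        if label not in seen:
            seen.add(label)
            labels.append(label)
    return labels


def _plant_effects(
    config: SimulationConfig, analyte_roles: dict[str, tuple[str, str]], rng
) -> pd.DataFrame:
    """Draw the signed per-(cell line, time) log2 effects for every annotated analyte.

    Primary analytes share one sign and one active timepoint across both cell
    lines; secondary analytes draw sign and active timepoint independently per
    cell line; null analytes get zero effect everywhere.
    """
    rows = []
    for analyte, (process, role) in analyte_roles.items():
        if role == "primary":
            sign = rng.choice([-1.0, 1.0])
            t_active = rng.choice(config.timepoints_h)
            for line in config.cell_lines:
                for t in config.timepoints_h:
                    eff = sign * config.effect_log2 if t == t_active else 0.0
                    rows.append((analyte, process, role, line, t, eff))
        elif role == "secondary":
            for line in config.cell_lines:
                sign = rng.choice([-1.0, 1.0])
                t_active = rng.choice(config.timepoints_h)
                for t in config.timepoints_h:
                    eff = sign * config.effect_log2 if t == t_active else 0.0
                    rows.append((analyte, process, role, line, t, eff))
        else:  # null
            for line in config.cell_lines:
                for t in config.timepoints_h:
                    rows.append((analyte, process, role, line, t, 0.0))
    return pd.DataFrame(
        rows,
        columns=["analyte", "process", "role", "cell_line", "timepoint_h", "effect_log2"],
    )


def _calibrate_censoring(log2_values: np.ndarray, rate: float, steepness: float, rng):
    """Left-censoring mask with overall frequency ``rate``.

    P(missing | z) = expit(-(z - tau) / steepness) in log2 intensity z; tau is
    solved by bisection so that the mean dropout probability equals ``rate``.
    """
    from scipy.special import expit

    z = log2_values.ravel()
    lo, hi = z.min() - 20, z.max() + 20

    def mean_p(tau):
        return expit(-(z - tau) / steepness).mean()

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < rate:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    p = expit(-(log2_values - tau) / steepness)
    return rng.random(log2_values.shape) < p


def generate_experiment(config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Simulate all omics layers of one two-cell-line treatment experiment.

    ``seed`` overrides ``config.seed`` when given. Returns matrices on the
    linear intensity scale (2**log2), the process membership map and the
    planted ground truth in long format.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sigma = _noise_sd_log2(config.noise_cv)

    # analyte ids per layer; process members are the first analytes of the
    # annotated layer, in declaration order
    layer_ids: dict[str, list[str]] = {}
    for layer, n in config.n_analytes_per_layer.items():
        if layer == "lipid":
            layer_ids[layer] = _lipid_species_labels(n, rng)
        else:
            layer_ids[layer] = [f"{layer}_{i:04d}" for i in range(n)]

    analyte_roles: dict[str, tuple[str, str]] = {}
    gene_sets: dict[str, set[str]] = {}
    cursor = 0
    members_of = layer_ids[config.process_layer]
    for proc in config.processes:
        ids = members_of[cursor : cursor + proc.n_members]
        cursor += proc.n_members
        gene_sets[proc.name] = set(ids)
        for a in ids:
            analyte_roles[a] = (proc.name, proc.role)

    truth = _plant_effects(config, analyte_roles, rng)
    effect_lookup = {
        (r.analyte, r.cell_line, r.timepoint_h): r.effect_log2
        for r in truth.itertuples(index=False)
    }

    # sample grid, identical for every layer
    sample_rows = []
    for line in config.cell_lines:
        for t in config.timepoints_h:
            for treatment in (VEHICLE, DRUG):
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{line}_{treatment}_{t}h_r{rep}"
                    sample_rows.append((sid, line, treatment, t, rep))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "cell_line", "treatment", "timepoint_h", "replicate"]
    ).set_index("sample_id")

    layers: dict[str, AnalyteMatrix] = {}
    for layer, ids in layer_ids.items():
        n = len(ids)
        baseline = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, size=n)
        log2 = np.empty((n, len(samples)))
        for j, (sid, meta) in enumerate(samples.iterrows()):
            shift = np.zeros(n)
            if meta["treatment"] == DRUG:
                for i, a in enumerate(ids):
                    shift[i] = effect_lookup.get(
                        (a, meta["cell_line"], meta["timepoint_h"]), 0.0
                    )
            noise = rng.normal(0.0, sigma, size=n) if sigma > 0 else 0.0
            log2[:, j] = baseline + shift + noise
        if config.missing_rate > 0:
            mask = _calibrate_censoring(
                log2, config.missing_rate, config.missing_steepness_log2, rng
            )
        else:
            mask = np.zeros(log2.shape, dtype=bool)
        values = np.power(2.0, log2)
        values[mask] = np.nan
        layers[layer] = AnalyteMatrix(
            pd.DataFrame(values, index=ids, columns=samples.index), samples.copy()
        )

    return SimulationResult(layers, gene_sets, truth, replace(config))


# -- persistence -----------------------------------------------------------


def write_gmt(gene_sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            members = "\t".join(sorted(gene_sets[term]))
            fh.write(f"{term}\t{term}\t{members}\n")


def write_experiment(result: SimulationResult, outdir) -> None:
    """Write matrices, metadata, gene sets (GMT) and ground truth as text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for layer, matrix in result.layers.items():
        matrix.to_tsv(outdir / f"{layer}_matrix.tsv", outdir / "samples.tsv")
    write_gmt(result.gene_sets, outdir / "processes.gmt")
    result.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
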