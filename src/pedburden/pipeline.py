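"""End-to-end pipeline runner: simulate/load → filter → burden → growth.

Given a :class:`RunConfig` holding either fixture paths or a
:class:`~pedburden.simulate.SimulationConfig`, :func:`run_all` executes
the full analysis and writes all artifacts (candidate variant table,
candidate gene list, filter trace, burden table, classified growth
table, manifest with checksums and per-stage counts) into the output
directory.  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations


import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import io as cio
from .burden import QualifyingRule, results_table, run_burden
from .filters import FilterConfig, run_cascade
from .growth import analyze_growth_records
from .simulate import SimulationConfig, simulate_cohort, write_fixture_set
from .types import Cohort, ConfigurationError

log = logging.getLogger("pedburden")


@dataclass
class InputPaths:
    vcf: str
    ped: str
    annotations: str
    panel: str
    growth: str | None = None


@dataclass
class RunConfig:
    inputs: InputPaths | None = None
    simulation: SimulationConfig | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    qualifying_rule: QualifyingRule = field(default_factory=QualifyingRule)
    out_dir: str = "pedburden_run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ConfigurationError(
                "provide exactly one of input paths or a simulation config"
            )


def _load(config: RunConfig) -> Cohort:
    if config.simulation is not None:
        sim = simulate_cohort(config.simulation)
        fixtures = Path(config.out_dir) / "fixtures"
        write_fixture_set(sim, fixtures)
        log.info("simulated cohort written to %s", fixtures)
        return sim.cohort
    paths = config.inputs
    for name in ("vcf", "ped", "annotations", "panel"):
        p = getattr(paths, name)
        if not Path(p).exists():
            raise ConfigurationError(f"input {name} path does not exist: {p}")
    return cio.load_cohort(paths.vcf, paths.ped, paths.annotations,
                           paths.panel, paths.growth)


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline; return the manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _load(config)
    candidates, genes, trace = run_cascade(cohort, config.filter_config)
    for line in trace.log_lines():
        log.info("filter %s", line)

    gene_of = {v.key: v.gene for v in cohort.variants}
    with open(out / "candidate_variants.tsv", "w") as fh:
        fh.write("variant_key\tgene\n")
        for key in candidates:
            fh.write(f"{key}\t{gene_of[key]}\n")
    (out / "candidate_genes.txt").write_text(
        "".join(f"{g}\n" for g in genes))
    with open(out / "filter_trace.tsv", "w") as fh:
        fh.write("stage\tvariants_in\tvariants_out\n")
        for name, n_in, n_out in trace.counts():
            fh.write(f"{name}\t{n_in}\t{n_out}\n")
    (out / "filter_trace.log").write_text(
        "".join(f"{line}\n" for line in trace.log_lines()))

    burden_results = []
    if genes and cohort.probands:
        burden_results = run_burden(cohort, genes, config.qualifying_rule)
        results_table(burden_results).to_csv(
            out / "burden.tsv", sep="\t", index=False)
    elif genes:
        log.warning("no probands in cohort; burden testing skipped")

    if cohort.growth:
        analyze_growth_records(cohort.growth).to_csv(
            out / "growth_classified.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": (config.simulation.seed
                 if config.simulation is not None else None),
        "stage_counts": [
            {"stage": name, "in": n_in, "out": n_out}
            for name, n_in, n_out in trace.counts()
        ],
        "n_candidate_variants": len(candidates),
        "candidate_genes": genes,
        "top_gene": burden_results[0].gene if burden_results else None,
        "files": {},
    }
    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][path.name] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def config_from_yaml(data: dict) -> RunConfig:
    """Build a RunConfig from a parsed YAML mapping."""
    kwargs: dict = {}
    if "inputs" in data:
        kwargs["inputs"] = InputPaths(**data["inputs"])
    if "simulation" in data:
        sim = dict(data["simulation"])
        mix = sim.pop("background_maf_distribution", None)
        from .simulate import MAFMixture
        if mix is not None:
            sim["background_maf_distribution"] = MAFMixture(**mix)
        kwargs["simulation"] = SimulationConfig(**sim)
    if "filter" in data:
        fc = dict(data["filter"])
        if "allowed_consequences" in fc:
            fc["allowed_consequences"] = frozenset(fc["allowed_consequences"])
        if fc.get("gene_allowlist") is not None:
            fc["gene_allowlist"] = frozenset(fc["gene_allowlist"])
        kwargs["filter_config"] = FilterConfig(**fc)
    if "qualifying" in data:
        kwargs["qualifying_rule"] = QualifyingRule(**data["qualifying"])
    for key in ("out_dir", "log_level"):
        if key in data:
            kwargs[key] = data[key]
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
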