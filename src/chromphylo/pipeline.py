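"""End-to-end analysis orchestration.

One configuration drives the whole study design: obtain a matrix (simulate
or load), classify site time courses per lineage, infer trees with the
requested methods over the analysis variants (all sites vs. without OTHER
sites; full panel vs. without iMK), reconstruct ancestral states on the
fixed constraint topology after dropping everywhere-STABLE sites, validate
the reconstructed progenitor states against the observed progenitor
columns, quantify treelikeness for the lymphoid and myeloid taxon sets,
and count lineage-specific branch changes.  Every stage's outputs land in
the run directory and in a JSON report; all randomness derives from the
configured seed, so a rerun overwrites the outputs bit-identically
(timestamps aside).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import hematopoiesis as hp
from ._tree import to_newick
from .ancestral import reconstruct
from .classify import (classify_matrix, other_site_mask,
                       stable_everywhere_mask, summarize_across_paths)
from .data import (AccessibilityMatrix, filter_sites,
                   read_accessibility_table, subset_cells)
from .errors import ConfigurationError
from .evaluation import (branch_change_sites, delta_scores, rf_distance,
                         sensitivity_specificity)
from .infer import bootstrap_support, nj_tree, pairwise_difference_matrix
from .likelihood import ml_search, select_model_aic
from .parsimony import mp_exhaustive
from .simulate import SimulationConfig, reference_topology, simulate_matrix

__all__ = ["RunConfig", "RunReport", "run_analysis"]

logger = logging.getLogger(__name__)

#: Parent-child steps of the myeloid hierarchy (for the "no change
#: elsewhere" condition of lineage-specific site selection).
MYELOID_STEPS = (("LSK", "CMP"), ("CMP", "GMP"), ("CMP", "MEP"),
                 ("GMP", "Neu"), ("GMP", "Mon"), ("MEP", "Ery"), ("MEP", "iMK"))


@dataclass
class RunConfig:
    """Everything one analysis run needs."""

    out_dir: str = "chromphylo_run"
    input_table: str | None = None            # load this table ...
    cell_columns: Sequence[str] = hp.OBSERVED_CELLS
    simulation: SimulationConfig | None = None  # ... or simulate (default)
    methods: Sequence[str] = ("nj", "mp", "ml")
    model: str = "BIN+I+R4"                   # ML model tag or "auto"
    bootstrap: int = 0                        # replicates (0 = skip)
    seed: int = 0
    analysis_cells: Sequence[str] = hp.ANALYSIS_CELLS
    paths: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(hp.LINEAGE_PATHS))
    drop_other_variant: bool = True
    drop_imk_variant: bool = False
    outgroup: str = hp.STEM

    def validate(self) -> None:
        bad = [m for m in self.methods if m not in ("nj", "mp", "ml")]
        if bad:
            raise ConfigurationError(f"unknown methods {bad}")
        for name, path in self.paths.items():
            for cell in path:
                if cell not in self.cell_columns:
                    raise ConfigurationError(
                        f"path {name!r} uses {cell!r}, not in cell_columns")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


@dataclass
class RunReport:
    """Structured record of one run; serialisable to JSON."""

    config: dict
    stages: dict[str, Any] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonify)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _infer_tree(method: str, matrix: AccessibilityMatrix, config: RunConfig):
    if method == "nj":
        return nj_tree(pairwise_difference_matrix(matrix)), {}
    if method == "mp":
        score, trees = mp_exhaustive(matrix)
        return trees[0], {"score": score, "n_cooptimal": len(trees)}
    tag = config.model
    extra = {}
    if tag == "auto":
        start = nj_tree(pairwise_difference_matrix(matrix))
        best, table = select_model_aic(start, matrix)
        tag = best.model.tag
        extra["aic_table"] = table.to_dict(orient="records")
    tree = ml_search(matrix, tag)
    extra.update({"model": tag, "lnL": tree.ml_result.lnL,
                  "AIC": tree.ml_result.aic})
    return tree, extra


def run_analysis(config: RunConfig) -> RunReport:
    """Execute all stages in order; see the module docstring."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=_config_dict(config))
    report.version = __import__("chromphylo").__version__
    t_start = time.time()

    # ------------------------------------------------ stage: input
    truth = None
    if config.input_table is not None:
        matrix = read_accessibility_table(config.input_table, config.cell_columns)
        report.stages["input"] = {"source": str(config.input_table)}
    else:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        matrix, truth = simulate_matrix(sim)
        report.stages["input"] = {"source": "simulation",
                                  "seed": sim.seed, "n_sites": sim.n_sites}
    logger.info("input: %s", matrix)

    # ------------------------------------------------ stage: classification
    cls = classify_matrix(matrix, config.paths)
    summary = summarize_across_paths(cls)
    other = other_site_mask(cls)
    stable_all = stable_everywhere_mask(cls)
    report.stages["classification"] = {
        "per_path_counts": cls.counts.to_dict(orient="index"),
        "summary_counts": summary.value_counts().to_dict(),
        "n_other_any_path": int(other.sum()),
        "n_stable_all_paths": int(stable_all.sum()),
    }
    cls.labels.map(str).assign(summary=summary).to_csv(
        out / "site_classes.tsv", sep="\t", index_label="site_id")
    report.manifest["site_classes"] = str(out / "site_classes.tsv")

    # ------------------------------------------------ stage: tree inference
    ref = reference_topology(config.simulation or SimulationConfig()) \
        if truth is not None else None
    site_variants = {"all_sites": np.ones(matrix.n_sites, dtype=bool)}
    if config.drop_other_variant:
        site_variants["no_other"] = ~other
    panels = {"full": list(config.analysis_cells)}
    if config.drop_imk_variant:
        panels["no_iMK"] = [c for c in config.analysis_cells if c != "iMK"]
    trees_stage: dict[str, Any] = {}
    for method in config.methods:
        for vname, mask in site_variants.items():
            for pname, panel in panels.items():
                sub = subset_cells(filter_sites(matrix, mask), panel)
                tree, extra = _infer_tree(method, sub, config)
                if config.bootstrap:
                    tree = bootstrap_support(sub, method, B=config.bootstrap,
                                             seed=config.seed)
                key = f"{method}:{vname}:{pname}"
                fname = out / f"tree_{method}_{vname}_{pname}.nwk"
                fname.write_text(to_newick(tree) + "\n")
                report.manifest[f"tree:{key}"] = str(fname)
                entry = {"newick": to_newick(tree), **extra}
                if ref is not None and pname == "full":
                    entry["rf_to_truth"] = rf_distance(tree, ref)
                trees_stage[key] = entry
                logger.info("tree %s done", key)
    report.stages["trees"] = trees_stage

    # ------------------------------------------------ stage: reconstruction
    recon_methods = []
    if "mp" in config.methods:
        recon_methods += ["acctran", "deltran"]
    if "ml" in config.methods:
        recon_methods += ["ml"]
    validation: dict[str, Any] = {"skipped": [m for m in
                                              ("acctran", "deltran", "ml")
                                              if m not in recon_methods]}
    have_progenitors = all(p in matrix.cell_names for p in hp.PROGENITOR_NODES)
    if recon_methods:
        informative = filter_sites(matrix, ~stable_all)
        tag = config.model if config.model != "auto" else "BIN+I+R4"
        est = reconstruct(informative, model_tag=tag, outgroup=config.outgroup)
        validation["n_sites_used"] = informative.n_sites
        validation["ambiguous_counts"] = est.ambiguous_counts().to_dict()
        calls_out = est.acctran.add_suffix(":acctran") \
            .join(est.deltran.add_suffix(":deltran")) \
            .join(est.ml_calls.add_suffix(":ml")) \
            .join(est.marginals.add_suffix(":p_open"))
        calls_out.to_csv(out / "ancestral_states.tsv", sep="\t",
                         index_label="site_id")
        report.manifest["ancestral_states"] = str(out / "ancestral_states.tsv")
        if have_progenitors:
            cls_inf = classify_matrix(informative, config.paths)
            other_inf = other_site_mask(cls_inf)
            for variant, vmask in (("all_sites", np.ones(informative.n_sites, bool)),
                                   ("no_other", ~other_inf)):
                if variant == "no_other" and not config.drop_other_variant:
                    continue
                block = {}
                for node, progenitor in hp.PROGENITOR_NODES.items():
                    obs = informative.column(progenitor)[vmask]
                    for m in recon_methods:
                        pred = est.calls(m)[node].to_numpy()[vmask]
                        cs = sensitivity_specificity(pred, obs,
                                                     node=f"{node}:{m}")
                        block[f"{node}:{m}"] = cs.as_dict()
                validation[variant] = block
    report.stages["validation"] = validation

    # ------------------------------------------------ stage: treelikeness
    delta_stage: dict[str, Any] = {}
    for vname, mask in site_variants.items():
        sub = subset_cells(filter_sites(matrix, mask), config.analysis_cells)
        d = pairwise_difference_matrix(sub)
        for group, taxa in (("lymphoid", hp.LYMPHOID_DELTA_TAXA),
                            ("myeloid", hp.MYELOID_DELTA_TAXA)):
            if all(t in sub.cell_names for t in taxa):
                ds = delta_scores(d, taxa)
                delta_stage[f"{group}:{vname}"] = {
                    "mean": ds.mean,
                    "n_quartets": len(ds.quartets),
                    "per_taxon_mean": ds.per_taxon_mean().to_dict(),
                }
    report.stages["delta"] = delta_stage

    # ------------------------------------------------ stage: branch changes
    if have_progenitors:
        changes = {}
        for parent, child in (("LSK", "CMP"), ("CMP", "MEP"), ("CMP", "GMP")):
            others = [s for s in MYELOID_STEPS if s != (parent, child)]
            for direction in ("open_to_closed", "closed_to_open"):
                ids = branch_change_sites(matrix, parent, child, direction,
                                          unchanged_in=others)
                changes[f"{parent}->{child}:{direction}"] = len(ids)
        report.stages["branch_changes"] = changes

    report.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
    report.stages["runtime_s"] = round(time.time() - t_start, 2)
    report.write(out / "report.json")
    report.manifest["report"] = str(out / "report.json")
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["methods"] = list(config.methods)
    d["cell_columns"] = list(config.cell_columns)
    d["analysis_cells"] = list(config.analysis_cells)
    d["paths"] = {k: list(v) for k, v in config.paths.items()}
    return d
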