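"""End-to-end pipeline: simulate/load -> filter -> dissimilarity ->
cluster -> ordinate -> indicators -> PD partition -> classify.

One JSON config drives all stages.  Every stage writes its outputs
under the configured output directory and records an entry in
``manifest.json`` holding the SHA-256 of its inputs and outputs, its
parameters and runtime.  On rerun with unchanged inputs a stage is
skipped (cache hit) after verifying its recorded output checksums; a
checksum mismatch (e.g. a corrupted cache file) raises instead of
silently reusing or recomputing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .assemblages import (
    AssemblageMatrix,
    SiteCovariates,
    align_to_tree,
    filter_min_genera,
)
from .classification import (
    compare_classifiers,
    delimitation_correspondence,
    rank_climate_variables,
)
from .clustering import select_k
from .dissimilarity import (
    DissimilarityMatrix,
    phylosor_complement,
    unifrac_complement,
)
from .indicators import indicator_nodes, indval_genera
from .ordination import evopca
from .pd_partition import partition_pd
from .simulate import SimulationConfig, simulate_dataset
from .tree import read_newick

__all__ = ["PipelineConfig", "run_pipeline", "StaleCacheError"]

log = logging.getLogger(__name__)

_CONFIG_KEYS = {
    "output_dir", "tree_path", "matrix_path", "covariates_path",
    "simulation", "min_genera", "metric", "k_max", "k_values", "n_init",
    "seed", "n_axes", "specificity_threshold", "n_trees",
    "representation", "classify_k",
}


class StaleCacheError(RuntimeError):
    """A cached stage output no longer matches its recorded checksum."""


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    Either the three input paths (tree/matrix/covariates) or a
    ``simulation`` block must be given.  Unknown keys are rejected.
    """

    output_dir: str
    seed: int
    tree_path: str = None
    matrix_path: str = None
    covariates_path: str = None
    simulation: dict = None
    min_genera: int = 5
    metric: str = "phylosor"
    k_max: int = 10
    k_values: list = field(default_factory=lambda: [2, 3, 4, 5])
    n_init: int = 25
    n_axes: int = 5
    specificity_threshold: float = 0.6
    n_trees: int = 500
    representation: str = "rows"
    classify_k: int = 4

    def __post_init__(self):
        if self.simulation is None and not (
            self.tree_path and self.matrix_path
        ):
            raise ValueError(
                "config needs either a simulation block or tree_path "
                "and matrix_path"
            )
        if self.metric not in ("phylosor", "unifrac"):
            raise ValueError("metric must be 'phylosor' or 'unifrac'")
        if self.classify_k not in self.k_values:
            raise ValueError("classify_k must be one of k_values")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in d or "seed" not in d:
            raise ValueError("config requires output_dir and seed")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


class _Manifest:
    def __init__(self, path):
        self.path = path
        self.entries = {}
        if os.path.exists(path):
            with open(path) as fh:
                self.entries = json.load(fh)

    def save(self):
        with open(self.path, "w") as fh:
            json.dump(self.entries, fh, indent=2)

    def cache_hit(self, stage: str, inputs_hash: str) -> bool:
        """True if the stage ran before on identical inputs and its
        outputs are intact; raises :class:`StaleCacheError` on
        corruption."""
        entry = self.entries.get(stage)
        if entry is None or entry["inputs_hash"] != inputs_hash:
            return False
        for path, digest in entry["outputs"].items():
            if not os.path.exists(path):
                return False
            if _sha256(path) != digest:
                raise StaleCacheError(
                    f"stage {stage!r}: output {path} does not match its "
                    "recorded checksum; delete it to recompute"
                )
        return True

    def record(self, stage: str, inputs_hash: str, params: dict,
               outputs: list, runtime: float):
        self.entries[stage] = {
            "inputs_hash": inputs_hash,
            "params": params,
            "outputs": {p: _sha256(p) for p in outputs},
            "runtime_s": runtime,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.save()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest
    entries.  Stages whose inputs are unchanged since the last run are
    skipped."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest = _Manifest(os.path.join(out, "manifest.json"))

    def path(name):
        return os.path.join(out, name)

    # -- stage: inputs (simulate or load) ---------------------------------
    t0 = time.time()
    if config.simulation is not None:
        sim_params = dict(config.simulation)
        sim_params.setdefault("seed", config.seed)
        sim_cfg = SimulationConfig(**sim_params)
        ih = _hash_obj(("simulate", asdict(sim_cfg)))
        sim_out = [path("tree.nwk"), path("assemblages.csv"),
                   path("covariates.csv"), path("truth.json")]
        if not manifest.cache_hit("simulate", ih):
            ds = simulate_dataset(sim_cfg)
            ds.write(out)
            manifest.record("simulate", ih, asdict(sim_cfg), sim_out,
                            time.time() - t0)
        tree_path, matrix_path = path("tree.nwk"), path("assemblages.csv")
        covariates_path = path("covariates.csv")
    else:
        tree_path, matrix_path = config.tree_path, config.matrix_path
        covariates_path = config.covariates_path

    tree = read_newick(tree_path)
    matrix = AssemblageMatrix.from_wide_csv(matrix_path)
    cov = (SiteCovariates.from_csv(covariates_path)
           if covariates_path else None)

    # -- stage: filter -----------------------------------------------------
    t0 = time.time()
    ih = _hash_obj(("filter", _sha256(tree_path), _sha256(matrix_path),
                    config.min_genera))
    filtered_path = path("assemblages_filtered.csv")
    if not manifest.cache_hit("filter", ih):
        aligned, rep_align = align_to_tree(matrix, tree)
        filtered, rep_min = filter_min_genera(aligned, config.min_genera)
        filtered.to_csv(filtered_path)
        manifest.record("filter", ih, {
            "min_genera": config.min_genera,
            "aligned": str(rep_align), "filtered": str(rep_min),
        }, [filtered_path], time.time() - t0)
    matrix = AssemblageMatrix.from_wide_csv(filtered_path)
    if cov is not None:
        cov = cov.subset(matrix.site_ids)

    # -- stage: dissimilarity ---------------------------------------------
    t0 = time.time()
    ih = _hash_obj(("dissim", _sha256(filtered_path),
                    _sha256(tree_path), config.metric))
    dissim_path = path("dissimilarity.csv")
    if not manifest.cache_hit("dissim", ih):
        fn = (phylosor_complement if config.metric == "phylosor"
              else unifrac_complement)
        d = fn(tree, matrix)
        d.to_csv(dissim_path)
        manifest.record("dissim", ih, {"metric": config.metric},
                        [dissim_path], time.time() - t0)
    d = DissimilarityMatrix.from_csv(dissim_path)

    # -- stage: cluster ----------------------------------------------------
    t0 = time.time()
    ih = _hash_obj(("cluster", _sha256(dissim_path), config.k_max,
                    config.k_values, config.n_init, config.seed,
                    config.representation))
    labels_path, ksel_path = path("labels.csv"), path("k_selection.json")
    if not manifest.cache_hit("cluster", ih):
        report, solutions = select_k(
            d, seed=config.seed, k_max=config.k_max, n_init=config.n_init,
            representation=config.representation,
        )
        lab = pd.DataFrame(
            {f"K{k}": solutions[k].labels for k in config.k_values},
            index=d.site_ids,
        )
        lab.index.name = "site"
        lab.to_csv(labels_path)
        with open(ksel_path, "w") as fh:
            json.dump({
                "elbow_k": report.elbow_k,
                "silhouette_k": report.silhouette_k,
                "tss_curve": {str(k): v for k, v in
                              report.tss_curve.items()},
                "avg_sil_curve": {str(k): v for k, v in
                                  report.avg_sil_curve.items()},
            }, fh, indent=2)
        manifest.record("cluster", ih, {
            "k_max": config.k_max, "n_init": config.n_init,
            "seed": config.seed,
        }, [labels_path, ksel_path], time.time() - t0)
    labels = pd.read_csv(labels_path, index_col=0)

    # -- stage: evoPCA -----------------------------------------------------
    t0 = time.time()
    ih = _hash_obj(("evopca", _sha256(filtered_path), _sha256(tree_path),
                    config.n_axes))
    evo_outs = [path("evopca_site_scores.csv"),
                path("evopca_clade_loadings.csv"),
                path("evopca_eigenvalues.csv")]
    if not manifest.cache_hit("evopca", ih):
        res = evopca(tree, matrix, n_axes=config.n_axes)
        res.site_scores.to_csv(evo_outs[0])
        loads = res.clade_loadings.copy()
        loads["mrca_tips"] = ["|".join(p) for p in res.mrca_pairs]
        loads.to_csv(evo_outs[1])
        pd.DataFrame({
            "eigenvalue": res.eigenvalues,
            "var_explained": res.var_explained,
        }, index=[f"axis{i+1}" for i in range(len(res.eigenvalues))]
        ).to_csv(evo_outs[2])
        manifest.record("evopca", ih, {"n_axes": config.n_axes},
                        evo_outs, time.time() - t0)

    # -- stage: indicators + PD partition per K ---------------------------
    for k in config.k_values:
        lab_k = labels[f"K{k}"].to_numpy()
        t0 = time.time()
        ih = _hash_obj(("indicators", _sha256(filtered_path),
                        _sha256(tree_path), _sha256(labels_path), k,
                        config.specificity_threshold))
        outs = [path(f"indicator_genera_K{k}.csv"),
                path(f"indicator_clades_K{k}.csv"),
                path(f"pd_partition_K{k}.json")]
        if manifest.cache_hit(f"indicators_K{k}", ih):
            continue
        gen_table = indval_genera(matrix, lab_k)
        best = gen_table.best.copy()
        best["combo"] = best["combo"].map(
            lambda c: "+".join(map(str, c)))
        best.to_csv(outs[0], index=False)
        _, selection, _ = indicator_nodes(tree, matrix, lab_k)
        sel = selection.copy()
        sel["combo"] = sel["combo"].map(lambda c: "+".join(map(str, c)))
        sel.to_csv(outs[1], index=False)
        part = partition_pd(tree, matrix, gen_table,
                            threshold=config.specificity_threshold)
        part.to_json(outs[2])
        manifest.record(f"indicators_K{k}", ih, {
            "K": k, "threshold": config.specificity_threshold,
        }, outs, time.time() - t0)

    # -- stage: classify ---------------------------------------------------
    if cov is not None:
        t0 = time.time()
        ih = _hash_obj(("classify", _sha256(covariates_path),
                        _sha256(labels_path), config.classify_k,
                        config.n_trees, config.seed))
        cls_path = path("classification.json")
        if not manifest.cache_hit("classify", ih):
            lab_c = labels[f"K{config.classify_k}"].to_numpy()
            clim, geo = compare_classifiers(
                cov, lab_c, seed=config.seed, n_trees=config.n_trees)
            lab2 = labels["K2"].to_numpy() if "K2" in labels else None
            report = {
                "classify_k": config.classify_k,
                "climate": asdict(clim),
                "geography": asdict(geo),
            }
            if lab2 is not None:
                report["delimitations"] = [
                    asdict(mm) for mm in
                    delimitation_correspondence(cov, lab2)
                ]
                aic = rank_climate_variables(cov, lab2)
                report["aic_table_K2"] = aic.to_dict(orient="records")
            with open(cls_path, "w") as fh:
                json.dump(report, fh, indent=2, default=float)
            manifest.record("classify", ih, {
                "classify_k": config.classify_k,
                "n_trees": config.n_trees, "seed": config.seed,
            }, [cls_path], time.time() - t0)

    return manifest.entries
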