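"""End-to-end pipeline runner: chains the analysis stages and writes TSVs.

Stages run in the fixed order simulate -> preprocess -> network -> annotate
-> associate -> preserve; each writes its result tables into the output
directory and the run ends with a JSON manifest recording parameters, seed
and outputs so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, preprocess, simulate
from .annotate import enrichment_table, identify_hubs
from .associate import (differential_abundance, fit_cognitive_slopes,
                        module_group_comparison, trait_correlations)
from .config import PipelineConfig
from .containers import AbundanceMatrix, ModuleAssignment, validate_metadata
from .network import (build_network, cluster_dendrogram, detect_modules,
                      enforce_kme_consistency, kme_table, merge_close_modules,
                      module_eigenproteins)
from .preserve import (compare_synthetic_eigenproteins, module_preservation,
                       synthetic_eigenproteins)

log = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "preprocess", "network", "annotate", "associate", "preserve"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the in-memory result bundle."""
    unknown = set(config.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in config.stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {"config": config}
    written: list[str] = []

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        written.append(name)

    for stage in stages:
        log.info("stage: %s", stage)
        if stage == "simulate":
            sizes = np.random.default_rng(config.seed).integers(
                40, 81, size=config.sim_n_modules)
            budget = 0.6 * config.sim_n_proteins
            if sizes.sum() > budget:  # keep background proteins in small runs
                sizes = np.maximum(config.min_module_size,
                                   (sizes * budget / sizes.sum()).astype(int))
            matrix, metadata, truth = simulate.generate_discovery_cohort(
                n_proteins=config.sim_n_proteins,
                n_samples=config.sim_n_samples,
                module_sizes=tuple(int(s) for s in sizes),
                loading_range=config.sim_loading_range,
                noise_sd=config.sim_noise_sd,
                min_module_size=config.min_module_size,
                seed=config.seed,
            )
            cognition = simulate.generate_cognition(metadata, truth,
                                                    seed=config.seed + 1)
            io.write_abundance(matrix, out / "abundance.tsv")
            written.append("abundance.tsv")
            save(metadata, "metadata.tsv", index=False)
            save(cognition, "cognition.tsv", index=False)
            io.write_manifest(out / "truth.json",
                              membership=truth.membership,
                              loadings=truth.loadings,
                              group_effects={str(k): v for k, v in
                                             truth.group_effects.items()})
            written.append("truth.json")
            state.update(matrix=matrix, metadata=metadata, truth=truth,
                         cognition=cognition)
        elif stage == "preprocess":
            matrix = state.get("matrix") or _require_input(
                config.abundance, "preprocess", io.read_abundance)
            metadata = state.get("metadata")
            if metadata is None:
                metadata = _require_input(config.metadata, "preprocess",
                                          io.read_metadata)
            metadata = validate_metadata(metadata.reset_index(drop=True))
            matrix, removed = preprocess.remove_outliers(
                matrix, cutoff=config.outlier_cutoff,
                iterate=config.outlier_iterate)
            model = preprocess.fit_covariate_model(
                matrix, metadata, n_boot=config.n_boot, seed=config.seed)
            matrix = preprocess.apply_adjustment(matrix, model, metadata)
            save(pd.DataFrame({"removed_sample": removed}), "outliers.tsv",
                 index=False)
            save(pd.DataFrame({"beta_age": model.beta_age,
                               "beta_sex": model.beta_sex}),
                 "covariate_coefficients.tsv", index_label="protein_id")
            io.write_abundance(matrix, out / "adjusted_abundance.tsv")
            written.append("adjusted_abundance.tsv")
            state.update(matrix=matrix, metadata=metadata, removed=removed,
                         covariate_model=model)
        elif stage == "network":
            matrix = state.get("matrix") or _require_input(
                config.abundance, "network", io.read_abundance)
            model = build_network(matrix, beta=config.power,
                                  tom_denom=config.tom_denom,
                                  correlation=config.correlation)
            linkage, d = cluster_dendrogram(model.tom)
            assignment = detect_modules(
                linkage, d, matrix.protein_ids,
                deep_split=config.deep_split,
                min_module_size=config.min_module_size,
                pam_stage=config.pam_stage,
                pam_respects_dendro=config.pam_respects_dendro)
            assignment = merge_close_modules(matrix, assignment,
                                             cut_height=config.merge_cut_height)
            grey_before = assignment.grey_fraction()
            assignment = enforce_kme_consistency(
                matrix, assignment, p_threshold=config.kme_p_threshold,
                max_iter=config.kme_max_iter)
            eig = module_eigenproteins(matrix, assignment)
            kme = kme_table(matrix, eig, method=config.correlation)
            own = kme.own_module_kme(assignment)
            io.write_assignment(assignment, matrix, out / "modules.tsv",
                                kme_own=own.to_dict())
            written.append("modules.tsv")
            save(eig.values, "eigenproteins.tsv", index_label="module")
            save(kme.kme, "kme.tsv", index_label="protein_id")
            save(pd.DataFrame(linkage,
                              columns=["left", "right", "height", "count"]),
                 "dendrogram.tsv", index=False)
            state.update(matrix=matrix, network=model, assignment=assignment,
                         eigenproteins=eig, kme=kme, grey_before=grey_before)
        elif stage == "annotate":
            _need(state, "assignment", "annotate")
            tables = []
            for key, path in (("gene_sets", config.gene_sets),
                              ("cell_markers", config.cell_markers)):
                if path is None:
                    continue
                sets = io.read_gmt(path, source=key)
                tables.append(enrichment_table(state["assignment"], sets,
                                               state["matrix"]))
            if tables:
                save(pd.concat(tables, ignore_index=True), "enrichment.tsv",
                     index=False)
            hubs = identify_hubs(state["kme"], state["assignment"],
                                 percentile=config.hub_percentile)
            save(hubs.table, "hubs.tsv", index=False)
            state["hubs"] = hubs
        elif stage == "associate":
            _need(state, "eigenproteins", "associate")
            metadata = state["metadata"]
            comp = module_group_comparison(state["eigenproteins"], metadata)
            save(comp, "module_group_comparison.tsv", index=False)
            traits = trait_correlations(state["eigenproteins"].values,
                                        metadata.set_index("sample_id", drop=False)
                                        if metadata.index.name != "sample_id"
                                        else metadata)
            save(traits, "module_trait_correlations.tsv", index=False)
            cognition = state.get("cognition")
            if cognition is None and config.cognition:
                cognition = io.read_cognition(config.cognition)
            if cognition is not None:
                slopes = fit_cognitive_slopes(cognition, metadata)
                save(slopes.slopes.to_frame(), "cognitive_slopes.tsv",
                     index_label="subject_id")
                state["slopes"] = slopes
            da = differential_abundance(state["matrix"], metadata,
                                        assignment=state["assignment"])
            save(da, "differential_abundance.tsv", index=False)
            state["da"] = da
        elif stage == "preserve":
            assignment = state.get("assignment")
            if assignment is None:
                if not config.reference_assignment:
                    raise ValueError("reference modules required for the "
                                     "preserve stage")
                assignment = io.read_assignment(config.reference_assignment)
            if config.target_abundance is None and "target_matrix" not in state:
                raise ValueError("preserve stage needs target_abundance")
            target = state.get("target_matrix") or io.read_abundance(
                config.target_abundance)
            report = module_preservation(state["matrix"], target, assignment,
                                         n_perm=config.n_perm, seed=config.seed,
                                         beta=config.power,
                                         correlation=config.correlation)
            save(report.table, "preservation.tsv")
            synth = synthetic_eigenproteins(target, assignment,
                                            missing_threshold=config.missing_threshold)
            save(synth.values, "synthetic_eigenproteins.tsv",
                 index_label="module")
            tmd = state.get("target_metadata")
            if tmd is None and config.target_metadata:
                tmd = io.read_metadata(config.target_metadata)
            if tmd is not None and "group" in tmd.columns:
                grps = [g for g in pd.unique(tmd["group"]) if g != "control"]
                contrasts = [(g, "control") for g in grps]
                cmp = compare_synthetic_eigenproteins(synth, tmd, contrasts)
                save(cmp, "synthetic_contrasts.tsv", index=False)
            state["preservation"] = report
            state["synthetic"] = synth

    io.write_manifest(out / "manifest.json",
                      stages=stages, seed=config.seed,
                      parameters={k: v for k, v in vars(config).items()
                                  if not isinstance(v, (list,)) or k == "stages"},
                      outputs=sorted(written))
    state["outputs"] = written
    return state


def _require_input(path, stage: str, reader):
    if path is None:
        raise ValueError(f"stage {stage!r} needs an upstream input that was "
                         "neither configured nor produced by an earlier stage")
    return reader(path)


def _need(state: dict, key: str, stage: str) -> None:
    if key not in state:
        raise ValueError(f"stage {stage!r} requires the network stage output "
                         f"({key}) — run network first or point the config at it")
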