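"""End-to-end orchestration: simulate -> preprocess -> deconvolve -> scan ->
mediate -> report, with a manifest for exact re-runs.

Every stage derives its random stream from the single configured seed, logs
its parameters and hashes its outputs into ``manifest.json``; no stage reads
system entropy, so the same configuration and seed reproduce the artifact
directory byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np

from . import io as mio
from .association import ewas_scan, stratified_by_smoking
from .cells import append_cell_proportions, estimate_cell_proportions, select_discriminating_probes
from .config import RunConfig, config_to_dict
from .containers import MethylationMatrix
from .mediation import bootstrap_mediation, report_mediation_block
from .preprocess import filter_missingness
from .reporting import cessation_trajectories, incremental_prediction, render_tables
from .simulate import (
    apply_technical_layer,
    assign_chips,
    draw_nested_case_control,
    mediator_probe_ids,
    simulate_population,
    simulate_reference_panel,
)

logger = logging.getLogger("methmediate")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs stay on disk for inspection."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage subset and return the manifest.

    Later stages require the artifacts of earlier ones in ``config.out_dir``
    (either produced in the same run or by a previous run with the same
    layout). The manifest records, per stage, the derived seed, the parameter
    set and the SHA-256 of every file written.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    sim = config.simulation.with_(seed=config.seed)
    ana = config.analysis
    stage_seeds = {
        name: int(np.random.SeedSequence((config.seed, i)).generate_state(1)[0] % (2**31))
        for i, name in enumerate(RunConfig.VALID_STAGES)
    }
    manifest: dict = {"seed": config.seed, "config": config_to_dict(config), "stages": {}}

    def path(name: str) -> str:
        return os.path.join(out, name)

    def finish(stage: str, files: list[str], **params) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seeds[stage],
            "params": params,
            "outputs": {os.path.basename(f): _sha256(f) for f in files},
        }

    matrix = sheet = None

    if "simulate" in config.stages:
        try:
            logger.info("simulate: population of %d subjects", sim.n_population)
            pop_matrix, pop_sheet, truth = simulate_population(sim)
            cc_sheet = draw_nested_case_control(
                pop_sheet, sim.n_pairs, matching_vars=(), seed=stage_seeds["simulate"]
            )
            cc_sheet = assign_chips(
                cc_sheet, sim.batch.samples_per_chip, seed=stage_seeds["simulate"]
            )
            cc_matrix = pop_matrix.subset_samples(list(cc_sheet["sample_id"]))
            cc_matrix = apply_technical_layer(
                cc_matrix, cc_sheet, sim, seed=stage_seeds["simulate"]
            )
            profiles, purified, labels = simulate_reference_panel(
                sim, seed=stage_seeds["simulate"]
            )
            files = [
                path("beta_matrix.tsv"),
                path("probe_annotations.tsv"),
                path("sample_sheet.csv"),
                path("truth.json"),
                path("reference_profiles.tsv"),
                path("purified_panel.tsv"),
                path("purified_labels.csv"),
            ]
            mio.write_beta_matrix(cc_matrix, files[0], files[1])
            mio.write_sample_sheet(cc_sheet, files[2])
            mio.write_truth(truth, files[3])
            mio.write_reference_profiles(profiles, files[4])
            mio.write_beta_matrix(purified, files[5])
            labels.rename_axis("sample_id").to_frame().to_csv(files[6])
            finish("simulate", files, n_pairs=sim.n_pairs, n_probes=sim.n_probes)
        except Exception as exc:  # noqa: BLE001 - halt with stage context
            raise StageError("simulate", exc) from exc

    def load_matrix_sheet():
        m = mio.read_beta_matrix(path("beta_matrix.tsv"), path("probe_annotations.tsv"))
        s = mio.read_sample_sheet(path("sample_sheet.csv"))
        return m, s

    if "preprocess" in config.stages:
        try:
            matrix, sheet = load_matrix_sheet()
            matrix, report = filter_missingness(
                matrix, ana.probe_missing_threshold, ana.sample_missing_threshold
            )
            sheet = sheet[sheet["sample_id"].isin(matrix.sample_ids)].reset_index(drop=True)
            # a sample exclusion orphans its matched partner: drop broken pairs
            if "pair_id" in sheet.columns and sheet["pair_id"].notna().any():
                counts = sheet["pair_id"].value_counts()
                whole = counts[counts == 2].index
                sheet = sheet[sheet["pair_id"].isin(whole)].reset_index(drop=True)
                matrix = matrix.subset_samples(list(sheet["sample_id"]))
            mio.write_beta_matrix(
                matrix, path("beta_filtered.tsv"), path("probe_annotations_filtered.tsv")
            )
            mio.write_sample_sheet(sheet, path("sample_sheet_filtered.csv"))
            mio.write_filter_report(report, path("filter_report.json"))
            finish(
                "preprocess",
                [
                    path("beta_filtered.tsv"),
                    path("probe_annotations_filtered.tsv"),
                    path("sample_sheet_filtered.csv"),
                    path("filter_report.json"),
                ],
                probe_threshold=ana.probe_missing_threshold,
                sample_threshold=ana.sample_missing_threshold,
            )
        except Exception as exc:
            raise StageError("preprocess", exc) from exc

    def load_filtered():
        m = mio.read_beta_matrix(
            path("beta_filtered.tsv"), path("probe_annotations_filtered.tsv")
        )
        s = mio.read_sample_sheet(path("sample_sheet_filtered.csv"))
        return m, s

    if "deconvolve" in config.stages:
        try:
            matrix, sheet = load_filtered()
            purified = mio.read_beta_matrix(path("purified_panel.tsv"))
            labels = __import__("pandas").read_csv(path("purified_labels.csv"), index_col=0)[
                "cell_type"
            ]
            profiles = mio.read_reference_profiles(path("reference_profiles.tsv"))
            selected = select_discriminating_probes(purified, labels, fwer=ana.fwer_cells)
            usable = [p for p in selected if p in matrix.probe_ids]
            props = estimate_cell_proportions(
                matrix.subset_probes(usable),
                type(profiles)(profiles.profiles.loc[usable]),
            )
            sheet = append_cell_proportions(sheet, props)
            mio.write_sample_sheet(sheet, path("sample_sheet_cells.csv"))
            props.to_csv(path("cell_proportions.tsv"), sep="\t", index_label="sample_id")
            finish(
                "deconvolve",
                [path("sample_sheet_cells.csv"), path("cell_proportions.tsv")],
                n_discriminating=len(usable),
                fwer=ana.fwer_cells,
            )
        except Exception as exc:
            raise StageError("deconvolve", exc) from exc

    if "scan" in config.stages:
        try:
            matrix, _ = load_filtered()
            sheet = mio.read_sample_sheet(path("sample_sheet_cells.csv"))
            scan = ewas_scan(matrix, sheet, adjust=("chip", "position", "cells", "age"))
            scan.to_csv(path("scan_results.tsv"), sep="\t", index=False)
            finish("scan", [path("scan_results.tsv")], n_probes=matrix.n_probes)
        except Exception as exc:
            raise StageError("scan", exc) from exc

    if "mediate" in config.stages:
        try:
            matrix, _ = load_filtered()
            sheet = mio.read_sample_sheet(path("sample_sheet_cells.csv"))
            mediators = [p for p in mediator_probe_ids(sim) if p in matrix.probe_ids]
            blocks = {}
            for label, probes in _mediator_blocks(mediators):
                blocks[label] = bootstrap_mediation(
                    sheet,
                    matrix,
                    probes,
                    prevalence=ana.prevalence,
                    n_bootstrap=ana.n_bootstrap,
                    n_mc=ana.n_mc,
                    seed=stage_seeds["mediate"],
                )
            table = report_mediation_block(blocks)
            table.to_csv(path("mediation_results.tsv"), sep="\t", index=False)
            with open(path("mediation_results.json"), "w") as fh:
                json.dump({k: v.to_dict() for k, v in blocks.items()}, fh, indent=1, sort_keys=True)
            finish(
                "mediate",
                [path("mediation_results.tsv"), path("mediation_results.json")],
                prevalence=ana.prevalence,
                n_mc=ana.n_mc,
                n_bootstrap=ana.n_bootstrap,
            )
        except Exception as exc:
            raise StageError("mediate", exc) from exc

    if "report" in config.stages:
        try:
            import pandas as pd

            matrix, _ = load_filtered()
            sheet = mio.read_sample_sheet(path("sample_sheet_cells.csv"))
            mediators = [p for p in mediator_probe_ids(sim) if p in matrix.probe_ids]
            scan = (
                pd.read_csv(path("scan_results.tsv"), sep="\t")
                if os.path.exists(path("scan_results.tsv"))
                else None
            )
            mediation = (
                pd.read_csv(path("mediation_results.tsv"), sep="\t")
                if os.path.exists(path("mediation_results.tsv"))
                else None
            )
            prediction = incremental_prediction(sheet, matrix, mediators) if mediators else None
            trajectory = (
                cessation_trajectories(matrix, sheet, mediators[0]) if mediators else None
            )
            stratified = (
                stratified_by_smoking(matrix, sheet, mediators[0]) if mediators else None
            )
            files = render_tables(
                os.path.join(out, "report"),
                scan=scan,
                stratified=stratified,
                mediation=mediation,
                trajectory=trajectory,
                prediction=prediction,
            )
            finish("report", files)
        except Exception as exc:
            raise StageError("report", exc) from exc

    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _mediator_blocks(mediators: list[str]):
    for m in mediators:
        yield m, [m]
    if len(mediators) > 1:
        yield "joint", list(mediators)
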