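"""End-to-end pipeline: counts -> CSTs -> frequency/GEE tables -> stability -> differential abundance.

``run_pipeline`` executes every analysis stage on one cohort and writes all
tabular outputs as TSV plus a JSON run manifest (config, seed, package
version, per-stage row counts and collected warnings), so a run can be
reproduced exactly from its manifest.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from . import __version__
from .tables import CountTable, read_count_table, to_relative_abundance
from .divergence import pairwise_distances
from .cst import ward_cluster, name_csts, cst_frequency_table
from .stability import stability_table, stability_contrast
from .gee import cst_gee_screen, nugent_association
from .countmodels import differential_abundance

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All analysis thresholds in one serialisable record."""

    counts_path: str = ""
    metadata_path: str = ""
    out_dir: str = "results"
    k_csts: int = 5
    log_base: float = 2.0
    cluster_metric: str = "js_distance"
    min_prevalence: float = 0.25
    q_cut_cst: float = 0.05
    q_cut_diffabund: float = 0.1
    fc_cut: float = 1.5
    nugent_high: int = 7
    quadrature_nodes: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.k_csts < 1 or not 0 < self.min_prevalence <= 1:
            raise ValueError("invalid k_csts or min_prevalence")
        for q in (self.q_cut_cst, self.q_cut_diffabund):
            if not 0 < q < 1:
                raise ValueError("q thresholds must be in (0, 1)")
        if self.fc_cut < 1 or self.nugent_high not in range(0, 11):
            raise ValueError("invalid fc_cut or nugent_high")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def run_pipeline(config: PipelineConfig, table: CountTable | None = None) -> dict:
    """Run every stage on a cohort; returns the manifest dict.

    ``table`` may be passed directly (e.g. a freshly simulated cohort);
    otherwise counts/metadata are read from the configured paths.  Stage
    failures abort with the stage name while earlier outputs stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "version": __version__,
                      "stages": {}, "warnings": []}
    stage = "load"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            t0 = time.time()
            if table is None:
                table = read_count_table(config.counts_path, config.metadata_path)
            manifest["stages"]["load"] = {"n_samples": table.n_samples,
                                          "n_taxa": len(table.taxon_names),
                                          "seconds": round(time.time() - t0, 3)}

            stage = "distances"
            t0 = time.time()
            states = to_relative_abundance(table)
            dist = pairwise_distances(states.to_numpy(), ids=table.sample_ids,
                                      metric=config.cluster_metric,
                                      log_base=config.log_base)
            dist.to_tsv(out / "distance_matrix.tsv")
            manifest["stages"]["distances"] = {"n": len(dist),
                                               "seconds": round(time.time() - t0, 3)}

            stage = "cst_typing"
            t0 = time.time()
            model = name_csts(ward_cluster(dist, k=config.k_csts), states)
            model.to_frame().to_csv(out / "cst_labels.tsv", sep="\t", index=False)
            model.centroids.to_csv(out / "cst_centroids.tsv", sep="\t",
                                   index_label="cst")
            (out / "cst_tree.nwk").write_text(model.tree_newick() + "\n")
            labels = pd.Series(model.label_names(), index=table.sample_ids)
            contingency = cst_frequency_table(labels, table.metadata["group"])
            contingency.to_tsv(out / "cst_frequency.tsv")
            manifest["stages"]["cst_typing"] = {
                "k": config.k_csts,
                "csts": sorted(set(model.cst_names.values())),
                "seconds": round(time.time() - t0, 3)}

            stage = "cst_gee"
            t0 = time.time()
            if labels.nunique() >= 2:
                screen = cst_gee_screen(labels, table.metadata["group"],
                                        table.metadata["subject_id"],
                                        q_threshold=config.q_cut_cst)
                screen.to_csv(out / "cst_gee.tsv", sep="\t", index_label="cst")
                gee_note = {"n_csts": int(labels.nunique())}
            else:
                screen = None
                gee_note = {"n_csts": int(labels.nunique()),
                            "note": "degenerate screen: fewer than 2 CSTs"}
            if "nugent" in table.metadata.columns:
                nug = nugent_association(labels, table.metadata["nugent"],
                                         table.metadata["subject_id"],
                                         high_cutoff=config.nugent_high)
                (out / "nugent_association.json").write_text(
                    json.dumps(nug.to_dict(), indent=1, default=str))
            manifest["stages"]["cst_gee"] = {**gee_note,
                                             "seconds": round(time.time() - t0, 3)}

            stage = "stability"
            t0 = time.time()
            try:
                stab = stability_table(table, labels, log_base=config.log_base)
            except ValueError as exc:
                # no IV-A/IV-B samples: keep the within-subject statistic only
                from .stability import instability_distances
                stab = instability_distances(table, log_base=config.log_base)
                manifest["warnings"].append(f"d_cst4 unavailable: {exc}")
            stab.to_csv(out / "stability.tsv", sep="\t", index_label="sample_id")
            contrasts = {}
            for column in ("log_d_subject_mean", "log_d_cst4"):
                try:
                    contrasts[column] = stability_contrast(stab, column).to_dict()
                except ValueError as exc:
                    contrasts[column] = {"error": str(exc)}
            (out / "stability_contrasts.json").write_text(
                json.dumps(contrasts, indent=1, default=str))
            manifest["stages"]["stability"] = {"n_samples": len(stab),
                                               "seconds": round(time.time() - t0, 3)}

            stage = "differential_abundance"
            t0 = time.time()
            diff = differential_abundance(
                table, min_prevalence=config.min_prevalence,
                q_cut=config.q_cut_diffabund, fc_cut=config.fc_cut,
                n_nodes=config.quadrature_nodes, seed=config.seed)
            diff.to_csv(out / "differential_abundance.tsv", sep="\t",
                        index_label="phylotype")
            manifest["stages"]["differential_abundance"] = {
                "n_phylotypes": len(diff),
                "n_significant": int(diff["significant"].sum()),
                "seconds": round(time.time() - t0, 3)}

            manifest["warnings"] = [str(w.message) for w in caught]
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
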