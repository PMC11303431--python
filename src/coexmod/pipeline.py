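"""End-to-end orchestration: normalize -> network -> modules -> traits -> hubs.

:func:`run_pipeline` wires the stages together the way the CLI's
``run-all`` subcommand exposes them, writing every intermediate table
as TSV plus a JSON manifest.  Machine outputs carry full float
precision and no timestamps, so a rerun with the same config and
inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import pandas as pd

from . import io, modules, network, preprocess, ranking, traits as traits_mod

logger = logging.getLogger("coexmod")


def _version() -> str:
    try:
        return metadata.version("coexmod")
    except metadata.PackageNotFoundError:  # pragma: no cover - dev tree
        return "unknown"


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]             # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)  # stage -> path
    version: str = field(default_factory=_version)
    seed: int = 0

    def write(self, path: str | Path) -> None:
        for stage, out in self.outputs.items():
            if not Path(out).exists():
                raise FileNotFoundError(f"manifest lists missing output "
                                        f"{out!r} for stage {stage!r}")
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True)
                              + "\n")


def run_pipeline(expression_path: str | Path,
                 traits_path: str | Path,
                 out_dir: str | Path,
                 config: io.RunConfig | None = None,
                 orientation: str = "rows-are-samples") -> RunManifest:
    """Run preprocess -> network -> modules -> module-trait -> hub ranking.

    The hub-ranking stage targets the (module, trait) cell with the
    smallest p-value in the module-trait matrix.  On any stage failure
    the partially written table keeps a ``.partial`` suffix and the
    error propagates with the stage name.
    """
    config = config or io.RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        inputs={str(expression_path): _digest(expression_path),
                str(traits_path): _digest(traits_path)},
        seed=config.seed,
    )

    stage = "read-inputs"
    try:
        expression = io.read_expression_matrix(expression_path, orientation)
        trait_table = io.read_trait_table(traits_path)

        stage = "preprocess"
        if config.filter_top_n is not None:
            expression, report = preprocess.filter_features(
                expression, top_n=config.filter_top_n)
            logger.info("kept %d / %d features", report.n_features_out,
                        report.n_features_in)

        stage = "network"
        scan = network.scan_soft_threshold(expression, config.power_grid,
                                           signed=config.signed)
        _write(scan, out / "soft_threshold_scan.tsv", manifest, "scan")
        choice = network.pick_power(scan, r2_cut=config.r2_cut)
        cap = network.recommended_max_power(expression.shape[0],
                                            signed=config.signed)
        power = min(choice.power, cap)
        if power < choice.power:
            logger.info("scale-free criterion suggested power %g; capped at "
                        "the n=%d-sample recommendation %g", choice.power,
                        expression.shape[0], cap)
        cor = network.correlation_matrix(expression)
        adjacency = network.adjacency(cor, power, signed=config.signed)
        tom = network.topological_overlap(adjacency)

        stage = "modules"
        dendrogram = modules.cluster_features(tom)
        assignment = modules.cut_tree(dendrogram, height=config.cut_height,
                                      min_size=config.min_module_size)
        if (assignment != modules.GREY).any():
            eigengenes = modules.compute_eigengenes(expression, assignment)
            assignment, eigengenes = modules.merge_similar_modules(
                expression, assignment, eigengenes,
                max_dissimilarity=config.merge_dissimilarity)
        else:
            raise RuntimeError("no module survived the tree cut; lower "
                               "min_module_size or raise cut_height")
        _write(assignment.to_frame(), out / "module_assignment.tsv",
               manifest, "assignment")
        _write(modules.color_alias_table(assignment),
               out / "module_colors.tsv", manifest, "colors", index=False)
        _write(eigengenes.values, out / "eigengenes.tsv", manifest, "eigengenes")
        kme = modules.module_membership(expression, eigengenes)
        _write(kme, out / "module_membership.tsv", manifest, "kme")

        stage = "trait-association"
        mt = traits_mod.correlate_with_traits(
            eigengenes, trait_table, method=config.correlation_method,
            bh_correction=config.bh_correction)
        _write(mt.r, out / "module_trait_r.tsv", manifest, "module_trait_r")
        _write(mt.p, out / "module_trait_p.tsv", manifest, "module_trait_p")

        stage = "hub-ranking"
        best_module, best_trait = _best_cell(mt)
        gs = traits_mod.gene_significance(expression, trait_table, best_trait,
                                          method=config.correlation_method)
        members = sorted(assignment.index[assignment == best_module])
        if config.centrality == "kIM":
            # kIM on the TOM-weighted subnetwork: shared-neighbour weights
            # are steadier than raw adjacency at these sample sizes
            centrality = ranking.intramodular_connectivity(
                tom, assignment, best_module)
        else:
            centrality = kme.loc[members, best_module]
        hubs = ranking.rank_hub_genes(gs, centrality, members)
        hubs.attrs["module"] = best_module
        hubs.attrs["trait"] = best_trait
        _write(hubs, out / "hub_ranking.tsv", manifest, "hub_ranking")
    except Exception as error:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {error}") from error

    manifest.write(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest


def _best_cell(mt) -> tuple[str, str]:
    """The (module, trait) cell with the smallest p-value."""
    p = mt.p.stack().dropna()
    if p.empty:
        raise RuntimeError("module-trait matrix has no testable cell")
    module, trait = p.idxmin()
    return str(module), str(trait)


def _write(table: pd.DataFrame, path: Path, manifest: RunManifest,
           stage: str, index: bool = True) -> None:
    partial = path.with_suffix(path.suffix + ".partial")
    table.to_csv(partial, sep="\t", float_format="%.17g", index=index)
    partial.rename(path)
    manifest.outputs[stage] = str(path)
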