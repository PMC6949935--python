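"""End-to-end orchestration: per-group network analysis and report bundle.

Each group's samples are analysed independently (the two networks are never
merged): preprocess -> threshold -> topology -> node roles -> environment
linkage -> diversity.  The bundle mirrors the standard reporting shape: a
side-by-side topology panel, a Z-p role table, a module-environment
correlation table, a Mantel table, a per-sample diversity table, network
exports and a JSON run log with every config value and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import diversity as div
from . import envlink, preprocess, rmt, roles, topology
from .io_model import (Config, EcoNetwork, OtuTable, SampleMetadata,
                       TopologyPanel, ValidationError, logger, write_network)


@dataclass
class GroupResult:
    group: str
    network: EcoNetwork
    partition: topology.ModulePartition
    panel: TopologyPanel
    role_table: pd.DataFrame
    role_counts: pd.Series
    heatmap: pd.DataFrame
    mantel: pd.DataFrame
    hierarchy_newick: str | None
    threshold: float


def _split_groups(table: OtuTable, metadata: SampleMetadata,
                  ) -> dict[str, tuple[OtuTable, SampleMetadata]]:
    group = table.group or metadata.group
    if not group:
        raise ValidationError("no group labels in OTU table or metadata")
    out = {}
    for label in sorted(set(group.values())):
        samples = [s for s in table.sample_ids if group.get(s) == label]
        out[label] = (table.subset_samples(samples),
                      metadata.subset_samples(samples))
    return out


def analyze_group(table: OtuTable, metadata: SampleMetadata, group: str,
                  config: Config) -> GroupResult:
    """Run the full single-network analysis chain for one sample group."""
    logged, sim = preprocess.preprocess_table(table, config.prevalence_rule,
                                        config.fill_value,
                                        config.pairwise_valid)
    if config.threshold_mode == "fixed":
        threshold = config.fixed_threshold
    else:
        scan = rmt.scan_threshold(sim, config.scan_from, config.scan_to,
                                  config.scan_step, config.rmt_alpha,
                                  config.unfold_degree)
        if scan.selected_threshold is None:
            raise ValidationError(
                f"group {group}: RMT scan found no Poisson-consistent "
                "threshold; use a fixed threshold")
        threshold = scan.selected_threshold

    net = topology.build_network(sim, threshold, table=table)
    partition = topology.detect_modules(net)
    net.partition = partition.assignment
    panel = topology.topology_panel(net, partition, n_original_otus=sim.n_otus,
                                    min_module_size_for_reporting=
                                    config.min_module_size_for_reporting)
    role_list = roles.node_roles(net, partition, table.taxonomy)
    role_df, role_counts = roles.zp_table(role_list)

    eigengenes = envlink.module_eigengenes(logged, partition)
    heatmap = envlink.module_env_heatmap(eigengenes, metadata)
    newick = None
    if len(eigengenes) >= 2:
        newick, _ = envlink.eigengene_hierarchy(eigengenes)
    mantel = envlink.mantel_table(table, metadata, config.permutations,
                                  config.rng_seed)
    return GroupResult(group, net, partition, panel, role_df, role_counts,
                       heatmap, mantel, newick, threshold)


def run_pipeline(config: Config, table: OtuTable, metadata: SampleMetadata,
                 out_dir: str | Path) -> dict[str, GroupResult]:
    """Execute the pipeline per group and write the report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = _split_groups(table, metadata)
    results: dict[str, GroupResult] = {}
    for label, (g_table, g_meta) in groups.items():
        logger.info("analysing group %s (%d samples)", label,
                    g_table.n_samples)
        try:
            results[label] = analyze_group(g_table, g_meta, label, config)
        except ValidationError as err:
            raise ValidationError(f"group {label}: {err}") from err

    # topology panel, groups side by side
    panel = pd.concat([r.panel.to_series(label)
                       for label, r in results.items()], axis=1)
    panel.to_csv(out / "topology_panel.tsv", sep="\t",
                 index_label="Topological property")

    for label, r in results.items():
        r.role_table.to_csv(out / f"roles_{label}.tsv", sep="\t", index=False)
        r.heatmap.to_csv(out / f"module_env_{label}.tsv", sep="\t",
                         index=False)
        r.mantel.to_csv(out / f"mantel_{label}.tsv", sep="\t", index=False)
        write_network(r.network, out / f"network_{label}.tsv", "edgelist")
        write_network(r.network, out / f"network_{label}.graphml", "graphml")
        if r.hierarchy_newick:
            (out / f"eigengene_tree_{label}.nwk").write_text(
                r.hierarchy_newick + "\n")

    # diversity on the raw per-group tables (unfiltered counts)
    frames = []
    for label, (g_table, _) in groups.items():
        df = div.alpha_diversity_table(g_table)
        df.insert(0, "group", label)
        frames.append(df)
    pd.concat(frames).to_csv(out / "alpha_diversity.tsv", sep="\t",
                             index=False)

    # group comparison of environmental variables when both groups exist
    if len(groups) == 2 and metadata.group:
        try:
            envlink.group_ttests(metadata).to_csv(
                out / "env_ttests.tsv", sep="\t", index=False)
        except ValidationError:
            pass

    log = {
        "config": config.to_dict(),
        "groups": {label: {"threshold": r.threshold,
                           "nodes": r.network.n_nodes,
                           "links": r.network.n_links,
                           "modules": r.partition.n_modules}
                   for label, r in results.items()},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return results
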