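"""Config-driven end-to-end screen analysis.

One call runs simulate-or-read -> channel-sum normalization -> hit calling
-> known-target assessment -> correlation network, writing every stage
output (TSV/GraphML), a JSON summary, and a run log recording the seed and
cutoffs so that every downstream count can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hit_calling import (
    call_hits,
    compute_log2fc,
    dmso_false_hit_rate,
    per_compound_hit_counts,
)
from .network import (
    all_by_all_spearman,
    build_network,
    build_profile_matrix,
    filter_edges,
    write_edge_list,
    write_graphml,
)
from .quant_io import AbundanceMatrix, normalize_channel_sums, read_matrix, write_matrix
from .simulate import simulate_screen, write_ground_truth
from .target_assessment import (
    ground_truth_recovery,
    hit_rate_summary,
    on_target_table,
    target_separation_test,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated pipeline settings; exactly one of ``simulate``/``inputs``."""

    out_dir: str
    mode: str = "cell"
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    fc_cutoff: float = 0.2
    nsd_cutoff: float = 3.5
    trim_fraction: float = 0.1
    rho_threshold: float = 0.35
    min_pairs: int = 10
    network_max_proteins: int = 500

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must set exactly one of 'simulate' or 'inputs'")
        for name in ("fc_cutoff", "nsd_cutoff", "rho_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cutoffs = raw.pop("cutoffs", {})
        mapping = {"fc": "fc_cutoff", "nsd": "nsd_cutoff", "trim": "trim_fraction",
                   "rho_threshold": "rho_threshold", "min_pairs": "min_pairs"}
        for k, v in cutoffs.items():
            raw[mapping.get(k, k)] = v
        return cls(**raw)


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the summary dict it also writes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"pisa-screen {__version__}", f"seed={config.seed}",
                      f"cutoffs: fc={config.fc_cutoff} nsd={config.nsd_cutoff} "
                      f"trim={config.trim_fraction} rho>{config.rho_threshold} "
                      f"min_pairs={config.min_pairs}"]
    summary: dict = {"seed": config.seed, "mode": config.mode}

    truth = None
    target_ann = None
    informative = None
    if config.simulate is not None:
        sim = dict(config.simulate)
        matrix, truth, design, proteome = simulate_screen(
            n_compounds=sim.get("n_compounds", 50),
            n_proteins=sim.get("n_proteins", 5000),
            mode=config.mode, seed=config.seed,
        )
        from .simulate import window_informative

        informative = window_informative(proteome, design.window_low,
                                         design.window_high, design.n_temperatures)
        write_matrix(matrix, out / "matrix.tsv", out / "annotations.tsv")
        write_ground_truth(truth, out / "ground_truth.tsv")
        primary = truth[(truth["effect_class"] == "primary")]
        target_ann = primary.rename(
            columns={"protein_id": "target_protein_id"}
        )[["compound_id", "target_protein_id"]]
        target_ann["target_class"] = "simulated"
        target_ann.to_csv(out / "targets.tsv", sep="\t", index=False)
        log.append(f"simulated screen: {matrix.n_proteins} proteins x "
                   f"{matrix.n_channels} channels ({design.layout().n_plexes} plexes)")
    else:
        inp = config.inputs
        matrix = read_matrix(inp["matrix"], inp["annotations"])
        if inp.get("targets"):
            from .target_assessment import read_target_annotations

            target_ann = read_target_annotations(inp["targets"])
        log.append(f"read screen: {matrix.n_proteins} proteins x {matrix.n_channels} channels")
    summary["n_proteins"] = matrix.n_proteins
    summary["n_channels"] = matrix.n_channels

    norm = normalize_channel_sums(matrix)
    write_matrix(norm, out / "matrix_normalized.tsv", out / "annotations_normalized.tsv")

    log2fc = compute_log2fc(norm)
    hits = call_hits(log2fc, fc_cutoff=config.fc_cutoff, nsd_cutoff=config.nsd_cutoff,
                     trim_fraction=config.trim_fraction)
    hit_cols = ["protein_id", "treatment_id", "rep1_log2fc", "rep2_log2fc",
                "mean_log2fc", "nsd", "is_hit", "direction"]
    hits_out = hits[~hits["is_vehicle"].astype(bool)][hit_cols]
    hits_out.to_csv(out / "hits.tsv", sep="\t", index=False, float_format="%.10g")
    counts, median_hits = per_compound_hit_counts(hits)
    counts.to_csv(out / "per_compound_hit_counts.tsv", sep="\t", index=False)
    summary["n_hits"] = int(hits_out["is_hit"].sum())
    summary["n_measurements"] = int(hits_out["mean_log2fc"].notna().sum())
    summary["median_hits_per_compound"] = median_hits
    log.append(f"hit calling: {summary['n_hits']} hits / "
               f"{summary['n_measurements']} measurements")

    veh_per_plex = norm.annotations.groupby("plex_id")["is_vehicle"].sum()
    if (veh_per_plex >= 4).all():
        fhr = dmso_false_hit_rate(norm, fc_cutoff=config.fc_cutoff,
                                  nsd_cutoff=config.nsd_cutoff,
                                  trim_fraction=config.trim_fraction)
        fhr.per_plex.to_csv(out / "dmso_false_hit_rate.tsv", sep="\t", index=False,
                            float_format="%.10g")
        summary["dmso_false_hit_rate"] = fhr.rate
        log.append(f"DMSO false-hit rate: {fhr.rate:.5f} "
                   f"({fhr.n_hits}/{fhr.n_measurements})")
    else:
        summary["dmso_false_hit_rate"] = None
        log.append("DMSO false-hit rate skipped: a plex has fewer than 4 vehicle channels")

    if target_ann is not None:
        ot = on_target_table({config.mode: hits}, target_ann)
        ot.to_csv(out / "on_target_table.tsv", sep="\t", index=False)
        rates = hit_rate_summary(ot)
        rates.to_csv(out / "on_target_rates.tsv", sep="\t", index=False,
                     float_format="%.10g")
        summary["on_target_rate"] = float(
            rates.loc[rates["mode"] == config.mode, "rate"].iloc[0])
        sep_test = target_separation_test(hits, target_ann)
        summary["target_separation_pvalue"] = sep_test["pvalue"]
        log.append(f"on-target rate ({config.mode}): {summary['on_target_rate']:.3f}; "
                   f"target/non-target rank-sum p={sep_test['pvalue']:.3g}")
        if truth is not None:
            rec = ground_truth_recovery(hits, truth, informative=informative)
            summary["recovery"] = rec
            log.append(f"ground-truth recovery: sensitivity={rec['sensitivity']:.3f} "
                       f"false_call_rate={rec['false_call_rate']:.5f}")

    profile = build_profile_matrix(log2fc)
    if config.network_max_proteins and profile.shape[0] > config.network_max_proteins:
        # rank-based correlation at full proteome scale is quadratic in P;
        # keep the most variable profiles, as a practitioner would restrict
        # to an annotated subset (e.g. the quantified kinome)
        spread = profile.std(axis=1).sort_values(ascending=False)
        profile = profile.loc[sorted(spread.index[: config.network_max_proteins])]
        log.append(f"network restricted to {profile.shape[0]} most-variable proteins")
    edges = all_by_all_spearman(profile, min_pairs=config.min_pairs)
    edges = filter_edges(edges, mode="threshold", value=config.rho_threshold)
    write_edge_list(edges, out / "edges.tsv")
    graph = build_network(edges, nodes=profile.index.tolist())
    write_graphml(graph, out / "network.graphml")
    summary["network"] = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "total_comparisons": edges.attrs.get("total_comparisons"),
        "kept_fraction": edges.attrs.get("kept_fraction"),
    }
    log.append(f"network: {graph.number_of_nodes()} nodes, "
               f"{graph.number_of_edges()} edges pass |rho|>{config.rho_threshold}")

    _write_json(summary, out / "summary.json")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return summary
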