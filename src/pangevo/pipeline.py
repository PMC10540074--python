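"""End-to-end orchestration of the analysis stages.

``run_all`` executes cluster -> pangenome -> gainloss -> tajima -> dnds ->
screen in dependency order on a single machine (the target scale — hundreds
of genomes — needs no scheduler), writing per-stage TSV/JSON outputs and a
run manifest that records every threshold, seed, and engine decision so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .gainloss import WagnerConfig, binarize, wagner_reconstruct
from .io_formats import (
    read_alignment,
    read_ani_pairs,
    read_annotations,
    read_gene_counts,
    read_tree,
    write_table,
    write_tree,
)
from .pangenome import (
    accumulation_curve,
    cog_enrichment,
    fit_power_law,
    partition,
    single_copy_core,
)
from .popgen import compare_groups, tajimas_d
from .selection import (
    FilterPolicy,
    pairwise_selection,
    records_to_frame,
    screen_from_records,
)
from .species_clusters import MclConfig, build_ani_graph, cluster_summary, mcl


@dataclass
class RunConfig:
    """Pipeline configuration; every threshold is echoed into the manifest."""

    ani_path: Optional[str] = None
    counts_path: Optional[str] = None
    tree_path: Optional[str] = None
    annotations_path: Optional[str] = None
    alignments_dir: Optional[str] = None
    outdir: str = "pangevo_out"
    ani_threshold: float = 95.0
    mcl_inflation: float = 2.0
    n_permutations: int = 1000
    seed: int = 0
    outgroup_label: Optional[str] = None
    dnds_mode: str = "outgroup"
    screen_log2_cutoff: float = 1.0
    screen_alpha: float = 0.05
    min_cluster_size_pangenome: int = 2
    unknown: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "unknown"}
        bad = sorted(set(data) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        return cls(**data)


def _stage_cluster(config: RunConfig, outdir: Path, manifest: dict) -> dict[str, str]:
    pairs = read_ani_pairs(config.ani_path)
    graph = build_ani_graph(pairs, threshold=config.ani_threshold)
    clustering = mcl(graph, MclConfig(inflation=config.mcl_inflation))
    df = pd.DataFrame(
        sorted(clustering.assignments.items()), columns=["genome", "cluster"]
    )
    write_table(df, outdir / "clusters.tsv")
    write_table(cluster_summary(clustering), outdir / "cluster_summary.tsv")
    manifest["stages"]["cluster"] = {
        "ani_records": len(pairs),
        "genomes": graph.number_of_nodes(),
        "edges": graph.number_of_edges(),
        "clusters": clustering.n_clusters,
        "threshold": config.ani_threshold,
        "inflation": config.mcl_inflation,
        "converged": clustering.converged,
    }
    return clustering.assignments


def _stage_pangenome(config: RunConfig, outdir: Path, manifest: dict, assignments: dict) -> None:
    table = read_gene_counts(config.counts_path)
    annotations = read_annotations(config.annotations_path) if config.annotations_path else None
    per_cluster: dict[str, list[str]] = {}
    for genome, cluster in assignments.items():
        if genome in table.genome_ids:
            per_cluster.setdefault(cluster, []).append(genome)
    info: dict[str, dict] = {}
    frames = []
    for cluster in sorted(per_cluster):
        members = sorted(per_cluster[cluster])
        if len(members) < config.min_cluster_size_pangenome:
            continue
        from .io_formats import GeneCountTable

        sub = GeneCountTable(table.counts[members])
        part = partition(sub)
        curve = accumulation_curve(
            sub, n_permutations=config.n_permutations, seed=config.seed
        )
        fit = fit_power_law(curve)
        part_df = part.to_frame()
        part_df.insert(0, "cluster", cluster)
        frames.append(part_df)
        write_table(curve.to_frame(), outdir / f"curve_{cluster}.tsv")
        info[cluster] = {
            "genomes": len(members),
            "pangenome_size": part.pangenome_size,
            "class_counts": part.counts,
            "gamma": round(fit.gamma, 6),
            "a": round(fit.a, 6),
            "open_pangenome": fit.open_pangenome,
        }
        if annotations is not None:
            try:
                enr = cog_enrichment(part, annotations, sub)
                write_table(enr.table, outdir / f"cog_enrichment_{cluster}.tsv")
            except ValueError:
                pass
    if frames:
        write_table(pd.concat(frames, ignore_index=True), outdir / "partition.tsv")
    scc = single_copy_core(table)
    (outdir / "single_copy_core.txt").write_text("\n".join(scc) + ("\n" if scc else ""))
    manifest["stages"]["pangenome"] = {
        "orthogroups": len(table.orthogroup_ids),
        "n_permutations": config.n_permutations,
        "per_cluster": info,
        "single_copy_core": len(scc),
    }


def _stage_gainloss(config: RunConfig, outdir: Path, manifest: dict) -> None:
    tree = read_tree(config.tree_path)
    table = read_gene_counts(config.counts_path)
    content = wagner_reconstruct(tree, binarize(table), WagnerConfig())
    counts_df = content.event_counts()
    write_table(counts_df, outdir / "gainloss_summary.tsv")
    comments = {
        row["node"]: f"present={row['present']},gained={row['gained']},lost={row['lost']}"
        for _, row in counts_df.iterrows()
    }
    write_tree(tree, outdir / "gainloss_tree.nwk", comments=comments)
    lists_dir = outdir / "gainloss_families"
    lists_dir.mkdir(exist_ok=True)
    for node in content.states.columns:
        (lists_dir / f"{node}.txt").write_text(
            "\n".join(content.present(node)) + "\n"
        )
    manifest["stages"]["gainloss"] = {
        "nodes": len(content.states.columns),
        "families": content.states.shape[0],
        "total_cost": content.total_cost,
        "gain_penalty": content.config.gain_penalty,
        "loss_penalty": content.config.loss_penalty,
        "root_tie_break": content.config.root_tie_break,
    }


def _iter_alignments(config: RunConfig, codon: bool):
    for path in sorted(Path(config.alignments_dir).glob("*.fna")) + sorted(
        Path(config.alignments_dir).glob("*.fasta")
    ):
        yield read_alignment(path, codon=codon, orthogroup_id=path.stem)


def _stage_tajima(config: RunConfig, outdir: Path, manifest: dict) -> None:
    rows = []
    per_cluster_values: dict[str, list[float]] = {}
    for aln in _iter_alignments(config, codon=False):
        clusters = sorted(
            {
                lab
                for lab in aln.labels.values()
                if config.outgroup_label is None or lab != config.outgroup_label
            }
        )
        for cluster in clusters:
            ids = [sid for sid in aln.ids if aln.labels.get(sid) == cluster]
            if len(ids) < 2:
                continue
            res = tajimas_d(aln.subset(ids), orthogroup_id=aln.orthogroup_id)
            rows.append(
                {
                    "orthogroup": aln.orthogroup_id,
                    "cluster": cluster,
                    "n": res.n,
                    "S": res.S,
                    "pi": res.pi,
                    "D": np.nan if res.D is None else res.D,
                    "defined": res.defined,
                }
            )
            if res.defined:
                per_cluster_values.setdefault(cluster, []).append(res.D)
    df = pd.DataFrame(rows)
    write_table(df, outdir / "tajima.tsv")
    comps = []
    for a, b in itertools.combinations(sorted(per_cluster_values), 2):
        va, vb = per_cluster_values[a], per_cluster_values[b]
        if not va or not vb:
            continue
        comp = compare_groups(va, vb, a, b)
        comps.append(
            {
                "cluster_a": a,
                "cluster_b": b,
                "n1": comp.n1,
                "n2": comp.n2,
                "U": comp.U,
                "p": comp.p,
                "cles": comp.cles,
                "median_a": comp.median_a,
                "median_b": comp.median_b,
            }
        )
    write_table(pd.DataFrame(comps), outdir / "tajima_comparisons.tsv")
    manifest["stages"]["tajima"] = {
        "orthogroup_cluster_rows": len(rows),
        "defined": int(df["defined"].sum()) if len(df) else 0,
        "comparisons": len(comps),
        "gap_rule": "complete column deletion of non-ACGT columns",
    }


def _stage_dnds(config: RunConfig, outdir: Path, manifest: dict) -> None:
    all_records = []
    for aln in _iter_alignments(config, codon=True):
        all_records.extend(
            pairwise_selection(
                aln, outgroup_label=config.outgroup_label, mode=config.dnds_mode
            )
        )
    df = records_to_frame(all_records)
    write_table(df, outdir / "pairwise_dnds.tsv")
    clusters = sorted(
        {
            lab
            for rec in all_records
            for lab in (rec.cluster_a, rec.cluster_b)
            if lab and lab != config.outgroup_label
        }
    )
    screen_rows = []
    tallies = {}
    for a, b in itertools.combinations(clusters, 2):
        results, tally = screen_from_records(
            all_records,
            a,
            b,
            FilterPolicy(),
            log2_cutoff=config.screen_log2_cutoff,
            alpha=config.screen_alpha,
        )
        tallies[f"{a}__vs__{b}"] = tally
        for res in results:
            screen_rows.append(res.__dict__)
    write_table(pd.DataFrame(screen_rows), outdir / "screen.tsv")
    manifest["stages"]["dnds"] = {
        "pairwise_records": len(all_records),
        "engine": "NG86 counting with Jukes-Cantor correction",
        "mode": config.dnds_mode,
        "outgroup": config.outgroup_label,
        "filters": {"zero_distance": True, "max_omega": 5.0, "max_ds": 10.0},
        "screen_rule": {
            "log2_cutoff": config.screen_log2_cutoff,
            "alpha": config.screen_alpha,
        },
        "filter_tallies": tallies,
        "screen_calls": int(
            sum(1 for r in screen_rows if r["flag"] != "ns")
        ),
    }


def run_all(config: RunConfig) -> dict:
    """Run every stage whose inputs are configured; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in config.__dict__.items() if k != "unknown"},
        "stages": {},
    }
    failed = None
    try:
        assignments: dict[str, str] = {}
        if config.ani_path:
            assignments = _stage_cluster(config, outdir, manifest)
        if config.counts_path and assignments:
            _stage_pangenome(config, outdir, manifest, assignments)
        if config.counts_path and config.tree_path:
            _stage_gainloss(config, outdir, manifest)
        if config.alignments_dir:
            _stage_tajima(config, outdir, manifest)
            _stage_dnds(config, outdir, manifest)
    except Exception as exc:
        failed = f"{type(exc).__name__}: {exc}"
        manifest["failed"] = failed
        (outdir / "FAILED").write_text(failed + "\n")
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
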