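"""Synthetic-data generators with known ground truth for every pipeline
input: gene families gained and lost along a known tree, planted ANI cluster
structure, neutral coalescent alignments, and codon sequences evolved with a
known dN/dS.

Design choices shared by all generators:

* seed-determinism — identical configuration and seed give byte-identical
  output;
* the gene-content simulator uses an infinitely-many-genes assumption (a
  family is born once globally and never re-gained after loss on the same
  path), which keeps the true event log unambiguous for recovery tests;
* codon evolution is an exact event-by-event stochastic simulation of a
  GY94-style continuous-time chain (single-nucleotide codon moves, x kappa
  for transitions, x omega for nonsynonymous moves, stop codons excluded),
  so realized substitution counts are available as ground truth.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io_formats import (
    Alignment,
    AniPair,
    AniPairList,
    AnnotationTable,
    CodonAlignment,
    GeneCountTable,
    write_alignment,
    write_ani_pairs,
    write_annotations,
    write_gene_counts,
    write_tree,
)
from .selection import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, _TRANSITIONS
from .trees import RootedTree, TreeNode

# ---------------------------------------------------------------------------
# random trees
# ---------------------------------------------------------------------------


def yule_tree(n_leaves: int, seed: int, branch_scale: float = 0.1) -> RootedTree:
    """Draw a Yule (pure-birth) tree: split a uniformly chosen leaf until
    ``n_leaves`` tips exist; branch lengths are Exp(mean=branch_scale)."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    root = TreeNode("")
    leaves = [root.add_child(TreeNode("", rng.exponential(branch_scale))) for _ in range(2)]
    while len(leaves) < n_leaves:
        pick = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            leaves.append(pick.add_child(TreeNode("", rng.exponential(branch_scale))))
    for i, leaf in enumerate(leaves, 1):
        leaf.name = f"L{i:02d}"
    return RootedTree(root)


# ---------------------------------------------------------------------------
# gene-content evolution
# ---------------------------------------------------------------------------


@dataclass
class ContentSimConfig:
    """Gene-content birth/death along a tree.

    root_families is the Poisson mean of the root gene-family count;
    gain_rate is new families per unit branch length; loss_rate is the
    per-family loss hazard per unit length (survival over a branch of
    length t is exp(-loss_rate * t))."""

    tree: Optional[RootedTree] = None
    n_leaves: int = 10
    root_families: float = 300.0
    gain_rate: float = 10.0
    loss_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_families <= 0:
            raise ValueError("root_families must be > 0")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class ContentSimResult:
    leaf_matrix: pd.DataFrame  # families x leaves, 0/1
    events: dict[str, dict[str, list[str]]]  # node -> gained/lost
    node_contents: dict[str, list[str]]
    tree: RootedTree


def simulate_gene_content(config: ContentSimConfig) -> ContentSimResult:
    """Evolve presence/absence of gene families along a tree.

    Root content ~ Poisson(root_families) distinct families; along each
    edge each present family survives with prob exp(-loss_rate*t) and
    Poisson(gain_rate*t) brand-new families are born (infinitely-many-genes).
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree or yule_tree(config.n_leaves, seed=int(rng.integers(2**31)))
    counter = itertools.count(1)
    n_root = int(rng.poisson(config.root_families))
    root_content = [f"F{next(counter):06d}" for _ in range(n_root)]
    contents: dict[str, list[str]] = {tree.root.name: root_content}
    events: dict[str, dict[str, list[str]]] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = node.length if node.length is not None else 0.0
        parent_content = contents[node.parent.name]
        p_survive = float(np.exp(-config.loss_rate * t))
        survive_mask = rng.random(len(parent_content)) < p_survive
        survivors = [f for f, keep in zip(parent_content, survive_mask) if keep]
        lost = [f for f, keep in zip(parent_content, survive_mask) if not keep]
        n_gain = int(rng.poisson(config.gain_rate * t))
        gained = [f"F{next(counter):06d}" for _ in range(n_gain)]
        contents[node.name] = survivors + gained
        events[node.name] = {"gained": sorted(gained), "lost": sorted(lost)}
    all_families = [f"F{i:06d}" for i in range(1, next(counter))]
    leaf_names = tree.leaf_names
    mat = pd.DataFrame(0, index=all_families, columns=leaf_names, dtype=np.int8)
    for leaf in leaf_names:
        mat.loc[contents[leaf], leaf] = 1
    return ContentSimResult(
        leaf_matrix=mat,
        events=events,
        node_contents={k: sorted(v) for k, v in contents.items()},
        tree=tree,
    )


# ---------------------------------------------------------------------------
# neutral coalescent alignments
# ---------------------------------------------------------------------------


@dataclass
class CoalescentSimConfig:
    n: int = 10
    theta: float = 5.0
    L: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


_BASES = np.array(list("ACGT"))


def simulate_coalescent_sample(
    config: CoalescentSimConfig, rng: Optional[np.random.Generator] = None
) -> Alignment:
    """One neutral-coalescent alignment.

    Coalescence waiting times are Exp(k(k-1)/2) in scaled units; mutations
    ~ Poisson(theta * T_total / 2) fall uniformly on branches and each hits
    its own site (infinite sites mapped onto L positions, sampled without
    replacement).  Warns when the expected number of segregating sites
    exceeds 0.1 * L (site collisions no longer negligible).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, theta, L = config.n, config.theta, config.L
    a1 = sum(1.0 / i for i in range(1, n))
    if theta * a1 > 0.1 * L:
        warnings.warn(
            f"expected S = {theta * a1:.1f} exceeds 0.1*L; increase L",
            stacklevel=2,
        )
    # active lineages: (descendant leaf set, branch start time)
    active: list[tuple[frozenset[int], float]] = [(frozenset([i]), 0.0) for i in range(n)]
    branches: list[tuple[frozenset[int], float]] = []
    now = 0.0
    k = n
    while k > 1:
        now += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (set_j, start_j) = active.pop(int(j))
        (set_i, start_i) = active.pop(int(i))
        branches.append((set_i, now - start_i))
        branches.append((set_j, now - start_j))
        active.append((set_i | set_j, now))
        k -= 1
    total_length = sum(b[1] for b in branches)
    n_mut = int(rng.poisson(theta * total_length / 2.0))
    n_mut = min(n_mut, L)  # infinite-sites mapped onto finitely many positions
    sites = rng.choice(L, size=n_mut, replace=False)
    lengths = np.array([b[1] for b in branches])
    probs = lengths / total_length if total_length > 0 else None
    seqs = np.empty((n, L), dtype="<U1")
    ancestral = _BASES[rng.integers(0, 4, size=L)]
    seqs[:] = ancestral
    for site in sites:
        branch = int(rng.choice(len(branches), p=probs))
        carriers = branches[branch][0]
        anc = ancestral[site]
        derived = rng.choice([b for b in "ACGT" if b != anc])
        for leaf in carriers:
            seqs[leaf, site] = derived
    return Alignment(
        ids=[f"s{i + 1}" for i in range(n)],
        seqs=["".join(row) for row in seqs],
    )


# ---------------------------------------------------------------------------
# codon evolution (GY94-style exact stochastic simulation)
# ---------------------------------------------------------------------------


@dataclass
class CodonSimConfig:
    omega: float = 1.0
    kappa: float = 1.0
    n_codons: int = 300
    divergence: float = 0.2  # expected substitutions per codon site (pair total)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


def _is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


def _build_neighbors() -> dict[str, list[tuple[str, bool, bool]]]:
    out: dict[str, list[tuple[str, bool, bool]]] = {}
    for codon in SENSE_CODONS:
        nbrs = []
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                syn = CODON_TO_AA[alt] == CODON_TO_AA[codon]
                ts = _is_transition(codon[pos], nt)
                nbrs.append((alt, syn, ts))
        out[codon] = nbrs
    return out


_NEIGHBORS = _build_neighbors()
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def _rate_scale(omega: float, kappa: float) -> float:
    """Mean exit rate over a uniform sense-codon composition; dividing by it
    puts branch lengths on the expected-substitutions-per-codon scale."""
    total = 0.0
    for codon in SENSE_CODONS:
        for _, syn, ts in _NEIGHBORS[codon]:
            total += (kappa if ts else 1.0) * (1.0 if syn else omega)
    return total / len(SENSE_CODONS)


_RATE_CACHE: dict[tuple[float, float], dict] = {}


def _rate_tables(omega: float, kappa: float) -> dict:
    """Per-codon (targets, syn flags, cumulative probabilities, scaled exit
    rate) tables, cached per (omega, kappa)."""
    key = (omega, kappa)
    cached = _RATE_CACHE.get(key)
    if cached is not None:
        return cached
    scale = _rate_scale(omega, kappa)
    tables = {}
    for codon, nbrs in _NEIGHBORS.items():
        rates = np.array(
            [(kappa if ts else 1.0) * (1.0 if syn else omega) for _, syn, ts in nbrs]
        )
        total = rates.sum()
        tables[codon] = (
            [t for t, _, _ in nbrs],
            [syn for _, syn, _ in nbrs],
            np.cumsum(rates / total) if total > 0 else None,
            total / scale,
        )
    _RATE_CACHE[key] = tables
    return tables


def evolve_codon_sequence(
    codons: list[str],
    time: float,
    omega: float,
    kappa: float,
    rng: np.random.Generator,
) -> tuple[list[str], int, int]:
    """Evolve each codon independently for ``time`` (expected substitutions
    per codon units); returns (new codons, syn count, nonsyn count)."""
    tables = _rate_tables(omega, kappa)
    syn_count = nonsyn_count = 0
    out = []
    for codon in codons:
        current = codon
        t = 0.0
        while True:
            targets, syn_flags, cum, total = tables[current]
            if total <= 0 or cum is None:
                break
            t += rng.exponential(1.0 / total)
            if t > time:
                break
            pick = int(np.searchsorted(cum, rng.random()))
            if syn_flags[pick]:
                syn_count += 1
            else:
                nonsyn_count += 1
            current = targets[pick]
        out.append(current)
    return out, syn_count, nonsyn_count


def random_codons(n_codons: int, rng: np.random.Generator) -> list[str]:
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]


def simulate_codon_pair(
    config: CodonSimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[str, str, dict]:
    """A codon-aligned sequence pair diverged by ``divergence`` expected
    substitutions per codon site under (omega, kappa); each lineage evolves
    for divergence/2 from a common ancestor.  The returned dict carries the
    realized synonymous/nonsynonymous substitution counts."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ancestor = random_codons(config.n_codons, rng)
    half = config.divergence / 2.0
    left, s1, n1 = evolve_codon_sequence(ancestor, half, config.omega, config.kappa, rng)
    right, s2, n2 = evolve_codon_sequence(ancestor, half, config.omega, config.kappa, rng)
    truth = {
        "omega": config.omega,
        "kappa": config.kappa,
        "divergence": config.divergence,
        "syn_substitutions": s1 + s2,
        "nonsyn_substitutions": n1 + n2,
    }
    return "".join(left), "".join(right), truth


def simulate_screen_orthogroup(
    omega_by_cluster: dict[str, float],
    n_per_cluster: int,
    n_codons: int = 200,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    outgroup_label: str = "OUT",
    t_outgroup: float = 0.02,
    t_stem: float = 0.15,
    t_tip: float = 0.10,
    orthogroup_id: str = "OG0000001",
) -> CodonAlignment:
    """One orthogroup's codon alignment across several clusters plus a
    common outgroup sequence.

    A shared ancestor yields (a) one outgroup sequence after a short
    neutral stem ``t_outgroup``, and (b) per cluster a cluster ancestor
    after ``t_stem`` and ``n_per_cluster`` members after a further
    ``t_tip``, both evolved under that cluster's omega.  The divergence
    budget concentrates substitutions on the cluster-specific branches so
    member-vs-outgroup omega estimates reflect the cluster's omega.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    ancestor = random_codons(n_codons, rng)
    out_seq, _, _ = evolve_codon_sequence(ancestor, t_outgroup, 1.0, 1.0, rng)
    ids = [f"{outgroup_label}_g1|{orthogroup_id}"]
    seqs = ["".join(out_seq)]
    labels = {ids[0]: outgroup_label}
    for cluster in sorted(omega_by_cluster):
        omega = omega_by_cluster[cluster]
        stem, _, _ = evolve_codon_sequence(ancestor, t_stem, omega, 1.0, rng)
        for i in range(1, n_per_cluster + 1):
            tip, _, _ = evolve_codon_sequence(stem, t_tip, omega, 1.0, rng)
            sid = f"{cluster}_g{i}|{orthogroup_id}"
            ids.append(sid)
            seqs.append("".join(tip))
            labels[sid] = cluster
    return CodonAlignment(
        ids=ids, seqs=seqs, labels=labels, codon=True, orthogroup_id=orthogroup_id
    )


# ---------------------------------------------------------------------------
# planted ANI tables
# ---------------------------------------------------------------------------


@dataclass
class AniSimConfig:
    cluster_sizes: tuple[int, ...] = (5, 4, 3)
    within_mean: float = 97.5
    within_sd: float = 0.8
    within_low: float = 95.5
    between_mean: float = 82.0
    between_sd: float = 3.0
    between_high: float = 92.0
    jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.within_low > self.between_high:
            raise ValueError("within truncation must exceed between truncation")


def simulate_ani_table(config: AniSimConfig) -> tuple[AniPairList, dict[str, str]]:
    """Planted-cluster ANI table (both directions, independent jitter) plus
    the true genome -> cluster partition.

    Within-cluster values are truncated-normal above ``within_low`` (and
    below 100); between-cluster values truncated below ``between_high``, so
    a threshold between the two bounds guarantees zero between-cluster
    edges.
    """
    rng = np.random.default_rng(config.seed)
    genomes: list[str] = []
    truth: dict[str, str] = {}
    for c, size in enumerate(config.cluster_sizes, 1):
        for g in range(1, size + 1):
            name = f"sp{c:02d}_g{g:02d}"
            genomes.append(name)
            truth[name] = f"sp{c:02d}"

    def draw(mean: float, sd: float, low: float, high: float) -> float:
        a, b = (low - mean) / sd, (high - mean) / sd
        return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))

    records: list[AniPair] = []
    for g1, g2 in itertools.combinations(genomes, 2):
        same = truth[g1] == truth[g2]
        if same:
            base = draw(config.within_mean, config.within_sd, config.within_low, 100.0)
            low, high = config.within_low, 100.0
        else:
            base = draw(config.between_mean, config.between_sd, 0.0, config.between_high)
            low, high = 0.0, config.between_high
        for q, r in ((g1, g2), (g2, g1)):
            ani = float(np.clip(base + rng.normal(0.0, config.jitter_sd), low, high))
            records.append(AniPair(q, r, ani, 900, 1000))
    return AniPairList(records), truth


# ---------------------------------------------------------------------------
# end-to-end fixture
# ---------------------------------------------------------------------------


def _fixture_tree(cluster_names: list[str], n_per_cluster: int) -> RootedTree:
    """Balanced genome tree: ((c1,c2),(c3,c4)) with n tips per cluster."""
    root = TreeNode("root")
    pairs = [cluster_names[i : i + 2] for i in range(0, len(cluster_names), 2)]
    for pair in pairs:
        mid = root.add_child(TreeNode("", 0.2))
        for cname in pair:
            stem = mid.add_child(TreeNode("", 0.3))
            for g in range(1, n_per_cluster + 1):
                stem.add_child(TreeNode(f"{cname}_g{g:02d}", 0.05))
    return RootedTree(root)


def make_end_to_end_fixture(seed: int, outdir: str | Path) -> dict:
    """Write a complete miniature study (4 clusters x 5 genomes) that every
    pipeline stage can consume, plus a ground-truth JSON.

    Files: ``ani.tsv``, ``gene_counts.tsv``, ``tree.nwk``,
    ``annotations.tsv``, ``alignments/OG*.fna``, ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_clusters, n_per_cluster = 4, 5
    cluster_names = [f"sp{c:02d}" for c in range(1, n_clusters + 1)]

    # planted ANI structure
    ani_cfg = AniSimConfig(
        cluster_sizes=(n_per_cluster,) * n_clusters, seed=int(rng.integers(2**31))
    )
    ani_pairs, truth_partition = simulate_ani_table(ani_cfg)
    write_ani_pairs(ani_pairs, outdir / "ani.tsv")

    # gene content on the genome tree
    tree = _fixture_tree(cluster_names, n_per_cluster)
    content_cfg = ContentSimConfig(
        tree=tree,
        root_families=300.0,
        gain_rate=20.0,
        loss_rate=0.3,
        seed=int(rng.integers(2**31)),
    )
    content = simulate_gene_content(content_cfg)
    counts = content.leaf_matrix.astype(np.int64)
    # sprinkle a few duplications so single-copy selection has teeth
    dup_mask = (counts.values == 1) & (rng.random(counts.shape) < 0.03)
    counts = counts + pd.DataFrame(dup_mask.astype(np.int64), index=counts.index, columns=counts.columns)
    table = GeneCountTable(counts)
    write_gene_counts(table, outdir / "gene_counts.tsv")
    write_tree(tree, outdir / "tree.nwk")

    # annotations: one gene per present family copy, random COG letters
    cats = list("CDEFGHIJKLMNOPQTUV")
    rows = []
    fam_cat: dict[str, str] = {}
    for fam in counts.index:
        r = rng.random()
        if r < 0.15:
            fam_cat[fam] = "@"
        elif r < 0.25:
            fam_cat[fam] = "".join(rng.choice(cats, size=2, replace=False))
        else:
            fam_cat[fam] = str(rng.choice(cats))
    for fam in counts.index:
        for genome in counts.columns:
            for copy in range(int(counts.loc[fam, genome])):
                rows.append(
                    {
                        "gene_id": f"{genome}|{fam}_{copy + 1}",
                        "orthogroup_id": fam,
                        "cog_categories": "" if fam_cat[fam] == "@" else fam_cat[fam],
                    }
                )
    annotations = AnnotationTable(pd.DataFrame(rows))
    write_annotations(annotations, outdir / "annotations.tsv")

    # codon alignments for a handful of conserved orthogroups
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    true_omegas: dict[str, dict[str, float]] = {}
    n_ogs = 8
    for k in range(1, n_ogs + 1):
        og = f"OG{k:07d}"
        if k == 1:
            # one orthogroup with genuinely differential pressure
            omegas = {c: (1.0 if c == "sp01" else 0.2) for c in cluster_names}
        else:
            shared = float(rng.choice([0.2, 0.3, 0.5]))
            omegas = {c: shared for c in cluster_names}
        aln = simulate_screen_orthogroup(
            omegas,
            n_per_cluster=n_per_cluster,
            n_codons=200,
            rng=np.random.default_rng(int(rng.integers(2**31))),
            orthogroup_id=og,
        )
        write_alignment(aln, aln_dir / f"{og}.fna")
        true_omegas[og] = omegas

    truth = {
        "seed": seed,
        "partition": truth_partition,
        "n_clusters": n_clusters,
        "events_per_edge": {
            node: {"gained": len(ev["gained"]), "lost": len(ev["lost"])}
            for node, ev in sorted(content.events.items())
        },
        "root_content_size": len(content.node_contents[tree.root.name]),
        "true_omegas": true_omegas,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
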