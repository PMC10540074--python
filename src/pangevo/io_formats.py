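"""Readers and writers for every external dialect the pipeline touches.

Supported formats
-----------------
* gene-count tables — the Orthofinder ``Orthogroups.GeneCount.tsv`` dialect:
  first column ``Orthogroup``, one column per genome, optional trailing
  ``Total`` column (always recomputable, therefore always ignored);
* pairwise ANI tables — the FastANI five-column dialect (query path,
  reference path, ANI%, fragments mapped, fragments total), columns 4-5
  optional;
* nucleotide / codon alignments — FASTA, with sequence->cluster labels taken
  either from a ``>cluster|genome|gene`` header convention or a sidecar TSV;
* gene -> orthogroup -> COG-category annotation tables — 3-column TSV;
* rooted trees — newick (parsed with dendropy, converted to the package's
  own :class:`~pangevo.trees.RootedTree`).

All writers emit fixed column orders and 6-decimal floats so repeated runs
diff bit-for-bit.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import RootedTree, TreeNode

#: COG functional-category alphabet plus "@" for families without any COG.
COG_ALPHABET = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ@")

_ALLOWED_ALPHABET = set("ACGTN-")

_FASTA_EXT_RE = re.compile(r"(\.(fa|fna|fasta))?(\.gz)?$", re.IGNORECASE)


class FormatError(ValueError):
    """Raised when an input file violates its dialect."""


# ---------------------------------------------------------------------------
# gene-count tables
# ---------------------------------------------------------------------------


@dataclass
class GeneCountTable:
    """Orthogroup-by-genome gene-count matrix.

    ``counts`` is an integer DataFrame indexed by orthogroup ID with one
    column per genome.  Invariants: unique IDs on both axes, counts >= 0,
    at least one orthogroup and one genome.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise FormatError("gene-count table needs >=1 orthogroup and >=1 genome")
        if df.index.duplicated().any():
            dup = sorted(df.index[df.index.duplicated()].unique())
            raise FormatError(f"duplicate orthogroup IDs: {dup}")
        if df.columns.duplicated().any():
            dup = sorted(df.columns[df.columns.duplicated()].unique())
            raise FormatError(f"duplicate genome IDs: {dup}")
        if not np.issubdtype(df.values.dtype, np.integer):
            raise FormatError("gene counts must be integers")
        if (df.values < 0).any():
            raise FormatError("gene counts must be non-negative")

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genomes(self) -> int:
        return self.counts.shape[1]


def read_gene_counts(path: str | Path) -> GeneCountTable:
    """Read an Orthofinder-dialect gene-count TSV.

    The optional trailing ``Total`` column is dropped (it is a derived
    quantity); a mismatch between a present ``Total`` and the recomputed row
    sums produces a warning only.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    genome_cols = header[1:]
    if len(set(genome_cols)) != len(genome_cols):
        raise FormatError(f"{path}: duplicate genome IDs in header")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty gene-count table") from exc
    if df.shape[0] == 0:
        raise FormatError(f"{path}: gene-count table has no data rows")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate orthogroup IDs")
    total = None
    if len(df.columns) and df.columns[-1] == "Total":
        total = df["Total"]
        df = df.drop(columns="Total")
    try:
        mat = df.astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer cell in gene-count table: {exc}") from exc
    if total is not None:
        try:
            tot = total.astype(np.int64)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer Total column") from exc
        if not (mat.sum(axis=1) == tot).all():
            warnings.warn(
                f"{path}: Total column disagrees with row sums; ignoring it",
                stacklevel=2,
            )
    return GeneCountTable(mat)


def write_gene_counts(table: GeneCountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "Orthogroup"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# pairwise ANI tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AniPair:
    query: str
    reference: str
    ani: float
    fragments_mapped: Optional[int] = None
    fragments_total: Optional[int] = None


@dataclass
class AniPairList:
    records: list[AniPair] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def genome_id_from_path(path_like: str) -> str:
    """Strip directories and recognized FASTA extensions from a FastANI path.

    ``data/a.fna.gz`` -> ``a``; identifiers without a known extension are
    returned unchanged (minus directories).
    """
    base = Path(path_like).name
    return _FASTA_EXT_RE.sub("", base)


def read_ani_pairs(path: str | Path) -> AniPairList:
    """Read a FastANI-dialect ANI table (3 mandatory + 2 optional columns)."""
    records: list[AniPair] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            q = genome_id_from_path(parts[0])
            r = genome_id_from_path(parts[1])
            try:
                ani = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: ANI not numeric") from exc
            if not (0.0 <= ani <= 100.0):
                raise FormatError(f"{path}:{lineno}: ANI {ani} outside [0,100]")
            fm = ft = None
            if len(parts) >= 5:
                try:
                    fm, ft = int(parts[3]), int(parts[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: fragment counts not integers") from exc
            records.append(AniPair(q, r, ani, fm, ft))
    return AniPairList(records)


def write_ani_pairs(pairs: AniPairList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in pairs:
            cols = [rec.query, rec.reference, f"{rec.ani:.6f}"]
            if rec.fragments_mapped is not None and rec.fragments_total is not None:
                cols += [str(rec.fragments_mapped), str(rec.fragments_total)]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """gene -> orthogroup -> COG-category table.

    ``table`` has columns ``gene_id``, ``orthogroup_id``, ``cog_categories``
    (a string of category letters; ``@`` marks genes without any COG).
    A gene maps to at most one orthogroup.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "orthogroup_id", "cog_categories"]
        if list(self.table.columns) != required:
            raise FormatError(f"annotation table columns must be {required}")
        if self.table["gene_id"].duplicated().any():
            dup = sorted(self.table.loc[self.table["gene_id"].duplicated(), "gene_id"])
            raise FormatError(f"gene mapped more than once: {dup[:5]}")
        cats = self.table["cog_categories"].fillna("")
        bad = sorted({c for s in cats for c in s if c not in COG_ALPHABET})
        if bad:
            raise FormatError(f"unknown COG category letters: {bad}")
        self.table = self.table.assign(cog_categories=cats)

    def orthogroup_categories(self) -> dict[str, set[str]]:
        """Orthogroup-level category sets: union of member genes' letters
        (empty/unassigned genes contribute '@')."""
        out: dict[str, set[str]] = {}
        for og, cats in zip(self.table["orthogroup_id"], self.table["cog_categories"]):
            letters = set(cats) if cats else {"@"}
            out.setdefault(og, set()).update(letters)
        return out


def read_annotations(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(
        path,
        sep="\t",
        header=0,
        dtype=str,
        keep_default_na=False,
    )
    return AnnotationTable(df[["gene_id", "orthogroup_id", "cog_categories"]])


def write_annotations(annotations: AnnotationTable, path: str | Path) -> None:
    annotations.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """An equal-length nucleotide alignment with optional cluster labels.

    ``labels`` maps sequence ID -> cluster label; it is populated from the
    ``>cluster|genome|gene`` header convention when present.  In codon mode
    the length must be divisible by 3.
    """

    ids: list[str]
    seqs: list[str]
    labels: dict[str, str] = field(default_factory=dict)
    codon: bool = False
    orthogroup_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise FormatError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate sequence IDs in alignment")
        if not self.seqs:
            raise FormatError("empty alignment")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: lengths {sorted(lengths)}")
        (self.length,) = lengths
        if self.codon and self.length % 3 != 0:
            raise FormatError(f"codon alignment length {self.length} not divisible by 3")
        bad = sorted({c for s in self.seqs for c in s if c not in _ALLOWED_ALPHABET})
        if bad:
            raise FormatError(f"illegal alignment characters: {bad}")

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    def __len__(self) -> int:
        return self.length

    def subset(self, ids: Sequence[str]) -> "Alignment":
        index = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"sequences not in alignment: {missing}")
        return Alignment(
            ids=list(ids),
            seqs=[self.seqs[index[i]] for i in ids],
            labels={i: self.labels[i] for i in ids if i in self.labels},
            codon=self.codon,
            orthogroup_id=self.orthogroup_id,
        )


#: Alias used where the divisible-by-3 invariant is required.
CodonAlignment = Alignment


def _parse_header(header: str) -> tuple[str, Optional[str]]:
    """Return (sequence id, cluster label) from a FASTA header.

    ``cluster|genome|gene`` headers yield id ``genome|gene`` and label
    ``cluster``; anything else is an unlabeled id.
    """
    parts = header.split("|")
    if len(parts) == 3:
        return f"{parts[1]}|{parts[2]}", parts[0]
    return header, None


def read_alignment(
    path: str | Path,
    codon: bool = False,
    labels_path: Optional[str | Path] = None,
    orthogroup_id: Optional[str] = None,
) -> Alignment:
    """Read a FASTA alignment; sequences are uppercased on read.

    Cluster labels come from a sidecar two-column TSV (id, cluster) when
    ``labels_path`` is given, otherwise from the ``cluster|genome|gene``
    header convention when present.
    """
    ids: list[str] = []
    seqs: list[str] = []
    labels: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid, label = _parse_header(rec.id)
        ids.append(sid)
        seqs.append(str(rec.seq))
        if label is not None:
            labels[sid] = label
    if labels_path is not None:
        side = pd.read_csv(labels_path, sep="\t", header=None, names=["id", "cluster"], dtype=str)
        labels = dict(zip(side["id"], side["cluster"]))
    if not ids:
        raise FormatError(f"{path}: no sequences")
    return Alignment(ids=ids, seqs=seqs, labels=labels, codon=codon, orthogroup_id=orthogroup_id)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = []
    for sid, seq in zip(aln.ids, aln.seqs):
        header = f"{aln.labels[sid]}|{sid}" if sid in aln.labels else sid
        records.append(SeqRecord(Seq(seq), id=header, description=""))
    SeqIO.write(records, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def _convert_dendropy(dnode: dendropy.Node) -> TreeNode:
    if dnode.is_leaf():
        name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
    else:
        name = dnode.label or ""
    node = TreeNode(name=name, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_convert_dendropy(child))
    return node


def read_tree(path: str | Path) -> RootedTree:
    """Read a newick tree; unlabeled internal nodes are auto-named in
    preorder so ancestral-content reports are stable across runs.

    A trifurcating (unrooted-style) root is accepted; the resulting tree
    carries ``root_multifurcation=True``.
    """
    try:
        dt = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: invalid newick (duplicate labels or syntax): {exc}") from exc
    root = _convert_dendropy(dt.seed_node)
    tree = RootedTree(root)
    if tree.root_multifurcation:
        warnings.warn("tree root is multifurcating (unrooted-style newick accepted)", stacklevel=2)
    return tree


def parse_tree(newick: str) -> RootedTree:
    """Parse a newick string (convenience wrapper around :func:`read_tree`)."""
    try:
        dt = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"invalid newick (duplicate labels or syntax): {exc}") from exc
    return RootedTree(_convert_dendropy(dt.seed_node))


def write_tree(tree: RootedTree, path: str | Path, comments: Optional[dict[str, str]] = None) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(comments=comments) + "\n")


# ---------------------------------------------------------------------------
# generic numeric table output (fixed 6-decimal floats)
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a DataFrame as TSV with 6-decimal floats for bit-stable diffs."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6f")
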