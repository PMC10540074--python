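"""Pangenome partitioning, accumulation curves, Heaps-law openness, and
core-vs-accessory COG enrichment.

Frequency classes follow the standard five-way scheme: *core* families occur
in 100% of genomes, *soft-core* in [90%, 100%), *shell* in [15%, 90%),
*cloud* in >=2 genomes below 15%, and *unique* families occur in exactly one
genome.  Rule precedence (unique -> core -> soft_core -> shell -> cloud)
keeps the classes exhaustive for every genome count, including small panels
where two genomes already exceed 15%.

Openness is quantified by fitting the power law y = a*x**gamma to the mean
permutation accumulation curve; 0 < gamma < 1 indicates an open pangenome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io_formats import AnnotationTable, GeneCountTable

CLASSES = ("core", "soft_core", "shell", "cloud", "unique")


@dataclass
class PartitionThresholds:
    soft_core_fraction: float = 0.90
    shell_fraction: float = 0.15
    cloud_min_count: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.shell_fraction < self.soft_core_fraction < 1):
            raise ValueError("need 0 < shell_fraction < soft_core_fraction < 1")


@dataclass
class PangenomePartition:
    classes: dict[str, str]  # orthogroup -> class
    n_genomes: int

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for cls in self.classes.values():
            out[cls] += 1
        return out

    def members(self, cls: str) -> list[str]:
        return sorted(og for og, c in self.classes.items() if c == cls)

    @property
    def pangenome_size(self) -> int:
        return len(self.classes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"orthogroup": list(self.classes), "class": list(self.classes.values())}
        )


def classify_frequency(k: int, n_genomes: int, thresholds: Optional[PartitionThresholds] = None) -> Optional[str]:
    """Class of a family present in ``k`` of ``n_genomes`` genomes.

    Returns None for k == 0 (absent families are not part of the
    pangenome).  Precedence: unique -> core -> soft_core -> shell -> cloud.
    """
    t = thresholds or PartitionThresholds()
    if k == 0:
        return None
    if k == 1:
        return "unique"
    f = k / n_genomes
    if f == 1.0:
        return "core"
    if f >= t.soft_core_fraction:
        return "soft_core"
    if f >= t.shell_fraction:
        return "shell"
    if k >= t.cloud_min_count:
        return "cloud"
    return None  # unreachable: k >= 2 always matches cloud


def partition(
    matrix: GeneCountTable, thresholds: Optional[PartitionThresholds] = None
) -> PangenomePartition:
    """Partition orthogroups into the five frequency classes."""
    n = matrix.n_genomes
    if n < 2:
        raise ValueError("pangenome partition undefined for a single genome")
    presence = (matrix.counts.values >= 1).sum(axis=1)
    classes: dict[str, str] = {}
    for og, k in zip(matrix.orthogroup_ids, presence):
        cls = classify_frequency(int(k), n, thresholds)
        if cls is not None:
            classes[og] = cls
    return PangenomePartition(classes=classes, n_genomes=n)


@dataclass
class AccumulationCurve:
    x: np.ndarray
    y_mean: np.ndarray
    n_permutations: int
    seed: int
    per_permutation: Optional[np.ndarray] = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"genomes": self.x, "mean_pangenome_size": self.y_mean})


def accumulation_curve(
    matrix: GeneCountTable, n_permutations: int = 1000, seed: int = 0
) -> AccumulationCurve:
    """Permutation accumulation curve of pangenome size.

    For each permutation of the genome order, the pangenome size after k
    genomes is the number of orthogroups present in at least one of the
    first k; the reported curve is the mean across permutations.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    presence = matrix.counts.values >= 1  # orthogroups x genomes
    n = presence.shape[1]
    rng = np.random.default_rng(seed)
    curves = np.empty((n_permutations, n), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(n)
        seen = np.maximum.accumulate(presence[:, order], axis=1)
        curves[p] = seen.sum(axis=0)
    return AccumulationCurve(
        x=np.arange(1, n + 1),
        y_mean=curves.mean(axis=0),
        n_permutations=n_permutations,
        seed=seed,
        per_permutation=curves,
    )


@dataclass
class HeapsFit:
    a: float
    gamma: float
    residual_norm: float

    @property
    def open_pangenome(self) -> bool:
        return 0.0 < self.gamma < 1.0


def fit_power_law(curve: AccumulationCurve) -> HeapsFit:
    """Nonlinear least-squares fit of y = a * x**gamma to the mean curve."""
    x = np.asarray(curve.x, dtype=float)
    y = np.asarray(curve.y_mean, dtype=float)
    if x.size < 3:
        raise ValueError("power-law fit needs at least 3 curve points")
    if np.allclose(y, 0):
        raise ValueError("degenerate all-zero accumulation curve")

    def model(xx, a, gamma):
        return a * np.power(xx, gamma)

    popt, _ = curve_fit(
        model,
        x,
        y,
        p0=(max(y[0], 1e-9), 0.3),
        maxfev=20000,
        xtol=1e-10,
        ftol=1e-10,
    )
    a_hat, gamma_hat = popt
    resid = y - model(x, *popt)
    return HeapsFit(a=float(a_hat), gamma=float(gamma_hat), residual_norm=float(np.linalg.norm(resid)))


@dataclass
class CogEnrichment:
    table: pd.DataFrame  # category, core_percent, accessory_percent, log2_ratio, call


def cog_enrichment(
    part: PangenomePartition,
    annotations: AnnotationTable,
    matrix: GeneCountTable,
    log2_cutoff: float = 1.0,
    unit: str = "family",
) -> CogEnrichment:
    """Core-vs-accessory COG category enrichment.

    The accessory fraction pools soft-core, shell, cloud, and unique
    families.  Per category c, core_percent = 100 * (core families carrying
    c) / (core families); a category is ``core_enriched`` when the core
    percentage is at least two-fold the accessory one (log2 ratio >= 1),
    ``core_depleted`` for the mirror rule, and ``undefined`` when either
    percentage is zero.  With ``unit="family"`` (default) each orthogroup
    counts once; with ``unit="gene"`` it is weighted by its total gene count
    in the matrix.  A multi-letter family counts once in each of its
    categories; families with no annotated gene carry the '@'
    pseudo-category.
    """
    if unit not in ("family", "gene"):
        raise ValueError("unit must be 'family' or 'gene'")
    og_cats = annotations.orthogroup_categories()
    core = part.members("core")
    accessory = [og for og in part.classes if part.classes[og] != "core"]
    if not core or not accessory:
        raise ValueError("enrichment needs non-empty core and accessory fractions")
    gene_totals = matrix.counts.sum(axis=1)

    def percent(ogs: list[str]) -> dict[str, float]:
        tally: dict[str, float] = {}
        total = 0.0
        for og in ogs:
            w = 1.0 if unit == "family" else float(gene_totals.get(og, 0))
            total += w
            for cat in og_cats.get(og, {"@"}):
                tally[cat] = tally.get(cat, 0.0) + w
        return {cat: 100.0 * cnt / total for cat, cnt in tally.items()}

    core_pct = percent(core)
    acc_pct = percent(accessory)
    rows = []
    for cat in sorted(set(core_pct) | set(acc_pct)):
        cp = core_pct.get(cat, 0.0)
        ap = acc_pct.get(cat, 0.0)
        if cp == 0.0 or ap == 0.0:
            ratio, call = np.nan, "undefined"
        else:
            ratio = float(np.log2(cp / ap))
            if ratio >= log2_cutoff:
                call = "core_enriched"
            elif ratio <= -log2_cutoff:
                call = "core_depleted"
            else:
                call = "neutral"
        rows.append(
            {
                "category": cat,
                "core_percent": cp,
                "accessory_percent": ap,
                "log2_ratio": ratio,
                "call": call,
            }
        )
    return CogEnrichment(table=pd.DataFrame(rows))


def single_copy_core(matrix: GeneCountTable) -> list[str]:
    """Orthogroups with exactly one copy in every genome (the families used
    for concatenated species-tree alignments)."""
    mask = (matrix.counts.values == 1).all(axis=1)
    return [og for og, m in zip(matrix.orthogroup_ids, mask) if m]
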