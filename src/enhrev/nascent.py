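"""Exon/intron read partitioning and ongoing-transcription classification.

Intronic reads report nascent RNA: introns are removed co-transcriptionally,
so tags mapping to introns reflect transcription happening at the time of
sampling rather than accumulated mRNA.  Comparing exon-level and
intron-level differential results therefore separates genes regulated by
ongoing transcription from genes whose mRNA change is driven by turnover.

Gene models here are single-isoform: one sorted, disjoint exon chain per
gene, with introns defined as the gaps between consecutive exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .difftest import threshold_results
from .intervals import TagTrack


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform gene: sorted disjoint exons on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if not self.exons:
            raise ValueError("gene must have at least one exon")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon [{s}, {e})")
            if s < prev_end:
                raise ValueError("exons must be sorted and disjoint")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end of the gene on its strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        )

    @property
    def exon_length_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_length_bp(self) -> int:
        return sum(e - s for s, e in self.introns)


def read_genes_tsv(path: str) -> list[GeneModel]:
    """Read gene models from a TSV with columns
    gene_id, chrom, strand, tss, exon_starts, exon_ends (comma-joined)."""
    df = pd.read_csv(path, sep="\t")
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",") if x]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x]
        genes.append(
            GeneModel(row.gene_id, row.chrom, row.strand, tuple(zip(starts, ends)))
        )
    return genes


def write_genes_tsv(genes: Iterable[GeneModel], path: str) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "exon_starts": ",".join(str(s) for s, _ in g.exons),
            "exon_ends": ",".join(str(e) for _, e in g.exons),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def partition_tags(track: TagTrack, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Count tags in exons versus introns of each gene.

    A tag is an exon tag of a gene if its position lies in any exon of that
    gene, an intron tag if it lies in any intron; genes are tallied
    independently, so a position inside two overlapping genes contributes to
    both.  Returns a DataFrame indexed by gene id with columns
    ``exon_count`` and ``intron_count``.
    """
    exon_counts = np.zeros(len(genes), dtype=np.int64)
    intron_counts = np.zeros(len(genes), dtype=np.int64)
    for i, g in enumerate(genes):
        pos = track.tags.get(g.chrom)
        if pos is None or pos.size == 0:
            continue
        lo = np.searchsorted(pos, g.start, side="left")
        hi = np.searchsorted(pos, g.end, side="left")
        inside = pos[lo:hi]
        if inside.size == 0:
            continue
        for s, e in g.exons:
            exon_counts[i] += np.searchsorted(inside, e) - np.searchsorted(inside, s)
        for s, e in g.introns:
            intron_counts[i] += np.searchsorted(inside, e) - np.searchsorted(inside, s)
    return pd.DataFrame(
        {"exon_count": exon_counts, "intron_count": intron_counts},
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )


def rpkm(count: int, feature_length_bp: int, library_total: int) -> float:
    """Reads per kilobase of feature per million library tags."""
    if feature_length_bp <= 0:
        raise ValueError("feature length must be positive")
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return count / ((feature_length_bp / 1000.0) * (library_total / 1e6))


DEFAULT_INTRON_FDR_GRID = (0.01, 0.05, 0.1)


@dataclass
class OngoingClassification:
    """Per-gene nascent-transcription calls plus per-threshold fractions."""

    calls: pd.DataFrame  # direction + ongoing_at_<t> columns, indexed by gene
    fractions: pd.DataFrame  # rows (direction, threshold) -> fraction ongoing

    def fraction(self, direction: str, threshold: float) -> float:
        sel = self.fractions[
            (self.fractions["direction"] == direction)
            & (self.fractions["intron_fdr"] == threshold)
        ]
        return float(sel["fraction_ongoing"].iloc[0])


def classify_ongoing(
    exon_results: pd.DataFrame,
    intron_results: pd.DataFrame,
    exon_fdr_max: float = 0.01,
    min_fc: float = 1.5,
    intron_fdr_grid: Sequence[float] = DEFAULT_INTRON_FDR_GRID,
) -> OngoingClassification:
    """Label exon-regulated genes as transcribed 'ongoing' or not.

    A gene is exon-regulated (direction up/down) by the FDR + fold-change
    thresholds applied to the exon-level results.  For each intron-FDR
    threshold ``t`` in the grid the gene is called ongoing iff its intron
    FDR < t and the intron fold change has the same sign as the exon fold
    change.  Fractions of ongoing genes are reported per direction and
    threshold.
    """
    if len(intron_fdr_grid) == 0:
        raise ValueError("intron_fdr_grid must be non-empty")
    if set(exon_results.index) != set(intron_results.index):
        raise ValueError("exon and intron results must cover the same genes")

    up, down = threshold_results(exon_results, exon_fdr_max, min_fc)
    direction = pd.Series("none", index=exon_results.index)
    direction.loc[up] = "up"
    direction.loc[down] = "down"

    intron = intron_results.loc[exon_results.index]
    exon_sign = np.sign(exon_results["log2fc"].to_numpy())
    intron_sign = np.sign(intron["log2fc"].to_numpy())
    intron_fdr = intron["fdr"].to_numpy()
    regulated = (direction != "none").to_numpy()

    calls = pd.DataFrame({"direction": direction})
    frac_rows = []
    for t in intron_fdr_grid:
        ongoing = (
            regulated
            & ~np.isnan(intron_fdr)
            & (intron_fdr < t)
            & (intron_sign == exon_sign)
            & (intron_sign != 0)
        )
        calls[f"ongoing_at_{t:g}"] = ongoing
        for d in ("up", "down"):
            in_dir = (direction == d).to_numpy()
            n_dir = int(in_dir.sum())
            frac_rows.append(
                {
                    "direction": d,
                    "intron_fdr": t,
                    "n_regulated": n_dir,
                    "n_ongoing": int((ongoing & in_dir).sum()),
                    "fraction_ongoing": (
                        float((ongoing & in_dir).sum() / n_dir) if n_dir else np.nan
                    ),
                }
            )
    return OngoingClassification(calls=calls, fractions=pd.DataFrame(frac_rows))
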