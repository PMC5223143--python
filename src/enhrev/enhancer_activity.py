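"""Differential enhancer activity, enhancer-gene proximity enrichment, and
persistence/reversal classification.

Enhancer activity is proxied by an acetylation mark (H3K27ac) quantified at
a fixed universe of accessible regions; differential activity between
feeding groups reuses the NB count test.  Proximity enrichment asks whether
differentially active regions concentrate within a TSS-centered window
around a gene set of interest, compared with resampled random gene sets.
Persistence classification crosses the diet contrast (HFD vs Chow) with the
reversal contrast (HFD-chow vs Chow-chow) to separate reversible from
putatively persistent regulation, with FDR-distribution diagnostics that
expose persistent calls that are likely false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .difftest import (
    Contrast,
    CountMatrix,
    estimate_dispersion,
    estimate_size_factors,
    nb_wald_test,
)
from .nascent import GeneModel
from .intervals import RegionSet


def differential_acetylation(
    region_counts: CountMatrix, contrast: Contrast
) -> pd.DataFrame:
    """NB Wald test of mark density at accessible regions for one contrast.

    Size factors and dispersions are estimated on the full region matrix
    (all groups), then the two-group test is run.
    """
    sf = estimate_size_factors(region_counts)
    alpha = estimate_dispersion(region_counts, sf)
    return nb_wald_test(region_counts, sf, alpha, contrast)


# ---------------------------------------------------------------------------
# Proximity enrichment


@dataclass
class LinkageEnrichment:
    """Regions-per-gene enrichment of a region class near a gene set."""

    gene_set_name: str
    region_class: str
    window_bp: int
    observed: float  # qualifying region-gene pairs per test gene
    null_values: list[float]  # one pairs-per-gene value per resampling round
    ratio: float  # observed / mean(null); NaN when undefined
    p: float  # two-tailed one-sample t-test of null rounds vs observed
    frac_genes_with_hit: float

    def to_row(self) -> dict:
        return {
            "gene_set": self.gene_set_name,
            "region_class": self.region_class,
            "window_bp": self.window_bp,
            "observed_pairs_per_gene": self.observed,
            "null_mean": float(np.mean(self.null_values)) if self.null_values else np.nan,
            "ratio": self.ratio,
            "p": self.p,
            "frac_genes_with_hit": self.frac_genes_with_hit,
        }


def _pairs_per_gene(
    regions: RegionSet, genes: Sequence[GeneModel], window_bp: int
) -> tuple[float, float]:
    """(mean qualifying pairs per gene, fraction of genes with >= 1 pair).

    A region qualifies for a gene when any bp of it lies within
    [TSS - window, TSS + window].
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list] = {}
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        starts[chrom] = np.array([r.start for r in rs])
        ends[chrom] = np.sort(np.array([r.end for r in rs]))
    hits = np.zeros(len(genes), dtype=np.int64)
    for i, g in enumerate(genes):
        if g.chrom not in starts:
            continue
        lo, hi = g.tss - window_bp, g.tss + window_bp
        # overlap iff region.start < hi and region.end > lo
        n_start_ok = np.searchsorted(starts[g.chrom], hi, side="left")
        n_end_low = np.searchsorted(ends[g.chrom], lo, side="right")
        hits[i] = max(n_start_ok - n_end_low, 0)
    n = len(genes)
    return float(hits.sum() / n) if n else np.nan, float((hits > 0).mean()) if n else np.nan


def proximity_enrichment(
    diff_regions: RegionSet,
    genes: Sequence[GeneModel],
    test_set: Sequence[str],
    window_bp: int = 100_000,
    n_random: int = 200,
    rounds: int = 4,
    seed: int = 0,
    gene_set_name: str = "test",
    region_class: str = "",
) -> LinkageEnrichment:
    """Enrichment of regions near a gene set versus resampled random sets.

    The statistic is qualifying region-gene pairs per gene.  Each of
    ``rounds`` resampling rounds draws ``n_random`` genes uniformly without
    replacement from the genes *excluding* the test set, and the p-value is
    a two-tailed one-sample t-test of the round values against the observed
    value.  Deterministic for a given seed and invariant to region order.
    """
    by_id = {g.gene_id: g for g in genes}
    test_ids = list(dict.fromkeys(test_set))
    missing = [t for t in test_ids if t not in by_id]
    if missing:
        raise ValueError(f"test-set genes not in gene models: {missing[:3]}...")
    background = [g for g in genes if g.gene_id not in set(test_ids)]
    if len(background) < n_random:
        raise ValueError(
            f"need >= {n_random} background genes, have {len(background)}"
        )

    observed, frac_hit = _pairs_per_gene(
        diff_regions, [by_id[t] for t in test_ids], window_bp
    )

    rng = np.random.default_rng(seed)
    null_values = []
    for _ in range(rounds):
        pick = rng.choice(len(background), size=n_random, replace=False)
        sampled = [background[i] for i in pick]
        val, _ = _pairs_per_gene(diff_regions, sampled, window_bp)
        null_values.append(val)

    null_mean = float(np.mean(null_values))
    if len(diff_regions) == 0 or null_mean == 0:
        ratio = np.nan
    else:
        ratio = observed / null_mean
    if np.allclose(null_values, null_values[0]) and null_values[0] == observed:
        p = 1.0
    else:
        p = float(stats.ttest_1samp(null_values, observed).pvalue)
    return LinkageEnrichment(
        gene_set_name=gene_set_name,
        region_class=region_class,
        window_bp=window_bp,
        observed=observed,
        null_values=[float(v) for v in null_values],
        ratio=float(ratio) if not np.isnan(ratio) else np.nan,
        p=p,
        frac_genes_with_hit=frac_hit,
    )


# ---------------------------------------------------------------------------
# Persistence classification

PERSISTENCE_CLASSES = (
    "reversible",
    "putative_persistent",
    "weightloss_specific",
    "unregulated",
)


@dataclass
class PersistenceResult:
    """Per-region persistence calls plus Venn counts at both cutoffs."""

    calls: pd.DataFrame  # p/fdr for both contrasts + class, indexed by region
    venn_fdr: dict[str, int] = field(default_factory=dict)
    venn_p: dict[str, int] = field(default_factory=dict)

    def class_counts(self) -> dict[str, int]:
        vc = self.calls["persistence_class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in PERSISTENCE_CLASSES}


def classify_persistence(
    dio: pd.DataFrame,
    rev: pd.DataFrame,
    p_cut: float = 0.01,
    fdr_cut: float = 0.1,
) -> PersistenceResult:
    """Cross the diet and reversal contrasts into persistence classes.

    Using the lenient screen (raw p < ``p_cut``), each region is
    * putative_persistent: significant in both contrasts with concordant
      fold-change sign;
    * reversible: significant in the diet contrast but not called
      persistent;
    * weightloss_specific: significant in the reversal contrast only;
    * unregulated: otherwise.

    Venn overlap counts of the two significant sets are reported both at
    FDR < ``fdr_cut`` and at p < ``p_cut``.  The partition is exhaustive
    and mutually exclusive over the shared region universe.
    """
    if set(dio.index) != set(rev.index):
        raise ValueError("contrast results must cover the same region universe")
    rev = rev.loc[dio.index]

    p_dio = dio["p"].to_numpy()
    p_rev = rev["p"].to_numpy()
    sign_ok = (
        (np.sign(dio["log2fc"].to_numpy()) == np.sign(rev["log2fc"].to_numpy()))
        & (np.sign(dio["log2fc"].to_numpy()) != 0)
    )
    sig_dio = ~np.isnan(p_dio) & (p_dio < p_cut)
    sig_rev = ~np.isnan(p_rev) & (p_rev < p_cut)

    cls = np.where(
        sig_dio & sig_rev & sign_ok,
        "putative_persistent",
        np.where(
            sig_dio,
            "reversible",
            np.where(sig_rev, "weightloss_specific", "unregulated"),
        ),
    )

    calls = pd.DataFrame(
        {
            "p_dio": p_dio,
            "fdr_dio": dio["fdr"].to_numpy(),
            "log2fc_dio": dio["log2fc"].to_numpy(),
            "p_rev": p_rev,
            "fdr_rev": rev["fdr"].to_numpy(),
            "log2fc_rev": rev["log2fc"].to_numpy(),
            "persistence_class": cls,
        },
        index=dio.index.rename("region_id"),
    )

    def venn(sig_a: np.ndarray, sig_b: np.ndarray) -> dict[str, int]:
        return {
            "dio_only": int((sig_a & ~sig_b).sum()),
            "rev_only": int((sig_b & ~sig_a).sum()),
            "both": int((sig_a & sig_b).sum()),
        }

    f_dio = dio["fdr"].to_numpy()
    f_rev = rev["fdr"].to_numpy()
    venn_fdr = venn(
        ~np.isnan(f_dio) & (f_dio < fdr_cut), ~np.isnan(f_rev) & (f_rev < fdr_cut)
    )
    venn_p = venn(sig_dio, sig_rev)
    return PersistenceResult(calls=calls, venn_fdr=venn_fdr, venn_p=venn_p)


def persistence_diagnostics(
    result: PersistenceResult, region_counts: CountMatrix
) -> dict[str, dict]:
    """Per-class diagnostics: z-scored count quartiles per group and the
    empirical FDR distributions of both contrasts.

    Counts are size-factor normalized and z-scored per region across all
    samples; quartiles are then summarized within each feeding group.  The
    FDR quartiles reveal whether a class carries strong or weak evidence in
    each contrast — putative persistent calls arising from noise show weak
    (high-FDR) reversal evidence.
    """
    sf = estimate_size_factors(region_counts)
    norm = region_counts.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    mean = norm.mean(axis=1, keepdims=True)
    sd = norm.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (norm - mean) / sd, 0.0)
    zdf = pd.DataFrame(
        z, index=region_counts.counts.index, columns=region_counts.sample_ids
    )

    def quartiles(v: np.ndarray) -> dict[str, float]:
        if v.size == 0:
            return {}
        clean = v[~np.isnan(v)]
        if clean.size == 0:
            return {}
        q1, q2, q3 = np.percentile(clean, [25, 50, 75])
        return {"q1": float(q1), "median": float(q2), "q3": float(q3)}

    out: dict[str, dict] = {}
    for cls in PERSISTENCE_CLASSES:
        mask = result.calls["persistence_class"] == cls
        ids = result.calls.index[mask]
        entry: dict = {"n": int(mask.sum())}
        if mask.sum() == 0:
            out[cls] = entry
            continue
        group_z = {}
        for g in region_counts.meta["group"].unique():
            cols = region_counts.samples_in_group(g)
            group_z[g] = quartiles(zdf.loc[ids, cols].to_numpy().ravel())
        entry["zscore_by_group"] = group_z
        entry["fdr_dio"] = quartiles(result.calls.loc[ids, "fdr_dio"].to_numpy())
        entry["fdr_rev"] = quartiles(result.calls.loc[ids, "fdr_rev"].to_numpy())
        out[cls] = entry
    return out
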