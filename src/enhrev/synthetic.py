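"""Seed-reproducible synthetic four-group feeding study with known truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a Chow / HFD / Chow-chow / HFD-chow design with negative-binomial
exon, intron, acetylation-mark and accessibility counts; planted
diet-effect classes (transcriptional versus turnover-only genes, induced
versus reduced regions, persistent versus reversible effects); enhancer-gene
coupling within a TSS window; and motif instances planted in induced-region
sequences.  Accessibility counts are class-independent by default, encoding
the premise that diet modulates the activity of pre-established regulatory
regions rather than opening new ones.

Everything is drawn from one :class:`numpy.random.Generator`, so a given
seed reproduces the bundle bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .difftest import CountMatrix, GROUPS
from .intervals import GenomicInterval, RegionSet, TagTrack, read_bed, write_bed
from .motifs import PWM, example_pwm, read_fasta, write_fasta
from .nascent import GeneModel, read_genes_tsv, write_genes_tsv

GENE_CLASSES = (
    "null",
    "up_transcriptional",
    "down_transcriptional",
    "up_turnover",
    "down_turnover",
    "persistent_up",
)
REGION_CLASSES = ("null", "induced", "reduced", "persistent", "weightloss_only")


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the reference study design: four feeding groups with
    three RNA/ChIP replicates and two accessibility replicates each, NB
    dispersion 0.05, planted effects of |log2FC| = 1.5 in a few percent of
    features (roughly twice as many induced as reduced regions), 80% of
    affected regions coupled to a same-direction regulated gene within
    100 kb of its TSS, and a motif planted in 70% of induced regions.
    """

    seed: int = 0
    n_genes: int = 3000
    n_regions: int = 8000
    genome_length: int = 50_000_000
    chrom: str = "chrS"
    rna_replicates: int = 3
    chip_replicates: int = 3
    dnase_replicates: int = 2
    exon_mean: float = 200.0
    intron_mean: float = 100.0
    chip_mean: float = 150.0
    dnase_mean: float = 150.0
    dispersion: float = 0.05
    gene_class_props: dict = field(
        default_factory=lambda: {
            "up_transcriptional": 0.02,
            "down_transcriptional": 0.02,
            "up_turnover": 0.02,
            "down_turnover": 0.02,
            "persistent_up": 0.0,
        }
    )
    region_class_props: dict = field(
        default_factory=lambda: {
            "induced": 0.04,
            "reduced": 0.02,
            "persistent": 0.0,
            "weightloss_only": 0.0,
        }
    )
    log2fc: float = 1.5
    coupling: float = 0.8
    motif_prob: float = 0.7
    region_length: int = 500
    seq_length: int = 500
    min_gene_spacing: int = 10_000
    min_region_spacing: int = 1_000
    proximity_window: int = 100_000
    size_factor_range: tuple = (0.7, 1.4)

    def validate(self) -> None:
        for name, props, classes in (
            ("gene", self.gene_class_props, GENE_CLASSES),
            ("region", self.region_class_props, REGION_CLASSES),
        ):
            unknown = set(props) - set(classes)
            if unknown:
                raise ValueError(f"unknown {name} classes: {sorted(unknown)}")
            if any(v < 0 for v in props.values()) or sum(props.values()) > 1:
                raise ValueError(f"{name} class proportions must sum to <= 1")
        for attr in ("n_genes", "n_regions", "genome_length", "region_length"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SimBundle:
    """Everything a study run produces, plus the ground truth."""

    config: SimConfig
    genes: list[GeneModel]
    regions: RegionSet
    counts_exon: CountMatrix
    counts_intron: CountMatrix
    counts_k27ac: CountMatrix
    counts_dnase: CountMatrix
    sequences: dict[str, str]
    gene_truth: pd.DataFrame
    region_truth: pd.DataFrame
    samples: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_genes_tsv(self.genes, out / "genes.tsv")
        write_bed(self.regions, str(out / "regions.bed"))
        self.counts_exon.to_tsv(out / "counts_exon.tsv")
        self.counts_intron.to_tsv(out / "counts_intron.tsv")
        self.counts_k27ac.to_tsv(out / "counts_k27ac.tsv")
        self.counts_dnase.to_tsv(out / "counts_dnase.tsv")
        write_fasta(self.sequences, out / "regions.fa")
        self.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t")
        self.region_truth.to_csv(out / "truth_regions.tsv", sep="\t")
        self.samples.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
        _write_toml(asdict(self.config), out / "config.toml")

    @classmethod
    def read(cls, outdir: str | Path) -> "SimBundle":
        out = Path(outdir)
        samples = pd.read_csv(out / "samples.tsv", sep="\t", index_col="sample_id")

        def load_counts(name: str) -> CountMatrix:
            counts = pd.read_csv(out / name, sep="\t", index_col="feature_id")
            return CountMatrix(counts, samples.loc[counts.columns])

        cfg_dict = _read_toml(out / "config.toml")
        return cls(
            config=SimConfig(**cfg_dict),
            genes=read_genes_tsv(out / "genes.tsv"),
            regions=read_bed(str(out / "regions.bed"), name="regions"),
            counts_exon=load_counts("counts_exon.tsv"),
            counts_intron=load_counts("counts_intron.tsv"),
            counts_k27ac=load_counts("counts_k27ac.tsv"),
            counts_dnase=load_counts("counts_dnase.tsv"),
            sequences=read_fasta(out / "regions.fa"),
            # keep_default_na: the class label "null" is data, not missing
            gene_truth=pd.read_csv(
                out / "truth_genes.tsv", sep="\t", index_col=0,
                keep_default_na=False,
            ),
            region_truth=pd.read_csv(
                out / "truth_regions.tsv", sep="\t", index_col=0,
                keep_default_na=False,
            ),
            samples=samples,
        )


def _write_toml(d: dict, path: Path) -> None:
    """Echo a flat config dict as TOML (strings, numbers, lists, dicts)."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, str):
            return f'"{v}"'
        if isinstance(v, (list, tuple)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        return repr(v)

    lines = []
    tables = []
    for k, v in d.items():
        if isinstance(v, dict):
            tables.append((k, v))
        else:
            lines.append(f"{k} = {fmt(v)}")
    for k, v in tables:
        lines.append(f"\n[{k}]")
        for kk, vv in v.items():
            lines.append(f"{kk} = {fmt(vv)}")
    path.write_text("\n".join(lines) + "\n")


def _read_toml(path: Path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        d = tomllib.load(fh)
    if "size_factor_range" in d:
        d["size_factor_range"] = tuple(d["size_factor_range"])
    return d


# ---------------------------------------------------------------------------
# Generation internals


def _place_in_slots(
    rng: np.random.Generator, n: int, spacing: int, width: int, genome_length: int
) -> np.ndarray:
    """n sorted start positions with pairwise distance >= spacing - width."""
    n_slots = genome_length // spacing
    if n_slots < n:
        raise ValueError(
            f"cannot place {n} features with {spacing} bp spacing "
            f"in a {genome_length} bp genome"
        )
    slots = np.sort(rng.choice(n_slots, size=n, replace=False))
    jitter = rng.integers(0, max(spacing - width, 1), size=n)
    return slots * spacing + jitter


def _assign_classes(
    rng: np.random.Generator, n: int, props: dict[str, float]
) -> np.ndarray:
    classes = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    offset = 0
    for name in sorted(props):
        k = int(round(props[name] * n))
        classes[order[offset : offset + k]] = name
        offset += k
    return classes


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """NB draws with var = mu + alpha mu^2 (Poisson when alpha ~ 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _sample_sheet(prefix: str, replicates: int) -> pd.DataFrame:
    rows = {}
    for g in GROUPS:
        for r in range(1, replicates + 1):
            rows[f"{prefix}_{g}_{r}"] = {"group": g, "replicate": r}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def _count_matrix(
    rng: np.random.Generator,
    feature_ids: list[str],
    meta: pd.DataFrame,
    base_mean: float,
    lfc_dio: np.ndarray,
    lfc_rev: np.ndarray,
    alpha: float,
    sf_range: tuple,
) -> CountMatrix:
    """NB counts: mean = s_j * q_i * 2^(group effect)."""
    n = len(feature_ids)
    q = base_mean * np.exp(rng.normal(0.0, 0.8, size=n) - 0.32)
    lo, hi = np.log(sf_range[0]), np.log(sf_range[1])
    sf = np.exp(rng.uniform(lo, hi, size=len(meta)))
    effect = {
        "Chow": np.zeros(n),
        "HFD": lfc_dio,
        "ChowChow": np.zeros(n),
        "HFDChow": lfc_rev,
    }
    cols = {}
    for j, (sample, row) in enumerate(meta.iterrows()):
        mu = sf[j] * q * np.power(2.0, effect[row["group"]])
        cols[sample] = _nb_draw(rng, mu, alpha)
    counts = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"))
    return CountMatrix(counts, meta)


def simulate_study(config: SimConfig | None = None) -> SimBundle:
    """Generate the full synthetic study bundle for a config.

    Gene and region coordinates are laid out on one synthetic chromosome
    with minimum spacing; effect classes are planted per the configured
    proportions; induced/reduced regions are coupled to same-direction
    regulated genes within the proximity window with the configured
    probability.  Raises when coupling is infeasible (no regulated gene to
    couple to).
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- gene models -------------------------------------------------------
    n_exons, exon_len, intron_len = 4, 300, 2000
    gene_span = n_exons * exon_len + (n_exons - 1) * intron_len
    gene_starts = _place_in_slots(
        rng, cfg.n_genes, cfg.min_gene_spacing, gene_span, cfg.genome_length
    )
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    genes = []
    for i in range(cfg.n_genes):
        s = int(gene_starts[i])
        exons = tuple(
            (s + k * (exon_len + intron_len), s + k * (exon_len + intron_len) + exon_len)
            for k in range(n_exons)
        )
        genes.append(GeneModel(f"G{i + 1:05d}", cfg.chrom, str(strands[i]), exons))

    gene_class = _assign_classes(rng, cfg.n_genes, cfg.gene_class_props)

    def gene_lfcs(cls: str) -> tuple[float, float, float, float]:
        """(exon dio, intron dio, exon rev, intron rev) true log2 fold changes."""
        d = cfg.log2fc
        return {
            "null": (0, 0, 0, 0),
            "up_transcriptional": (d, d, 0, 0),
            "down_transcriptional": (-d, -d, 0, 0),
            "up_turnover": (d, 0, 0, 0),
            "down_turnover": (-d, 0, 0, 0),
            "persistent_up": (d, d, d, d),
        }[cls]

    lfc = np.array([gene_lfcs(c) for c in gene_class], dtype=float)
    gene_truth = pd.DataFrame(
        {
            "class": gene_class,
            "lfc_exon_dio": lfc[:, 0],
            "lfc_intron_dio": lfc[:, 1],
            "lfc_exon_rev": lfc[:, 2],
            "lfc_intron_rev": lfc[:, 3],
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )

    # --- regions with enhancer-gene coupling -------------------------------
    region_class = _assign_classes(rng, cfg.n_regions, cfg.region_class_props)
    coupled_dir = {"induced": "up", "reduced": "down", "persistent": "up"}
    up_genes = [
        g for g, c in zip(genes, gene_class) if c.startswith(("up_", "persistent"))
    ]
    down_genes = [g for g, c in zip(genes, gene_class) if c.startswith("down_")]

    base_starts = _place_in_slots(
        rng, cfg.n_regions, cfg.min_region_spacing, cfg.region_length,
        cfg.genome_length,
    )
    starts = base_starts.astype(np.int64).copy()
    linked_gene = np.array([""] * cfg.n_regions, dtype=object)
    occupied = set(base_starts // cfg.min_region_spacing)
    for i in range(cfg.n_regions):
        direction = coupled_dir.get(region_class[i])
        if direction is None or rng.random() >= cfg.coupling:
            continue
        pool = up_genes if direction == "up" else down_genes
        if not pool:
            raise ValueError(
                f"infeasible coupling: no {direction}-regulated genes available"
            )
        g = pool[rng.integers(len(pool))]
        for _ in range(200):
            lo = max(g.tss - cfg.proximity_window, 0)
            hi = min(
                g.tss + cfg.proximity_window - cfg.region_length,
                cfg.genome_length - cfg.region_length,
            )
            pos = int(rng.integers(lo, hi))
            slot = pos // cfg.min_region_spacing
            if slot not in occupied and (slot + 1) not in occupied:
                occupied.discard(int(base_starts[i]) // cfg.min_region_spacing)
                occupied.update((slot, slot + 1))
                starts[i] = pos
                linked_gene[i] = g.gene_id
                break
        else:
            raise ValueError("infeasible coupling: no free position near gene")

    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    region_class = region_class[order]
    linked_gene = linked_gene[order]
    region_ids = [f"R{i + 1:05d}" for i in range(cfg.n_regions)]
    regions = RegionSet(
        [
            GenomicInterval(
                cfg.chrom, int(s), int(s) + cfg.region_length, ".", rid
            )
            for rid, s in zip(region_ids, starts)
        ],
        name="accessible_regions",
    )

    def region_lfcs(cls: str) -> tuple[float, float]:
        d = cfg.log2fc
        return {
            "null": (0, 0),
            "induced": (d, 0),
            "reduced": (-d, 0),
            "persistent": (d, d),
            "weightloss_only": (0, d),
        }[cls]

    rlfc = np.array([region_lfcs(c) for c in region_class], dtype=float)

    # --- sequences with planted motifs -------------------------------------
    pwm = example_pwm()
    motif_planted = np.zeros(cfg.n_regions, dtype=bool)
    seqs: dict[str, str] = {}
    base_arr = np.array(list("ACGT"))
    for i, rid in enumerate(region_ids):
        seq = base_arr[rng.integers(0, 4, size=cfg.seq_length)]
        if region_class[i] in ("induced", "persistent") and rng.random() < cfg.motif_prob:
            inst = _sample_motif_instance(rng, pwm)
            mid = (cfg.seq_length - len(inst)) // 2
            seq[mid : mid + len(inst)] = list(inst)
            motif_planted[i] = True
        seqs[rid] = "".join(seq)

    region_truth = pd.DataFrame(
        {
            "class": region_class,
            "lfc_dio": rlfc[:, 0],
            "lfc_rev": rlfc[:, 1],
            "linked_gene": linked_gene,
            "motif_planted": motif_planted,
        },
        index=pd.Index(region_ids, name="region_id"),
    )

    # --- count matrices -----------------------------------------------------
    gene_ids = [g.gene_id for g in genes]
    rna_meta = _sample_sheet("rna", cfg.rna_replicates)
    chip_meta = _sample_sheet("chip", cfg.chip_replicates)
    dnase_meta = _sample_sheet("dnase", cfg.dnase_replicates)

    counts_exon = _count_matrix(
        rng, gene_ids, rna_meta, cfg.exon_mean,
        lfc[:, 0], lfc[:, 2], cfg.dispersion, cfg.size_factor_range,
    )
    counts_intron = _count_matrix(
        rng, gene_ids, rna_meta, cfg.intron_mean,
        lfc[:, 1], lfc[:, 3], cfg.dispersion, cfg.size_factor_range,
    )
    counts_k27ac = _count_matrix(
        rng, region_ids, chip_meta, cfg.chip_mean,
        rlfc[:, 0], rlfc[:, 1], cfg.dispersion, cfg.size_factor_range,
    )
    # accessibility is class-independent: open chromatin does not change
    zero = np.zeros(cfg.n_regions)
    counts_dnase = _count_matrix(
        rng, region_ids, dnase_meta, cfg.dnase_mean,
        zero, zero, cfg.dispersion, cfg.size_factor_range,
    )

    samples = pd.concat([rna_meta, chip_meta, dnase_meta])
    return SimBundle(
        config=cfg,
        genes=genes,
        regions=regions,
        counts_exon=counts_exon,
        counts_intron=counts_intron,
        counts_k27ac=counts_k27ac,
        counts_dnase=counts_dnase,
        sequences=seqs,
        gene_truth=gene_truth,
        region_truth=region_truth,
        samples=samples,
    )


def _sample_motif_instance(rng: np.random.Generator, pwm: PWM) -> str:
    """Draw one motif instance base-by-base from the PWM columns."""
    bases = "ACGT"
    return "".join(
        bases[rng.choice(4, p=pwm.matrix[:, j] / pwm.matrix[:, j].sum())]
        for j in range(pwm.length)
    )


def simulate_tag_cluster(
    region: GenomicInterval,
    n_tags: int,
    background_rate: float,
    seed: int = 0,
    genome_length: int = 10_000_000,
    sample_id: str = "sim_tags",
) -> TagTrack:
    """``n_tags`` uniform tags inside a region plus uniform Poisson background.

    ``background_rate`` is expected background tags per bp across the
    ``genome_length`` span.  Used as the fixture generator for peak calling.
    """
    if n_tags < 0:
        raise ValueError("n_tags must be >= 0")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    rng = np.random.default_rng(seed)
    fg = rng.integers(region.start, region.end, size=n_tags)
    n_bg = rng.poisson(background_rate * genome_length)
    bg = rng.integers(0, genome_length, size=n_bg)
    return TagTrack(sample_id, {region.chrom: np.concatenate([fg, bg])})
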