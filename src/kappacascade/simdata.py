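"""Synthetic multi-omics generator with ground-truth labels.

Emulates the statistical structure of a BCR-activation NF-kB experiment:
a small annotated genome with planted RelA/Rel binding sites; strand-aware
ChIP/input/ATAC tag libraries in which sites emit extra tags over a uniform
Poisson background with biphasic subunit dynamics (RelA peaks at 1 h with a
30% residual at 4 h, Rel peaks at 18 h, shared sites bind Rel weakly at
1 h); and negative-binomial RNA count matrices over a genotype x treatment x
time factorial in which BAY abolishes all induction, RelA loss abolishes
early RelA-selective induction, and Rel loss abolishes late Rel-dependent
induction while de-repressing Rel-repressed genes at 1 h.

Every generator is deterministic under the config seed; independent RNG
streams are derived per stage/sample with ``np.random.default_rng`` seed
sequences [seed, stage_code, ...].
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .annotate import GeneRecord, GenomeAnnotation
from .diffexpr import CountMatrix, SampleMeta
from .peakcall import TagLibrary

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedDataset",
    "CapacityError",
    "simulate_genome",
    "simulate_tags",
    "simulate_counts",
    "simulate_dataset",
    "standard_design",
    "SITE_SPAN_BP",
]

SITE_SPAN_BP = 200
TIMES = (0, 1, 4, 18)
GENE_CLASSES = (
    "relA_selective", "rel_dependent", "redundant_direct", "rel_repressed",
    "indirect", "down_regulated", "null",
)
# kinetic pattern tags: a-c up (transient-early / intermediate / late),
# d down
_CLASS_PATTERN = {
    "relA_selective": "a", "redundant_direct": "a", "rel_repressed": "a",
    "indirect": "b", "rel_dependent": "c", "down_regulated": "d", "null": "-",
}

# relative site activity per (subunit, site class, time); 1.0 = full binding
SITE_ACTIVITY = {
    "RelA": {"shared": {1: 1.0, 4: 0.3}, "relA_only": {1: 1.0, 4: 0.3}, "rel_only": {}},
    "Rel": {"shared": {1: 0.3, 18: 1.0}, "relA_only": {}, "rel_only": {18: 1.0}},
}

_FACTOR_CODE = {"RelA": 1, "Rel": 2, "input": 3, "atac": 4}


class CapacityError(ValueError):
    """Requested sites/genes do not fit the configured genome."""


def _default_class_counts() -> dict[str, int]:
    return {
        "relA_selective": 20, "rel_dependent": 20, "redundant_direct": 10,
        "rel_repressed": 10, "indirect": 20, "down_regulated": 20, "null": 100,
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 2_000_000
    n_genes: int = 200
    n_sites_shared: int = 50
    n_sites_relA_only: int = 25
    n_sites_rel_only: int = 25
    chip_depth_tags: int = 400_000  # 1e5 tags/Mb on the default 4-Mb genome
    enrichment_fold: float = 10.0
    rna_depth: int = 1_000_000
    dispersion: float = 0.05
    class_counts: dict[str, int] = field(default_factory=_default_class_counts)
    effect_log2fc: float = 2.5
    derepression_log2fc: float = 2.0
    replicates: int = 2
    gene_body_bp: int = 2000
    site_location_mix: tuple[float, float, float] = (0.2, 0.4, 0.4)  # promoter/intron/intergenic
    chip_panel: tuple = (("RelA", 1), ("Rel", 18))
    atac_times: tuple = ()

    def __post_init__(self) -> None:
        ints = (self.n_chromosomes, self.chrom_length_bp, self.n_genes,
                self.n_sites_shared, self.n_sites_relA_only, self.n_sites_rel_only,
                self.chip_depth_tags, self.rna_depth, self.replicates)
        if any(v < 0 for v in ints):
            raise ValueError("counts must be >= 0")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        unknown = set(self.class_counts) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes {sorted(unknown)}")
        if sum(self.class_counts.values()) > self.n_genes:
            raise ValueError("class_counts sum exceeds n_genes")

    @property
    def n_sites(self) -> int:
        return self.n_sites_shared + self.n_sites_relA_only + self.n_sites_rel_only

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chrom_length_bp

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chromosomes)}


@dataclass
class SimTruth:
    site_table: pd.DataFrame  # site_id, chrom, center, site_class, location, linked_gene
    gene_table: pd.DataFrame  # gene_id, gene_class, pattern, linked_sites

    def active_sites(self, factor: str, time_h: int, min_activity: float = 0.5) -> pd.DataFrame:
        if factor == "atac":
            act = self.site_table.site_class.map(
                lambda c: max(SITE_ACTIVITY["RelA"][c].get(time_h, 0.0),
                              SITE_ACTIVITY["Rel"][c].get(time_h, 0.0)))
        else:
            act = self.site_table.site_class.map(
                lambda c: SITE_ACTIVITY[factor][c].get(time_h, 0.0))
        return self.site_table[act >= min_activity]

    def bound_genes(self, factor: str, time_h: int, min_activity: float = 0.5) -> set:
        sites = self.active_sites(factor, time_h, min_activity)
        return set(sites.linked_gene.dropna())

    def class_labels(self) -> pd.Series:
        return self.gene_table.set_index("gene_id").gene_class


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: GenomeAnnotation
    truth: SimTruth
    tags: list[TagLibrary]
    counts: CountMatrix


# ---------------------------------------------------------------------------
# genome + truth

def _make_gene(gene_id: str, chrom: str, body_start: int, body_bp: int, strand: str) -> GeneRecord:
    exons = [
        (body_start, body_start + body_bp // 5),
        (body_start + 2 * body_bp // 5, body_start + 7 * body_bp // 10),
        (body_start + 17 * body_bp // 20, body_start + body_bp),
    ]
    if strand == "+":
        tss, tes = body_start, body_start + body_bp - 1
    else:
        tss, tes = body_start + body_bp - 1, body_start
    return GeneRecord(gene_id=gene_id, chrom=chrom, strand=strand,
                      tss_bp=tss, tes_bp=tes, exons=exons)


def simulate_genome(cfg: SimConfig) -> tuple[GenomeAnnotation, SimTruth]:
    """Lay out non-overlapping gene territories and plant binding sites.

    Each gene owns an equal territory of its chromosome; a planted site for a
    gene goes in its promoter, an intron, or nearby intergenic space
    (default 20/40/40% mixture) so the annotator's nearest-TSS rule recovers
    the link.  Raises :class:`CapacityError` when sites or genes do not fit.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    chroms = cfg.chrom_lengths
    empty_sites = pd.DataFrame(
        columns=["site_id", "chrom", "center", "site_class", "location", "linked_gene"])
    empty_genes = pd.DataFrame(columns=["gene_id", "gene_class", "pattern", "linked_sites"])
    if cfg.n_genes == 0:
        if cfg.n_sites > 0:
            raise CapacityError("sites requested but no gene territories to host them")
        return GenomeAnnotation(chroms, []), SimTruth(empty_sites, empty_genes)

    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    territory = cfg.chrom_length_bp // per_chrom
    min_territory = 2 * cfg.gene_body_bp + 4000
    if territory < min_territory:
        raise CapacityError(
            f"territory {territory} bp too small for gene body + site flanks "
            f"(need >= {min_territory}); enlarge the genome or reduce n_genes")
    if cfg.n_sites > cfg.n_genes:
        raise CapacityError("more sites than gene territories (one site per gene)")

    genes: list[GeneRecord] = []
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        t_start = (i % per_chrom) * territory
        center = t_start + territory // 2
        jitter = int(rng.integers(-territory // 8, territory // 8 + 1))
        body_start = center - cfg.gene_body_bp // 2 + jitter
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(_make_gene(f"g{i:0{width}d}", chrom, body_start, cfg.gene_body_bp, strand))
    genome = GenomeAnnotation(chroms, genes)

    # gene classes
    labels = []
    for cls in GENE_CLASSES:
        labels += [cls] * cfg.class_counts.get(cls, 0)
    labels += ["null"] * (cfg.n_genes - len(labels))
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)

    # site pools and assignment to genes
    pools = {"relA_only": cfg.n_sites_relA_only, "rel_only": cfg.n_sites_rel_only,
             "shared": cfg.n_sites_shared}
    needs = {"relA_selective": ("relA_only", "shared"),
             "rel_repressed": ("relA_only", "shared"),
             "rel_dependent": ("rel_only", "shared"),
             "redundant_direct": ("shared", None)}
    site_rows = []
    linked: dict[str, list[str]] = {g.gene_id: [] for g in genes}

    def draw_site(gene: GeneRecord, site_class: str) -> None:
        loc = rng.choice(["promoter", "intron", "intergenic"], p=cfg.site_location_mix)
        sign = 1 if gene.strand == "+" else -1
        if loc == "promoter":
            center = gene.tss_bp - sign * int(rng.integers(150, 851))
        elif loc == "intron":
            b = min(gene.tss_bp, gene.tes_bp)
            introns = [(b + cfg.gene_body_bp // 5 + 50, b + 2 * cfg.gene_body_bp // 5 - 50),
                       (b + 7 * cfg.gene_body_bp // 10 + 50, b + 17 * cfg.gene_body_bp // 20 - 50)]
            lo, hi = introns[int(rng.integers(0, 2))]
            center = int(rng.integers(lo, hi))
        else:
            reach = min(3500, territory // 2 - 500)
            center = gene.tss_bp - sign * int(rng.integers(1500, reach + 1))
        center = int(np.clip(center, SITE_SPAN_BP, cfg.chrom_length_bp - SITE_SPAN_BP))
        sid = f"s{len(site_rows):04d}"
        site_rows.append({"site_id": sid, "chrom": gene.chrom, "center": center,
                          "site_class": site_class, "location": loc,
                          "linked_gene": gene.gene_id})
        linked[gene.gene_id].append(sid)

    order = np.arange(cfg.n_genes)
    for gi in order:
        cls = labels[gi]
        if cls in needs:
            primary, fallback = needs[cls]
            if pools.get(primary, 0) > 0:
                pools[primary] -= 1
                draw_site(genes[gi], primary)
            elif fallback and pools.get(fallback, 0) > 0:
                pools[fallback] -= 1
                draw_site(genes[gi], fallback)
            else:
                raise CapacityError(
                    f"not enough {primary}/{fallback} sites for planted class {cls}")
    # leftover sites go to null genes (bound but non-responsive)
    null_idx = [i for i in order if labels[i] == "null"]
    rng.shuffle(null_idx)
    spare = [(sc, n) for sc, n in pools.items() if n > 0]
    pos = 0
    for sc, n in spare:
        for _ in range(n):
            if pos >= len(null_idx):
                raise CapacityError("not enough null genes to host leftover sites")
            draw_site(genes[null_idx[pos]], sc)
            pos += 1

    gene_rows = [{"gene_id": g.gene_id, "gene_class": labels[i],
                  "pattern": _CLASS_PATTERN[labels[i]],
                  "linked_sites": linked[g.gene_id]}
                 for i, g in enumerate(genes)]
    site_table = pd.DataFrame(site_rows) if site_rows else empty_sites
    truth = SimTruth(site_table=site_table, gene_table=pd.DataFrame(gene_rows))
    # indirect genes must stay unbound
    bad = truth.gene_table[(truth.gene_table.gene_class == "indirect")
                           & (truth.gene_table.linked_sites.map(len) > 0)]
    assert bad.empty
    return genome, truth


# ---------------------------------------------------------------------------
# tag libraries

def _site_activity(factor: str, site_class: str, time_h: int) -> float:
    if factor == "input":
        return 0.0
    if factor == "atac":
        return max(SITE_ACTIVITY["RelA"][site_class].get(time_h, 0.0),
                   SITE_ACTIVITY["Rel"][site_class].get(time_h, 0.0))
    return SITE_ACTIVITY[factor][site_class].get(time_h, 0.0)


def simulate_tags(truth: SimTruth, genome: GenomeAnnotation, factor: str,
                  time_h: int, replicate: int, cfg: SimConfig) -> TagLibrary:
    """One tag library: uniform Poisson background plus site enrichment.

    Site tags follow canonical ChIP geometry: + strand tags fall upstream of
    the site center, - strand tags downstream, 50/50.  The expected site tag
    mass is taken out of the background budget so the total tag count stays
    at ``chip_depth_tags`` in expectation.
    """
    if factor not in _FACTOR_CODE:
        raise ValueError(f"unknown factor {factor!r}")
    if time_h not in TIMES:
        raise ValueError(f"time_h must be one of {TIMES}")
    rng = np.random.default_rng([cfg.seed, 13, _FACTOR_CODE[factor], time_h, replicate])
    chroms = cfg.chrom_lengths
    genome_len = cfg.genome_length
    depth = cfg.chip_depth_tags
    rate = depth / genome_len if genome_len else 0.0

    sites = truth.site_table
    extras = np.array([
        _site_activity(factor, row.site_class, time_h) * cfg.enrichment_fold
        * rate * SITE_SPAN_BP
        for row in sites.itertuples()
    ]) if len(sites) else np.empty(0)
    bg_expected = max(depth - extras.sum(), 0.0)

    pos: dict[str, dict[str, list]] = {c: {"+": [], "-": []} for c in chroms}
    n_bg = rng.poisson(bg_expected)
    if n_bg:
        lengths = np.array([chroms[c] for c in chroms], dtype=float)
        split = rng.multinomial(n_bg, lengths / lengths.sum())
        for c, n in zip(chroms, split):
            if n == 0:
                continue
            p = rng.integers(0, chroms[c], size=n)
            s = rng.random(n) < 0.5
            pos[c]["+"].append(p[s])
            pos[c]["-"].append(p[~s])
    half = SITE_SPAN_BP // 2
    for i, row in enumerate(sites.itertuples()):
        if not len(extras) or extras[i] <= 0:
            continue
        n = rng.poisson(extras[i])
        if n == 0:
            continue
        n_plus = rng.binomial(n, 0.5)
        L = chroms[row.chrom]
        p_plus = np.clip(rng.integers(row.center - half, row.center, size=n_plus), 0, L - 1)
        p_minus = np.clip(rng.integers(row.center, row.center + half, size=n - n_plus), 0, L - 1)
        pos[row.chrom]["+"].append(p_plus)
        pos[row.chrom]["-"].append(p_minus)

    positions = {
        c: {s: np.sort(np.concatenate(v)) if v else np.empty(0, dtype=np.int64)
            for s, v in strands.items()}
        for c, strands in pos.items()
    }
    assay = {"input": "input", "atac": "atac"}.get(factor, "chip")
    return TagLibrary(
        sample_id=f"{factor}_{time_h}h_r{replicate}",
        assay=assay, factor=None if assay != "chip" else factor,
        time_h=time_h, replicate=replicate,
        chrom_lengths=dict(chroms), positions=positions,
    )


# ---------------------------------------------------------------------------
# RNA counts

def planted_log2fc(gene_class: str, genotype: str, treatment: str, time_h: int,
                   amplitude: float, derepression: float = 2.0) -> float:
    """Planted log2 fold change vs 0 h for one condition cell."""
    if time_h == 0 or treatment == "none" or gene_class == "null":
        return 0.0
    if treatment == "antiIgM_BAY":
        return 0.0  # IKK inhibition abolishes all induction
    a = amplitude
    base = {
        "relA_selective": {1: a, 4: 0.3 * a},
        "redundant_direct": {1: a, 4: 0.3 * a},
        "rel_repressed": {1: a, 4: 0.3 * a},
        "rel_dependent": {4: 0.3 * a, 18: a},
        "indirect": {4: a, 18: 0.5 * a},
        "down_regulated": {1: -a, 4: -a, 18: -0.3 * a},
    }[gene_class].get(time_h, 0.0)
    if genotype == "RelA_cKO" and gene_class == "relA_selective":
        return 0.0
    if genotype == "Rel_KO":
        if gene_class == "rel_dependent":
            return 0.0
        if gene_class == "rel_repressed" and time_h == 1:
            return base + derepression  # de-repression of early genes without Rel
    return base


def standard_design(cfg: SimConfig) -> list[SampleMeta]:
    """Factorial design: WT +/- BAY plus each knockout, all times, replicated."""
    metas = []
    conditions = [("WT", "antiIgM"), ("WT", "antiIgM_BAY"),
                  ("RelA_cKO", "antiIgM"), ("Rel_KO", "antiIgM")]
    for genotype, treatment in conditions:
        for t in TIMES:
            for r in range(1, cfg.replicates + 1):
                sid = f"{genotype}_{treatment}_{t}h_r{r}"
                metas.append(SampleMeta(sid, genotype, treatment, t, r, "rna"))
    return metas


def simulate_counts(truth: SimTruth, design: list[SampleMeta], cfg: SimConfig) -> CountMatrix:
    """NB counts: mean = baseline x 2^(planted log2fc) x library factor."""
    conds = {(s.genotype, s.treatment) for s in design}
    for genotype, treatment in conds:
        if not any(s.genotype == genotype and s.treatment == treatment and s.time_h == 0
                   for s in design):
            raise ValueError(f"missing 0 h baseline samples for {genotype}:{treatment}")
    rng = np.random.default_rng([cfg.seed, 17])
    genes = truth.gene_table.gene_id.tolist()
    classes = truth.gene_table.gene_class.tolist()
    n = len(genes)
    if n == 0:
        return CountMatrix(pd.DataFrame(index=pd.Index([], name="gene"),
                                        columns=[s.sample_id for s in design], dtype=int),
                           list(design))
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    base = base / base.sum() * cfg.rna_depth
    lib_factor = rng.uniform(0.7, 1.3, size=len(design))
    r = 1.0 / cfg.dispersion
    cols = {}
    for j, s in enumerate(design):
        lfc = np.array([planted_log2fc(c, s.genotype, s.treatment, s.time_h,
                                       cfg.effect_log2fc, cfg.derepression_log2fc)
                        for c in classes])
        mu = np.maximum(base * 2.0 ** lfc * lib_factor[j], 1e-8)
        cols[s.sample_id] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return CountMatrix(counts, list(design))


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Full dataset: genome/truth, ChIP+input(+ATAC) tag panel, RNA counts."""
    genome, truth = simulate_genome(cfg)
    tags: list[TagLibrary] = []
    for factor, t in cfg.chip_panel:
        for r in range(1, cfg.replicates + 1):
            tags.append(simulate_tags(truth, genome, factor, t, r, cfg))
    tags.append(simulate_tags(truth, genome, "input", 0, 1, cfg))
    for t in cfg.atac_times:
        for r in range(1, cfg.replicates + 1):
            tags.append(simulate_tags(truth, genome, "atac", t, r, cfg))
    counts = simulate_counts(truth, standard_design(cfg), cfg)
    return SimulatedDataset(config=cfg, genome=genome, truth=truth,
                            tags=tags, counts=counts)
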