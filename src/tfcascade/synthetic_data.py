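"""Deterministic generator of a miniature regulatory landscape.

The generator emulates the structure of a ligand-response study in a
single cell line: a root transcription factor (default name ``VDR``) is
activated by a treatment; genes respond early (2.5 h / 4 h) or late
(24 h); primary targets carry regulatory evidence near their TSS (root-TF
ChIP peaks, peak-overlapping regulatory elements, or root motif instances
embedded in open chromatin), while secondary targets carry none and are
instead driven by early-responding TFs whose motif instances open or
close with treatment.

Every artifact (FASTA genome, GTF annotation, BED peak and open-chromatin
tracks, REM and DEG tables, JASPAR motif file) is byte-deterministic for
a fixed seed, and ground truth (class labels, evidence channels, driver
TFs, planted network edges) is recorded for benchmarking every pipeline
stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_core import (
    Gene,
    GenomicInterval,
    REM,
    write_bed,
    write_gtf,
    write_rem_table,
    write_deg_table,
)
from .affinity_model import PWM

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedBundle",
    "generate_genome_and_genes",
    "make_motifs",
    "plant_regulatory_landscape",
    "simulate_deg_tables",
    "simulate_bundle",
    "simulate_driver_dataset",
    "CHANNEL_COMBOS",
]

# minimum bp of regulatory territory per gene: the +/-25 kb window plus a
# flank for window-external REM evidence
_TERRITORY_MIN = 60_000

CHANNEL_COMBOS: tuple[tuple[str, ...], ...] = (
    ("window_peak",),
    ("rem_overlap",),
    ("motif_open_chromatin",),
    ("window_peak", "rem_overlap"),
    ("window_peak", "motif_open_chromatin"),
    ("rem_overlap", "motif_open_chromatin"),
    ("window_peak", "rem_overlap", "motif_open_chromatin"),
)
# combos free of the open-chromatin-motif channel (used for TF genes so
# their loci stay clear of root-motif open regions)
_NON_MOTIF_COMBOS = (0, 1, 3)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic regulatory landscape.

    The defaults are the conditions every recovery benchmark runs under:
    300 genes on 2 x 9 Mb chromosomes (>= 60 kb of territory per gene so
    neighbouring TSS windows cannot share planted evidence), 6 TFs (the
    root plus early and late responders), noise-free peaks and labels.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 9_000_000
    n_genes: int = 300
    n_tfs: int = 6
    fraction_responsive: float = 0.5
    fraction_primary: float = 0.6
    fraction_early: float = 0.25
    motif_length: int = 12
    peak_noise_rate: float = 0.0
    label_noise_rate: float = 0.0
    gc_content: float = 0.41
    half_width: int = 25_000
    decay_constant: float = 5_000.0
    early_timepoints: tuple[str, ...] = ("2.5h", "4h")
    late_timepoints: tuple[str, ...] = ("24h",)
    channel_weights: tuple[float, ...] = (1.0,) * 7
    root_tf: str = "VDR"
    n_gap_blocks: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_responsive", "fraction_primary", "fraction_early",
            "peak_noise_rate", "label_noise_rate", "gc_content",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_tfs < 2:
            raise ValueError("need at least the root TF and one responder")
        if self.motif_length < 6:
            raise ValueError("motif_length must be >= 6")
        if len(self.channel_weights) != 7 or sum(self.channel_weights) <= 0:
            raise ValueError("channel_weights must be 7 non-degenerate weights")
        if self.n_chromosomes * self.chrom_length < self.n_genes * _TERRITORY_MIN:
            raise ValueError(
                f"genes do not fit: need {self.n_genes * _TERRITORY_MIN} bp "
                f"({_TERRITORY_MIN} bp of territory per gene), have "
                f"{self.n_chromosomes * self.chrom_length}"
            )

    @property
    def n_early_tfs(self) -> int:
        return max(1, (self.n_tfs - 1) // 2)

    @property
    def n_late_tfs(self) -> int:
        return self.n_tfs - 1 - self.n_early_tfs

    @property
    def tf_names(self) -> list[str]:
        early = [f"TF_E{i + 1}" for i in range(self.n_early_tfs)]
        late = [f"TF_L{i + 1}" for i in range(self.n_late_tfs)]
        return [self.root_tf, *early, *late]

    @property
    def timepoints(self) -> tuple[str, ...]:
        return tuple(self.early_timepoints) + tuple(self.late_timepoints)


@dataclass
class GroundTruth:
    """Planted truth of a simulated bundle."""

    root_tf: str
    classes: dict[str, str]                 # gene -> early-primary | late-primary | late-secondary | unresponsive
    direction: dict[str, int]               # responsive gene -> +1 / -1 (planted)
    channels: dict[str, list[str]]          # primary gene -> evidence channels
    driver: dict[str, str]                  # secondary gene -> early driver TF
    tf_genes: dict[str, str]                # non-root TF -> gene_id
    tf_timing: dict[str, str]               # non-root TF -> early | late
    planted_edges: list[list[str]]          # [early TF, target TF]
    consensus: dict[str, str]               # TF -> consensus sequence

    def genes_of_class(self, cls: str) -> list[str]:
        return sorted(g for g, c in self.classes.items() if c == cls)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


@dataclass
class SimulatedBundle:
    """Paths and ground truth of a written simulation."""

    config: SimulationConfig
    ground_truth: GroundTruth
    genes: list[Gene]
    paths: dict[str, Path]


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_genome_and_genes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], list[Gene]]:
    """I.i.d. background genome at the configured GC plus placed genes.

    Genes are laid out on non-overlapping territories (round-robin over
    chromosomes), with both strands represented and the TSS near the
    territory centre so every +/-25 kb window plus REM flank stays inside
    its own territory.
    """
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome: dict[str, np.ndarray] = {}
    for c in range(config.n_chromosomes):
        genome[f"chr{c + 1}"] = rng.choice(
            _BASE_BYTES, size=config.chrom_length, p=probs
        )
    if config.n_gap_blocks:
        for _ in range(config.n_gap_blocks):
            chrom = f"chr{rng.integers(config.n_chromosomes) + 1}"
            pos = int(rng.integers(0, config.chrom_length - 200))
            genome[chrom][pos : pos + 200] = ord("N")

    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if c < config.n_genes % config.n_chromosomes else 0)
        for c in range(config.n_chromosomes)
    ]
    genes: list[Gene] = []
    gene_idx = 0
    for c, count in enumerate(per_chrom):
        if count == 0:
            continue
        territory = config.chrom_length // count
        for slot in range(count):
            tss = slot * territory + territory // 2 + int(rng.integers(-2000, 2001))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(2_000, 10_001))
            if strand == "+":
                start, end = tss, tss + length
            else:
                start, end = tss + 1 - length, tss + 1
            gene_idx += 1
            genes.append(
                Gene(
                    gene_id=f"G{gene_idx:04d}",
                    chrom=f"chr{c + 1}",
                    strand=strand,
                    start=start,
                    end=end,
                    symbol=f"SYN{gene_idx:04d}",
                )
            )
    return genome, genes


def write_fasta(genome: Mapping[str, np.ndarray], path: str | Path, width: int = 80) -> None:
    with open(path, "wb") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n".encode())
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width].tobytes())
                fh.write(b"\n")


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

def make_motifs(
    config: SimulationConfig,
    rng: np.random.Generator,
    consensus_prob: float = 0.85,
) -> list[PWM]:
    """One synthetic PWM per TF with well-separated consensus sequences.

    Consensus sequences are rejection-sampled to pairwise Hamming
    distance >= max(4, m // 3) so motifs of different TFs cannot
    cross-react in the affinity model.
    """
    m = config.motif_length
    min_dist = max(4, m // 3)
    consensi: list[str] = []
    while len(consensi) < config.n_tfs:
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=m))
        if all(
            sum(a != b for a, b in zip(cand, prev)) >= min_dist for prev in consensi
        ):
            consensi.append(cand)
    off = (1.0 - consensus_prob) / 3.0
    motifs = []
    for tf, consensus in zip(config.tf_names, consensi):
        matrix = np.full((4, m), off)
        for i, base in enumerate(consensus):
            matrix["ACGT".index(base), i] = consensus_prob
        motifs.append(PWM(tf_name=tf, matrix=matrix, source="synthetic", motif_id=tf))
    return motifs


def write_jaspar(motifs: Sequence[PWM], path: str | Path, scale: float = 100.0) -> None:
    """Write PWMs as JASPAR count matrices (probabilities x ``scale``)."""
    with open(path, "w") as fh:
        for pwm in motifs:
            fh.write(f">{pwm.motif_id} {pwm.tf_name}\n")
            for base, row in zip("ACGT", pwm.matrix * scale):
                values = " ".join(f"{v:.2f}" for v in row)
                fh.write(f"{base} [ {values} ]\n")


# ---------------------------------------------------------------------------
# Regulatory landscape
# ---------------------------------------------------------------------------

@dataclass
class _Landscape:
    peaks: list[GenomicInterval] = field(default_factory=list)
    open_control: list[GenomicInterval] = field(default_factory=list)
    open_treated: list[GenomicInterval] = field(default_factory=list)
    rems: list[REM] = field(default_factory=list)


def _embed(genome: Mapping[str, np.ndarray], chrom: str, start: int, motif: str) -> None:
    genome[chrom][start : start + len(motif)] = np.frombuffer(
        motif.encode(), dtype=np.uint8
    )


def _signed_offset(
    rng: np.random.Generator, low: int, high: int, tss: int, chrom_len: int
) -> int:
    """Random offset in +/-[low, high] keeping [tss+off-500, tss+off+500] in bounds."""
    sides = []
    if tss - high - 500 >= 0:
        sides.append(-1)
    if tss + high + 500 < chrom_len:
        sides.append(1)
    side = sides[int(rng.integers(len(sides)))]
    return side * int(rng.integers(low, high + 1))


def plant_regulatory_landscape(
    config: SimulationConfig,
    genome: dict[str, np.ndarray],
    genes: Sequence[Gene],
    motifs: Sequence[PWM],
    rng: np.random.Generator,
) -> tuple[_Landscape, GroundTruth]:
    """Assign gene classes and plant the per-channel regulatory evidence.

    Primary genes receive, according to a 7-cell combination draw, a root
    ChIP peak in the TSS window, a gene-linked REM (placed 26-34 kb from
    the TSS, outside the window) overlapping a root peak, and/or a root
    consensus motif embedded in an open-chromatin region in the window.
    Secondary genes receive one early-driver motif instance in condition-
    specific open chromatin (treated-only for up-regulation, control-only
    for down).  Early-TF consensus instances are additionally planted
    near target TF genes to define the ground-truth network edges.
    Decoy peaks are added at ``peak_noise_rate`` per gene.
    """
    m = config.motif_length
    consensus = {pwm.tf_name: pwm.consensus for pwm in motifs}
    if config.motif_length > 300:
        raise ValueError("motif longer than the open-chromatin region width")

    n_resp = round(config.n_genes * config.fraction_responsive)
    n_primary = round(n_resp * config.fraction_primary)
    n_early = max(config.n_early_tfs, round(n_primary * config.fraction_early))
    n_late_primary = n_primary - n_early
    n_secondary = n_resp - n_primary
    if n_late_primary < config.n_late_tfs:
        raise ValueError("too few late-primary genes to host the late TF genes")

    order = rng.permutation(len(genes))
    early_primary = [genes[i] for i in order[:n_early]]
    late_primary = [genes[i] for i in order[n_early : n_early + n_late_primary]]
    secondary = [genes[i] for i in order[n_primary : n_primary + n_secondary]]
    unresponsive = [genes[i] for i in order[n_resp:]]

    tf_names = config.tf_names
    early_tfs = tf_names[1 : 1 + config.n_early_tfs]
    late_tfs = tf_names[1 + config.n_early_tfs :]
    tf_genes = {tf: g.gene_id for tf, g in zip(early_tfs, early_primary)}
    tf_genes.update({tf: g.gene_id for tf, g in zip(late_tfs, late_primary)})
    tf_gene_ids = set(tf_genes.values())
    tf_timing = {tf: "early" for tf in early_tfs}
    tf_timing.update({tf: "late" for tf in late_tfs})

    classes = {g.gene_id: "unresponsive" for g in unresponsive}
    classes.update({g.gene_id: "early-primary" for g in early_primary})
    classes.update({g.gene_id: "late-primary" for g in late_primary})
    classes.update({g.gene_id: "late-secondary" for g in secondary})
    direction = {
        g.gene_id: (1 if rng.random() < 0.5 else -1)
        for g in (*early_primary, *late_primary, *secondary)
    }

    land = _Landscape()
    channels: dict[str, list[str]] = {}
    weights = np.asarray(config.channel_weights, dtype=float)
    weights = weights / weights.sum()
    nm_weights = weights[list(_NON_MOTIF_COMBOS)]
    nm_weights = nm_weights / nm_weights.sum()
    root_consensus = consensus[config.root_tf]
    peak_counter = 0

    def add_peak(chrom: str, center: int, width: int) -> None:
        nonlocal peak_counter
        peak_counter += 1
        land.peaks.append(
            GenomicInterval(
                chrom, center - width // 2, center - width // 2 + width,
                name=f"pk{peak_counter:05d}",
            )
        )

    for gene in (*early_primary, *late_primary):
        chrom_len = len(genome[gene.chrom])
        if gene.gene_id in tf_gene_ids:
            combo = CHANNEL_COMBOS[
                _NON_MOTIF_COMBOS[int(rng.choice(len(_NON_MOTIF_COMBOS), p=nm_weights))]
            ]
        else:
            combo = CHANNEL_COMBOS[int(rng.choice(7, p=weights))]
        channels[gene.gene_id] = list(combo)
        if "window_peak" in combo:
            off = _signed_offset(rng, 1_000, 20_000, gene.tss, chrom_len)
            add_peak(gene.chrom, gene.tss + off, int(rng.integers(200, 601)))
        if "rem_overlap" in combo:
            off = _signed_offset(rng, 26_000, 34_000, gene.tss, chrom_len)
            center = gene.tss + off
            land.rems.append(
                REM(
                    region=GenomicInterval(gene.chrom, center - 250, center + 250),
                    rem_id=f"REM{len(land.rems) + 1:05d}",
                    linked_gene=gene.gene_id,
                )
            )
            add_peak(gene.chrom, center, 300)
        if "motif_open_chromatin" in combo:
            off = _signed_offset(rng, 1_000, 20_000, gene.tss, chrom_len)
            center = gene.tss + off
            region = GenomicInterval(
                gene.chrom, center - 150, center + 150, name=f"oc_{gene.gene_id}"
            )
            _embed(genome, gene.chrom, center - m // 2, root_consensus)
            land.open_control.append(region)
            land.open_treated.append(region)

    driver_map: dict[str, str] = {}
    for gene in secondary:
        chrom_len = len(genome[gene.chrom])
        driver = early_tfs[int(rng.integers(len(early_tfs)))]
        off = _signed_offset(rng, 500, 10_000, gene.tss, chrom_len)
        center = gene.tss + off
        region = GenomicInterval(
            gene.chrom, center - 150, center + 150, name=f"drv_{gene.gene_id}"
        )
        _embed(genome, gene.chrom, center - m // 2, consensus[driver])
        if direction[gene.gene_id] > 0:
            land.open_treated.append(region)      # site opens with treatment
        else:
            land.open_control.append(region)      # site closes with treatment
        driver_map[gene.gene_id] = driver

    gene_by_id = {g.gene_id: g for g in genes}
    planted_edges: list[list[str]] = []
    for k, e_tf in enumerate(early_tfs):
        for t_tf in tf_names[1:]:
            if t_tf == e_tf:
                continue
            if rng.random() < 0.5:
                target_gene = gene_by_id[tf_genes[t_tf]]
                center = target_gene.tss + 650 + 900 * k
                region = GenomicInterval(
                    target_gene.chrom, center - 150, center + 150,
                    name=f"edge_{e_tf}_{t_tf}",
                )
                _embed(genome, target_gene.chrom, center - m // 2, consensus[e_tf])
                land.open_control.append(region)
                land.open_treated.append(region)
                planted_edges.append([e_tf, t_tf])
    if not planted_edges:
        e_tf, t_tf = early_tfs[0], late_tfs[0] if late_tfs else early_tfs[-1]
        target_gene = gene_by_id[tf_genes[t_tf]]
        center = target_gene.tss + 650
        region = GenomicInterval(
            target_gene.chrom, center - 150, center + 150,
            name=f"edge_{e_tf}_{t_tf}",
        )
        _embed(genome, target_gene.chrom, center - m // 2, consensus[e_tf])
        land.open_control.append(region)
        land.open_treated.append(region)
        planted_edges.append([e_tf, t_tf])

    n_decoys = round(config.peak_noise_rate * config.n_genes)
    for _ in range(n_decoys):
        chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
        pos = int(rng.integers(500, len(genome[chrom]) - 500))
        add_peak(chrom, pos, int(rng.integers(200, 601)))

    truth = GroundTruth(
        root_tf=config.root_tf,
        classes=classes,
        direction=direction,
        channels=channels,
        driver=driver_map,
        tf_genes=tf_genes,
        tf_timing=tf_timing,
        planted_edges=planted_edges,
        consensus=consensus,
    )
    return land, truth


# ---------------------------------------------------------------------------
# Differential expression tables
# ---------------------------------------------------------------------------

def simulate_deg_tables(
    config: SimulationConfig,
    ground_truth: GroundTruth,
    genes: Sequence[Gene],
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Per-time-point DEG summary tables over all genes.

    Early-primary genes are significant at the early and the late time
    points (no transient responses), late-primary and secondary genes
    only at the late one; unresponsive genes are never significant.
    Secondary genes' fold-change sign is their driver's planted direction,
    flipped with probability ``label_noise_rate``.
    """
    tables: dict[str, list[dict]] = {tp: [] for tp in config.timepoints}
    for gene in genes:
        cls = ground_truth.classes[gene.gene_id]
        planted = ground_truth.direction.get(gene.gene_id, 0)
        observed = planted
        if cls == "late-secondary" and rng.random() < config.label_noise_rate:
            observed = -planted
        base = observed * float(rng.uniform(1.0, 3.0))
        for tp in config.timepoints:
            is_late = tp in config.late_timepoints
            if cls == "early-primary":
                sig = True
                lfc = (1.0 if is_late else 0.7) * base
            elif cls in ("late-primary", "late-secondary"):
                sig = is_late
                lfc = base if is_late else float(rng.normal(0.0, 0.1))
            else:
                sig = False
                lfc = float(rng.normal(0.0, 0.05))
            padj = (
                float(10.0 ** -rng.uniform(3.0, 8.0))
                if sig
                else float(rng.uniform(0.2, 1.0))
            )
            tables[tp].append(
                {"gene_id": gene.gene_id, "log2fc": round(lfc, 4), "padj": padj}
            )
    return {tp: pd.DataFrame(rows) for tp, rows in tables.items()}


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig, outdir: str | Path) -> SimulatedBundle:
    """Generate and write a complete input bundle plus ground truth.

    All randomness flows through one generator seeded from
    ``config.seed``, so the written files are byte-identical for a fixed
    configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, genes = generate_genome_and_genes(config, rng)
    motifs = make_motifs(config, rng)
    land, truth = plant_regulatory_landscape(config, genome, genes, motifs, rng)
    degs = simulate_deg_tables(config, truth, genes, rng)

    paths: dict[str, Path] = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gtf",
        "peaks": outdir / "peaks.bed",
        "open_control": outdir / "open_control.bed",
        "open_treated": outdir / "open_treated.bed",
        "rems": outdir / "rems.tsv",
        "motifs": outdir / "motifs.jaspar",
        "tf_genes": outdir / "tf_genes.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_fasta(genome, paths["genome"])
    write_gtf(genes, paths["genes"])
    write_bed(land.peaks, paths["peaks"])
    write_bed(land.open_control, paths["open_control"])
    write_bed(land.open_treated, paths["open_treated"])
    write_rem_table(land.rems, paths["rems"])
    write_jaspar(motifs, paths["motifs"])
    with open(paths["tf_genes"], "w") as fh:
        fh.write("tf_name\tgene_id\n")
        for tf in sorted(truth.tf_genes):
            fh.write(f"{tf}\t{truth.tf_genes[tf]}\n")
    truth.to_json(paths["ground_truth"])
    for tp, table in degs.items():
        path = outdir / f"deg_{tp}.tsv"
        write_deg_table(table, path)
        paths[f"deg_{tp}"] = path
    # clean any stale index so re-reads see the fresh genome
    fai = Path(str(paths["genome"]) + ".fai")
    if fai.exists():
        fai.unlink()
    return SimulatedBundle(config=config, ground_truth=truth, genes=genes, paths=paths)


def simulate_driver_dataset(
    n_genes: int = 60,
    n_tfs: int = 6,
    label_noise_rate: float = 0.1,
    effect_log2: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, str]:
    """Compact benchmark for the regression stage only.

    Generates control/treated TF-gene score matrices in which a single
    driver TF's score contrast determines each gene's up/down response
    (contrast ``+/- effect_log2`` in log2 units, non-driver columns carry
    lognormal jitter), plus a DEG table whose fold-change sign equals the
    planted response flipped with probability ``label_noise_rate``.
    Returns ``(scores_control, scores_treated, deg_table, driver_tf)``.
    """
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    driver = tfs[int(rng.integers(n_tfs))]
    gene_ids = [f"S{i + 1:04d}" for i in range(n_genes)]
    control = pd.DataFrame(
        np.exp(rng.normal(-3.0, 1.0, size=(n_genes, n_tfs))),
        index=gene_ids, columns=tfs,
    )
    jitter = 2.0 ** rng.normal(0.0, 0.25, size=(n_genes, n_tfs))
    treated = control * jitter
    signs = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    treated[driver] = control[driver] * 2.0 ** (signs * effect_log2)
    flips = rng.random(n_genes) < label_noise_rate
    observed = np.where(flips, -signs, signs)
    deg = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": observed * rng.uniform(0.5, 3.0, size=n_genes),
            "padj": 10.0 ** -rng.uniform(3.0, 8.0, size=n_genes),
        }
    )
    return control, treated, deg, driver
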