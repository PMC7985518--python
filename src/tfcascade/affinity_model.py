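"""Biophysical motif-affinity scanning and TF-gene score aggregation.

The scanning model follows TRAP: a position weight matrix is converted to
a position-specific mismatch-energy matrix, and the expected number of
bound sites in a sequence is the sum over both strands and all offsets of
the occupancy

    p_i = R0 * exp(-E_i) / (1 + R0 * exp(-E_i)),

where ``E_i`` is the summed mismatch energy of the window starting at
offset ``i``.  Default constants are the published TRAP values:
``lambda = 0.7`` and ``ln R0 = 0.584 * m - 5.66`` for a motif of width
``m``.

Region affinities are aggregated into per-gene, per-TF scores by summing
over the open-chromatin regions inside a gene's TSS window, each weighted
by exponential decay ``exp(-d / d0)`` in the distance ``d`` between the
region centre and the TSS (TEPIC-style; ``d0 = 5000`` bp by default).
"""

from __future__ import annotations

import io
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .genomic_core import Gene, GenomicInterval, extract_sequence, tss_window

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "EnergyMatrix",
    "RegionAffinity",
    "TFGeneScoreMatrix",
    "parse_motifs",
    "pwm_to_energy_matrix",
    "trap_affinity",
    "dinucleotide_shuffle",
    "make_background",
    "calibrate_threshold",
    "compute_region_affinities",
    "compute_gene_tf_scores",
    "DEFAULT_LAMBDA",
    "DEFAULT_R0_SLOPE",
    "DEFAULT_R0_INTERCEPT",
]

DEFAULT_LAMBDA = 0.7
DEFAULT_R0_SLOPE = 0.584
DEFAULT_R0_INTERCEPT = -5.66
DEFAULT_PSEUDOCOUNT = 1.0
MIN_PROBABILITY = 0.001

BASES = "ACGT"

# ASCII -> base index lookup; anything else (incl. N) maps to -1
_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PWM:
    """A motif as a 4 x m matrix of base probabilities (rows A, C, G, T)."""

    tf_name: str
    matrix: np.ndarray
    source: str = ""
    motif_id: str = ""

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape[0] != 4 or mat.shape[1] < 4:
            raise ValueError(
                f"PWM for {self.tf_name} must be 4 x m with m >= 4, got {mat.shape}"
            )
        if (mat <= 0).any():
            raise ValueError(f"PWM for {self.tf_name} has non-positive entries")
        if not np.allclose(mat.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError(f"PWM columns for {self.tf_name} do not sum to 1")
        object.__setattr__(self, "matrix", mat)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    @classmethod
    def from_counts(
        cls,
        tf_name: str,
        counts: np.ndarray,
        source: str = "",
        motif_id: str = "",
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PWM":
        """Build a PWM from a 4 x m count (or probability) matrix.

        A pseudocount regularizes zeros and probabilities are floored at
        ``MIN_PROBABILITY`` before renormalization.
        """
        counts = np.asarray(counts, dtype=float)
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=0, keepdims=True)
        probs = np.clip(probs, MIN_PROBABILITY, None)
        probs = probs / probs.sum(axis=0, keepdims=True)
        return cls(tf_name=tf_name, matrix=probs, source=source, motif_id=motif_id)


@dataclass(frozen=True)
class EnergyMatrix:
    """Position-specific mismatch energies derived from a PWM.

    Per column the consensus base has energy 0 and all energies are
    non-negative.  ``ln_r0`` is the log equilibrium constant of the TRAP
    occupancy model.
    """

    tf_name: str
    energies: np.ndarray
    lambda_param: float
    ln_r0: float
    motif_id: str = ""

    def __post_init__(self) -> None:
        en = np.asarray(self.energies, dtype=float)
        if (en < 0).any():
            raise ValueError("energies must be non-negative")
        if not np.allclose(en.min(axis=0), 0.0, atol=1e-12):
            raise ValueError("each column must contain a zero-energy consensus base")
        object.__setattr__(self, "energies", en)

    @property
    def width(self) -> int:
        return self.energies.shape[1]


@dataclass(frozen=True)
class RegionAffinity:
    """TRAP affinity (expected bound-site count) of one TF on one region."""

    region: GenomicInterval
    tf_name: str
    affinity: float

    def __post_init__(self) -> None:
        if self.affinity < 0:
            raise ValueError("affinity must be >= 0")


@dataclass
class TFGeneScoreMatrix:
    """Genes x TFs matrix of decayed affinity scores for one condition."""

    scores: pd.DataFrame
    condition: str = ""
    params: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# condition={self.condition}\n")
            for key in sorted(self.params):
                fh.write(f"# {key}={self.params[key]}\n")
            self.scores.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TFGeneScoreMatrix":
        params: dict = {}
        condition = ""
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    if key.strip() == "condition":
                        condition = value
                    else:
                        try:
                            params[key.strip()] = float(value)
                        except ValueError:
                            params[key.strip()] = value
                else:
                    lines.append(line)
        df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col="gene_id")
        return cls(scores=df, condition=condition, params=params)


# ---------------------------------------------------------------------------
# Motif parsing (JASPAR and a TRANSFAC-like dialect)
# ---------------------------------------------------------------------------

def parse_motifs(
    path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> list[PWM]:
    """Parse motif count matrices from a JASPAR-style file.

    Two dialects are auto-detected per record:

    * JASPAR: a ``>ID NAME`` header followed by four base rows, e.g.
      ``A  [ 3 5 1 ]`` (brackets optional);
    * TRANSFAC-like: a header followed by ``m`` position rows of four
      counts in A, C, G, T column order.
    """
    text = Path(path).read_text()
    motifs: list[PWM] = []
    block_header: str | None = None
    block_lines: list[str] = []

    def flush() -> None:
        if block_header is None:
            return
        parts = block_header[1:].split(None, 1)
        motif_id = parts[0]
        name = parts[1].strip() if len(parts) > 1 else motif_id
        counts = _parse_matrix_block(block_lines, f"{path}:{motif_id}")
        motifs.append(
            PWM.from_counts(
                tf_name=name,
                counts=counts,
                source=str(path),
                motif_id=motif_id,
                pseudocount=pseudocount,
            )
        )

    for line in text.splitlines():
        if line.startswith(">"):
            flush()
            block_header = line.strip()
            block_lines = []
        elif line.strip():
            block_lines.append(line)
    flush()
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


def _parse_matrix_block(lines: list[str], label: str) -> np.ndarray:
    rows: dict[str, list[float]] = {}
    position_rows: list[list[float]] = []
    for line in lines:
        stripped = line.strip().replace("[", " ").replace("]", " ")
        tokens = stripped.split()
        if not tokens:
            continue
        if tokens[0].upper() in ("A", "C", "G", "T"):
            rows[tokens[0].upper()] = [float(t) for t in tokens[1:]]
        elif tokens[0].upper() in ("P0", "PO", "DE", "XX", "//"):
            continue  # TRANSFAC bookkeeping lines
        else:
            values = [float(t) for t in tokens]
            # TRANSFAC rows may carry a leading position index and/or a
            # trailing consensus symbol already stripped by float parsing
            if len(values) == 5:
                values = values[1:]
            if len(values) != 4:
                raise ValueError(f"{label}: cannot parse matrix row {line!r}")
            position_rows.append(values)
    if len(rows) == 4:
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise ValueError(f"{label}: base rows have unequal lengths")
        return np.array([rows[b] for b in BASES], dtype=float)
    if position_rows:
        return np.array(position_rows, dtype=float).T
    raise ValueError(f"{label}: no matrix rows found")


# ---------------------------------------------------------------------------
# Energy matrix and TRAP scanning
# ---------------------------------------------------------------------------

def pwm_to_energy_matrix(
    pwm: PWM,
    lambda_param: float = DEFAULT_LAMBDA,
    r0_slope: float = DEFAULT_R0_SLOPE,
    r0_intercept: float = DEFAULT_R0_INTERCEPT,
) -> EnergyMatrix:
    """Convert a PWM into a TRAP mismatch-energy matrix.

    ``E(b, i) = ln(p_max,i / p_b,i) / lambda`` and
    ``ln R0 = r0_slope * m + r0_intercept``.
    """
    if lambda_param <= 0:
        raise ValueError("lambda_param must be > 0")
    p = pwm.matrix
    energies = np.log(p.max(axis=0, keepdims=True) / p) / lambda_param
    return EnergyMatrix(
        tf_name=pwm.tf_name,
        energies=energies,
        lambda_param=lambda_param,
        ln_r0=r0_slope * pwm.width + r0_intercept,
        motif_id=pwm.motif_id,
    )


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a DNA string as int8 base indices (A=0..T=3, other = -1)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def trap_affinity(energy_matrix: EnergyMatrix, sequence: str) -> float:
    """Expected bound-site count of a TF on ``sequence`` (both strands).

    Windows containing non-ACGT characters contribute 0.  A sequence
    shorter than the motif yields 0 with a warning rather than an error.
    """
    m = energy_matrix.width
    codes = encode_sequence(sequence)
    if codes.size < m:
        logger.warning(
            "sequence of length %d shorter than motif %s (m=%d); affinity 0",
            codes.size, energy_matrix.tf_name, m,
        )
        return 0.0
    windows = sliding_window_view(codes, m)          # (n_win, m)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return 0.0
    en = energy_matrix.energies                      # (4, m)
    en_rc = en[::-1, ::-1]                           # complement bases, reversed
    cols = np.arange(m)
    w = windows[valid]
    e_fwd = en[w, cols].sum(axis=1)
    e_rev = en_rc[w, cols].sum(axis=1)
    ln_r0 = energy_matrix.ln_r0
    occ = 1.0 / (1.0 + np.exp(e_fwd - ln_r0)) + 1.0 / (1.0 + np.exp(e_rev - ln_r0))
    return float(occ.sum())


# ---------------------------------------------------------------------------
# Background calibration
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul-Erikson algorithm: pick a random set of terminal edges that
    forms a spanning tree into the last character (guaranteeing an
    Eulerian walk exists), shuffle the remaining edges per vertex, and
    walk the graph from the first character.
    """
    s = sequence.upper()
    if len(s) < 3 or len(set(s)) == 1:
        return s
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    first, last = s[0], s[-1]
    vertices = [v for v in edges if v != last]
    while True:
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices
        }
        # every vertex must reach `last` by following chosen terminal edges
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    remaining: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        remaining[v] = pool
    out = [first]
    positions = {v: 0 for v in edges}
    cur = first
    for _ in range(len(s) - 1):
        nxt = remaining[cur][positions[cur]]
        positions[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_background(
    sequences: Sequence[str], n: int, rng: np.random.Generator
) -> list[str]:
    """``n`` dinucleotide-shuffled copies cycling over the input sequences."""
    if not sequences:
        raise ValueError("need at least one input sequence")
    return [
        dinucleotide_shuffle(sequences[i % len(sequences)], rng) for i in range(n)
    ]


def calibrate_threshold(
    energy_matrix: EnergyMatrix,
    random_sequences: Sequence[str],
    p_value: float = 0.05,
) -> float:
    """Affinity threshold from random sequences.

    Returns the empirical ``(1 - p_value)`` quantile (ceiling
    order-statistic definition) of :func:`trap_affinity` over the random
    set, so that at most a ``p_value`` fraction of random sequences score
    at or above the threshold.  Deterministic given the sequence set.
    """
    if len(random_sequences) == 0:
        raise ValueError("random sequence set is empty")
    if not 0.0 < p_value < 1.0:
        raise ValueError(f"p_value must be in (0, 1), got {p_value}")
    affinities = np.array(
        [trap_affinity(energy_matrix, seq) for seq in random_sequences]
    )
    return float(np.quantile(affinities, 1.0 - p_value, method="higher"))


# ---------------------------------------------------------------------------
# Region affinities and decayed gene scores
# ---------------------------------------------------------------------------

def compute_region_affinities(
    energy_matrices: Mapping[str, EnergyMatrix],
    regions: Sequence[GenomicInterval],
    fasta,
) -> pd.DataFrame:
    """TRAP affinity of every motif (columns) on every region (rows).

    Row order follows ``regions``; columns are the mapping keys.
    """
    data = {}
    sequences = [extract_sequence(fasta, r) for r in regions]
    for key, em in energy_matrices.items():
        data[key] = [trap_affinity(em, seq) for seq in sequences]
    return pd.DataFrame(data, index=range(len(regions)))


def compute_gene_tf_scores(
    regions: Sequence[GenomicInterval],
    region_affinities: pd.DataFrame,
    genes: Sequence[Gene],
    half_width: int = 25_000,
    decay_constant: float = 5_000.0,
    thresholds: Mapping[str, float] | None = None,
    condition: str = "",
    motif_to_tf: Mapping[str, str] | None = None,
    variant_agg: str = "max",
) -> TFGeneScoreMatrix:
    """Aggregate region affinities into decayed per-gene, per-TF scores.

    ``score(g, tf) = sum over regions r overlapping tss_window(g)`` of
    ``affinity(r, tf) * exp(-|center(r) - tss(g)| / decay_constant)``.
    With ``thresholds`` given, region affinities strictly below a TF's
    threshold contribute 0 (thresholding acts on raw affinities, before
    decay weighting).

    When several motif variants map to the same TF (via ``motif_to_tf``)
    the per-gene scores are combined by ``variant_agg`` (max, sum or
    mean).
    """
    if decay_constant <= 0:
        raise ValueError(f"decay_constant must be > 0, got {decay_constant}")
    if variant_agg not in ("max", "sum", "mean"):
        raise ValueError(f"unknown variant_agg {variant_agg!r}")
    motif_ids = list(region_affinities.columns)
    if motif_to_tf is None:
        motif_to_tf = {mid: mid for mid in motif_ids}

    by_chrom: dict[str, list[int]] = defaultdict(list)
    for idx, region in enumerate(regions):
        by_chrom[region.chrom].append(idx)
    chrom_arrays = {
        chrom: (
            np.array([regions[i].start for i in idxs]),
            np.array([regions[i].end for i in idxs]),
            np.array([regions[i].center for i in idxs]),
            np.array(idxs),
        )
        for chrom, idxs in by_chrom.items()
    }

    aff = region_affinities.to_numpy(dtype=float)       # (n_regions, n_motifs)
    if thresholds is not None:
        thr = np.array(
            [thresholds.get(motif_to_tf[mid], 0.0) for mid in motif_ids]
        )
        aff = np.where(aff >= thr[None, :], aff, 0.0)

    per_motif = np.zeros((len(genes), len(motif_ids)))
    for gi, gene in enumerate(genes):
        arrays = chrom_arrays.get(gene.chrom)
        if arrays is None:
            continue
        starts, ends, centers, idxs = arrays
        win = tss_window(gene, half_width)
        mask = (starts < win.end) & (ends > win.start)
        if not mask.any():
            continue
        weights = np.exp(-np.abs(centers[mask] - gene.tss) / decay_constant)
        per_motif[gi] = weights @ aff[idxs[mask]]

    tf_names = sorted(set(motif_to_tf[mid] for mid in motif_ids))
    scores = pd.DataFrame(
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=tf_names,
        data=0.0,
    )
    agg = {"max": np.maximum.reduce, "sum": np.add.reduce,
           "mean": lambda arrs: np.add.reduce(arrs) / len(arrs)}[variant_agg]
    for tf in tf_names:
        cols = [j for j, mid in enumerate(motif_ids) if motif_to_tf[mid] == tf]
        scores[tf] = agg([per_motif[:, j] for j in cols])
    return TFGeneScoreMatrix(
        scores=scores,
        condition=condition,
        params={
            "half_width": half_width,
            "decay_constant": decay_constant,
            "thresholded": thresholds is not None,
            "variant_agg": variant_agg,
        },
    )
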