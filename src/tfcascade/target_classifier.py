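"""Hierarchical primary/secondary target classification.

Three evidence channels flag a differentially expressed gene (DEG) as a
primary target of the root transcription factor:

* ``window_peak`` - a root-TF ChIP-seq peak overlaps the +/- 25 kb TSS
  window of the gene;
* ``rem_overlap`` - a regulatory element (REM) linked to the gene
  overlaps a root-TF peak;
* ``motif_open_chromatin`` - an above-threshold root-TF motif affinity in
  open chromatin inside the window (a positive decayed TF-gene score).

DEGs are split into an early response (significant at any early time
point) and a late response (significant only at the late time point).  A
DEG is primary when at least ``k_methods`` channels support it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .affinity_model import TFGeneScoreMatrix
from .genomic_core import Gene, GenomicInterval, REM, overlaps, tss_window

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "flag_window_targets",
    "flag_rem_targets",
    "flag_motif_targets",
    "combine_flags",
    "classify_degs",
    "percentage",
    "UpsetSummary",
    "summarize_upset",
    "compare_deg_sets",
]

METHODS = ("window_peak", "rem_overlap", "motif_open_chromatin")


def flag_window_targets(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[Gene],
    half_width: int = 25_000,
) -> pd.Series:
    """Per-gene flag: >= 1 peak overlaps the gene's TSS window."""
    windows = [tss_window(g, half_width) for g in genes]
    hits = {i for i, _ in overlaps(windows, list(peaks))}
    return pd.Series(
        [i in hits for i in range(len(genes))],
        index=[g.gene_id for g in genes],
        dtype=bool,
    )


def flag_rem_targets(
    peaks: Sequence[GenomicInterval],
    rems: Sequence[REM],
    known_genes: Iterable[str] | None = None,
) -> pd.Series:
    """Per-gene flag: >= 1 REM linked to the gene overlaps >= 1 peak.

    With ``known_genes`` given, REMs whose linked gene cannot be resolved
    are logged and excluded; the returned series covers only genes that
    have at least one (resolved) linked REM.
    """
    known = set(known_genes) if known_genes is not None else None
    usable: list[REM] = []
    for rem in rems:
        if known is not None and rem.linked_gene not in known:
            logger.warning(
                "REM %s links to unresolved gene %s; excluded",
                rem.rem_id, rem.linked_gene,
            )
            continue
        usable.append(rem)
    hits = {i for i, _ in overlaps([r.region for r in usable], list(peaks))}
    flags: dict[str, bool] = {}
    for i, rem in enumerate(usable):
        flags[rem.linked_gene] = flags.get(rem.linked_gene, False) or i in hits
    return pd.Series(flags, dtype=bool)


def flag_motif_targets(
    score_matrix: TFGeneScoreMatrix | pd.DataFrame, tf_name: str
) -> pd.Series:
    """Per-gene flag: positive (thresholded) decayed score for ``tf_name``."""
    scores = (
        score_matrix.scores
        if isinstance(score_matrix, TFGeneScoreMatrix)
        else score_matrix
    )
    if tf_name not in scores.columns:
        raise KeyError(f"TF {tf_name!r} not in score matrix")
    return scores[tf_name] > 0


def combine_flags(
    gene_ids: Iterable[str],
    window_peak: pd.Series | None = None,
    rem_overlap: pd.Series | None = None,
    motif_open_chromatin: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene boolean evidence table over ``gene_ids``.

    Channels absent from an input series default to False.
    """
    index = pd.Index(list(gene_ids), name="gene_id")
    frame = pd.DataFrame(False, index=index, columns=list(METHODS))
    for column, series in zip(
        METHODS, (window_peak, rem_overlap, motif_open_chromatin)
    ):
        if series is not None:
            common = index.intersection(series.index)
            frame.loc[common, column] = series.loc[common].astype(bool)
    return frame


def classify_degs(
    deg_tables: Mapping[str, pd.DataFrame],
    flags: pd.DataFrame,
    early_timepoints: Sequence[str],
    late_timepoints: Sequence[str],
    k_methods: int = 1,
    padj_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Classify DEGs by response timing and primary/secondary status.

    Returns a frame indexed by gene_id with columns ``timing`` (early /
    late), ``n_methods``, ``is_primary`` and ``methods`` (comma-joined
    supporting channels).  A gene is early if significant at any early
    time point, late if significant only at a late one; genes never
    significant are excluded.
    """
    if k_methods not in (1, 2, 3):
        raise ValueError(f"k_methods must be 1, 2 or 3, got {k_methods}")
    sig: dict[str, set[str]] = {}
    for tp, table in deg_tables.items():
        sig[tp] = set(table.loc[table["padj"] < padj_cutoff, "gene_id"])
    early_sig = set().union(*(sig.get(tp, set()) for tp in early_timepoints))
    late_sig = set().union(*(sig.get(tp, set()) for tp in late_timepoints))
    records = []
    for gene in sorted(early_sig | late_sig):
        timing = "early" if gene in early_sig else "late"
        if gene in flags.index:
            gene_flags = flags.loc[gene, list(METHODS)].astype(bool)
        else:
            logger.debug("DEG %s absent from evidence flags; treated as none", gene)
            gene_flags = pd.Series(False, index=list(METHODS))
        n_methods = int(gene_flags.sum())
        records.append(
            {
                "gene_id": gene,
                "timing": timing,
                "n_methods": n_methods,
                "is_primary": n_methods >= k_methods,
                "methods": ",".join(m for m in METHODS if gene_flags[m]),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["gene_id", "timing", "n_methods", "is_primary", "methods"]
    ).set_index("gene_id")


def percentage(count: int, total: int) -> float:
    """``100 * count / total`` reported to one decimal (round-half-even).

    Raises ``ValueError`` for a zero or negative total: percentages are
    always derived from actual counts, never stored independently.
    """
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if count < 0 or count > total:
        raise ValueError(f"count {count} outside [0, {total}]")
    return round(100.0 * count / total, 1)


_ALL_COMBOS = tuple(
    combo
    for r in (1, 2, 3)
    for combo in itertools.combinations(METHODS, r)
)


@dataclass
class UpsetSummary:
    """Exclusive evidence-combination counts, split by response timing.

    ``counts[timing][combo]`` is the number of predicted-primary genes
    whose supporting channels are exactly ``combo`` (a sorted tuple of
    method names).  Percentages are always recomputed from the counts.
    """

    counts: dict[str, dict[tuple[str, ...], int]]
    n_degs: dict[str, int]
    n_predicted: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.n_predicted = {
            timing: sum(combos.values()) for timing, combos in self.counts.items()
        }

    def count_at_least(self, k: int, timing: str) -> int:
        return sum(
            n for combo, n in self.counts.get(timing, {}).items() if len(combo) >= k
        )

    def percent_at_least(self, k: int, timing: str) -> float:
        """Percent of predicted-primary genes supported by >= k channels."""
        return percentage(self.count_at_least(k, timing), self.n_predicted[timing])

    def percent_predicted(self, timing: str) -> float:
        """Percent of DEGs in a timing class predicted primary."""
        return percentage(self.n_predicted[timing], self.n_degs[timing])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for timing in sorted(self.counts):
            for combo in _ALL_COMBOS:
                n = self.counts[timing].get(combo, 0)
                rows.append(
                    {
                        "timing": timing,
                        "combination": "+".join(combo),
                        "n_methods": len(combo),
                        "count": n,
                        "percent": percentage(n, self.n_predicted[timing])
                        if self.n_predicted[timing]
                        else 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "counts": {
                timing: {"+".join(combo): n for combo, n in combos.items()}
                for timing, combos in self.counts.items()
            },
            "n_degs": dict(self.n_degs),
            "n_predicted": dict(self.n_predicted),
        }


def summarize_upset(
    classifications: pd.DataFrame, flags: pd.DataFrame
) -> UpsetSummary:
    """Exclusive method-combination counts of predicted primary genes.

    ``classifications`` is the output of :func:`classify_degs` (computed
    at any stringency); combination counts are taken over genes with at
    least one supporting channel, split by timing.
    """
    counts: dict[str, dict[tuple[str, ...], int]] = {"early": {}, "late": {}}
    n_degs = {"early": 0, "late": 0}
    for gene, row in classifications.iterrows():
        timing = row["timing"]
        n_degs[timing] += 1
        if gene not in flags.index:
            continue
        combo = tuple(m for m in METHODS if bool(flags.loc[gene, m]))
        if not combo:
            continue
        counts[timing][combo] = counts[timing].get(combo, 0) + 1
    return UpsetSummary(counts=counts, n_degs=n_degs)


def compare_deg_sets(sets: Mapping[str, set]) -> dict[str, int]:
    """Exclusive partition sizes over the union of 2 or 3 named gene sets.

    For 2 sets the keys are ``a_only``, ``b_only`` and ``a&b`` (with the
    given names); for 3 sets the full 7-cell partition is returned.
    """
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("compare_deg_sets expects 2 or 3 sets")
    universe = set().union(*sets.values())
    partition: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in members))
            outside = set().union(
                *(sets[n] for n in names if n not in members), set()
            )
            count = len(inside - outside)
            key = (
                f"{members[0]}_only" if r == 1 else "&".join(members)
            )
            partition[key] = count
    partition["union"] = len(universe)
    return partition
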