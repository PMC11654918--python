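"""TRACS enrichment scoring for guide-only-controlled CRISPR screens.

The method scores every gene three times, each against a reference that
isolates one source of abundance change:

* **Library contrast** — Cas9-negative T0 replicates vs the sequenced
  library pool L0: captures Cas9-independent changes (transduction and
  selection bottlenecks, stochastic guide loss).
* **Initial contrast** — Cas9-positive T0 vs Cas9-negative T0: captures
  editing-driven changes present before the selective pressure.
* **Final contrast** — Cas9-positive Tf vs Cas9-negative Tf: captures
  editing-driven changes after the selective pressure.

Per replicate, a gene's Gene Score (GS) is the sum of log2 fold changes
of its detected sgRNAs between the replicate and the mean of the
reference samples.  GS values are ranked ascending within each replicate
(average ranks on ties) and the Enrichment Score is the mean rank across
replicates divided by the number of detected sgRNAs s.  The Enrichment
Ratio ER = log2(Final ES / Initial ES) is negative when a gene's guides
drop out under selection in Cas9-positive cells only — the fitness
essentiality signal.  A paired t-test across replicates plus
Benjamini-Hochberg adjustment attaches significance, and genes in the
bottom quartile of Library ES are flagged as unreliable (their guides
were already lost before editing could matter).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import (
    NormalizedMatrix,
    add_pseudocount,
    detection_table,
    median_ratio_normalize,
)
from .screen_io import CountMatrix, ScreenDesign

logger = logging.getLogger("gocrispr")

RESULT_COLUMNS = [
    "gene", "library_es", "initial_es", "final_es", "er", "p", "p_adj",
    "s_library", "s_initial", "s_final",
    "low_library_es", "significant", "excluded", "constant_difference",
]


# ---------------------------------------------------------------------------
# Parameters and contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TracsParams:
    """Tunable knobs of the scoring pipeline.

    pseudocount: constant added to every raw count before normalization.
    library_quantile: quantile of Library ES below which genes are flagged.
    fdr_level: Benjamini-Hochberg control level for the `significant` flag.
    er_max / padj_max: strict thresholds used by :func:`filter_essential`.
    pair_statistic: what the paired t-test pairs across replicates —
        "scaled_rank" (rank/s, the per-replicate contribution to ES) or
        "gene_score" (raw GS).
    s_mode: divide ES by the detected guide count ("detected") or by the
        library design's guide count ("library").
    """

    pseudocount: float = 1.0
    library_quantile: float = 0.25
    fdr_level: float = 0.10
    er_max: float = 0.0
    padj_max: float = 0.05
    pair_statistic: str = "scaled_rank"
    s_mode: str = "detected"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not 0 < self.library_quantile < 1:
            raise ValueError("library_quantile must be in (0, 1)")
        if not 0 < self.fdr_level <= 1:
            raise ValueError("fdr_level must be in (0, 1]")
        if self.pair_statistic not in ("scaled_rank", "gene_score"):
            raise ValueError(f"unknown pair_statistic {self.pair_statistic!r}")
        if self.s_mode not in ("detected", "library"):
            raise ValueError(f"unknown s_mode {self.s_mode!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass(frozen=True)
class Contrast:
    """One scoring comparison: per-replicate numerator samples vs a reference.

    ``numerator_samples`` is ordered by replicate; ``denominator_samples``
    are averaged (arithmetic mean of normalized abundances) into the
    reference.
    """

    name: str  # library | initial | final
    numerator_samples: tuple[str, ...]
    denominator_samples: tuple[str, ...]

    @staticmethod
    def library(design: ScreenDesign) -> "Contrast":
        return Contrast("library", tuple(design.group("cas9_neg", "T0")),
                        (design.library_sample,))

    @staticmethod
    def initial(design: ScreenDesign) -> "Contrast":
        return Contrast("initial", tuple(design.group("cas9_pos", "T0")),
                        tuple(design.group("cas9_neg", "T0")))

    @staticmethod
    def final(design: ScreenDesign) -> "Contrast":
        return Contrast("final", tuple(design.group("cas9_pos", "Tf")),
                        tuple(design.group("cas9_neg", "Tf")))

    @property
    def all_samples(self) -> list[str]:
        return list(self.numerator_samples) + list(self.denominator_samples)


@dataclass
class GeneScoreTable:
    """Per-gene, per-replicate Gene Scores and ranks for one contrast."""

    contrast: Contrast
    gs: pd.DataFrame  # index gene, one column per replicate
    s: pd.Series  # detected sgRNA count per gene
    ranks: pd.DataFrame | None = None

    @property
    def n_replicates(self) -> int:
        return self.gs.shape[1]


@dataclass
class TracsResult:
    """Full per-gene output table plus the parameters that produced it."""

    table: pd.DataFrame  # columns RESULT_COLUMNS, indexed by gene
    params: TracsParams
    library_cutoff_value: float

    def write(self, path: str | Path) -> None:
        """Write the result TSV and a run-parameters JSON sidecar."""
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(path.suffix + ".params.json")
        payload = dataclasses.asdict(self.params)
        payload["library_cutoff"] = self.library_cutoff_value
        sidecar.write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Scoring operations
# ---------------------------------------------------------------------------

def gene_scores(
    norm: NormalizedMatrix,
    contrast: Contrast,
    detection: pd.Series,
    genes: pd.Series,
    detected_mask: pd.Series,
) -> GeneScoreTable:
    """Per-gene, per-replicate Gene Scores for one contrast.

    GS_jr = sum over gene j's detected sgRNAs of
    log2(abundance in replicate r / mean abundance across the reference
    samples).  Only detected sgRNAs contribute; genes with s = 0 are not
    scored (callers exclude them).

    ``detection`` is the per-gene s for this contrast, ``detected_mask``
    the per-sgRNA detection flags it was computed from, and ``genes`` the
    sgRNA-to-gene map aligned with the abundance index.
    """
    for s in contrast.all_samples:
        if s not in norm.abundance.columns:
            raise KeyError(f"contrast sample {s!r} not in matrix")
    if len(contrast.numerator_samples) < 2:
        raise ValueError("need >= 2 numerator replicates")

    ref = norm.abundance[list(contrast.denominator_samples)].mean(axis=1)
    lfc = np.log2(norm.abundance[list(contrast.numerator_samples)].div(ref, axis=0))
    lfc = lfc.where(detected_mask, 0.0)  # undetected guides contribute nothing
    gs = lfc.groupby(genes).sum()
    gs.columns = [f"r{i + 1}" for i in range(len(contrast.numerator_samples))]

    scored = detection[detection > 0]
    gs = gs.loc[scored.index]
    return GeneScoreTable(contrast, gs, scored)


def rank_scores(table: GeneScoreTable) -> GeneScoreTable:
    """Assign ascending ranks per replicate (1 = most negative GS).

    Ties receive the average of the ranks they span, so the result is
    invariant to input order; each replicate's ranks sum to x(x+1)/2.
    """
    ranks = table.gs.apply(lambda col: stats.rankdata(col, method="average"),
                           axis=0, result_type="broadcast")
    x = len(table.gs)
    expected = x * (x + 1) / 2
    sums = ranks.sum(axis=0)
    if not np.allclose(sums, expected):
        raise AssertionError(f"rank sums {sums.tolist()} != {expected}")
    table.ranks = ranks
    return table


def enrichment_scores(table: GeneScoreTable, s: pd.Series | None = None) -> pd.Series:
    """ES_j = (mean rank of gene j across replicates) / s_j.

    ``s`` defaults to the table's detected guide counts; pass the library
    design counts to weight by designed rather than detected guides.
    """
    if table.ranks is None:
        raise ValueError("call rank_scores first")
    divisor = table.s if s is None else s.loc[table.ranks.index]
    return table.ranks.mean(axis=1) / divisor


def scaled_ranks(table: GeneScoreTable, s: pd.Series | None = None) -> pd.DataFrame:
    """Per-replicate rank / s — the replicate-level contribution to ES."""
    if table.ranks is None:
        raise ValueError("call rank_scores first")
    divisor = table.s if s is None else s.loc[table.ranks.index]
    return table.ranks.div(divisor, axis=0)


def enrichment_ratio(initial_es: float, final_es: float):
    """ER = log2(final_es / initial_es); negative = depleted under selection.

    Accepts scalars or aligned vectors; both scores must be positive.
    """
    initial = np.asarray(initial_es, dtype=float)
    final = np.asarray(final_es, dtype=float)
    if (initial <= 0).any() or (final <= 0).any():
        raise ValueError("enrichment scores must be positive")
    out = np.log2(final / initial)
    return float(out) if out.ndim == 0 else out


def paired_t_test(
    initial_scores: np.ndarray, final_scores: np.ndarray
) -> tuple[float, float, bool]:
    """Two-sided paired t-test across replicates.

    Replicate i's initial-contrast statistic pairs with replicate i's
    final-contrast statistic; df = n - 1.  Zero-variance differences give
    p = 1 with a ``constant_difference`` flag instead of NaN so BH stays
    well-defined downstream.

    Returns (t, p, constant_difference).
    """
    a = np.asarray(initial_scores, dtype=float)
    b = np.asarray(final_scores, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired scores must be equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2 replicates")
    diff = b - a
    if np.ptp(diff) == 0.0:
        return 0.0, 1.0, True
    t, p = stats.ttest_rel(b, a)
    return float(t), float(p), False


def bh_adjust(
    p: np.ndarray, fdr_level: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (p_adj, significant) where significant_i = (p_adj_i <= fdr_level),
    equivalent to the classic step-up rejection rule.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p values must be finite and within [0, 1]")
    if not 0 < fdr_level <= 1:
        raise ValueError("fdr_level must be in (0, 1]")
    significant, p_adj, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
    return p_adj, significant


def library_cutoff(library_es: np.ndarray, q: float = 0.25) -> float:
    """q-quantile of Library ES (linear interpolation between order stats).

    Genes with Library ES below this value are flagged ``low_library_es``:
    their guides were already underrepresented before editing, so small
    absolute changes produce extreme Initial/Final scores.
    """
    values = np.asarray(library_es, dtype=float)
    if values.size == 0:
        raise ValueError("no Library ES values to take a quantile of")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(values, q, method="linear"))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_tracs(
    counts: CountMatrix,
    design: ScreenDesign | None = None,
    params: TracsParams = TracsParams(),
) -> TracsResult:
    """Run the full scoring pipeline on raw counts.

    pseudocount -> median-of-ratios normalization -> per-contrast
    detection -> Gene Scores -> ranks -> Enrichment Scores for the
    library/initial/final contrasts -> ER -> paired t-test -> BH ->
    library-ES quartile flag.  Deterministic given inputs.

    All three contrasts are scored over the same gene universe: a gene
    with no detected guide in ANY contrast is excluded globally (flagged,
    not scored) so ranks are comparable across contrasts.
    """
    design = design or counts.design
    bumped = add_pseudocount(counts, params.pseudocount)
    norm = median_ratio_normalize(bumped, pseudocount=params.pseudocount)
    genes = counts.genes

    contrasts = {
        "library": Contrast.library(design),
        "initial": Contrast.initial(design),
        "final": Contrast.final(design),
    }
    # detection per contrast, on raw counts, over the union of the
    # contrast's samples
    detected_masks = {
        name: (counts.counts[c.all_samples] >= 1).any(axis=1)
        for name, c in contrasts.items()
    }
    detection = {
        name: mask.groupby(genes).sum().astype(int)
        for name, mask in detected_masks.items()
    }
    library_s = genes.groupby(genes).size()

    all_genes = detection["library"].index
    excluded = pd.Series(False, index=all_genes)
    for name, det in detection.items():
        excluded |= det == 0
    if excluded.any():
        logger.warning("excluding %d gene(s) with no detected sgRNA in at "
                       "least one contrast", int(excluded.sum()))
    scored_genes = all_genes[~excluded]

    es: dict[str, pd.Series] = {}
    tables: dict[str, GeneScoreTable] = {}
    for name, c in contrasts.items():
        det = detection[name].loc[scored_genes]
        tbl = gene_scores(norm, c, det, genes, detected_masks[name])
        tbl = rank_scores(tbl)
        s = library_s if params.s_mode == "library" else None
        es[name] = enrichment_scores(tbl, s)
        tables[name] = tbl

    er = enrichment_ratio(es["initial"], es["final"])
    er = pd.Series(er, index=scored_genes)

    s_div = library_s if params.s_mode == "library" else None
    if params.pair_statistic == "scaled_rank":
        paired_initial = scaled_ranks(tables["initial"], s_div)
        paired_final = scaled_ranks(tables["final"], s_div)
    else:
        paired_initial = tables["initial"].gs
        paired_final = tables["final"].gs

    p = pd.Series(np.nan, index=scored_genes)
    constant = pd.Series(False, index=scored_genes)
    t_stats = np.asarray(paired_initial), np.asarray(paired_final)
    diffs = t_stats[1] - t_stats[0]
    flat = np.ptp(diffs, axis=1) == 0.0
    constant[:] = flat
    p[flat] = 1.0
    if (~flat).any():
        with warnings.catch_warnings():
            # near-identical pairs trigger a harmless precision warning
            warnings.simplefilter("ignore", RuntimeWarning)
            t_vals, p_vals = stats.ttest_rel(t_stats[1][~flat],
                                             t_stats[0][~flat], axis=1)
        p[~flat] = p_vals
    if constant.any():
        logger.warning("%d gene(s) had constant paired differences (p set to 1)",
                       int(constant.sum()))

    p_adj, significant = bh_adjust(p.to_numpy(), params.fdr_level)
    cutoff = library_cutoff(es["library"].to_numpy(), params.library_quantile)
    low_lib = es["library"] < cutoff
    logger.info("Library ES %.0f%% quantile cutoff: %.4g (%d gene(s) flagged)",
                100 * params.library_quantile, cutoff, int(low_lib.sum()))

    table = pd.DataFrame({
        "gene": scored_genes,
        "library_es": es["library"].to_numpy(),
        "initial_es": es["initial"].to_numpy(),
        "final_es": es["final"].to_numpy(),
        "er": er.to_numpy(),
        "p": p.to_numpy(),
        "p_adj": p_adj,
        "s_library": detection["library"].loc[scored_genes].to_numpy(),
        "s_initial": detection["initial"].loc[scored_genes].to_numpy(),
        "s_final": detection["final"].loc[scored_genes].to_numpy(),
        "low_library_es": low_lib.to_numpy(),
        "significant": significant,
        "excluded": False,
    })
    if excluded.any():
        dropped = pd.DataFrame({"gene": all_genes[excluded]})
        for col in table.columns:
            if col not in dropped.columns:
                dropped[col] = (False if table[col].dtype == bool else np.nan)
        dropped["excluded"] = True
        table = pd.concat([table, dropped], ignore_index=True)
    table["constant_difference"] = False
    table.loc[table["gene"].isin(scored_genes[constant]), "constant_difference"] = True
    table = table[RESULT_COLUMNS].sort_values("gene", kind="mergesort")
    table = table.reset_index(drop=True)
    return TracsResult(table, params, cutoff)


def filter_essential(
    result: TracsResult,
    cutoff: float | None = None,
    er_max: float | None = None,
    padj_max: float | None = None,
) -> pd.DataFrame:
    """Genes with library_es > cutoff AND er < er_max AND p_adj < padj_max.

    All inequalities strict; rows sorted by ascending ER (most depleted
    first).  Defaults come from the run's parameters and its computed
    library cutoff.
    """
    cutoff = result.library_cutoff_value if cutoff is None else cutoff
    er_max = result.params.er_max if er_max is None else er_max
    padj_max = result.params.padj_max if padj_max is None else padj_max
    t = result.table
    keep = (
        ~t["excluded"].astype(bool)
        & (t["library_es"] > cutoff)
        & (t["er"] < er_max)
        & (t["p_adj"] < padj_max)
    )
    return t[keep].sort_values("er", kind="mergesort").reset_index(drop=True)
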