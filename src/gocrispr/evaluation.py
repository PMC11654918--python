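"""Assess essentiality calls against labeled gene sets.

Scores are compared with ROC analysis: the caller orients the score so
higher means "more positive" (for essentiality, score = -ER), and AUC is
the probability a random positive outranks a random negative, ties
counted half (Mann-Whitney).  Against simulation ground truth this also
reports precision/recall of the final gene filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .core import TracsResult, filter_essential

logger = logging.getLogger("gocrispr")

GENE_SET_LABELS = ("essential", "non_essential", "non_targeting")


@dataclass(frozen=True)
class LabeledGeneSet:
    """A named set of genes with a shared label."""

    name: str
    genes: frozenset[str]
    label: str

    def __post_init__(self) -> None:
        if self.label not in GENE_SET_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class RocResult:
    """ROC points ordered by threshold, plus the trapezoidal AUC."""

    points: pd.DataFrame  # columns fpr, tpr, non-decreasing; (0,0)..(1,1)
    auc: float

    def write_points(self, path: str | Path) -> None:
        self.points.to_csv(Path(path), sep="\t", index=False)


def read_gene_set(path: str | Path, label: str, name: str | None = None) -> LabeledGeneSet:
    """One gene symbol per line, case-insensitive (stored upper-cased)."""
    path = Path(path)
    genes = frozenset(
        line.strip().upper() for line in path.read_text().splitlines()
        if line.strip()
    )
    return LabeledGeneSet(name or path.stem, genes, label)


def roc_auc(
    scores: pd.Series, positives: set[str], negatives: set[str]
) -> RocResult:
    """ROC over a threshold sweep; higher score = more positive.

    AUC equals Mann-Whitney U / (|P|*|N|) with ties counted 0.5
    (trapezoidal interpolation across tied thresholds).
    """
    positives, negatives = set(positives), set(negatives)
    if not positives or not negatives:
        raise ValueError("need at least one positive and one negative gene")
    if positives & negatives:
        raise ValueError("positive and negative sets overlap")
    labeled = sorted(positives | negatives)
    missing = [g for g in labeled if g not in scores.index]
    if missing:
        raise KeyError(f"no score for genes: {missing[:5]}")
    y = np.array([g in positives for g in labeled])
    s = scores.loc[labeled].to_numpy(dtype=float)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(points, auc)


def evaluate_truth(
    result: TracsResult, truth_genes: pd.DataFrame
) -> dict:
    """Metrics of a scored screen against simulation ground truth.

    ``truth_genes`` is the TruthTable.genes frame (index gene, column
    is_essential).  AUC uses score = -ER restricted to genes passing the
    Library ES filter; precision/recall describe
    :func:`filter_essential` at the run's thresholds.  With zero truly
    essential genes the AUC is refused (None) and only the filter's
    false-positive count is reported.
    """
    t = result.table.set_index("gene")
    truth_universe = set(truth_genes.index)
    if truth_universe != set(t.index):
        diff = truth_universe ^ set(t.index)
        raise ValueError("truth table and result do not share a gene "
                         f"universe (differ by {sorted(diff)[:5]})")

    essential = set(truth_genes.index[truth_genes["is_essential"]])
    non_essential = truth_universe - essential

    passing = t[~t["excluded"].astype(bool) & ~t["low_library_es"].astype(bool)]
    hits = filter_essential(result)
    hit_genes = set(hits["gene"])
    n_tp = len(hit_genes & essential)
    n_fp = len(hit_genes - essential)

    metrics: dict = {
        "n_genes": len(truth_universe),
        "n_essential_truth": len(essential),
        "n_passing_library_filter": int(len(passing)),
        "n_called_essential": len(hit_genes),
        "false_positives": n_fp,
    }
    if not essential:
        logger.warning("no essential genes in truth: AUC refused, reporting "
                       "filter false positives only")
        metrics["auc_essential"] = None
        return metrics

    pos = essential & set(passing.index)
    neg = non_essential & set(passing.index)
    if pos and neg:
        roc = roc_auc(-passing["er"], pos, neg)
        metrics["auc_essential"] = roc.auc
        metrics["roc"] = roc
    else:
        metrics["auc_essential"] = None
    metrics["precision"] = n_tp / len(hit_genes) if hit_genes else float("nan")
    metrics["recall"] = n_tp / len(essential)
    return metrics


def write_metrics(metrics: dict, path: str | Path) -> None:
    """Metrics as JSON; the RocResult (if any) goes to a points TSV sidecar."""
    path = Path(path)
    payload = dict(metrics)
    roc = payload.pop("roc", None)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if roc is not None:
        roc.write_points(path.with_suffix(".roc.tsv"))
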