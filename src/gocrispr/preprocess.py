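"""Count preprocessing: pseudocount, median-of-ratios normalization, detection.

Raw counts are incremented by a pseudocount (default 1) so that no
abundance is ever zero, then normalized with the DESeq-style
median-of-ratios method: per-sgRNA geometric means across samples form
the reference, each sample's size factor is the median of its
count-to-reference ratios, and abundances are counts divided by the size
factor.  Detection of a gene's sgRNAs is always judged on the RAW counts
so the universal pseudocount cannot make every guide look observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen_io import CountMatrix

logger = logging.getLogger("gocrispr")


@dataclass
class NormalizedMatrix:
    """Positive normalized abundances plus the size factors that produced them."""

    abundance: pd.DataFrame  # index sgrna_id, columns sample_id, all > 0
    size_factors: pd.Series  # one positive factor per sample
    pseudocount: float

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() <= 0).any():
            raise ValueError("normalized abundances must all be positive")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must all be positive")


def add_pseudocount(matrix: CountMatrix, c: float = 1.0) -> CountMatrix:
    """Return a copy of the matrix with every entry increased by exactly c.

    The caller keeps the raw matrix for detection calls; c must be > 0.
    """
    if c <= 0:
        raise ValueError(f"pseudocount must be positive, got {c}")
    bumped = matrix.counts.astype(float) + c
    return CountMatrix(bumped, matrix.library, matrix.design, matrix.unassigned)


def median_ratio_normalize(
    matrix: CountMatrix, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """DESeq-style median-of-ratios normalization of a pseudocounted matrix.

    For each sgRNA i the reference is the geometric mean g_i of its counts
    across samples; sample j's size factor is median_i(count_ij / g_i) and
    its abundances are count_ij / f_j.  Requires strictly positive entries
    (apply :func:`add_pseudocount` first).  A single-sample matrix passes
    through with size factor 1 and a warning.
    """
    counts = matrix.counts.astype(float)
    if (counts.to_numpy() <= 0).any():
        raise ValueError(
            "median-of-ratios needs strictly positive entries; "
            "apply add_pseudocount first"
        )
    if counts.shape[1] == 1:
        logger.warning("single-sample matrix: size factor set to 1 (pass-through)")
        factors = pd.Series(1.0, index=counts.columns)
        return NormalizedMatrix(counts, factors, pseudocount=pseudocount)

    geo_mean = np.exp(np.log(counts).mean(axis=1))
    factors = counts.div(geo_mean, axis=0).median(axis=0)
    abundance = counts.div(factors, axis=1)
    logger.info("size factors: %s",
                ", ".join(f"{s}={f:.4g}" for s, f in factors.items()))
    return NormalizedMatrix(abundance, factors, pseudocount=pseudocount)


def detected_sgrnas(
    raw: CountMatrix, gene: str, sample_group: list[str] | set[str]
) -> int:
    """Number of the gene's sgRNAs with raw count >= 1 in any group sample.

    Computed on raw (pre-pseudocount) counts.  Genes whose guides are all
    unobserved return 0; callers flag those genes as excluded rather than
    scoring them.
    """
    sgrnas = raw.library.sgrnas_of(gene)
    if not sgrnas:
        raise KeyError(f"gene {gene!r} is not in the library")
    sub = raw.counts.loc[sgrnas, list(sample_group)]
    return int((sub >= 1).any(axis=1).sum())


def detection_table(raw: CountMatrix, sample_group: list[str]) -> pd.Series:
    """Per-gene detected-sgRNA counts s over a sample group (vectorized).

    Equivalent to calling :func:`detected_sgrnas` for every gene.
    """
    detected = (raw.counts[list(sample_group)] >= 1).any(axis=1)
    return detected.groupby(raw.genes).sum().astype(int)


def write_normalized(norm: NormalizedMatrix, genes: pd.Series, path) -> None:
    """Export abundances as TSV mirroring the count-table layout.

    Size factors go to a ``<path>.size_factors.txt`` sidecar.
    """
    out = norm.abundance.copy()
    out.insert(0, "gene", genes)
    out.index.name = "sgrna"
    out.to_csv(path, sep="\t")
    with open(f"{path}.size_factors.txt", "w") as fh:
        for sample, f in norm.size_factors.items():
            fh.write(f"{sample}\t{f:.10g}\n")
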