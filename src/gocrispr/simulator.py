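"""Synthetic GO-CRISPR screens with known ground truth.

The generative model mirrors the screen design the scoring pipeline
assumes: a log-normally skewed pooled library is transduced into two
populations (with and without Cas9) in independent infection events, so
each population independently loses a fraction of guides before T0
(Cas9-INdependent stochastic dropout, same probability in both).  Between
T0 and Tf nothing happens in Cas9-negative cells, while in Cas9-positive
cells guides targeting essential genes deplete by a fold-effect with a
per-guide editing probability.  Observed counts are negative-binomial
draws around depth-scaled abundances; replicates are independent draws.

Defaults mirror the screen design the method was built for: 6 sgRNAs per
gene, triplicates, non-targeting controls included as single-guide
pseudo-genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .screen_io import (
    CountMatrix,
    LibraryReference,
    ScreenDesign,
    SpacerLocator,
)

logger = logging.getLogger("gocrispr")


@dataclass(frozen=True)
class SimulationParams:
    """Generative-model settings for one synthetic screen.

    n_genes: targeting genes in the library.
    sgrnas_per_gene: guides designed per gene (default 6).
    n_ntc: non-targeting control guides, each its own single-guide
        pseudo-gene named ``NTC_####`` (scaled down from the 1,000 NTCs of
        a genome-wide library).
    n_replicates: replicates per (population, timepoint), >= 2.
    library_skew_sigma: std dev of the log-normal library representation;
        0 = perfectly uniform pool.
    dropout_prob: per-guide probability of Cas9-independent stochastic
        loss (a severe lineage bottleneck) between transduction and T0,
        drawn independently per population.
    frac_essential: fraction of targeting genes that are truly essential.
    depletion_effect: fold-depletion of essential-gene guides in
        Cas9-positive cells at Tf (> 1).
    editing_efficiency: probability a guide actually produces a knockout
        in Cas9-positive cells.
    mean_depth: mean reads per guide per sample.
    nb_dispersion: negative-binomial dispersion alpha in
        var = mu + alpha * mu^2; 0 degenerates to Poisson.
    """

    n_genes: int = 2000
    sgrnas_per_gene: int = 6
    n_ntc: int = 100
    n_replicates: int = 3
    library_skew_sigma: float = 0.8
    dropout_prob: float = 0.05
    frac_essential: float = 0.1
    depletion_effect: float = 10.0
    editing_efficiency: float = 0.9
    mean_depth: float = 500.0
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.sgrnas_per_gene < 1:
            raise ValueError("n_genes and sgrnas_per_gene must be >= 1")
        if self.n_ntc < 0:
            raise ValueError("n_ntc must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.library_skew_sigma < 0:
            raise ValueError("library_skew_sigma must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if not 0 <= self.frac_essential <= 1:
            raise ValueError("frac_essential must be in [0, 1]")
        if self.depletion_effect <= 1:
            raise ValueError("depletion_effect must be > 1")
        if not 0 < self.editing_efficiency <= 1:
            raise ValueError("editing_efficiency must be in (0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of a simulated screen.

    ``genes``: per gene — is_essential, effect_size (fold depletion
    applied; 1 for non-essential), label (targeting / non_targeting).
    ``sgrnas``: per guide — dropout flags per population and whether the
    guide edits in Cas9-positive cells.
    """

    genes: pd.DataFrame
    sgrnas: pd.DataFrame

    @property
    def essential_genes(self) -> list[str]:
        return self.genes.index[self.genes["is_essential"]].tolist()

    def write(self, path: str | Path) -> None:
        self.genes.to_csv(Path(path), sep="\t")


def _unique_spacers(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            sp = "".join(bases[row])
            if sp not in seen:
                seen.add(sp)
                out.append(sp)
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu, var mu + alpha*mu^2 (Poisson if alpha=0)."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype="int64")
    pos = mu > 0
    if alpha == 0:
        out[pos] = rng.poisson(mu[pos])
        return out
    size = 1.0 / alpha
    p = size / (size + mu[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_screen(
    params: SimulationParams = SimulationParams(),
) -> tuple[CountMatrix, ScreenDesign, LibraryReference, TruthTable]:
    """Generate one synthetic screen: counts, design, library, ground truth.

    Latent-abundance pipeline: (1) guide representation ~ log-normal(0,
    library_skew_sigma); (2) per population, each guide independently
    bottlenecked with probability dropout_prob to a small surviving
    fraction (independent draws for the two populations — the loss is
    Cas9-independent); (3) T0 abundance = surviving
    representation; (4) Tf: Cas9-negative unchanged, Cas9-positive
    essential-gene guides divided by depletion_effect with probability
    editing_efficiency; (5) per-sample counts ~ NB(depth-scaled
    abundance, nb_dispersion), replicates independent.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(params.seed)

    gene_names = [f"G{i + 1:05d}" for i in range(params.n_genes)]
    ntc_names = [f"NTC_{i + 1:04d}" for i in range(params.n_ntc)]
    sgrna_ids: list[str] = []
    sgrna_gene: list[str] = []
    for g in gene_names:
        for k in range(params.sgrnas_per_gene):
            sgrna_ids.append(f"{g}_sg{k + 1}")
            sgrna_gene.append(g)
    for g in ntc_names:  # one guide per NTC pseudo-gene
        sgrna_ids.append(f"{g}_sg1")
        sgrna_gene.append(g)
    n_guides = len(sgrna_ids)
    spacers = _unique_spacers(rng, n_guides)
    library = LibraryReference(tuple(zip(sgrna_ids, sgrna_gene, spacers)))
    design = ScreenDesign.default(params.n_replicates)

    # ground truth: which targeting genes are essential
    n_ess = int(round(params.frac_essential * params.n_genes))
    ess_idx = rng.choice(params.n_genes, size=n_ess, replace=False)
    is_essential = np.zeros(params.n_genes, dtype=bool)
    is_essential[ess_idx] = True
    gene_truth = pd.DataFrame({
        "is_essential": np.concatenate(
            [is_essential, np.zeros(params.n_ntc, dtype=bool)]),
        "effect_size": np.concatenate([
            np.where(is_essential, params.depletion_effect, 1.0),
            np.ones(params.n_ntc),
        ]),
        "label": ["targeting"] * params.n_genes + ["non_targeting"] * params.n_ntc,
    }, index=pd.Index(gene_names + ntc_names, name="gene"))

    # (1) library representation
    rep = rng.lognormal(mean=0.0, sigma=params.library_skew_sigma, size=n_guides)

    # (2) independent per-population stochastic loss: an affected guide's
    # lineage collapses to a small surviving fraction (severe bottleneck,
    # 0.1-10% of its representation) rather than an exact zero — exact
    # zeros would yield constant pseudocount-only signals downstream,
    # which real lost guides do not produce
    drop_pos = rng.random(n_guides) < params.dropout_prob
    drop_neg = rng.random(n_guides) < params.dropout_prob
    surv_pos = np.where(drop_pos, 10.0 ** rng.uniform(-3, -1, n_guides), 1.0)
    surv_neg = np.where(drop_neg, 10.0 ** rng.uniform(-3, -1, n_guides), 1.0)

    # (4) per-guide editing success in Cas9-positive cells
    guide_essential = gene_truth["is_essential"].reindex(sgrna_gene).to_numpy()
    edited = guide_essential & (rng.random(n_guides) < params.editing_efficiency)

    sgrna_truth = pd.DataFrame({
        "gene": sgrna_gene,
        "dropped_cas9_pos": drop_pos,
        "dropped_cas9_neg": drop_neg,
        "survival_cas9_pos": surv_pos,
        "survival_cas9_neg": surv_neg,
        "edited": edited,
    }, index=pd.Index(sgrna_ids, name="sgrna"))

    # latent abundances per (population, timepoint)
    abundance = {
        ("library", "L0"): rep,
        ("cas9_neg", "T0"): rep * surv_neg,
        ("cas9_neg", "Tf"): rep * surv_neg,
        ("cas9_pos", "T0"): rep * surv_pos,
        ("cas9_pos", "Tf"): rep * surv_pos
        / np.where(edited, params.depletion_effect, 1.0),
    }

    # (5) observed counts: total depth fixed per sample at mean_depth*n_guides
    counts = pd.DataFrame(0, index=sgrna_ids, columns=design.sample_ids,
                          dtype="int64")
    total_reads = params.mean_depth * n_guides
    for sample in design.samples:
        lat = abundance[(sample.population, sample.timepoint)]
        mu = total_reads * lat / lat.sum()
        counts[sample.sample_id] = _nb_draw(rng, mu, params.nb_dispersion)

    matrix = CountMatrix(counts, library, design)
    truth = TruthTable(gene_truth, sgrna_truth)
    logger.info("simulated screen: %d genes + %d NTCs, %d guides, %d samples, "
                "%d essential", params.n_genes, params.n_ntc, n_guides,
                len(design.samples), n_ess)
    return matrix, design, library, truth


def simulate_fastq(
    matrix: CountMatrix,
    library: LibraryReference,
    out_dir: str | Path,
    locator: SpacerLocator = SpacerLocator(),
    read_length: int = 50,
    seed: int = 0,
) -> dict[str, Path]:
    """Write per-sample FASTQ files that recount exactly to ``matrix``.

    Each count_ij becomes count_ij reads carrying guide i's spacer at the
    locator position, embedded in random flanking sequence (and preceded
    by the anchor, if the locator uses one).  Returns sample_id -> path.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bases = "ACGT"
    anchor = locator.anchor.upper() if locator.anchor is not None else ""
    prefix_len = locator.offset if locator.offset is not None else 0

    paths: dict[str, Path] = {}
    for sample_id in matrix.counts.columns:
        path = out_dir / f"{sample_id}.fastq"
        with open(path, "w") as fh:
            r = 0
            for sgrna_id, n in matrix.counts[sample_id].items():
                spacer = library.spacer_of(sgrna_id)
                for _ in range(int(n)):
                    prefix = "".join(rng.choice(list(bases), size=prefix_len))
                    read = prefix + anchor + spacer
                    pad = read_length - len(read)
                    if pad > 0:
                        read += "".join(rng.choice(list(bases), size=pad))
                    r += 1
                    fh.write(f"@{sample_id}:{r}\n{read}\n+\n{'I' * len(read)}\n")
        paths[sample_id] = path
    return paths
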