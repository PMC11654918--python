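"""File formats and read counting for GO-CRISPR screens.

A screen consists of a pooled sgRNA library (each guide a unique 20-nt
spacer targeting one gene), a library-pool sequencing sample (L0), and
replicate samples of Cas9-positive and Cas9-negative populations at the
initial (T0) and final (Tf) timepoints.  This module reads the library
reference CSV, turns per-sample FASTQ files into an sgRNA-by-sample count
matrix by exact spacer matching, and round-trips count tables as TSV.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

logger = logging.getLogger("gocrispr")

VALID_BASES = frozenset("ACGT")
POPULATIONS = ("cas9_pos", "cas9_neg", "library")
TIMEPOINTS = ("L0", "T0", "Tf")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryReference:
    """Maps each sgRNA identifier/spacer to its target gene.

    Invariants enforced at construction: unique sgRNA ids, spacers are
    non-empty uppercase strings over {A,C,G,T}, every sgRNA maps to exactly
    one gene.
    """

    records: tuple[tuple[str, str, str], ...]  # (sgrna_id, gene, spacer)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("library reference is empty")
        seen: set[str] = set()
        for sgrna_id, gene, spacer in self.records:
            if sgrna_id in seen:
                raise ValueError(f"duplicate sgRNA id {sgrna_id!r}")
            seen.add(sgrna_id)
            if not spacer or not set(spacer) <= VALID_BASES:
                raise ValueError(
                    f"sgRNA {sgrna_id!r}: spacer {spacer!r} is not a "
                    "non-empty A/C/G/T string"
                )
            if not gene:
                raise ValueError(f"sgRNA {sgrna_id!r} has no target gene")

    @property
    def sgrna_ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def genes(self) -> list[str]:
        """Unique gene names, in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for _, gene, _ in self.records:
            if gene not in seen:
                seen.add(gene)
                out.append(gene)
        return out

    def gene_of(self, sgrna_id: str) -> str:
        return self._by_id()[sgrna_id][0]

    def spacer_of(self, sgrna_id: str) -> str:
        return self._by_id()[sgrna_id][1]

    def sgrnas_of(self, gene: str) -> list[str]:
        return [sid for sid, g, _ in self.records if g == gene]

    @cached_property
    def _index(self) -> dict[str, tuple[str, str]]:
        return {sid: (g, sp) for sid, g, sp in self.records}

    def _by_id(self) -> dict[str, tuple[str, str]]:
        return self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.records), columns=["sgrna", "gene", "sequence"]
        ).set_index("sgrna")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Sample:
    sample_id: str
    population: str  # cas9_pos | cas9_neg | library
    timepoint: str  # L0 | T0 | Tf
    replicate: int


@dataclass(frozen=True)
class ScreenDesign:
    """Declares which samples are L0, Cas9+/-, T0/Tf and how replicates pair.

    Replicate i of a population at T0 pairs with replicate i at Tf.
    """

    samples: tuple[Sample, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design")
        for s in self.samples:
            if s.population not in POPULATIONS:
                raise ValueError(f"unknown population {s.population!r}")
            if s.timepoint not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {s.timepoint!r}")
            if s.replicate < 1:
                raise ValueError(f"sample {s.sample_id!r}: replicate must be >= 1")
            if (s.timepoint == "L0") != (s.population == "library"):
                raise ValueError(
                    f"sample {s.sample_id!r}: timepoint L0 and population "
                    "'library' must coincide"
                )
        n_l0 = sum(s.timepoint == "L0" for s in self.samples)
        if n_l0 != 1:
            raise ValueError(f"design must have exactly one L0 sample, found {n_l0}")
        reps: dict[tuple[str, str], list[int]] = {}
        for s in self.samples:
            if s.population != "library":
                reps.setdefault((s.population, s.timepoint), []).append(s.replicate)
        expected = {(p, t) for p in ("cas9_pos", "cas9_neg") for t in ("T0", "Tf")}
        if set(reps) != expected:
            missing = expected - set(reps)
            raise ValueError(f"design missing sample groups: {sorted(missing)}")
        rep_sets = {k: frozenset(v) for k, v in reps.items()}
        for k, v in reps.items():
            if len(set(v)) != len(v):
                raise ValueError(f"duplicate replicate index in group {k}")
        first = next(iter(rep_sets.values()))
        if any(v != first for v in rep_sets.values()):
            raise ValueError("replicate indices must be shared across all groups")
        if len(first) < 2:
            raise ValueError("at least 2 replicates are required")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_replicates(self) -> int:
        return len(self.group("cas9_pos", "T0"))

    @property
    def library_sample(self) -> str:
        return next(s.sample_id for s in self.samples if s.timepoint == "L0")

    def group(self, population: str, timepoint: str) -> list[str]:
        """Sample ids of one (population, timepoint) group, ordered by replicate."""
        members = [
            s for s in self.samples
            if s.population == population and s.timepoint == timepoint
        ]
        return [s.sample_id for s in sorted(members, key=lambda s: s.replicate)]

    @classmethod
    def default(cls, n_replicates: int = 3) -> "ScreenDesign":
        """The canonical 13-sample layout: L0 + 2 populations x 2 timepoints x n."""
        samples = [Sample("L0", "library", "L0", 1)]
        for pop, tag in (("cas9_pos", "cas9pos"), ("cas9_neg", "cas9neg")):
            for tp in ("T0", "Tf"):
                for r in range(1, n_replicates + 1):
                    samples.append(Sample(f"{tag}_{tp}_r{r}", pop, tp, r))
        return cls(tuple(samples))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScreenDesign":
        required = {"sample_id", "population", "timepoint", "replicate"}
        if not required <= set(df.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        return cls(tuple(
            Sample(str(r.sample_id), str(r.population), str(r.timepoint),
                   int(r.replicate))
            for r in df.itertuples()
        ))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.population, s.timepoint, s.replicate)
             for s in self.samples],
            columns=["sample_id", "population", "timepoint", "replicate"],
        )


@dataclass
class CountMatrix:
    """Integer read counts, sgRNAs x samples, plus per-sample unassigned tallies.

    Rows always cover the full library (unobserved sgRNAs are stored as 0).
    """

    counts: pd.DataFrame  # index sgrna_id, columns sample_id
    library: LibraryReference
    design: ScreenDesign
    unassigned: pd.Series | None = None

    def __post_init__(self) -> None:
        lib_ids = self.library.sgrna_ids
        missing = set(lib_ids) - set(self.counts.index)
        if missing:
            raise ValueError(f"count matrix missing library sgRNAs: {sorted(missing)[:5]}")
        extra = set(self.counts.index) - set(lib_ids)
        if extra:
            raise ValueError(f"count matrix has unknown sgRNAs: {sorted(extra)[:5]}")
        # canonical row order = library order; canonical index name
        self.counts = self.counts.loc[lib_ids]
        self.counts.index.name = "sgrna"
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")

    @property
    def genes(self) -> pd.Series:
        """Gene of each row, aligned with counts.index."""
        mapping = {sid: g for sid, g, _ in self.library.records}
        return pd.Series(
            [mapping[sid] for sid in self.counts.index],
            index=self.counts.index, name="gene",
        )


# ---------------------------------------------------------------------------
# Spacer locator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpacerLocator:
    """Where the spacer sits in a read.

    Either a fixed 0-based ``offset`` or a 5' ``anchor`` sequence that
    immediately precedes the spacer; ``length`` is the spacer length.
    Matching is exact and case-insensitive; ``check_reverse_complement``
    additionally tries the reverse complement of the read.
    """

    length: int = 20
    offset: int | None = 0
    anchor: str | None = None
    check_reverse_complement: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("spacer length must be >= 1")
        if (self.offset is None) == (self.anchor is None):
            raise ValueError("specify exactly one of offset or anchor")
        if self.anchor is not None and not self.anchor:
            raise ValueError("anchor must be non-empty")

    def extract(self, read: str) -> str | None:
        read = read.upper()
        if self.offset is not None:
            sub = read[self.offset:self.offset + self.length]
            return sub if len(sub) == self.length else None
        pos = read.find(self.anchor.upper())
        if pos < 0:
            return None
        start = pos + len(self.anchor)
        sub = read[start:start + self.length]
        return sub if len(sub) == self.length else None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def read_library_reference(
    path: str | Path,
    gene_col: str = "gene",
    sgrna_col: str = "sgrna",
    sequence_col: str = "sequence",
) -> LibraryReference:
    """Read a library reference CSV (gene, sgRNA id, spacer sequence).

    Column names are configurable; spacers are upper-cased.  Duplicate
    sgRNA ids and non-ACGT spacers are hard errors naming the offender.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: library reference file is empty") from None
    if df.empty:
        raise ValueError(f"{path}: library reference file has no records")
    for col in (gene_col, sgrna_col, sequence_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r} (found {list(df.columns)})")
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        sid = str(getattr(row, sgrna_col)).strip()
        gene = str(getattr(row, gene_col)).strip()
        spacer = str(getattr(row, sequence_col)).strip().upper()
        if sid in seen:
            raise ValueError(f"{path}: duplicate sgRNA id {sid!r}")
        seen.add(sid)
        if not set(spacer) <= VALID_BASES or not spacer:
            raise ValueError(
                f"{path}, line {i}: spacer {spacer!r} contains non-ACGT characters"
            )
        records.append((sid, gene, spacer))
    lib = LibraryReference(tuple(records))
    logger.info("read library reference: %d sgRNAs, %d genes from %s",
                len(lib), len(lib.genes), path)
    return lib


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq_reads(path: Path) -> Iterable[str]:
    with _open_maybe_gzip(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
            yield str(rec.seq)


def build_spacer_index(library: LibraryReference) -> dict[str, str]:
    """spacer -> sgrna_id; duplicate spacers are a hard error (ambiguous)."""
    index: dict[str, str] = {}
    for sid, _, spacer in library.records:
        if spacer in index:
            raise ValueError(
                f"ambiguous library: sgRNAs {index[spacer]!r} and {sid!r} "
                f"share spacer {spacer}"
            )
        index[spacer] = sid
    return index


def count_guides(
    fastq_paths: dict[str, str | Path | Sequence[str | Path]],
    library: LibraryReference,
    design: ScreenDesign,
    locator: SpacerLocator = SpacerLocator(),
) -> CountMatrix:
    """Count reads per sgRNA by exact spacer matching at the locator position.

    ``fastq_paths`` maps sample_id -> FASTQ path(s).  A read counts for
    sgRNA s iff the subsequence the locator extracts equals s's spacer
    exactly; everything else increments the sample's unassigned tally, so
    assigned + unassigned = total reads.
    """
    lengths = {len(sp) for _, _, sp in library.records}
    if lengths != {locator.length}:
        raise ValueError(
            f"library spacer lengths {sorted(lengths)} do not all equal the "
            f"locator length {locator.length}"
        )
    index = build_spacer_index(library)
    missing = set(design.sample_ids) - set(fastq_paths)
    if missing:
        raise ValueError(f"no FASTQ given for design samples: {sorted(missing)}")

    counts = pd.DataFrame(
        0, index=library.sgrna_ids, columns=design.sample_ids, dtype="int64"
    )
    unassigned = pd.Series(0, index=design.sample_ids, dtype="int64")
    for sample_id in design.sample_ids:
        paths = fastq_paths[sample_id]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        col = counts[sample_id].to_dict()
        n_un = 0
        for p in paths:
            for read in _iter_fastq_reads(Path(p)):
                sub = locator.extract(read)
                sid = index.get(sub) if sub is not None else None
                if sid is None and locator.check_reverse_complement:
                    sub_rc = locator.extract(reverse_complement(read))
                    sid = index.get(sub_rc) if sub_rc is not None else None
                if sid is None:
                    n_un += 1
                else:
                    col[sid] += 1
        counts[sample_id] = pd.Series(col)
        unassigned[sample_id] = n_un
        total = counts[sample_id].sum() + n_un
        logger.info("sample %s: %d reads, %d assigned (%.1f%%)",
                    sample_id, total, total - n_un,
                    100.0 * (total - n_un) / total if total else 0.0)
    return CountMatrix(counts, library, design, unassigned)


def read_counts(
    path: str | Path, library: LibraryReference, design: ScreenDesign
) -> CountMatrix:
    """Read a TSV count table (sgrna, optional gene, one column per sample).

    Library sgRNAs absent from the file get count 0 with a warning; sample
    columns not in the design, and negative or non-integer counts, are
    hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sgrna":
        raise ValueError(f"{path}: first column must be 'sgrna', got {df.columns[0]!r}")
    df = df.set_index("sgrna")
    if "gene" in df.columns:
        df = df.drop(columns=["gene"])
    unknown = set(df.columns) - set(design.sample_ids)
    if unknown:
        raise ValueError(f"{path}: sample columns not in design: {sorted(unknown)}")
    missing_samples = set(design.sample_ids) - set(df.columns)
    if missing_samples:
        raise ValueError(f"{path}: design samples missing from file: "
                         f"{sorted(missing_samples)}")
    for col in df.columns:
        for sid, v in df[col].items():
            fv = float(v)
            if not fv.is_integer() or fv < 0:
                raise ValueError(
                    f"{path}: invalid count {v!r} at sgRNA {sid!r}, sample {col!r}"
                )
        df[col] = df[col].astype("int64")
    missing_rows = set(library.sgrna_ids) - set(df.index)
    if missing_rows:
        logger.warning("%s: %d library sgRNAs absent from count file, filled with 0",
                       path, len(missing_rows))
    full = df.reindex(library.sgrna_ids).fillna(0).astype("int64")
    return CountMatrix(full[design.sample_ids], library, design)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write a count table as TSV: sgrna <TAB> gene <TAB> one column per sample."""
    out = matrix.counts.copy()
    out.insert(0, "gene", matrix.genes)
    out.index.name = "sgrna"
    out.to_csv(Path(path), sep="\t")
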