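"""Readers and writers for every external representation the pipeline touches.

All genomic intervals are 0-based, half-open (BED convention) internally;
1-based coordinates appear only in display strings.  Table writers emit a
deterministic column and row order so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

logger = logging.getLogger(__name__)


def _float_repr(v) -> str:
    """Shortest round-trippable decimal representation of a float."""
    return repr(float(v))

BASES = "ACGT"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Peak:
    """A single H3K27ac enhancer peak with sample and matched-input signal.

    ``sample_signal`` is the H3K27ac read density summed over the interval
    (arbitrary units, >= 0); ``input_signal`` is the matched input density.
    """

    chrom: str
    start: int
    end: int
    name: str
    sample_signal: float = 0.0
    input_signal: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"peak {self.name}: invalid interval [{self.start}, {self.end})"
            )
        if self.sample_signal < 0 or self.input_signal < 0:
            raise FormatError(f"peak {self.name}: negative signal")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with its strand-resolved transcription start site.

    ``tss`` is txStart for + strand genes and txEnd - 1 (the last
    transcribed base) for - strand genes; resolved at load time.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise FormatError(f"gene {self.gene_id}: negative TSS")


@dataclass(frozen=True)
class DEGRecord:
    """One row of a differential-expression table (DESeq2-style)."""

    gene_id: str
    log2fc: float
    pvalue: float
    qvalue: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc):
            raise FormatError(f"DEG {self.gene_id}: non-finite log2fc")
        for label, v in (("pvalue", self.pvalue), ("qvalue", self.qvalue)):
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"DEG {self.gene_id}: {label}={v} outside [0,1]")


@dataclass(frozen=True)
class PWM:
    """A position weight matrix of per-position base probabilities.

    ``matrix`` has shape (length, 4) over A, C, G, T; every row sums to 1
    within 1e-9 after pseudocount normalisation.
    """

    tf_name: str
    matrix: tuple[tuple[float, float, float, float], ...]
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] != 4:
            raise FormatError(f"PWM {self.tf_name}: matrix must be (length, 4)")
        if (m < 0).any():
            raise FormatError(f"PWM {self.tf_name}: negative probabilities")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise FormatError(f"PWM {self.tf_name}: columns do not sum to 1")

    @classmethod
    def from_counts(
        cls, tf_name: str, counts: np.ndarray, pseudocount: float = 1e-3
    ) -> "PWM":
        """Convert a (length, 4) count or probability matrix to a PWM.

        A pseudocount is added to every cell and rows are renormalised, so
        zero entries become small positive probabilities.
        """
        c = np.asarray(counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4:
            raise FormatError(f"PWM {tf_name}: counts must be (length, 4)")
        if c.shape[0] < 1:
            raise FormatError(f"PWM {tf_name}: zero-length motif")
        if (c < 0).any():
            raise FormatError(f"PWM {tf_name}: negative counts")
        if (c.sum(axis=1) == 0).any():
            raise FormatError(f"PWM {tf_name}: column of all zeros")
        c = c + pseudocount
        c = c / c.sum(axis=1, keepdims=True)
        return cls(tf_name, tuple(map(tuple, c)), pseudocount)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @property
    def length(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.as_array().argmax(axis=1))


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        members = frozenset(members)
        if not members:
            raise FormatError(f"gene set {name!r}: empty member set")
        if name in self.sets:
            raise FormatError(f"gene set {name!r}: duplicate name")
        self.sets[name] = members
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)


# ---------------------------------------------------------------------------
# Peak I/O
# ---------------------------------------------------------------------------

def _parse_peak_line(
    fields: list[str], lineno: int, path: str, dialect: str
) -> Peak:
    if len(fields) < 4:
        raise FormatError(f"{path}:{lineno}: expected >= 4 columns, got {len(fields)}")
    chrom, start_s, end_s, name = fields[:4]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: unparseable coordinates") from exc
    if start >= end:
        raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
    sample = inp = 0.0
    try:
        if dialect == "narrowPeak":
            # narrowPeak column 7 (index 6) is signalValue
            if len(fields) >= 7:
                sample = float(fields[6])
        elif dialect == "bed6+signal":
            if len(fields) >= 7:
                sample = float(fields[6])
            if len(fields) >= 8:
                inp = float(fields[7])
        else:
            raise FormatError(f"unknown peak dialect {dialect!r}")
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: unparseable signal column") from exc
    return Peak(chrom, start, end, name, sample, inp)


def read_peaks(
    path: str | Path,
    dialect: str = "narrowPeak",
    input_path: str | Path | None = None,
) -> list[Peak]:
    """Read enhancer peaks from a narrowPeak or BED6+2 file.

    For the ``narrowPeak`` dialect, column 7 (signalValue) supplies
    sample_signal; input_signal is 0 unless ``input_path`` names a same-shape
    file whose peaks match by (chrom, start, end), in which case that file's
    signalValue column supplies input_signal.  For ``bed6+signal`` column 7
    is sample_signal and column 8 input_signal.  Peaks are returned sorted by
    (chrom, start, end, name).
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            peaks.append(_parse_peak_line(line.split("\t"), lineno, str(path), dialect))
    if not peaks:
        logger.warning("no peaks read from %s", path)
    if input_path is not None:
        inputs = {
            (p.chrom, p.start, p.end): p.sample_signal
            for p in read_peaks(input_path, dialect=dialect)
        }
        peaks = [
            Peak(p.chrom, p.start, p.end, p.name, p.sample_signal,
                 inputs.get((p.chrom, p.start, p.end), 0.0))
            for p in peaks
        ]
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end, p.name))
    seen: set[tuple] = set()
    for p in peaks:
        key = (p.chrom, p.start, p.end, p.name)
        if key in seen:
            raise FormatError(f"{path}: duplicate peak {key}")
        seen.add(key)
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED6+2 (name, score=0, strand=., sample, input)."""
    rows = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.name))
    with open(path, "w") as fh:
        for p in rows:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                f"{p.sample_signal!r}\t{p.input_signal!r}\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["gene_id", "chrom", "strand", "txStart", "txEnd", "is_tf"]


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read a tab-separated gene table and resolve strand-aware TSS.

    Requires columns gene_id, chrom, strand, txStart, txEnd, is_tf.  The TSS
    is txStart on the + strand and txEnd - 1 on the - strand.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene_id(s) {dups}")
    genes = []
    for row in df.itertuples(index=False):
        tss = int(row.txStart) if row.strand == "+" else int(row.txEnd) - 1
        genes.append(
            GeneModel(str(row.gene_id), str(row.chrom), str(row.strand), tss,
                      bool(int(row.is_tf)))
        )
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path: str | Path,
                          gene_spans: Mapping[str, tuple[int, int]] | None = None
                          ) -> None:
    """Write genes as the tabular annotation format read_gene_annotation expects.

    ``gene_spans`` optionally gives (txStart, txEnd) per gene; otherwise a
    minimal 1 bp span consistent with the TSS is emitted.
    """
    rows = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        if gene_spans and g.gene_id in gene_spans:
            tx_start, tx_end = gene_spans[g.gene_id]
        elif g.strand == "+":
            tx_start, tx_end = g.tss, g.tss + 1
        else:
            tx_start, tx_end = g.tss, g.tss + 1
        rows.append((g.gene_id, g.chrom, g.strand, tx_start, tx_end, int(g.is_tf)))
    df = pd.DataFrame(rows, columns=_GENE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Motif libraries
# ---------------------------------------------------------------------------

def read_motif_library(
    path: str | Path, format: str = "jaspar", pseudocount: float = 1e-3
) -> list[PWM]:
    """Read PWMs from JASPAR or minimal-MEME motif text.

    Counts are converted to probabilities with a pseudocount (default 0.001)
    and renormalised, so the column-sum invariant holds.  Parsing is done by
    Bio.motifs; this function owns validation and the probability conversion.
    """
    fmt = {"jaspar": "jaspar", "meme": "minimal"}.get(format)
    if fmt is None:
        raise FormatError(f"unknown motif format {format!r}")
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, fmt)
    pwms = []
    for m in parsed:
        name = m.name or m.base_id or "motif"
        counts = np.array([[m.counts[b][i] for b in BASES]
                           for i in range(m.length)], dtype=float)
        pwms.append(PWM.from_counts(str(name), counts, pseudocount))
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def write_motif_library_jaspar(pwms: Sequence[PWM], path: str | Path,
                               scale: float = 100.0) -> None:
    """Write PWMs as JASPAR count blocks (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for pwm in sorted(pwms, key=lambda p: p.tf_name):
            fh.write(f">{pwm.tf_name}\t{pwm.tf_name}\n")
            m = pwm.as_array() * scale
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:.2f}" for v in m[:, bi])
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# DEG / expression / gene-set tables
# ---------------------------------------------------------------------------

_DEG_COLUMNS = ["gene_id", "log2fc", "pvalue", "qvalue"]


def read_deg_table(path: str | Path) -> list[DEGRecord]:
    """Read a DEG table (gene_id, log2fc, pvalue, qvalue) with a header."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     float_precision="round_trip")
    missing = [c for c in _DEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return [
        DEGRecord(str(r.gene_id), float(r.log2fc), float(r.pvalue), float(r.qvalue))
        for r in df.itertuples(index=False)
    ]


def write_deg_table(records: Sequence[DEGRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        sorted((r.gene_id, r.log2fc, r.pvalue, r.qvalue) for r in records),
        columns=_DEG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format=_float_repr)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            coll.add(fields[0], [g for g in fields[2:] if g], fields[1])
    return coll


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(coll.sets):
            members = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{coll.descriptions.get(name, '')}\t{members}\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read an FPKM matrix (rows = genes, columns = samples) from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative expression values")
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.sort_index().to_csv(path, sep="\t", float_format=_float_repr)


def write_table(df: pd.DataFrame, path: str | Path,
                sort_by: str | list[str] | None = None) -> None:
    """Write a generic TSV with deterministic row/column order.

    Rows are sorted by ``sort_by`` (default: the first column) so that
    reruns from identical inputs are byte-identical.
    """
    if sort_by is None:
        sort_by = list(df.columns[:1])
    out = df.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    """Write sequences as FASTA in sorted name order with fixed line width."""
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordinary dict of upper-case sequences."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
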