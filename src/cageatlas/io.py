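"""Readers and writers for the genomic file formats used by the pipeline.

Coordinate conventions
----------------------
Everything in memory is 0-based, half-open ``[start, end)``.  GTF is the one
format with 1-based, closed coordinates; the conversion happens on read and
on write and nowhere else.  A transcript's 5' end is computed strand-aware:
``start`` for ``+`` transcripts and ``end - 1`` for ``-`` transcripts.

CTSS dialect: BED6 with one row per (position, strand), ``end == start + 1``
and the score column carrying the raw integer tag count.
"""

from __future__ import annotations

import io as _stdio
import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A file violated the expected format contract."""


# ---------------------------------------------------------------------------
# intervals


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


# ---------------------------------------------------------------------------
# CTSS tracks


@dataclass
class CtssTrack:
    """Per-sample stranded 5'-tag counts, one row per genomic position."""

    sample_id: str
    data: pd.DataFrame  # columns: chrom, pos, strand, count; sorted

    @property
    def total(self) -> int:
        """Total mapped tags in this track (the TPM denominator)."""
        return int(self.data["count"].sum())

    def __len__(self) -> int:
        return len(self.data)


def _finalize_ctss_frame(df: pd.DataFrame, where: str) -> pd.DataFrame:
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(["chrom", "pos", "strand"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"{where}: duplicate CTSS row for ({row['chrom']}, {row['pos']}, {row['strand']})"
        )
    return df


def read_ctss(path, sample_id: str | None = None) -> CtssTrack:
    """Read a CTSS BED6 file.

    Errors carry the 1-based line number; ``end != start + 1`` is a format
    error, as are duplicate (chrom, pos, strand) rows.
    """
    chroms, poss, strands, counts = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start_s, end_s, _name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                count = int(score_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate or count") from exc
            if end != start + 1:
                raise FormatError(f"{path}:{lineno}: CTSS rows must have end == start + 1")
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative tag count")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: CTSS strand must be + or -")
            chroms.append(chrom)
            poss.append(start)
            strands.append(strand)
            counts.append(count)
    df = pd.DataFrame({"chrom": chroms, "pos": poss, "strand": strands, "count": counts})
    df = _finalize_ctss_frame(df, str(path))
    if sample_id is None:
        sample_id = re.sub(r"(\.ctss)?\.bed$", "", str(path).rsplit("/", 1)[-1])
    return CtssTrack(sample_id=sample_id, data=df)


def write_ctss(track: CtssTrack, path) -> None:
    df = track.data
    with open(path, "w") as fh:
        for chrom, pos, strand, count in zip(
            df["chrom"], df["pos"], df["strand"], df["count"]
        ):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{track.sample_id}\t{count}\t{strand}\n")


# ---------------------------------------------------------------------------
# gene models (GTF / BED12)


@dataclass
class GeneModels:
    """Transcript and gene extents with precomputed strand-aware 5' ends.

    ``transcripts`` columns: transcript_id, gene_id, chrom, start, end,
    strand, tss5p.  ``genes`` columns: gene_id, chrom, start, end, strand.
    """

    transcripts: pd.DataFrame
    genes: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.genes is None:
            self.genes = (
                self.transcripts.groupby("gene_id")
                .agg(
                    chrom=("chrom", "first"),
                    start=("start", "min"),
                    end=("end", "max"),
                    strand=("strand", "first"),
                )
                .reset_index()
                .sort_values(["chrom", "start"], kind="mergesort")
                .reset_index(drop=True)
            )


def five_prime_end(start: int, end: int, strand: str) -> int:
    """5' position of a [start, end) transcript; end-1 on the minus strand."""
    return start if strand == "+" else end - 1


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> GeneModels:
    """Parse a GTF into gene models.

    Uses ``transcript`` feature rows when present, otherwise aggregates
    ``exon`` rows per transcript_id.  GTF is 1-based closed; internal
    coordinates are 0-based half-open.  A transcript feature without a
    gene_id attribute is an error.
    """
    tx_rows: dict[str, dict] = {}
    exon_rows: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("transcript", "exon"):
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if tid is None:
                raise FormatError(f"{path}:{lineno}: {feature} without transcript_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: transcript {tid!r} without gene_id")
            start = int(start_s) - 1  # 1-based closed -> 0-based half-open
            end = int(end_s)
            store = tx_rows if feature == "transcript" else exon_rows
            if tid in store:
                rec = store[tid]
                rec["start"] = min(rec["start"], start)
                rec["end"] = max(rec["end"], end)
            else:
                store[tid] = {
                    "transcript_id": tid,
                    "gene_id": gid,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                }
    rows = tx_rows if tx_rows else exon_rows
    if not rows:
        raise FormatError(f"{path}: no transcript or exon features found")
    df = pd.DataFrame(list(rows.values()))
    df["tss5p"] = [
        five_prime_end(s, e, st) for s, e, st in zip(df["start"], df["end"], df["strand"])
    ]
    df = df.sort_values(["chrom", "start", "transcript_id"], kind="mergesort").reset_index(
        drop=True
    )
    return GeneModels(transcripts=df)


def write_gtf(models: GeneModels, path, source: str = "cageatlas") -> None:
    """Write gene and transcript (plus one covering exon) features."""
    with open(path, "w") as fh:
        for g in models.genes.itertuples():
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
            txs = models.transcripts[models.transcripts["gene_id"] == g.gene_id]
            for t in txs.itertuples():
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                for feat in ("transcript", "exon"):
                    fh.write(
                        f"{t.chrom}\t{source}\t{feat}\t{t.start + 1}\t{t.end}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )


def read_bed12(path) -> GeneModels:
    """Read BED12 transcript models; the name column doubles as gene_id."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            rows.append(
                {
                    "transcript_id": name,
                    "gene_id": name,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "tss5p": five_prime_end(start, end, strand),
                }
            )
    if not rows:
        raise FormatError(f"{path}: empty BED12 file")
    df = pd.DataFrame(rows).sort_values(
        ["chrom", "start", "transcript_id"], kind="mergesort"
    ).reset_index(drop=True)
    return GeneModels(transcripts=df)


# ---------------------------------------------------------------------------
# plain BED intervals


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED3-6 into a 6-column frame (missing columns get defaults)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else "."
            score = fields[4] if len(fields) > 4 else "0"
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((fields[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed(intervals: pd.DataFrame, path) -> None:
    df = intervals
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            name = getattr(row, "name", ".")
            score = getattr(row, "score", 0)
            strand = getattr(row, "strand", ".")
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# PWMs (JASPAR plain text)

BASES = "ACGT"


@dataclass
class Pwm:
    """Position probability matrix in A,C,G,T row order.

    ``probs`` is 4 x L and column-stochastic; built from JASPAR counts with a
    pseudocount added to every cell.
    """

    id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValueError("probs must be a 4 x L matrix with L >= 1")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(
        cls, motif_id: str, counts: np.ndarray, pseudocount: float = 1.0
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise FormatError(f"{motif_id}: counts must have 4 rows (A,C,G,T)")
        if (counts < 0).any():
            raise FormatError(f"{motif_id}: negative counts")
        padded = counts + pseudocount
        return cls(id=motif_id, probs=padded / padded.sum(axis=0), pseudocount=pseudocount)

    def log_odds(self) -> np.ndarray:
        """4 x L log2(p/background) matrix."""
        return np.log2(self.probs / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            id=self.id,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


def read_pwm(path, pseudocount: float = 1.0) -> list[Pwm]:
    """Read a JASPAR-style plain-text file of 4-row count matrices."""
    with open(path) as fh:
        text = fh.read()
    try:
        records = bio_motifs.parse(_stdio.StringIO(text), "jaspar")
    except Exception as exc:  # Biopython raises bare ValueError/KeyError
        raise FormatError(f"{path}: cannot parse JASPAR matrices: {exc}") from exc
    pwms = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in BASES], dtype=float)
        motif_id = rec.matrix_id or rec.name
        pwms.append(Pwm.from_counts(motif_id, counts, pseudocount=pseudocount))
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def write_pwm(motif_counts: dict[str, np.ndarray], path) -> None:
    """Write integer count matrices in JASPAR plain-text format."""
    with open(path, "w") as fh:
        for motif_id, counts in motif_counts.items():
            counts = np.asarray(counts)
            fh.write(f">{motif_id} {motif_id}\n")
            for base, row in zip(BASES, counts):
                cells = " ".join(str(int(v)) for v in row)
                fh.write(f"{base} [ {cells} ]\n")


# ---------------------------------------------------------------------------
# expression matrices and sample sheets

MATRIX_UNITS = ("counts", "tpm", "log2tpm")


@dataclass
class ExpressionMatrix:
    """Feature x sample matrix with a units flag."""

    values: pd.DataFrame
    units: str = "tpm"

    def __post_init__(self) -> None:
        if self.units not in MATRIX_UNITS:
            raise ValueError(f"units must be one of {MATRIX_UNITS}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix must not contain missing values")
        if self.values.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if (self.values.values < 0).any() and self.units != "log2tpm":
            raise ValueError("negative values in a counts/tpm matrix")


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix(path, units: str = "tpm") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    df.index.name = None
    return ExpressionMatrix(values=df, units=units)


SAMPLE_SHEET_COLUMNS = ["sample_id", "cell_type", "replicate", "stage_order"]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False, columns=SAMPLE_SHEET_COLUMNS)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    return df


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
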