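"""Input/output for the pipeline's text formats and core containers.

All genomic coordinates are 0-based half-open (BED convention) everywhere
inside the package.  GTF gene input (1-based inclusive) is converted at the
boundary.  Supported formats: chrom.sizes (two-column TSV), BED3/BED6 read
and interval files, minimal GTF gene subset, bedGraph signal tracks, and a
two-column TSV expression table keyed by gene_id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NAN_SENTINEL = "nan"

VALID_PHASES = ("G1", "S", "G2M", "M", "asynchronous")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths; the coordinate frame for everything.

    Chromosome order is preserved from the input file and defines the sort
    order of every window grid and rendered karyogram.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise FormatError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise FormatError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"chromosome {name!r} not in layout") from None

    def __len__(self) -> int:
        return len(self.chromosomes)


@dataclass(frozen=True)
class SampleMeta:
    """Sample metadata attached to a read collection."""

    mark: str = ""
    phase: str = "asynchronous"
    cell_type: str = ""
    total_reads: int = 0


@dataclass
class ReadCollection:
    """Aligned read intervals (0-based half-open) with sample metadata.

    ``chrom_idx`` indexes into ``layout.chromosomes``; strand is '+', '-' or
    '.' (native ChIP fragments are unstranded).
    """

    layout: GenomeLayout
    chrom_idx: np.ndarray  # int32
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    strand: np.ndarray  # '<U1'
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        n = len(self.start)
        if not (len(self.end) == len(self.chrom_idx) == len(self.strand) == n):
            raise ValueError("read arrays have mismatched lengths")
        if n and np.any(self.start >= self.end):
            bad = int(np.argmax(self.start >= self.end))
            raise ValueError(f"read {bad}: start >= end")
        lengths = np.array([l for _, l in self.layout.chromosomes], dtype=np.int64)
        if n and (np.any(self.start < 0) or np.any(self.end > lengths[self.chrom_idx])):
            raise ValueError("read outside chromosome bounds")
        if self.meta.total_reads != n:
            self.meta = replace(self.meta, total_reads=n)

    def __len__(self) -> int:
        return len(self.start)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def on_chrom(self, name: str) -> "ReadCollection":
        sel = self.chrom_idx == self.layout.index(name)
        return ReadCollection(
            self.layout,
            self.chrom_idx[sel],
            self.start[sel],
            self.end[sel],
            self.strand[sel],
            replace(self.meta, total_reads=int(sel.sum())),
        )


@dataclass
class GeneAnnotation:
    """Per-gene records with strand-aware TSS and optional class labels.

    ``df`` columns: gene_id, chrom, start, end, strand, classes (frozenset).
    One TSS per gene_id: start for '+' genes, end for '-' genes (the 5'-most
    annotated position).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene_id {dup!r}")
        if not self.df["strand"].isin(["+", "-"]).all():
            raise FormatError("gene strand must be '+' or '-'")
        if "classes" not in self.df.columns:
            self.df = self.df.assign(classes=[frozenset()] * len(self.df))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tss(self) -> np.ndarray:
        """Strand-aware transcription start positions (0-based)."""
        return np.where(
            self.df["strand"].to_numpy() == "+",
            self.df["start"].to_numpy(),
            self.df["end"].to_numpy() - 1,
        )

    def with_class(self, label: str) -> "GeneAnnotation":
        mask = self.df["classes"].map(lambda cs: label in cs)
        if not mask.any():
            raise ValueError(f"no gene carries class label {label!r}")
        return GeneAnnotation(self.df.loc[mask].reset_index(drop=True))


@dataclass
class IntervalSet:
    """Named genomic intervals (TADs, bands, sub-bands, truth sets).

    ``df`` columns: chrom, start, end, name; extra columns (e.g. a planted
    enrichment multiplier) are preserved.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if required - set(self.df.columns):
            raise ValueError("interval table needs chrom/start/end")
        if "name" not in self.df.columns:
            self.df = self.df.assign(name=[f"iv{i}" for i in range(len(self.df))])
        if len(self.df) and (self.df["start"] >= self.df["end"]).any():
            raise ValueError("interval with start >= end")
        if len(self.df) and (self.df["start"] < 0).any():
            raise ValueError("negative interval start")

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> GenomeLayout:
    """Parse a two-column (name, length) chromosome-sizes file."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from None
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length for {name!r}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise FormatError(f"{path}: no chromosomes")
    return GenomeLayout(tuple(chroms))


def read_reads_bed(
    path,
    layout: GenomeLayout,
    meta: SampleMeta | None = None,
    unknown_chrom: str = "error",
) -> ReadCollection:
    """Read aligned read intervals from BED3/BED6.

    Reads on chromosomes absent from ``layout`` trigger a hard error by
    default, or are skipped with a counted warning under
    ``unknown_chrom='skip'``.  Reads outside chromosome bounds are always
    rejected the same way.
    """
    if unknown_chrom not in ("error", "skip"):
        raise ValueError("unknown_chrom must be 'error' or 'skip'")
    name_to_idx = {n: i for i, n in enumerate(layout.names)}
    lengths = layout.lengths
    cidx: list[int] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if e <= s:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if chrom not in name_to_idx:
                if unknown_chrom == "error":
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                skipped += 1
                continue
            if s < 0 or e > lengths[chrom]:
                if unknown_chrom == "error":
                    raise FormatError(f"{path}:{lineno}: read outside {chrom!r} bounds")
                skipped += 1
                continue
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            cidx.append(name_to_idx[chrom])
            starts.append(s)
            ends.append(e)
            strands.append(strand)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} reads outside layout", stacklevel=2)
    meta = meta or SampleMeta()
    return ReadCollection(
        layout,
        np.asarray(cidx, dtype=np.int32),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.asarray(strands, dtype="<U1"),
        replace(meta, total_reads=len(starts)),
    )


def read_intervals_bed(path, layout: GenomeLayout | None = None) -> IntervalSet:
    """Read BED3/BED4(+) intervals (TADs, bands); bounds-checked if a layout is given."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if e <= s or s < 0:
                raise FormatError(f"{path}:{lineno}: invalid interval [{s},{e})")
            if layout is not None:
                if parts[0] not in layout.lengths:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {parts[0]!r}")
                if e > layout.lengths[parts[0]]:
                    raise FormatError(f"{path}:{lineno}: interval beyond chromosome end")
            name = parts[3] if len(parts) >= 4 else f"iv{len(rows)}"
            rows.append((parts[0], s, e, name))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def read_genes_bed(path, layout: GenomeLayout | None = None) -> GeneAnnotation:
    """Read genes from BED6/BED12 (name column = gene_id; strand required)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: genes need >=6 BED columns (strand)")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if parts[5] not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: gene strand must be + or -")
            rows.append((parts[3], parts[0], s, e, parts[5]))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if layout is not None:
        unknown = set(df["chrom"]) - set(layout.names)
        if unknown:
            raise FormatError(f"{path}: unknown chromosomes {sorted(unknown)}")
    return GeneAnnotation(df)


def read_genes_gtf(path, feature: str = "gene") -> GeneAnnotation:
    """Read a minimal GTF subset; 1-based inclusive coordinates are shifted
    to 0-based half-open at this boundary."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if parts[2] != feature:
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in parts[8].rstrip(";").split(";")
                if kv.strip()
            )
            gene_id = attrs.get("gene_id", "").strip('"')
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            rows.append((gene_id, parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )


def read_gene_classes(path) -> dict[str, frozenset[str]]:
    """Read a TSV of (gene_id, comma-separated class labels)."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected gene_id<TAB>classes")
            out[parts[0]] = frozenset(c for c in parts[1].split(",") if c)
    return out


def read_expression_table(path) -> pd.Series:
    """Read a two-column TSV (gene_id, value) into a Series indexed by gene."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "value"], comment="#"
    )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicated gene_id {dup!r}")
    return df.set_index("gene_id")["value"].astype(float)


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph into (chrom, start, end, value); 'nan' → missing."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            value = float("nan") if parts[3] == NAN_SENTINEL else float(parts[3])
            rows.append((parts[0], int(parts[1]), int(parts[2]), value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_bedgraph(track, path, which: str = "value") -> None:
    """Write a SignalTrack's normalized values (or raw counts) as bedGraph.

    NaN values are written as the literal sentinel ``nan`` and re-read as
    missing; six decimal places give exact round-trips at the printed
    precision.
    """
    grid = track.grid
    data = track.value if which == "value" else track.raw
    if data is None:
        raise ValueError(f"track has no {which!r} data")
    names = grid.layout.names
    with open(path, "w") as fh:
        for ci, s, e, v in zip(grid.chrom_idx, grid.start, grid.end, data):
            if isinstance(v, (float, np.floating)) and np.isnan(v):
                sval = NAN_SENTINEL
            elif which == "raw":
                sval = str(int(v))
            else:
                sval = f"{v:.6f}"
            fh.write(f"{names[ci]}\t{s}\t{e}\t{sval}\n")


def write_intervals_bed(intervals: IntervalSet, path, extra_cols=()) -> None:
    cols = ["chrom", "start", "end", "name", *extra_cols]
    intervals.df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_reads_bed(reads: ReadCollection, path) -> None:
    names = reads.layout.names
    with open(path, "w") as fh:
        for i in range(len(reads)):
            fh.write(
                f"{names[reads.chrom_idx[i]]}\t{reads.start[i]}\t{reads.end[i]}"
                f"\tread{i}\t0\t{reads.strand[i]}\n"
            )


def write_genes_bed(genes: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for row in genes.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )


def write_gene_classes(genes: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for row in genes.df.itertuples(index=False):
            fh.write(f"{row.gene_id}\t{','.join(sorted(row.classes))}\n")
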