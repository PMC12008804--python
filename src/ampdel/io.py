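"""Tabular genomic formats: SEG-like copy-number tables, BEDPE junctions,
BED loci, bedGraph depth tracks, expression matrices and sample sheets.

All coordinates are 0-based, half-open, everywhere. Readers validate on
load and fail with the offending line; writers emit canonical, sorted,
standard-compliant columns. Gzipped inputs are accepted transparently.
"""
from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# minor_cn may exceed total/2 slightly in purity-corrected real-valued calls
MINOR_CN_TOL = 0.05


class GenomicIOError(ValueError):
    """Base class for format-layer failures."""


class ParseError(GenomicIOError):
    """Malformed row; message carries the 1-based line number."""


class ValidationError(GenomicIOError):
    """Structurally parseable but contract-violating input."""


def _opener(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# copy-number segments


@dataclass(frozen=True, order=True)
class CopyNumberSegment:
    """One per-sample genomic interval with total and minor-allele copy number.

    ``minor_cn`` is the copy number of the less-abundant parental haplotype
    (``None`` when allelic information is unavailable); the major haplotype
    is ``total_cn - minor_cn``.
    """

    sample: str
    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: float | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"segment {self.sample} {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if not math.isfinite(self.total_cn) or self.total_cn < 0:
            raise ValidationError(
                f"segment {self.sample} {self.chrom}:{self.start}-{self.end}: "
                f"total_cn must be finite and >= 0, got {self.total_cn}"
            )
        if self.minor_cn is not None:
            if not math.isfinite(self.minor_cn) or self.minor_cn < 0:
                raise ValidationError(
                    f"segment {self.sample} {self.chrom}:{self.start}-{self.end}: "
                    f"minor_cn must be finite and >= 0, got {self.minor_cn}"
                )
            if self.minor_cn > self.total_cn / 2 + MINOR_CN_TOL:
                raise ValidationError(
                    f"segment {self.sample} {self.chrom}:{self.start}-{self.end}: "
                    f"minor_cn {self.minor_cn} exceeds total_cn/2 = {self.total_cn / 2}"
                )

    @property
    def major_cn(self) -> float | None:
        if self.minor_cn is None:
            return None
        return self.total_cn - self.minor_cn

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


def validate_segments(segments: Sequence[CopyNumberSegment]) -> None:
    """Reject overlapping segments within one sample/chromosome."""
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample, seg.chrom), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments for sample {sample} on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn"]


def read_seg(path) -> list[CopyNumberSegment]:
    """Read a SEG-like TSV (absolute copy number, explicit header).

    The ``minor_cn`` column is optional; missing values load as ``None`` and
    the timing stage reports such samples unusable for allelic inference.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = SEG_COLUMNS[:5]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required SEG columns {missing}")
    has_minor = "minor_cn" in df.columns
    segments = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        try:
            start, end = int(row.start), int(row.end)
            total = float(row.total_cn)
            minor = None
            if has_minor:
                raw = row.minor_cn
                if raw is not None and str(raw).strip() not in ("", "NA", "nan", "NaN"):
                    minor = float(raw)
            segments.append(
                CopyNumberSegment(str(row.sample), str(row.chrom), start, end, total, minor)
            )
        except GenomicIOError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed SEG row: {exc}") from exc
    validate_segments(segments)
    return segments


def write_seg(segments: Iterable[CopyNumberSegment], path) -> None:
    segs = sorted(segments, key=lambda s: (s.sample, s.chrom, s.start))
    validate_segments(segs)
    rows = [
        (
            s.sample,
            s.chrom,
            s.start,
            s.end,
            _fmt(s.total_cn),
            "NA" if s.minor_cn is None else _fmt(s.minor_cn),
        )
        for s in segs
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def _fmt(x: float) -> str:
    # canonical float formatting so reruns are byte-identical
    return format(float(x), ".6g")


def segments_by_sample(
    segments: Iterable[CopyNumberSegment],
) -> dict[str, list[CopyNumberSegment]]:
    out: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        out.setdefault(seg.sample, []).append(seg)
    for segs in out.values():
        segs.sort(key=lambda s: (s.chrom, s.start))
    return out


# ---------------------------------------------------------------------------
# SV junctions


@dataclass(frozen=True)
class SVJunction:
    """A breakpoint pair; each breakend has an orientation.

    '+' means the joined fragment continues toward lower coordinates from
    the breakend (fragment to the left retained); '-' means it continues
    toward higher coordinates. Ends are stored sorted by (chrom, pos).
    """

    sample: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    name: str = "."

    def __post_init__(self):
        for strand in (self.strand1, self.strand2):
            if strand not in ("+", "-"):
                raise ValidationError(f"junction {self.name}: strand {strand!r} not in {{+,-}}")
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValidationError(f"junction {self.name}: negative breakend position")
        # canonicalize: store ends sorted in genome order
        e1 = (self.chrom1, self.pos1, self.strand1)
        e2 = (self.chrom2, self.pos2, self.strand2)
        lo, hi = sorted([e1, e2], key=lambda e: (e[0], e[1]))
        object.__setattr__(self, "chrom1", lo[0])
        object.__setattr__(self, "pos1", lo[1])
        object.__setattr__(self, "strand1", lo[2])
        object.__setattr__(self, "chrom2", hi[0])
        object.__setattr__(self, "pos2", hi[1])
        object.__setattr__(self, "strand2", hi[2])

    @property
    def span(self) -> int | None:
        """Breakend distance for intrachromosomal junctions, else None."""
        if self.chrom1 != self.chrom2:
            return None
        return self.pos2 - self.pos1

    def is_deletion_consistent(self) -> bool:
        """Both breakends point outward from the bracketed interval:
        lower end '+', higher end '-', same chromosome — the signature of
        a simple copy-loss junction."""
        return (
            self.chrom1 == self.chrom2
            and self.strand1 == "+"
            and self.strand2 == "-"
        )


BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "sample",
]


def read_bedpe(path) -> list[SVJunction]:
    """Read a >= 10-column BEDPE. Breakend position is the interval start
    (point breakends; width-1 intervals accepted). An 11th column carries
    the sample identifier; without it the name column is used."""
    junctions = []
    with _opener(path) as fh:
        header = fh.readline()
        if not header:
            return junctions
        first = header.rstrip("\n").split("\t")
        lines = enumerate(fh, start=2)
        if first and first[0] not in ("chrom1", "#chrom1", "track"):
            lines = [(1, header)] + list(lines)  # headerless BEDPE
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(f"{path}:{lineno}: BEDPE needs >= 10 columns, got {len(fields)}")
            try:
                sample = fields[10] if len(fields) > 10 else fields[6]
                junctions.append(
                    SVJunction(
                        sample=sample,
                        chrom1=fields[0], pos1=int(fields[1]), strand1=fields[8],
                        chrom2=fields[3], pos2=int(fields[4]), strand2=fields[9],
                        name=fields[6],
                    )
                )
            except GenomicIOError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BEDPE row: {exc}") from exc
    return junctions


def write_bedpe(junctions: Iterable[SVJunction], path) -> None:
    rows = []
    for j in sorted(junctions, key=lambda j: (j.sample, j.chrom1, j.pos1, j.pos2, j.name)):
        rows.append(
            (
                j.chrom1, j.pos1, j.pos1 + 1,
                j.chrom2, j.pos2, j.pos2 + 1,
                j.name, ".", j.strand1, j.strand2, j.sample,
            )
        )
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(path, sep="\t", index=False)


def junctions_by_sample(junctions: Iterable[SVJunction]) -> dict[str, list[SVJunction]]:
    out: dict[str, list[SVJunction]] = {}
    for j in junctions:
        out.setdefault(j.sample, []).append(j)
    for js in out.values():
        js.sort(key=lambda j: (j.chrom1, j.pos1, j.pos2))
    return out


# ---------------------------------------------------------------------------
# gene loci


@dataclass(frozen=True)
class GeneLocus:
    """A named gene interval, optionally with a sub-window of interest
    (e.g. the exon1-intron1 regulatory window of the target gene)."""

    name: str
    chrom: str
    start: int
    end: int
    window: tuple[int, int] | None = None

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(f"locus {self.name}: require 0 <= start < end")
        if self.window is not None:
            ws, we = self.window
            if not (self.start <= ws < we <= self.end):
                raise ValidationError(
                    f"locus {self.name}: window [{ws},{we}) not contained in "
                    f"[{self.start},{self.end})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def effective_window(self) -> tuple[int, int]:
        return self.window if self.window is not None else (self.start, self.end)

    def distance_to(self, pos: int) -> int:
        """Distance from a position to the locus interval (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


def read_bed(path) -> list[GeneLocus]:
    """Read loci from BED (>= 4 columns). When thickStart/thickEnd (columns
    7-8) are present and differ from the full interval they define the
    locus sub-window."""
    loci = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED needs >= 4 columns for named loci")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                window = None
                if len(fields) >= 8:
                    ws, we = int(fields[6]), int(fields[7])
                    if (ws, we) != (start, end):
                        window = (ws, we)
                loci.append(GeneLocus(name, chrom, start, end, window))
            except GenomicIOError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED row: {exc}") from exc
    return loci


def write_bed(loci: Iterable[GeneLocus], path) -> None:
    with open(path, "w") as fh:
        for loc in sorted(loci, key=lambda l: (l.chrom, l.start)):
            ws, we = loc.effective_window()
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.name}\t0\t+\t{ws}\t{we}\n"
            )


# ---------------------------------------------------------------------------
# read-depth tracks


@dataclass
class ReadDepthTrack:
    """Per-sample tumor/normal depth ratios over uniform fixed-width bins
    (conventionally 200 bp; the last bin may be short)."""

    sample: str
    chrom: str
    starts: np.ndarray  # bin start coordinates, sorted
    ends: np.ndarray
    ratios: np.ndarray  # depth ratio >= 0

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.ratios = np.asarray(self.ratios, dtype=float)
        n = len(self.starts)
        if not (len(self.ends) == len(self.ratios) == n):
            raise ValidationError(f"track {self.sample}: ragged bin arrays")
        if n == 0:
            return
        if np.any(self.ends <= self.starts):
            raise ValidationError(f"track {self.sample}: empty or inverted bin")
        if np.any(np.diff(self.starts) <= 0) or np.any(self.starts[1:] < self.ends[:-1]):
            raise ValidationError(f"track {self.sample}: bins unsorted or overlapping")
        widths = self.ends - self.starts
        if n > 1 and len(np.unique(widths[:-1])) > 1:
            raise ValidationError(f"track {self.sample}: mixed bin widths")
        if n > 1 and widths[-1] > widths[0]:
            raise ValidationError(f"track {self.sample}: last bin wider than bin size")
        if np.any(~np.isfinite(self.ratios)) or np.any(self.ratios < 0):
            raise ValidationError(f"track {self.sample}: ratios must be finite and >= 0")

    @property
    def bin_size(self) -> int:
        return int(self.ends[0] - self.starts[0]) if len(self.starts) else 0

    def mean_ratio(self, start: int, end: int) -> float:
        """Overlap-weighted mean ratio over [start, end); NaN if uncovered."""
        ov = np.minimum(self.ends, end) - np.maximum(self.starts, start)
        ov = np.clip(ov, 0, None)
        total = ov.sum()
        if total == 0:
            return float("nan")
        return float((self.ratios * ov).sum() / total)

    def covers(self, start: int, end: int, min_frac: float = 0.9) -> bool:
        ov = np.clip(np.minimum(self.ends, end) - np.maximum(self.starts, start), 0, None)
        return ov.sum() >= min_frac * (end - start)


def read_bedgraph(path, sample: str | None = None) -> ReadDepthTrack:
    if sample is None:
        sample = Path(path).name
        for suffix in (".gz", ".bedgraph", ".bedGraph", ".bg"):
            if sample.endswith(suffix):
                sample = sample[: -len(suffix)]
    chroms, starts, ends, ratios = [], [], [], []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed value: {exc}") from exc
            if math.isnan(value):
                raise ParseError(f"{path}:{lineno}: NaN depth ratio")
            chroms.append(fields[0])
            starts.append(int(fields[1]))
            ends.append(int(fields[2]))
            ratios.append(value)
    if len(set(chroms)) > 1:
        raise ValidationError(f"{path}: multi-chromosome depth tracks unsupported")
    chrom = chroms[0] if chroms else ""
    return ReadDepthTrack(sample, chrom, np.array(starts), np.array(ends), np.array(ratios))


def write_bedgraph(track: ReadDepthTrack, path) -> None:
    with open(path, "w") as fh:
        for s, e, r in zip(track.starts, track.ends, track.ratios):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{_fmt(r)}\n")


# ---------------------------------------------------------------------------
# expression matrix and sample sheet


@dataclass
class ExpressionTable:
    """Features (genes/transcripts) x samples, FPKM units, non-negative."""

    values: pd.DataFrame  # index = feature id, columns = sample id

    def __post_init__(self):
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature identifiers: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes}")
        arr = df.to_numpy(dtype=float)
        bad = np.argwhere(~np.isfinite(arr) | (arr < 0))
        if len(bad):
            r, c = bad[0]
            raise ValidationError(
                f"expression value at feature {df.index[r]!r}, sample "
                f"{df.columns[c]!r} is negative or not finite: {arr[r, c]}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)


def read_expression(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionTable(df.astype(float))


def write_expression(table: ExpressionTable, path) -> None:
    out = table.values.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class SampleTable:
    """Sample sheet: sample id, tumor type, patient (for collapsing
    multi-sample patients to per-patient means before model fits)."""

    table: pd.DataFrame  # columns: sample, tumor_type, patient

    def __post_init__(self):
        df = self.table
        for col in ("sample", "tumor_type"):
            if col not in df.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        if "patient" not in df.columns:
            df = df.assign(patient=df["sample"])
            self.table = df
        if df["sample"].duplicated().any():
            dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes}")

    def tumor_type(self) -> pd.Series:
        return self.table.set_index("sample")["tumor_type"]

    def patient(self) -> pd.Series:
        return self.table.set_index("sample")["patient"]


def read_samples(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(df)


def write_samples(samples: SampleTable, path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)
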