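"""Readers and writers for the plain-text formats the toolkit consumes.

Supported formats:

* per-base coverage tables in the BBMap ``basecov`` dialect (0-based
  positions, optional ``#`` header) or the ``samtools depth`` dialect
  (1-based positions, zero rows may be omitted);
* FASTQ, plain or gzip-compressed;
* k-mer histograms in the Jellyfish ``histo`` two-column text format;
* BED3(+name) locus definitions.

All coordinates are normalised to 0-based, half-open on ingestion.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ParseError

__all__ = [
    "CoverageSet",
    "LibraryStats",
    "KmerHistogram",
    "read_basecov",
    "write_basecov",
    "scan_reads",
    "iter_fastq",
    "write_fastq",
    "read_histogram",
    "write_histogram",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
]

_DIALECTS = {
    "bbmap": "bbmap_basecov",
    "bbmap_basecov": "bbmap_basecov",
    "samtools": "samtools_depth",
    "samtools_depth": "samtools_depth",
}


@dataclass
class CoverageSet:
    """Per-locus arrays of per-base read depth.

    ``loci`` maps locus id -> integer depth array, one entry per base,
    0-based internal coordinates.  Insertion order is preserved and is the
    order of first appearance in the source file.
    """

    loci: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, arr in self.loci.items():
            arr = np.asarray(arr)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"locus {name!r}: depth array must be 1-D and non-empty")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(arr == np.floor(arr)):
                    raise ValueError(f"locus {name!r}: depths must be integers")
                arr = arr.astype(np.int64)
            if np.any(arr < 0):
                raise ValueError(f"locus {name!r}: negative depth")
            self.loci[name] = arr.astype(np.int64)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[str]:
        return iter(self.loci)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.loci[key]

    def items(self):
        return self.loci.items()

    def lengths(self) -> dict[str, int]:
        return {name: int(arr.size) for name, arr in self.loci.items()}


@dataclass
class LibraryStats:
    """Read-count accounting for a sequencing library.

    ``n_reads`` (N) and ``total_bases`` (B) feed the Lander-Waterman
    conversion G = B / C; the mitochondrial fields support the "No Mito"
    accounting in which reads matching the mitochondrial genome are
    subtracted before estimating nuclear genome size.
    """

    n_reads: int
    total_bases: int
    n_mito_reads: int = 0
    mito_bases: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0 or self.total_bases < 0:
            raise ValueError("read and base counts must be non-negative")
        if self.n_reads > 0 and self.total_bases < self.n_reads:
            raise ValueError("total_bases < n_reads: reads must have length >= 1")
        if self.n_mito_reads > self.n_reads:
            raise ValueError("n_mito_reads exceeds n_reads")
        if self.mito_bases > self.total_bases:
            raise ValueError("mito_bases exceeds total_bases")

    @property
    def mean_read_length(self) -> float:
        """Mean read length L = B / N (0.0 for an empty library)."""
        if self.n_reads == 0:
            return 0.0
        return self.total_bases / self.n_reads

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "total_bases": self.total_bases,
            "mean_read_length": self.mean_read_length,
            "n_mito_reads": self.n_mito_reads,
            "mito_bases": self.mito_bases,
        }


@dataclass
class KmerHistogram:
    """Counts ``h_i`` of distinct canonical k-mers observed exactly i times.

    ``counts`` maps multiplicity (>= 1) to the number of distinct k-mers at
    that multiplicity.  The total mass ``T = sum(i * h_i)`` equals the number
    of k-mer tokens ingested by the counter.
    """

    k: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd integer >= 3, got {self.k}")
        clean: dict[int, int] = {}
        for mult in sorted(self.counts):
            cnt = int(self.counts[mult])
            if mult < 1:
                raise ValueError(f"multiplicity must be >= 1, got {mult}")
            if cnt < 0:
                raise ValueError(f"negative count at multiplicity {mult}")
            if cnt > 0:
                clean[int(mult)] = cnt
        self.counts = clean

    @property
    def total_mass(self) -> int:
        """T = sum over i of i * h_i (number of ingested k-mer tokens)."""
        return int(sum(i * h for i, h in self.counts.items()))

    @property
    def n_distinct(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def max_multiplicity(self) -> int:
        return max(self.counts) if self.counts else 0

    def to_dense(self) -> np.ndarray:
        """Dense array ``d`` with ``d[i] = h_i`` (index 0 unused)."""
        dense = np.zeros(self.max_multiplicity + 1, dtype=np.int64)
        for i, h in self.counts.items():
            dense[i] = h
        return dense


# ---------------------------------------------------------------------------
# per-base coverage


def _norm_dialect(dialect: str) -> str:
    try:
        return _DIALECTS[dialect.lower().replace("-", "_")]
    except KeyError:
        raise ValueError(
            f"unknown coverage dialect {dialect!r}; expected one of {sorted(set(_DIALECTS))}"
        ) from None


def read_basecov(
    path: str | Path,
    dialect: str = "bbmap_basecov",
    locus_lengths: Mapping[str, int] | None = None,
) -> CoverageSet:
    """Read a per-base coverage file into a :class:`CoverageSet`.

    ``bbmap_basecov`` lines are ``ref<TAB>pos0<TAB>depth`` with an optional
    leading ``#`` header; ``samtools_depth`` lines are ``ref<TAB>pos1<TAB>
    depth`` (1-based) and positions absent from the file are taken as depth
    0.  Records for different loci may interleave, but positions within a
    locus must be strictly increasing.

    When ``locus_lengths`` is given (e.g. from a BED of reference loci) the
    declared length wins and trailing zero-depth positions are padded.
    """
    dialect = _norm_dialect(dialect)
    offset = 0 if dialect == "bbmap_basecov" else 1
    depths: dict[str, list[int]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns, got {len(fields)}")
            ref = "\t".join(fields[:-2]) if "\t" in line else " ".join(fields[:-2])
            try:
                pos = int(fields[-2]) - offset
                depth = int(fields[-1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer position or depth") from None
            if pos < 0:
                raise ParseError(f"{path}: line {lineno}: position underflows 0-based coordinates")
            if depth < 0:
                raise ParseError(f"{path}: line {lineno}: negative depth")
            arr = depths.setdefault(ref, [])
            if pos < len(arr):
                raise ParseError(
                    f"{path}: line {lineno}: non-monotone position {pos + offset} for locus {ref!r}"
                )
            if pos > len(arr):  # gap: absent positions are depth 0
                arr.extend([0] * (pos - len(arr)))
            arr.append(depth)
    if not depths:
        raise ParseError(f"{path}: no coverage records found")
    loci: dict[str, np.ndarray] = {}
    for ref, arr in depths.items():
        if locus_lengths is not None and ref in locus_lengths:
            declared = int(locus_lengths[ref])
            if declared < len(arr):
                raise ParseError(
                    f"{path}: locus {ref!r} has {len(arr)} positions but declared length {declared}"
                )
            arr = arr + [0] * (declared - len(arr))
        loci[ref] = np.asarray(arr, dtype=np.int64)
    return CoverageSet(loci)


def write_basecov(cov: CoverageSet, path: str | Path, dialect: str = "bbmap_basecov") -> None:
    """Write a :class:`CoverageSet` in either coverage dialect.

    Every position is emitted (including zero-depth rows) so that
    write -> read round-trips losslessly in both dialects.
    """
    dialect = _norm_dialect(dialect)
    offset = 0 if dialect == "bbmap_basecov" else 1
    with open(path, "w") as fh:
        if dialect == "bbmap_basecov":
            fh.write("#RefName\tPosition\tCoverage\n")
        for name, arr in cov.items():
            for pos, depth in enumerate(arr.tolist()):
                fh.write(f"{name}\t{pos + offset}\t{depth}\n")


# ---------------------------------------------------------------------------
# FASTQ


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(paths: str | Path | Sequence[str | Path]) -> Iterator[tuple[str, str, str]]:
    """Yield ``(title, sequence, quality)`` tuples across one or more FASTQ files."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    for path in paths:
        n = 0
        try:
            with _open_maybe_gzip(path) as fh:
                for rec in FastqGeneralIterator(fh):
                    n += 1
                    yield rec
        except ValueError as exc:  # Biopython signals truncation/corruption
            raise ParseError(f"{path}: bad FASTQ record after record {n}: {exc}") from exc


def scan_reads(paths: str | Path | Sequence[str | Path]) -> LibraryStats:
    """Count reads and bases across FASTQ files (N, B and L = B/N)."""
    n_reads = 0
    total_bases = 0
    for _title, seq, _qual in iter_fastq(paths):
        n_reads += 1
        total_bases += len(seq)
    return LibraryStats(n_reads=n_reads, total_bases=total_bases)


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write ``(title, sequence, quality)`` records; returns the record count."""
    n = 0
    with _open_maybe_gzip(path, "wt") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# k-mer histograms (Jellyfish "histo" text format)

_K_HEADER = re.compile(r"#\s*k\s*=\s*(\d+)")


def read_histogram(path: str | Path, k: int | None = None) -> KmerHistogram:
    """Read a two-column multiplicity/count histogram.

    ``k`` may be carried in a ``# k=21`` comment line; otherwise the caller
    must supply it.  Duplicate multiplicity rows are an error.
    """
    path = Path(path)
    counts: dict[int, int] = {}
    file_k: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _K_HEADER.search(line)
                if m:
                    file_k = int(m.group(1))
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
            try:
                mult, cnt = int(fields[0]), int(fields[1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer value") from None
            if mult in counts:
                raise ParseError(f"{path}: line {lineno}: duplicate multiplicity {mult}")
            counts[mult] = cnt
    use_k = file_k if file_k is not None else k
    if use_k is None:
        raise ValueError(f"{path}: no '# k=' header; pass k explicitly")
    if k is not None and file_k is not None and k != file_k:
        raise ValueError(f"{path}: header says k={file_k} but caller passed k={k}")
    return KmerHistogram(k=use_k, counts=counts)


def write_histogram(h: KmerHistogram, path: str | Path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# k={h.k}\n")
        for mult in sorted(h.counts):
            fh.write(f"{mult} {h.counts[mult]}\n")


# ---------------------------------------------------------------------------
# BED / FASTA


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED3(+name) into ``(chrom, start, end, name)`` tuples (0-based, half-open)."""
    path = Path(path)
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer interval") from None
            if not 0 <= start < end:
                raise ParseError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else f"{fields[0]}:{start}-{end}"
            out.append((fields[0], start, end, name))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA file into an ordered ``{name: sequence}`` dict."""
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                if name is None:
                    raise ParseError(f"{path}: sequence data before first FASTA header")
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    if not seqs:
        raise ParseError(f"{path}: empty FASTA")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
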