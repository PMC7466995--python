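"""Canonical k-mer counting and spectrum-based genome-size estimation.

The counter is exact: every k-mer window free of non-ACGT characters is
2-bit encoded, canonicalised against its reverse complement (lexicographic
minimum, hence odd k only), and tallied with vectorised numpy.  It is meant
for desk-scale libraries (up to ~1e8 windows held as 8-byte codes), not for
streaming whole HiSeq lanes.

The estimator is the classic spectrum method: choose an error cutoff at the
first valley of the histogram, locate the coverage peak, and divide the
retained k-mer mass by the peak depth.  For shotgun reads with negligible
artifacts the spectrum approximates a Poisson distribution centered on the
k-mer-level sequencing depth; the divisor is therefore taken as the center
of a truncated Poisson fitted around the modal bin (``peak_depth``), which
avoids the up-to-half-unit quantisation of the integer mode.  Base-level
depth relates to k-mer depth through C_b = lambda * L / (L - k + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .errors import EstimationError
from .io_formats import KmerHistogram, iter_fastq

__all__ = [
    "KmerEstimate",
    "count_kmers",
    "count_kmer_seqs",
    "error_cutoff",
    "find_peak",
    "PeakResult",
    "kmer_genome_size",
    "k_sweep",
    "encode_seq",
    "canonical_kmer_codes",
    "kmer_set",
    "shared_kmer_counts",
]

logger = logging.getLogger(__name__)

MAX_K = 31  # 2 bits/base in a uint64, with headroom for the sentinel logic

# base codes: A=0 C=1 G=2 T=3; anything else = 4 (invalid sentinel)
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

_SENTINEL = np.uint8(4)


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError(f"k must be odd (even k admits reverse-complement palindromes): {k}")
    if not 3 <= k <= MAX_K:
        raise ValueError(f"k must be in [3, {MAX_K}], got {k}")


def encode_seq(seq: str | bytes) -> np.ndarray:
    """2-bit-encode a sequence; non-ACGT characters become the invalid code 4."""
    if isinstance(seq, str):
        seq = seq.encode("ascii", errors="replace")
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def canonical_kmer_codes(codes: np.ndarray, k: int, return_mask: bool = False):
    """Canonical k-mer codes of every valid window of a code array.

    ``codes`` may contain invalid entries (>= 4), e.g. sentinels separating
    concatenated reads; windows touching them are dropped (or masked out
    when ``return_mask`` is set, in which case codes for *all* windows are
    returned together with the validity mask).
    """
    _check_k(k)
    codes = np.asarray(codes, dtype=np.uint8)
    n = codes.size - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return (empty, np.empty(0, dtype=bool)) if return_mask else empty
    invalid = (codes >= 4).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(invalid)])
    valid = (csum[k:] - csum[:-k]) == 0
    b = codes.astype(np.uint64)
    b[codes >= 4] = 0  # masked out by `valid`; keeps shifts well-defined
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | b[j : j + n]
        rc |= (three - b[j : j + n]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rc)
    if return_mask:
        return canon, valid
    return canon[valid]


def _hist_from_canon(canon: np.ndarray, k: int) -> KmerHistogram:
    if canon.size == 0:
        return KmerHistogram(k=k, counts={})
    _uniq, per_kmer = np.unique(canon, return_counts=True)
    mult, h = np.unique(per_kmer, return_counts=True)
    return KmerHistogram(k=k, counts=dict(zip(mult.tolist(), h.tolist())))


def _canon_chunks_from_seqs(seqs: Iterable[str], k: int, chunk_bases: int = 8_000_000):
    """Yield canonical-code arrays from sequences, concatenated with sentinels."""
    buf: list[str] = []
    size = 0
    short = 0
    for seq in seqs:
        if len(seq) < k:
            short += 1
        buf.append(seq)
        size += len(seq) + 1
        if size >= chunk_bases:
            yield canonical_kmer_codes(encode_seq("N".join(buf)), k)
            buf, size = [], 0
    if buf:
        yield canonical_kmer_codes(encode_seq("N".join(buf)), k)
    if short:
        warnings.warn(f"{short} reads shorter than k={k} contributed zero k-mer windows")


def count_kmer_seqs(seqs: Iterable[str], k: int) -> KmerHistogram:
    """Count canonical k-mers over in-memory sequences."""
    _check_k(k)
    chunks = list(_canon_chunks_from_seqs(seqs, k))
    canon = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    return _hist_from_canon(canon, k)


def count_kmers(paths: str | Path | Sequence[str | Path], k: int) -> KmerHistogram:
    """Count canonical k-mers across FASTQ files into a :class:`KmerHistogram`.

    Windows containing non-ACGT characters are skipped, so the histogram
    mass T equals ``sum(max(0, len - k + 1))`` minus skipped windows.
    """
    return count_kmer_seqs((seq for _t, seq, _q in iter_fastq(paths)), k)


def kmer_set(seq: str | np.ndarray, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of a sequence (e.g. a mito reference)."""
    codes = encode_seq(seq) if isinstance(seq, (str, bytes)) else np.asarray(seq, dtype=np.uint8)
    return np.unique(canonical_kmer_codes(codes, k))


def shared_kmer_counts(
    seqs: Sequence[str], ref_kmers: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-read counts of canonical k-mers shared with a reference k-mer set.

    Returns ``(shared, windows)`` arrays, one entry per read, where
    ``windows`` is the number of valid k-mer windows in the read.
    """
    _check_k(k)
    shared = np.zeros(len(seqs), dtype=np.int64)
    windows = np.zeros(len(seqs), dtype=np.int64)
    chunk: list[str] = []
    idx0 = 0
    size = 0

    def _flush(chunk: list[str], idx0: int) -> None:
        if not chunk:
            return
        flat = encode_seq("N".join(chunk))
        canon, valid = canonical_kmer_codes(flat, k, return_mask=True)
        hit = valid & np.isin(canon, ref_kmers)
        cs_hit = np.concatenate([[0], np.cumsum(hit)])
        cs_valid = np.concatenate([[0], np.cumsum(valid)])
        pos = 0
        for j, seq in enumerate(chunk):
            lo = pos
            hi = max(pos, pos + len(seq) - k + 1)
            hi = min(hi, canon.size)
            shared[idx0 + j] = cs_hit[hi] - cs_hit[lo]
            windows[idx0 + j] = cs_valid[hi] - cs_valid[lo]
            pos += len(seq) + 1

    for seq in seqs:
        chunk.append(seq)
        size += len(seq) + 1
        if size >= 8_000_000:
            _flush(chunk, idx0)
            idx0 += len(chunk)
            chunk, size = [], 0
    _flush(chunk, idx0)
    return shared, windows


# ---------------------------------------------------------------------------
# spectrum analysis


def error_cutoff(h: KmerHistogram) -> int:
    """Smallest retained multiplicity c0: the first valley of the spectrum.

    c0 is the smallest i >= 2 with ``h_i <= h_{i+1}`` before the global
    maximum; absent multiplicities count as zero.  If the spectrum decays
    monotonically to its maximum at 1 there is no valley and c0 = 1 (with a
    warning): error and signal k-mers cannot be separated.
    """
    if not h.counts:
        raise EstimationError("empty k-mer histogram")
    dense = h.to_dense()
    for i in range(2, dense.size - 1):
        if dense[i] <= dense[i + 1]:
            logger.info("error cutoff c0=%d (first valley of the spectrum)", i)
            return i
    warnings.warn("monotone spectrum with no valley; using c0=1 (no error exclusion)")
    return 1


@dataclass(frozen=True)
class PeakResult:
    """Coverage peak(s) of a k-mer spectrum.

    ``primary`` is the modal multiplicity at or above the error cutoff;
    ``secondary`` (if any) is a local maximum near twice or half the primary,
    the signature of a heterozygous diploid spectrum.  ``lam`` is the peak
    selected for downstream use (the homozygous-mode option picks the
    larger-coverage peak when a secondary exists).
    """

    primary: int
    secondary: int | None
    lam: int


def find_peak(h: KmerHistogram, c0: int = 1, ploidy_peak: str = "primary") -> PeakResult:
    """Locate the coverage peak lambda = argmax_{i>=c0} h_i (ties -> smallest i).

    A secondary peak is searched within +/-20% of 2*lambda and of lambda/2;
    a candidate must rise above the valley separating it from the primary
    peak and reach at least 5% of the primary's height.
    """
    if ploidy_peak not in ("primary", "homozygous"):
        raise ValueError(f"ploidy_peak must be 'primary' or 'homozygous', got {ploidy_peak!r}")
    dense = h.to_dense()
    if c0 >= dense.size or not np.any(dense[c0:] > 0):
        raise EstimationError(f"no k-mers at multiplicity >= c0={c0}")
    lam = int(np.argmax(dense[c0:])) + c0  # argmax takes the first (smallest) on ties

    def _candidate(center: float) -> int | None:
        lo = max(c0, int(np.ceil(0.8 * center)))
        hi = min(dense.size - 1, int(np.floor(1.2 * center)))
        if hi < lo or (lo <= lam <= hi):
            return None
        window = dense[lo : hi + 1]
        if not np.any(window > 0):
            return None
        cand = int(np.argmax(window)) + lo
        a, b = sorted((lam, cand))
        valley = int(dense[a + 1 : b].min()) if b - a > 1 else int(min(dense[a], dense[b]))
        # a genuine second mode must rise above the valley separating it from
        # the primary peak by more than counting noise (~sqrt(h)), and reach
        # at least 5% of the primary's height
        rise = dense[cand] - valley
        noise = np.sqrt(max(1.0, dense[cand] + valley))
        if rise > 3.0 * noise and dense[cand] >= 0.05 * dense[lam]:
            return cand
        return None

    # prefer the doubled-coverage (homozygous) companion, else the halved one
    secondary = _candidate(2.0 * lam)
    if secondary is None:
        secondary = _candidate(0.5 * lam)
    chosen = lam
    if ploidy_peak == "homozygous" and secondary is not None:
        chosen = max(lam, secondary)
    if secondary is not None:
        logger.info("spectrum peaks: primary=%d secondary=%d (using %d)", lam, secondary, chosen)
    return PeakResult(primary=lam, secondary=secondary, lam=chosen)


def _refine_peak_depth(dense: np.ndarray, lam: int, c0: int) -> float:
    """Center of a truncated Poisson fitted to the histogram around ``lam``.

    The spectrum near the coverage peak approximates a Poisson distribution
    whose *mean* is the sequencing depth; the integer mode undershoots that
    mean by up to half a unit (and ties when the depth is integral).  Fitting
    within +/- 2*sqrt(lam) of the mode recovers the center at sub-unit
    resolution.  Degenerate windows (a single occupied bin) return ``lam``.
    """
    w = max(3, int(np.ceil(2.0 * np.sqrt(lam))))
    lo = max(c0, lam - w, 1)
    hi = min(dense.size - 1, lam + w)
    ii = np.arange(lo, hi + 1)
    hh = dense[lo : hi + 1].astype(np.float64)
    if np.count_nonzero(hh) <= 1:
        return float(lam)

    def nll(mu: float) -> float:
        logpmf = ii * np.log(mu) - mu - gammaln(ii + 1)
        return -float(np.dot(hh, logpmf - logsumexp(logpmf)))

    res = minimize_scalar(nll, bounds=(max(0.5, lo - 0.5), hi + 0.5), method="bounded")
    if not res.success:  # pragma: no cover - bounded Brent essentially always converges
        return float(lam)
    return float(res.x)


@dataclass
class KmerEstimate:
    """Result of the spectrum genome-size estimator for one value of k."""

    k: int
    error_cutoff: int
    peak: int
    peak_depth: float
    secondary_peak: int | None
    retained_mass: int
    n_distinct_retained: int
    size_bases: float
    base_coverage: float | None = None
    params: dict = field(default_factory=dict)

    @property
    def size_mb(self) -> float:
        return self.size_bases / 1e6

    def to_dict(self) -> dict:
        return {
            "method": "kmer",
            "k": self.k,
            "error_cutoff": self.error_cutoff,
            "peak": self.peak,
            "peak_depth": self.peak_depth,
            "secondary_peak": self.secondary_peak,
            "retained_mass": self.retained_mass,
            "n_distinct_retained": self.n_distinct_retained,
            "size_bases": self.size_bases,
            "size_mb": self.size_mb,
            "base_coverage": self.base_coverage,
            "params": self.params,
        }


def kmer_genome_size(
    h: KmerHistogram,
    c0: int | None = None,
    peak: PeakResult | int | None = None,
    read_length: float | None = None,
    ploidy_peak: str = "primary",
) -> KmerEstimate:
    """Estimate haploid genome size from a k-mer spectrum.

    G = (retained mass T_r) / (peak depth), with T_r the k-mer mass at
    multiplicities >= c0 and the peak depth the fitted center of the
    coverage peak (equal to the modal multiplicity for degenerate spectra).
    When the mean read length L is known, the base-level coverage
    C_b = peak_depth * L / (L - k + 1) is attached.
    """
    if c0 is None:
        c0 = error_cutoff(h)
    if peak is None:
        peak = find_peak(h, c0, ploidy_peak=ploidy_peak)
    if isinstance(peak, int):
        peak = PeakResult(primary=peak, secondary=None, lam=peak)
    lam = peak.lam
    if lam < c0 or c0 < 1:
        raise EstimationError(f"invalid cutoff/peak combination: c0={c0}, lambda={lam}")
    if lam == 0:
        raise EstimationError("zero coverage peak")
    dense = h.to_dense()
    retained = {i: cnt for i, cnt in h.counts.items() if i >= c0}
    t_r = sum(i * cnt for i, cnt in retained.items())
    if t_r == 0:
        raise EstimationError("no retained k-mer mass above the error cutoff")
    depth = _refine_peak_depth(dense, lam, c0)
    size = t_r / depth
    c_b = None
    if read_length is not None and read_length > h.k - 1:
        c_b = depth * read_length / (read_length - h.k + 1)
    return KmerEstimate(
        k=h.k,
        error_cutoff=c0,
        peak=peak.primary,
        peak_depth=depth,
        secondary_peak=peak.secondary,
        retained_mass=int(t_r),
        n_distinct_retained=int(sum(retained.values())),
        size_bases=size,
        base_coverage=c_b,
        params={"ploidy_peak": ploidy_peak},
    )


def k_sweep(
    reads: str | Path | Sequence[str | Path],
    ks: Sequence[int],
    read_length: float | None = None,
    c0: int | None = None,
    ploidy_peak: str = "primary",
) -> pd.DataFrame:
    """Run the spectrum estimator for several values of k.

    Returns one row per k with the estimate fields, or an ``error`` message
    for values of k that fail; a single failing k does not abort the sweep.
    """
    uniq: list[int] = []
    for k in ks:
        if k in uniq:
            warnings.warn(f"duplicate k={k} in sweep; ignored")
        else:
            uniq.append(k)
    rows = []
    for k in uniq:
        row: dict = {"k": k}
        try:
            h = count_kmers(reads, k)
            est = kmer_genome_size(h, c0=c0, read_length=read_length, ploidy_peak=ploidy_peak)
            row.update(
                error_cutoff=est.error_cutoff,
                peak=est.peak,
                peak_depth=est.peak_depth,
                secondary_peak=est.secondary_peak,
                retained_mass=est.retained_mass,
                size_bases=est.size_bases,
                size_mb=est.size_mb,
                base_coverage=est.base_coverage,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - per-k failures become table rows
            row["error"] = str(exc)
            logger.warning("k=%d failed: %s", k, exc)
        rows.append(row)
    return pd.DataFrame(rows)
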