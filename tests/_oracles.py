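"""Independent brute-force reference implementations.

These are deliberately written in plain Python (lists, dicts, string
slicing) with no shared code paths into covsize, so that agreement between
the two is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_trim(profile: list[int], t: int) -> list[int] | None:
    """Slice off t bases per end; None when the locus is untrimmable."""
    if len(profile) <= 2 * t:
        return None
    return list(profile[t : len(profile) - t])


def naive_quantile(values: list[float], q: float) -> float:
    """Linear-interpolation quantile between order statistics."""
    srt = sorted(values)
    pos = (len(srt) - 1) * q
    lo = int(pos)
    hi = min(lo + 1, len(srt) - 1)
    frac = pos - lo
    return srt[lo] + frac * (srt[hi] - srt[lo])


def naive_iqr_keep(values: list[float], m: float = 3.0) -> list[int]:
    """Indices within m interquartile ranges of the median."""
    if len(values) < 4:
        return list(range(len(values)))
    q1 = naive_quantile(values, 0.25)
    med = naive_quantile(values, 0.50)
    q3 = naive_quantile(values, 0.75)
    iqr = q3 - q1
    return [i for i, v in enumerate(values) if abs(v - med) <= m * iqr]


def naive_estimate_coverage(
    loci: dict[str, list[int]], t: int, m: float, averaging: str = "locus_mean"
) -> tuple[float, set[str]]:
    """Trim -> per-locus means -> independent IQR filters -> average.

    Returns (C, kept locus ids).
    """
    names, means, lengths, sums = [], [], [], []
    for name, profile in loci.items():
        trimmed = naive_trim(list(profile), t)
        if trimmed is None:
            continue
        names.append(name)
        means.append(sum(trimmed) / len(trimmed))
        lengths.append(float(len(trimmed)))
        sums.append(float(sum(trimmed)))
    keep_cov = set(naive_iqr_keep(means, m))
    keep_len = set(naive_iqr_keep(lengths, m))
    kept = sorted(keep_cov & keep_len)
    if not kept:
        raise ValueError("no loci kept")
    if averaging == "locus_mean":
        c = sum(means[i] for i in kept) / len(kept)
    else:
        c = sum(sums[i] for i in kept) / sum(lengths[i] for i in kept)
    return c, {names[i] for i in kept}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def naive_count_kmers(seqs: list[str], k: int) -> dict[int, int]:
    """Canonical k-mer histogram by string slicing."""
    counts: dict[str, int] = {}
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if any(b not in _COMPLEMENT for b in kmer):
                continue
            canon = min(kmer, revcomp(kmer))
            counts[canon] = counts.get(canon, 0) + 1
    hist: dict[int, int] = {}
    for cnt in counts.values():
        hist[cnt] = hist.get(cnt, 0) + 1
    return hist


def naive_basecov_tally(
    lines: list[str], one_based: bool = False
) -> dict[str, list[int]]:
    """Line-by-line tally of a coverage file into dense per-locus arrays."""
    out: dict[str, dict[int, int]] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ref, pos, depth = line.split()
        out.setdefault(ref, {})[int(pos) - (1 if one_based else 0)] = int(depth)
    dense: dict[str, list[int]] = {}
    for ref, sparse in out.items():
        n = max(sparse) + 1
        dense[ref] = [sparse.get(i, 0) for i in range(n)]
    return dense
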