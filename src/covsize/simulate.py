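"""Synthetic genome, read and coverage simulator with known ground truth.

The generator emulates the data a shallow shotgun sequencing project hands
to the two estimators, so that each can be validated by parameter recovery
without any external downloads:

* a haploid background genome with a target GC content, optional
  near-identical repeat families, and a set of single-copy loci recorded in
  BED;
* an optional second haplotype carrying heterozygous SNPs (the origin of
  bimodal k-mer spectra);
* an optional mitochondrial contaminant sequence contributing a fixed
  fraction of reads;
* uniform-start, substitution-error shotgun reads with logged origins;
* per-locus coverage projected under a mapper-style minimum-overlap
  contract (a read counts toward a locus only if at least a fraction ``f``
  of it lies inside), which reproduces the depressed coverage ramps at
  locus flanks that flank trimming corrects.

All randomness flows from one seed, expanded into independent per-stage
substreams so regenerating one stage never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError
from .io_formats import CoverageSet, LibraryStats, write_basecov, write_bed, write_fasta

__all__ = [
    "RepeatFamily",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "make_genome",
    "make_diploid",
    "simulate_reads",
    "project_locus_coverage",
    "run_simulation",
    "write_outputs",
]

logger = logging.getLogger(__name__)

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_STAGES = ("genome", "repeats", "loci", "diploid", "mito", "reads", "errors")


@dataclass(frozen=True)
class RepeatFamily:
    """A repeat family: ``copy_number`` copies of a ``unit_length``-bp unit,
    each copy independently mutated at rate ``divergence``."""

    unit_length: int
    copy_number: int
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.unit_length < 1 or self.copy_number < 0:
            raise ValueError("unit_length >= 1 and copy_number >= 0 required")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation.

    Defaults are the reference validation scenario: a 1 Mb homozygous,
    repeat-free genome carrying 40 single-copy loci of 1.5 kb, sequenced
    error-free at 30x with 100 bp reads, and a strict full-overlap mapping
    contract (f = 1) that produces the locus flank ramps.
    """

    genome_size: int = 1_000_000
    gc: float = 0.4
    n_loci: int = 40
    locus_length: int = 1500
    repeat_spec: tuple[RepeatFamily, ...] = ()
    het_rate: float = 0.0
    mito_size: int = 16_000
    mito_fraction: float = 0.0
    depth: float = 30.0
    read_length: int = 100
    error_rate: float = 0.0
    min_overlap_frac: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc", "het_rate", "error_rate", "mito_fraction", "min_overlap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_size < 1 or self.read_length < 1:
            raise ValueError("genome_size and read_length must be >= 1")
        if self.n_loci < 0 or self.locus_length < 1 or self.mito_size < 0:
            raise ValueError("counts and lengths must be non-negative")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.genome_size < self.n_loci * self.locus_length:
            raise ValueError("genome_size must accommodate n_loci * locus_length")
        object.__setattr__(
            self, "repeat_spec", tuple(
                f if isinstance(f, RepeatFamily) else RepeatFamily(*f) for f in self.repeat_spec
            )
        )

    @property
    def n_reads(self) -> int:
        return int(round(self.depth * self.genome_size / self.read_length))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["repeat_spec"] = [dataclasses.asdict(f) for f in self.repeat_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["repeat_spec"] = tuple(
            RepeatFamily(**f) if isinstance(f, dict) else RepeatFamily(*f)
            for f in d.get("repeat_spec", ())
        )
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulation, for parameter-recovery checks."""

    config: SimConfig
    loci: list[tuple[int, int, str]]
    repeats: list[tuple[int, int, int]]
    het_positions: int
    n_reads: int
    n_mito_reads: int
    realized_depth_mean: float

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "genome_size": self.config.genome_size,
            "loci": [{"start": s, "end": e, "name": n} for s, e, n in self.loci],
            "repeats": [
                {"start": s, "end": e, "family": f} for s, e, f in self.repeats
            ],
            "het_positions": self.het_positions,
            "n_reads": self.n_reads,
            "n_mito_reads": self.n_mito_reads,
            "realized_depth_mean": self.realized_depth_mean,
        }


@dataclass
class SimResult:
    """In-memory product of :func:`run_simulation`."""

    config: SimConfig
    haplotypes: list[np.ndarray]  # uint8 base codes, shared coordinates
    mito: np.ndarray | None
    loci: list[tuple[int, int, str]]
    origins: pd.DataFrame  # columns: source, start, strand
    reads: np.ndarray  # (N, L) uint8 base codes, oriented as sequenced
    truth: SimTruth

    @property
    def library_stats(self) -> LibraryStats:
        n = self.reads.shape[0]
        n_mito = int((self.origins["source"] == "mito").sum())
        L = self.config.read_length
        return LibraryStats(
            n_reads=n, total_bases=n * L, n_mito_reads=n_mito, mito_bases=n_mito * L
        )

    def read_seqs(self) -> list[str]:
        """Decode reads to ACGT strings."""
        ascii_mat = _DECODE[self.reads]
        L = self.config.read_length
        flat = ascii_mat.tobytes().decode("ascii")
        return [flat[i * L : (i + 1) * L] for i in range(self.reads.shape[0])]

    def fastq_records(self):
        qual = "I" * self.config.read_length
        src = self.origins["source"].to_numpy()
        start = self.origins["start"].to_numpy()
        strand = self.origins["strand"].to_numpy()
        for i, seq in enumerate(self.read_seqs()):
            yield (f"r{i} src={src[i]} start={start[i]} strand={strand[i]}", seq, qual)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    streams = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, streams)}


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    if rate > 0:
        mask = rng.random(seq.size) < rate
        n = int(mask.sum())
        if n:
            out[mask] = (out[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


def _place_intervals(
    rng: np.random.Generator,
    lengths: Sequence[int],
    lo: int,
    hi: int,
    occupied: list[tuple[int, int]],
    margin: int,
    what: str,
) -> list[tuple[int, int]]:
    """Rejection-sample non-overlapping intervals in [lo, hi), keeping at
    least ``margin`` bases away from already-occupied intervals."""
    placed: list[tuple[int, int]] = []
    blocked = list(occupied)
    for length in lengths:
        if hi - length < lo:
            raise SimulationError(f"cannot place {what}: genome too small")
        for _try in range(10_000):
            start = int(rng.integers(lo, hi - length + 1))
            end = start + length
            if all(end + margin <= s or e + margin <= start for s, e in blocked):
                placed.append((start, end))
                blocked.append((start, end))
                break
        else:
            raise SimulationError(
                f"infeasible packing: could not place {what} of length {length} "
                f"after 10000 attempts"
            )
    return placed


def make_genome(cfg: SimConfig) -> tuple[np.ndarray, list[tuple[int, int, str]], SimTruth]:
    """Build the haploid genome: i.i.d. background at the target GC, repeat
    copies overwritten at random non-overlapping positions, and single-copy
    loci placed at least one read length away from any repeat copy."""
    rngs = _rngs(cfg.seed)
    L = cfg.read_length
    repeat_total = sum(f.unit_length * f.copy_number for f in cfg.repeat_spec)
    if cfg.n_loci * cfg.locus_length + repeat_total > cfg.genome_size:
        raise SimulationError("infeasible packing: loci + repeats exceed genome size")
    genome = _random_seq(rngs["genome"], cfg.genome_size, cfg.gc)

    rep_rng = rngs["repeats"]
    repeats: list[tuple[int, int, int]] = []
    occupied: list[tuple[int, int]] = []
    for fam_idx, fam in enumerate(cfg.repeat_spec):
        unit = _random_seq(rep_rng, fam.unit_length, cfg.gc)
        spans = _place_intervals(
            rep_rng,
            [fam.unit_length] * fam.copy_number,
            0,
            cfg.genome_size,
            occupied,
            margin=0,
            what=f"repeat family {fam_idx}",
        )
        for start, end in spans:
            genome[start:end] = _mutate(rep_rng, unit, fam.divergence)
            repeats.append((start, end, fam_idx))
            occupied.append((start, end))

    # loci: non-repetitive, >= L from repeats and clear of genome ends so
    # that read coverage over a locus is not depressed by boundary effects
    lo = min(L, max(0, cfg.genome_size - cfg.locus_length))
    hi = max(lo + cfg.locus_length, cfg.genome_size - L)
    spans = _place_intervals(
        rngs["loci"],
        [cfg.locus_length] * cfg.n_loci,
        lo,
        hi,
        occupied,
        margin=L,
        what="locus",
    )
    width = max(4, len(str(cfg.n_loci)))
    loci = [
        (start, end, f"locus_{i:0{width}d}")
        for i, (start, end) in enumerate(sorted(spans), start=1)
    ]
    truth = SimTruth(
        config=cfg,
        loci=loci,
        repeats=repeats,
        het_positions=0,
        n_reads=0,
        n_mito_reads=0,
        realized_depth_mean=0.0,
    )
    return genome, loci, truth


def make_diploid(
    haploid: np.ndarray, het_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Derive two haplotypes from a haploid sequence.

    Haplotype A is the input; haplotype B differs at Binomial(G, het_rate)
    positions with substitutions uniform over the three alternatives.
    Returns (hapA, hapB, variant_positions).
    """
    if not 0.0 <= het_rate <= 1.0:
        raise ValueError("het_rate must be in [0, 1]")
    hap_a = haploid
    hap_b = haploid.copy()
    n_sites = rng.binomial(haploid.size, het_rate) if het_rate > 0 else 0
    if n_sites:
        pos = rng.choice(haploid.size, size=n_sites, replace=False)
        hap_b[pos] = (hap_b[pos] + rng.integers(1, 4, size=n_sites).astype(np.uint8)) % 4
    else:
        pos = np.empty(0, dtype=np.int64)
    return hap_a, hap_b, np.sort(pos)


def simulate_reads(
    sequences: dict[str, np.ndarray],
    cfg: SimConfig,
    rng_reads: np.random.Generator,
    rng_errors: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw N = round(C* x G* / L) shotgun reads with logged origins.

    ``sequences`` maps source name -> base-code array; nuclear haplotypes
    (names not equal to ``"mito"``) are sampled equally, the mitochondrial
    source with probability ``mito_fraction``.  Start positions are uniform
    over valid positions, strands uniform, substitution errors i.i.d. at
    ``error_rate``.  Returns the read matrix (oriented as sequenced) and an
    origins table with genomic start coordinates.
    """
    L = cfg.read_length
    for name, seq in sequences.items():
        if seq.size < L:
            raise SimulationError(f"read length {L} exceeds sequence {name!r} ({seq.size} bp)")
    n = cfg.n_reads
    nuclear = [name for name in sequences if name != "mito"]
    if not nuclear:
        raise SimulationError("at least one nuclear sequence is required")
    is_mito = (
        rng_reads.random(n) < cfg.mito_fraction
        if (cfg.mito_fraction > 0 and "mito" in sequences)
        else np.zeros(n, dtype=bool)
    )
    hap_choice = rng_reads.integers(0, len(nuclear), size=n)
    source = np.where(is_mito, "mito", np.array(nuclear, dtype=object)[hap_choice])
    starts = np.empty(n, dtype=np.int64)
    for name, seq in sequences.items():
        sel = source == name
        starts[sel] = rng_reads.integers(0, seq.size - L + 1, size=int(sel.sum()))
    strand = rng_reads.integers(0, 2, size=n).astype(np.int8)

    reads = np.empty((n, L), dtype=np.uint8)
    offsets = np.arange(L)
    for name, seq in sequences.items():
        sel = np.flatnonzero(source == name)
        if sel.size:
            reads[sel] = seq[starts[sel, None] + offsets]
    if cfg.error_rate > 0:
        mask = rng_errors.random(reads.shape) < cfg.error_rate
        n_err = int(mask.sum())
        if n_err:
            reads[mask] = (reads[mask] + rng_errors.integers(1, 4, size=n_err).astype(np.uint8)) % 4
    rev = np.flatnonzero(strand == 1)
    if rev.size:
        reads[rev] = (3 - reads[rev])[:, ::-1]
    origins = pd.DataFrame({"source": source, "start": starts, "strand": strand})
    return reads, origins


def project_locus_coverage(
    origins: pd.DataFrame,
    loci: Sequence[tuple[int, int, str]],
    read_length: int,
    min_overlap_frac: float = 1.0,
) -> CoverageSet:
    """Per-base locus coverage under a minimum-overlap mapping contract.

    A read contributes depth to the bases it overlaps within a locus iff
    its overlap with the locus is at least ``min_overlap_frac * L`` (ties
    kept).  With f = 1 the profile of a deeply covered locus shows linear
    ramps of width L - 1 at both flanks and a flat interior — the artifact
    flank trimming removes.  With f = 0 the profile equals the genome-wide
    depth restricted to the locus.
    """
    L = read_length
    need = min_overlap_frac * L
    nuclear = origins.loc[origins["source"] != "mito", "start"].to_numpy()
    starts = np.sort(nuclear)
    result: dict[str, np.ndarray] = {}
    for s, e, name in loci:
        lo = np.searchsorted(starts, s - L + 1, side="left")
        hi = np.searchsorted(starts, e - 1, side="right")
        a = starts[lo:hi]
        overlap = np.minimum(e, a + L) - np.maximum(s, a)
        a = a[overlap >= need]
        depth = np.zeros(e - s + 1, dtype=np.int64)
        left = np.clip(a - s, 0, e - s)
        right = np.clip(a + L - s, 0, e - s)
        np.add.at(depth, left, 1)
        np.add.at(depth, right, -1)
        result[name] = np.cumsum(depth)[: e - s]
    return CoverageSet(result)


def genome_depth(origins: pd.DataFrame, genome_size: int, read_length: int) -> np.ndarray:
    """Realized per-base depth of nuclear reads over the genome."""
    starts = origins.loc[origins["source"] != "mito", "start"].to_numpy()
    diff = np.zeros(genome_size + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, np.minimum(starts + read_length, genome_size), -1)
    return np.cumsum(diff)[:genome_size]


def run_simulation(cfg: SimConfig) -> SimResult:
    """Run the full generator: genome, haplotypes, mito, reads, truth."""
    rngs = _rngs(cfg.seed)
    genome, loci, truth = make_genome(cfg)
    if cfg.het_rate > 0:
        hap_a, hap_b, het_pos = make_diploid(genome, cfg.het_rate, rngs["diploid"])
        haplotypes = [hap_a, hap_b]
    else:
        haplotypes = [genome]
        het_pos = np.empty(0, dtype=np.int64)
    sequences = {f"hap{chr(65 + i)}": h for i, h in enumerate(haplotypes)}
    mito = None
    if cfg.mito_fraction > 0 and cfg.mito_size > 0:
        mito = _random_seq(rngs["mito"], cfg.mito_size, cfg.gc)
        sequences["mito"] = mito
    reads, origins = simulate_reads(sequences, cfg, rngs["reads"], rngs["errors"])
    depth = genome_depth(origins, cfg.genome_size, cfg.read_length)
    truth.het_positions = int(het_pos.size)
    truth.n_reads = int(reads.shape[0])
    truth.n_mito_reads = int((origins["source"] == "mito").sum())
    truth.realized_depth_mean = float(depth.mean())
    logger.info(
        "simulated %d reads (%d mito), realized nuclear depth %.3f",
        truth.n_reads,
        truth.n_mito_reads,
        truth.realized_depth_mean,
    )
    return SimResult(
        config=cfg,
        haplotypes=haplotypes,
        mito=mito,
        loci=loci,
        origins=origins,
        reads=reads,
        truth=truth,
    )


def _decode(seq: np.ndarray) -> str:
    return _DECODE[seq].tobytes().decode("ascii")


def write_outputs(res: SimResult, outdir: str | Path, gzip_reads: bool = False) -> dict[str, Path]:
    """Write genome.fa, haplotypes.fa, loci.bed, reads.fq[.gz], basecov.txt
    (BBMap dialect, under the configured overlap contract) and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta({"genome": _decode(res.haplotypes[0])}, paths["genome"])
    if len(res.haplotypes) > 1:
        paths["haplotypes"] = outdir / "haplotypes.fa"
        write_fasta(
            {f"hap{chr(65 + i)}": _decode(h) for i, h in enumerate(res.haplotypes)},
            paths["haplotypes"],
        )
    if res.mito is not None:
        paths["mito"] = outdir / "mito.fa"
        write_fasta({"mito": _decode(res.mito)}, paths["mito"])
    paths["loci"] = outdir / "loci.bed"
    write_bed([("genome", s, e, n) for s, e, n in res.loci], paths["loci"])

    paths["reads"] = outdir / ("reads.fq.gz" if gzip_reads else "reads.fq")
    from .io_formats import write_fastq

    write_fastq(res.fastq_records(), paths["reads"])

    cov = project_locus_coverage(
        res.origins, res.loci, res.config.read_length, res.config.min_overlap_frac
    )
    paths["basecov"] = outdir / "basecov.txt"
    write_basecov(cov, paths["basecov"], dialect="bbmap_basecov")

    paths["origins"] = outdir / "origins.tsv"
    res.origins.to_csv(paths["origins"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(res.truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
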