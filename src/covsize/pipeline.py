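"""Run configuration, cross-method reports, and estimate comparison.

``run_all`` executes the requested estimators (read-depth and/or k-mer) on
a library described by a single JSON-style config — either real inputs
(FASTQ + per-base coverage file) or a simulation block — and emits a
self-describing report whose numbers are reproducible from the recorded
inputs, parameters and seed.  ``compare_estimates`` juxtaposes methods per
library, against ground truth when available.
"""

from __future__ import annotations

import datetime
import json
import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import __version__
from .depth_core import DepthParams, estimate_coverage, lander_waterman, mito_screen
from .errors import CovsizeError
from .io_formats import LibraryStats, read_basecov, read_bed, scan_reads, write_histogram
from .kmer_core import count_kmer_seqs, count_kmers, kmer_genome_size
from .simulate import SimConfig, project_locus_coverage, run_simulation, write_outputs

__all__ = ["RunReport", "run_all", "compare_estimates", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Cross-method report for one library."""

    library_id: str
    config: dict
    library: LibraryStats | None = None
    gsec: dict | None = None
    kmer: list[dict] = field(default_factory=list)
    truth: dict | None = None
    errors: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "library_id": self.library_id,
            "version": self.version,
            "timestamp": self.timestamp,
            "config": self.config,
            "library": self.library.to_dict() if self.library else None,
            "gsec": self.gsec,
            "kmer": self.kmer,
            "truth": self.truth,
            "errors": self.errors,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        if self.gsec:
            rows.append(
                {
                    "library": self.library_id,
                    "method": "read_depth",
                    "coverage": self.gsec["coverage"],
                    "size_mb": self.gsec["size_mb"],
                    "detail": f"loci_kept={self.gsec['n_loci_kept']}/{self.gsec['n_loci']}",
                }
            )
        for est in self.kmer:
            rows.append(
                {
                    "library": self.library_id,
                    "method": f"kmer_k{est['k']}",
                    "coverage": est.get("base_coverage"),
                    "size_mb": est["size_mb"],
                    "detail": f"peak={est['peak']} c0={est['error_cutoff']}",
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """Load a run config: JSON, or plain ``key = value`` lines."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return json.loads(text)
    config: dict[str, Any] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise CovsizeError(f"{path}: expected 'key = value' lines, got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            config[key] = json.loads(value)
        except json.JSONDecodeError:
            config[key] = value
    return config


def _gsec_summary_dict(summary, estimate) -> dict:
    return {
        "coverage": summary.mean_coverage,
        "size_bases": estimate.size_bases,
        "size_mb": estimate.size_mb,
        "effective_bases": estimate.effective_bases,
        "exclude_mito": estimate.exclude_mito,
        "n_loci": int(len(summary.table)),
        "n_loci_kept": summary.n_kept,
        "rejections": summary.rejection_counts,
        "params": summary.params.to_dict(),
    }


def run_all(config: dict, outdir: str | Path | None = None, seed: int | None = None) -> RunReport:
    """Execute the estimators a config requests and assemble a report.

    The config names either real inputs (``reads`` plus ``basecov`` /
    ``dialect``) or a ``simulate`` block; ``estimators`` defaults to both
    ``gsec`` and ``kmer``.  Per-method failures are recorded in the report
    rather than raised, and a partial report is still produced.
    """
    config = dict(config)
    if seed is not None:
        config["seed"] = seed
    library_id = str(config.get("library_id", "library"))
    estimators = list(config.get("estimators", ["gsec", "kmer"]))
    report = RunReport(
        library_id=library_id,
        config=config,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )

    sim = None
    tmpdir = None
    try:
        if "simulate" in config:
            sim_params = dict(config["simulate"])
            if "seed" in config:
                sim_params.setdefault("seed", int(config["seed"]))
            cfg = SimConfig.from_dict(sim_params)
            sim = run_simulation(cfg)
            report.truth = sim.truth.to_dict()
            if outdir is not None:
                write_outputs(sim, Path(outdir) / "sim")
            stats = sim.library_stats
            cov = project_locus_coverage(
                sim.origins, sim.loci, cfg.read_length, cfg.min_overlap_frac
            )
            read_seqs = sim.read_seqs()
        else:
            reads = config.get("reads")
            if not reads:
                raise CovsizeError("config must name 'reads' or contain a 'simulate' block")
            if isinstance(reads, str):
                reads = [reads]
            mito_ref = config.get("mito_ref")
            if mito_ref:
                _kept, stats = mito_screen(reads, mito_ref, k=int(config.get("mito_k", 21)))
            else:
                stats = scan_reads(reads)
            cov = None
            if "basecov" in config:
                lengths = None
                if config.get("loci_bed"):
                    lengths = {
                        name: end - start
                        for _c, start, end, name in read_bed(config["loci_bed"])
                    }
                cov = read_basecov(
                    config["basecov"],
                    dialect=config.get("dialect", "bbmap_basecov"),
                    locus_lengths=lengths,
                )
            read_seqs = None
        report.library = stats

        if "gsec" in estimators:
            try:
                if cov is None:
                    raise CovsizeError("gsec requested but no coverage input available")
                gsec_cfg = dict(config.get("gsec", {}))
                params = DepthParams(
                    trim_bases=int(gsec_cfg.get("trim", 75)),
                    iqr_multiplier=float(gsec_cfg.get("iqr_multiplier", 3.0)),
                    averaging=str(gsec_cfg.get("averaging", "locus_mean")).replace("-", "_"),
                )
                exclude_mito = bool(gsec_cfg.get("exclude_mito", stats.n_mito_reads > 0))
                summary = estimate_coverage(cov, params)
                est = lander_waterman(stats, summary.mean_coverage, exclude_mito=exclude_mito)
                report.gsec = _gsec_summary_dict(summary, est)
                if outdir is not None:
                    summary.table.to_csv(Path(outdir) / "gsec_loci.tsv", sep="\t", index=False)
            except Exception as exc:  # noqa: BLE001 - recorded, not raised
                report.errors["gsec"] = str(exc)
                logger.error("gsec estimator failed: %s", exc)

        if "kmer" in estimators:
            kmer_cfg = dict(config.get("kmer", {}))
            ks = kmer_cfg.get("k", [21])
            if isinstance(ks, int):
                ks = [ks]
            cutoff = kmer_cfg.get("cutoff", "auto")
            c0 = None if str(cutoff).lower() == "auto" else int(cutoff)
            ploidy_peak = kmer_cfg.get("ploidy_peak", "primary")
            mean_l = stats.mean_read_length or None
            for k in ks:
                try:
                    if read_seqs is not None:
                        h = count_kmer_seqs(read_seqs, int(k))
                    else:
                        h = count_kmers(reads, int(k))
                    est = kmer_genome_size(
                        h, c0=c0, read_length=mean_l, ploidy_peak=ploidy_peak
                    )
                    report.kmer.append(est.to_dict())
                    if outdir is not None:
                        write_histogram(h, Path(outdir) / f"k{k}.histo")
                except Exception as exc:  # noqa: BLE001
                    report.errors[f"kmer_k{k}"] = str(exc)
                    logger.error("k-mer estimator failed for k=%d: %s", k, exc)
    finally:
        if tmpdir is not None:
            tmpdir.cleanup()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        report.to_tsv(outdir / "report.tsv")
    return report


def compare_estimates(
    reports: Sequence[RunReport], truth: float | None = None
) -> pd.DataFrame:
    """Per-library comparison table of methods.

    ``deviation_pct`` is the signed percent deviation from the supplied
    ground-truth genome size, or (when none is given) from the mean of the
    methods reported for that library.
    """
    if not reports:
        raise ValueError("at least one report is required")
    rows = []
    for rep in reports:
        ref = truth
        if ref is None and rep.truth is not None:
            ref = float(rep.truth["genome_size"])
        methods: list[tuple[str, float]] = []
        if rep.gsec:
            methods.append(("read_depth", rep.gsec["size_bases"]))
        for est in rep.kmer:
            tag = "kmer" if est["params"].get("ploidy_peak", "primary") == "primary" else "kmer_hom"
            methods.append((f"{tag}_k{est['k']}", est["size_bases"]))
        baseline = ref if ref is not None else (
            sum(g for _m, g in methods) / len(methods) if methods else None
        )
        for method, g in methods:
            rows.append(
                {
                    "library": rep.library_id,
                    "method": method,
                    "size_mb": g / 1e6,
                    "baseline_mb": baseline / 1e6 if baseline else None,
                    "deviation_pct": 100.0 * (g - baseline) / baseline if baseline else None,
                }
            )
    return pd.DataFrame(rows)
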