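"""End-to-end orchestration of the four-stage selection scan.

A single declarative YAML config drives: (1) per-population allele frequencies
at candidate sites, (2) FDIST envelope calibration and per-candidate outlier
probabilities, (3) pairwise Weir-Cockerham F_ST with chromosome-wide empirical
percentiles, and (4) Gabriel blocks plus the REHH scan with frequency-binned
percentiles.  One TSV per stage, a JSON summary, and a run log are written to
the output directory; all randomness flows from one master seed recorded in
the log, so a re-run with the same config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .ehh import CoreRegion, rehh_scan
from .fdist import IslandModelConfig, calibrate_migration, scan_outliers, simulate_envelope
from .fst_stats import allele_freq_matrix, allele_freqs, pairwise_fst, wc_theta_sites
from .haplo_io import GeneticMap, HaplotypePanel, load_genetic_map, load_panel
from .ld_blocks import gabriel_blocks

__all__ = ["AnalysisConfig", "ConfigError", "StageError", "validate_config", "run_analysis"]


class ConfigError(ValueError):
    """Invalid analysis configuration; ``.errors`` lists every problem."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    panel_path: str
    panel_format: str  # phased-vcf | impute-hls | tsv
    pop_map_path: str
    map_path: str | None = None
    candidate_sites: list[str] = field(default_factory=list)
    populations: list[str] | None = None  # None = all panels in the file
    # FDIST settings
    fdist_replicates: int = 10_000
    fdist_demes: int = 100
    fdist_theta_mut: tuple[float, float] | float = (0.05, 2.0)
    fdist_bandwidth: float = 0.025
    # block settings
    block_maf_min: float = 0.05
    block_max_span_bp: int | None = 200_000
    # REHH settings
    rehh_distance_cM: float = 0.25
    rehh_min_freq: float = 0.05
    rehh_pops: list[str] | None = None  # None = same as `populations`
    extra_core_sites: list[list[str]] = field(default_factory=list)
    # run settings
    out_dir: str = "sweepscan_out"
    seed: int = 0
    run_fdist: bool = True
    run_blocks: bool = True


def validate_config(path_or_dict: str | dict) -> AnalysisConfig:
    """Parse and validate a YAML config; collects every error before raising."""
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    for k in raw:
        if k not in known:
            errors.append(f"unknown field {k!r}")
    for req in ("panel_path", "panel_format", "pop_map_path"):
        if not raw.get(req):
            errors.append(f"missing required field {req!r}")
    fmt = raw.get("panel_format")
    if fmt and fmt not in {"phased-vcf", "impute-hls", "tsv"}:
        errors.append(f"panel_format must be phased-vcf|impute-hls|tsv, got {fmt!r}")
    for key in ("panel_path", "pop_map_path", "map_path"):
        p = raw.get(key)
        if p and key != "panel_path" and not os.path.exists(p):
            errors.append(f"{key} does not exist: {p}")
        if key == "panel_path" and p and fmt != "impute-hls" and not os.path.exists(p):
            errors.append(f"panel_path does not exist: {p}")
    if raw.get("rehh_distance_cM") is not None and raw["rehh_distance_cM"] <= 0:
        errors.append("rehh_distance_cM must be > 0")
    if raw.get("fdist_replicates") is not None and raw["fdist_replicates"] < 500:
        errors.append("fdist_replicates must be >= 500")
    for key, lo, hi in (("block_maf_min", 0.0, 0.5), ("rehh_min_freq", 0.0, 0.5),
                        ("fdist_bandwidth", 0.0, 0.5)):
        v = raw.get(key)
        if v is not None and not (lo < v <= hi):
            errors.append(f"{key} must be in ({lo}, {hi}]")
    if errors:
        raise ConfigError(errors)
    if isinstance(raw.get("fdist_theta_mut"), list):
        raw["fdist_theta_mut"] = tuple(raw["fdist_theta_mut"])
    return AnalysisConfig(**{k: v for k, v in raw.items() if k in known})


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_tsv(path: str, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return f"{v:.6g}"
    if v is None:
        return "NA"
    return str(v)


def run_analysis(config: AnalysisConfig) -> dict:
    """Execute all configured stages; returns the JSON-able summary dict.

    Stage failures raise :class:`StageError` naming the stage; outputs of
    earlier stages are preserved in ``config.out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    log_lines: list[str] = [f"sweepscan {__version__} seed={config.seed}"]
    summary: dict = {"seed": config.seed, "version": __version__}

    def log(stage: str, **kv) -> None:
        log_lines.append(stage + " " + " ".join(f"{k}={v}" for k, v in kv.items()))

    # ---- load ------------------------------------------------------------
    stage = "load"
    try:
        panel, report = load_panel(
            config.panel_path, config.panel_format, config.pop_map_path,
            return_report=True,
        )
        pops = config.populations or panel.populations
        gmap = load_genetic_map(config.map_path) if config.map_path else None
        log(stage, panel=config.panel_path, digest=_digest(config.pop_map_path),
            n_chrom=panel.n_chrom, n_sites=panel.n_sites,
            n_excluded=report.n_excluded, pops=",".join(pops))
        summary["n_sites"] = panel.n_sites
        summary["n_chrom"] = panel.n_chrom
        summary["n_excluded_sites"] = report.n_excluded
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(stage, e) from e

    cand = [s for s in config.candidate_sites if _has_site(panel, s)]
    cand_idx = [panel.site_index(s) for s in cand]

    # ---- stage 1: allele frequencies ------------------------------------
    stage = "freqs"
    try:
        rows = []
        for i in cand_idx:
            for rec in allele_freqs(panel, i, pops):
                rows.append((rec.site_id, rec.pop, rec.n_chrom,
                             round(rec.p, 6), round(rec.He, 6)))
        _write_tsv(os.path.join(config.out_dir, "freqs.tsv"),
                   ("site_id", "pop", "n_chrom", "p_allele1", "He"), rows)
        log(stage, n_candidates=len(cand))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- stage 2: FDIST outlier test ------------------------------------
    if config.run_fdist:
        stage = "fdist"
        try:
            P, n = allele_freq_matrix(panel, pops)
            a, b = wc_theta_sites(P, n)
            tot = a + b
            with np.errstate(invalid="ignore", divide="ignore"):
                theta_all = np.where(tot != 0, a / tot, np.nan)
            p_bar = (n[:, None] * P).sum(axis=0) / n.sum()
            he_all = 2 * p_bar * (1 - p_bar)
            base = IslandModelConfig(
                sample_sizes=list(n), n_demes_total=config.fdist_demes,
                theta_mut=config.fdist_theta_mut,
                n_replicates=config.fdist_replicates, seed=config.seed,
            )
            M, achieved = calibrate_migration(theta_all, base)
            base.scaled_migration = M
            env = simulate_envelope(base, target_mean_fst=achieved)
            results = scan_outliers(
                [panel.sites[i].site_id for i in cand_idx],
                he_all[cand_idx], theta_all[cand_idx], env,
                bandwidth=config.fdist_bandwidth,
            )
            _write_tsv(
                os.path.join(config.out_dir, "fdist.tsv"),
                ("site_id", "He", "Fst", "P", "classification"),
                [(r.site_id, round(r.observed_he, 6), round(r.observed_fst, 6),
                  round(r.p_below, 6) if not math.isnan(r.p_below) else float("nan"),
                  r.classification) for r in results],
            )
            summary["fdist"] = {
                "M": M, "achieved_mean_fst": achieved,
                "n_positive": sum(r.classification == "positive-candidate" for r in results),
                "n_balancing": sum(r.classification == "balancing-candidate" for r in results),
            }
            log(stage, M=f"{M:.4g}", mean_fst=f"{achieved:.4f}",
                replicates=config.fdist_replicates)
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    # ---- stage 3: pairwise F_ST ------------------------------------------
    stage = "fst-pair"
    try:
        recs = pairwise_fst(panel, cand, pops) if cand else []
        _write_tsv(
            os.path.join(config.out_dir, "fst_pairs.tsv"),
            ("site_ids", "pop_a", "pop_b", "theta", "percentile", "significant"),
            [(";".join(r.site_ids), r.pop_a, r.pop_b,
              round(r.theta, 6) if r.defined else float("nan"),
              round(r.percentile, 3) if r.percentile is not None else None,
              int(r.percentile is not None and r.percentile >= 95.0))
             for r in recs],
        )
        n_sig = sum(1 for r in recs if r.percentile is not None and r.percentile >= 95)
        summary["fst_pairs"] = {"n_records": len(recs), "n_significant": n_sig}
        log(stage, n_records=len(recs), n_significant=n_sig)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- stage 4: blocks + REHH scan -------------------------------------
    if config.run_blocks:
        stage = "rehh-scan"
        try:
            if gmap is None:
                raise ValueError("REHH stage requires a genetic map (map_path)")
            extra = [
                CoreRegion(tuple(sorted(panel.site_index(s) for s in grp)))
                for grp in config.extra_core_sites
            ]
            rows = []
            block_rows = []
            scan_pops = config.rehh_pops or pops
            summary["rehh"] = {}
            for pop in scan_pops:
                blocks = gabriel_blocks(
                    panel, pop, maf_min=config.block_maf_min,
                    max_span_bp=config.block_max_span_bp,
                )
                for bi, blk in enumerate(blocks):
                    block_rows.append(
                        (pop, bi, panel.sites[blk.site_indices[0]].chrom,
                         blk.start_bp, blk.end_bp, blk.n_sites,
                         round(blk.frac_strong_ld, 4))
                    )
                records = rehh_scan(
                    panel, pop, gmap, blocks,
                    distance_cM=config.rehh_distance_cM,
                    min_freq=config.rehh_min_freq,
                    extra_cores=extra,
                )
                for r in records:
                    core_sites = r.core.core.site_indices
                    rows.append(
                        (pop, panel.sites[core_sites[0]].site_id,
                         panel.sites[core_sites[-1]].site_id,
                         r.core.allele_string, round(r.core.frequency, 4),
                         r.direction, r.rehh_value, r.freq_bin,
                         round(r.percentile, 3) if r.percentile is not None else None,
                         int(r.significant), int(r.highlighted))
                    )
                summary["rehh"][pop] = {
                    "n_blocks": sum(1 for b in block_rows if b[0] == pop),
                    "n_records": sum(1 for r in records),
                    "n_flagged": sum(r.significant for r in records),
                }
                log(stage, pop=pop, **summary["rehh"][pop])
            _write_tsv(
                os.path.join(config.out_dir, "blocks.tsv"),
                ("pop", "block", "chrom", "start_bp", "end_bp", "n_sites", "frac_strong_ld"),
                block_rows,
            )
            _write_tsv(
                os.path.join(config.out_dir, "rehh_scan.tsv"),
                ("pop", "core_start", "core_end", "core_haplotype", "frequency",
                 "direction", "rehh", "freq_bin", "percentile", "significant",
                 "highlighted"),
                rows,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary


def _has_site(panel: HaplotypePanel, site_id: str) -> bool:
    try:
        panel.site_index(site_id)
        return True
    except KeyError:
        return False
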