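"""Synthetic haplotype panels: island-model differentiation, background LD,
genetic maps, and planted selective sweeps.

Two generators cover the statistical structures the scan assumes:

* :func:`gen_island_snp_panel` draws unlinked SNPs under the Balding-Nichols
  model — per-site ancestral frequency p0 ~ Uniform(0.05, 0.95), deme
  frequencies ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F) with F the target F_ST, and
  chromosomes as independent Bernoulli draws.  Fast, with a closed-form
  differentiation target; the test bed for F_ST estimation and FDIST.

* :func:`gen_sweep_panel` runs a forward-time haploid Wright-Fisher simulation
  with recombination on a genetic map.  The founding generation is a mosaic
  copying process over 20 founder haplotypes (segment lengths ~
  Exponential(mean 0.05 cM), i.e. ~50 kb — the scale of empirical haplotype
  blocks) which creates block-like background LD; each
  generation samples parents proportional to fitness 1 + s (sweep-allele
  carriers in the selected deme), recombines with crossovers placed as a
  Poisson process on the cM scale, and exchanges migrants between demes.  The
  sweep allele is seeded in deme 0 at frequency f0.  This is the test bed for
  hitchhiking: a planted high-frequency core haplotype with a long
  unrecombined flank.

All generators are deterministic under a fixed seed.  Default scales
(N = 1,000 chromosomes per deme, 2,000 sites over 5 Mb at 1 cM/Mb,
200 generations) emulate HapMap-like SNP density at desk scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .haplo_io import (
    GeneticMap,
    HaplotypePanel,
    VariantSite,
    interpolate_cM,
    write_genetic_map,
    write_panel_impute,
    write_panel_tsv,
    write_panel_vcf,
    write_pop_map,
)

__all__ = [
    "SweepSimConfig",
    "TruthRecord",
    "gen_island_snp_panel",
    "gen_sweep_panel",
    "write_fixture_set",
]

_NUC = np.array(list("ACGT"))


@dataclass
class SweepSimConfig:
    """Forward Wright-Fisher sweep simulation settings.

    ``deme_size_N`` counts haploid chromosomes per deme; ``migration_m`` is the
    per-generation per-chromosome probability of migrating (chromosomes are
    exchanged pairwise between demes, so deme sizes are conserved);
    ``sel_coefficient_s`` multiplies fitness of sweep-allele carriers in
    ``selected_deme`` only.  ``sample_per_deme`` chromosomes (an even number,
    paired into individuals) are drawn per deme at the end.
    """

    n_demes: int = 2
    deme_size_N: int = 1000
    migration_m: float = 0.01
    n_sites: int = 2000
    region_bp: int = 5_000_000
    map_rate_cM_per_Mb: float = 1.0
    sel_coefficient_s: float = 0.1
    sweep_site_index: int | None = None  # default: middle site
    init_sweep_freq_f0: float = 0.05
    n_generations: int = 200
    sample_per_deme: int = 200  # chromosomes; comparable to a HapMap panel
    selected_deme: int = 0
    n_founders: int = 20
    founder_segment_cM: float = 0.05  # ~50 kb at 1 cM/Mb: empirical LD-block scale
    core_n_snps: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.migration_m <= 1.0):
            raise ValueError("migration_m must be in [0, 1]")
        if self.sel_coefficient_s < 0:
            raise ValueError("s must be >= 0")
        if not (0.0 < self.init_sweep_freq_f0 < 1.0):
            raise ValueError("f0 must be in (0, 1)")
        if self.sweep_site_index is None:
            self.sweep_site_index = self.n_sites // 2
        if not (0 <= self.sweep_site_index < self.n_sites):
            raise ValueError("sweep site outside the site range")
        if self.sample_per_deme % 2 or self.sample_per_deme > self.deme_size_N:
            raise ValueError("sample_per_deme must be even and <= deme_size_N")


@dataclass
class TruthRecord:
    """Ground truth emitted with a sweep panel."""

    sweep_site_id: str
    sweep_pos_bp: int
    sweep_site_index: int | None  # index in the emitted panel; None if dropped
    final_sweep_freq: list[float]  # per deme, full population
    sweep_core_site_ids: list[str]
    sweep_core_string: str
    s: float
    f0: float
    n_restarts: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


# ---------------------------------------------------------------------------
# Balding-Nichols island panel
# ---------------------------------------------------------------------------


def gen_island_snp_panel(
    d: int,
    n: int,
    target_fst: float,
    L: int,
    seed: int = 0,
    spacing_bp: int = 10_000,
    chrom: str = "1",
) -> HaplotypePanel:
    """Unlinked differentiated SNPs under the Balding-Nichols model.

    ``n`` chromosomes (must be even) are sampled per deme for each of ``d``
    demes, labelled ``deme0`` .. ``deme{d-1}``.
    """
    if d < 2 or L < 1:
        raise ValueError("need d >= 2 demes and L >= 1 sites")
    if not (0.0 < target_fst < 1.0):
        raise ValueError("target_fst must be in (0, 1)")
    if n % 2:
        raise ValueError("n (chromosomes per deme) must be even")
    rng = np.random.default_rng(seed)
    F = target_fst
    p0 = rng.uniform(0.05, 0.95, size=L)
    alpha = p0 * (1 - F) / F
    beta = (1 - p0) * (1 - F) / F
    pd = rng.beta(alpha, beta, size=(d, L))
    H = (rng.random((d, n, L)) < pd[:, None, :]).astype(np.int8)
    H = H.reshape(d * n, L)
    ref = _NUC[rng.integers(0, 4, L)]
    alt = np.array([
        _NUC[(np.flatnonzero(_NUC != r)[rng.integers(0, 3)])] for r in ref
    ])
    sites = [
        VariantSite(f"snp{i}", chrom, (i + 1) * spacing_bp, ref[i], alt[i])
        for i in range(L)
    ]
    samples = [f"deme{j}_s{k}" for j in range(d) for k in range(n // 2)]
    pops = np.array([f"deme{j}" for j in range(d) for _ in range(n)], dtype=object)
    return HaplotypePanel(sites, H, samples, pops)


# ---------------------------------------------------------------------------
# forward Wright-Fisher sweep simulation
# ---------------------------------------------------------------------------


def _founder_mosaic(rng, N: int, site_cM: np.ndarray, founders: np.ndarray,
                    segment_cM: float) -> np.ndarray:
    """Mosaic-copying initial generation: each chromosome copies founder
    segments with Exponential(mean segment_cM) lengths on the genetic map."""
    n_f, L = founders.shape
    total_cM = site_cM[-1]
    out = np.empty((N, L), dtype=np.int8)
    for i in range(N):
        pos = 0.0
        start_idx = 0
        while start_idx < L:
            seg = rng.exponential(segment_cM)
            pos += seg
            end_idx = int(np.searchsorted(site_cM, pos, side="right")) if pos < total_cM else L
            f = rng.integers(0, n_f)
            out[i, start_idx:end_idx] = founders[f, start_idx:end_idx]
            start_idx = end_idx
    return out


def _next_generation(rng, pop: np.ndarray, fitness: np.ndarray,
                     site_cM: np.ndarray) -> np.ndarray:
    """One Wright-Fisher generation with selection and recombination."""
    N, L = pop.shape
    prob = fitness / fitness.sum()
    pa = rng.choice(N, size=N, p=prob)
    pb = rng.choice(N, size=N, p=prob)
    total_M = site_cM[-1] / 100.0  # Morgans
    n_x = rng.poisson(total_M, size=N)
    start = rng.integers(0, 2, size=N)
    first = np.where(start == 0, pa, pb)
    child = pop[first].copy()
    for i in np.flatnonzero(n_x):
        cuts_cM = np.sort(rng.random(n_x[i]) * site_cM[-1])
        parity = np.searchsorted(cuts_cM, site_cM, side="right") % 2
        use_second = parity == 1
        other = pb[i] if start[i] == 0 else pa[i]
        child[i, use_second] = pop[other, use_second]
    return child


def _migrate(rng, demes: list[np.ndarray], m: float) -> None:
    """Pairwise size-conserving exchange: for each deme pair, swap
    Binomial(N, m/(d-1)) chromosomes in place."""
    d = len(demes)
    if d < 2 or m <= 0:
        return
    rate = m / (d - 1)
    for a in range(d):
        for b in range(a + 1, d):
            N = min(demes[a].shape[0], demes[b].shape[0])
            k = rng.binomial(N, rate)
            if k == 0:
                continue
            ia = rng.choice(demes[a].shape[0], size=k, replace=False)
            ib = rng.choice(demes[b].shape[0], size=k, replace=False)
            tmp = demes[a][ia].copy()
            demes[a][ia] = demes[b][ib]
            demes[b][ib] = tmp


def gen_sweep_panel(config: SweepSimConfig):
    """Simulate a sweep panel; returns (panel, genetic_map, truth).

    If the sweep allele is lost in every deme the simulation restarts with the
    next derived seed (up to 50 attempts).  Sites monomorphic in the pooled
    sample are removed from the emitted panel.
    """
    last_err = None
    for attempt in range(50):
        seed = int(np.random.SeedSequence([config.seed, attempt]).generate_state(1)[0] % (2**31 - 1))
        result = _run_sweep_once(config, seed)
        if result is not None:
            panel, gmap, truth = result
            truth.n_restarts = attempt
            return panel, gmap, truth
        last_err = f"sweep allele lost (attempt {attempt})"
    raise RuntimeError(f"sweep simulation failed after 50 attempts: {last_err}")


def _run_sweep_once(config: SweepSimConfig, seed: int):
    rng = np.random.default_rng(seed)
    L = config.n_sites
    pos = np.sort(rng.choice(np.arange(1, config.region_bp + 1), size=L, replace=False))
    rate = config.map_rate_cM_per_Mb
    gmap = GeneticMap(
        np.array([1, config.region_bp]),
        np.array([0.0, (config.region_bp - 1) / 1e6 * rate]),
    )
    site_cM = np.asarray(interpolate_cM(gmap, pos), dtype=np.float64)

    # per-site allele frequencies among founders span the full range, so the
    # panel's site-frequency spectrum covers low- and high-MAF variants as a
    # real SNP panel does
    p_site = rng.uniform(0.05, 0.95, size=L)
    founders = (rng.random((config.n_founders, L)) < p_site).astype(np.int8)
    demes = [
        _founder_mosaic(rng, config.deme_size_N, site_cM, founders,
                        config.founder_segment_cM)
        for _ in range(config.n_demes)
    ]
    # seed the sweep allele: a single-origin derived allele already at
    # frequency f0 — all initial carriers are copies of one chromosome, as for
    # a young mutation that has escaped early loss (this is what produces one
    # long high-frequency haplotype once selection lifts it)
    sw = config.sweep_site_index
    for dm in demes:
        dm[:, sw] = 0
    n_init = max(1, round(config.init_sweep_freq_f0 * config.deme_size_N))
    carriers = rng.choice(config.deme_size_N, size=n_init, replace=False)
    demes[0][carriers] = demes[0][carriers[0]]
    demes[0][carriers, sw] = 1

    for _ in range(config.n_generations):
        for j in range(config.n_demes):
            fitness = np.ones(demes[j].shape[0])
            if j == config.selected_deme and config.sel_coefficient_s > 0:
                fitness += config.sel_coefficient_s * demes[j][:, sw]
            demes[j] = _next_generation(rng, demes[j], fitness, site_cM)
        _migrate(rng, demes, config.migration_m)
        if config.sel_coefficient_s > 0:
            if sum(int(dm[:, sw].sum()) for dm in demes) == 0:
                return None  # lost; caller restarts

    final_freq = [float(dm[:, sw].mean()) for dm in demes]
    # sample chromosomes per deme
    sampled = []
    for dm in demes:
        rows = rng.choice(dm.shape[0], size=config.sample_per_deme, replace=False)
        sampled.append(dm[rows])
    H = np.concatenate(sampled, axis=0)

    pooled = H.mean(axis=0)
    keep = np.flatnonzero((pooled > 0) & (pooled < 1))
    H = np.ascontiguousarray(H[:, keep])
    pos_k = pos[keep]
    ref = _NUC[rng.integers(0, 4, L)]
    alt_off = rng.integers(0, 3, L)
    sites = []
    for newi, i in enumerate(keep):
        r = ref[i]
        a = _NUC[np.flatnonzero(_NUC != r)[alt_off[i]]]
        sites.append(VariantSite(f"snp{i}", "1", int(pos[i]), r, a))
    samples = [
        f"deme{j}_s{k}"
        for j in range(config.n_demes)
        for k in range(config.sample_per_deme // 2)
    ]
    pops = np.array(
        [f"deme{j}" for j in range(config.n_demes)
         for _ in range(config.sample_per_deme)],
        dtype=object,
    )
    panel = HaplotypePanel(sites, H, samples, pops)

    # truth: declared core of core_n_snps retained sites centred on the sweep
    sw_new = int(np.searchsorted(pos_k, pos[sw]))
    sweep_retained = sw_new < len(keep) and keep[sw_new] == sw
    if sweep_retained:
        half = config.core_n_snps // 2
        lo = max(0, sw_new - half)
        hi = min(panel.n_sites, lo + config.core_n_snps)
        lo = max(0, hi - config.core_n_snps)
        core_idx = list(range(lo, hi))
        carriers = np.flatnonzero(H[:, sw_new] == 1)
        core_alleles = H[np.ix_(carriers, np.asarray(core_idx))]
        consensus = (core_alleles.mean(axis=0) >= 0.5).astype(np.int8)
        core_string = "".join(
            (panel.sites[i].allele1 if a else panel.sites[i].allele0)
            for i, a in zip(core_idx, consensus)
        )
        core_ids = [panel.sites[i].site_id for i in core_idx]
        sweep_idx_panel: int | None = sw_new
    else:
        core_string = ""
        core_ids = []
        sweep_idx_panel = None
    truth = TruthRecord(
        sweep_site_id=f"snp{sw}",
        sweep_pos_bp=int(pos[sw]),
        sweep_site_index=sweep_idx_panel,
        final_sweep_freq=final_freq,
        sweep_core_site_ids=core_ids,
        sweep_core_string=core_string,
        s=config.sel_coefficient_s,
        f0=config.init_sweep_freq_f0,
    )
    return panel, gmap, truth


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_set(
    panel: HaplotypePanel,
    gmap: GeneticMap | None,
    truth: TruthRecord | None,
    out_dir: str,
    formats: Sequence[str] = ("vcf", "impute", "tsv"),
) -> dict[str, str]:
    """Write the panel in each requested format plus map, pop map, and truth;
    returns (and saves as ``manifest.json``) a filename -> sha256 manifest."""
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    for fmt in formats:
        if fmt == "vcf":
            write_panel_vcf(panel, os.path.join(out_dir, "panel.vcf"))
            written.append("panel.vcf")
        elif fmt == "impute":
            write_panel_impute(panel, os.path.join(out_dir, "panel"))
            written += ["panel.hap", "panel.legend", "panel.sample"]
        elif fmt == "tsv":
            write_panel_tsv(panel, os.path.join(out_dir, "panel.tsv"))
            written.append("panel.tsv")
        else:
            raise ValueError(f"unknown fixture format {fmt!r}")
    pop_map = {s: panel.pop_labels[2 * k] for k, s in enumerate(panel.sample_ids)}
    write_pop_map(pop_map, os.path.join(out_dir, "pops.tsv"))
    written.append("pops.tsv")
    if gmap is not None:
        write_genetic_map(gmap, os.path.join(out_dir, "map.txt"))
        written.append("map.txt")
    if truth is not None:
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            fh.write(truth.to_json())
        written.append("truth.json")
    manifest = {f: _sha256(os.path.join(out_dir, f)) for f in sorted(written)}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
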