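"""Core haplotypes, EHH decay, and REHH with frequency-binned significance.

A *core region* is a contiguous run of SNPs; each distinct allele string over
those SNPs among one population's chromosomes is a *core haplotype*.  EHH of a
core haplotype at distance x is the probability that two randomly chosen
carrier chromosomes are identical over every marker between the core edge and
x; writing e_g for the sizes of the identity classes of c carriers,

    EHH(x) = sum_g C(e_g, 2) / C(c, 2).

REHH divides the core haplotype's EHH by the pooled homozygosity of all other
core haplotypes at the same locus,

    EHH_others = sum_{j != t} sum_g C(e_gj, 2) / sum_{j != t} C(c_j, 2),

which cancels the local recombination-rate dependence.  Evaluation is at
marker boundaries: the first marker whose genetic distance from the core edge
reaches the target (default 0.25 cM).

A chromosome-wide scan computes REHH for every core haplotype of every
haplotype block in both directions, places records into 20 frequency bins of
width 0.05, and ranks log(REHH) within each bin by midrank empirical
percentile; records at or above the 95th percentile are flagged, the 99th
highlighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fst_stats import empirical_percentile
from .haplo_io import GeneticMap, HaplotypePanel, interpolate_cM
from .ld_blocks import HaploBlock

__all__ = [
    "CoreRegion",
    "CoreHaplotype",
    "EHHCurve",
    "RehhRecord",
    "enumerate_core_haplotypes",
    "ehh",
    "ehh_curve",
    "rehh",
    "rehh_scan",
    "frequency_bin",
    "bin_reference",
    "rank_against_reference",
    "sweep_core_records",
]

N_BINS = 20
BIN_WIDTH = 0.05
FLAG_PERCENTILE = 95.0
HIGHLIGHT_PERCENTILE = 99.0


@dataclass(frozen=True)
class CoreRegion:
    """Contiguous core SNPs (panel site indices, ascending)."""

    site_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = self.site_indices
        if len(idx) < 1:
            raise ValueError("core region needs >= 1 site")
        if any(b != a + 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("core sites must be contiguous in the panel")

    @property
    def left(self) -> int:
        return self.site_indices[0]

    @property
    def right(self) -> int:
        return self.site_indices[-1]

    @staticmethod
    def from_block(block: HaploBlock, panel: HaplotypePanel) -> "CoreRegion":
        # blocks are contiguous in the MAF-filtered sequence; the core spans
        # the full panel run between their outermost markers
        return CoreRegion(tuple(range(block.site_indices[0], block.site_indices[-1] + 1)))


@dataclass
class CoreHaplotype:
    """One distinct allele string over a core region, with its carriers."""

    core: CoreRegion
    allele_string: str
    carrier_rows: np.ndarray  # chromosome rows (within the scanned population)
    frequency: float
    pop: str | None = None

    @property
    def n_carriers(self) -> int:
        return self.carrier_rows.size


@dataclass
class EHHCurve:
    direction: str  # "upstream" | "downstream"
    core: CoreHaplotype
    pos_bp: np.ndarray
    distance_cM: np.ndarray
    ehh_values: np.ndarray


@dataclass
class RehhRecord:
    core: CoreHaplotype
    direction: str
    distance_cM: float
    rehh_value: float  # NaN when undefined, inf when EHH_others == 0
    ehh_core: float = float("nan")
    ehh_others: float = float("nan")
    boundary_bp: int | None = None
    freq_bin: int | None = None
    percentile: float | None = None
    significant: bool = False
    highlighted: bool = False
    block: HaploBlock | None = None

    @property
    def defined(self) -> bool:
        return math.isfinite(self.rehh_value)


def frequency_bin(freq: float) -> int:
    """Bin index among 20 bins of width 0.05; frequency 1.0 maps to bin 19."""
    if not (0.0 <= freq <= 1.0):
        raise ValueError("frequency outside [0, 1]")
    # guard against 0.30/0.05 -> 5.999...; frequencies are ratios of counts
    return min(int(freq / BIN_WIDTH + 1e-9), N_BINS - 1)


def _allele_string(panel: HaplotypePanel, core: CoreRegion, row_alleles: np.ndarray) -> str:
    sites = [panel.sites[i] for i in core.site_indices]
    return "".join(
        (s.allele1 if a else s.allele0) for s, a in zip(sites, row_alleles)
    )


def enumerate_core_haplotypes(
    panel: HaplotypePanel,
    core: CoreRegion,
    pop: str | None = None,
    min_freq: float = 0.05,
    return_rare: bool = False,
):
    """Distinct core haplotypes in one population, most frequent first.

    Haplotypes below ``min_freq`` are excluded from the main list (so reported
    frequencies may sum to < 1); pass ``return_rare=True`` to also receive
    them.  Allele strings use the sites' nucleotide symbols.
    """
    rows = panel.rows_for_pop(pop)
    sub = panel.haplotypes[np.ix_(rows, np.asarray(core.site_indices))]
    uniq, inverse, counts = np.unique(
        sub, axis=0, return_inverse=True, return_counts=True
    )
    order = np.argsort(-counts, kind="stable")
    main, rare = [], []
    for u in order:
        ch = CoreHaplotype(
            core=core,
            allele_string=_allele_string(panel, core, uniq[u]),
            carrier_rows=rows[inverse == u],
            frequency=counts[u] / rows.size,
            pop=pop,
        )
        (main if ch.frequency >= min_freq else rare).append(ch)
    return (main, rare) if return_rare else main


def _interval_sites(panel: HaplotypePanel, core: CoreRegion, direction: str, x_bp: int):
    """Site indices strictly outside the core edge out to x_bp inclusive."""
    pos = panel.positions_bp
    if direction == "downstream":
        edge = core.right
        sel = np.arange(edge + 1, panel.n_sites)
        sel = sel[pos[sel] <= x_bp]
    elif direction == "upstream":
        edge = core.left
        sel = np.arange(0, edge)
        sel = sel[pos[sel] >= x_bp]
    else:
        raise ValueError("direction must be 'upstream' or 'downstream'")
    return sel


def _pair_homozygosity(group_sizes: np.ndarray) -> tuple[float, float]:
    """(identical pairs, total pairs) for one partition of carriers."""
    e = np.asarray(group_sizes, dtype=np.float64)
    same = float((e * (e - 1) / 2).sum())
    c = float(e.sum())
    return same, c * (c - 1) / 2


def _partition_sizes(panel: HaplotypePanel, rows: np.ndarray, interval: np.ndarray) -> np.ndarray:
    if interval.size == 0:
        return np.array([rows.size])
    sub = panel.haplotypes[np.ix_(rows, interval)]
    _, counts = np.unique(sub, axis=0, return_counts=True)
    return counts


def ehh(panel: HaplotypePanel, core_hap: CoreHaplotype, direction: str, x_bp: int) -> float:
    """EHH of one core haplotype at physical boundary ``x_bp``.

    Carriers are partitioned by identity of their allele vector over all sites
    strictly between the core edge and x_bp inclusive; an empty interval gives
    EHH = 1.  Raises on fewer than two carriers.
    """
    if core_hap.n_carriers < 2:
        raise ValueError("EHH undefined for a core haplotype with < 2 carriers")
    interval = _interval_sites(panel, core_hap.core, direction, x_bp)
    same, pairs = _pair_homozygosity(
        _partition_sizes(panel, core_hap.carrier_rows, interval)
    )
    return same / pairs


def ehh_curve(
    panel: HaplotypePanel,
    core_hap: CoreHaplotype,
    direction: str,
    gmap: GeneticMap,
    max_cM: float = 0.5,
) -> EHHCurve:
    """EHH evaluated at successive marker boundaries out to ``max_cM``.

    The partition refines incrementally marker by marker, so the curve is
    non-increasing by construction.
    """
    if core_hap.n_carriers < 2:
        raise ValueError("EHH undefined for a core haplotype with < 2 carriers")
    core = core_hap.core
    pos = panel.positions_bp
    edge = core.right if direction == "downstream" else core.left
    edge_cM = interpolate_cM(gmap, int(pos[edge]))
    if direction == "downstream":
        markers = np.arange(edge + 1, panel.n_sites)
    else:
        markers = np.arange(edge - 1, -1, -1)
    rows = core_hap.carrier_rows
    labels = np.zeros(rows.size, dtype=np.int64)
    out_pos, out_d, out_e = [], [], []
    n_pairs = rows.size * (rows.size - 1) / 2
    for m in markers:
        d = abs(interpolate_cM(gmap, int(pos[m])) - edge_cM)
        if d > max_cM:
            break
        col = panel.haplotypes[rows, m]
        labels = labels * 2 + col
        _, labels, counts = np.unique(labels, return_inverse=True, return_counts=True)
        same = float((counts * (counts - 1) / 2).sum())
        out_pos.append(int(pos[m]))
        out_d.append(float(d))
        out_e.append(same / n_pairs)
    return EHHCurve(
        direction, core_hap,
        np.asarray(out_pos), np.asarray(out_d), np.asarray(out_e),
    )


def _boundary_marker(
    panel: HaplotypePanel, core: CoreRegion, direction: str,
    distance_cM: float, gmap: GeneticMap,
) -> int | None:
    """First marker at genetic distance >= distance_cM from the core edge."""
    pos = panel.positions_bp
    cms = interpolate_cM(gmap, pos)
    if direction == "downstream":
        edge_cM = cms[core.right]
        for m in range(core.right + 1, panel.n_sites):
            if cms[m] - edge_cM >= distance_cM:
                return m
    else:
        edge_cM = cms[core.left]
        for m in range(core.left - 1, -1, -1):
            if edge_cM - cms[m] >= distance_cM:
                return m
    return None


def rehh(
    panel: HaplotypePanel,
    core_haps: Sequence[CoreHaplotype],
    target: CoreHaplotype,
    direction: str,
    gmap: GeneticMap,
    distance_cM: float = 0.25,
) -> RehhRecord:
    """REHH of ``target`` against the other enumerated core haplotypes pooled.

    The evaluation boundary is the first marker whose genetic distance from
    the core edge reaches ``distance_cM``.  Undefined (NaN) when no such
    marker exists, when the target has < 2 carriers, or when no other core
    haplotype has >= 2 carriers; infinite when the others' pooled EHH is zero.
    """
    rec = RehhRecord(core=target, direction=direction, distance_cM=distance_cM,
                     rehh_value=float("nan"))
    m = _boundary_marker(panel, target.core, direction, distance_cM, gmap)
    if m is None or target.n_carriers < 2:
        return rec
    x_bp = int(panel.positions_bp[m])
    rec.boundary_bp = x_bp
    interval = _interval_sites(panel, target.core, direction, x_bp)
    same_t, pairs_t = _pair_homozygosity(
        _partition_sizes(panel, target.carrier_rows, interval)
    )
    others = [h for h in core_haps if h is not target and h.n_carriers >= 2]
    if not others:
        return rec
    same_o = 0.0
    pairs_o = 0.0
    for h in others:
        s, pr = _pair_homozygosity(_partition_sizes(panel, h.carrier_rows, interval))
        same_o += s
        pairs_o += pr
    rec.ehh_core = same_t / pairs_t
    rec.ehh_others = same_o / pairs_o
    if rec.ehh_others == 0.0:
        rec.rehh_value = float("inf") if rec.ehh_core > 0 else float("nan")
    else:
        rec.rehh_value = rec.ehh_core / rec.ehh_others
    return rec


def rehh_scan(
    panel: HaplotypePanel,
    pop: str | None,
    gmap: GeneticMap,
    blocks: Sequence[HaploBlock],
    distance_cM: float = 0.25,
    min_freq: float = 0.05,
    extra_cores: Sequence[CoreRegion] = (),
    log_transform: bool = True,
) -> list[RehhRecord]:
    """REHH for every core haplotype of every block, both directions, with
    within-bin empirical percentiles.

    Records are binned by core-haplotype frequency (20 bins of 0.05); the
    percentile of log(REHH) is midrank-ranked against all defined records in
    the same bin, pooling directions.  Records with percentile >= 95 are
    flagged ``significant``, >= 99 ``highlighted``.  Infinite or undefined
    REHH values are reported but excluded from ranking.
    """
    cores = [CoreRegion.from_block(b, panel) for b in blocks]
    blocks_by_core: list[HaploBlock | None] = list(blocks)
    for c in extra_cores:
        cores.append(c)
        blocks_by_core.append(None)
    records: list[RehhRecord] = []
    for core, blk in zip(cores, blocks_by_core):
        haps = enumerate_core_haplotypes(panel, core, pop, min_freq=min_freq)
        for target in haps:
            if target.n_carriers < 2:
                continue
            for direction in ("upstream", "downstream"):
                rec = rehh(panel, haps, target, direction, gmap, distance_cM)
                rec.block = blk
                rec.freq_bin = frequency_bin(target.frequency)
                records.append(rec)
    # within-bin percentile ranking
    for b in range(N_BINS):
        in_bin = [r for r in records if r.freq_bin == b and r.defined and r.rehh_value > 0]
        if not in_bin:
            continue
        vals = np.array([
            math.log(r.rehh_value) if log_transform else r.rehh_value
            for r in in_bin
        ])
        for r, v in zip(in_bin, vals):
            r.percentile = empirical_percentile(float(v), vals)
            r.significant = r.percentile >= FLAG_PERCENTILE
            r.highlighted = r.percentile >= HIGHLIGHT_PERCENTILE
    return records


def bin_reference(records: Sequence[RehhRecord], log_transform: bool = True) -> dict[int, np.ndarray]:
    """Frequency-binned log-REHH reference values from a set of scan records.

    Use records from neutral (or genome-wide) scans as an external empirical
    null when the scanned region itself is suspected to be under selection —
    e.g. ranking a candidate region against whole-chromosome bins.
    """
    out: dict[int, list[float]] = {b: [] for b in range(N_BINS)}
    for r in records:
        if r.defined and r.rehh_value > 0 and r.freq_bin is not None:
            out[r.freq_bin].append(
                math.log(r.rehh_value) if log_transform else r.rehh_value
            )
    return {b: np.asarray(v) for b, v in out.items()}


def rank_against_reference(
    record: RehhRecord,
    reference: dict[int, np.ndarray],
    min_bin_size: int = 20,
    log_transform: bool = True,
) -> float | None:
    """Midrank percentile of one record's (log-)REHH within its frequency bin
    of an external reference; None when the record is undefined or its bin has
    fewer than ``min_bin_size`` reference values."""
    if record.freq_bin is None or not record.defined or record.rehh_value <= 0:
        return None
    ref = reference.get(record.freq_bin)
    if ref is None or ref.size < min_bin_size:
        return None
    v = math.log(record.rehh_value) if log_transform else record.rehh_value
    return empirical_percentile(v, ref)


def sweep_core_records(
    records: Sequence[RehhRecord],
    panel: HaplotypePanel,
    focal_site: int,
    min_carrier_fraction: float = 0.5,
) -> list[RehhRecord]:
    """Scan records whose core spans ``focal_site`` and whose carriers are
    predominantly derived-allele carriers at that site — the records that test
    a putative sweep at the site."""
    carriers = set(np.flatnonzero(panel.haplotypes[:, focal_site] == 1).tolist())
    out = []
    for r in records:
        cs = r.core.core.site_indices
        if not (cs[0] <= focal_site <= cs[-1]) or r.core.n_carriers == 0:
            continue
        frac = len(set(r.core.carrier_rows.tolist()) & carriers) / r.core.n_carriers
        if frac > min_carrier_fraction:
            out.append(r)
    return out
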