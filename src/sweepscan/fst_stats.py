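"""Allele frequencies, expected heterozygosity, and Weir-Cockerham F_ST.

The estimator is the haploid (chromosome-level) Weir-Cockerham variance-
components theta: data are phased chromosomes, so the sampling unit is a single
chromosome and there is no within-individual component.  With r populations,
n_i sampled chromosomes and allele-1 frequency p_i in population i:

    n_bar = sum(n_i) / r
    n_c   = (sum(n_i) - sum(n_i^2)/sum(n_i)) / (r - 1)
    p_bar = sum(n_i p_i) / sum(n_i)
    s2    = sum(n_i (p_i - p_bar)^2) / ((r - 1) n_bar)
    b     = n_bar/(n_bar - 1) * (p_bar(1 - p_bar) - s2 (r - 1)/r)
    a     = n_bar/n_c * (s2 - b/n_bar)
    theta = a / (a + b)

Negative theta is reported as computed (the estimator is unbiased around zero
under panmixia); multi-site estimates combine components by the ratio of sums
sum(a) / sum(a + b).  Sites monomorphic and identical in every population have
a + b = 0 and an undefined theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .haplo_io import HaplotypePanel, PopulationLabelError

__all__ = [
    "AlleleFreqRecord",
    "FstRecord",
    "expected_het",
    "allele_freqs",
    "allele_freq_matrix",
    "wc_theta_site",
    "wc_theta_sites",
    "wc_theta_multi",
    "empirical_percentile",
    "pairwise_fst",
]


@dataclass(frozen=True)
class AlleleFreqRecord:
    site_id: str
    pop: str
    n_chrom: int
    p: float  # frequency of allele1
    He: float  # 2 p (1 - p)


@dataclass
class FstRecord:
    """Weir-Cockerham components for one or more sites.

    ``theta`` is ``a_comp / (a_comp + b_comp)``; ``defined`` is False when the
    denominator is zero (site monomorphic and identical everywhere), in which
    case ``theta`` is NaN and the record is excluded from empirical rankings.
    """

    site_ids: tuple[str, ...]
    pop_a: str
    pop_b: str
    a_comp: float
    b_comp: float
    theta: float
    defined: bool = True
    percentile: float | None = None


def expected_het(p) -> np.ndarray | float:
    """Expected heterozygosity 2p(1-p) of a biallelic site."""
    p = np.asarray(p, dtype=np.float64)
    he = 2.0 * p * (1.0 - p)
    return float(he) if he.ndim == 0 else he


def allele_freqs(
    panel: HaplotypePanel, site: int, pops: Iterable[str] | None = None
) -> list[AlleleFreqRecord]:
    """Per-population allele-1 frequency and He at one site (by site index)."""
    if pops is None:
        pops = panel.populations
    out = []
    sid = panel.sites[site].site_id
    for pop in pops:
        rows = panel.rows_for_pop(pop)
        col = panel.haplotypes[rows, site]
        p = float(col.mean())
        out.append(AlleleFreqRecord(sid, pop, len(rows), p, expected_het(p)))
    return out


def allele_freq_matrix(
    panel: HaplotypePanel, pops: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Allele-1 frequencies for all sites: returns ``(P, n)`` with ``P`` of
    shape (n_pops, n_sites) and ``n`` the chromosome count per population."""
    P = np.empty((len(pops), panel.n_sites))
    n = np.empty(len(pops), dtype=np.int64)
    for k, pop in enumerate(pops):
        rows = panel.rows_for_pop(pop)
        if rows.size == 0:
            raise PopulationLabelError(f"empty population {pop!r}")
        P[k] = panel.haplotypes[rows].mean(axis=0)
        n[k] = rows.size
    return P, n


def wc_theta_sites(P: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised haploid Weir-Cockerham components.

    Parameters
    ----------
    P : (r, L) array of allele-1 frequencies per population and site.
    n : (r,) chromosome counts per population.

    Returns
    -------
    (a, b) : per-site among-population and residual variance components.
    """
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    n = np.asarray(n, dtype=np.float64)
    r = n.size
    if r < 2:
        raise ValueError("need at least two populations")
    if np.any(n < 2):
        raise ValueError("each population needs >= 2 chromosomes")
    n_tot = n.sum()
    n_bar = n_tot / r
    n_c = (n_tot - (n ** 2).sum() / n_tot) / (r - 1)
    p_bar = (n[:, None] * P).sum(axis=0) / n_tot
    s2 = (n[:, None] * (P - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    b = n_bar / (n_bar - 1.0) * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r)
    a = n_bar / n_c * (s2 - b / n_bar)
    return a, b


def _record(a: float, b: float, site_ids, pop_a: str, pop_b: str) -> FstRecord:
    tot = a + b
    if tot == 0.0:
        return FstRecord(tuple(site_ids), pop_a, pop_b, a, b, float("nan"), defined=False)
    return FstRecord(tuple(site_ids), pop_a, pop_b, a, b, a / tot)


def wc_theta_site(
    freqs: Sequence[tuple[float, int]],
    site_ids: Sequence[str] = ("?",),
    pop_a: str = "multi",
    pop_b: str = "multi",
) -> FstRecord:
    """Weir-Cockerham theta for one site from (p_i, n_i) pairs over r >= 2
    populations (n_i in chromosomes).  For two populations pass the pair codes
    in ``pop_a``/``pop_b``; for r > 2 the record is labelled "multi"."""
    p = np.array([f[0] for f in freqs], dtype=np.float64)
    n = np.array([f[1] for f in freqs], dtype=np.float64)
    a, b = wc_theta_sites(p[:, None], n)
    return _record(float(a[0]), float(b[0]), site_ids, pop_a, pop_b)


def wc_theta_multi(records: Sequence[FstRecord]) -> FstRecord:
    """Multi-site theta by ratio of sums over the defined per-site records."""
    defined = [rec for rec in records if rec.defined]
    if not defined:
        rec0 = records[0] if records else FstRecord((), "multi", "multi", 0, 0, float("nan"), False)
        return FstRecord(
            tuple(s for rec in records for s in rec.site_ids),
            rec0.pop_a, rec0.pop_b, 0.0, 0.0, float("nan"), defined=False,
        )
    a = sum(rec.a_comp for rec in defined)
    b = sum(rec.b_comp for rec in defined)
    ids = tuple(s for rec in defined for s in rec.site_ids)
    return _record(a, b, ids, defined[0].pop_a, defined[0].pop_b)


def empirical_percentile(value: float, reference) -> float:
    """Midrank empirical percentile of ``value`` in ``reference``:
    ``100 * (#strictly below + 0.5 * #equal) / N``.  Values at or above the
    95th percentile are conventionally flagged significant."""
    ref = np.asarray(reference, dtype=np.float64)
    ref = ref[~np.isnan(ref)]
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    below = int(np.count_nonzero(ref < value))
    equal = int(np.count_nonzero(ref == value))
    return 100.0 * (below + 0.5 * equal) / ref.size


def pairwise_fst(
    panel: HaplotypePanel,
    site_ids: Sequence[str],
    pops: Sequence[str] | None = None,
    combine: bool = True,
    reference_sites: str = "all",
) -> list[FstRecord]:
    """Pairwise population F_ST at candidate sites with chromosome-wide
    empirical percentiles.

    For every population pair, per-site theta is computed at each candidate
    site; with ``combine=True`` a ratio-of-sums record over all candidates is
    appended.  Each defined record's percentile is its midrank position in the
    distribution of per-site thetas for that pair over the whole panel
    (monomorphic-everywhere sites excluded).
    """
    if pops is None:
        pops = panel.populations
    idx = [panel.site_index(s) for s in site_ids]
    out: list[FstRecord] = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pa, pb = pops[i], pops[j]
            P, n = allele_freq_matrix(panel, [pa, pb])
            a, b = wc_theta_sites(P, n)
            tot = a + b
            with np.errstate(invalid="ignore", divide="ignore"):
                theta_all = np.where(tot != 0, a / tot, np.nan)
            recs = []
            for k in idx:
                rec = _record(float(a[k]), float(b[k]), (panel.sites[k].site_id,), pa, pb)
                recs.append(rec)
            if combine and len(idx) > 1:
                recs.append(wc_theta_multi(recs))
            ref = theta_all if reference_sites == "all" else theta_all[idx]
            for rec in recs:
                if rec.defined:
                    rec.percentile = empirical_percentile(rec.theta, ref)
                out.append(rec)
    return out
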