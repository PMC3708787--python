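"""Phased haplotype panels, genetic maps, and readers/writers.

The central container is :class:`HaplotypePanel`: a chromosome x site matrix of
allele indices (0/1) over biallelic sites, with one population label per
chromosome row and paired rows per individual.  Everything downstream —
allele-frequency and F_ST estimation, LD/block construction, and EHH — consumes
this object, so loading is strict: only phased, biallelic, fully observed sites
survive.

Supported on-disk formats:

* phased VCF (``GT`` with ``|`` separators), read through :mod:`cyvcf2`;
* IMPUTE-style ``.hap``/``.legend``/``.sample`` triplet;
* an internal TSV dialect (header ``site_id chrom pos allele0 allele1`` then one
  column per chromosome named ``<sampleID>_A`` / ``<sampleID>_B``);
* HapMap-format genetic maps (``position  rate(cM/Mb)  cM``).

Coordinates are 1-based in files; region queries use half-open ``[start, end)``
intervals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantSite",
    "HaplotypePanel",
    "GeneticMap",
    "LoadReport",
    "PanelFormatError",
    "PopulationLabelError",
    "MapValidationError",
    "load_panel",
    "load_pop_map",
    "load_genetic_map",
    "interpolate_cM",
    "subset_panel",
    "write_panel_tsv",
    "write_panel_vcf",
    "write_panel_impute",
    "write_genetic_map",
]


class PanelFormatError(ValueError):
    """Raised when a haplotype file violates the format contract."""


class PopulationLabelError(KeyError):
    """Raised when an individual or requested population has no valid label."""


class MapValidationError(ValueError):
    """Raised when a genetic map file violates monotonicity or is empty."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic site: marker name, position, and its two allele labels."""

    site_id: str
    chrom: str
    pos_bp: int
    allele0: str
    allele1: str
    map_cM: float | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"{self.site_id}: pos_bp must be >= 1")
        if self.allele0 == self.allele1:
            raise ValueError(f"{self.site_id}: allele0 == allele1")


@dataclass
class LoadReport:
    """Bookkeeping from :func:`load_panel`: what was kept and what was dropped."""

    n_sites_kept: int = 0
    excluded_multiallelic: list[str] = field(default_factory=list)
    excluded_missing: list[str] = field(default_factory=list)
    excluded_nonsnp: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return (
            len(self.excluded_multiallelic)
            + len(self.excluded_missing)
            + len(self.excluded_nonsnp)
        )


@dataclass
class HaplotypePanel:
    """Phased chromosomes over ordered biallelic sites with population labels.

    ``haplotypes`` has one row per chromosome (2 per individual, stored
    adjacently: rows ``2k`` and ``2k+1`` belong to ``sample_ids[k]``) and one
    0/1 column per site in ``sites``.
    """

    sites: list[VariantSite]
    haplotypes: np.ndarray  # (n_chrom, n_sites) int8, entries in {0, 1}
    sample_ids: list[str]
    pop_labels: np.ndarray  # (n_chrom,) str

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        self.pop_labels = np.asarray(self.pop_labels, dtype=object)
        n_chrom, n_sites = self.haplotypes.shape
        if n_chrom != 2 * len(self.sample_ids):
            raise ValueError("chromosome rows must be 2 x individuals (paired)")
        if n_sites != len(self.sites):
            raise ValueError("site metadata / matrix width mismatch")
        if self.pop_labels.shape[0] != n_chrom:
            raise ValueError("one population label per chromosome row required")
        if n_sites and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("allele matrix entries must be 0/1 with no missing")
        pos = [(s.chrom, s.pos_bp) for s in self.sites]
        if any(a >= b for a, b in zip(pos, pos[1:]) if a[0] == b[0]):
            raise ValueError("(chrom, pos_bp) must be strictly increasing")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_chrom(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def rows_for_pop(self, pop: str | None) -> np.ndarray:
        """Chromosome row indices for one population (``None`` = all rows)."""
        if pop is None:
            return np.arange(self.n_chrom)
        rows = np.flatnonzero(self.pop_labels == pop)
        if rows.size == 0:
            raise PopulationLabelError(f"unknown or empty population {pop!r}")
        return rows

    def sample_of_row(self, row: int) -> str:
        return self.sample_ids[row // 2]

    @property
    def positions_bp(self) -> np.ndarray:
        return np.array([s.pos_bp for s in self.sites], dtype=np.int64)

    def site_index(self, site_id: str) -> int:
        for i, s in enumerate(self.sites):
            if s.site_id == site_id:
                return i
        raise KeyError(site_id)


@dataclass(frozen=True)
class GeneticMap:
    """Monotone physical-position -> centiMorgan function for one chromosome."""

    pos_bp: np.ndarray  # strictly increasing int64
    cM: np.ndarray  # non-decreasing float64
    chrom: str = "1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pos_bp", np.asarray(self.pos_bp, dtype=np.int64))
        object.__setattr__(self, "cM", np.asarray(self.cM, dtype=np.float64))
        if self.pos_bp.size == 0:
            raise MapValidationError("no map points")
        if np.any(np.diff(self.pos_bp) <= 0):
            raise MapValidationError("map positions must be strictly increasing")
        if np.any(np.diff(self.cM) < 0):
            raise MapValidationError("map cM must be non-decreasing")

    @property
    def n_points(self) -> int:
        return self.pos_bp.size


# ---------------------------------------------------------------------------
# population maps
# ---------------------------------------------------------------------------


def load_pop_map(source: str | Mapping[str, str]) -> dict[str, str]:
    """Read an individual -> population table (two-column TSV, optional header)."""
    if isinstance(source, Mapping):
        return dict(source)
    out: dict[str, str] = {}
    with open(source) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or line.startswith("#"):
                continue
            if ln == 1 and parts[0].lower() in {"sample", "sample_id", "individual", "id"}:
                continue
            if len(parts) < 2:
                raise PanelFormatError(f"pop map line {ln}: expected two columns")
            out[parts[0]] = parts[1]
    return out


def _labels_for(sample_ids: Sequence[str], pop_map: Mapping[str, str]) -> np.ndarray:
    missing = [s for s in sample_ids if s not in pop_map]
    if missing:
        raise PopulationLabelError(
            f"individuals absent from pop_map: {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    return np.array(
        [pop_map[s] for s in sample_ids for _ in (0, 1)], dtype=object
    )


# ---------------------------------------------------------------------------
# panel loading
# ---------------------------------------------------------------------------


def load_panel(
    path: str,
    format: str,
    pop_map: str | Mapping[str, str],
    return_report: bool = False,
):
    """Load a phased multi-population haplotype panel.

    Parameters
    ----------
    path
        File path.  For ``impute-hls`` pass the common prefix of the
        ``.hap``/``.legend``/``.sample`` triplet (or any one of the three files).
    format
        One of ``phased-vcf``, ``impute-hls``, ``tsv``.
    pop_map
        Individual -> population mapping (dict or two-column TSV path).  Every
        individual in the file must be present.
    return_report
        Also return a :class:`LoadReport` listing excluded sites.

    Sites that are multiallelic, non-biallelic after parsing, or carry missing
    genotypes are dropped (and reported); an *unphased* genotype is a format
    error naming the offending site.
    """
    popd = load_pop_map(pop_map)
    if format == "phased-vcf":
        panel, report = _load_vcf(path, popd)
    elif format == "impute-hls":
        panel, report = _load_impute(path, popd)
    elif format == "tsv":
        panel, report = _load_tsv(path, popd)
    else:
        raise ValueError(f"unknown panel format {format!r}")
    report.n_sites_kept = panel.n_sites
    return (panel, report) if return_report else panel


def _finish_panel(
    sites: list[VariantSite],
    columns: list[np.ndarray],
    sample_ids: list[str],
    pop_map: Mapping[str, str],
) -> HaplotypePanel:
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos_bp))
    sites = [sites[i] for i in order]
    if columns:
        mat = np.stack([columns[i] for i in order], axis=1).astype(np.int8)
    else:
        mat = np.zeros((2 * len(sample_ids), 0), dtype=np.int8)
    return HaplotypePanel(
        sites=sites,
        haplotypes=mat,
        sample_ids=sample_ids,
        pop_labels=_labels_for(sample_ids, pop_map),
    )


def _load_vcf(path: str, pop_map: Mapping[str, str]):
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    report = LoadReport()
    sites: list[VariantSite] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            report.excluded_multiallelic.append(vid)
            continue
        gts = var.genotypes  # [[a, b, phased], ...]
        col = np.empty(2 * len(sample_ids), dtype=np.int8)
        missing = False
        for k, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0 or len(g) < 3:
                missing = True
                break
            if not g[2]:
                raise PanelFormatError(
                    f"unphased genotype at site {vid} (sample {sample_ids[k]})"
                )
            col[2 * k] = a
            col[2 * k + 1] = b
        if missing:
            report.excluded_missing.append(vid)
            continue
        sites.append(
            VariantSite(vid, str(var.CHROM), int(var.POS), var.REF, var.ALT[0])
        )
        cols.append(col)
    return _finish_panel(sites, cols, sample_ids, pop_map), report


def _impute_paths(path: str) -> tuple[str, str, str]:
    base = path
    for ext in (".hap", ".legend", ".sample"):
        if base.endswith(ext):
            base = base[: -len(ext)]
    return base + ".hap", base + ".legend", base + ".sample"


def _load_impute(path: str, pop_map: Mapping[str, str]):
    hap_p, leg_p, smp_p = _impute_paths(path)
    samples: list[str] = []
    with open(smp_p) as fh:
        for ln, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if ln == 0 and parts[0].lower() in {"id", "id_1", "sample"}:
                continue
            samples.append(parts[0])
    legend = pd.read_csv(leg_p, sep=r"\s+")
    required = {"id", "position", "allele0", "allele1"}
    if not required.issubset(legend.columns):
        raise PanelFormatError(f"legend must have columns {sorted(required)}")
    chrom_col = legend["chrom"] if "chrom" in legend.columns else ["1"] * len(legend)
    hap = np.loadtxt(hap_p, dtype=np.int8, ndmin=2)
    if hap.shape[0] != len(legend):
        raise PanelFormatError("hap rows do not match legend rows")
    if hap.shape[1] != 2 * len(samples):
        raise PanelFormatError("hap columns do not match 2 x samples")
    report = LoadReport()
    sites: list[VariantSite] = []
    cols: list[np.ndarray] = []
    for i, row in enumerate(legend.itertuples(index=False)):
        col = hap[i]
        if not np.isin(col, (0, 1)).all():
            report.excluded_missing.append(str(row.id))
            continue
        sites.append(
            VariantSite(
                str(row.id), str(chrom_col[i]), int(row.position),
                str(row.allele0), str(row.allele1),
            )
        )
        cols.append(col.copy())
    return _finish_panel(sites, cols, samples, pop_map), report


def _load_tsv(path: str, pop_map: Mapping[str, str]):
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta = ["site_id", "chrom", "pos", "allele0", "allele1"]
    if list(df.columns[:5]) != meta:
        raise PanelFormatError(f"TSV header must start with {meta}")
    hap_cols = list(df.columns[5:])
    samples: list[str] = []
    for j in range(0, len(hap_cols), 2):
        a, b = hap_cols[j], hap_cols[j + 1]
        if not (a.endswith("_A") and b.endswith("_B") and a[:-2] == b[:-2]):
            raise PanelFormatError(f"chromosome columns must pair as ID_A/ID_B, got {a}/{b}")
        samples.append(a[:-2])
    report = LoadReport()
    sites: list[VariantSite] = []
    cols: list[np.ndarray] = []
    vals = df[hap_cols].to_numpy()
    for i in range(len(df)):
        try:
            col = vals[i].astype(np.int8)
        except ValueError:
            report.excluded_missing.append(df.iloc[i, 0])
            continue
        if not np.isin(col, (0, 1)).all():
            report.excluded_missing.append(df.iloc[i, 0])
            continue
        sites.append(
            VariantSite(
                str(df.iloc[i, 0]), str(df.iloc[i, 1]), int(df.iloc[i, 2]),
                str(df.iloc[i, 3]), str(df.iloc[i, 4]),
            )
        )
        cols.append(col)
    return _finish_panel(sites, cols, samples, pop_map), report


# ---------------------------------------------------------------------------
# genetic maps
# ---------------------------------------------------------------------------


def load_genetic_map(path: str, chrom: str = "1") -> GeneticMap:
    """Read a HapMap-format map (``position  rate_cM/Mb  cM``; header optional).

    Duplicate positions are collapsed to the last occurrence; a decreasing cM
    column raises :class:`MapValidationError` naming the offending line.
    """
    pos: list[int] = []
    cms: list[float] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or line.startswith("#"):
                continue
            try:
                p = int(float(parts[0]))
                c = float(parts[-1])
            except ValueError:
                if ln == 1:  # header
                    continue
                raise MapValidationError(f"map line {ln}: cannot parse {line.strip()!r}")
            if pos and p == pos[-1]:
                cms[-1] = c
                continue
            if pos and c < cms[-1]:
                raise MapValidationError(f"map line {ln}: cM decreases ({cms[-1]} -> {c})")
            if pos and p < pos[-1]:
                raise MapValidationError(f"map line {ln}: position decreases")
            pos.append(p)
            cms.append(c)
    if not pos:
        raise MapValidationError("no map points")
    return GeneticMap(np.array(pos), np.array(cms), chrom=chrom)


def interpolate_cM(gmap: GeneticMap, pos_bp) -> np.ndarray | float:
    """Genetic position (cM) at ``pos_bp``: linear between map points, with the
    terminal interval's rate extended beyond the map ends.  Exact at map points.
    """
    p = np.asarray(pos_bp, dtype=np.float64)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    x, y = gmap.pos_bp.astype(np.float64), gmap.cM
    out = np.interp(p, x, y)
    if x.size >= 2:
        lo_rate = (y[1] - y[0]) / (x[1] - x[0])
        hi_rate = (y[-1] - y[-2]) / (x[-1] - x[-2])
        below = p < x[0]
        above = p > x[-1]
        out[below] = y[0] + (p[below] - x[0]) * lo_rate
        out[above] = y[-1] + (p[above] - x[-1]) * hi_rate
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# subsetting
# ---------------------------------------------------------------------------


def subset_panel(
    panel: HaplotypePanel,
    region: tuple[str, int, int] | None = None,
    pops: Iterable[str] | None = None,
) -> HaplotypePanel:
    """Restrict a panel to a half-open region ``(chrom, start, end)`` and/or a
    set of populations.  Ordering is preserved; the result may have 0 sites.
    """
    site_idx = np.arange(panel.n_sites)
    if region is not None:
        chrom, start, end = region
        if start >= end:
            raise ValueError("region start must be < end")
        keep = [
            i for i, s in enumerate(panel.sites)
            if s.chrom == str(chrom) and start <= s.pos_bp < end
        ]
        site_idx = np.array(keep, dtype=int)
    if pops is None:
        rows = np.arange(panel.n_chrom)
        samples = list(panel.sample_ids)
    else:
        pops = list(pops)
        known = set(panel.populations)
        unknown = [p for p in pops if p not in known]
        if unknown:
            raise PopulationLabelError(f"unknown population code(s): {unknown}")
        keep_sample = [
            k for k, s in enumerate(panel.sample_ids)
            if panel.pop_labels[2 * k] in pops
        ]
        rows = np.array([r for k in keep_sample for r in (2 * k, 2 * k + 1)], dtype=int)
        samples = [panel.sample_ids[k] for k in keep_sample]
    return HaplotypePanel(
        sites=[panel.sites[i] for i in site_idx],
        haplotypes=panel.haplotypes[np.ix_(rows, site_idx)],
        sample_ids=samples,
        pop_labels=panel.pop_labels[rows],
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_panel_tsv(panel: HaplotypePanel, path: str) -> None:
    with open(path, "w") as fh:
        cols = [f"{s}_{ab}" for s in panel.sample_ids for ab in ("A", "B")]
        fh.write("\t".join(["site_id", "chrom", "pos", "allele0", "allele1"] + cols) + "\n")
        for j, s in enumerate(panel.sites):
            row = panel.haplotypes[:, j]
            fh.write(
                "\t".join(
                    [s.site_id, s.chrom, str(s.pos_bp), s.allele0, s.allele1]
                    + [str(int(v)) for v in row]
                )
                + "\n"
            )


def write_panel_vcf(panel: HaplotypePanel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(s.chrom for s in panel.sites):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j, s in enumerate(panel.sites):
            col = panel.haplotypes[:, j]
            gts = "\t".join(
                f"{col[2 * k]}|{col[2 * k + 1]}" for k in range(len(panel.sample_ids))
            )
            fh.write(
                f"{s.chrom}\t{s.pos_bp}\t{s.site_id}\t{s.allele0}\t{s.allele1}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_panel_impute(panel: HaplotypePanel, prefix: str) -> None:
    with open(prefix + ".legend", "w") as fh:
        fh.write("id position allele0 allele1 chrom\n")
        for s in panel.sites:
            fh.write(f"{s.site_id} {s.pos_bp} {s.allele0} {s.allele1} {s.chrom}\n")
    np.savetxt(prefix + ".hap", panel.haplotypes.T, fmt="%d")
    with open(prefix + ".sample", "w") as fh:
        fh.write("sample\n")
        for s in panel.sample_ids:
            fh.write(s + "\n")


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    """Write HapMap-format (position, rate cM/Mb, cumulative cM)."""
    with open(path, "w") as fh:
        fh.write("position\trate_cM_Mb\tcM\n")
        for i in range(gmap.n_points):
            if i + 1 < gmap.n_points:
                rate = (gmap.cM[i + 1] - gmap.cM[i]) / (gmap.pos_bp[i + 1] - gmap.pos_bp[i]) * 1e6
            else:
                rate = 0.0 if gmap.n_points == 1 else (
                    (gmap.cM[i] - gmap.cM[i - 1]) / (gmap.pos_bp[i] - gmap.pos_bp[i - 1]) * 1e6
                )
            fh.write(f"{gmap.pos_bp[i]}\t{rate:.6f}\t{gmap.cM[i]:.8f}\n")


def write_pop_map(pop_map: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpop\n")
        for k, v in pop_map.items():
            fh.write(f"{k}\t{v}\n")
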