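"""Per-site and windowed selection statistics.

Site-frequency-spectrum statistics (nucleotide diversity, Watterson's theta,
Tajima's D, Fu & Li's D, Fay & Wu's H) are computed over a set of sites
within one population; cross-population statistics (Weir-Cockerham FST,
dDAF, XP-EHH) compare the two populations of a panel per site.  The sliding
window scan uses 30 kb windows at a 3 kb offset; SFS statistics are computed
from the sites inside each window, per-site statistics are summarized by the
window maximum.

Undefined values (monomorphic windows, statistics whose preconditions fail
at a site) are reported as NaN and excluded from window summaries - never
silently zero.

Chromosomes are treated as haploid units throughout: the FST estimator is
the haploid Weir-Cockerham ANOVA on chromosome counts, with the Hudson
estimator available as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel import HaplotypePanel, PanelError

__all__ = [
    "WindowSpec",
    "StatTrack",
    "nucleotide_diversity",
    "watterson_theta",
    "theta_h",
    "tajimas_d",
    "fay_wu_h",
    "fu_li_d",
    "fst_weir_cockerham",
    "fst_hudson",
    "ddaf",
    "ehh",
    "xp_ehh",
    "windowed",
    "write_track_tsv",
    "SFS_STATISTICS",
    "PER_SITE_STATISTICS",
]

SFS_STATISTICS = ("pi", "theta_w", "tajima_d", "fu_li_d", "fay_wu_h")
PER_SITE_STATISTICS = ("fst", "ddaf", "xp_ehh")

#: statistics that require 0=ancestral / 1=derived coding
_POLARIZED = {"fu_li_d", "fay_wu_h", "ddaf"}


# ---------------------------------------------------------------------------
# helpers


def _site_counts(
    panel: HaplotypePanel,
    site_subset: np.ndarray | None,
    population: str | None,
    require_polarized: bool,
) -> tuple[np.ndarray, int]:
    """Derived-count per selected site within the population, and n."""
    rows = panel.rows(population)
    if rows.size < 2:
        raise PanelError("at least two chromosomes are required")
    if site_subset is None:
        idx = np.arange(panel.n_sites)
    else:
        idx = np.asarray(site_subset)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
    if require_polarized:
        if not panel.polarized:
            raise PanelError(
                "this statistic requires a polarized panel "
                "(0 = ancestral, 1 = derived); polarize the input first"
            )
        idx = idx[panel.ancestral_known[idx]]
    counts = panel.alleles[np.ix_(rows, idx)].sum(axis=0)
    return counts, rows.size


def _segregating(counts: np.ndarray, n: int) -> np.ndarray:
    return counts[(counts > 0) & (counts < n)]


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


# ---------------------------------------------------------------------------
# SFS statistics


def nucleotide_diversity(
    panel: HaplotypePanel,
    site_subset: np.ndarray | None = None,
    population: str | None = None,
) -> float:
    """Mean pairwise difference pi = sum_sites 2p(1-p) n/(n-1)."""
    counts, n = _site_counts(panel, site_subset, population, False)
    p = counts / n
    return float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))


def watterson_theta(
    panel: HaplotypePanel,
    site_subset: np.ndarray | None = None,
    population: str | None = None,
) -> float:
    """Watterson's estimator S / a_n with a_n the (n-1)-th harmonic number."""
    counts, n = _site_counts(panel, site_subset, population, False)
    s = _segregating(counts, n).size
    return s / _harmonic(n)


def theta_h(
    panel: HaplotypePanel,
    site_subset: np.ndarray | None = None,
    population: str | None = None,
) -> float:
    """Fay & Wu's homozygosity-weighted theta_H = sum_i S_i 2 i^2 / (n(n-1))."""
    counts, n = _site_counts(panel, site_subset, population, True)
    i = _segregating(counts, n).astype(float)
    return float(np.sum(2.0 * i**2) / (n * (n - 1)))


def tajimas_d(
    panel: HaplotypePanel,
    site_subset: np.ndarray | None = None,
    population: str | None = None,
) -> float:
    """Tajima's D; NaN when there are no segregating sites."""
    counts, n = _site_counts(panel, site_subset, population, False)
    seg = _segregating(counts, n)
    s = seg.size
    if s == 0:
        return float("nan")
    p = seg / n
    pi = float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return (pi - s / a1) / np.sqrt(var)


def fay_wu_h(
    panel: HaplotypePanel,
    site_subset: np.ndarray | None = None,
    population: str | None = None,
) -> float:
    """Unstandardized Fay & Wu's H = pi - theta_H (polarized sites only)."""
    counts, n = _site_counts(panel, site_subset, population, True)
    i = _segregating(counts, n).astype(float)
    p = i / n
    pi = float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))
    th = float(np.sum(2.0 * i**2) / (n * (n - 1)))
    return pi - th


def fu_li_d(
    panel: HaplotypePanel,
    site_subset: np.ndarray | None = None,
    population: str | None = None,
) -> float:
    """Fu & Li's D, outgroup variant: singletons are *derived* singletons.

    D = (eta - a_n * eta_e) / sqrt(u_D * eta + v_D * eta^2) with the Fu & Li
    (1993) constants; eta is the number of segregating mutations and eta_e
    the number of sites whose derived allele occurs exactly once.  NaN when
    eta = 0.
    """
    counts, n = _site_counts(panel, site_subset, population, True)
    seg = _segregating(counts, n)
    eta = seg.size
    if eta == 0:
        return float("nan")
    eta_e = int(np.sum(seg == 1))
    a_n = _harmonic(n)
    b_n = _harmonic(n, 2)
    if n == 2:
        c_n = 1.0
    else:
        c_n = 2.0 * (n * a_n - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1.0 + (a_n**2 / (b_n + a_n**2)) * (c_n - (n + 1.0) / (n - 1.0))
    u_d = a_n - 1.0 - v_d
    var = u_d * eta + v_d * eta**2
    if var <= 0:
        return float("nan")
    return (eta - a_n * eta_e) / np.sqrt(var)


# ---------------------------------------------------------------------------
# population differentiation


def fst_weir_cockerham(
    count_derived_1: float,
    n_1: int,
    count_derived_2: float,
    n_2: int,
) -> float:
    """Haploid Weir-Cockerham ANOVA FST from per-population derived counts.

    Counts may be fractional when reconstructed from published frequencies.
    With p_i = c_i / n_i the estimator is (MSP - MSG) / (MSP + (n_c - 1) MSG)
    where MSP and MSG are the between- and within-population mean squares and
    n_c the variance-effective sample size.  NaN when the pooled sample is
    monomorphic; negative estimates are reported as computed.
    """
    n = np.array([n_1, n_2], dtype=float)
    if np.any(n < 2):
        raise ValueError("chromosome counts must be >= 2 per population")
    p = np.array([count_derived_1, count_derived_2], dtype=float) / n
    if np.any((p < 0) | (p > 1)):
        raise ValueError("derived counts must lie in [0, n]")
    pbar = float(np.sum(n * p) / np.sum(n))
    if pbar in (0.0, 1.0):
        return float("nan")
    r = 2
    msp = float(np.sum(n * (p - pbar) ** 2) / (r - 1))
    msg = float(np.sum(n * p * (1.0 - p)) / np.sum(n - 1.0))
    n_c = (np.sum(n) - np.sum(n**2) / np.sum(n)) / (r - 1)
    denom = msp + (n_c - 1.0) * msg
    if denom == 0.0:
        return float("nan")
    return (msp - msg) / denom


def fst_hudson(
    count_derived_1: float,
    n_1: int,
    count_derived_2: float,
    n_2: int,
) -> float:
    """Hudson's FST: 1 - (mean unbiased within-het.) / (between-het.).

    Serves as the independent cross-check for the Weir-Cockerham estimator.
    """
    p1 = count_derived_1 / n_1
    p2 = count_derived_2 / n_2
    hw = 0.5 * (
        2.0 * p1 * (1 - p1) * n_1 / (n_1 - 1) + 2.0 * p2 * (1 - p2) * n_2 / (n_2 - 1)
    )
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    if hb == 0.0:
        return float("nan")
    return 1.0 - hw / hb


def ddaf(
    panel: HaplotypePanel, site_index: int, pop_a: str, pop_b: str
) -> float:
    """Signed derived-allele-frequency difference DAF(pop_a) - DAF(pop_b)."""
    from .panel import derived_allele_freq

    return derived_allele_freq(panel, site_index, pop_a) - derived_allele_freq(
        panel, site_index, pop_b
    )


def _fst_track_values(panel: HaplotypePanel, pop_a: str, pop_b: str) -> np.ndarray:
    """Vectorized per-site Weir-Cockerham FST between two populations."""
    ra, rb = panel.rows(pop_a), panel.rows(pop_b)
    n = np.array([[ra.size], [rb.size]], dtype=float)
    c = np.vstack(
        [panel.alleles[ra].sum(axis=0), panel.alleles[rb].sum(axis=0)]
    ).astype(float)
    p = c / n
    pbar = (n * p).sum(axis=0) / n.sum()
    msp = (n * (p - pbar) ** 2).sum(axis=0)
    msg = (n * p * (1 - p)).sum(axis=0) / (n - 1).sum()
    n_c = n.sum() - (n**2).sum() / n.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (msp - msg) / (msp + (n_c - 1) * msg)
    out[(pbar == 0) | (pbar == 1)] = np.nan
    return out


# ---------------------------------------------------------------------------
# haplotype homozygosity


def _ehh_curve(
    alleles: np.ndarray,
    positions: np.ndarray,
    core_idx: int,
    direction: str,
    stop_below: float | None = None,
    limit: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH at each site outward from the core (exclusive).

    Returns (distance from core in bp, EHH), starting at (0, 1).  The
    spanning haplotype covers the sites strictly beyond the core, so the
    curve starts at exactly 1 and is non-increasing.  ``stop_below`` ends
    the curve one point after EHH first drops below the threshold;
    ``limit`` caps the number of extension sites.
    """
    n = alleles.shape[0]
    pairs = n * (n - 1) / 2.0
    if direction == "right":
        order = range(core_idx + 1, alleles.shape[1])
    elif direction == "left":
        order = range(core_idx - 1, -1, -1)
    else:
        raise ValueError("direction must be 'left' or 'right'")
    core_pos = positions[core_idx]
    dists = [0.0]
    values = [1.0]
    group = np.zeros(n, dtype=np.int64)
    for step, j in enumerate(order):
        if limit is not None and step >= limit:
            break
        group = group * 2 + alleles[:, j]
        _, group, counts = np.unique(group, return_inverse=True, return_counts=True)
        v = float(np.sum(counts * (counts - 1) / 2.0) / pairs)
        values.append(v)
        dists.append(abs(float(positions[j]) - float(core_pos)))
        if stop_below is not None and v < stop_below:
            break
    return np.array(dists), np.array(values)


def ehh(
    panel: HaplotypePanel,
    core_site: int,
    direction: str = "right",
    population: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extended haplotype homozygosity decay from a core site (bp position).

    Returns arrays (distance, EHH); EHH(0) = 1 and the curve is
    non-increasing with distance.
    """
    idx = panel.site_at(core_site)
    rows = panel.rows(population)
    return _ehh_curve(panel.alleles[rows], panel.positions, idx, direction)


def _ihh_pair(
    alleles_a: np.ndarray,
    alleles_b: np.ndarray,
    alleles_pooled: np.ndarray,
    positions: np.ndarray,
    core_idx: int,
    threshold: float = 0.05,
) -> tuple[float, float]:
    """Integrated EHH for two populations, truncated where pooled EHH < threshold."""
    ihh_a = ihh_b = 0.0
    for direction in ("left", "right"):
        d, e_pool = _ehh_curve(
            alleles_pooled, positions, core_idx, direction, stop_below=threshold
        )
        span = d.size - 1  # pooled curve already ends where EHH < threshold
        _, e_a = _ehh_curve(alleles_a, positions, core_idx, direction, limit=span)
        _, e_b = _ehh_curve(alleles_b, positions, core_idx, direction, limit=span)
        ihh_a += float(np.trapezoid(e_a, d))
        ihh_b += float(np.trapezoid(e_b, d))
    return ihh_a, ihh_b


def xp_ehh(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    core_site: int,
    reference_ensemble: np.ndarray | None = None,
) -> float:
    """Cross-population EHH score at a core site (bp position).

    EHH decay curves for both populations are integrated (trapezoid, over
    physical distance, both directions) out to where the pooled-sample EHH
    drops below 0.05 or the region edge; the unstandardized score is
    ln(iHH_A / iHH_B).  If ``reference_ensemble`` (scores from neutral
    replicates) is given, the standardized score
    (score - mean) / sd is returned instead.  NaN when either integral is 0.
    """
    if not np.array_equal(panel_a.positions, panel_b.positions):
        raise PanelError("panels must share the same site positions")
    idx = panel_a.site_at(core_site)
    pooled = np.vstack([panel_a.alleles, panel_b.alleles])
    ihh_a, ihh_b = _ihh_pair(
        panel_a.alleles, panel_b.alleles, pooled, panel_a.positions, idx
    )
    if ihh_a <= 0.0 or ihh_b <= 0.0:
        return float("nan")
    score = float(np.log(ihh_a / ihh_b))
    if reference_ensemble is not None:
        ref = np.asarray(reference_ensemble, dtype=float)
        ref = ref[~np.isnan(ref)]
        return (score - ref.mean()) / ref.std(ddof=0)
    return score


def xp_ehh_between(
    panel: HaplotypePanel,
    core_site: int,
    pop_a: str,
    pop_b: str,
    reference_ensemble: np.ndarray | None = None,
) -> float:
    """XP-EHH between two populations of one panel (see :func:`xp_ehh`)."""
    idx = panel.site_at(core_site)
    ra, rb = panel.rows(pop_a), panel.rows(pop_b)
    ihh_a, ihh_b = _ihh_pair(
        panel.alleles[ra],
        panel.alleles[rb],
        panel.alleles[np.concatenate([ra, rb])],
        panel.positions,
        idx,
    )
    if ihh_a <= 0.0 or ihh_b <= 0.0:
        return float("nan")
    score = float(np.log(ihh_a / ihh_b))
    if reference_ensemble is not None:
        ref = np.asarray(reference_ensemble, dtype=float)
        ref = ref[~np.isnan(ref)]
        return (score - ref.mean()) / ref.std(ddof=0)
    return score


# ---------------------------------------------------------------------------
# windows


@dataclass
class WindowSpec:
    """Sliding-window convention: 30 kb windows every 3 kb, half-open."""

    width: int = 30_000
    offset: int = 3_000

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")
        if not 0 < self.offset <= self.width:
            raise ValueError("offset must satisfy 0 < offset <= width")

    def starts(self, region_length: int) -> np.ndarray:
        """Window start positions: multiples of the offset with the full
        window inside [0, region_length)."""
        if region_length < self.width:
            raise ValueError("region shorter than the window width")
        last = (region_length - self.width) // self.offset
        return np.arange(last + 1, dtype=np.int64) * self.offset


@dataclass
class StatTrack:
    """One statistic evaluated along a region (windows or single sites)."""

    statistic: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    populations: tuple[str, ...] = ()
    n_sites: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.n_sites is None:
            self.n_sites = np.zeros_like(self.starts)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts, ends, values must have equal length")
        if np.any(np.diff(self.starts) < 0):
            raise ValueError("track coordinates must be sorted")


_SFS_FUNCS = {
    "pi": nucleotide_diversity,
    "theta_w": watterson_theta,
    "tajima_d": tajimas_d,
    "fu_li_d": fu_li_d,
    "fay_wu_h": fay_wu_h,
}


def per_site_track(
    panel: HaplotypePanel, statistic: str, pop_a: str, pop_b: str
) -> StatTrack:
    """Per-site FST, dDAF or XP-EHH values between two populations."""
    if statistic == "fst":
        values = _fst_track_values(panel, pop_a, pop_b)
    elif statistic == "ddaf":
        if not panel.polarized:
            raise PanelError("dDAF requires a polarized panel")
        fa = panel.derived_counts(pop_a) / panel.rows(pop_a).size
        fb = panel.derived_counts(pop_b) / panel.rows(pop_b).size
        values = fa - fb
        values = np.where(panel.ancestral_known, values, np.nan)
    elif statistic == "xp_ehh":
        values = np.array(
            [
                xp_ehh_between(panel, int(pos), pop_a, pop_b)
                for pos in panel.positions
            ]
        )
    else:
        raise ValueError(f"unknown per-site statistic {statistic!r}")
    return StatTrack(
        statistic=statistic,
        starts=panel.positions,
        ends=panel.positions + 1,
        values=values,
        populations=(pop_a, pop_b),
        n_sites=np.ones(panel.n_sites, dtype=np.int64),
    )


def windowed(
    panel: HaplotypePanel,
    statistic: str,
    window: WindowSpec | None = None,
    population: str | None = None,
    populations: tuple[str, str] | None = None,
) -> StatTrack:
    """Sliding-window track of one statistic.

    SFS statistics are computed from the sites inside each half-open window
    ``[start, start + width)``; per-site statistics (``fst``, ``ddaf``,
    ``xp_ehh``) are summarized by the maximum defined per-site value in the
    window.  Windows with no usable site carry NaN.
    """
    window = window or WindowSpec()
    starts = window.starts(panel.region_length)
    ends = starts + window.width
    values = np.full(starts.size, np.nan)
    nsites = np.zeros(starts.size, dtype=np.int64)
    if statistic in _SFS_FUNCS:
        func = _SFS_FUNCS[statistic]
        for k, (a, b) in enumerate(zip(starts, ends)):
            idx = np.flatnonzero((panel.positions >= a) & (panel.positions < b))
            nsites[k] = idx.size
            if idx.size:
                values[k] = func(panel, site_subset=idx, population=population)
        pops = (population,) if population else ()
    elif statistic in PER_SITE_STATISTICS:
        if populations is None:
            pops_all = panel.populations
            if len(pops_all) != 2:
                raise PanelError(
                    f"{statistic} needs exactly two populations; pass `populations`"
                )
            populations = (pops_all[0], pops_all[1])
        site_track = per_site_track(panel, statistic, *populations)
        for k, (a, b) in enumerate(zip(starts, ends)):
            inside = (panel.positions >= a) & (panel.positions < b)
            vals = site_track.values[inside]
            vals = vals[~np.isnan(vals)]
            nsites[k] = vals.size
            if vals.size:
                values[k] = vals.max()
        pops = populations
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return StatTrack(
        statistic=statistic,
        starts=starts,
        ends=ends,
        values=values,
        populations=tuple(p for p in pops if p),
        n_sites=nsites,
    )


def write_track_tsv(track: StatTrack, path: str | Path, region_id: str = "region") -> None:
    """Write a track as TSV: statistic, region, start, end, value, n_sites."""
    with Path(path).open("w") as fh:
        fh.write("statistic\tregion\tstart\tend\tvalue\tn_sites\n")
        for a, b, v, m in zip(track.starts, track.ends, track.values, track.n_sites):
            val = "NA" if np.isnan(v) else f"{v:.6g}"
            fh.write(f"{track.statistic}\t{region_id}\t{a}\t{b}\t{val}\t{m}\n")
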