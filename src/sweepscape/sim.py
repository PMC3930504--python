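"""Two-population sweep simulator with configurable recombination landscape.

The demographic model is the calibrated human two-population history of the
cosi best-fit model (African and European demes, out-of-Africa split 3,500
generations ago), with three modifications: all migration is set to zero,
both post-split population bottlenecks are moved back to 3,300 generations
before present, and the selective sweep ends 350 generations before present
so that the terminal population expansions are retained.  A sweep raises a
single derived allele in the African population to frequency 0.98.

Because migration is zero, the two-population genealogy decomposes exactly:
African lineages (with the structured sweep coalescent) and European
lineages (neutral) are simulated separately back to the split time, the two
partial tree sequences are joined, and the ancestral population is
coalesced in a final pass.  msprime provides the coalescent machinery; the
sweep conditioning follows the discoal-style stochastic frequency
trajectory.  Note msprime parameterizes genic selection with heterozygote
fitness 1 + s/2, half the cosi convention, so the engine passes ``2 s``.

The simulated region is 100 kb with the selected site at the midpoint;
sample sizes default to 176 African and 194 European chromosomes.  To mimic
the under-calling of singletons in low-coverage sequence data, 48% of
singleton sites are removed from each simulated panel before statistics are
taken.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import HaplotypePanel
from . import stats as sstats

logger = logging.getLogger(__name__)

__all__ = [
    "RecombinationMap",
    "TwoPopDemography",
    "SweepScenario",
    "Trajectory",
    "SimulationEnsemble",
    "SweepSimulationError",
    "sweep_trajectory",
    "build_recomb_map",
    "simulate_panel",
    "thin_singletons",
    "extract_summaries",
    "run_ensemble",
    "DEFAULT_SCENARIOS",
    "SUMMARY_STATISTICS",
]

CM_PER_MB = 1e-8  # 1 cM/Mb in crossovers per bp per generation

SUMMARY_STATISTICS = ("fst", "ddaf", "xp_ehh", "tajima_d", "fu_li_d", "fay_wu_h")


class SweepSimulationError(RuntimeError):
    """A replicate could not be simulated (e.g. the stochastic sweep
    trajectory outlasted the constant-size epoch); the caller may redraw."""


# ---------------------------------------------------------------------------
# recombination maps


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination rates over [0, region_length).

    ``breakpoints`` has one more entry than ``rates`` and spans the region
    exactly; rates are crossovers per bp per generation.
    """

    breakpoints: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.breakpoints.size != self.rates.size + 1:
            raise ValueError("need one more breakpoint than rates")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.breakpoints[0] != 0:
            raise ValueError("map must start at position 0")
        if np.any(self.rates < 0):
            raise ValueError("recombination rates must be non-negative")

    @property
    def region_length(self) -> int:
        return int(self.breakpoints[-1])

    @property
    def map_length(self) -> float:
        """Expected crossovers per generation over the whole region."""
        return float(np.sum(self.rates * np.diff(self.breakpoints)))

    def to_msprime(self):
        import msprime

        return msprime.RateMap(position=self.breakpoints, rate=self.rates)

    @property
    def mean_rate(self) -> float:
        return self.map_length / self.region_length


def build_recomb_map(
    kind: str,
    region_length: int = 100_000,
    *,
    rate: float = 8.17e-9,
    background: float = 1e-8,
    hotspot_rate: float = 7e-8,
    hotspot_width: int = 3_500,
    hotspot_start: int | None = None,
    path: str | Path | None = None,
) -> RecombinationMap:
    """Build a constant, background-plus-hotspot, or file-based map.

    ``constant``: one interval at ``rate`` (default 8.17e-9, the mean rate
    of the studied 100 kb region).  ``hotspot``: ``background`` everywhere
    except a ``hotspot_width`` bp interval at ``hotspot_rate`` (~7 cM/Mb,
    roughly 7-fold background) placed immediately to the right of the region
    midpoint, next to the selected site.  ``from_file``: two-column text
    (position_bp, rate_cM_per_Mb), HapMap style: each rate applies from its
    position to the next.
    """
    if kind == "constant":
        return RecombinationMap(np.array([0.0, region_length]), np.array([rate]))
    if kind == "hotspot":
        if hotspot_width == 0:
            return RecombinationMap(
                np.array([0.0, region_length]), np.array([background])
            )
        start = region_length // 2 + 1 if hotspot_start is None else hotspot_start
        end = start + hotspot_width
        if not 0 < start < end < region_length:
            raise ValueError("hotspot must lie inside the region")
        return RecombinationMap(
            np.array([0.0, start, end, region_length]),
            np.array([background, hotspot_rate, background]),
        )
    if kind == "from_file":
        if path is None:
            raise ValueError("from_file requires a path")
        data = np.loadtxt(path, ndmin=2)
        pos = data[:, 0]
        cm_mb = data[:, 1]
        if pos[0] != 0:
            pos = np.insert(pos, 0, 0.0)
            cm_mb = np.insert(cm_mb, 0, cm_mb[0])
        breakpoints = np.append(pos, region_length)
        return RecombinationMap(breakpoints, cm_mb * CM_PER_MB)
    raise ValueError(f"unknown map kind {kind!r}")


# ---------------------------------------------------------------------------
# demography


@dataclass
class TwoPopDemography:
    """Calibrated African/European history with the sweep-study modifications.

    Sizes are diploid effective sizes; times are generations before present.
    Migration is structurally zero (the genealogy decomposition relies on
    it).  Bottlenecks are cosi-style instantaneous events with inbreeding
    probability F, mapped to coalescent bottleneck strength -2N ln(1-F).
    """

    n_afr_present: int = 100_000
    afr_expansion_time: float = 200.0
    n_afr: int = 24_000  # agriculture-era African size; the sweep epoch
    n_eur_present: int = 100_000
    eur_expansion_time: float = 350.0
    n_eur: int = 7_700
    bottleneck_time: float = 3_300.0  # both post-split bottlenecks (modified)
    afr_bottleneck_f: float = 0.008
    eur_bottleneck_f: float = 0.02
    ooa_bottleneck_time: float = 3_499.0
    ooa_bottleneck_f: float = 0.085
    split_time: float = 3_500.0
    n_ancestral: int = 12_500
    ancestral_change_time: float = 17_000.0

    @property
    def sweep_epoch_size(self) -> int:
        """African size during the sweep window (end_time .. bottleneck)."""
        return self.n_afr

    @staticmethod
    def _bneck_strength(n: int, f: float) -> float:
        return float(-2.0 * n * np.log1p(-f))

    def afr_demography(self):
        """Single-deme African history up to the split (for the sweep stage)."""
        import msprime

        d = msprime.Demography()
        d.add_population(name="AFR", initial_size=self.n_afr_present)
        d.add_population_parameters_change(
            time=self.afr_expansion_time, initial_size=self.n_afr, population="AFR"
        )
        d.add_instantaneous_bottleneck(
            time=self.bottleneck_time,
            strength=self._bneck_strength(self.n_afr, self.afr_bottleneck_f),
            population="AFR",
        )
        return d

    def eur_demography(self):
        import msprime

        d = msprime.Demography()
        d.add_population(name="EUR", initial_size=self.n_eur_present)
        d.add_population_parameters_change(
            time=self.eur_expansion_time, initial_size=self.n_eur, population="EUR"
        )
        d.add_instantaneous_bottleneck(
            time=self.bottleneck_time,
            strength=self._bneck_strength(self.n_eur, self.eur_bottleneck_f),
            population="EUR",
        )
        d.add_instantaneous_bottleneck(
            time=self.ooa_bottleneck_time,
            strength=self._bneck_strength(self.n_eur, self.ooa_bottleneck_f),
            population="EUR",
        )
        return d

    def merge_demography(self):
        """Post-split (backward) demography: both demes merge into the
        ancestral African lineage just after the split time."""
        import msprime

        d = msprime.Demography()
        d.add_population(name="AFR", initial_size=self.n_afr)
        d.add_population(name="EUR", initial_size=self.n_eur)
        # an event at exactly the resume time would not fire; offset by half
        # a generation (no coalescence can be lost in half a generation)
        d.add_mass_migration(
            time=self.split_time + 0.5, source="EUR", dest="AFR", proportion=1.0
        )
        d.add_population_parameters_change(
            time=self.ancestral_change_time,
            initial_size=self.n_ancestral,
            population="AFR",
        )
        return d

    def event_schedule(self) -> list[dict]:
        """Human-readable event list for run manifests."""
        return [
            {"time": 0, "event": "size", "pop": "AFR", "size": self.n_afr_present},
            {"time": 0, "event": "size", "pop": "EUR", "size": self.n_eur_present},
            {"time": self.afr_expansion_time, "event": "size", "pop": "AFR", "size": self.n_afr},
            {"time": self.eur_expansion_time, "event": "size", "pop": "EUR", "size": self.n_eur},
            {"time": self.bottleneck_time, "event": "bottleneck", "pop": "AFR", "F": self.afr_bottleneck_f},
            {"time": self.bottleneck_time, "event": "bottleneck", "pop": "EUR", "F": self.eur_bottleneck_f},
            {"time": self.ooa_bottleneck_time, "event": "bottleneck", "pop": "EUR", "F": self.ooa_bottleneck_f},
            {"time": self.split_time, "event": "split", "derived": ["AFR", "EUR"]},
            {"time": self.ancestral_change_time, "event": "size", "pop": "AFR", "size": self.n_ancestral},
            {"event": "migration", "rate": 0.0},
        ]


# ---------------------------------------------------------------------------
# scenarios and trajectories


@dataclass
class SweepScenario:
    """Directional selection on one derived allele in the African deme.

    ``s`` is the cosi-convention selection coefficient (homozygote fitness
    1 + 2s, additive); ``s = 0`` means neutrality.  The sweep reaches
    ``final_freq`` at ``end_time`` generations before present; the selected
    site sits at the region midpoint unless given.
    """

    s: float = 0.0
    final_freq: float = 0.98
    end_time: float = 350.0
    position: int | None = None
    recomb: str = "constant"  # label only; the map is passed separately
    trajectory_mode: str = "stochastic"

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0.0 < self.final_freq < 1.0:
            raise ValueError("final frequency must lie in (0, 1)")
        if self.end_time < 0:
            raise ValueError("sweep end time must be >= 0")

    @property
    def neutral(self) -> bool:
        return self.s == 0.0

    @property
    def name(self) -> str:
        base = "neutral" if self.neutral else f"s{self.s:g}"
        return f"{base}_{self.recomb}"


@dataclass
class Trajectory:
    """Allele-frequency path of the selected allele.

    ``times`` are generations before present, decreasing toward the present;
    ``freqs`` run from the origination frequency 1/(2N) up to the final
    frequency.
    """

    times: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.times.shape != self.freqs.shape:
            raise ValueError("times and freqs must have equal length")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if np.any(np.diff(self.times) > 0):
            raise ValueError("times must decrease toward the present")

    @property
    def duration(self) -> float:
        return float(self.times[0] - self.times[-1])

    @property
    def onset_time(self) -> float:
        return float(self.times[0])


def deterministic_sweep_duration(s: float, n_pop: int, p_final: float = 0.98) -> float:
    """Closed-form logistic sweep duration from p0 = 1/(2N) to p_final.

    T = (1/s) ln( p_f (1 - p0) / (p0 (1 - p_f)) ); doubling s exactly halves
    the duration.  With N = 24,000 and p_f = 0.98 this gives 2,934 / 1,467 /
    489 generations for s = 0.005 / 0.01 / 0.03.
    """
    if s <= 0:
        raise ValueError("selection coefficient must be positive")
    p0 = 1.0 / (2.0 * n_pop)
    if p_final <= p0:
        raise ValueError("final frequency must exceed the origination frequency")
    return float(np.log(p_final * (1 - p0) / (p0 * (1 - p_final))) / s)


def sweep_trajectory(
    s: float,
    demography: TwoPopDemography | int,
    p_final: float = 0.98,
    end_time: float = 350.0,
    mode: str = "deterministic",
    seed: int | None = None,
    n_points: int = 512,
) -> Trajectory:
    """Frequency path of the selected allele, ending at ``end_time``.

    ``deterministic``: the logistic genic-selection path integrated from
    p0 = 1/(2N).  ``stochastic``: a conditioned Wright-Fisher diffusion
    bridge with the same endpoints, generated backward in time with drift
    s x (1-x) / (1 - exp(-2Ns x)) (the fixation-conditioned genic drift) and
    per-generation variance x(1-x)/(2N).
    """
    n_pop = (
        demography.sweep_epoch_size
        if isinstance(demography, TwoPopDemography)
        else int(demography)
    )
    if s <= 0:
        raise ValueError("a sweep requires s > 0")
    p0 = 1.0 / (2.0 * n_pop)
    if p_final <= p0:
        raise ValueError("final frequency must exceed 1/(2N)")
    if mode == "deterministic":
        duration = deterministic_sweep_duration(s, n_pop, p_final)
        tau = np.linspace(0.0, duration, n_points)  # time since onset
        logit0 = np.log(p0 / (1 - p0))
        freqs = 1.0 / (1.0 + np.exp(-(logit0 + s * tau)))
        freqs[0], freqs[-1] = p0, p_final
        times = end_time + duration - tau
        return Trajectory(times=times, freqs=freqs)
    if mode == "stochastic":
        rng = np.random.default_rng(seed)
        alpha = 2.0 * n_pop * s
        x = p_final
        t = end_time
        times = [t]
        freqs = [x]
        max_steps = int(200.0 / s)  # generous cap; E[T] ~ (2/s) ln(2Ns)
        for _ in range(max_steps):
            drift = s * x * (1 - x) / -np.expm1(-alpha * x)
            noise = rng.normal(0.0, np.sqrt(max(x * (1 - x), 0.0) / (2 * n_pop)))
            x = x - drift + noise
            t += 1.0
            if x >= 1.0:
                x = 1.0 - 1.0 / (4 * n_pop)
            if x <= p0:
                x = p0
                times.append(t)
                freqs.append(x)
                break
            times.append(t)
            freqs.append(x)
        else:
            raise SweepSimulationError("stochastic trajectory failed to absorb")
        return Trajectory(times=np.array(times[::-1]), freqs=np.array(freqs[::-1]))
    raise ValueError(f"unknown trajectory mode {mode!r}")


# ---------------------------------------------------------------------------
# the coalescent engine


def _child_seeds(seed: int, *key: int, n: int = 1) -> list[int]:
    """Deterministic counter-based seed derivation (documented scheme:
    SeedSequence spawned from (master, *key), mapped into [1, 2^31)."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    state = ss.generate_state(n, dtype=np.uint64)
    return [int(s % (2**31 - 2)) + 1 for s in state]


def simulate_panel(
    demography: TwoPopDemography | None = None,
    recomb_map: RecombinationMap | None = None,
    scenario: SweepScenario | None = None,
    n_afr: int = 176,
    n_eur: int = 194,
    region_length: int = 100_000,
    mutation_rate: float = 1.5e-8,
    seed: int | None = None,
) -> HaplotypePanel:
    """Simulate one polarized two-population panel.

    Under a sweep scenario the African ancestry at the selected site is
    conditioned on the sweep trajectory (structured coalescent in allelic
    classes); the derived allele is then placed on the swept clade, so it
    segregates near ``final_freq`` in the African sample and is absent from
    the European sample.  A fixed seed gives a byte-identical panel.

    Raises :class:`SweepSimulationError` when the stochastic sweep phase
    collides with a demographic event (trajectory older than the
    constant-size epoch); callers should redraw with a fresh seed.
    """
    import msprime
    import tskit

    demography = demography or TwoPopDemography()
    recomb_map = recomb_map or build_recomb_map("constant", region_length)
    scenario = scenario or SweepScenario()
    if recomb_map.region_length != region_length:
        raise ValueError("recombination map does not span the region")
    if n_afr % 2 or n_eur % 2:
        raise ValueError("chromosome counts must be even (diploid expansion)")
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31 - 2)) + 1
    s_afr, s_eur, s_merge, s_mut = _child_seeds(seed, 0, n=4)
    rate_map = recomb_map.to_msprime()
    position = (
        region_length // 2 if scenario.position is None else int(scenario.position)
    )

    model: object = msprime.StandardCoalescent()
    if not scenario.neutral:
        n_sweep = demography.sweep_epoch_size
        onset_guess = scenario.end_time + deterministic_sweep_duration(
            scenario.s, n_sweep, scenario.final_freq
        )
        if onset_guess >= demography.split_time:
            raise SweepSimulationError(
                "sweep onset predates the population split; the scenario is infeasible"
            )
        sweep = msprime.SweepGenicSelection(
            position=position,
            start_frequency=1.0 / (2 * n_sweep),
            end_frequency=scenario.final_freq,
            # msprime heterozygote fitness is 1 + s/2 (half the cosi scale)
            s=2.0 * scenario.s,
            dt=1.0 / (40.0 * n_sweep),
        )
        model = [
            msprime.StandardCoalescent(duration=scenario.end_time),
            sweep,
            msprime.StandardCoalescent(),
        ]
    try:
        ts_afr = msprime.sim_ancestry(
            samples={"AFR": n_afr // 2},
            demography=demography.afr_demography(),
            recombination_rate=rate_map,
            model=model,
            end_time=demography.split_time,
            random_seed=s_afr,
        )
    except Exception as exc:  # msprime LibraryError: events during sweep
        raise SweepSimulationError(
            f"sweep phase collided with a demographic event: {exc}"
        ) from exc
    ts_eur = msprime.sim_ancestry(
        samples={"EUR": n_eur // 2},
        demography=demography.eur_demography(),
        recombination_rate=rate_map,
        end_time=demography.split_time,
        random_seed=s_eur,
    )
    tables = ts_afr.dump_tables()
    tables.union(
        ts_eur.dump_tables(),
        node_mapping=np.full(ts_eur.num_nodes, tskit.NULL),
        add_populations=True,
        check_shared_equality=False,
    )
    ts = msprime.sim_ancestry(
        initial_state=tables.tree_sequence(),
        demography=demography.merge_demography(),
        recombination_rate=rate_map,
        random_seed=s_merge,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mutation_rate,
        model=msprime.BinaryMutationModel(),
        random_seed=s_mut,
    )

    afr_samples = ts.samples(population=0)
    eur_samples = ts.samples(population=1)
    order = np.concatenate([afr_samples, eur_samples])  # node ids, AFR first
    col_of = {int(n): i for i, n in enumerate(ts.samples())}
    genotypes = ts.genotype_matrix()  # sites x samples, in ts.samples() order
    positions = ts.sites_position.astype(np.int64)
    matrix = genotypes.T[[col_of[int(n)] for n in order]].astype(np.int8)
    matrix = np.clip(matrix, 0, 1)

    if not scenario.neutral:
        carriers = _swept_carriers(
            ts, position, afr_samples, eur_samples, scenario.final_freq
        )
        column = np.isin(order, carriers).astype(np.int8)
        at = int(np.searchsorted(positions, position))
        if at < positions.size and positions[at] == position:
            matrix[:, at] = column
        else:
            matrix = np.insert(matrix, at, column, axis=1)
            positions = np.insert(positions, at, position)

    counts = matrix.sum(axis=0)
    keep = (counts > 0) & (counts < matrix.shape[0])
    labels = np.array(["AFR"] * n_afr + ["EUR"] * n_eur)
    return HaplotypePanel(
        alleles=matrix[:, keep],
        positions=positions[keep],
        pop_labels=labels,
        polarized=True,
        region_length=region_length,
    )


def _swept_carriers(
    ts, position: int, afr_samples: np.ndarray, eur_samples: np.ndarray, p_final: float
) -> np.ndarray:
    """Chromosomes carrying the beneficial allele at the selected site.

    The swept class coalesces into a single lineage by the sweep origin, so
    at the selected position there is a clade containing (almost exactly) a
    fraction ``p_final`` of the African sample and no European chromosome;
    the derived allele is placed on that clade.
    """
    tree = ts.at(position, tracked_samples=eur_samples)
    n_afr = afr_samples.size
    best_u, best_gap = -1, np.inf
    for u in tree.nodes():
        if tree.num_tracked_samples(u) > 0:
            continue  # clade touches Europe: cannot be the swept class
        afr_count = tree.num_samples(u)
        gap = abs(afr_count / n_afr - p_final)
        if gap < best_gap:
            best_gap, best_u = gap, u
    return np.fromiter(tree.samples(best_u), dtype=np.int64)


# ---------------------------------------------------------------------------
# singleton thinning and summaries


def thin_singletons(
    panel: HaplotypePanel, fraction: float = 0.48, seed: int | None = None
) -> HaplotypePanel:
    """Remove a random ``fraction`` of pooled-singleton sites.

    Sites whose pooled derived count is exactly 1 are identified and
    round(fraction x count) of them (round half away from zero) are removed
    uniformly at random; every other site is untouched.  This emulates the
    under-calling of singletons in low-coverage sequencing data.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    singles = np.flatnonzero(panel.derived_counts() == 1)
    n_remove = int(np.floor(fraction * singles.size + 0.5))
    if n_remove == 0:
        return panel
    rng = np.random.default_rng(seed)
    drop = rng.choice(singles, size=n_remove, replace=False)
    keep = np.setdiff1d(np.arange(panel.n_sites), drop)
    return panel.take_sites(keep)


def extract_summaries(
    panel: HaplotypePanel,
    selected_site: int,
    window: int = 10_000,
    pop_sel: str = "AFR",
    pop_ref: str = "EUR",
    xp_max_cores: int = 16,
) -> dict[str, float]:
    """Per-replicate summary of each statistic at/around the selected site.

    SFS statistics (Tajima's D, Fu & Li's D, Fay & Wu's H) are computed in
    the selected population from the sites inside the ``window`` bp window
    centered on the selected site.  FST and dDAF are taken at the selected
    site itself, falling back to the window maximum when the site is absent.
    XP-EHH is the mean of per-site scores across the window (the same
    averaging applied to the observed data), evaluated on at most
    ``xp_max_cores`` evenly spaced in-window sites.  Undefined values are
    NaN.
    """
    half = window // 2
    lo, hi = selected_site - half, selected_site + half
    inside = (panel.positions >= lo) & (panel.positions < hi)
    idx = np.flatnonzero(inside)
    out: dict[str, float] = {}
    for name, func in (
        ("tajima_d", sstats.tajimas_d),
        ("fu_li_d", sstats.fu_li_d),
        ("fay_wu_h", sstats.fay_wu_h),
    ):
        out[name] = (
            float(func(panel, site_subset=idx, population=pop_sel))
            if idx.size
            else float("nan")
        )

    n_a, n_b = panel.rows(pop_sel).size, panel.rows(pop_ref).size
    c_a, c_b = panel.derived_counts(pop_sel), panel.derived_counts(pop_ref)
    at = int(np.searchsorted(panel.positions, selected_site))
    at_site = at < panel.n_sites and panel.positions[at] == selected_site

    if at_site:
        out["fst"] = float(sstats.fst_weir_cockerham(c_a[at], n_a, c_b[at], n_b))
        out["ddaf"] = float(c_a[at] / n_a - c_b[at] / n_b)
    elif idx.size:
        fst_vals = np.array(
            [sstats.fst_weir_cockerham(c_a[j], n_a, c_b[j], n_b) for j in idx]
        )
        ddaf_vals = c_a[idx] / n_a - c_b[idx] / n_b
        out["fst"] = float(np.nanmax(fst_vals)) if not np.all(np.isnan(fst_vals)) else float("nan")
        out["ddaf"] = float(np.max(ddaf_vals))
    else:
        out["fst"] = out["ddaf"] = float("nan")

    cores = idx
    if cores.size > xp_max_cores:
        pick = np.linspace(0, cores.size - 1, xp_max_cores).round().astype(int)
        cores = cores[pick]
    if cores.size:
        scores = np.array(
            [
                sstats.xp_ehh_between(panel, int(panel.positions[j]), pop_sel, pop_ref)
                for j in cores
            ],
            dtype=float,
        )
        defined = scores[~np.isnan(scores)]
        out["xp_ehh"] = float(defined.mean()) if defined.size else float("nan")
    else:
        out["xp_ehh"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class SimulationEnsemble:
    """Per-replicate summaries of every statistic for one scenario."""

    scenario: dict
    replicates: int
    summaries: pd.DataFrame
    master_seed: int
    redraws: int = 0
    version: str = "1"

    def __post_init__(self) -> None:
        if len(self.summaries) != self.replicates:
            raise ValueError("summary count must match the replicate count")

    @property
    def name(self) -> str:
        return self.scenario["name"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": self.version,
            "scenario": self.scenario,
            "replicates": self.replicates,
            "master_seed": self.master_seed,
            "redraws": self.redraws,
            "statistics": list(self.summaries.columns),
            "summaries": self.summaries.values.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationEnsemble":
        payload = json.loads(Path(path).read_text())
        df = pd.DataFrame(payload["summaries"], columns=payload["statistics"])
        return cls(
            scenario=payload["scenario"],
            replicates=payload["replicates"],
            summaries=df,
            master_seed=payload["master_seed"],
            redraws=payload.get("redraws", 0),
            version=payload.get("schema_version", "1"),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.summaries.to_csv(path, sep="\t", index_label="replicate")


def default_scenarios() -> list[SweepScenario]:
    """The 4 x 2 scenario grid: s in {0, 0.005, 0.01, 0.03} x
    {constant, hotspot} recombination."""
    return [
        SweepScenario(s=s, recomb=kind)
        for s in (0.0, 0.005, 0.01, 0.03)
        for kind in ("constant", "hotspot")
    ]


DEFAULT_SCENARIOS = default_scenarios()


def run_ensemble(
    scenarios: list[SweepScenario] | None = None,
    replicates: int = 500,
    master_seed: int = 1,
    demography: TwoPopDemography | None = None,
    n_afr: int = 176,
    n_eur: int = 194,
    region_length: int = 100_000,
    mutation_rate: float = 1.5e-8,
    thin_fraction: float = 0.48,
    summary_window: int = 10_000,
    max_redraws: int = 25,
) -> list[SimulationEnsemble]:
    """Simulate an ensemble of per-replicate summaries for each scenario.

    Replicate seeds derive deterministically from ``master_seed`` via a
    counter-based scheme keyed on (scenario index, replicate index, attempt);
    a failed replicate (infeasible sweep trajectory) is redrawn with the next
    attempt counter and the redraw total is recorded on the ensemble.
    """
    scenarios = scenarios if scenarios is not None else default_scenarios()
    demography = demography or TwoPopDemography()
    out: list[SimulationEnsemble] = []
    for i, scn in enumerate(scenarios):
        rmap = build_recomb_map(scn.recomb, region_length)
        position = (
            region_length // 2 if scn.position is None else int(scn.position)
        )
        rows = []
        redraws = 0
        for j in range(replicates):
            for attempt in range(max_redraws):
                rep_seed, thin_seed = _child_seeds(
                    master_seed, i, j, attempt, n=2
                )
                try:
                    panel = simulate_panel(
                        demography=demography,
                        recomb_map=rmap,
                        scenario=scn,
                        n_afr=n_afr,
                        n_eur=n_eur,
                        region_length=region_length,
                        mutation_rate=mutation_rate,
                        seed=rep_seed,
                    )
                except SweepSimulationError as exc:
                    redraws += 1
                    logger.warning(
                        "scenario %s replicate %d redrawn (attempt %d): %s",
                        scn.name, j, attempt + 1, exc,
                    )
                    continue
                panel = thin_singletons(panel, thin_fraction, seed=thin_seed)
                rows.append(extract_summaries(panel, position, summary_window))
                break
            else:
                raise SweepSimulationError(
                    f"scenario {scn.name}: replicate {j} failed {max_redraws} times"
                )
        out.append(
            SimulationEnsemble(
                scenario={
                    "name": scn.name,
                    "s": scn.s,
                    "recomb": scn.recomb,
                    "final_freq": scn.final_freq,
                    "end_time": scn.end_time,
                    "position": position,
                    "n_afr": n_afr,
                    "n_eur": n_eur,
                    "region_length": region_length,
                    "mutation_rate": mutation_rate,
                    "thin_fraction": thin_fraction,
                    "summary_window": summary_window,
                },
                replicates=replicates,
                summaries=pd.DataFrame(rows, columns=list(SUMMARY_STATISTICS)),
                master_seed=master_seed,
                redraws=redraws,
            )
        )
        logger.info(
            "scenario %s: %d replicates (%d redraws)", scn.name, replicates, redraws
        )
    return out
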