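"""Selection statistics against brute-force oracles and known identities."""

import itertools

import numpy as np
import pytest

import sweepscape as sw
from sweepscape.panel import PanelError
from sweepscape.stats import per_site_track, _fst_track_values

from conftest import random_panel


# ---------------------------------------------------------------------------
# brute-force oracles


def pi_bruteforce(alleles: np.ndarray) -> float:
    n = alleles.shape[0]
    total = sum(
        np.sum(alleles[i] != alleles[j]) for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2)


def theta_w_bruteforce(alleles: np.ndarray) -> float:
    n = alleles.shape[0]
    counts = alleles.sum(axis=0)
    s = int(np.sum((counts > 0) & (counts < n)))
    return s / sum(1 / i for i in range(1, n))


def theta_h_bruteforce(alleles: np.ndarray) -> float:
    n = alleles.shape[0]
    counts = alleles.sum(axis=0)
    tally = {i: int(np.sum(counts == i)) for i in range(1, n)}
    return sum(s_i * 2 * i**2 for i, s_i in tally.items()) / (n * (n - 1))


class TestSfsOracles:
    def test_worked_panel_values(self, worked_panel):
        assert sw.nucleotide_diversity(worked_panel) == pytest.approx(10 / 6)
        assert sw.watterson_theta(worked_panel) == pytest.approx(3 / (11 / 6))
        assert sw.theta_h(worked_panel) == pytest.approx(28 / 12)
        assert sw.tajimas_d(worked_panel) == pytest.approx(0.168, abs=1e-3)
        assert sw.fay_wu_h(worked_panel) == pytest.approx(-2 / 3)
        assert sw.fu_li_d(worked_panel) == pytest.approx(0.644, abs=1e-3)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_panels_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        panel = random_panel(rng, n=rng.integers(3, 11), s=rng.integers(5, 21))
        assert sw.nucleotide_diversity(panel) == pytest.approx(
            pi_bruteforce(panel.alleles)
        )
        assert sw.watterson_theta(panel) == pytest.approx(
            theta_w_bruteforce(panel.alleles)
        )
        assert sw.theta_h(panel) == pytest.approx(theta_h_bruteforce(panel.alleles))

    def test_two_chromosomes_pi_counts_differences(self):
        panel = sw.HaplotypePanel(
            alleles=[[0, 0, 0, 1], [1, 1, 1, 0]],
            positions=[1, 2, 3, 4],
            pop_labels=["a", "a"],
            polarized=True,
        )
        assert sw.nucleotide_diversity(panel) == pytest.approx(4.0)
        # a_1 = 1 so Watterson's theta equals S
        assert sw.watterson_theta(panel) == pytest.approx(4.0)

    def test_reordering_invariance(self, worked_panel):
        rng = np.random.default_rng(0)
        rows = rng.permutation(worked_panel.n_chromosomes)
        cols = np.array([2, 0, 1])
        shuffled = sw.HaplotypePanel(
            alleles=worked_panel.alleles[rows][:, cols],
            positions=worked_panel.positions,  # same grid, permuted content
            pop_labels=worked_panel.pop_labels,
            polarized=True,
            region_length=worked_panel.region_length,
        )
        for f in (sw.tajimas_d, sw.fu_li_d, sw.fay_wu_h):
            assert f(shuffled) == pytest.approx(f(worked_panel))

    def test_singleton_excess_drives_tajima_negative(self):
        # star-like: every mutation a singleton
        alleles = np.eye(8, dtype=np.int8)
        panel = sw.HaplotypePanel(
            alleles=alleles,
            positions=np.arange(8) * 10,
            pop_labels=["a"] * 8,
            polarized=True,
        )
        assert sw.tajimas_d(panel) < 0
        # ... and singletons contribute less to theta_H than to pi: H > 0
        assert sw.fay_wu_h(panel) > 0
        # outgroup Fu & Li: eta_e = eta makes the numerator negative
        assert sw.fu_li_d(panel) < 0

    def test_no_segregating_sites_is_nan_not_error(self, worked_panel):
        empty = np.array([], dtype=int)
        assert np.isnan(sw.tajimas_d(worked_panel, site_subset=empty))
        assert np.isnan(sw.fu_li_d(worked_panel, site_subset=empty))

    def test_polarization_required(self, worked_panel):
        worked_panel.polarized = False
        with pytest.raises(PanelError, match="polarized"):
            sw.fay_wu_h(worked_panel)
        with pytest.raises(PanelError, match="polarized"):
            sw.fu_li_d(worked_panel)

    def test_unknown_ancestral_sites_masked_not_dropped(self, worked_panel):
        # hiding the singleton site changes eta for Fu & Li but not FST inputs
        worked_panel.ancestral_known[2] = False
        assert sw.theta_h(worked_panel) == pytest.approx((2 * (9 + 4)) / 12)
        # Tajima's D does not need polarization: unchanged
        assert sw.tajimas_d(worked_panel) == pytest.approx(0.168, abs=1e-3)

    def test_neutral_coalescent_expectations(self):
        """Mean Tajima's D and mean Fay & Wu's H across neutral constant-N
        replicates lie within Monte-Carlo error of zero."""
        import msprime

        ds, hs = [], []
        for ts in msprime.sim_ancestry(
            samples=10,
            population_size=1_000,
            sequence_length=20_000,
            recombination_rate=0,
            num_replicates=200,
            random_seed=1234,
        ):
            ts = msprime.sim_mutations(
                ts, rate=5e-8, model=msprime.BinaryMutationModel(), random_seed=ts.num_edges + 1
            )
            if ts.num_sites < 2:
                continue
            g = ts.genotype_matrix().T
            counts = g.sum(axis=0)
            keep = (counts > 0) & (counts < g.shape[0])
            panel = sw.HaplotypePanel(
                alleles=np.clip(g[:, keep], 0, 1),
                positions=ts.sites_position.astype(int)[keep],
                pop_labels=["x"] * g.shape[0],
                polarized=True,
                region_length=20_000,
            )
            d = sw.tajimas_d(panel)
            if not np.isnan(d):
                ds.append(d)
                hs.append(sw.fay_wu_h(panel))
        for values in (ds, hs):
            values = np.asarray(values)
            sem = values.std(ddof=1) / np.sqrt(values.size)
            assert abs(values.mean()) < 4 * sem + 0.05


# ---------------------------------------------------------------------------
# FST and dDAF


class TestFst:
    def test_worked_anova_example(self):
        assert sw.fst_weir_cockerham(2, 10, 8, 10) == pytest.approx(0.4771, abs=1e-4)

    def test_hudson_cross_oracle_equal_n(self):
        # equal sample sizes: the two estimators agree to 1e-6
        wc = sw.fst_weir_cockerham(2, 10, 8, 10)
        hu = sw.fst_hudson(2, 10, 8, 10)
        assert wc == pytest.approx(hu, abs=1e-6)

    @pytest.mark.parametrize(
        "daf1,n1,daf2,n2,printed",
        [
            (0.4941, 170, 0.0057, 176, 0.4823),  # rs2272662 CEU-YRI
            (0.0059, 170, 0.9787, 176, 0.9765),  # rs1871534 CEU-YRI
            (0.9787, 176, 0.0000, 194, 0.9837),  # rs1871534 YRI-CHB
        ],
    )
    def test_published_daf_configurations(self, daf1, n1, daf2, n2, printed):
        wc = sw.fst_weir_cockerham(daf1 * n1, n1, daf2 * n2, n2)
        assert wc == pytest.approx(printed, rel=0.01)
        assert sw.fst_hudson(daf1 * n1, n1, daf2 * n2, n2) == pytest.approx(
            wc, abs=0.01
        )

    def test_equal_frequencies_nonpositive(self):
        assert sw.fst_weir_cockerham(3, 10, 3, 10) <= 0

    def test_pooled_monomorphic_is_nan(self):
        assert np.isnan(sw.fst_weir_cockerham(0, 10, 0, 10))
        assert np.isnan(sw.fst_weir_cockerham(10, 10, 10, 10))

    def test_vectorized_track_matches_scalar(self):
        rng = np.random.default_rng(3)
        panel = random_panel(rng, n=8, s=12, pops=("A", "B"))
        track = _fst_track_values(panel, "A", "B")
        ca = panel.derived_counts("A")
        cb = panel.derived_counts("B")
        na, nb = panel.rows("A").size, panel.rows("B").size
        for j in range(panel.n_sites):
            expected = sw.fst_weir_cockerham(ca[j], na, cb[j], nb)
            if np.isnan(expected):
                assert np.isnan(track[j])
            else:
                assert track[j] == pytest.approx(expected)


class TestDdaf:
    def test_signed_difference(self):
        panel = sw.HaplotypePanel(
            alleles=np.array([[1], [1], [1], [0], [1], [0], [0], [0]]),
            positions=[5],
            pop_labels=["a"] * 4 + ["b"] * 4,
            polarized=True,
        )
        assert sw.ddaf(panel, 0, "a", "b") == pytest.approx(0.5)
        assert sw.ddaf(panel, 0, "b", "a") == pytest.approx(-0.5)

    def test_fixed_vs_absent_is_one(self):
        panel = sw.HaplotypePanel(
            alleles=np.array([[1], [1], [0], [0]]),
            positions=[5],
            pop_labels=["a", "a", "b", "b"],
            polarized=True,
        )
        assert sw.ddaf(panel, 0, "a", "b") == 1.0

    def test_equal_frequencies_zero(self):
        panel = sw.HaplotypePanel(
            alleles=np.array([[1], [0], [1], [0]]),
            positions=[5],
            pop_labels=["a", "a", "b", "b"],
            polarized=True,
        )
        assert sw.ddaf(panel, 0, "a", "b") == 0.0


# ---------------------------------------------------------------------------
# EHH / XP-EHH


def panel_from_rows(rows, positions, labels=None, region_length=None):
    rows = np.array(rows, dtype=np.int8)
    return sw.HaplotypePanel(
        alleles=rows,
        positions=positions,
        pop_labels=labels if labels is not None else ["x"] * rows.shape[0],
        polarized=True,
        region_length=region_length,
    )


class TestEhh:
    def test_two_identical_pairs_beyond_core(self):
        panel = panel_from_rows(
            [[0, 0, 1], [0, 0, 1], [1, 1, 0], [1, 1, 0]], [10, 20, 30]
        )
        d, e = sw.ehh(panel, 20, "right")
        assert e[0] == 1.0
        # beyond the core the two identical pairs give 2*C(2,2)/C(4,2)
        assert e[1] == pytest.approx(2 / 6)

    def test_all_distinct_adjacent_drops_to_zero(self):
        panel = panel_from_rows(
            [[0, 0, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1]], [10, 20, 30]
        )
        d, e = sw.ehh(panel, 10, "right")
        assert e[-1] == 0.0

    def test_nonincreasing_with_distance(self):
        rng = np.random.default_rng(7)
        panel = random_panel(rng, n=10, s=15)
        core = int(panel.positions[panel.n_sites // 2])
        for direction in ("left", "right"):
            _, e = sw.ehh(panel, core, direction)
            assert np.all(np.diff(e) <= 1e-12)

    def test_missing_core_site_raises(self):
        panel = panel_from_rows([[0, 1], [1, 0]], [10, 20])
        with pytest.raises(PanelError, match="no site"):
            sw.ehh(panel, 15)


class TestXpEhh:
    def test_identical_panels_score_zero(self):
        rng = np.random.default_rng(1)
        panel = random_panel(rng, n=6, s=10)
        core = int(panel.positions[panel.n_sites // 2])
        assert sw.xp_ehh(panel, panel, core) == pytest.approx(0.0)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(2)
        a = random_panel(rng, n=6, s=12, region_length=5_000)
        b = sw.HaplotypePanel(
            alleles=a.alleles[rng.permutation(6)],
            positions=a.positions,
            pop_labels=a.pop_labels,
            polarized=True,
            region_length=a.region_length,
        )
        core = int(a.positions[a.n_sites // 2])
        fwd = sw.xp_ehh(a, b, core)
        rev = sw.xp_ehh(b, a, core)
        assert fwd == pytest.approx(-rev)

    def test_homogeneous_panel_beats_diverse(self):
        positions = [0, 1000, 2000, 3000, 4000]
        a = panel_from_rows(
            [[0, 1, 0, 1, 0]] * 3 + [[1, 0, 1, 0, 1]], positions, region_length=4001
        )
        b_rows = [
            [0, 0, 0, 0, 0],
            [0, 1, 1, 0, 1],
            [1, 0, 1, 1, 0],
            [1, 1, 0, 1, 1],
        ]
        b = panel_from_rows(b_rows, positions, region_length=4001)
        assert sw.xp_ehh(a, b, 2000) > 0

    def test_standardized_score_uses_reference_ensemble(self):
        rng = np.random.default_rng(5)
        a = random_panel(rng, n=6, s=12, region_length=5_000, pops=("A", "B"))
        core = int(a.positions[a.n_sites // 2])
        raw = sw.xp_ehh_between(a, core, "A", "B")
        ref = rng.normal(0.2, 0.7, size=200)
        standardized = sw.xp_ehh_between(a, core, "A", "B", reference_ensemble=ref)
        assert standardized == pytest.approx((raw - ref.mean()) / ref.std(ddof=0))
        # a whole ensemble standardized against itself has mean 0, sd 1
        z = (ref - ref.mean()) / ref.std(ddof=0)
        assert abs(z.mean()) < 1e-12 and z.std(ddof=0) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# windows


class TestWindowed:
    def test_window_grid_is_24_windows_over_100kb(self):
        starts = sw.WindowSpec().starts(100_000)
        assert starts.size == 24
        assert starts[0] == 0 and starts[-1] == 69_000

    def test_region_shorter_than_window_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            sw.WindowSpec().starts(10_000)

    def test_constant_per_site_statistic_fills_every_window(self):
        # both populations identical at every site: dDAF = 0 per site
        rng = np.random.default_rng(11)
        half = rng.integers(0, 2, size=(4, 40), dtype=np.int8)
        alleles = np.vstack([half, half])
        counts = alleles.sum(axis=0)
        keep = (counts > 0) & (counts < 8)
        positions = np.sort(rng.choice(100_000, size=40, replace=False))[keep]
        panel = sw.HaplotypePanel(
            alleles=alleles[:, keep],
            positions=positions,
            pop_labels=["A"] * 4 + ["B"] * 4,
            polarized=True,
            region_length=100_000,
        )
        track = sw.windowed(panel, "ddaf", populations=("A", "B"))
        defined = ~np.isnan(track.values)
        assert np.all(track.values[defined] == 0.0)

    def test_single_site_defined_only_in_covering_windows(self):
        panel = sw.HaplotypePanel(
            alleles=np.array([[0], [1], [0], [1]]),
            positions=[50_000],
            pop_labels=["A", "A", "B", "B"],
            polarized=True,
            region_length=100_000,
        )
        track = sw.windowed(panel, "pi", population="A")
        covering = (track.starts <= 50_000) & (track.ends > 50_000)
        assert np.all(~np.isnan(track.values[covering]))
        assert np.all(np.isnan(track.values[~covering]))

    def test_track_tsv_marks_undefined(self, tmp_path):
        panel = sw.HaplotypePanel(
            alleles=np.array([[0], [1], [0], [1]]),
            positions=[50_000],
            pop_labels=["A"] * 4,
            polarized=True,
            region_length=100_000,
        )
        track = sw.windowed(panel, "tajima_d", population="A")
        out = tmp_path / "track.tsv"
        sw.stats.write_track_tsv(track, out)
        text = out.read_text()
        assert "NA" in text and text.count("\n") == 25  # header + 24 windows
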