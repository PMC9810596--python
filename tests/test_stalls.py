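"""Occupancy statistics: relative transcript occupancy, size factors,
terminal-window stall quantification, codon-identity profiles, queue scan."""

import numpy as np
import pandas as pd
import pytest

from mitoribo.genome import MitoGenome, OrfAnnotation
from mitoribo.occupancy import CodonCountTable
from mitoribo.simulate import TERMINAL, SimulationConfig, StallSpec, simulate_reads
from mitoribo.stalls import (
    codon_identity_fold_change,
    codon_identity_profile,
    relative_transcript_occupancy,
    size_factors,
    stall_fold_change,
    stall_report,
    terminal_window_occupancy,
    upstream_queue_scan,
)


def _uniform_table(orfs, per_codon=1, sample="s"):
    counts = {(o.gene, i): per_codon for o in orfs for i in range(o.n_codons)}
    return CodonCountTable(sample, counts)


class TestRelativeOccupancy:
    def test_fractions(self):
        t = CodonCountTable("s", {("A", 0): 20, ("B", 0): 80})
        occ = relative_transcript_occupancy(t)
        assert occ["A"] == 0.2 and occ["B"] == 0.8

    def test_sums_to_one_and_rescaling_invariant(self, genome, orfs):
        _, truth = simulate_reads(genome, orfs, SimulationConfig(n_reads=3000, seed=2))
        hist = truth.groupby(["gene", "a_site_codon_index"]).size()
        t = CodonCountTable("s", {k: int(v) for k, v in hist.items()})
        occ = relative_transcript_occupancy(t, orfs)
        assert abs(occ.sum() - 1) < 1e-12
        scaled = CodonCountTable("s", {k: 7 * v for k, v in t.counts.items()})
        pd.testing.assert_series_equal(occ, relative_transcript_occupancy(scaled, orfs))

    def test_single_gene_is_one_and_empty_rejected(self):
        assert relative_transcript_occupancy(CodonCountTable("s", {("A", 0): 5}))["A"] == 1.0
        with pytest.raises(ValueError):
            relative_transcript_occupancy(CodonCountTable("s", {}))


class TestSizeFactors:
    def test_stated_formula(self):
        t = CodonCountTable("s", {("A", 0): 100, ("B", 0): 300})
        sf = size_factors(t)
        assert sf["A"] == pytest.approx(2.0)
        assert sf["B"] == pytest.approx(2 / 3)

    def test_equal_totals_and_single_gene_give_unity(self):
        t = CodonCountTable("s", {("A", 0): 50, ("B", 3): 50})
        assert (size_factors(t) == 1.0).all()
        assert size_factors(CodonCountTable("s", {("A", 0): 9}))["A"] == 1.0

    def test_scaling_equalizes_gene_totals(self, genome, orfs):
        _, truth = simulate_reads(genome, orfs, SimulationConfig(n_reads=5000, seed=4))
        hist = truth.groupby(["gene", "a_site_codon_index"]).size()
        t = CodonCountTable("s", {k: int(v) for k, v in hist.items()})
        sf = size_factors(t)
        totals = pd.Series(t.gene_totals, dtype=float)
        scaled = totals * sf
        assert np.allclose(scaled, totals.mean(), rtol=1e-9)

    def test_zero_gene_warned_all_zero_rejected(self):
        t = CodonCountTable("s", {("A", 0): 10, ("B", 0): 0})
        with pytest.warns(UserWarning):
            sf = size_factors(t)
        assert "B" not in sf.index
        with pytest.raises(ValueError):
            size_factors(CodonCountTable("s", {("A", 0): 0}))


def _orf(n_codons, gene="G"):
    return OrfAnnotation(gene, 0, 3 * n_codons, "+")


class TestTerminalWindow:
    def test_uniform_counts_give_window_fraction(self):
        orf = _orf(100)
        t = _uniform_table([orf])
        occ = terminal_window_occupancy(t, [orf], window_codons=15)
        assert occ.loc["G", "window_occupancy"] == pytest.approx(0.15)

    def test_all_counts_on_stop(self):
        orf = _orf(100)
        t = CodonCountTable("s", {("G", 99): 42})
        occ = terminal_window_occupancy(t, [orf])
        assert occ.loc["G", "window_occupancy"] == 1.0

    def test_include_stop_false_shifts_window(self):
        orf = _orf(100)
        t = CodonCountTable("s", {("G", 99): 10, ("G", 50): 10})
        with_stop = terminal_window_occupancy(t, [orf], include_stop=True)
        without = terminal_window_occupancy(t, [orf], include_stop=False)
        assert with_stop.loc["G", "window_occupancy"] == 0.5
        assert without.loc["G", "window_occupancy"] == 0.0

    def test_size_factor_invariance_within_gene(self):
        orfs = [_orf(100, "A"), _orf(60, "B")]
        t = CodonCountTable("s", {("A", 99): 5, ("A", 0): 5, ("B", 59): 3, ("B", 1): 9})
        sf = size_factors(t)
        with_sf = terminal_window_occupancy(t, orfs, sf=sf)
        without_sf = terminal_window_occupancy(t, orfs, sf=None)
        pd.testing.assert_series_equal(
            with_sf["window_occupancy"], without_sf["window_occupancy"]
        )
        # but the scaled totals are equalized across genes
        assert with_sf["scaled_gene_total"].nunique() == 1

    def test_short_gene_skipped_with_warning(self):
        orfs = [_orf(10, "S"), _orf(100, "L")]
        t = _uniform_table(orfs)
        with pytest.warns(UserWarning, match="S"):
            occ = terminal_window_occupancy(t, orfs, window_codons=15)
        assert list(occ.index) == ["L"]


class TestStallFoldChange:
    def test_identical_samples_give_unity(self, genome, orfs):
        _, truth = simulate_reads(genome, orfs, SimulationConfig(n_reads=4000, seed=6))
        hist = truth.groupby(["gene", "a_site_codon_index"]).size()
        t = CodonCountTable("s", {k: int(v) for k, v in hist.items()})
        occ = terminal_window_occupancy(t, orfs)
        fc = stall_fold_change(occ, occ)
        assert np.allclose(fc, 1.0)

    def test_window_definition_mismatch_rejected(self):
        orf = _orf(100)
        t = _uniform_table([orf])
        a = terminal_window_occupancy(t, [orf], include_stop=True)
        b = terminal_window_occupancy(t, [orf], include_stop=False)
        with pytest.raises(ValueError):
            stall_fold_change(a, b)

    def test_pseudocount_stabilizes_zero_windows(self):
        orf = _orf(100)
        empty_end = CodonCountTable("s", {("G", 0): 50})
        full_end = CodonCountTable("r", {("G", 99): 10, ("G", 0): 40})
        occ_s = terminal_window_occupancy(empty_end, [orf])
        occ_r = terminal_window_occupancy(full_end, [orf])
        fc = stall_fold_change(occ_s, occ_r, pseudocount=0.5)
        assert np.isfinite(fc["G"]) and fc["G"] > 0

    def test_gene_missing_from_reference_skipped(self):
        orfA, orfB = _orf(100, "A"), _orf(100, "B")
        t_s = _uniform_table([orfA, orfB])
        t_r = _uniform_table([orfA])
        occ_s = terminal_window_occupancy(t_s, [orfA, orfB])
        occ_r = terminal_window_occupancy(t_r, [orfA])
        with pytest.warns(UserWarning, match="B"):
            fc = stall_fold_change(occ_s, occ_r)
        assert list(fc.index) == ["A"]

    def test_analytic_expectation_on_simulated_stall(self, genome, orfs, orf_by_gene):
        """Terminal multiplier m: expected fold change of the last-15-codon
        statistic is ((14 + m)/(n - 1 + m)) / (15/n) for an n-codon gene."""
        m, gene = 6.0, "COX2"
        n = orf_by_gene[gene].n_codons
        wt_cfg = SimulationConfig(n_reads=30_000, seed=31)
        ko_cfg = SimulationConfig(
            n_reads=30_000, seed=32, stalls=[StallSpec(gene, TERMINAL, multiplier=m)]
        )
        tables = {}
        for name, cfg in (("wt", wt_cfg), ("ko", ko_cfg)):
            _, truth = simulate_reads(genome, orfs, cfg)
            hist = truth.groupby(["gene", "a_site_codon_index"]).size()
            tables[name] = CodonCountTable(name, {k: int(v) for k, v in hist.items()})
        rep = stall_report(tables["ko"], tables["wt"], orfs)
        fc = rep.per_gene.loc[gene, "fold_change"]
        expected = ((14 + m) / (n - 1 + m)) / (15 / n)
        p_ko = (14 + m) / (n - 1 + m)
        p_wt = 15 / n
        n_ko = tables["ko"].gene_totals[gene]
        n_wt = tables["wt"].gene_totals[gene]
        se = expected * np.sqrt(
            (1 - p_ko) / (p_ko * n_ko) + (1 - p_wt) / (p_wt * n_wt)
        )
        assert abs(fc - expected) < 3 * se


class TestCodonIdentityProfile:
    @pytest.fixture
    def small(self):
        g = MitoGenome("g", "ATGAAAAAATAA")
        orf = OrfAnnotation("G", 0, 12, "+")
        t = CodonCountTable("s", {("G", 0): 1, ("G", 1): 2, ("G", 2): 3, ("G", 3): 4})
        return g, [orf], t

    def test_hand_aggregation(self, small):
        g, orfs, t = small
        prof = codon_identity_profile(t, g, orfs)
        assert prof.raw_counts["ATG"] == 1
        assert prof.raw_counts["AAA"] == 5
        assert prof.raw_counts["TAA"] == 4
        assert prof.values["ATG"] == pytest.approx(0.1)
        assert prof.values["AAA"] == pytest.approx(0.5)
        assert prof.values["TAA"] == pytest.approx(0.4)
        assert prof.values.sum() == pytest.approx(1.0)

    def test_per_occurrence_flat_under_uniform_occupancy(self, genome, orfs):
        t = _uniform_table(orfs)
        prof = codon_identity_profile(t, genome, orfs, normalization="per_occurrence")
        vals = prof.values[prof.values > 0]
        assert np.allclose(vals, vals.iloc[0])

    def test_orderings_carried(self, small):
        g, orfs, t = small
        prof = codon_identity_profile(t, g, orfs)
        assert prof.frequency_order[0] == "AAA"  # 2 occurrences
        assert prof.coverage_order[0] == "AAA"  # 5 counts
        assert len(prof.frequency_order) == 64

    def test_unknown_normalization_rejected(self, small):
        g, orfs, t = small
        with pytest.raises(ValueError):
            codon_identity_profile(t, g, orfs, normalization="quantile")

    def test_identity_fold_change_unity_and_stabilization(self, small):
        g, orfs, t = small
        prof = codon_identity_profile(t, g, orfs)
        fc = codon_identity_fold_change(prof, prof)
        nonzero = fc.loc[["ATG", "AAA", "TAA"]]
        assert np.allclose(nonzero["fold_change"], 1.0)
        assert not nonzero["stabilized"].any()
        zero = fc.drop(["ATG", "AAA", "TAA"])
        assert zero["stabilized"].all()
        assert np.isfinite(zero["fold_change"]).all()

    def test_mode_mismatch_rejected(self, small):
        g, orfs, t = small
        a = codon_identity_profile(t, g, orfs, "total")
        b = codon_identity_profile(t, g, orfs, "per_occurrence")
        with pytest.raises(ValueError):
            codon_identity_fold_change(a, b)

    def test_aga_agg_top_identities_in_stalled_simulation(self, genome, orfs):
        """Stalls planted only at the AGA/AGG terminal codons make those the
        top fold-change identities versus a uniform reference."""
        ko_cfg = SimulationConfig(
            n_reads=40_000,
            seed=41,
            stalls=[
                StallSpec("COX1", TERMINAL, multiplier=20),
                StallSpec("ND6", TERMINAL, multiplier=20),
            ],
        )
        wt_cfg = SimulationConfig(n_reads=40_000, seed=40)
        profs = {}
        for name, cfg in (("ko", ko_cfg), ("wt", wt_cfg)):
            _, truth = simulate_reads(genome, orfs, cfg)
            hist = truth.groupby(["gene", "a_site_codon_index"]).size()
            t = CodonCountTable(name, {k: int(v) for k, v in hist.items()})
            profs[name] = codon_identity_profile(t, genome, orfs)
        fc = codon_identity_fold_change(profs["ko"], profs["wt"])
        observed = fc.loc[~fc["stabilized"], "fold_change"]
        top2 = set(observed.sort_values(ascending=False).head(2).index)
        assert top2 == {"AGA", "AGG"}


class TestQueueScan:
    def test_recovers_planted_queue_offset(self, genome, orfs, orf_by_gene):
        cfg = SimulationConfig(
            n_reads=30_000,
            transcript_weights={"COX1": 1.0},
            stalls=[StallSpec("COX1", TERMINAL, multiplier=10, queue_multiplier=8, queue_offset=12)],
            seed=51,
        )
        _, truth = simulate_reads(genome, orfs, cfg)
        hist = truth.groupby(["gene", "a_site_codon_index"]).size()
        t = CodonCountTable("ko", {k: int(v) for k, v in hist.items()})
        res = upstream_queue_scan(t, orf_by_gene["COX1"])
        assert res.offset_codons == 12
        assert res.significant and res.fold_over_median > 2

    def test_uniform_counts_not_significant(self):
        orf = _orf(100)
        t = _uniform_table([orf])
        res = upstream_queue_scan(t, orf)
        assert res.fold_over_median == pytest.approx(1.0)
        assert not res.significant

    def test_footprint_length_implies_twelve_codons(self):
        assert round(35 / 3) == 12

    def test_window_outside_gene_rejected(self):
        orf = _orf(12)
        t = _uniform_table([orf])
        with pytest.raises(ValueError):
            upstream_queue_scan(t, orf)


class TestParameterRecovery:
    def test_planted_multipliers_recovered_in_rank_order(self, genome, orfs):
        """Terminal multipliers {2, 5, 10} on three genes are recovered
        monotonically by the terminal-window fold change."""
        plants = {"ND1": 2.0, "COX2": 5.0, "CYTB": 10.0}
        ko_cfg = SimulationConfig(
            n_reads=40_000,
            seed=61,
            stalls=[StallSpec(g, TERMINAL, multiplier=m) for g, m in plants.items()],
        )
        wt_cfg = SimulationConfig(n_reads=40_000, seed=60)
        tables = {}
        for name, cfg in (("ko", ko_cfg), ("wt", wt_cfg)):
            _, truth = simulate_reads(genome, orfs, cfg)
            hist = truth.groupby(["gene", "a_site_codon_index"]).size()
            tables[name] = CodonCountTable(name, {k: int(v) for k, v in hist.items()})
        rep = stall_report(tables["ko"], tables["wt"], orfs)
        fcs = rep.per_gene.loc[list(plants), "fold_change"]
        assert list(fcs.sort_values().index) == ["ND1", "COX2", "CYTB"]

    def test_fold_change_centered_at_unity_between_replicate_draws(self, genome, orfs):
        """Independent draws from identical parameters: mean log fold change
        across replicate pairs is within 3 SE of 0."""
        logs = []
        for rep in range(20):
            tables = []
            for half in range(2):
                cfg = SimulationConfig(n_reads=3000, seed=1000 + 2 * rep + half)
                _, truth = simulate_reads(genome, orfs, cfg)
                hist = truth.groupby(["gene", "a_site_codon_index"]).size()
                tables.append(CodonCountTable(f"t{half}", {k: int(v) for k, v in hist.items()}))
            occ_a = terminal_window_occupancy(tables[0], orfs)
            occ_b = terminal_window_occupancy(tables[1], orfs)
            fc = stall_fold_change(occ_a, occ_b)
            logs.extend(np.log(fc.values))
        logs = np.array(logs)
        se = logs.std(ddof=1) / np.sqrt(len(logs))
        assert abs(logs.mean()) < 3 * se
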