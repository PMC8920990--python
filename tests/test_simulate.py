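import numpy as np
import pytest

from trnaterm.simulate import (
    CALL_CC,
    CALL_CCA,
    CALL_OTHER,
    SimConfig,
    TIRNA_WINDOW,
    TRNA_WINDOW,
    _draw_fragments,
    expected_truth,
    generate_reference,
    simulate_library,
)


class TestGenerateReference:
    def test_group_sizes_forced(self):
        _, cat = generate_reference(10, 2, 1, gene_len=72, genome_len=10_000, seed=1)
        assert cat.group_sizes() == {"CCA": 2, "CC": 1, "OTHER": 7}

    def test_deterministic_for_seed(self):
        r1, c1 = generate_reference(10, 2, 1, genome_len=10_000, seed=5)
        r2, c2 = generate_reference(10, 2, 1, genome_len=10_000, seed=5)
        assert r1 == r2
        assert [g.seq for g in c1] == [g.seq for g in c2]
        r3, _ = generate_reference(10, 2, 1, genome_len=10_000, seed=6)
        assert r3 != r1

    def test_both_strands_and_mito(self):
        _, cat = generate_reference(8, 2, 1, genome_len=10_000, seed=2, n_mito=1)
        strands = {g.strand for g in cat}
        assert strands == {"+", "-"}
        assert sum(g.is_mito for g in cat) == 1

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="pack"):
            generate_reference(100, 10, 5, gene_len=72, genome_len=5_000, seed=0)

    def test_gene_seq_matches_genome(self):
        refs, cat = generate_reference(6, 1, 1, genome_len=8_000, seed=3)
        from trnaterm.catalog import revcomp

        g = refs["chrSim"]
        for gene in cat:
            sub = g[gene.start:gene.end]
            assert gene.seq == (sub if gene.strand == "+" else revcomp(sub))


@pytest.fixture(scope="module")
def catalog():
    _, cat = generate_reference(12, 2, 1, gene_len=72, genome_len=20_000, seed=11)
    return cat


def _pure_trna_cfg(**kw):
    base = dict(
        n_reads=2_000, background_weight=0.0, p_frag_base=0.0,
        conditions=(("control", 1.0),), n_replicates=1,
        p_ccloss=0.0, p_immature=0.0, error_rate=0.0,
        size_window=TRNA_WINDOW, read_length=150, seed=9,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateLibrary:
    def test_pure_mature_library_is_gene_plus_cca_plus_adapter(self, catalog):
        cfg = _pure_trna_cfg()
        reads, truth = simulate_library(catalog, cfg, "control", 1)
        assert len(reads) == cfg.n_reads
        by_seq = {g.seq + "CCA": g for g in catalog}
        for r in reads[:200]:
            core = r.seq[: r.seq.find(cfg.adapter)]
            assert core in by_seq
        assert truth.group_props["OTHER"][CALL_CCA] == pytest.approx(1.0)

    def test_ccloss_one_gives_all_cc(self, catalog):
        cfg = _pure_trna_cfg(p_ccloss=1.0)
        reads, truth = simulate_library(catalog, cfg, "control", 1)
        for r in reads[:200]:
            core = r.seq[: r.seq.find(cfg.adapter)]
            assert core.endswith("CC") and not core.endswith("CCA")
        assert truth.group_props["OTHER"][CALL_CC] == pytest.approx(1.0)

    def test_deterministic_fastq(self, catalog):
        cfg = _pure_trna_cfg(p_ccloss=0.1, p_immature=0.1, error_rate=0.01)
        a, _ = simulate_library(catalog, cfg, "control", 1)
        b, _ = simulate_library(catalog, cfg, "control", 1)
        assert a == b
        c, _ = simulate_library(catalog, cfg, "control", 2)  # other replicate
        assert a != c

    def test_read_ids_unique_and_plain(self, catalog):
        cfg = _pure_trna_cfg(p_ccloss=0.3, p_immature=0.2)
        reads, _ = simulate_library(catalog, cfg, "control", 1)
        ids = [r.read_id for r in reads]
        assert len(set(ids)) == len(ids)
        for token in ("CCA", "CC", "IMM", "full", "3p", "5p"):
            assert all(token not in i for i in ids)

    def test_cc_fraction_within_binomial_noise(self, catalog):
        """At p_ccloss=0.05 the fraction of reads ending CC (before the
        adapter) sits within 3 binomial SE of 0.05."""
        n = 100_000
        cfg = _pure_trna_cfg(n_reads=n, p_ccloss=0.05)
        reads, _ = simulate_library(catalog, cfg, "control", 1)
        n_cc = sum(
            1 for r in reads
            if r.seq[: r.seq.find(cfg.adapter)].endswith("CC")
        )
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(n_cc / n - 0.05) < 3 * se

    def test_empty_window_warns_and_returns_empty(self, catalog):
        cfg = _pure_trna_cfg(size_window=(140, 149))  # no molecule class fits
        with pytest.warns(UserWarning, match="size window"):
            reads, _ = simulate_library(catalog, cfg, "control", 1)
        assert reads == []


class TestFragmentPool:
    def test_cleavage_conservation(self, catalog):
        """Every cleaved molecule contributes exactly one 5'-half and one
        3'-half before size filtering, and the 3'-half keeps the parent's
        terminus."""
        cfg = SimConfig(p_frag_base=1.0, background_weight=0.0, p_immature=0.0,
                        p_ccloss=0.0, conditions=(("c", 1.0),), seed=4)
        rng = np.random.default_rng(0)
        frags = _draw_fragments(catalog, cfg, 1.0, rng, 500)
        kinds = [f.kind for f in frags]
        assert kinds.count("5p") == kinds.count("3p") == 500
        for f in frags:
            if f.kind == "3p":
                assert f.seq.endswith("CCA")
        # halves re-assemble into gene + CCA
        by_gene = {}
        it = iter(frags)
        for five, three in zip(it, it):
            assert five.kind == "5p" and three.kind == "3p"
            assert five.seq + three.seq == catalog.genes[five.gene_idx].seq + "CCA"

    def test_cut_site_within_clamp(self, catalog):
        cfg = SimConfig(p_frag_base=1.0, background_weight=0.0, seed=4)
        frags = _draw_fragments(catalog, cfg, 1.0, np.random.default_rng(1), 2000)
        lens = [len(f.seq) for f in frags if f.kind == "5p"]
        assert min(lens) >= cfg.cleavage_site_min
        assert max(lens) <= cfg.cleavage_site_max


class TestExpectedTruth:
    def test_no_fragmentation_means_empty_tirna_fraction(self, catalog):
        cfg = SimConfig(p_frag_base=0.0, background_weight=0.0,
                        size_window=TIRNA_WINDOW, read_length=75,
                        conditions=(("control", 1.0),), seed=1)
        truth = expected_truth(cfg, catalog).conditions["control"]
        assert all(v == 0 for v in truth.expected_end_counts.values())

    def test_pool_level_half_mass_ratio_is_exactly_fold(self, catalog):
        cfg = SimConfig(seed=1)
        truth = expected_truth(cfg, catalog)
        r = (truth.conditions["ANG"].three_prime_half_mass
             / truth.conditions["control"].three_prime_half_mass)
        assert r == pytest.approx(6.3, rel=1e-12)

    def test_proportions_sum_to_one(self, catalog):
        truth = expected_truth(SimConfig(seed=1), catalog)
        for cond in truth.conditions.values():
            for grp, props in cond.group_props.items():
                assert sum(props.values()) == pytest.approx(1.0)

    def test_group_cca_inflation_direction(self, catalog):
        """Immature reads inflate the apparent CCA_added proportion for genes
        whose genome already ends in CCA — the ambiguity the grouping
        exposes."""
        cfg = SimConfig(p_immature=0.2, seed=1)
        truth = expected_truth(cfg, catalog).conditions["control"]
        assert truth.group_props["CCA"][CALL_CCA] > truth.group_props["OTHER"][CALL_CCA]
        assert truth.group_props["CC"][CALL_CC] > truth.group_props["OTHER"][CALL_CC]

    def test_monte_carlo_matches_closed_form(self, catalog):
        """Fragment-level Monte Carlo tallies of (group, class) proportions
        match the closed form within 3 SE, error-free conditions."""
        cfg = SimConfig(n_reads=1, error_rate=0.0, seed=21,
                        size_window=TRNA_WINDOW)
        p_c = cfg.frag_prob("control")
        rng = np.random.default_rng(99)
        n = 200_000
        frags = _draw_fragments(catalog, cfg, p_c, rng, n)
        tallies = {g: {CALL_CCA: 0, CALL_CC: 0, CALL_OTHER: 0}
                   for g in ("CCA", "CC", "OTHER")}
        for f in frags:
            if f.kind in ("bg", "5p"):
                continue
            if not (cfg.size_window[0] <= len(f.seq) <= cfg.size_window[1]):
                continue
            grp = catalog.genes[f.gene_idx].terminal_group
            s = f.seq
            if s.endswith("CCA"):
                tallies[grp][CALL_CCA] += 1
            elif s.endswith("CC"):
                tallies[grp][CALL_CC] += 1
            else:
                tallies[grp][CALL_OTHER] += 1
        truth = expected_truth(cfg, catalog).conditions["control"]
        for grp, counts in tallies.items():
            tot = sum(counts.values())
            assert tot > 0
            for call in (CALL_CCA, CALL_CC, CALL_OTHER):
                p = truth.group_props[grp][call]
                se = np.sqrt(max(p * (1 - p), 1e-9) / tot)
                assert abs(counts[call] / tot - p) <= 3 * se + 1e-9, (
                    f"{grp}/{call}: mc={counts[call]/tot:.4f} truth={p:.4f}")
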