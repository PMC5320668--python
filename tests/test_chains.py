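"""Haplotype-chain inference: feasibility, priors, the constrained Viterbi,
and the coordinate-ascent optimizer against exhaustive oracles."""

import itertools
import math

import numpy as np
import pytest

from epichain.chains import (
    WindowModel,
    brute_force_fit,
    fit,
    is_feasible_addition,
    log_posterior,
    log_prior_B,
    log_prior_G,
    optimal_epigenotype_chain,
    overlap_stats,
)
from epichain.config import ModelConfig
from epichain.model import (
    BASE_CODE,
    EPIGENOTYPES,
    Epigenotype,
    StrandLabel,
    emission_prob,
)
from epichain.reference import ReferenceWindow, classify_contexts
from epichain.simulate import EpiAlleleSpec, SimConfig, make_reference, simulate_reads

from conftest import read


def small_wm(seq: str, mode="wgbs-single", **over) -> WindowModel:
    cfg = ModelConfig.from_mode(mode, **over)
    return WindowModel(ReferenceWindow("chrT", 0, seq), cfg)


class TestOverlapStats:
    def test_read_inside_chain(self, tiny_window):
        ctx = classify_contexts(tiny_window)
        r = read("r", 2, "CGTTACGTAA")
        bp, *_ = overlap_stats((0, 22), r, ctx)
        assert bp == 10

    def test_disjoint(self, tiny_window):
        ctx = classify_contexts(tiny_window)
        r = read("r", 15, "TGCATT")
        assert overlap_stats((0, 10), r, ctx) == (0, 0, 0, 0)

    def test_context_counts(self):
        # reference ACGT: one isolated CpG, no GpC
        w = ReferenceWindow("c", 0, "ACGT")
        ctx = classify_contexts(w)
        r = read("r", 0, "ACGT")
        assert overlap_stats((0, 4), r, ctx) == (4, 1, 1, 0)

    def test_mate_pair_uses_both_footprints(self, tiny_window):
        ctx = classify_contexts(tiny_window)
        r = read("r", 0, "AACG", mate=(10, "AAGC"))
        bp, n_cpg, _, _ = overlap_stats((0, 22), r, ctx)
        assert bp == 8  # two 4 bp mates, insert gap not counted


class TestFeasibility:
    def test_k0_boundary(self):
        wm = small_wm("ACGT" * 30, mode="wgbs-paired")  # K0=50, K1=2
        K = wm.config.feasibility
        ctx = wm.ctx
        r49 = read("r", 0, "A" * 49)
        r50 = read("r", 0, "A" * 50)
        assert not is_feasible_addition((0, 120), r49, K, ctx)
        # 50 bp of ACGT-repeat contain >= 2 CpGs: boundary is inclusive
        assert is_feasible_addition((0, 120), r50, K, ctx)

    def test_k1_gate(self):
        # CpG-free reference: overlap long enough but no CpGs
        wm = small_wm("AT" * 60, mode="wgbs-paired")
        r = read("r", 0, "A" * 60)
        assert not is_feasible_addition((0, 120), r, wm.config.feasibility, wm.ctx)

    def test_k3_gate_nome(self):
        wm = small_wm("AT" * 60, mode="nome")  # K3=2 isolated GpCs
        r = read("r", 0, "A" * 60)
        assert not is_feasible_addition((0, 120), r, wm.config.feasibility, wm.ctx)


class TestOptimalEpigenotypeChain:
    def enumerate_oracle(self, reads, strands, wm):
        """Exhaustive max over all strand-compatible 6-state chains (L <= 6)."""
        L = len(wm.window)
        params = wm.config.conversion
        # per-position per-state score table from scalar emission calls
        S = wm.prior6[:L].copy()
        for r, strand in zip(reads, strands):
            lab = StrandLabel.fwd if strand == "fwd" else StrandLabel.rev
            for seg in r.segments:
                for k, b in enumerate(seg.bases):
                    for s in range(6):
                        S[seg.start + k, s] += math.log(
                            emission_prob(
                                "ACGTN"[b],
                                EPIGENOTYPES[s],
                                lab,
                                params,
                                epsilon=seg.epsilons[k],
                            )
                        )
        best = (-math.inf, None)
        for states in itertools.product(range(6), repeat=L):
            ok = True
            for j, s in enumerate(states):
                if s == 4 and (j + 1 >= L or states[j + 1] != 5):
                    ok = False
                if s == 5 and (j == 0 or states[j - 1] != 4):
                    ok = False
            if not ok:
                continue
            score = sum(S[j, states[j]] for j in range(L))
            if score > best[0]:
                best = (score, states)
        return best

    def test_matches_exhaustive_enumeration(self):
        wm = small_wm("TACGTA")
        reads = [read("a", 0, "TACGTA", eps=0.01), read("b", 0, "TATGTA", eps=0.01)]
        strands = ["fwd", "fwd"]
        g, score = optimal_epigenotype_chain(reads, strands, wm)
        oracle_score, oracle_states = self.enumerate_oracle(reads, strands, wm)
        assert score == pytest.approx(oracle_score, abs=1e-9)
        assert tuple(g) == oracle_states

    def test_error_free_pair_T_C_decodes_unmethylated(self):
        wm = small_wm("AACGTT")
        # forward read shows the converted T, reverse read the untouched C
        reads = [read("f", 0, "AATGTT", eps=1e-6), read("r", 0, "AACATT", eps=1e-6)]
        g, _ = optimal_epigenotype_chain(reads, ["fwd", "rev"], wm)
        assert g[2] == BASE_CODE["C"] and g[3] == BASE_CODE["G"]

    def test_error_free_pair_C_C_decodes_methylated(self):
        wm = small_wm("AACGTT")
        reads = [read("f", 0, "AACGTT", eps=1e-6), read("r", 0, "AACGTT", eps=1e-6)]
        g, _ = optimal_epigenotype_chain(reads, ["fwd", "rev"], wm)
        assert g[2] == 4 and g[3] == 5  # meC, meG

    def test_methylation_only_as_cpg_pairs(self):
        wm = small_wm("TACGTA")
        reads = [read(f"r{i}", 0, "TACGTA", eps=0.01) for i in range(10)]
        g, score = optimal_epigenotype_chain(reads, ["fwd"] * 10, wm)
        assert g[2] == 4 and g[3] == 5
        oracle_score, _ = self.enumerate_oracle(reads, ["fwd"] * 10, wm)
        assert score == pytest.approx(oracle_score, abs=1e-9)

    def test_gap_rejected(self):
        wm = small_wm("A" * 30)
        reads = [read("a", 0, "AAAA"), read("b", 20, "AAAA")]
        with pytest.raises(ValueError):
            optimal_epigenotype_chain(reads, ["fwd", "fwd"], wm)


class TestPriors:
    def test_prior_B_formula(self):
        got = log_prior_B([(150, [100, 100])])
        assert got == pytest.approx(2 * (0.5 * math.log(150) + 2 * math.log(200)))

    def test_equal_length_form_matches_up_to_constant(self):
        """With equal-length reads the general form equals prod n_i^2 sqrt(L)
        up to a structure-independent constant."""
        l = 80
        structures = [
            [(300, [l] * 3), (200, [l] * 2)],
            [(500, [l] * 5)],
            [(100, [l]), (120, [l]), (250, [l] * 3)],
        ]
        for chains in structures:
            general = log_prior_B(chains)
            simple = sum(
                len(lens) * (2 * math.log(len(lens)) + 0.5 * math.log(L))
                for L, lens in chains
            )
            n_total = sum(len(lens) for _, lens in chains)
            # difference is n_total * 2 log(l), independent of the structure
            assert general - simple == pytest.approx(n_total * 2 * math.log(l))

    def test_singletons_have_finite_weight(self):
        assert math.isfinite(log_prior_B([(100, [100]), (50, [50])]))

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            log_prior_B([(100, [])])

    def test_prior_G_reference_match(self):
        wm = small_wm("A" * 100)
        g = np.zeros(100, dtype=np.int8)  # all A = reference
        assert log_prior_G([(g, 0)], wm) == pytest.approx(100 * math.log(0.9999))

    def test_prior_G_private_mutation_cost(self):
        wm = small_wm("A" * 10)
        g0 = np.zeros(10, dtype=np.int8)
        g1 = g0.copy()
        g1[4] = BASE_CODE["T"]
        d = log_prior_G([(g0, 0)], wm) - log_prior_G([(g1, 0)], wm)
        assert d == pytest.approx(math.log(0.9999 / 0.0001))

    def test_q_half_is_uniform(self):
        wm = small_wm("ACGTAGGT", q=0.5)
        g_ref = wm.window.codes.copy()
        g_alt = g_ref.copy()
        g_alt[:] = BASE_CODE["T"]
        assert log_prior_G([(g_ref, 0)], wm) == pytest.approx(
            log_prior_G([(g_alt, 0)], wm)
        )


def _sim_instance(seed, n_reads=8, length=300):
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        seed=seed,
        length=length,
        cpg_positions=list(range(10, length - 10, 25)),
        depth=n_reads * 60 / length,
        read_length=60,
        layout="single",
        phred=25,
    )
    win = make_reference(cfg)
    alleles = [
        EpiAlleleSpec.uniform(win, "m", 0.5, methylated=True),
        EpiAlleleSpec.uniform(win, "u", 0.5, methylated=False),
    ]
    reads, truth = simulate_reads(alleles, cfg, win)
    return reads, truth, win


class TestFit:
    def test_identical_reads_merge(self):
        wm = small_wm("TT" + "ACGT" * 10 + "TT", K0=20, K1=1)
        reads = [read("a", 2, "ACGT" * 10, eps=0.01), read("b", 2, "ACGT" * 10, eps=0.01)]
        res = fit(reads, wm)
        assert len(res.chains) == 1
        oracle = brute_force_fit(reads, wm)
        assert res.log_lambda == pytest.approx(oracle.log_lambda, abs=1e-6)
        assert len(oracle.chains) == 1

    def test_discordant_reads_stay_split(self):
        wm = small_wm("TT" + "ACGT" * 10 + "TT", K0=20, K1=1)
        meth = "ACGT" * 10
        unmeth = "ATGT" * 10  # every CpG C converted
        reads = [read("a", 2, meth, eps=0.01), read("b", 2, unmeth, eps=0.01)]
        res = fit(reads, wm)
        assert len(res.chains) == 2
        oracle = brute_force_fit(reads, wm)
        assert res.log_lambda == pytest.approx(oracle.log_lambda, abs=1e-6)
        assert len(oracle.chains) == 2

    def test_no_cpg_overlap_never_merges(self):
        # reads overlapping only in a CpG-free zone
        wm = small_wm("TACGTA" + "T" * 30 + "A" * 20, K0=4, K1=1)
        r1 = read("a", 0, "TACGTA" + "T" * 10, eps=0.01)
        r2 = read("b", 8, "T" * 20, eps=0.01)
        res = fit([r1, r2], wm)
        assert res.assignment["a"] != res.assignment["b"]

    def test_strand_recovery_on_clean_reads(self):
        cfg = SimConfig(
            seed=5,
            length=400,
            cpg_positions=list(range(20, 380, 40)),
            depth=5,
            read_length=80,
            layout="single",
            conversion_rate=1.0,
            beta=0.0,
            phred=90,
        )
        win = make_reference(cfg)
        alleles = [EpiAlleleSpec.uniform(win, "u", 1.0, methylated=False)]
        reads, truth = simulate_reads(alleles, cfg, win)
        wm = WindowModel(win, ModelConfig.from_mode("wgbs-single", K0=20, K1=1))
        res = fit(reads, wm)
        agree = sum(
            res.strands[r.id] == truth.read_truth[r.id][1] for r in reads
        )
        assert agree == len(reads)

    def test_monotone_trajectory_and_termination(self):
        for seed in (11, 12, 13):
            reads, _, win = _sim_instance(seed, n_reads=20, length=400)
            wm = WindowModel(win, ModelConfig.from_mode("wgbs-single", K0=20, K1=1))
            res = fit(reads, wm)
            assert np.all(np.diff(res.trajectory) > 0)
            assert res.converged

    def test_log_posterior_matches_naive_recomputation(self):
        """Assembled posterior equals a from-scratch scalar recomputation."""
        for seed in range(3):
            reads, _, win = _sim_instance(100 + seed, n_reads=10, length=250)
            wm = WindowModel(win, ModelConfig.from_mode("wgbs-single", K0=15, K1=1))
            res = fit(reads, wm)
            naive = log_prior_B(
                [
                    (c.length, [res.reads[i].length for i in c.member_idx])
                    for c in res.chains
                ]
            )
            for c in res.chains:
                for j in range(c.length):
                    naive += wm.prior6[c.start + j, c.g[j]]
            params = wm.config.conversion
            for c in res.chains:
                for i in c.member_idx:
                    r = res.reads[i]
                    lab = (
                        StrandLabel.fwd
                        if res.strands[r.id] == "fwd"
                        else StrandLabel.rev
                    )
                    for seg in r.segments:
                        for k, b in enumerate(seg.bases):
                            naive += math.log(
                                emission_prob(
                                    "ACGTN"[b],
                                    EPIGENOTYPES[c.state_at(seg.start + k)],
                                    lab,
                                    params,
                                    epsilon=seg.epsilons[k],
                                )
                            )
            assert res.log_lambda == pytest.approx(naive, abs=1e-6)
            assert log_posterior(res) == pytest.approx(naive, abs=1e-6)


class TestBruteForce:
    def test_single_read_equals_fit(self):
        wm = small_wm("TACGTTTACGTT", K0=4, K1=1)
        reads = [read("a", 0, "TACGTTTACG", eps=0.01)]
        res = fit(reads, wm)
        oracle = brute_force_fit(reads, wm)
        assert res.log_lambda == pytest.approx(oracle.log_lambda, abs=1e-9)

    def test_size_guard(self):
        wm = small_wm("TACGTT" * 2, K0=4, K1=1)
        reads = [read(f"r{i}", 0, "TACGTT", eps=0.01) for i in range(7)]
        with pytest.raises(ValueError):
            brute_force_fit(reads, wm)

    def test_fit_never_beats_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            seed = int(rng.integers(1, 2**31))
            cfg = SimConfig(
                seed=seed,
                length=80,
                cpg_positions=[15, 35, 55],
                depth=2.0,
                read_length=40,
                layout="single",
                phred=20,
            )
            win = make_reference(cfg)
            alleles = [
                EpiAlleleSpec.uniform(win, "m", 0.5, methylated=True),
                EpiAlleleSpec.uniform(win, "u", 0.5, methylated=False),
            ]
            reads, _ = simulate_reads(alleles, cfg, win)
            reads = reads[:4]
            wm = WindowModel(win, ModelConfig.from_mode("wgbs-single", K0=15, K1=1))
            res = fit(reads, wm)
            oracle = brute_force_fit(reads, wm)
            assert res.log_lambda <= oracle.log_lambda + 1e-6
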