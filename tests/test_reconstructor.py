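"""Snippet libraries, fragment insertion and the annealing search."""

import numpy as np
import pytest

from cafold.fixtures import synthetic_snippets
from cafold.metrics import gdt_score, kabsch_superpose
from cafold.reconstructor import (
    AnnealParams,
    Snippet,
    SnippetLibrary,
    build_snippet_library,
    clash_penalty,
    energy,
    insert_snippet,
    metropolis_accept,
    pick_insertion_site,
    reconstruct,
    temperature,
)
from cafold.structures import CaTrace, random_extended_trace, to_internal

from .conftest import featured


def snippet_from(trace, pos, source="t"):
    return Snippet(trace.coords[pos : pos + 9].copy(), source, pos)


class TestSnippetLibrary:
    def test_identity_alignment_covers_chain(self, random_trace):
        L = len(random_trace)
        rows = [(i, "self", i) for i in range(L)]
        lib = build_snippet_library(L, rows, {"self": random_trace})
        assert lib.positions == list(range(L - 8))
        for pos in lib.positions:
            s = lib.snippets_at(pos)[0]
            assert np.array_equal(s.coords, random_trace.coords[pos : pos + 9])

    def test_tail_rows_skipped(self, random_trace):
        L = len(random_trace)
        rows = [(0, "self", L - 4)]  # < 9 residues left in template
        lib = build_snippet_library(L, rows, {"self": random_trace})
        assert len(lib) == 0

    def test_unknown_template_rejected(self, random_trace):
        with pytest.raises(KeyError):
            build_snippet_library(20, [(0, "nope", 0)], {"self": random_trace})

    def test_jsonl_round_trip(self, tmp_path, random_trace):
        lib = synthetic_snippets(featured(random_trace), n_per_pos=2, seed=0)
        p = tmp_path / "lib.jsonl"
        lib.save_jsonl(p)
        back = SnippetLibrary.load_jsonl(p)
        assert back.positions == lib.positions
        assert len(back) == len(lib)

    def test_snippet_invariants_enforced(self):
        with pytest.raises(ValueError):
            Snippet(np.zeros((9, 3)), "bad", 0)  # coincident points
        with pytest.raises(ValueError):
            Snippet(np.zeros((8, 3)), "bad", 0)


class TestPickInsertionSite:
    def test_all_coil_uniform(self, random_trace):
        trace = featured(random_trace)  # all-coil ss3
        lib = synthetic_snippets(trace, n_per_pos=1, seed=0)
        rng = np.random.default_rng(0)
        n_pos = len(lib.positions)
        counts = np.zeros(n_pos)
        draws = 10000
        for _ in range(draws):
            pos, _ = pick_insertion_site(trace, lib, rng)
            counts[pos] += 1
        from scipy.stats import chisquare
        assert chisquare(counts).pvalue > 0.01

    def test_no_coil_fallback(self, random_trace):
        trace = CaTrace(random_trace.sequence, random_trace.coords,
                        "H" * len(random_trace), ("buried",) * len(random_trace))
        lib = synthetic_snippets(trace, n_per_pos=1, seed=0)
        rng = np.random.default_rng(0)
        pos, snip = pick_insertion_site(trace, lib, rng)
        assert pos in lib.positions

    def test_coil_bias_frequency(self):
        # 1 coil position among 10: expect 0.8 + 0.2/10 = 0.82
        L = 18  # 10 window positions
        trace = random_extended_trace("A" * L, 0)
        ss3 = ["H"] * L
        ss3[4] = "C"
        trace = CaTrace(trace.sequence, trace.coords, "".join(ss3),
                        ("exposed",) * L)
        lib = synthetic_snippets(trace, n_per_pos=1, seed=0)
        assert len(lib.positions) == 10
        rng = np.random.default_rng(1)
        draws = 10000
        hits = sum(
            pick_insertion_site(trace, lib, rng)[0] == 4 for _ in range(draws))
        p = 0.8 + 0.2 / 10
        sigma = np.sqrt(p * (1 - p) * draws)
        assert abs(hits - p * draws) < 3 * sigma

    def test_empty_library_rejected(self, random_trace):
        with pytest.raises(ValueError):
            pick_insertion_site(featured(random_trace), SnippetLibrary(),
                                np.random.default_rng(0))


class TestInsertSnippet:
    @pytest.mark.parametrize("pos", [0, 1, 5, 31])
    def test_identity_insertion_is_noop(self, random_trace, pos):
        out = insert_snippet(random_trace, snippet_from(random_trace, pos), pos)
        assert np.abs(out.coords - random_trace.coords).max() < 1e-9

    def test_window_adopts_snippet_internal_geometry(self, random_trace):
        other = random_extended_trace("A" * 40, 99)
        snip = snippet_from(other, 12)
        out = insert_snippet(random_trace, snip, 10)
        got = to_internal(out.coords[10:19])
        want = to_internal(snip.coords)
        assert np.abs(got.bond_lengths - want.bond_lengths).max() < 1e-9
        assert np.abs(got.torsions - want.torsions).max() < 1e-9

    def test_upstream_unchanged_downstream_rigid(self, random_trace):
        other = random_extended_trace("A" * 40, 98)
        out = insert_snippet(random_trace, snippet_from(other, 3), 15)
        assert np.abs(out.coords[:15] - random_trace.coords[:15]).max() < 1e-9
        _, _, r = kabsch_superpose(random_trace.coords[24:], out.coords[24:])
        assert r < 1e-9

    def test_input_not_mutated(self, random_trace):
        before = random_trace.coords.copy()
        other = random_extended_trace("A" * 40, 97)
        insert_snippet(random_trace, snippet_from(other, 0), 10)
        assert np.array_equal(random_trace.coords, before)

    def test_window_overflow_rejected(self, random_trace):
        snip = snippet_from(random_trace, 0)
        with pytest.raises(ValueError):
            insert_snippet(random_trace, snip, len(random_trace) - 8)


class TestClashPenalty:
    def test_extended_chain_clash_free(self):
        for seed in range(5):
            t = random_extended_trace("A" * 50, seed)
            # bonded pairs at 3.73-3.87 A are never counted
            assert clash_penalty(t) >= 0.0

    def test_forced_clash_counted_once(self):
        t = random_extended_trace("A" * 12, 0)
        coords = t.coords.copy()
        coords[7] = coords[2] + [2.0, 0.0, 0.0]
        c = clash_penalty(CaTrace(t.sequence, coords), weight=2.5)
        brute = sum(
            np.linalg.norm(coords[i] - coords[j]) < 3.73
            for i in range(12) for j in range(i + 2, 12))
        assert c == pytest.approx(2.5 * brute)
        assert brute >= 1

    def test_matches_brute_force(self):
        for seed in range(50):
            t = random_extended_trace("A" * 25, seed)
            brute = sum(
                np.linalg.norm(t.coords[i] - t.coords[j]) < 3.73
                for i in range(25) for j in range(i + 2, 25))
            assert clash_penalty(t) == pytest.approx(float(brute))


class TestEnergy:
    def test_perfect_model_zero_energy(self):
        assert energy(1.0, 60, 0.0) == 0.0

    def test_worst_model_energy_is_length(self):
        assert energy(-1.0, 60, 0.0) == 60.0

    def test_direct_arithmetic(self):
        # L = 60, O01 = 0.5, C = 2 -> 60 - 30 + 2 = 32
        assert energy(0.0, 60, 2.0) == 32.0


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(10.0, 5.0, t, rng)
                   for t in (0.01, 1.0, 100.0))

    def test_equal_energy_accepted(self):
        rng = np.random.default_rng(0)
        assert metropolis_accept(5.0, 5.0, 1e-9, rng)

    def test_uphill_acceptance_rate_matches_boltzmann(self):
        rng = np.random.default_rng(1)
        n = 100000
        for dE, T in [(1.0, 1.0), (2.0, 1.0), (1.0, 0.5)]:
            acc = sum(metropolis_accept(0.0, dE, T, rng) for _ in range(n))
            p = np.exp(-dE / T)
            sigma = np.sqrt(p * (1 - p) * n)
            assert abs(acc - p * n) < 3 * sigma


class TestTemperature:
    def test_quadratic_schedule(self):
        assert temperature(0, 100, 8.0) == 8.0
        assert temperature(50, 100, 8.0) == pytest.approx(2.0)
        assert temperature(100, 100, 8.0) == pytest.approx(1e-6)

    def test_step_bounds_checked(self):
        with pytest.raises(ValueError):
            temperature(101, 100, 1.0)


class TestReconstruct:
    def test_zero_steps_returns_start(self, native_trace):
        lib = synthetic_snippets(native_trace, n_per_pos=2, seed=0)
        from cafold.nnpif import init_model
        from cafold.encoding import ENCODING_DIM
        model = init_model(ENCODING_DIM, 0)
        final, traj = reconstruct(native_trace, lib, model,
                                  AnnealParams(steps=0, seed=0))
        assert np.array_equal(final.coords, native_trace.coords)
        assert traj.n_steps == 0

    def test_energy_changes_only_on_acceptance(self, native_trace):
        lib = synthetic_snippets(native_trace, n_per_pos=2, seed=0)
        final, traj = reconstruct(
            native_trace, lib, None, AnnealParams(steps=120, seed=1),
            score_fn=lambda c: 0.0)
        prev = traj.initial_energy
        for e, acc in zip(traj.energies, traj.accepted):
            if not acc:
                assert e == prev
            prev = e

    def test_bitwise_deterministic(self, native_trace):
        lib = synthetic_snippets(native_trace, n_per_pos=2, seed=0)
        from cafold.nnpif import init_model
        from cafold.encoding import ENCODING_DIM
        model = init_model(ENCODING_DIM, 0)
        p = AnnealParams(steps=60, seed=3)
        f1, t1 = reconstruct(native_trace, lib, model, p)
        f2, t2 = reconstruct(native_trace, lib, model, p)
        assert np.array_equal(f1.coords, f2.coords)
        assert t1.energies == t2.energies

    def test_oracle_guided_search_improves_gdt(self, native_trace):
        # replace the network by an oracle O = 2*GDT(current, native) - 1
        lib = synthetic_snippets(native_trace, n_per_pos=4,
                                 native_fraction=0.5, noise_A=0.2, seed=0)
        gains = []
        for seed in range(5):
            start = random_extended_trace(native_trace.sequence, 100 + seed)
            start = CaTrace(native_trace.sequence, start.coords,
                            native_trace.ss3, native_trace.acc)
            final, _ = reconstruct(
                start, lib, None, AnnealParams(steps=250, seed=seed),
                score_fn=lambda c: 2 * gdt_score(c, native_trace.coords) - 1)
            gains.append(gdt_score(final, native_trace)
                         - gdt_score(start, native_trace))
        assert np.mean(gains) > 0
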