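"""Particle-based simulator: rates, stepping, conservation, consistency."""
import numpy as np
import pytest

from rulesim import bngl, fixtures, network_free as nf
from rulesim.trajectory import Addition, Protocol


def _model(text):
    return bngl.parse_model(text)


class TestInitialize:
    def test_seed_instantiation_and_embedding_counts(self):
        model = fixtures.build_toy("binding", nA=100, nB=50)
        st = nf.initialize(model, seed=0)
        assert len(st.particles) == 150
        # pattern A(b) of the forward rule sees every free A
        assert len(st.rule_rt[0].slots[0].embs) == 100
        assert len(st.rule_rt[0].slots[1].embs) == 50

    def test_empty_seed_block_gives_zero_rate(self):
        model = _model("""
begin parameters
  k 1.0
end parameters
begin molecule types
  A(b)
end molecule types
begin seed species
end seed species
begin observables
end observables
begin reaction rules
  dim: A(b) + A(b) -> A(b!1).A(b!1) k
end reaction rules
""")
        st = nf.initialize(model, seed=0)
        assert len(st.particles) == 0
        assert st.total_rate() == 0.0

    def test_scale_multiplies_copy_numbers_with_bankers_rounding(self):
        model = fixtures.build_toy("binding", nA=25, nB=35)
        st = nf.initialize(model, seed=0, scale=0.2)
        # 25*0.2 = 5.0, 35*0.2 = 7.0
        counts = st.molecule_counts()
        assert counts == {"A": 5, "B": 7}
        st2 = nf.initialize(fixtures.build_toy("binding", nA=12, nB=13),
                            seed=0, scale=0.5)
        # 6.0 and 6.5 -> round-half-to-even gives 6 and 6
        assert st2.molecule_counts() == {"A": 6, "B": 6}

    def test_particle_cap_enforced(self):
        model = fixtures.build_toy("binding", nA=100, nB=100)
        with pytest.raises(nf.SimulationError, match="scale"):
            nf.initialize(model, seed=0, max_particles=50)


class TestTotalRate:
    def test_unimolecular(self):
        model = fixtures.build_toy("isomerization", n=50, kf=0.1, kr=0.0)
        st = nf.initialize(model, seed=0)
        assert st.total_rate() == pytest.approx(0.1 * 50)

    def test_bimolecular_heterotypic(self):
        model = fixtures.build_toy("binding", nA=100, nB=200, kon=1e-6,
                                   koff=0.0)
        st = nf.initialize(model, seed=0)
        assert st.total_rate() == pytest.approx(1e-6 * 100 * 200)

    def test_bimolecular_homotypic_counts_unordered_pairs(self):
        model = fixtures.build_toy("dimerization", n=10, kon=1e-6, koff=0.0)
        st = nf.initialize(model, seed=0)
        # 10*9/2 distinct unordered pairs
        assert st.total_rate() == pytest.approx(10 * 9 / 2 * 1e-6)


class TestStep:
    def test_single_irreversible_conversion(self):
        model = _model("""
begin parameters
  k 1.0
end parameters
begin molecule types
  A(s~X~Y)
end molecule types
begin seed species
  A(s~X) 1
end seed species
begin observables
  Molecules inY A(s~Y!?)
end observables
begin reaction rules
  conv: A(s~X) -> A(s~Y) k
end reaction rules
""")
        st = nf.initialize(model, seed=1)
        rec = st.step()
        assert rec is not None and not rec["null"]
        assert st.observable_values() == [1]
        assert st.step() is None   # nothing left to do

    def test_stoichiometric_exhaustion(self):
        model = fixtures.build_toy("binding", nA=5, nB=8, kon=1.0, koff=0.0)
        st = nf.initialize(model, seed=2)
        while st.step() is not None:
            pass
        # AB, freeA, freeB
        assert st.observable_values() == [5, 0, 3]

    def test_mean_waiting_time_matches_exponential(self):
        # X<->Y at equal rates: every molecule matches exactly one rule, so
        # the total rate is constant = n*k regardless of state
        model = fixtures.build_toy("isomerization", n=50, kf=0.1, kr=0.1)
        st = nf.initialize(model, seed=3)
        n_steps = 10_000
        t0 = st.time
        for _ in range(n_steps):
            st.step()
        mean_dt = (st.time - t0) / n_steps
        expect = 1.0 / (50 * 0.1)
        se = expect / np.sqrt(n_steps)
        assert abs(mean_dt - expect) < 3 * se

    def test_molecularity_null_events_prevent_ring_closure(self):
        # chain toy: polymerization must never close a ring, and selecting
        # two ends of one chain must be a null event
        model = fixtures.build_toy("chain", n=20, kon=0.1, koff=0.0)
        st = nf.initialize(model, seed=4)
        for _ in range(200):
            if st.step() is None:
                break
        # every complex is a linear chain: bonds = molecules - 1
        seen = set()
        for pid in list(st.particles):
            if pid in seen:
                continue
            cx = nf.complex_of(st.particles, [pid])
            seen |= cx
            n_bonds = sum(
                1 for q in cx for b in st.particles[q].bonds
                if b is not None) // 2
            assert n_bonds == len(cx) - 1
        assert st.null_count > 0


class TestRun:
    def test_determinism_per_seed(self):
        model = fixtures.build_toy("binding")
        a = nf.run(model, t_end=20, sample_dt=2, seed=7)
        b = nf.run(model, t_end=20, sample_dt=2, seed=7)
        assert np.array_equal(a.values, b.values)
        c = nf.run(model, t_end=20, sample_dt=2, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_isomerization_symmetry(self):
        # equal forward/backward rates: long-time mean fraction in Y = 1/2
        model = fixtures.build_toy("isomerization", n=40, kf=0.2, kr=0.2)
        fracs = []
        for s in range(100):
            traj = nf.run(model, t_end=60, sample_dt=60, seed=s)
            fracs.append(traj.observable("inY")[-1] / 40)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.5) < 3 * se

    def test_conservation_without_create_delete(self):
        model = fixtures.build_erbb_mini(fixtures.ErbbConfig(tier=1))
        proto = fixtures.ligand_dose_protocol(model, scale=0.2)
        traj = nf.run(model, protocol=proto, t_end=30, sample_dt=10,
                      seed=5, scale=0.2)
        counts = traj.state.molecule_counts()
        seeds = {g.molecules[0].typename: int(round(c * 0.2))
                 for g, c in model.seed_species}
        for tname, n in seeds.items():
            assert counts[tname] == n
        assert counts["EGF"] == 602 and counts["HRG"] == 602

    def test_embedding_index_consistency_along_run(self):
        model = fixtures.build_erbb_mini(fixtures.ErbbConfig(tier=1))
        proto = fixtures.ligand_dose_protocol(model, scale=0.2)
        traj = nf.run(model, protocol=proto, t_end=40, sample_dt=20, seed=6,
                      scale=0.2, debug_check_interval=500)
        traj.state.check_index()   # final state, full recompute

    def test_equilibration_runs_before_time_zero(self):
        model = fixtures.build_toy("binding", nA=60, nB=60)
        proto = Protocol(equilibrate=200.0)
        traj = nf.run(model, protocol=proto, t_end=10, sample_dt=10, seed=9)
        # the system was pre-relaxed: AB is already near equilibrium at t=0
        assert traj.observable("AB")[0] > 10

    def test_addition_intervention(self):
        model = fixtures.build_toy("binding", nA=10, nB=0)
        proto = Protocol(additions=[Addition(5.0, "B(a)", 30)])
        traj = nf.run(model, protocol=proto, t_end=10, sample_dt=1, seed=10)
        b = traj.observable("freeB") + traj.observable("AB")
        assert b[0] == 0 and b[-1] == 30

    def test_csv_export_roundtrip(self, tmp_path):
        model = fixtures.build_toy("binding")
        traj = nf.run(model, t_end=5, sample_dt=1, seed=0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "AB", "freeA", "freeB"]
        assert (path.parent / "traj.csv.json").exists()
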