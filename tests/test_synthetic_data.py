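import itertools

import numpy as np
import pytest
from scipy import stats

from regland import scenarios as sc
from regland import synthetic_data as syn
from regland.library_design import MutagenesisConfig, decode, encode, mutate_promoter


@pytest.fixture
def window(window160):
    return window160


def make_matrix(window, start, length, penalty=2.0):
    return syn.EnergyMatrix.from_window(window, start, length, penalty)


class TestSiteEnergy:
    def test_wildtype_zero(self, window):
        m = make_matrix(window, -30, 10)
        sub = window.sequence[window.index(-30) : window.index(-30) + 10]
        assert syn.site_energy(m, sub) == 0.0

    def test_single_mutation_penalty(self, window):
        m = make_matrix(window, -30, 10, penalty=2.0)
        sub = list(window.sequence[window.index(-30) : window.index(-30) + 10])
        sub[3] = "ACGT"[(encode(sub[3])[0] + 1) % 4]
        assert syn.site_energy(m, "".join(sub)) == pytest.approx(2.0)

    def test_matches_per_position_loop(self, window):
        rng = np.random.default_rng(4)
        m = syn.EnergyMatrix(
            start=-20,
            energies=np.minimum(rng.normal(size=(5, 4)), 0.0)
            + np.maximum(rng.normal(size=(5, 4)), 0.0) * 0,
        )
        seq = decode(rng.integers(0, 4, size=5))
        expected = 0.0
        for i, base in enumerate(seq):  # independent per-position lookup oracle
            expected += m.energies[i, "ACGT".index(base)]
        assert syn.site_energy(m, seq) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self, window):
        m = make_matrix(window, -30, 10)
        with pytest.raises(ValueError):
            syn.site_energy(m, "ACGT")


def brute_force_rate(arch, variant, condition):
    """Independent exhaustive state-sum oracle over admissible occupancy states."""
    weights = []
    for s in arch.sites:
        i0 = arch.promoter.index(s.matrix.start)
        e = syn.site_energy(s.matrix, variant[i0 : i0 + len(s.matrix)])
        weights.append(s.base_weight * arch.activity(condition, s) * np.exp(-e))
    rnap_i = next(i for i, s in enumerate(arch.sites) if s.role == "RNAP")
    z = 0.0
    z_on = 0.0
    for occ in itertools.product([0, 1], repeat=len(arch.sites)):
        if occ[rnap_i] and any(
            occ[i] and arch.sites[i].excludes_rnap
            for i in range(len(arch.sites))
            if i != rnap_i
        ):
            continue
        w = 1.0
        for i, on in enumerate(occ):
            if on:
                w *= weights[i]
                if i != rnap_i and occ[rnap_i] and arch.sites[i].role == "activator":
                    w *= arch.sites[i].interaction_omega
        z += w
        if occ[rnap_i]:
            z_on += w
    return z_on / z


class TestExpressionRate:
    def test_rnap_only_half(self, window):
        m = syn.EnergyMatrix(start=-30, energies=np.zeros((10, 4)))
        arch = syn.ArchitectureSpec(
            promoter=window,
            sites=[syn.SiteSpec("rnap", "RNAP", m, base_weight=1.0)],
        )
        assert syn.expression_rate(arch, window.sequence, "c") == pytest.approx(0.5)

    def test_inactive_repressor_equals_rnap_only(self, window):
        arch = sc.repressor_architecture(window)
        rnap_only = syn.ArchitectureSpec(promoter=window, sites=[arch.rnap])
        r_off = syn.expression_rate(arch, window.sequence, "inactive")
        r_base = syn.expression_rate(rnap_only, window.sequence, "c")
        assert r_off == pytest.approx(r_base, rel=1e-12)

    def test_three_site_brute_force(self, window):
        rnap = syn.SiteSpec("rnap", "RNAP", make_matrix(window, -35, 20, 1.5), 0.05)
        rep = syn.SiteSpec("rep", "repressor", make_matrix(window, -80, 12, 2.0), 30.0)
        act = syn.SiteSpec(
            "act", "activator", make_matrix(window, -110, 10, 2.5), 3.0, interaction_omega=20.0
        )
        arch = syn.ArchitectureSpec(
            promoter=window,
            sites=[rnap, rep, act],
            condition_activity={"c": {"rep": 0.7, "act": 0.4}},
        )
        rng = np.random.default_rng(8)
        lib = mutate_promoter(window, MutagenesisConfig(n_variants=10, seed=8))
        for v in lib.variants:
            got = syn.expression_rate(arch, v, "c")
            assert got == pytest.approx(brute_force_rate(arch, v, "c"), rel=1e-10)

    def test_rates_in_unit_interval(self, window):
        arch = sc.repressor_architecture(window)
        lib = mutate_promoter(window, MutagenesisConfig(n_variants=200, seed=0))
        for cond in ("active", "inactive"):
            rates = syn.expression_rates(arch, lib.codes, cond)
            assert (rates >= 0).all() and (rates <= 1).all()

    def test_repressor_activity_monotone(self, window):
        """Increasing a repressor's active fraction never increases any rate."""
        lib = mutate_promoter(window, MutagenesisConfig(n_variants=50, seed=1))
        base = sc.repressor_architecture(window)
        prev = None
        for a in (0.0, 0.3, 0.7, 1.0):
            arch = syn.ArchitectureSpec(
                promoter=window,
                sites=base.sites,
                condition_activity={"c": {"rep1": a}},
            )
            rates = syn.expression_rates(arch, lib.codes, "c")
            if prev is not None:
                assert (rates <= prev + 1e-12).all()
            prev = rates

    def test_activator_omega_monotone(self, window):
        prev = None
        for omega in (1.0, 5.0, 50.0):
            arch = sc.activator_architecture(window, omega=omega)
            r = syn.expression_rate(arch, window.sequence, "active")
            if prev is not None:
                assert r >= prev - 1e-12
            prev = r

    def test_overlapping_sites_without_exclusion_error(self, window):
        rnap = syn.SiteSpec("rnap", "RNAP", make_matrix(window, -35, 20), 0.05)
        act = syn.SiteSpec("act", "activator", make_matrix(window, -40, 20), 1.0)
        with pytest.raises(ValueError, match="mutual-exclusion"):
            syn.ArchitectureSpec(promoter=window, sites=[rnap, act])

    def test_exactly_one_rnap_required(self, window):
        rep = syn.SiteSpec("rep", "repressor", make_matrix(window, -80, 10), 1.0)
        with pytest.raises(ValueError, match="RNAP"):
            syn.ArchitectureSpec(promoter=window, sites=[rep])


class TestSimulateCounts:
    @pytest.fixture
    def lib2(self, window):
        return mutate_promoter(window, MutagenesisConfig(n_variants=1, seed=0))

    def test_counts_sum_to_depth(self, window):
        lib = mutate_promoter(window, MutagenesisConfig(n_variants=100, seed=0))
        cfg = syn.SimulationConfig(depth_dna=5000, depth_rna=7000)
        t = syn.simulate_counts(lib, np.full(lib.n_variants, 0.5), cfg, seed=1)
        assert t.total_dna == 5000
        assert t.total_rna == 7000

    def test_zero_rate_zero_rna(self, lib2):
        cfg = syn.SimulationConfig(depth_dna=1000, depth_rna=1000)
        t = syn.simulate_counts(lib2, np.array([0.0, 0.9]), cfg, seed=2)
        assert t.rna[0] == 0

    def test_all_zero_rates_error(self, lib2):
        cfg = syn.SimulationConfig()
        with pytest.raises(ValueError, match="zero"):
            syn.simulate_counts(lib2, np.zeros(2), cfg, seed=0)

    def test_uniform_not_rejected(self, window):
        """Equal abundances/rates: chi-square GoF rejections over 20 seeded
        runs stay at the nominal alpha=0.01 level."""
        lib = mutate_promoter(window, MutagenesisConfig(n_variants=19, seed=0))
        cfg = syn.SimulationConfig(depth_dna=20000, depth_rna=20000, abundance_dispersion=0.0)
        rejected = 0
        for seed in range(20):
            t = syn.simulate_counts(lib, np.full(20, 0.5), cfg, seed=seed)
            p_dna = stats.chisquare(t.dna).pvalue
            p_rna = stats.chisquare(t.rna).pvalue
            rejected += (p_dna < 0.01) + (p_rna < 0.01)
        assert rejected <= 2

    def test_rna_share_matches_rates(self, lib2):
        cfg = syn.SimulationConfig(
            depth_dna=1000, depth_rna=1_000_000, abundance_dispersion=0.0
        )
        t = syn.simulate_counts(lib2, np.array([0.2, 0.8]), cfg, seed=3)
        share = t.rna[1] / t.total_rna
        se = np.sqrt(0.8 * 0.2 / 1_000_000)
        assert abs(share - 0.8) < 3 * se


class TestGenerateDataset:
    def test_bookkeeping(self, window):
        arch = sc.repressor_architecture(window)
        cfg = syn.SimulationConfig(depth_dna=10000, depth_rna=10000, n_replicates=2)
        ds = syn.generate_dataset(
            [arch], ["active", "inactive"], cfg, seed=0,
            mutagenesis=MutagenesisConfig(n_variants=100),
        )
        name = window.promoter_name
        assert set(ds.count_tables) == {
            (name, c, r) for c in ("active", "inactive") for r in (0, 1)
        }
        truth = ds.ground_truth["promoters"][name]["sites"]
        rep = next(s for s in truth if s["role"] == "repressor")
        assert (rep["start"], rep["end"]) == (-75, -60)

    def test_deterministic_outputs(self, tmp_path, window):
        arch = sc.repressor_architecture(window)
        cfg = syn.SimulationConfig(depth_dna=5000, depth_rna=5000, n_replicates=1)
        outs = []
        for d in ("a", "b"):
            ds = syn.generate_dataset(
                [arch], ["active"], cfg, seed=9,
                mutagenesis=MutagenesisConfig(n_variants=50),
            )
            outdir = tmp_path / d
            syn.write_dataset(ds, outdir)
            outs.append(sorted(p.read_bytes() for p in outdir.iterdir()))
        assert outs[0] == outs[1]

    def test_repressor_direction(self, simulated_repressor):
        """Heavily site-mutated variants out-express site-intact ones when
        the repressor is active (direction forced by the model)."""
        window, arch, library, table, _ = simulated_repressor
        site = slice(window.index(-75), window.index(-60))
        n_mut = library.masks[:, site].sum(axis=1)
        expr = (table.rna + 1) / (table.dna + 1)
        assert expr[n_mut >= 2].mean() > expr[n_mut == 0].mean()


def test_energy_matrix_validation():
    with pytest.raises(ValueError):
        syn.EnergyMatrix(start=0, energies=np.ones((5, 4)))  # no zero entry
    with pytest.raises(ValueError):
        syn.EnergyMatrix(start=0, energies=np.zeros((5, 3)))


def test_arch_from_config_roundtrip(window):
    doc = {
        "promoter": {"promoter_name": "p1", "sequence": window.sequence},
        "sites": [
            {"name": "rnap", "role": "RNAP", "start": -35, "length": 30,
             "base_weight": 0.05, "mismatch_penalty": 1.5},
            {"name": "rep1", "role": "repressor", "start": -75, "length": 15,
             "base_weight": 50.0},
        ],
        "condition_activity": {"A": {"rep1": 1.0}, "B": {"rep1": 0.0}},
    }
    arch = syn.arch_from_config(doc)
    assert arch.promoter.promoter_name == "p1"
    assert arch.rnap.base_weight == 0.05
    assert arch.activity("B", arch.sites[1]) == 0.0
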