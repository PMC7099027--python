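"""Forward-simulator tests: conservation, determinism, design arithmetic."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from strawtrace import (
    FRACTION_POOLS,
    SimulationConfig,
    excess_13c_added,
    generate_dataset,
    simulate_community,
    simulate_pools,
)


class TestConfigValidation:
    def test_alloc_curves_must_sum_to_one(self):
        bad = {
            "DOC": (0.5,), "MBC": (0.2,), "POC": (0.2,), "MaOC": (0.2,),
            "CO2": (0.2,),
        }
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(alloc_knot_days=(0.0,), alloc_curves=bad)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_delta_sd=-0.1)

    def test_coupled_cannot_exceed_taxa(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_taxa=5, n_coupled=6)


class TestMassConservation:
    def test_straw_c_fully_accounted(self, noisefree_cfg):
        """At every day the sinks plus residual straw sum to the input."""
        from strawtrace.simulate import _integrate
        states = _integrate(noisefree_cfg)
        sw = states.pivot(index="day", columns="pool", values="straw_c")
        total = noisefree_cfg.straw.c_added_mg_per_kg
        balance = (sw[list(FRACTION_POOLS)].sum(axis=1) + sw["CO2"]
                   + sw["straw_remaining"])
        assert np.allclose(balance, total, rtol=1e-9)
        assert (sw["CO2"] >= -1e-9 * total).all()

    def test_excess_13c_conserved(self, noisefree_cfg):
        """Straw-derived ¹³C across sinks equals the excess added, pre-noise."""
        from strawtrace.simulate import _integrate
        from strawtrace.isotope import delta_to_atom_fraction
        cfg = noisefree_cfg
        states = _integrate(cfg)
        sw = states.pivot(index="day", columns="pool", values="straw_c")
        a_m = delta_to_atom_fraction(cfg.amendment["delta"])
        a_s = delta_to_atom_fraction(cfg.soil_delta)
        excess = (sw[list(FRACTION_POOLS)].sum(axis=1) + sw["CO2"]) * (a_m - a_s)
        expected = (excess_13c_added(cfg.straw, cfg.end_members)
                    * (1 - sw["straw_remaining"] / cfg.straw.c_added_mg_per_kg))
        assert np.allclose(excess, expected, rtol=1e-9)

    def test_unlabelled_straw_leaves_deltas_at_baseline(self, noisefree_cfg):
        cfg = dataclasses.replace(
            noisefree_cfg,
            amendment={**noisefree_cfg.amendment, "delta": -27.78})
        m, _ = simulate_pools(cfg)
        am = m[m["treatment"] == "amended"]["delta13c_permil"]
        ct = m[m["treatment"] == "control"]["delta13c_permil"]
        assert np.allclose(am, cfg.soil_delta, atol=1e-9)
        assert np.allclose(ct, cfg.soil_delta, atol=1e-9)


class TestDeterminismAndDesign:
    def test_fixed_seed_reproducible(self, fast_cfg):
        m1, t1 = simulate_pools(fast_cfg)
        m2, t2 = simulate_pools(fast_cfg)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1.pools, t2.pools)
        c1, _ = simulate_community(fast_cfg, t1)
        c2, _ = simulate_community(fast_cfg, t2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_different_seed_differs(self, fast_cfg):
        m1, _ = simulate_pools(fast_cfg)
        m2, _ = simulate_pools(fast_cfg.with_seed(fast_cfg.seed + 1))
        assert not np.allclose(m1["c_content_mg_per_kg"],
                               m2["c_content_mg_per_kg"])

    @pytest.mark.parametrize("schedule, expected", [
        ((7, 14, 28, 60, 180), 150),  # 2 treatments × 5 days × 3 reps × 5 pools
        ((7, 60), 60),
    ])
    def test_record_count(self, schedule, expected):
        cfg = SimulationConfig(schedule=schedule)
        m, _ = simulate_pools(cfg)
        assert len(m) == expected

    def test_increasing_decay_increases_decomposition(self):
        """More straw leaves the straw pool at any day when k rises."""
        base = SimulationConfig()
        faster = dataclasses.replace(base, k_decay=base.k_decay * 2,
                                     k_decay_slow=base.k_decay_slow * 2)
        from strawtrace.simulate import _integrate
        rem_a = _integrate(base).pivot(index="day", columns="pool",
                                       values="straw_c")["straw_remaining"]
        rem_b = _integrate(faster).pivot(index="day", columns="pool",
                                         values="straw_c")["straw_remaining"]
        assert (rem_b <= rem_a + 1e-12).all()
        assert (rem_b < rem_a).any()


class TestNoisePropagation:
    def test_estimate_spread_monotone_in_noise(self, default_cfg):
        """Replicate spread of allocation estimates grows with measurement
        noise."""
        from strawtrace import partition_table

        def pooled_sd(noise_scale, seeds=range(6)):
            sds = []
            for s in seeds:
                cfg = dataclasses.replace(
                    default_cfg.with_seed(500 + s),
                    noise_delta_sd=0.3 * noise_scale,
                    noise_c_rel_sd=0.05 * noise_scale)
                m, _ = simulate_pools(cfg)
                res = partition_table(m, cfg.straw, cfg.end_members)
                a = res.allocation
                sds.append(a[a["pool"].isin(FRACTION_POOLS)]["sd"].mean())
            return np.mean(sds)

        assert pooled_sd(0.5) < pooled_sd(2.0)


class TestCommunity:
    def test_counts_shape_and_metadata(self, fast_cfg):
        _, truth = simulate_pools(fast_cfg)
        counts, meta = simulate_community(fast_cfg, truth)
        n_samples = 2 * len(fast_cfg.schedule) * fast_cfg.n_rep
        assert counts.shape == (fast_cfg.n_taxa, n_samples)
        assert len(meta) == n_samples
        assert (counts.to_numpy() >= 0).all()
        assert counts.to_numpy().dtype.kind == "i"

    def test_uncoupled_taxa_ignore_the_carbon_trajectory(self, default_cfg):
        """With coupling off, amended and control arms are exchangeable."""
        cfg = dataclasses.replace(default_cfg, n_coupled=0)
        _, truth = simulate_pools(cfg)
        counts, meta = simulate_community(cfg, truth)
        rel = counts / counts.sum(axis=0)
        am = rel[meta[meta["treatment"] == "amended"]["sample"]].mean(axis=1)
        ct = rel[meta[meta["treatment"] == "control"]["sample"]].mean(axis=1)
        # mean relative abundances agree within overdispersed sampling noise
        assert np.corrcoef(am, ct)[0, 1] > 0.9

    def test_coupled_taxon_tracks_its_pool(self, default_cfg):
        _, truth = simulate_pools(default_cfg)
        counts, meta = simulate_community(default_cfg, truth)
        taxa = truth.taxa
        coupled = taxa[taxa["coupling"] > 0].iloc[0]
        pool_c = truth.pools.set_index(["day", "pool"])["straw_c"]
        am = meta[meta["treatment"] == "amended"]
        x = [pool_c[(d, coupled["coupled_pool"])] for d in am["day"]]
        y = counts.loc[coupled["taxon"], am["sample"]].to_numpy()
        from scipy.stats import spearmanr
        rho, _ = spearmanr(x, y)
        assert rho > 0.6


class TestGenerateDataset:
    def test_writes_four_files_and_reruns_identically(self, fast_cfg, tmp_path):
        paths = generate_dataset(fast_cfg, tmp_path / "a")
        assert set(paths) == {"pools", "taxa", "metadata", "ground_truth"}
        blobs = {k: p.read_bytes() for k, p in paths.items()}
        paths2 = generate_dataset(fast_cfg, tmp_path / "b")
        for k, p in paths2.items():
            assert p.read_bytes() == blobs[k]

    def test_pool_file_row_count(self, tmp_path):
        cfg = SimulationConfig(schedule=(7, 14, 28, 60, 180))
        paths = generate_dataset(cfg, tmp_path)
        df = pd.read_csv(paths["pools"], sep="\t", comment="#")
        assert len(df) == 150
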