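"""The generator must reproduce the field design and its declared truth."""

import numpy as np
import pandas as pd
import pytest

from ramets import allometry
from ramets.simulate import (
    SimulationConfig,
    null_scenario,
    scenario_field_effects,
    simulate_dataset,
)


class TestDesignStructure:
    def test_default_layout_counts(self, field_like_df):
        df = field_like_df
        # 10 blocks x 4 transects x 5 ramets, 3 years x 3 censuses
        assert df["ramet_id"].nunique() == 200
        assert len(df) == 200 * 9
        assert df.groupby("ramet_id").size().eq(9).all()
        per_block = df.drop_duplicates("transect_id").groupby("block_id")["treatment"]
        assert per_block.apply(lambda s: (s == "meja").sum()).eq(2).all()

    def test_distance_classes_per_transect(self, field_like_df):
        per_tr = field_like_df.drop_duplicates(["transect_id", "ramet_id"])
        assert (
            per_tr.groupby("transect_id")["distance_class"]
            .apply(lambda s: sorted(s) == [0, 1, 2, 3, 4])
            .all()
        )

    def test_seeded_determinism(self):
        df1, t1 = simulate_dataset(scenario_field_effects(seed=99, n_blocks=3))
        df2, t2 = simulate_dataset(scenario_field_effects(seed=99, n_blocks=3))
        pd.testing.assert_frame_equal(df1, df2)
        assert t1.alpha == t2.alpha
        df3, _ = simulate_dataset(scenario_field_effects(seed=100, n_blocks=3))
        assert not df1.equals(df3)

    def test_mortality_monotone_across_years(self, field_like_df):
        alive = field_like_df.groupby("year")["alive"].sum()
        assert alive.loc[1] >= alive.loc[2] >= alive.loc[3]
        assert alive.loc[3] < alive.loc[1]  # hazard > 0 actually kills some

    def test_berry_invariant_and_reproduction_timing(self, field_like_df):
        df = field_like_df
        y1c1 = df[(df["year"] == 1) & (df["census"] == 1)]
        assert y1c1["n_berries"].isna().all()
        live_last = df[(df["census"] == 3) & df["alive"].astype(bool)]
        assert live_last["n_flowers"].notna().all()
        assert df[df["census"] == 1]["n_flowers"].isna().all()

    def test_backsolved_sizes_match_allometry_domain(self, field_like_df):
        live = field_like_df[field_like_df["alive"].astype(bool)]
        log2dm = allometry.log2_dry_mass(
            live["stem_diameter_mm"].to_numpy(dtype=float),
            live["height_cm"].to_numpy(dtype=float),
            live["n_shoots"].to_numpy(dtype=float),
        )
        assert np.all(np.isfinite(log2dm))
        h = live["height_cm"]
        assert h.between(10, 25).all()  # marked ramets were 10-25 cm tall


class TestDispersionOracle:
    def test_poisson_dispersion_unity_without_extra_variance(self):
        """With sigma_u = sigma_eps = 0, psi = 1 and no mortality, browsing
        counts within a group-year-census slice are iid Poisson, so the
        variance/mean dispersion index must average 1."""
        cfg = null_scenario(seed=5, n_blocks=40, mortality_hazard=0.0)
        cfg.variance["browsed_shoots"] = [0.0, 0.0, 1.0, None]
        df, _ = simulate_dataset(cfg)
        meja = df[df["treatment"] == "meja"]
        idx = []
        for _, g in meja.groupby(["distance_class", "year", "census"]):
            x = g["n_browsed_shoots"].astype(float)
            if x.mean() > 0:
                idx.append(x.var(ddof=1) / x.mean())
        assert len(idx) >= 40
        assert np.mean(idx) == pytest.approx(1.0, abs=0.08)

    def test_overdispersion_raises_index(self):
        cfg = null_scenario(seed=5, n_blocks=40, mortality_hazard=0.0)
        cfg.variance["browsed_shoots"] = [0.0, 0.8, 1.0, None]
        df, _ = simulate_dataset(cfg)
        meja = df[df["treatment"] == "meja"]
        idx = [
            g["n_browsed_shoots"].astype(float).var(ddof=1)
            / g["n_browsed_shoots"].astype(float).mean()
            for _, g in meja.groupby(["distance_class", "year", "census"])
        ]
        assert np.mean(idx) > 1.3


class TestScenarios:
    def test_field_like_sign_pattern_in_truth(self, field_like_truth):
        t = field_like_truth
        grazed_y = {y: t.true_contrast("grazed_ratio", "meja_d0", y) for y in (1, 2, 3)}
        assert grazed_y[2] == min(grazed_y.values()) and grazed_y[2] < 0
        browsed_y = {y: t.true_contrast("browsed_shoots", "meja_d0", y) for y in (1, 2, 3)}
        assert browsed_y[3] == min(browsed_y.values()) and browsed_y[3] < 0
        assert t.true_contrast("flowers", "meja_d0", 3) > 0
        assert t.true_contrast("berries", "meja_d0", 3) > 0

    def test_neighbor_effects_decay_with_distance(self, field_like_truth):
        t = field_like_truth
        for resp in ("grazed_ratio", "browsed_shoots", "flowers"):
            for yr in (1, 2, 3):
                mags = [abs(t.true_contrast(resp, f"meja_d{d}", yr)) for d in range(1, 5)]
                assert all(a >= b for a, b in zip(mags, mags[1:]))

    def test_null_scenario_truth_is_flat(self):
        _, t = simulate_dataset(null_scenario(seed=1, n_blocks=2))
        for resp in t.alpha:
            for g in ("meja_d0", "meja_d3"):
                for yr in (1, 2, 3):
                    assert t.true_contrast(resp, g, yr) == 0.0
                    assert t.true_contrast(resp, g, yr, "slope") == 0.0

    def test_truth_serializes_to_json(self, tmp_path, field_like_truth):
        import json

        path = tmp_path / "truth.json"
        field_like_truth.to_json(path)
        d = json.loads(path.read_text())
        assert d["alpha"]["grazed_ratio"]["control:1"] == pytest.approx(-2.0)
        frame = field_like_truth.to_frame()
        assert {"response", "group", "year", "alpha", "beta"} <= set(frame.columns)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(mortality_hazard=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_blocks=0)
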