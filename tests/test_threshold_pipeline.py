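import numpy as np
import pandas as pd
import pytest

from cortistim.cable_solver import PulseSpec, simulate_batch
from cortistim.errors import ParameterError
from cortistim.threshold_pipeline import (
    CampaignConfig,
    build_neuron_batch,
    excitation_threshold,
    run_campaign,
    search_thresholds,
)

# wm_margin must accommodate the ~8 mm L5 axon below the deepest soma
SMALL_GEOMETRY = dict(sulcal_depth=10.0, crown_to_crown_path_length=40.0,
                      extrusion_length_z=20.0, x_half_extent=16.0,
                      wm_margin=11.0)


@pytest.fixture(scope="module")
def small_config():
    return CampaignConfig(geometry_params=dict(SMALL_GEOMETRY),
                          polarities=("anodal", "cathodal"),
                          mesh_resolution_mm=1.5, duration_ms=2.0)


@pytest.fixture(scope="module")
def small_records(small_config):
    return run_campaign(small_config)


class TestCampaign:
    def test_complete_records(self, small_config, small_records):
        df = small_records
        for layer in small_config.layers:
            for pol in small_config.polarities:
                g = df[(df["layer"] == layer) & (df["polarity"] == pol)]
                assert len(g) > 0
                assert g["neuron"].is_unique

    def test_thresholds_within_cap(self, small_records):
        thr = small_records.loc[small_records["excitable"], "threshold_ma"]
        assert (thr > 0).all()
        assert (thr <= 100.0).all()

    def test_initiation_fields_only_when_excitable(self, small_records):
        not_exc = small_records[~small_records["excitable"]]
        assert (not_exc["init_category"] == "").all()
        assert (not_exc["init_compartment"] == -1).all()

    def test_polarity_subset(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, polarities=("anodal",),
                                  layers=("L3",), duration_ms=1.5)
        df = run_campaign(cfg)
        assert set(df["polarity"]) == {"anodal"}

    def test_bad_polarity_rejected(self):
        with pytest.raises(ParameterError):
            CampaignConfig(polarities=("sideways",))


class TestDeterminism:
    def test_same_config_same_records(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, polarities=("anodal",),
                                  layers=("L3",), duration_ms=1.5)
        df1 = run_campaign(cfg)
        df2 = run_campaign(cfg)
        pd.testing.assert_frame_equal(df1, df2)

    def test_resumable_checkpoints(self, small_config, tmp_path):
        import dataclasses

        cfg = dataclasses.replace(small_config, polarities=("anodal",),
                                  layers=("L3",), duration_ms=1.5)
        out = tmp_path / "records.csv"
        df1 = run_campaign(cfg, out_path=str(out))
        assert out.exists()
        df2 = run_campaign(cfg, out_path=str(out))  # resumes, skips group
        assert len(df2) == len(df1)


@pytest.fixture(scope="module")
def batch_and_phi(small_config):
    from cortistim.conductivity_model import build_conductivity
    from cortistim.placement import distribute_neurons
    from cortistim.scenario_geometry import generate_mesh
    from cortistim.volume_conductor import StimulusDrive, VolumeConductor

    geom = small_config.build_geometry()
    mesh = generate_mesh(geom, small_config.mesh_resolution_mm)
    cond = build_conductivity(geom, mesh, "anisotropic")
    vc = VolumeConductor(mesh, cond)
    field = vc.solve(StimulusDrive("anodal"))
    z0 = geom.active_electrode.center_z
    pset = distribute_neurons(geom, "L3", planes=np.array([z0]))
    batch = build_neuron_batch(geom, pset)
    phi = field.sample(batch.centers.reshape(-1, 3)).reshape(pset.n, -1)
    return geom, vc, batch, phi


class TestBisection:
    def test_bracket_verified_by_direct_simulation(self, batch_and_phi):
        geom, _, batch, phi = batch_and_phi
        pulse = PulseSpec()
        thr, exc, _ = search_thresholds(batch.model, phi, pulse, 100.0, 1.0,
                                        5.0, 2.0)
        i = int(np.nanargmin(thr))
        record = excitation_threshold(batch, i, phi[i], pulse,
                                      resolution_ma=1.0, duration_ms=2.0,
                                      gm_thickness=geom.params.gm_thickness)
        assert record["excitable"]
        # the returned amplitude fires and (amplitude - resolution) does not
        at = simulate_batch(batch.model, phi[[i]],
                            np.array([record["threshold_ma"]]), pulse,
                            duration_ms=2.0)
        below = simulate_batch(batch.model, phi[[i]],
                               np.array([record["threshold_ma"] - 1.0]),
                               pulse, duration_ms=2.0)
        assert at.fired[0]
        assert not below.fired[0]

    def test_not_excitable_record(self, batch_and_phi):
        _, _, batch, phi = batch_and_phi
        pulse = PulseSpec()
        thr, exc, _ = search_thresholds(batch.model, 1e-6 * phi, pulse,
                                        100.0, 1.0, 5.0, 1.0)
        assert not exc.any()
        assert np.isnan(thr).all()

    def test_unit_field_scaling_matches_resolved_fields(self, batch_and_phi):
        """Dual route: scaling one unit solve vs re-solving per amplitude."""
        from cortistim.volume_conductor import StimulusDrive

        geom, vc, batch, phi = batch_and_phi
        pulse = PulseSpec()
        thr, exc, _ = search_thresholds(batch.model, phi, pulse, 100.0, 1.0,
                                        5.0, 2.0)
        i = int(np.nanargmin(thr))
        amp = float(thr[i])
        for trial, expect_fire in ((amp, True), (amp - 1.0, False)):
            field = vc.solve(StimulusDrive("anodal", amplitude=trial))
            phi_resolved = field.sample(batch.centers[i])
            res = simulate_batch(batch.model, phi_resolved[None, :],
                                 np.array([1.0]), pulse, duration_ms=2.0)
            assert bool(res.fired[0]) == expect_fire


class TestCampaignOrderings:
    def test_anodal_min_below_cathodal_min(self, small_records):
        exc = small_records[small_records["excitable"]]
        mins = exc.groupby("polarity")["threshold_ma"].min()
        assert mins["anodal"] < mins["cathodal"]


class TestSensitivityWorkflow:
    def test_position_shift_comparison(self, small_config):
        """End-to-end +1 mm normal-shift arm vs baseline (Discussion-style)."""
        import dataclasses

        from cortistim.analysis_report import compare_sensitivity
        from cortistim.placement import distribute_neurons, perturb_positions

        cfg = dataclasses.replace(small_config, polarities=("anodal",),
                                  layers=("L3",), duration_ms=1.5)
        geom = cfg.build_geometry()
        z0 = geom.active_electrode.center_z
        base = distribute_neurons(geom, "L3", planes=np.array([z0]))
        # downward: L3 somata sit 0.7 mm below the pia, an upward 1 mm
        # shift would leave the gray matter entirely
        shifted = perturb_positions(base, geom, 1.0, "down")
        df_base = run_campaign(cfg, geometry=geom,
                               placements={"L3": base})
        df_shift = run_campaign(cfg, geometry=geom,
                                placements={"L3": shifted})
        report = compare_sensitivity(df_base, df_shift)
        assert report.n_compared > 0
        assert np.isfinite(report.mean_percent)
        assert report.max_percent >= report.mean_percent >= 0.0
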