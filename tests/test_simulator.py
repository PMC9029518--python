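"""Staged-addition precipitation simulator: conservation laws, mechanism
monotonicities, determinism, and study-grid bookkeeping."""

import math

import numpy as np
import pytest

from nanoprecip import datasets
from nanoprecip.simulator import (
    ConfigError,
    ParticlePopulation,
    SimConfig,
    run_precipitation,
    simulate_protocol,
    simulate_study,
    study_grid,
)


@pytest.fixture(scope="module")
def ami_config(compounds, protocols_by_variant):
    return SimConfig(
        compound=compounds["AMI"], protocol=protocols_by_variant["AMIa"][0],
        label="AMIa", seed=11,
    )


class TestConservation:
    def test_solute_mass_conserved_at_every_portion(self, ami_config):
        for _, audit in run_precipitation(ami_config):
            total = audit.dissolved_moles + audit.particulate_moles
            assert total == pytest.approx(audit.added_moles, rel=1e-9)

    def test_aggregation_conserves_volume_and_decreases_count(self, ami_config):
        merged = 0
        for _, audit in run_precipitation(ami_config):
            assert audit.volume_after_aggregation == pytest.approx(
                audit.volume_before_aggregation, rel=1e-9
            )
            assert audit.count_after_aggregation <= audit.count_before_aggregation
            merged += audit.count_after_aggregation < audit.count_before_aggregation
        assert merged > 0  # aggregation actually happened

    def test_population_consolidation_conserves_count_and_volume(self):
        rng = np.random.default_rng(0)
        pop = ParticlePopulation(
            diameters=rng.uniform(1e-9, 1e-7, 200), counts=rng.uniform(1e10, 1e14, 200)
        )
        n0, v0 = pop.total_number, pop.particulate_volume
        pop.consolidate(max_bins=32)
        assert pop.diameters.size <= 32
        assert pop.total_number == pytest.approx(n0, rel=1e-12)
        assert pop.particulate_volume == pytest.approx(v0, rel=1e-9)


class TestMechanisms:
    def quiet(self, compounds, protocols_by_variant, variant="AMIa", protocol=0, **kw):
        design = datasets.load_study_design()
        name = design[variant]["compound"]
        base = dict(
            compound=compounds[name], protocol=protocols_by_variant[variant][protocol],
            label=variant, noise_sigma=0.0, mixing_uniformity=1.0, seed=5,
        )
        base.update(kw)
        return SimConfig(**base)

    def test_final_size_increases_with_interfacial_tension(self, compounds, protocols_by_variant):
        finals = [
            simulate_protocol(
                self.quiet(compounds, protocols_by_variant, gamma_logp_intercept=g)
            )[-1].dh_nm
            for g in (0.003, 0.004, 0.005)
        ]
        assert finals[0] < finals[1] < finals[2]

    def test_beta_before_nucleation_increases_with_c0_solvent(self, compounds, protocols_by_variant):
        import dataclasses

        cfg_lo = self.quiet(compounds, protocols_by_variant)
        proto_hi = dataclasses.replace(cfg_lo.protocol, c0_solvent=cfg_lo.protocol.c0_solvent * 2)
        cfg_hi = self.quiet(compounds, protocols_by_variant)
        cfg_hi.protocol = proto_hi
        betas_lo = [a.beta_before_nucleation for _, a in run_precipitation(cfg_lo)]
        betas_hi = [a.beta_before_nucleation for _, a in run_precipitation(cfg_hi)]
        assert all(h > l for h, l in zip(betas_hi, betas_lo))

    def test_sas_ratio_controls_cosolvency_contribution(self, compounds, protocols_by_variant):
        from nanoprecip.process import c0_trajectory

        ami = compounds["AMI"]
        p20 = protocols_by_variant["AMIa"][0]  # No. 1, 1:20
        p10 = protocols_by_variant["AMIa"][4]  # No. 5, 1:10
        phi20 = c0_trajectory(p20, ami, 5.0)[-1].solvent_fraction
        phi10 = c0_trajectory(p10, ami, 5.0)[-1].solvent_fraction
        assert phi20 < phi10  # more antisolvent -> lower phi -> lower C* boost
        cs20 = c0_trajectory(p20, ami, 5.0)[-1].c_star
        cs10 = c0_trajectory(p10, ami, 5.0)[-1].c_star
        assert cs20 < cs10

    def test_dh_series_rises_with_cumulative_concentration(self, compounds, protocols_by_variant):
        for variant in ("AMIa", "CUR", "NOR"):
            records = simulate_protocol(self.quiet(compounds, protocols_by_variant, variant=variant))
            dh = [r.dh_nm for r in records]
            assert all(b >= a for a, b in zip(dh, dh[1:]))

    def test_ripening_flag_coarsens_final_size(self, compounds, protocols_by_variant):
        plain = simulate_protocol(self.quiet(compounds, protocols_by_variant))[-1].dh_nm
        ripened = simulate_protocol(
            self.quiet(compounds, protocols_by_variant, ripening=True)
        )[-1].dh_nm
        assert ripened >= plain


class TestContractsAndGrid:
    def test_seed_determinism(self, ami_config):
        a = [r.dh_nm for r in simulate_protocol(ami_config)]
        b = [r.dh_nm for r in simulate_protocol(ami_config)]
        assert a == b

    def test_one_record_per_portion(self, ami_config):
        records = simulate_protocol(ami_config)
        assert len(records) == ami_config.protocol.n_portions
        assert all(r.dh_nm > 0 for r in records)

    def test_nonpositive_gamma_mapping_rejected(self, compounds, protocols_by_variant):
        with pytest.raises(ConfigError):
            SimConfig(
                compound=compounds["CUR"], protocol=protocols_by_variant["CUR"][0],
                gamma_logp_intercept=0.0, gamma_logp_slope=-0.01,
            )

    def test_duplicate_keys_rejected(self, ami_config):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_study([ami_config, ami_config])

    def test_grid_covers_thirty_series(self, compounds):
        frame = simulate_study(study_grid(seed=2, compounds=compounds))
        assert frame.groupby(["compound", "protocol"]).ngroups == 30
        assert set(frame["compound"]) == {"AMIa", "AMIb", "COU", "CUR", "NOR", "PRO"}
        assert frame.groupby(["compound", "protocol"]).size().eq(10).all()

    def test_simulated_average_final_size_tracks_lipophilicity(self, compounds, variant_map):
        """With a positive logP->gamma slope the compound-level mean final
        size regresses positively on (logP)av (the Fig-6c-style readout)."""
        from nanoprecip.analysis import trend_report

        frame = simulate_study(study_grid(seed=4, compounds=compounds))
        report = trend_report(frame, compounds, variant_map=variant_map)
        assert report.fit is not None and report.fit.slope > 0
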