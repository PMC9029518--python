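"""Size analysis: DHf extraction, averaging, the OLS fit against an
independent normal-equations oracle, and the study-level trend report."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nanoprecip import datasets
from nanoprecip.analysis import (
    dhf_average,
    extract_dhf,
    fit_size_vs_logp,
    trend_report,
)
from nanoprecip.compounds import logp_average
from nanoprecip.simulator import DLSRecord


def ols_oracle(x, y):
    """Brute-force least squares via normal equations in extended precision."""
    x = np.asarray(x, dtype=np.longdouble)
    y = np.asarray(y, dtype=np.longdouble)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    coef = np.array([slope, intercept], dtype=np.longdouble)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return float(coef[0]), float(coef[1]), 1.0 - ss_res / ss_tot


def series(values, c0s=None):
    c0s = c0s if c0s is not None else range(1, len(values) + 1)
    return [
        DLSRecord(c0=c * 1e-3, dh_nm=v, protocol_id="No. 1", compound_name="X")
        for c, v in zip(c0s, values)
    ]


class TestExtractDhf:
    def test_single_record(self):
        assert extract_dhf(series([150.0])) == 150.0

    def test_rising_series_returns_last(self):
        rising = series([216, 240, 255, 270, 280, 290, 298, 305, 310, 313])
        assert extract_dhf(rising) == 313

    def test_order_invariance(self):
        recs = series([100, 150, 120, 180], c0s=[1, 4, 2, 3])
        for perm in ([0, 1, 2, 3], [3, 2, 1, 0], [1, 3, 0, 2]):
            assert extract_dhf([recs[i] for i in perm]) == 150  # max c0 = 4


    def test_c0_tie_broken_by_last_record(self):
        recs = series([100, 200], c0s=[5, 5])
        assert extract_dhf(recs) == 200

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            extract_dhf([])


class TestDhfAverage:
    def test_mean_and_pooling_cardinality(self):
        assert dhf_average([100, 200]) == 150
        pooled = dhf_average([313, 369, 301, 361, 254, 284, 513, 745, 265, 582])
        assert pooled == pytest.approx(398.7)

    def test_measured_upper_bound_proxy_for_cur(self):
        assert dhf_average([152, 159, 168, 157, 168]) == pytest.approx(160.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dhf_average([])


class TestFit:
    def test_collinear_points_give_unit_r_squared(self):
        fit = fit_size_vs_logp([(1, 10), (2, 20), (3, 30)])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(10.0)

    def test_constant_x_degenerate(self):
        with pytest.raises(ValueError):
            fit_size_vs_logp([(2, 10), (2, 20), (2, 30)])
        with pytest.raises(ValueError):
            fit_size_vs_logp([(1, 10), (2, 20)])

    def test_measured_upper_bound_proxy_fit_is_positive(self, compounds):
        """Protocol-table upper bounds as DHf proxies give a clearly
        positive size-vs-logP slope (R^2 ~ 0.92 on this proxy)."""
        ranges = datasets.load_dh_ranges()
        vmap = datasets.variant_compound_map()
        pooled = {}
        for _, row in ranges.iterrows():
            pooled.setdefault(vmap[row["variant"]], []).append(row["dh_max_nm"])
        points = [
            (logp_average(compounds[name]), dhf_average(vals))
            for name, vals in pooled.items()
        ]
        fit = fit_size_vs_logp(points)
        assert fit.slope > 0
        assert fit.r_squared == pytest.approx(0.9167, abs=5e-3)

    @given(
        seed=st.integers(0, 1000),
        n=st.integers(3, 12),
    )
    def test_fit_matches_normal_equations_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 6, n)
        if np.ptp(x) < 1e-6:
            return
        y = 50 * x + rng.normal(0, 20, n)
        fit = fit_size_vs_logp(list(zip(x, y)))
        slope, intercept, r2 = ols_oracle(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-10, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-8, abs=1e-10)

    @given(
        ax=st.floats(0.1, 10), bx=st.floats(-5, 5),
        ay=st.floats(0.1, 10), by=st.floats(-100, 100),
    )
    def test_r_squared_invariant_under_affine_rescaling(self, ax, bx, ay, by):
        x = np.array([1.0, 2.0, 3.5, 4.0, 5.5])
        y = np.array([120.0, 180.0, 210.0, 340.0, 330.0])
        base = fit_size_vs_logp(list(zip(x, y)))
        scaled = fit_size_vs_logp(list(zip(ax * x + bx, ay * y + by)))
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-9)


@pytest.fixture(scope="module")
def proxy_study():
    """Table-shaped fixture: each (variant, protocol) series ends at the
    measured upper-bound DH, rising from the lower bound."""
    ranges = datasets.load_dh_ranges()
    rows = []
    for _, row in ranges.iterrows():
        for portion in range(1, 11):
            frac = portion / 10
            rows.append(
                {
                    "compound": row["variant"],
                    "protocol": row["protocol"],
                    "portion": portion,
                    "c0_mM": portion * 0.1,
                    "dh_nm": row["dh_min_nm"] + frac * (row["dh_max_nm"] - row["dh_min_nm"]),
                    "replicate": 1,
                }
            )
    return pd.DataFrame(rows)


class TestTrendReport:
    def test_six_variant_dhf_table_and_pooled_averages(self, proxy_study, compounds, variant_map):
        report = trend_report(proxy_study, compounds, variant_map=variant_map)
        assert report.dhf_table.groupby("compound").size().to_dict() == {
            v: 5 for v in ("AMIa", "AMIb", "COU", "CUR", "NOR", "PRO")
        }
        assert report.dhf_av["CUR"] == pytest.approx(160.8)
        assert report.dhf_av["AMI"] == pytest.approx(398.7)  # ten pooled values
        assert report.fit is not None and report.fit.slope > 0

    def test_contrast_table_isolates_design_factors(self, proxy_study, compounds, variant_map):
        report = trend_report(proxy_study, compounds, variant_map=variant_map)
        effects = set(report.contrasts["effect"])
        assert effects == {"flow_rate", "c0_solvent", "sas_ratio", "antisolvent_ph"}
        ph_rows = report.contrasts[report.contrasts["effect"] == "antisolvent_ph"]
        assert len(ph_rows) == 5  # AMIa vs AMIb per protocol
        flow = report.contrasts.query("effect == 'flow_rate' and compound == 'AMIb'")
        # measured proxies: DHf(No. 3) - DHf(No. 1) = 745 - 284
        assert flow["delta_dhf_nm"].iloc[0] == pytest.approx(461.0)

    def test_single_compound_input_no_global_fit(self, proxy_study, compounds):
        sub = proxy_study[proxy_study["compound"] == "CUR"]
        report = trend_report(sub, compounds)
        assert report.fit is None
        assert list(report.dhf_av) == ["CUR"]

    def test_missing_protocols_drop_contrasts_silently(self, proxy_study, compounds, variant_map):
        sub = proxy_study[proxy_study["protocol"].isin(["No. 1", "No. 3"])]
        report = trend_report(sub, compounds, variant_map=variant_map)
        assert set(report.contrasts["effect"]) >= {"flow_rate"}
        assert "c0_solvent" not in set(
            report.contrasts.query("protocols == 'No. 5 - No. 2'")["effect"]
        )

    def test_missing_columns_rejected(self, compounds):
        with pytest.raises(ValueError, match="lacks columns"):
            trend_report(pd.DataFrame({"compound": [], "protocol": []}), compounds)
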