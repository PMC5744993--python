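"""Network assembly: pathway totals, P_app, route classification."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import monoperm as mp

finite_r = st.floats(1.0, 1e9)


def breakdown(**kw):
    defaults = dict(
        r_uwl=2.5e4, r_filter=770.0, r_cytosol=600.0,
        r_m_apical=100.0, r_m_basal=2400.0, r_para=3.7e5, r_lateral=1.6e4,
    )
    defaults.update(kw)
    return mp.pathway_totals(**defaults)


class TestPathwayTotals:
    @given(finite_r, finite_r, finite_r, finite_r, finite_r, finite_r, finite_r)
    def test_totals_are_exact_serial_sums(self, u, f, c, ma, mb, p, l):
        bd = mp.pathway_totals(
            r_uwl=u, r_filter=f, r_cytosol=c, r_m_apical=ma,
            r_m_basal=mb, r_para=p, r_lateral=l,
        )
        assert bd.r_para_total == pytest.approx(u + p + f, rel=1e-12)
        assert bd.r_lateral_total == pytest.approx(u + l + f, rel=1e-12)
        assert bd.r_cytosol_total == pytest.approx(u + ma + c + mb + f, rel=1e-12)
        assert bd.p_app == pytest.approx(
            1 / bd.r_para_total + 1 / bd.r_lateral_total + 1 / bd.r_cytosol_total,
            rel=1e-12,
        )

    def test_infinite_membrane_closes_only_cytosolic_route(self):
        bd = breakdown(r_m_basal=math.inf)
        assert math.isinf(bd.r_cytosol_total)
        assert math.isfinite(bd.r_para_total) and math.isfinite(bd.r_lateral_total)

    def test_published_lateral_dominant_totals_reproduce_papp(self):
        """The three published pathway totals of the protease inhibitor
        ritonavir combine to the published apparent permeability."""
        for totals, log_papp in [
            ((6.34, 4.44, 4.42), -4.13),  # ritonavir
            ((6.19, 4.79, 4.53), -4.33),  # saquinavir
            ((5.97, 4.43, 4.43), -4.12),  # terfenadine
        ]:
            papp = sum(10.0 ** -t for t in totals)
            assert math.log10(papp) == pytest.approx(log_papp, abs=0.005)


class TestTotalPapp:
    def test_single_open_pathway(self):
        bd = breakdown(r_m_basal=math.inf, r_lateral=math.inf)
        assert mp.total_papp(bd) == pytest.approx(1.0 / bd.r_para_total)

    def test_three_equal_pathways(self):
        bd = breakdown(r_uwl=0.0, r_filter=0.0, r_para=300.0, r_lateral=300.0,
                       r_m_apical=100.0, r_cytosol=100.0, r_m_basal=100.0)
        assert mp.total_papp(bd) == pytest.approx(3.0 / 300.0)

    def test_all_closed_is_an_error(self):
        with pytest.raises(mp.ValidationError):
            breakdown(r_para=math.inf, r_lateral=math.inf, r_m_basal=math.inf,
                      r_uwl=math.inf, r_filter=math.inf)

    @given(
        st.lists(finite_r, min_size=7, max_size=7)
    )
    def test_oracle_equivalence_with_conductance_network(self, rs):
        """Independent oracle: build the conductance matrix of the
        serial/parallel network with numpy and compare."""
        import numpy as np

        u, f, c, ma, mb, p, l = rs
        bd = mp.pathway_totals(
            r_uwl=u, r_filter=f, r_cytosol=c, r_m_apical=ma,
            r_m_basal=mb, r_para=p, r_lateral=l,
        )
        serial = np.array(
            [[u, p, f, 0, 0], [u, l, f, 0, 0], [u, ma, c, mb, f]], dtype=float
        )
        oracle = float(np.sum(1.0 / serial.sum(axis=1)))
        assert mp.total_papp(bd) == pytest.approx(oracle, rel=1e-12)


class TestClassification:
    def test_fully_ionized_is_paracellular(self, params, typical_chemical, cationic):
        bd = mp.compute_breakdown(typical_chemical, cationic, mp.AssayConditions(), params)
        cls = mp.classify_routes(bd)
        assert cls.dominant_route == "paracellular"
        assert cls.cytosolic_main_barrier == "n/a"

    def test_polar_neutral_is_membrane_limited_cytosolic(self, params, neutral):
        chem = mp.ChemicalDescriptors(
            name="polar", mw=300.0, log_khexw=-7.5, log_klipw=-1.0,
            d_aq_37=1e-5, d_hex=5e-6, d_lateral=1e-8,
        )
        cls = mp.classify_routes(
            mp.compute_breakdown(chem, neutral, mp.AssayConditions(), params)
        )
        # very polar but neutral: paracellular may compete; membrane must
        # dominate within the cytosolic pathway itself
        bd = mp.compute_breakdown(chem, neutral, mp.AssayConditions(), params)
        assert bd.r_m_apical + bd.r_m_basal > max(bd.r_uwl, bd.r_cytosol, bd.r_filter)

    def test_moderately_polar_neutral_cytosolic_membrane_barrier(self, params, neutral):
        chem = mp.ChemicalDescriptors(
            name="polar-neutral", mw=360.0, log_khexw=-6.0, log_klipw=1.5,
            d_aq_37=8e-6, d_hex=4e-6, d_lateral=1e-8,
        )
        cls = mp.classify_routes(
            mp.compute_breakdown(chem, neutral, mp.AssayConditions(), params)
        )
        assert cls.dominant_route == "cytosolic"
        assert cls.cytosolic_main_barrier == "membranes"

    def test_lipophilic_neutral_cytosolic_uwl_barrier(self, params, neutral):
        chem = mp.ChemicalDescriptors(
            name="lipophile", mw=300.0, log_khexw=2.0, log_klipw=3.0,
            d_aq_37=1e-5, d_hex=5e-6, d_lateral=1e-8,
        )
        cls = mp.classify_routes(
            mp.compute_breakdown(chem, neutral, mp.AssayConditions(), params)
        )
        assert cls.dominant_route == "cytosolic"
        assert cls.cytosolic_main_barrier == "UWL"

    def test_tie_break_is_deterministic(self):
        bd = breakdown(r_para=1000.0, r_lateral=1000.0, r_m_apical=500.0,
                       r_m_basal=250.0, r_cytosol=250.0)
        # all three totals equal -> cytosolic wins by documented order
        assert bd.r_para_total == bd.r_lateral_total == bd.r_cytosol_total
        assert mp.classify_routes(bd).dominant_route == "cytosolic"


class TestMonotonicity:
    def run(self, params, neutral, **kw):
        base = dict(name="x", mw=300.0, log_khexw=-3.0, log_klipw=2.0,
                    d_aq_37=1e-5, d_hex=5e-6, d_lateral=1e-8)
        base.update(kw)
        chem = mp.ChemicalDescriptors(**base)
        return mp.compute_breakdown(chem, neutral, mp.AssayConditions(), params).p_app

    @pytest.mark.parametrize("field,lo,hi", [
        ("log_khexw", -5.0, -1.0),
        ("log_klipw", 0.0, 4.0),
        ("d_aq_37", 5e-6, 2e-5),
        ("d_hex", 2e-6, 8e-6),
        ("d_lateral", 5e-9, 5e-8),
    ])
    def test_papp_nondecreasing_in_descriptor(self, params, neutral, field, lo, hi):
        assert self.run(params, neutral, **{field: lo}) <= self.run(
            params, neutral, **{field: hi}
        )

    def test_papp_nondecreasing_in_neutral_fraction(self, params, typical_chemical):
        papps = []
        for fn in (0.1, 0.5, 1.0):
            spec = mp.SpeciationProfile(f_neutral=fn, f_anion=1.0 - fn)
            papps.append(
                mp.compute_breakdown(
                    typical_chemical, spec, mp.AssayConditions(), params
                ).p_app
            )
        assert papps == sorted(papps)

    def test_papp_nondecreasing_in_stirring(self, params, typical_chemical, neutral):
        papps = [
            mp.compute_breakdown(
                typical_chemical, neutral, mp.AssayConditions(stirring_rpm=rpm), params
            ).p_app
            for rpm in (150.0, 600.0, 1200.0)
        ]
        assert papps == sorted(papps)

    def test_uwl_caps_papp(self, params, neutral):
        """The lumped UWL is serial in every pathway, so P_app <= 3/R_UWL
        and log P_app sits near -4 with default stirring."""
        chem = mp.ChemicalDescriptors(
            name="superlipophile", mw=200.0, log_khexw=4.0, log_klipw=6.0,
            d_aq_37=2e-5, d_hex=1e-5, d_lateral=1e-7,
        )
        bd = mp.compute_breakdown(chem, neutral, mp.AssayConditions(), params)
        assert bd.p_app <= 3.0 / bd.r_uwl
        assert math.log10(bd.p_app) < -3.8

    def test_removing_a_pathway_never_increases_papp(self, params, typical_chemical, neutral):
        full = mp.compute_breakdown(typical_chemical, neutral, mp.AssayConditions(), params)
        off = params.replace(lateral_enabled=False)
        reduced = mp.compute_breakdown(typical_chemical, neutral, mp.AssayConditions(), off)
        assert reduced.p_app <= full.p_app
        assert full.p_app >= max(
            1 / full.r_para_total, 1 / full.r_lateral_total, 1 / full.r_cytosol_total
        )
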