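"""Speciation ladder and microspecies-weighted descriptor averaging."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsrrkit.descriptors import (
    MicrospeciesProfile,
    build_matrix,
    speciate,
    weighted_descriptors,
)
from qsrrkit.exceptions import ValidationError


def ladder_oracle(pkas, ph):
    """Independent partition-function computation: state j (j protons lost)
    has relative population 10**sum(pH - pKa_i, i<=j)."""
    logw = [0.0]
    for i, pka in enumerate(pkas):
        logw.append(logw[-1] + (ph - pka))
    w = np.power(10.0, np.array(logw) - max(logw))
    return w / w.sum()


class TestSpeciate:
    def test_monoprotic_acid_at_its_pka_is_half_ionized(self):
        res = speciate([4.0], ["acidic"], ph=4.0)
        assert res.fractions["neutral"] == pytest.approx(0.5, abs=1e-12)
        assert res.fractions["anion"] == pytest.approx(0.5, abs=1e-12)

    def test_strong_base_fully_protonated_at_low_ph(self):
        res = speciate([9.0], ["basic"], ph=2.0)
        assert res.fractions["cation"] >= 0.9999

    def test_diprotic_acid_matches_partition_function_oracle(self):
        res = speciate([3.0, 8.0], ["acidic", "acidic"], ph=5.0)
        expected = ladder_oracle([3.0, 8.0], 5.0)
        got = np.array([res.fractions["neutral"], res.fractions["anion"],
                        res.fractions["anion2"]])
        assert np.max(np.abs(got - expected)) < 1e-12

    def test_no_ionizable_sites_gives_single_neutral_species(self):
        res = speciate([], [], ph=7.0)
        assert res.fractions == {"neutral": 1.0}

    @given(
        pkas=st.lists(
            st.floats(min_value=-2, max_value=16), min_size=1, max_size=4
        ).map(sorted),
        ph=st.floats(min_value=0, max_value=14),
    )
    @settings(max_examples=100, deadline=None)
    def test_fractions_sum_to_one_and_match_oracle(self, pkas, ph):
        n_basic = len(pkas) // 2
        sites = ["basic"] * n_basic + ["acidic"] * (len(pkas) - n_basic)
        res = speciate(pkas, sites, ph)
        total = sum(res.fractions.values())
        assert abs(total - 1.0) < 1e-12
        assert all(0.0 <= f <= 1.0 for f in res.fractions.values())
        expected = ladder_oracle(pkas, ph)
        assert np.max(np.abs(np.array(list(res.fractions.values())) - expected)) < 1e-12

    def test_deprotonated_fraction_monotone_in_ph(self):
        fracs = [
            speciate([4.5], ["acidic"], ph).fractions["anion"]
            for ph in np.linspace(1, 12, 40)
        ]
        assert all(b >= a - 1e-15 for a, b in zip(fracs, fracs[1:]))

    @pytest.mark.parametrize(
        "pkas, sites, msg",
        [
            ([np.nan], ["acidic"], "finite"),
            ([5.0, 3.0], ["acidic", "acidic"], "ascending"),
            ([5.0], ["weird"], "site"),
        ],
    )
    def test_invalid_inputs_rejected(self, pkas, sites, msg):
        with pytest.raises(ValidationError, match=msg):
            speciate(pkas, sites, 7.0)


def make_profile(values_by_species, pkas=(), sites=(), logd=None, cid="c1"):
    return MicrospeciesProfile(
        compound_id=cid,
        species=values_by_species,
        pka_values=list(pkas),
        site_types=list(sites),
        logd_by_ph=logd or {7.0: 1.5},
    )


class TestWeightedDescriptors:
    def test_single_species_is_identity(self):
        prof = make_profile({"neutral": {"a": 3.0, "b": -1.0}})
        res = speciate([], [], 7.0)
        out = weighted_descriptors(prof, res)
        assert out["a"] == 3.0 and out["b"] == -1.0 and out["logD"] == 1.5

    def test_half_half_mixture_gives_midpoint(self):
        prof = make_profile(
            {"neutral": {"d": 0.0}, "anion": {"d": 10.0}},
            pkas=[4.0],
            sites=["acidic"],
            logd={4.0: 0.3},
        )
        out = weighted_descriptors(prof, speciate([4.0], ["acidic"], 4.0))
        assert out["d"] == pytest.approx(5.0, abs=1e-12)

    def test_three_species_matches_dot_product_oracle(self, rng):
        names = [f"d{i}" for i in range(6)]
        vals = {
            lab: {n: float(v) for n, v in zip(names, rng.standard_normal(6))}
            for lab in ("cation", "neutral", "anion")
        }
        prof = make_profile(
            vals, pkas=[4.0, 9.0], sites=["basic", "acidic"], logd={5.5: -0.2}
        )
        res = speciate([4.0, 9.0], ["basic", "acidic"], 5.5)
        out = weighted_descriptors(prof, res)
        for n in names:
            oracle = sum(res.fractions[lab] * vals[lab][n] for lab in vals)
            assert out[n] == pytest.approx(oracle, abs=1e-12)

    def test_invariant_to_species_ordering(self):
        a = {"neutral": {"x": 1.0}, "anion": {"x": 2.0}}
        b = {"anion": {"x": 2.0}, "neutral": {"x": 1.0}}
        res = speciate([6.0], ["acidic"], 6.3)
        out_a = weighted_descriptors(make_profile(a, [6.0], ["acidic"]), res)
        out_b = weighted_descriptors(make_profile(b, [6.0], ["acidic"]), res)
        assert out_a == out_b

    def test_identical_species_independent_of_fractions(self):
        vec = {"x": 2.5, "y": -1.0}
        prof = make_profile(
            {"neutral": dict(vec), "anion": dict(vec)}, [5.0], ["acidic"]
        )
        for ph in (2.0, 5.0, 9.0):
            out = weighted_descriptors(prof, speciate([5.0], ["acidic"], ph))
            assert out["x"] == pytest.approx(2.5, abs=1e-12)

    def test_descriptor_name_mismatch_lists_missing_names(self):
        prof = make_profile(
            {"neutral": {"x": 1.0}, "anion": {"x": 1.0, "extra": 2.0}},
            [5.0],
            ["acidic"],
        )
        with pytest.raises(ValidationError, match="extra"):
            weighted_descriptors(prof, speciate([5.0], ["acidic"], 5.0))


class TestBuildMatrix:
    def _profiles(self):
        return [
            make_profile(
                {"neutral": {"a": 1.0, "b": 2.0, "c": 3.0}},
                logd={7.0: 0.5},
                cid="c1",
            ),
            make_profile(
                {"neutral": {"a": 4.0, "b": 5.0, "c": 6.0}},
                logd={7.0: -1.0},
                cid="c2",
            ),
        ]

    def test_shape_is_compounds_by_descriptors_plus_logd(self):
        m = build_matrix(self._profiles(), ph=7.0)
        assert m.shape == (2, 4)
        assert list(m.columns) == ["a", "b", "c", "logD"]
        assert list(m.index) == ["c1", "c2"]

    def test_every_cell_within_species_range(self, rng):
        profiles = []
        for i in range(5):
            species = {
                lab: {"u": float(rng.uniform(-5, 5)), "v": float(rng.uniform(-5, 5))}
                for lab in ("neutral", "anion")
            }
            profiles.append(
                make_profile(
                    species, [float(rng.uniform(3, 9))], ["acidic"],
                    logd={6.0: 0.0}, cid=f"c{i}",
                )
            )
        m = build_matrix(profiles, ph=6.0)
        for prof in profiles:
            for col in ("u", "v"):
                vals = [prof.species[lab][col] for lab in prof.species]
                cell = m.loc[prof.compound_id, col]
                assert min(vals) - 1e-12 <= cell <= max(vals) + 1e-12

    def test_duplicate_compound_id_rejected(self):
        profs = self._profiles()
        profs[1].compound_id = "c1"
        with pytest.raises(ValidationError, match="duplicate"):
            build_matrix(profs, ph=7.0)

    def test_matrix_matches_hand_assembled_fixture(self):
        m = build_matrix(self._profiles(), ph=7.0)
        expected = (
            "id,a,b,c,logD\n"
            "c1,1,2,3,0.5\n"
            "c2,4,5,6,-1\n"
        )
        assert m.to_csv(float_format="%.10g") == expected
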