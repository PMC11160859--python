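import pytest

from genfilter import builtin_model, total_rate, validate_model
from genfilter.models import (JumpMark, Participants, builtin_model as bm,
                              model_from_config, model_to_config)


def test_seirs_structure():
    m = builtin_model("seirs", {"N": 100, "beta": 2, "sigma": 1, "gamma": 1,
                                "psi": 0.1, "omega": 0.2})
    assert m.demes == ("E", "I")
    assert len(m.marks) == 5
    classes = {mk.name: mk.event_class for mk in m.marks}
    assert classes == {"trans": "birth", "prog": "migration",
                       "recov": "death", "sample": "sample",
                       "wane": "neutral"}
    # productions by the emergent-lineage rule
    assert m.mark("trans").production(m.demes) == (1, 1)
    assert m.mark("prog").production(m.demes) == (0, 1)
    assert m.mark("recov").production(m.demes) == (0, 0)
    assert m.mark("sample").production(m.demes) == (0, 1)
    assert m.mark("wane").production(m.demes) == (0, 0)
    assert m.occupancy((97, 2, 1, 0)) == (2, 1)


def test_moran_compound_mark_and_constant_occupancy():
    m = builtin_model("moran", {"n": 10, "mu": 1.0})
    (event,) = [mk for mk in m.marks if mk.name == "event"]
    assert event.event_class == "birth_death"
    assert event.production(m.demes) == (2,)
    for x in m.state_space.states:
        assert m.occupancy(x) == (10,)
        assert m.occupancy(event.state_update(x)) == (10,)


@pytest.mark.parametrize("x,expected", [((3,), 10.5), ((0,), 0.0)])
def test_lbd_total_rate_is_additive(x, expected):
    m = builtin_model("lbd", {"lam": 1, "mu": 2, "psi": 0.5, "rho": 1.0,
                              "x0": 3})
    assert total_rate(m, 0.0, x) == pytest.approx(expected)
    assert total_rate(m, 0.0, x) == pytest.approx(
        sum(mk.rate(0.0, x) for mk in m.marks))


def test_zero_rate_model_has_zero_total_rate():
    m = builtin_model("lbd", {"lam": 0, "mu": 0, "psi": 0, "rho": 1.0,
                              "x0": 1})
    assert all(total_rate(m, 0.0, x) == 0 for x in m.state_space.states[:10])


def test_total_rate_rejects_states_outside_truncation():
    m = builtin_model("lbd", {"lam": 1, "mu": 1, "psi": 0, "rho": 1,
                              "x0": 1, "xmax": 10})
    with pytest.raises(ValueError):
        total_rate(m, 0.0, (11,))


def test_unknown_model_and_missing_params():
    with pytest.raises(ValueError):
        builtin_model("nope", {})
    with pytest.raises(ValueError):
        builtin_model("seirs", {"N": 10})
    with pytest.raises(ValueError):
        builtin_model("lbd", {"lam": -1, "mu": 0, "psi": 0, "rho": 1})
    with pytest.raises(ValueError):
        builtin_model("lbd", {"lam": 1, "mu": 0, "psi": 0, "rho": 1.5})


# -- production rule on the worked event examples ---------------------------

def test_production_birth_with_cross_deme_child():
    """A blue parent siring one blue and one yellow child: the parent and
    both offspring emerge, so r = (2, 1)."""
    mark = JumpMark("b", "birth", lambda t, x: 1.0, lambda x: x,
                    Participants(parent="blue",
                                 children=("blue", "yellow")))
    assert mark.production(("blue", "yellow")) == (2, 1)


def test_production_simultaneous_two_deme_samples():
    """Two lineages sampled at once, one per deme, both surviving: each
    sampled lineage emerges, so r = (1, 1)."""
    mark = JumpMark("s", "sample", lambda t, x: 1.0, lambda x: x,
                    Participants(samples=("blue", "yellow")))
    assert mark.production(("blue", "yellow")) == (1, 1)


def test_production_sample_death_compound():
    """A sampled lineage that is simultaneously extinguished does not
    emerge: r = (0, 0)."""
    mark = JumpMark("sd", "sample_death", lambda t, x: 1.0, lambda x: x,
                    Participants(samples=("blue",),
                                 sampled_lineages_die=True))
    assert mark.production(("blue", "yellow")) == (0, 0)


def test_production_migration_and_compound_birth_death():
    mig = JumpMark("m", "migration", lambda t, x: 1.0, lambda x: x,
                   Participants(migrations=(("yellow", "blue"),)))
    assert mig.production(("blue", "yellow")) == (1, 0)
    bd = JumpMark("bd", "birth_death", lambda t, x: 1.0, lambda x: x,
                  Participants(parent="blue", children=("blue",),
                               deaths=("yellow",)))
    assert bd.production(("blue", "yellow")) == (2, 0)


# -- validation --------------------------------------------------------------

@pytest.mark.parametrize("name,params", [
    ("seirs", {"N": 10, "beta": 2, "sigma": 1, "gamma": 1, "psi": 0.1,
               "omega": 0.2}),
    ("sirs", {"N": 10, "beta": 2, "gamma": 1, "psi": 0.1, "omega": 0.2}),
    ("moran", {"n": 5, "mu": 1.0, "psi": 0.5}),
    ("lbd", {"lam": 1, "mu": 0.5, "psi": 0.2, "rho": 0.5, "x0": 2,
             "xmax": 20}),
    ("two_strain", {"N": 8, "beta1": 2, "beta2": 1.5, "sigma1": 1,
                    "sigma2": 1, "gamma1": 1, "gamma2": 1, "psi1": 0.1,
                    "psi2": 0.1, "omega": 0.1}),
    ("progression", {"N": 8, "beta_a": 1, "beta_s": 2, "sigma_a": 0.5,
                     "sigma_s": 1, "gamma_a": 1, "gamma_s": 1, "eta": 0.3,
                     "delta": 0.5, "psi": 0.2}),
    ("superspreading", {"N": 8, "beta_l": 1, "beta_h": 4, "sigma": 1,
                        "p_h": 0.2, "w_lh": 0.3, "w_hl": 0.6, "gamma": 1,
                        "psi": 0.2}),
])
def test_builtin_models_validate_clean(name, params):
    assert validate_model(builtin_model(name, params)) == []


def test_validate_flags_multi_deme_sampling():
    m = builtin_model("seirs", {"N": 6, "beta": 2, "sigma": 1, "gamma": 1,
                                "psi": 0.1, "omega": 0.2})
    bad = JumpMark("s2", "sample", lambda t, x: 0.1, lambda x: x,
                   Participants(samples=("E", "I")), demes=m.demes)
    m.marks = m.marks + (bad,)
    out = validate_model(m)
    assert any("multi-deme" in v for v in out)


def test_validate_flags_negative_occupancy_update():
    m = builtin_model("seirs", {"N": 6, "beta": 2, "sigma": 1, "gamma": 1,
                                "psi": 0.1, "omega": 0.2})
    # a death mark whose rate stays positive at zero occupancy
    bad = JumpMark("bad_death", "death", lambda t, x: 1.0,
                   lambda x: (x[0], x[1], x[2] - 1, x[3] + 1),
                   Participants(deaths=("I",)), demes=m.demes)
    m.marks = m.marks + (bad,)
    out = validate_model(m)
    assert out  # update at I=0 leaves the state space / breaks occupancy


def test_validate_flags_state_dependent_production():
    class ShiftyMark(JumpMark):
        _flip = [False]

        def production(self, demes=None):
            self._flip[0] = not self._flip[0]
            return (1, 0) if self._flip[0] else (0, 1)

    m = builtin_model("seirs", {"N": 6, "beta": 2, "sigma": 1, "gamma": 1,
                                "psi": 0.1, "omega": 0.2})
    bad = ShiftyMark("shifty", "neutral", lambda t, x: 0.0, lambda x: x,
                     Participants(), demes=m.demes)
    m.marks = m.marks + (bad,)
    assert any("not constant" in v for v in validate_model(m))


def test_config_round_trip_is_exact():
    params = {"N": 12, "beta": 2.5, "sigma": 1.0, "gamma": 0.75,
              "psi": 0.125, "omega": 0.5, "I0": 2}
    m = bm("seirs", params)
    text = model_to_config(m)
    m2 = model_from_config(text)
    assert model_to_config(m2) == text
    assert m2.params == params
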