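import math
from fractions import Fraction

import pytest

from genfilter import (History, ObscuredGenealogy, PrunedGenealogy,
                       builtin_model, filter_adjoint, filter_forward,
                       filter_obscured, hidden_source_terms,
                       loglik_given_history, montecarlo_loglik,
                       moran_serial_loglik, obscure, prune,
                       simulate_genealogy)
from oracles import colored_moran


def pair_tree(horizon=1.0, branch=0.5, deme="L"):
    p = PrunedGenealogy(horizon)
    r = p.add_node(0.0, "root")
    b = p.add_node(branch, "internal", deme=deme, parent=r)
    p.add_node(horizon, "sample", deme=deme, parent=b, label="s1")
    p.add_node(horizon, "sample", deme=deme, parent=b, label="s2")
    return p


# -- likelihood of a genealogy given a full history ---------------------------

def test_loglik_given_history_moran_single_event():
    m = builtin_model("moran", {"n": 4, "mu": 1.0, "terminal_samples": 2})
    p = pair_tree()
    h = History(horizon=1.0, x0=(), times=[0.5], marks=["event"],
                states=[()])
    assert loglik_given_history(m, p, h) == pytest.approx(math.log(1 / 6))


def test_loglik_given_history_requires_event_times():
    m = builtin_model("moran", {"n": 4, "mu": 1.0, "terminal_samples": 2})
    p = pair_tree()
    h = History(horizon=1.0, x0=(), times=[0.4], marks=["event"],
                states=[()])
    assert loglik_given_history(m, p, h) == -math.inf


def test_loglik_given_history_empty_genealogy_is_free():
    m = builtin_model("moran", {"n": 4, "mu": 1.0})
    p = PrunedGenealogy(1.0)   # no samples at all
    h = History(horizon=1.0, x0=(), times=[0.2, 0.7],
                marks=["event", "event"], states=[(), ()])
    assert loglik_given_history(m, p, h) == pytest.approx(0.0)


# -- deterministic filters ----------------------------------------------------

def test_filter_trivial_no_events_zero_rates():
    m = builtin_model("lbd", {"lam": 0, "mu": 0, "psi": 0, "rho": 0,
                              "x0": 3, "xmax": 5})
    z = ObscuredGenealogy(2.0)   # empty genealogy
    assert float(filter_forward(m, z)) == pytest.approx(0.0)
    assert float(filter_adjoint(m, z)) == pytest.approx(0.0)


def test_filter_empty_genealogy_counts_unobserved_sampling():
    """With no samples observed, the likelihood is the probability that the
    sampling process produced none."""
    m = builtin_model("moran", {"n": 4, "mu": 1.0})
    # add a true-hazard sampling mark via the lbd model instead
    lm = builtin_model("lbd", {"lam": 0, "mu": 0, "psi": 0.3, "rho": 0,
                               "x0": 2, "xmax": 4})
    z = ObscuredGenealogy(2.0)
    # no jumps possible except sampling, which must not have happened
    assert float(filter_forward(lm, z)) == pytest.approx(-0.3 * 2 * 2.0)


def test_forward_adjoint_duality(moran_serial_case, seirs_case):
    for model, _, p, z in (moran_serial_case, seirs_case):
        for tree in (p, z):
            f = float(filter_forward(model, tree))
            a = float(filter_adjoint(model, tree))
            assert abs(f - a) <= 1e-6


def test_obscured_equals_serial_closed_form(moran_serial_case):
    model, _, _, z = moran_serial_case
    cf = moran_serial_loglik(z, n=6, mu=1.0, psi=0.9)
    assert float(filter_obscured(model, z)) == pytest.approx(cf, abs=1e-8)


def test_obscured_multi_deme_reduces_to_neutral_coloring():
    """Two-deme model whose colors are dynamically neutral: the obscured
    likelihood must equal the single-deme Moran closed form for any switch
    rate and initial coloring."""
    n, mu, psi = 5, 1.3, 0.9
    plain = builtin_model("moran", {"n": n, "mu": mu, "psi": psi})
    _, g = simulate_genealogy(plain, horizon=3.0, seed=7)
    z = obscure(prune(g))
    assert len(z.samples()) >= 2
    cf = moran_serial_loglik(z, n=n, mu=mu, psi=psi)
    for m_switch, nA0 in ((0.0, 5), (0.7, 2), (2.3, 1)):
        cm = colored_moran(n, mu, m_switch, psi, nA0)
        assert float(filter_obscured(cm, z)) == pytest.approx(cf, abs=1e-8)


def test_truncation_invariance_lbd(lbd_case):
    model, _, _, z = lbd_case
    lo = builtin_model("lbd", {**model.params, "xmax": 80})
    hi = builtin_model("lbd", {**model.params, "xmax": 140})
    assert float(filter_adjoint(lo, z)) == pytest.approx(
        float(filter_adjoint(hi, z)), abs=1e-8)
    assert filter_forward(hi, z).boundary_mass < 1e-10


def test_likelihood_invariant_to_simultaneous_sample_relabeling(kingman_case):
    model, _, _, z = kingman_case
    ll = float(filter_obscured(model, z))
    labels = [nd for nd in z.nodes.values() if nd.kind == "sample"]
    labels[0].label, labels[1].label = labels[1].label, labels[0].label
    assert float(filter_obscured(model, z)) == pytest.approx(ll, abs=1e-12)


def test_colored_filter_agrees_with_montecarlo(seirs_case):
    model, _, p, _ = seirs_case
    ff = float(filter_forward(model, p))
    mc = montecarlo_loglik(model, p, n_histories=20000, seed=11)
    assert abs(mc.mean_natural - math.exp(ff)) <= 3 * mc.se_natural


def test_montecarlo_agrees_with_exact_moran_value(moran_serial_case):
    model, _, _, z = moran_serial_case
    cf = moran_serial_loglik(z, n=6, mu=1.0, psi=0.9)
    mc = montecarlo_loglik(model, z, n_histories=20000, seed=1)
    assert abs(mc.mean_natural - math.exp(cf)) <= 3 * mc.se_natural


def test_structurally_impossible_data_gives_minus_inf():
    # three lineages in a population of two
    z = ObscuredGenealogy(1.0)
    r = z.add_node(0.0, "root")
    b1 = z.add_node(0.2, "internal", parent=r)
    b2 = z.add_node(0.4, "internal", parent=b1)
    for i, par in enumerate((b1, b2, b2)):
        z.add_node(1.0, "sample", parent=par, label=f"s{i+1}")
    m = builtin_model("moran", {"n": 2, "mu": 1.0, "terminal_samples": 3})
    assert float(filter_obscured(m, z)) == -math.inf


def test_hidden_source_terms_match_coalescent_coefficient():
    """Summed hidden gains reproduce the Moran regular-part coefficient
    1 − C(l,2)/C(n,2) exactly, slot by slot."""
    m = builtin_model("moran", {"n": 6, "mu": 1.0})
    mark = m.mark("event")
    for l in range(0, 7):
        terms = hidden_source_terms(mark, m.demes, (6,), ("L",) * l,
                                    exact=True)
        assert sum(w for _, w in terms) == \
            1 - Fraction(math.comb(l, 2), math.comb(6, 2))
        # exactly one no-involvement term plus l hidden-parent terms
        assert len(terms) == 1 + l
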