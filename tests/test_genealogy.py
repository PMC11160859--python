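import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from genfilter import (Genealogy, ObscuredGenealogy, PrunedGenealogy,
                       binomial_ratio, builtin_model, coalescent_intervals,
                       compatibility, event_weight, lineage_count, obscure,
                       prune, read_newick, saturation,
                       write_newick)
from genfilter.fixtures import worked_example_trees

from oracles import lineage_profile_by_paths


def three_tip_one_sample():
    """Three lineages, one sampled: pruning must keep only the sampled path,
    retaining the birth node on it as an inline node."""
    g = Genealogy(2.0)
    r1 = g.add_node(0.0, "root")
    b = g.add_node(0.5, "internal", deme="I", parent=r1)   # birth node
    t1 = g.add_node(2.0, "tip", deme="I", parent=b)        # unsampled child
    s_mid = g.add_node(1.0, "sample", deme="I", parent=b, label="s1")
    t2 = g.add_node(2.0, "tip", deme="I", parent=s_mid)
    r2 = g.add_node(0.0, "root")
    t3 = g.add_node(2.0, "tip", deme="I", parent=r2)       # unrelated lineage
    return g, {"root": r1, "birth": b, "sample": s_mid}


def test_prune_keeps_inline_birth_node_on_sample_path():
    g, ids = three_tip_one_sample()
    p = prune(g)
    assert isinstance(p, PrunedGenealogy)
    kinds = sorted(nd.kind for nd in p.nodes.values())
    assert kinds == ["internal", "root", "sample"]
    assert ids["birth"] in p.nodes          # inline node retained
    assert p.nodes[ids["sample"]].kind == "sample"
    assert p.n_children(ids["birth"]) == 1


def test_prune_idempotent_and_empty_without_samples():
    g, _ = three_tip_one_sample()
    p = prune(g)
    p2 = prune(p)
    assert set(p2.nodes) == set(p.nodes)
    g2 = Genealogy(1.0)
    r = g2.add_node(0.0, "root")
    g2.add_node(1.0, "tip", deme="I", parent=r)
    assert prune(g2).nodes == {}


def test_obscure_splices_inline_nodes_and_erases_demes():
    g, ids = three_tip_one_sample()
    z = obscure(prune(g))
    assert isinstance(z, ObscuredGenealogy)
    assert ids["birth"] not in z.nodes
    assert all(nd.deme is None for nd in z.nodes.values())
    # chain root -> inline -> sample collapses to a single edge
    sample = z.nodes[ids["sample"]]
    assert z.nodes[sample.parent].kind == "root"
    # every unifurcating internal node is gone
    assert all(not (nd.kind == "internal" and z.n_children(nd.id) == 1)
               for nd in z.nodes.values())


def test_node_count_after_obscuring(seirs_case):
    _, _, p, z = seirs_case
    n_samples = len(z.samples())
    n_branch = sum(1 for nd in z.nodes.values() if nd.kind == "internal")
    n_roots = len(z.roots())
    assert len(z.nodes) == n_samples + n_branch + n_roots


def test_lineage_count_matches_path_walking_oracle(seirs_case):
    model, _, p, _ = seirs_case
    times = sorted({nd.time for nd in p.nodes.values()})
    probes = [0.0] + times + [0.5 * (a + b)
                              for a, b in zip(times[:-1], times[1:])]
    for t in probes:
        if not 0 <= t <= p.horizon:
            continue
        got = lineage_count(p, t)
        want = lineage_profile_by_paths(p, t)
        assert {k: v for k, v in got.items() if v} == want


def test_lineage_count_single_edge_and_bounds():
    p = PrunedGenealogy(2.0)
    r = p.add_node(0.0, "root")
    p.add_node(2.0, "sample", deme="blue", parent=r, label="s1")
    assert lineage_count(p, 1.0, ["blue", "yellow"]) == [1, 0]
    assert lineage_count(ObscuredGenealogy(1.0), 0.5) == {}
    with pytest.raises(ValueError):
        lineage_count(p, 3.0)


def test_saturation_rules():
    p = PrunedGenealogy(3.0)
    r = p.add_node(0.0, "root")
    b = p.add_node(1.0, "internal", deme="blue", parent=r)
    c1 = p.add_node(2.0, "sample", deme="blue", parent=b, label="s1")
    p.add_node(3.0, "sample", deme="blue", parent=c1, label="s2")  # inline s1
    p.add_node(2.5, "sample", deme="blue", parent=b, label="s3")   # terminal
    demes = ["blue", "yellow"]
    assert saturation(p, 1.0, demes) == [2, 0]   # binary branch
    assert saturation(p, 2.5, demes) == [0, 0]   # terminal sample
    assert saturation(p, 2.0, demes) == [1, 0]   # inline sample
    assert saturation(p, 1.7, demes) == [0, 0]   # not a node time


def test_binomial_ratio_hand_values():
    assert binomial_ratio((5,), (2,), (0,), (0,)) == 1.0
    assert binomial_ratio((5,), (2,), (1,), (2,)) == 0.0   # s > r
    assert binomial_ratio((5,), (2,), (2,), (2,)) == pytest.approx(0.1)
    assert binomial_ratio((3,), (4,), (0,), (0,)) == 0.0   # n < l
    assert binomial_ratio((5, 7), (2, 3), (2, 1), (2, 0)) == pytest.approx(
        (1 / math.comb(5, 2)) * (math.comb(4, 1) / math.comb(7, 1)))


@settings(derandomize=True, max_examples=100)
@given(st.integers(1, 3).flatmap(
    lambda nd: st.tuples(
        st.lists(st.integers(0, 12), min_size=nd, max_size=nd),
        st.lists(st.integers(0, 12), min_size=nd, max_size=nd),
        st.lists(st.integers(0, 6), min_size=nd, max_size=nd))))
def test_chu_vandermonde_normalization(nlr):
    """Σ_s ratio(n,l,r,s) Π_i C(l_i, s_i) = 1 whenever n_i ≥ l_i, exactly."""
    n, l, r = nlr
    n = [a + b for a, b in zip(n, l)]      # enforce n >= l
    r = [min(ri, ni) for ri, ni in zip(r, n)]  # the ratio needs C(n,r) > 0
    total = Fraction(0)
    import itertools
    for s in itertools.product(*[range(0, ri + 1) for ri in r]):
        w = binomial_ratio(n, l, r, s, exact=True)
        mult = 1
        for li, si in zip(l, s):
            if si > li:
                mult = 0
                break
            mult *= math.comb(li, si)
        total += w * mult
    assert total == 1


def test_coalescent_intervals():
    z = worked_example_trees()["pair_coalescent"]
    assert coalescent_intervals(z) == {1: 0.5, 2: 0.5}
    single = ObscuredGenealogy(4.0)
    r = single.add_node(0.0, "root")
    single.add_node(4.0, "sample", parent=r, label="s1")
    assert coalescent_intervals(single) == {1: 4.0}
    assert sum(coalescent_intervals(z).values()) == pytest.approx(z.horizon)


def test_compatibility_rule_table():
    m = builtin_model("seirs", {"N": 10, "beta": 2, "sigma": 1, "gamma": 1,
                                "psi": 0.1, "omega": 0.2})
    p = PrunedGenealogy(2.0)
    r = p.add_node(0.0, "root")
    mig = p.add_node(0.8, "internal", deme="E", parent=r)   # E -> I change
    s1 = p.add_node(1.2, "sample", deme="I", parent=mig, label="s1")
    b = p.add_node(1.5, "internal", deme="I", parent=s1)
    p.add_node(2.0, "sample", deme="E", parent=b, label="s2")
    p.add_node(2.0, "sample", deme="I", parent=b, label="s3")
    # color change along an edge: progression yes, transmission/recovery no
    assert compatibility(m.mark("prog"), p, 0.8) == 1
    assert compatibility(m.mark("trans"), p, 0.8) == 0
    assert compatibility(m.mark("recov"), p, 0.8) == 0
    # branch point: birth-type only, parent deme I, children (E, I) <= r
    assert compatibility(m.mark("trans"), p, 1.5) == 1
    assert compatibility(m.mark("prog"), p, 1.5) == 0
    assert compatibility(m.mark("recov"), p, 1.5) == 0
    # sample node in deme I vs the I-sampling mark
    assert compatibility(m.mark("sample"), p, 1.2) == 1
    assert compatibility(m.mark("trans"), p, 1.2) == 0
    # non-node times: sampling cannot go unobserved, everything else can
    assert compatibility(m.mark("sample"), p, 0.3) == 0
    assert compatibility(m.mark("trans"), p, 0.3) == 1
    assert compatibility(m.mark("wane"), p, 0.3) == 1


def test_event_weight_moran_branch_and_free_jump():
    m = builtin_model("moran", {"n": 4, "mu": 1.0})
    p = PrunedGenealogy(1.0)
    r = p.add_node(0.0, "root")
    b = p.add_node(0.5, "internal", deme="L", parent=r)
    p.add_node(1.0, "sample", deme="L", parent=b, label="s1")
    p.add_node(1.0, "sample", deme="L", parent=b, label="s2")
    ev = m.mark("event")
    assert event_weight(m, ev, (), p, 0.5) == pytest.approx(1 / 6)
    # at a non-node time with l=2: the saturation-0 weight C(2,2)/C(4,2)
    assert event_weight(m, ev, (), p, 0.75) == pytest.approx(1 / 6)
    # before the branch only one lineage is extant: C(3,2)/C(4,2)
    assert event_weight(m, ev, (), p, 0.25) == pytest.approx(0.5)


def test_newick_round_trip_hand_and_simulated(seirs_case, moran_serial_case):
    trees = list(worked_example_trees().values())
    trees += [seirs_case[2], seirs_case[3], moran_serial_case[3]]
    for tree in trees:
        text = write_newick(tree)
        back = read_newick(text)
        assert write_newick(back) == text
        assert back.horizon == tree.horizon
        assert len(back.nodes) == len(tree.nodes)
        assert sorted(nd.kind for nd in back.nodes.values()) == \
            sorted(nd.kind for nd in tree.nodes.values())
        assert sorted(str(nd.deme) for nd in back.nodes.values()) == \
            sorted(str(nd.deme) for nd in tree.nodes.values())


def test_newick_minimal_obscured_example():
    z = read_newick("(s1:1.0,s2:1.0):0.0;")
    assert isinstance(z, ObscuredGenealogy)
    assert len(z.samples()) == 2
    assert {nd.time for nd in z.samples()} == {1.0}
    assert sum(lineage_count(z, 0.5).values()) == 2


def test_newick_rejects_negative_branch_lengths():
    with pytest.raises(ValueError):
        read_newick("(s1:-1.0,s2:1.0):0.0;")


def test_prune_never_removes_samples_and_counts_match(seirs_case):
    model, h, p, _ = seirs_case
    assert all(nd.kind != "tip" for nd in p.nodes.values())
    leaves = [nd for nd in p.nodes.values()
              if p.n_children(nd.id) == 0]
    assert all(nd.kind == "sample" for nd in leaves)
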