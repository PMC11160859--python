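"""Independent oracles and model builders used by the tests.

The two-colored Moran model builds a two-deme population whose deme labels
are dynamically neutral: births copy the parent's color, deaths and event
rates are color-blind, and lineages switch color at an arbitrary rate.  The
law of the *obscured* genealogy it induces is therefore exactly that of the
plain single-deme Moran model — an exact closed-form oracle that exercises
every multi-deme code path of the hidden-coloring filter.
"""

from __future__ import annotations

from genfilter.models import (JumpMark, Participants, PopulationModel,
                              StateSpace)


def colored_moran(n: int, mu: float, m_switch: float, psi: float,
                  nA0: int) -> PopulationModel:
    demes = ("A", "B")
    marks = []

    def upd_bd(pd, dd):
        def f(x):
            x = list(x)
            x[dd] -= 1
            x[pd] += 1
            return tuple(x)
        return f

    for pd, pname in enumerate(demes):
        for dd, dname in enumerate(demes):
            def rate(t, x, pd=pd, dd=dd):
                num = x[dd] * (x[pd] - (1 if pd == dd else 0))
                return mu * num / (n * (n - 1))

            marks.append(JumpMark(
                f"bd_{pname}{dname}", "birth_death", rate, upd_bd(pd, dd),
                Participants(parent=pname, children=(pname,),
                             deaths=(dname,)), demes=demes))

    def upd_mig(i, j):
        def f(x):
            x = list(x)
            x[i] -= 1
            x[j] += 1
            return tuple(x)
        return f

    marks.append(JumpMark("migAB", "migration",
                          lambda t, x: m_switch * x[0], upd_mig(0, 1),
                          Participants(migrations=(("A", "B"),)),
                          demes=demes))
    marks.append(JumpMark("migBA", "migration",
                          lambda t, x: m_switch * x[1], upd_mig(1, 0),
                          Participants(migrations=(("B", "A"),)),
                          demes=demes))
    # serial sampling conditioned on its times, uniform over all lineages:
    # the per-deme sampling density is psi * x_d / n
    for di, dname in enumerate(demes):
        marks.append(JumpMark(
            f"sample{dname}", "sample",
            (lambda di: lambda t, x: psi * x[di] / n)(di),
            lambda x: x, Participants(samples=(dname,)), demes=demes,
            observed_only=True))
    space = StateSpace.simplex(("A", "B"), n)
    return PopulationModel(demes=demes, marks=tuple(marks),
                           occupancy=lambda x: x,
                           p0={(nA0, n - nA0): 1.0}, state_space=space)


def lineage_profile_by_paths(tree, t):
    """Per-deme lineage count at t computed by walking each leaf's ancestor
    chain and collecting the unique edge stabbed by t — an oracle traversal
    independent of Genealogy.edges()."""
    children = tree.children_map()
    leaves = [i for i in tree.nodes if not children[i]]
    stabbed = {}
    for leaf in leaves:
        cur = leaf
        while cur is not None:
            nd = tree.nodes[cur]
            if nd.parent is None:
                break
            pt = tree.nodes[nd.parent].time
            if pt <= t < nd.time:
                stabbed[cur] = nd.deme
                break
            cur = nd.parent
    counts: dict = {}
    for deme in stabbed.values():
        counts[deme] = counts.get(deme, 0) + 1
    return counts
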