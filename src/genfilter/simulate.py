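"""Simulation of the population process and its induced genealogy.

The population process is simulated by the Gillespie algorithm (exact for
time-homogeneous rates) or by thinning against a declared rate bound for
time-varying rates.  At every jump the genealogy is updated according to the
mark's event class, with uniform lineage choices within demes; per-deme tip
counts track the deme occupancy n(X_t) at all times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .genealogy import Genealogy, INTERNAL, ROOT, SAMPLE, TIP
from .models import (BIRTH, BIRTH_DEATH, DEATH, MIGRATION, NEUTRAL,
                     PopulationModel, SAMPLE as SAMPLE_EC, SAMPLE_DEATH)


@dataclass
class History:
    """One realization of the jump process: times, marks, embedded chain."""
    horizon: float
    x0: tuple
    times: list[float] = field(default_factory=list)
    marks: list[str] = field(default_factory=list)
    states: list[tuple] = field(default_factory=list)  # post-jump states

    def __post_init__(self):
        if len(self.times) != len(self.marks) or \
                len(self.times) != len(self.states):
            raise ValueError("times, marks, states must align")

    @property
    def all_states(self):
        return [self.x0] + list(self.states)

    def state_at(self, t: float) -> tuple:
        x = self.x0
        for tk, xk in zip(self.times, self.states):
            if tk <= t:
                x = xk
            else:
                break
        return x

    def to_tsv(self) -> str:
        rows = ["time\tmark\tstate_before\tstate_after"]
        x = self.x0
        for t, u, x2 in zip(self.times, self.marks, self.states):
            rows.append(f"{t!r}\t{u}\t{','.join(map(str, x))}"
                        f"\t{','.join(map(str, x2))}")
            x = x2
        return "\n".join(rows) + "\n"


def _draw_jump(model, t, x, rng):
    """Return (dt, mark) for the next jump, or (None, None) past any jump."""
    rates = [m.rate(t, x) for m in model.marks]
    total = sum(rates)
    if model.time_homogeneous:
        if total <= 0:
            return None, None
        dt = rng.exponential(1.0 / total)
        u = rng.choice(len(rates), p=np.asarray(rates) / total)
        return dt, model.marks[u]
    bound = model.rate_bound
    if bound is None:
        raise ValueError("time-varying rates require a declared rate_bound")
    elapsed = 0.0
    while True:
        elapsed += rng.exponential(1.0 / bound)
        rates = [m.rate(t + elapsed, x) for m in model.marks]
        total = sum(rates)
        if total > bound * (1 + 1e-12):
            raise RuntimeError("rate bound violated during thinning")
        if rng.uniform() < total / bound:
            u = rng.choice(len(rates), p=np.asarray(rates) / total)
            return elapsed, model.marks[u]
        if t + elapsed > 1e6:
            return None, None


def simulate_history(model: PopulationModel, horizon: float,
                     seed: int | np.random.Generator) -> History:
    """Simulate the jump process X_t on [0, horizon]."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    x = _draw_initial(model, rng)
    h = History(horizon=float(horizon), x0=x)
    t = 0.0
    while True:
        dt, mark = _draw_jump(model, t, x, rng)
        if dt is None or t + dt > horizon:
            return h
        t += dt
        x = tuple(mark.state_update(x))
        if x not in model.state_space:
            raise RuntimeError(f"state {x} left truncation bounds at t={t}")
        h.times.append(t)
        h.marks.append(mark.name)
        h.states.append(x)


def _draw_initial(model, rng):
    states = list(model.p0)
    probs = np.array([model.p0[s] for s in states], dtype=float)
    return states[rng.choice(len(states), p=probs / probs.sum())]


def history_log_density(model: PopulationModel, h: History) -> float:
    """Log density of a history: Σ log α at jumps − ∫ total rate dt + log p0."""
    x = h.x0
    if h.x0 not in model.p0 or model.p0[h.x0] <= 0:
        return -math.inf
    ll = math.log(model.p0[h.x0])
    marks = {m.name: m for m in model.marks}
    if any(b <= a for a, b in zip([0.0] + list(h.times), h.times)) or \
            (h.times and h.times[-1] > h.horizon):
        raise ValueError("jump times must be strictly increasing in (0, T]")
    knots = [0.0] + list(h.times) + [h.horizon]
    xs = h.all_states
    for k, (t, uname) in enumerate(zip(h.times, h.marks)):
        u = marks[uname]
        if tuple(u.state_update(xs[k])) != tuple(xs[k + 1]):
            raise ValueError(f"history inconsistent with mark {uname} at {t}")
        a = u.rate(t, xs[k])
        if a <= 0:
            return -math.inf
        ll += math.log(a)
    for k in range(len(knots) - 1):
        a, b = knots[k], knots[k + 1]
        if b <= a:
            continue
        xk = xs[min(k, len(xs) - 1)]
        if model.time_homogeneous:
            lam = sum(m.rate(a, xk) for m in model.marks)
            ll -= lam * (b - a)
        else:
            lam_int, _ = quad(
                lambda s: sum(m.rate(s, xk) for m in model.marks), a, b)
            ll -= lam_int
    return ll


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------

class _Forest:
    """Mutable genealogy under construction, with per-deme tip registries."""

    def __init__(self, model, x0, horizon):
        self.g = Genealogy(horizon)
        self.tips: dict[str, list[int]] = {d: [] for d in model.demes}
        self.n_samples = 0
        n0 = model.occupancy(x0)
        for d, k in zip(model.demes, n0):
            for _ in range(int(k)):
                r = self.g.add_node(0.0, ROOT)
                tid = self.g.add_node(horizon, TIP, deme=d, parent=r)
                self.tips[d].append(tid)

    def _pick(self, deme, rng, exclude=None):
        pool = self.tips[deme]
        if exclude is not None:
            pool = [i for i in pool if i != exclude]
        if not pool:
            raise RuntimeError(f"event needs a lineage in deme {deme!r} "
                               "but none is present")
        return pool[rng.integers(len(pool))]

    def _insert_above(self, tid, t, kind):
        tip = self.g.nodes[tid]
        nid = self.g.add_node(t, kind, deme=tip.deme, parent=tip.parent)
        tip.parent = nid
        return nid

    def birth(self, t, parent_deme, child_demes, rng, dier_deme=None):
        a = self._pick(parent_deme, rng)
        dier = None
        if dier_deme is not None:  # compound birth/death (Moran-type)
            dier = self._pick(dier_deme, rng, exclude=a)
        b = self._insert_above(a, t, INTERNAL)
        for d in child_demes:
            cid = self.g.add_node(self.g.horizon, TIP, deme=d, parent=b)
            self.tips[d].append(cid)
        if dier is not None:
            self.kill(dier)

    def kill(self, tid):
        nd = self.g.nodes[tid]
        self.tips[nd.deme].remove(tid)
        cur = tid
        ch = self.g.children_map()
        while cur is not None:
            nd = self.g.nodes[cur]
            kids = [c for c in ch.get(cur, []) if c in self.g.nodes]
            if kids or nd.kind == SAMPLE:
                break
            del self.g.nodes[cur]
            cur = nd.parent

    def migrate(self, t, src, dst, rng):
        a = self._pick(src, rng)
        self._insert_above(a, t, INTERNAL)
        nd = self.g.nodes[a]
        self.tips[src].remove(a)
        nd.deme = dst
        self.tips[dst].append(a)

    def sample(self, t, deme, rng, dies=False, tip_id=None):
        a = self._pick(deme, rng) if tip_id is None else tip_id
        self.n_samples += 1
        s = self._insert_above(a, t, SAMPLE)
        self.g.nodes[s].label = f"s{self.n_samples}"
        if dies:
            self.kill(a)

    def check_occupancy(self, model, x):
        want = list(map(int, model.occupancy(x)))
        have = [len(self.tips[d]) for d in model.demes]
        if want != have:
            raise RuntimeError(f"tip counts {have} != occupancy {want}")


def _apply_mark(forest, mark, t, rng):
    P = mark.participants
    ec = mark.event_class
    if ec == NEUTRAL:
        return
    if ec == BIRTH:
        forest.birth(t, P.parent, P.children, rng)
    elif ec == BIRTH_DEATH:
        (dd,) = P.deaths
        forest.birth(t, P.parent, P.children, rng, dier_deme=dd)
    elif ec == DEATH:
        for d in P.deaths:
            forest.kill(forest._pick(d, rng))
    elif ec == MIGRATION:
        for (i, j) in P.migrations:
            forest.migrate(t, i, j, rng)
    elif ec in (SAMPLE_EC, SAMPLE_DEATH):
        for d in sorted(P.samples):
            forest.sample(t, d, rng, dies=P.sampled_lineages_die)
    else:
        raise ValueError(f"unknown event class {ec!r}")


def simulate_genealogy(model: PopulationModel, horizon: float,
                       seed: int | np.random.Generator,
                       check: bool = False) -> tuple[History, Genealogy]:
    """Simulate the population process and its induced genealogy jointly."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    x = _draw_initial(model, rng)
    h = History(horizon=float(horizon), x0=x)
    forest = _Forest(model, x, horizon)
    t = 0.0
    while True:
        dt, mark = _draw_jump(model, t, x, rng)
        if dt is None or t + dt > horizon:
            break
        t += dt
        x = tuple(mark.state_update(x))
        if x not in model.state_space:
            raise RuntimeError(f"state {x} left truncation bounds at t={t}")
        h.times.append(t)
        h.marks.append(mark.name)
        h.states.append(x)
        _apply_mark(forest, mark, t, rng)
        if check:
            forest.check_occupancy(model, x)
    for ev in model.scheduled:
        when = horizon if ev.time is None else ev.time
        if when > horizon:
            continue
        if ev.kind == "binomial_sample":
            for tid in list(forest.tips[ev.deme]):
                if rng.uniform() < ev.prob:
                    forest.sample(when, ev.deme, rng, tip_id=tid)
        elif ev.kind == "conditioned_sample":
            pool = list(forest.tips[ev.deme])
            k = min(ev.count or 0, len(pool))
            for tid in rng.choice(pool, size=k, replace=False):
                forest.sample(when, ev.deme, rng, tip_id=int(tid))
    return h, forest.g
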