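"""Exact genealogy likelihoods via filter equations.

The likelihood of a pruned (colored) or obscured genealogy under a
population model is the terminal mass of a weight function w propagated by

* a *regular* linear ODE between genealogical event times, whose gain terms
  carry the per-event factor φ = (binomial ratio) × (compatibility), and
* *singular* multiplicative updates at event times.

For colored genealogies (coloring and inline nodes fully specified) the
weight lives on population states.  For obscured genealogies the weight is
extended over hidden colorings — a deme assignment for each extant lineage —
and the regular part additionally marginalizes events whose only trace would
be a hidden inline node (a birth whose unobserved descendants were pruned, or
an unobserved migration).  Both directions (forward from p0, adjoint from a
terminal condition of ones) are available and agree.

Between events of a time-homogeneous model the regular part is a constant
sparse linear system, propagated by the action of the matrix exponential;
time-varying rates fall back to an adaptive ODE integrator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.sparse.linalg import expm_multiply
from scipy.special import gammaln

from .genealogy import (Genealogy, INTERNAL, ObscuredGenealogy, ROOT,
                        SAMPLE, binomial_ratio, event_weight)
from .models import (BIRTH, BIRTH_DEATH, MIGRATION, PopulationModel,
                     SAMPLE as SAMPLE_EC, SAMPLE_DEATH)

_SAMPLE_CLASSES = (SAMPLE_EC, SAMPLE_DEATH)
_BIRTH_CLASSES = (BIRTH, BIRTH_DEATH)


# ---------------------------------------------------------------------------
# vectorized binomial ratio over the state space
# ---------------------------------------------------------------------------

def _log_comb(a, k):
    """log C(a, k) elementwise; -inf where undefined."""
    a = np.asarray(a, dtype=float)
    k = np.asarray(k, dtype=float)
    out = np.full(np.broadcast(a, k).shape, -np.inf)
    ok = (k >= 0) & (a >= k)
    av, kv = np.broadcast_arrays(a, k)
    out[ok] = (gammaln(av[ok] + 1) - gammaln(kv[ok] + 1)
               - gammaln(av[ok] - kv[ok] + 1))
    return out


def _ratio_vec(occ: np.ndarray, l, r, s) -> np.ndarray:
    """binomial_ratio(n(x), l, r, s) for every state (rows of occ)."""
    l = np.asarray(l, int)
    r = np.asarray(r, int)
    s = np.asarray(s, int)
    if np.any(s < 0) or np.any(r - s < 0):
        return np.zeros(occ.shape[0])
    feas = (occ >= l).all(axis=1)
    with np.errstate(invalid="ignore"):
        logs = (_log_comb(occ - l, r - s) - _log_comb(occ, r)).sum(axis=1)
        out = np.where(feas & np.isfinite(logs), np.exp(logs), 0.0)
    return out


# ---------------------------------------------------------------------------
# structural enumeration of hidden transitions (scalar, exact-capable)
# ---------------------------------------------------------------------------

def hidden_source_terms(mark, demes, occ, y_post, exact: bool = False):
    """All (y_pre, φ) contributions to one population jump of ``mark``
    occurring *between* genealogical events, given the post-jump occupancy
    and the post-jump hidden coloring (a deme label per extant lineage).

    Includes the no-involvement term (saturation 0) and, for birth- and
    migration-type marks, the hidden-inline terms in which one observed
    lineage passes invisibly through the event.  Sampling events always
    leave a node, hence contribute no terms here.
    """
    demes = list(demes)
    l = [0] * len(demes)
    for d in y_post:
        l[demes.index(d)] += 1
    ec = mark.event_class
    if ec in _SAMPLE_CLASSES:
        return []
    r = mark.production(demes)
    zero = [0] * len(demes)
    terms = [(tuple(y_post), binomial_ratio(occ, l, r, zero, exact=exact))]
    if ec in _BIRTH_CLASSES:
        par = mark.participants.parent
        for k, j in enumerate(y_post):
            ji = demes.index(j)
            if r[ji] < 1:
                continue
            s = list(zero)
            s[ji] = 1
            y_pre = tuple(y_post[:k]) + (par,) + tuple(y_post[k + 1:])
            terms.append((y_pre, binomial_ratio(occ, l, r, s, exact=exact)))
    elif ec == MIGRATION:
        for (src, dst) in mark.participants.migrations:
            di = demes.index(dst)
            s = list(zero)
            s[di] = 1
            e = list(zero)
            e[di] = 1
            for k, j in enumerate(y_post):
                if j != dst:
                    continue
                y_pre = tuple(y_post[:k]) + (src,) + tuple(y_post[k + 1:])
                terms.append((y_pre,
                              binomial_ratio(occ, l, e, s, exact=exact)))
    return terms


# ---------------------------------------------------------------------------
# tree schedule
# ---------------------------------------------------------------------------

class _Event:
    """A singular update: genealogical nodes or a scheduled-time event."""

    def __init__(self, time, kind, nodes=None, scheduled=None):
        self.time = time
        self.kind = kind               # "nodes" or scheduled-event kind
        self.nodes = nodes or []
        self.scheduled = scheduled


@dataclass
class _Interval:
    t0: float
    t1: float
    edges: tuple[int, ...]         # child-node ids of live edges, sorted
    demes: tuple[str | None, ...]  # tree deme of each edge (colored trees)


def _binomial_sample_factor(se, nd_vec: np.ndarray, k: int) -> np.ndarray:
    """Per-state factor C(n_d, k) ρ^k (1−ρ)^{n_d−k} for a scheduled
    binomial sampling of k observed lineages."""
    rho = se.prob
    if rho == 0.0:
        return np.where(nd_vec >= 0, 1.0, 0.0) if k == 0 else \
            np.zeros_like(nd_vec, dtype=float)
    logf = _log_comb(nd_vec, k) + k * math.log(rho)
    if rho < 1.0:
        logf = logf + (nd_vec - k) * math.log1p(-rho)
    else:
        logf = np.where(nd_vec == k, logf, -np.inf)
    return np.where(np.isfinite(logf), np.exp(logf), 0.0)


class TreeSchedule:
    """Intervals and singular events of a genealogy, in time order."""

    def __init__(self, tree: Genealogy, model: PopulationModel):
        self.tree = tree
        T = tree.horizon
        sched = []
        consumed_times = set()
        for ev in model.scheduled:
            ts = T if ev.time is None else float(ev.time)
            if ts > T:
                continue
            nodes = [nd for nd in tree.nodes_at(ts) if nd.kind == SAMPLE]
            sched.append(_Event(ts, ev.kind, nodes=nodes, scheduled=ev))
            consumed_times.add(ts)
        node_times = [t for t in tree.event_times()
                      if t > 0 and t not in consumed_times]
        events = [
            _Event(t, "nodes", nodes=tree.nodes_at(t)) for t in node_times
        ] + sched
        events.sort(key=lambda e: (e.time, e.kind != "nodes"))
        self.events = events
        edges = tree.edges()
        knots = [0.0] + [e.time for e in events] + [T]
        self.intervals = []
        for a, b in zip(knots[:-1], knots[1:]):
            mid = 0.5 * (a + b) if b > a else a
            live = sorted(cid for (s, e, _, cid) in edges
                          if s <= mid < e) if b > a else []
            self.intervals.append(_Interval(
                a, b, tuple(live),
                tuple(tree.nodes[c].deme for c in live)))
        self.T = T


# ---------------------------------------------------------------------------
# the filter engine
# ---------------------------------------------------------------------------

class FilterResult(float):
    """Log-likelihood with diagnostics attached."""
    boundary_mass: float = 0.0

    def __new__(cls, value, boundary_mass=0.0):
        obj = super().__new__(cls, value)
        obj.boundary_mass = boundary_mass
        return obj


class _Engine:
    def __init__(self, model: PopulationModel, tree: Genealogy,
                 hidden: bool, rtol: float, atol: float,
                 max_joint: int = 2_000_000):
        self.model = model
        self.tree = tree
        self.hidden = hidden
        self.rtol, self.atol = rtol, atol
        self.demes = list(model.demes)
        self.nd = len(self.demes)
        self.space = model.state_space
        self.states = self.space.states
        self.ns = len(self.states)
        self.occ = np.array([model.occupancy(x) for x in self.states],
                            dtype=int)
        self.sched = TreeSchedule(tree, model)
        if not hidden:
            missing = [iv for iv in self.sched.intervals
                       if None in iv.demes]
            if missing:
                raise ValueError("colored filtering needs deme labels on "
                                 "every branch; use the obscured filter")
        maxL = max((len(iv.edges) for iv in self.sched.intervals), default=0)
        if hidden and self.ns * self.nd ** maxL > max_joint:
            raise ValueError(
                f"hidden coloring space too large: {self.ns} states x "
                f"{self.nd}^{maxL} colorings")
        # per-mark transition tables
        self.tables = []
        for m in model.marks:
            dst = np.full(self.ns, -1, dtype=np.int64)
            for i, x in enumerate(self.states):
                x2 = tuple(m.state_update(x))
                dst[i] = self.space.index.get(x2, -1)
            self.tables.append((m, dst))
        self._rate_cache: dict[tuple, np.ndarray] = {}
        self._A_cache: dict[int, sparse.csr_matrix] = {}
        # truncation-boundary states: positive rate but update leaves space
        bnd = np.zeros(self.ns, dtype=bool)
        for m, dst in self.tables:
            rv = self._rates(m, 0.0)
            bnd |= (dst < 0) & (rv > 0)
        self.boundary = bnd

    # -- rates -------------------------------------------------------------
    def _rates(self, mark, t) -> np.ndarray:
        key = (mark.name, None if self.model.time_homogeneous else t)
        if key not in self._rate_cache:
            self._rate_cache[key] = np.array(
                [mark.rate(t, x) for x in self.states], dtype=float)
        return self._rate_cache[key]

    def _loss_vec(self, t) -> np.ndarray:
        lam = np.zeros(self.ns)
        for m, _ in self.tables:
            if not m.observed_only:
                lam += self._rates(m, t)
        return lam

    # -- colorings ----------------------------------------------------------
    def _yspace(self, interval: _Interval) -> list[tuple[str, ...]]:
        L = len(interval.edges)
        if self.hidden:
            return [tuple(c) for c in itertools.product(self.demes, repeat=L)]
        return [tuple(interval.demes)]

    def _lvec(self, y) -> np.ndarray:
        l = np.zeros(self.nd, dtype=int)
        for d in y:
            l[self.demes.index(d)] += 1
        return l

    # -- regular part --------------------------------------------------------
    def _generator(self, i_interval: int, t: float) -> sparse.csr_matrix:
        if self.model.time_homogeneous and i_interval in self._A_cache:
            return self._A_cache[i_interval]
        iv = self.sched.intervals[i_interval]
        ys = self._yspace(iv)
        yindex = {y: i for i, y in enumerate(ys)}
        ny = len(ys)
        njoint = self.ns * ny
        rows, cols, vals = [], [], []
        lam = self._loss_vec(t)
        idx = np.arange(self.ns)
        # diagonal loss for every coloring
        for yi in range(ny):
            rows.append(idx * ny + yi)
            cols.append(idx * ny + yi)
            vals.append(-lam)
        lvecs = [self._lvec(y) for y in ys]
        for m, dst in self.tables:
            if m.observed_only or m.event_class in _SAMPLE_CLASSES:
                continue
            rv = self._rates(m, t)
            ok = (dst >= 0) & (rv > 0)
            if not ok.any():
                continue
            src = idx[ok]
            tgt = dst[ok]
            r = np.array(m.production(self.demes), dtype=int)
            zero = np.zeros(self.nd, dtype=int)
            for yi, y in enumerate(ys):
                l = lvecs[yi]
                # saturation-0 term: the event misses the genealogy
                R0 = _ratio_vec(self.occ, l, r, zero)
                rows.append(tgt * ny + yi)
                cols.append(src * ny + yi)
                vals.append(rv[ok] * R0[tgt])
                if not self.hidden:
                    continue
                # hidden-inline participation of one observed lineage
                ec = m.event_class
                if ec in _BIRTH_CLASSES:
                    par = m.participants.parent
                    for k, dj in enumerate(y):
                        ji = self.demes.index(dj)
                        if r[ji] < 1:
                            continue
                        s = zero.copy()
                        s[ji] = 1
                        y_pre = y[:k] + (par,) + y[k + 1:]
                        yp = yindex[y_pre]
                        R1 = _ratio_vec(self.occ, l, r, s)
                        rows.append(tgt * ny + yi)
                        cols.append(src * ny + yp)
                        vals.append(rv[ok] * R1[tgt])
                elif ec == MIGRATION:
                    for (sd, dd) in m.participants.migrations:
                        di = self.demes.index(dd)
                        e = zero.copy()
                        e[di] = 1
                        R1 = _ratio_vec(self.occ, l, e, e)
                        for k, dj in enumerate(y):
                            if dj != dd:
                                continue
                            y_pre = y[:k] + (sd,) + y[k + 1:]
                            yp = yindex[y_pre]
                            rows.append(tgt * ny + yi)
                            cols.append(src * ny + yp)
                            vals.append(rv[ok] * R1[tgt])
        A = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows),
                                    np.concatenate(cols))),
            shape=(njoint, njoint))
        if self.model.time_homogeneous:
            self._A_cache[i_interval] = A
        return A

    # -- singular part --------------------------------------------------------
    def _event_matrix(self, ie: int) -> sparse.csr_matrix:
        ev = self.sched.events[ie]
        pre = self.sched.intervals[ie]
        post = self.sched.intervals[ie + 1]
        ys_pre = self._yspace(pre)
        ys_post = self._yspace(post)
        ypre_index = {y: i for i, y in enumerate(ys_pre)}
        ny_pre, ny_post = len(ys_pre), len(ys_post)
        tree = self.tree
        ch = tree.children_map()
        pre_ids, post_ids = list(pre.edges), list(post.edges)
        shared = [cid for cid in post_ids if cid in pre_ids]
        created = [cid for cid in post_ids if cid not in pre_ids]
        consumed = [cid for cid in pre_ids if cid not in post_ids]
        pre_pos = {cid: i for i, cid in enumerate(pre_ids)}
        post_pos = {cid: i for i, cid in enumerate(post_ids)}
        rows, cols, vals = [], [], []
        idx = np.arange(self.ns)

        def emit(y_pre, y_post, src, tgt, coef):
            yp, yq = ypre_index[y_pre], ys_post.index(y_post)
            rows.append(tgt * ny_post + yq)
            cols.append(src * ny_pre + yp)
            vals.append(coef)

        if ev.kind == "nodes":
            self._node_event_terms(ev, pre, post, ch, pre_pos, post_pos,
                                   consumed, created, ys_post, emit, idx)
        else:
            self._scheduled_event_terms(ev, pre, post, pre_pos, ys_post,
                                        emit, idx)
        if not rows:
            return sparse.csr_matrix((self.ns * ny_post, self.ns * ny_pre))
        return sparse.csr_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ns * ny_post, self.ns * ny_pre))

    def _node_event_terms(self, ev, pre, post, ch, pre_pos, post_pos,
                          consumed, created, ys_post, emit, idx):
        t = ev.time
        nodes = ev.nodes
        kinds = {nd.kind for nd in nodes}
        for m, dst in self.tables:
            rv = self._rates(m, t)
            ok = (dst >= 0) & (rv > 0)
            if not ok.any():
                continue
            src = idx[ok]
            tgt = dst[ok]
            P = m.participants
            ec = m.event_class
            r = np.array(m.production(self.demes), dtype=int)
            if ec in _SAMPLE_CLASSES and kinds == {SAMPLE}:
                if len(nodes) != len(P.samples):
                    continue
                d = P.samples[0]
                inline_children = [c for nd in nodes for c in ch[nd.id]]
                if ec == SAMPLE_DEATH and inline_children:
                    continue
                sample_in = [nd.id for nd in nodes]
                for y_post in ys_post:
                    if any(y_post[post_pos[c]] != d for c in inline_children):
                        continue
                    y_pre = self._lift(y_post, pre, post, post_pos,
                                       {cid: d for cid in sample_in})
                    if y_pre is None:
                        continue
                    s = np.zeros(self.nd, dtype=int)
                    s[self.demes.index(d)] = len(inline_children)
                    l = self._lvec(y_post)
                    R = _ratio_vec(self.occ, l, r, s)
                    emit(y_pre, y_post, src, tgt, rv[ok] * R[tgt])
            elif ec in _BIRTH_CLASSES and kinds == {INTERNAL} \
                    and len(nodes) == 1:
                nd = nodes[0]
                kids = ch[nd.id]
                if not kids or set(created) != set(kids) or \
                        consumed != [nd.id]:
                    continue
                par = P.parent
                for y_post in ys_post:
                    s = np.zeros(self.nd, dtype=int)
                    for c in kids:
                        s[self.demes.index(y_post[post_pos[c]])] += 1
                    if np.any(s > r):
                        continue
                    y_pre = self._lift(y_post, pre, post, post_pos,
                                       {nd.id: par})
                    if y_pre is None:
                        continue
                    l = self._lvec(y_post)
                    R = _ratio_vec(self.occ, l, r, s)
                    emit(y_pre, y_post, src, tgt, rv[ok] * R[tgt])
            elif ec == MIGRATION and kinds == {INTERNAL} and len(nodes) == 1:
                nd = nodes[0]
                kids = ch[nd.id]
                if len(kids) != 1 or consumed != [nd.id] or \
                        set(created) != set(kids):
                    continue
                (sd, dd), = P.migrations
                di = self.demes.index(dd)
                for y_post in ys_post:
                    if y_post[post_pos[kids[0]]] != dd:
                        continue
                    y_pre = self._lift(y_post, pre, post, post_pos,
                                       {nd.id: sd})
                    if y_pre is None:
                        continue
                    e = np.zeros(self.nd, dtype=int)
                    e[di] = 1
                    l = self._lvec(y_post)
                    R = _ratio_vec(self.occ, l, e, e)
                    emit(y_pre, y_post, src, tgt, rv[ok] * R[tgt])

    def _lift(self, y_post, pre, post, post_pos, forced: dict):
        """Build the pre-event coloring implied by y_post: shared edges keep
        their deme, consumed edges take the forced demes.  Returns None if a
        colored tree contradicts the assignment."""
        y_pre = []
        for cid, tree_deme in zip(pre.edges, pre.demes):
            if cid in forced:
                d = forced[cid]
            elif cid in post_pos:
                d = y_post[post_pos[cid]]
            else:
                return None  # pre edge vanished without an event node
            if not self.hidden and tree_deme is not None and d != tree_deme:
                return None
            y_pre.append(d)
        return tuple(y_pre)

    def _scheduled_event_terms(self, ev, pre, post, pre_pos, ys_post,
                               emit, idx):
        se = ev.scheduled
        d = se.deme
        di = self.demes.index(d)
        k = len(ev.nodes)
        sample_ids = {nd.id for nd in ev.nodes}
        post_pos = {cid: i for i, cid in enumerate(post.edges)}
        # sampled lineages terminate at the event (leaf sample nodes)
        for y_post in ys_post:
            y_pre = self._lift(y_post, pre, post, post_pos,
                               {cid: d for cid in sample_ids})
            if y_pre is None:
                continue
            l_pre = self._lvec(y_pre)
            feas = (self.occ >= l_pre).all(axis=1)
            nd_vec = self.occ[:, di]
            f = _binomial_sample_factor(se, nd_vec, k) if \
                se.kind == "binomial_sample" else None
            if se.kind == "conditioned_sample":
                f = np.where(nd_vec >= k, 1.0, 0.0)
            elif f is None:
                raise ValueError(f"unknown scheduled event {se.kind!r}")
            f = np.where(feas, f, 0.0)
            live = f > 0
            src = idx[live]
            emit(y_pre, y_post, src, src, f[live])

    # -- propagation ----------------------------------------------------------
    def _initial(self) -> np.ndarray:
        iv0 = self.sched.intervals[0]
        ys = self._yspace(iv0)
        w = np.zeros(self.ns * len(ys))
        for x, p in self.model.p0.items():
            if p <= 0:
                continue
            i = self.space.index[tuple(x)]
            n = self.occ[i]
            for yi, y in enumerate(ys):
                if (n >= self._lvec(y)).all():
                    w[i * len(ys) + yi] = p
        return w

    def _propagate_interval(self, i, vec, transpose):
        iv = self.sched.intervals[i]
        dt = iv.t1 - iv.t0
        if dt <= 0 or not np.any(vec):
            return vec
        A = self._generator(i, iv.t0)
        if transpose:
            A = A.T.tocsr()
        if self.model.time_homogeneous:
            return expm_multiply(A * dt, vec)

        def rhs(t, v):
            G = self._generator(i, t)
            # adjoint: dF/ds = -A(s)^T F, integrated from t1 down to t0
            return -(G.T @ v) if transpose else (G @ v)

        span = (iv.t1, iv.t0) if transpose else (iv.t0, iv.t1)
        sol = solve_ivp(rhs, span, vec, method="LSODA",
                        rtol=self.rtol, atol=self.atol)
        return sol.y[:, -1]

    def loglik(self, direction: str = "forward") -> FilterResult:
        nseg = len(self.sched.intervals)
        logscale = 0.0
        if direction == "forward":
            w = self._initial()
            for i in range(nseg):
                w = self._propagate_interval(i, w, transpose=False)
                if i < nseg - 1:
                    w = self._event_matrix(i) @ w
                tot = w.sum()
                if tot <= 0:
                    return FilterResult(-math.inf)
                logscale += math.log(tot)
                w = w / tot
            ys_last = self._yspace(self.sched.intervals[-1])
            bmass = float(w.reshape(self.ns, len(ys_last))[self.boundary].sum())
            return FilterResult(logscale, boundary_mass=bmass)
        # adjoint: integrate backward from F(T) = 1
        ys_last = self._yspace(self.sched.intervals[-1])
        F = np.ones(self.ns * len(ys_last))
        for i in range(nseg - 1, -1, -1):
            F = self._propagate_interval(i, F, transpose=True)
            if i > 0:
                F = self._event_matrix(i - 1).T @ F
            m = F.max()
            if m <= 0:
                return FilterResult(-math.inf)
            logscale += math.log(m)
            F = F / m
        w0 = self._initial()
        val = float(w0 @ F)
        if val <= 0:
            return FilterResult(-math.inf)
        bmass = float(w0[np.repeat(self.boundary,
                                   len(self._yspace(self.sched.intervals[0]))
                                   )].sum())
        return FilterResult(logscale + math.log(val), boundary_mass=bmass)


def _is_obscured(tree: Genealogy) -> bool:
    if isinstance(tree, ObscuredGenealogy):
        return True
    return all(nd.deme is None for nd in tree.nodes.values()
               if nd.kind != ROOT)


def filter_forward(model: PopulationModel, tree: Genealogy,
                   rtol: float = 1e-8, atol: float = 1e-12) -> FilterResult:
    """Log-likelihood of a genealogy by forward filtering.

    Colored pruned genealogies are filtered over population states; obscured
    genealogies over states × hidden colorings (deme marginalization).
    """
    hidden = _is_obscured(tree)
    return _Engine(model, tree, hidden, rtol, atol).loglik("forward")


def filter_adjoint(model: PopulationModel, tree: Genealogy,
                   rtol: float = 1e-8, atol: float = 1e-12) -> FilterResult:
    """Log-likelihood by backward (adjoint) filtering; equals the forward
    value up to integration error."""
    hidden = _is_obscured(tree)
    return _Engine(model, tree, hidden, rtol, atol).loglik("adjoint")


def filter_obscured(model: PopulationModel, z: Genealogy,
                    rtol: float = 1e-8, atol: float = 1e-12) -> FilterResult:
    """Log-likelihood of an obscured genealogy (hidden-coloring filter)."""
    return _Engine(model, z, True, rtol, atol).loglik("forward")


# ---------------------------------------------------------------------------
# Likelihood given a history
# ---------------------------------------------------------------------------

def loglik_given_history(model: PopulationModel, p: Genealogy, h) -> float:
    """Log conditional probability of a colored pruned genealogy given one
    full population history: Σ_{jumps} log φ, −∞ unless every genealogical
    event time appears among the history's jump times."""
    if abs(p.horizon - h.horizon) > 1e-9:
        raise ValueError("genealogy and history horizons differ")
    ev_p = set(p.event_times())
    sched_times = {h.horizon if s.time is None else s.time
                   for s in model.scheduled}
    ev_p -= sched_times
    if not ev_p.issubset(set(h.times)):
        return -math.inf
    marks = {m.name: m for m in model.marks}
    ll = 0.0
    for t, uname, x in zip(h.times, h.marks, h.states):
        phi = event_weight(model, marks[uname], x, p, t)
        if phi <= 0:
            return -math.inf
        ll += math.log(phi)
    ll += _scheduled_factor(model, p, h)
    return ll


def _scheduled_factor(model, p, h) -> float:
    out = 0.0
    for se in model.scheduled:
        ts = h.horizon if se.time is None else se.time
        nodes = [nd for nd in p.nodes_at(ts) if nd.kind == SAMPLE]
        k = len(nodes)
        x = h.state_at(ts)
        n_d = model.occupancy(x)[list(model.demes).index(se.deme)]
        if se.kind == "binomial_sample":
            rho = se.prob
            if n_d < k or (rho == 0 and k > 0):
                return -math.inf
            out += (_log_comb(n_d, k).item()
                    + (k * math.log(rho) if k else 0.0)
                    + ((n_d - k) * math.log1p(-rho) if rho < 1
                       else (-math.inf if n_d > k else 0.0)))
        elif se.kind == "conditioned_sample":
            if n_d < k:
                return -math.inf
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo estimator (forced-history importance sampling)
# ---------------------------------------------------------------------------

@dataclass
class MCEstimate:
    loglik: float
    se_natural: float      # standard error of the natural-scale mean
    mean_natural: float
    n: int


def montecarlo_loglik(model: PopulationModel, p: Genealogy,
                      n_histories: int, seed: int) -> MCEstimate:
    """Unbiased Monte-Carlo estimate of the colored-genealogy likelihood.

    Histories are simulated from the population process with jumps *forced*
    at the genealogical event times (uniform choice among compatible marks,
    importance weight m_t · α_u · φ_u); sample-type hazards are removed from
    the proposal and restored as an exact exp(−∫Σα dt) factor.  The mean of
    the weights estimates the filter likelihood; comparison against
    the deterministic filter is the standard cross-check.
    """
    if not model.time_homogeneous:
        raise ValueError("Monte-Carlo estimator requires time-homogeneous "
                         "rates")
    rng = np.random.default_rng(seed)
    hidden = _is_obscured(p)
    if hidden and len(model.demes) > 1:
        raise ValueError("Monte-Carlo estimator supports colored genealogies "
                         "and single-deme obscured genealogies")
    eng = _Engine(model, p, hidden=hidden, rtol=1e-8, atol=1e-12)
    sched = eng.sched
    demes = eng.demes
    marks = list(model.marks)
    free_marks = [m for m in marks
                  if m.event_class not in _SAMPLE_CLASSES
                  and not m.observed_only]
    free_dst = []
    name2dst = {m.name: dst for m, dst in eng.tables}
    for m in free_marks:
        free_dst.append(name2dst[m.name])
    # per-interval colorings of the live edges (unique for these tree kinds)
    iv_colorings = []
    for iv in sched.intervals:
        if hidden:
            iv_colorings.append(tuple(demes[0] for _ in iv.edges))
        else:
            iv_colorings.append(tuple(iv.demes))
    rate_cache: dict = {}
    phi_cache: dict = {}

    def rates_at(xi):
        if xi not in rate_cache:
            x = eng.states[xi]
            fr = np.array([m.rate(0.0, x) for m in free_marks])
            lam_s = sum(m.rate(0.0, x) for m in marks
                        if m.event_class in _SAMPLE_CLASSES
                        and not m.observed_only)
            rate_cache[xi] = (fr, fr.sum(), lam_s)
        return rate_cache[xi]

    def free_phi(mi, xj, ii):
        """Marginal φ of a free jump: saturation-0 term, plus hidden-inline
        terms when the genealogy coloring is marginalized."""
        key = (mi, xj, ii)
        if key not in phi_cache:
            m = free_marks[mi]
            occ = tuple(int(v) for v in eng.occ[xj])
            if hidden:
                phi = sum(w for _, w in hidden_source_terms(
                    m, demes, occ, iv_colorings[ii]))
            else:
                y = iv_colorings[ii]
                l = [sum(1 for d in y if d == dm) for dm in demes]
                phi = binomial_ratio(occ, l, m.production(demes),
                                     [0] * eng.nd)
            phi_cache[key] = float(phi)
        return phi_cache[key]

    event_opts_cache: dict = {}

    def event_options(ie, xi):
        key = (ie, xi)
        if key in event_opts_cache:
            return event_opts_cache[key]
        B = eng._event_matrix(ie).tocsc()  # ny = 1 on both sides here
        col = B.getcol(xi).tocoo()
        opts = [(int(r), float(v)) for r, v in zip(col.row, col.data)
                if v > 0]
        event_opts_cache[key] = opts
        return opts

    x0s = list(model.p0)
    p0w = np.array([model.p0[x] for x in x0s])
    p0w = p0w / p0w.sum()
    logw = np.full(n_histories, -np.inf)
    nseg = len(sched.intervals)
    for it in range(n_histories):
        xi = eng.space.index[x0s[rng.choice(len(x0s), p=p0w)]]
        lw = 0.0
        dead = False
        for ii in range(nseg):
            iv = sched.intervals[ii]
            t = iv.t0
            while True:
                fr, tot, lam_s = rates_at(xi)
                dt = rng.exponential(1.0 / tot) if tot > 0 else math.inf
                t2 = min(iv.t1, t + dt)
                lw -= lam_s * (t2 - t)
                t = t2
                if t >= iv.t1:
                    break
                mi = int(rng.choice(len(fr), p=fr / tot))
                xj = int(free_dst[mi][xi])
                if xj < 0:
                    dead = True
                    break
                phi = free_phi(mi, xj, ii)
                if phi <= 0:
                    dead = True
                    break
                lw += math.log(phi)
                xi = xj
            if dead:
                break
            if ii < nseg - 1:
                opts = event_options(ii, xi)
                if not opts:
                    dead = True
                    break
                j = int(rng.integers(len(opts)))
                xj, coef = opts[j]
                lw += math.log(len(opts)) + math.log(coef)
                xi = xj
        if not dead:
            logw[it] = lw
    mx = logw.max()
    if not np.isfinite(mx):
        return MCEstimate(-math.inf, 0.0, 0.0, n_histories)
    w = np.exp(logw - mx)
    mean = w.mean()
    se = w.std(ddof=1) / math.sqrt(n_histories)
    return MCEstimate(mx + math.log(mean), float(se * math.exp(mx)),
                      float(mean * math.exp(mx)), n_histories)
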