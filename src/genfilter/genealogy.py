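"""Genealogy data structures, pruning/obscuring, and combinatorial weights.

A genealogy is a time-stamped forest.  Each node records the deme of the
*edge above it* (the lineage segment ending at that node); root nodes anchor
trees at time 0 and carry no deme.  Conventions:

* paths are càdlàg: values at an event time are post-event; an edge spans the
  half-open interval ``[t(parent), t(node))``;
* sample labels are assigned in collection order and the likelihood computed
  downstream is that of the *ordered* samples (simultaneous samples are
  ordered by deme, then draw order).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Sequence

import dendropy

ROOT = "root"
INTERNAL = "internal"
SAMPLE = "sample"
TIP = "tip"


@dataclass
class Node:
    id: int
    time: float
    kind: str
    deme: str | None = None  # deme of the edge ending at this node
    parent: int | None = None
    label: str | None = None


class Genealogy:
    """Mutable node-table representation of a genealogy forest."""

    def __init__(self, horizon: float, nodes: Iterable[Node] = ()):
        self.horizon = float(horizon)
        self.nodes: dict[int, Node] = {}
        self._next_id = 0
        for nd in nodes:
            self.nodes[nd.id] = nd
            self._next_id = max(self._next_id, nd.id + 1)

    # -- construction -----------------------------------------------------
    def add_node(self, time, kind, deme=None, parent=None, label=None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.nodes[nid] = Node(nid, float(time), kind, deme, parent, label)
        return nid

    def copy(self):
        g = self.__class__.__new__(self.__class__)
        g.horizon = self.horizon
        g.nodes = {i: replace(nd) for i, nd in self.nodes.items()}
        g._next_id = self._next_id
        return g

    # -- derived structure -------------------------------------------------
    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in self.nodes}
        for nd in self.nodes.values():
            if nd.parent is not None:
                ch[nd.parent].append(nd.id)
        return ch

    def roots(self) -> list[int]:
        return [i for i, nd in self.nodes.items() if nd.parent is None]

    def n_children(self, nid: int) -> int:
        return sum(1 for nd in self.nodes.values() if nd.parent == nid)

    def event_times(self) -> list[float]:
        """Sorted distinct times of internal and sample nodes (ev(G))."""
        return sorted({nd.time for nd in self.nodes.values()
                       if nd.kind in (INTERNAL, SAMPLE)})

    def nodes_at(self, t: float) -> list[Node]:
        return [nd for nd in self.nodes.values()
                if nd.time == t and nd.kind in (INTERNAL, SAMPLE)]

    def edges(self) -> list[tuple[float, float, str | None, int]]:
        """Edges as (t_start, t_end, deme, child_node_id).

        The edge above node ``c`` spans ``[t(parent(c)), t(c))`` and carries
        ``c.deme``.
        """
        out = []
        for nd in self.nodes.values():
            if nd.parent is None:
                continue
            p = self.nodes[nd.parent]
            out.append((p.time, nd.time, nd.deme, nd.id))
        return out

    def edges_crossing(self, t: float) -> list[int]:
        """Child-node ids of edges alive at time t (half-open convention)."""
        return [cid for (a, b, _, cid) in self.edges() if a <= t < b]

    def samples(self) -> list[Node]:
        return sorted((nd for nd in self.nodes.values() if nd.kind == SAMPLE),
                      key=lambda nd: (nd.time, nd.label or ""))

    def validate(self) -> list[str]:
        errs = []
        for nd in self.nodes.values():
            if nd.parent is not None:
                p = self.nodes.get(nd.parent)
                if p is None:
                    errs.append(f"node {nd.id}: dangling parent {nd.parent}")
                elif p.time > nd.time:
                    errs.append(f"node {nd.id}: parent time {p.time} > {nd.time}")
            else:
                if nd.kind == ROOT and nd.time != 0.0:
                    errs.append(f"root {nd.id} not at time 0")
            if not (0.0 <= nd.time <= self.horizon):
                errs.append(f"node {nd.id}: time {nd.time} outside [0, T]")
        return errs


class PrunedGenealogy(Genealogy):
    """Sample-spanning colored genealogy: no tips, all leaves are samples."""


class ObscuredGenealogy(Genealogy):
    """Tree structure only: demes erased, inline internal nodes removed."""


# ---------------------------------------------------------------------------
# pruning and obscuring
# ---------------------------------------------------------------------------

def prune(g: Genealogy) -> PrunedGenealogy:
    """Drop tip nodes, then recursively drop childless non-sample nodes.

    Sample nodes are never removed; internal nodes left with a single child
    (inline nodes) are retained, as is the coloring.
    """
    nodes = {i: replace(nd) for i, nd in g.nodes.items()}
    nchild = Counter(nd.parent for nd in nodes.values() if nd.parent is not None)
    doomed = [i for i, nd in nodes.items() if nd.kind == TIP]
    while doomed:
        i = doomed.pop()
        nd = nodes.pop(i)
        if nd.parent is not None:
            nchild[nd.parent] -= 1
            pn = nodes.get(nd.parent)
            if pn is not None and nchild[nd.parent] == 0 and pn.kind != SAMPLE:
                doomed.append(nd.parent)
    p = PrunedGenealogy(g.horizon)
    p.nodes = nodes
    p._next_id = g._next_id
    return p


def obscure(p: PrunedGenealogy) -> ObscuredGenealogy:
    """Erase demes and splice out inline (single-child internal) nodes."""
    nodes = {i: replace(nd, deme=None) for i, nd in p.nodes.items()}
    nchild = Counter(nd.parent for nd in nodes.values() if nd.parent is not None)
    inline = [i for i, nd in nodes.items()
              if nd.kind == INTERNAL and nchild[i] == 1]
    for i in inline:
        nd = nodes.pop(i)
        for other in nodes.values():
            if other.parent == i:
                other.parent = nd.parent
    z = ObscuredGenealogy(p.horizon)
    z.nodes = nodes
    z._next_id = p._next_id
    return z


# ---------------------------------------------------------------------------
# lineage count, saturation, local structure
# ---------------------------------------------------------------------------

def lineage_count(p: Genealogy, t: float,
                  demes: Sequence[str] | None = None):
    """Per-deme number of edges alive at time t (post-event convention)."""
    if not (0.0 <= t <= p.horizon):
        raise ValueError(f"time {t} outside [0, {p.horizon}]")
    cnt: Counter = Counter()
    for (a, b, deme, _) in p.edges():
        if a <= t < b:
            cnt[deme] += 1
    if demes is None:
        return dict(cnt)
    return [cnt.get(d, 0) for d in demes]


def saturation(p: Genealogy, t: float,
               demes: Sequence[str] | None = None):
    """Per-deme number of edges emerging from nodes at exactly time t."""
    cnt: Counter = Counter()
    for nd in p.nodes.values():
        if nd.parent is not None:
            parent = p.nodes[nd.parent]
            if parent.time == t and parent.kind in (INTERNAL, SAMPLE):
                cnt[nd.deme] += 1
    if demes is None:
        return dict(cnt)
    return [cnt.get(d, 0) for d in demes]


@dataclass(frozen=True)
class LocalNode:
    """Local structure of one genealogy node: its kind, the deme of the edge
    arriving into it, and the demes of the edges emerging from it."""
    kind: str
    node_id: int
    in_deme: str | None
    out_demes: tuple[str | None, ...]


def local_structure(p: Genealogy, t: float) -> list[LocalNode]:
    """Local structure of p at time t: one entry per internal/sample node."""
    ch = p.children_map()
    out = []
    for nd in p.nodes.values():
        if nd.time != t or nd.kind not in (INTERNAL, SAMPLE):
            continue
        outs = tuple(sorted((p.nodes[c].deme for c in ch[nd.id]),
                            key=lambda d: (d is None, d)))
        out.append(LocalNode(nd.kind, nd.id, nd.deme, outs))
    return sorted(out, key=lambda ln: ln.node_id)


# ---------------------------------------------------------------------------
# binomial ratio and per-event weight
# ---------------------------------------------------------------------------

def _log_binom(n: int, k: int) -> float:
    return (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1))


def binomial_ratio(n, l, r, s, exact: bool = False):
    """The combinatorial event weight  Π_i C(n_i−l_i, r_i−s_i) / Π_i C(n_i, r_i).

    Arguments are per-deme integer vectors (any common length).  Returns 0
    unless ``n_i ≥ l_i`` and ``r_i ≥ s_i ≥ 0`` and every binomial is
    well-defined.  Computed in log space; with ``exact=True`` returns a
    :class:`fractions.Fraction` (valid for any size, intended for small n).
    """
    n, l, r, s = (list(map(int, v)) for v in (n, l, r, s))
    if not (len(n) == len(l) == len(r) == len(s)):
        raise ValueError("deme vectors must share a length")
    for ni, li, ri, si in zip(n, l, r, s):
        if si < 0 or ri < si or ni < li:
            return Fraction(0) if exact else 0.0
        if ri - si > ni - li or ri > ni:
            return Fraction(0) if exact else 0.0
    if exact:
        num = den = Fraction(1)
        for ni, li, ri, si in zip(n, l, r, s):
            num *= math.comb(ni - li, ri - si)
            den *= math.comb(ni, ri)
        return num / den
    acc = 0.0
    for ni, li, ri, si in zip(n, l, r, s):
        acc += _log_binom(ni - li, ri - si) - _log_binom(ni, ri)
    return math.exp(acc)


def coalescent_intervals(z: Genealogy) -> dict[int, float]:
    """Total duration spent at each (total) lineage count.

    ``s_i`` is the Lebesgue measure of ``{t : ℓ(t) = i}`` where ℓ is the
    total number of edges alive, ignoring demes.
    """
    edges = z.edges()
    if not edges:
        return {}
    breaks = sorted({a for a, *_ in edges} | {b for _, b, *_ in edges})
    out: dict[int, float] = {}
    for a, b in zip(breaks[:-1], breaks[1:]):
        k = sum(1 for (s, e, *_ ) in edges if s <= a < e)
        if b > a:
            out[k] = out.get(k, 0.0) + (b - a)
    return out


# ---------------------------------------------------------------------------
# compatibility and event weight (rule table over local structure)
# ---------------------------------------------------------------------------

def compatibility(u, p: Genealogy, t: float) -> int:
    """Indicator: can the local structure of p at t be generated by mark u?

    Implemented as an explicit rule table over (event class, node kinds,
    deme pattern).  At a non-node time, any mark whose events can leave the
    pruned genealogy untouched is compatible (everything except sample-type
    marks, whose sample nodes are never pruned).
    """
    local = local_structure(p, t)
    ec = u.event_class
    if not local:
        # an event leaving no trace: impossible only for sampling events
        return 0 if ec in ("sample", "sample_death") else 1
    kinds = {ln.kind for ln in local}
    if kinds == {SAMPLE}:
        if ec not in ("sample", "sample_death"):
            return 0
        k = len(local)
        if k != len(u.participants.samples):
            return 0
        for ln in local:
            if ln.in_deme is not None and u.participants.samples and \
               set(u.participants.samples) != {None}:
                if ln.in_deme not in u.participants.samples:
                    return 0
            if ec == "sample_death" and ln.out_demes:
                return 0  # sampled lineage dies: sample node must be terminal
            if ec == "sample" and ln.out_demes:
                if len(ln.out_demes) != 1:
                    return 0
                if ln.in_deme is not None and ln.out_demes[0] != ln.in_deme:
                    return 0  # sampling does not move the lineage
        # componentwise s <= r for colored structure
        demes = u.production_demes
        if demes is not None:
            s = _saturation_of_local(local, demes)
            r = u.production(demes)
            if any(si > ri for si, ri in zip(s, r)):
                return 0
        return 1
    if kinds == {INTERNAL}:
        if len(local) != 1:
            return 0  # at most one non-sample event per instant
        ln = local[0]
        if not ln.out_demes:
            return 0
        if ec in ("birth", "birth_death"):
            par = u.participants.parent
            if ln.in_deme is not None and par is not None and ln.in_deme != par:
                return 0
            demes = u.production_demes
            if demes is not None and ln.in_deme is not None:
                s = [sum(1 for d in ln.out_demes if d == dm) for dm in demes]
                r = u.production(demes)
                if any(si > ri for si, ri in zip(s, r)):
                    return 0
            return 1
        if ec == "migration":
            if len(ln.out_demes) != 1:
                return 0
            (src, dst), = u.participants.migrations or ((None, None),)
            if ln.in_deme is not None and src is not None and ln.in_deme != src:
                return 0
            if ln.out_demes[0] is not None and dst is not None and \
               ln.out_demes[0] != dst:
                return 0
            return 1
        return 0
    return 0


def _saturation_of_local(local: list[LocalNode], demes) -> list[int]:
    s = [0] * len(demes)
    for ln in local:
        for d in ln.out_demes:
            if d is not None:
                s[list(demes).index(d)] += 1
    return s


def event_weight(model, u, x, p: Genealogy, t: float) -> float:
    """Per-event likelihood factor φ_u = binomial_ratio(n(x), ℓ, r^u, s) · Q.

    ``x`` is the post-jump population state; ℓ and s use the post-event
    (càdlàg) convention.
    """
    if compatibility(u, p, t) == 0:
        return 0.0
    demes = model.demes
    n = model.occupancy(x)
    l = lineage_count(p, t, demes)
    s = saturation(p, t, demes)
    r = u.production(demes)
    return binomial_ratio(n, l, r, s)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(g: Genealogy) -> str:
    """Serialize a genealogy forest: one Newick line per tree.

    Times are absolute via the root-at-0 convention (root branch length 0).
    Node metadata rides in ``[&kind=...,deme=...]`` comments; the horizon is
    recorded as ``[&T=...]`` on each root.
    """
    ch = g.children_map()

    def fmt(nid: int) -> str:
        nd = g.nodes[nid]
        kids = sorted(ch[nid], key=lambda c: (g.nodes[c].time, c))
        sub = f"({','.join(fmt(c) for c in kids)})" if kids else ""
        label = nd.label or ""
        meta = [f"kind={nd.kind}", f"t={nd.time!r}"]
        if nd.deme is not None:
            meta.append(f"deme={nd.deme}")
        if nd.parent is None:
            meta.append(f"T={g.horizon!r}")
            blen = 0.0
        else:
            blen = nd.time - g.nodes[nd.parent].time
        return f"{sub}{label}[&{','.join(meta)}]:{blen!r}"

    return "".join(fmt(r) + ";\n" for r in sorted(g.roots()))


def _parse_meta(comments: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for c in comments:
        c = c.strip().lstrip("&")
        for item in c.split(","):
            if "=" in item:
                k, v = item.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_newick(text: str,
                horizon: float | None = None) -> Genealogy:
    """Parse one-or-more Newick lines into a genealogy forest.

    Returns an :class:`ObscuredGenealogy` when no deme annotations are
    present, else a :class:`PrunedGenealogy` (or plain :class:`Genealogy` if
    tip nodes occur).  Node kinds honour ``[&kind=...]`` annotations; absent
    those, leaves are samples and inner nodes internal.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty Newick input")
    trees = dendropy.TreeList.get(
        data="\n".join(lines), schema="newick",
        suppress_internal_node_taxa=True, extract_comment_metadata=False)
    any_deme = False
    any_tip = False
    entries = []  # (tree-local structure)
    tmax = 0.0
    declared_T = horizon
    for tree in trees:
        rows = []
        for nd in tree.preorder_node_iter():
            meta = _parse_meta(list(nd.comments))
            elen = nd.edge.length or 0.0
            if elen < 0:
                raise ValueError("negative branch length")
            parent = nd.parent_node
            if "t" in meta:
                time = float(meta["t"])
            elif parent is None:
                time = 0.0
            else:
                time = parent._gf_time + elen
            nd._gf_time = time
            tmax = max(tmax, time)
            if "T" in meta:
                declared_T = float(meta["T"]) if declared_T is None else declared_T
            label = nd.taxon.label if nd.taxon else (nd.label or None)
            kind = meta.get("kind")
            if kind is None:
                if parent is None:
                    kind = ROOT
                elif nd.is_leaf():
                    kind = SAMPLE
                else:
                    kind = INTERNAL
            deme = meta.get("deme")
            any_deme = any_deme or deme is not None
            any_tip = any_tip or kind == TIP
            rows.append((nd, parent, time, kind, deme, label))
        entries.append(rows)
    T = declared_T if declared_T is not None else tmax
    cls = Genealogy if any_tip else (PrunedGenealogy if any_deme
                                     else ObscuredGenealogy)
    g = cls(T)
    for rows in entries:
        idmap: dict[int, int] = {}
        for (nd, parent, time, kind, deme, label) in rows:
            pid = idmap[id(parent)] if parent is not None else None
            nid = g.add_node(time, kind, deme=deme, parent=pid, label=label)
            idmap[id(nd)] = nid
    errs = g.validate()
    if errs:
        raise ValueError("malformed genealogy: " + "; ".join(errs))
    return g
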