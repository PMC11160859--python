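"""Population-process models: jump marks, state spaces, builtin models.

A population model is a continuous-time Markov jump process on a finite
(truncated) integer lattice, together with a *deme occupancy* map n(x) giving
the number of genealogy-bearing lineages in each deme, and a set of *jump
marks*.  Each mark couples a transition rate and state update to a genealogy
action (who branches, dies, migrates, or is sampled), from which its
*production* — the per-deme number of lineages emerging from one event — is
derived: offspring and surviving participants count, dying lineages do not.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import yaml

State = tuple  # integer tuple

BIRTH = "birth"
DEATH = "death"
MIGRATION = "migration"
SAMPLE = "sample"
NEUTRAL = "neutral"
BIRTH_DEATH = "birth_death"      # compound: one lineage born, another dies
SAMPLE_DEATH = "sample_death"    # compound: sampled lineage removed

EVENT_CLASSES = (BIRTH, DEATH, MIGRATION, SAMPLE, NEUTRAL,
                 BIRTH_DEATH, SAMPLE_DEATH)


@dataclass(frozen=True)
class Participants:
    """How one event touches lineages, by deme.

    ``parent``: deme of the (single) parent at a birth-type event;
    ``children``: demes of new offspring; ``deaths``: demes of dying
    lineages; ``migrations``: (source, destination) pairs; ``samples``:
    demes of sampled lineages (``sampled_lineages_die`` marks the
    sample/death compound).
    """
    parent: str | None = None
    children: tuple[str, ...] = ()
    deaths: tuple[str, ...] = ()
    migrations: tuple[tuple[str, str], ...] = ()
    samples: tuple[str, ...] = ()
    sampled_lineages_die: bool = False


@dataclass(frozen=True)
class JumpMark:
    """One category of population-process jump.

    ``rate(t, x)`` is the total hazard of events of this mark from state
    ``x`` at time ``t``; ``state_update(x)`` its deterministic effect.
    ``observed_only`` marks sampling schemes whose event *times* are
    conditioned on: such marks contribute their rate as a density factor at
    observed sample nodes but no hazard between them (the serially-sampled
    coalescent convention).
    """
    name: str
    event_class: str
    rate: Callable[[float, State], float]
    state_update: Callable[[State], State]
    participants: Participants = field(default_factory=Participants)
    demes: tuple[str, ...] | None = None
    observed_only: bool = False

    def production(self, demes: Sequence[str] | None = None) -> tuple[int, ...]:
        """Per-deme count of lineages emerging from one event of this mark."""
        if demes is None:
            demes = self.demes
        if demes is None:
            raise ValueError("no deme ordering available")
        demes = list(demes)
        r = [0] * len(demes)
        P = self.participants
        if self.event_class in (BIRTH, BIRTH_DEATH) and P.parent is not None:
            r[demes.index(P.parent)] += 1
        for d in P.children:
            r[demes.index(d)] += 1
        for (_, j) in P.migrations:
            r[demes.index(j)] += 1
        if not P.sampled_lineages_die:
            for d in P.samples:
                r[demes.index(d)] += 1
        return tuple(r)

    @property
    def production_demes(self):
        return self.demes


@dataclass(frozen=True)
class ScheduledEvent:
    """A deterministic-time singular event.

    ``time=None`` means "at the genealogy horizon".  Kinds:

    * ``binomial_sample``: every lineage of ``deme`` is sampled
      independently with probability ``prob`` (sampled lineages survive);
    * ``conditioned_sample``: ``count`` lineages of ``deme`` are sampled and
      the event is fully conditioned on (likelihood factor 1).
    """
    kind: str
    time: float | None = None
    deme: str | None = None
    prob: float = 1.0
    count: int | None = None


class StateSpace:
    """Finite enumeration of a truncated integer lattice."""

    def __init__(self, labels: Sequence[str], states: Sequence[State]):
        self.labels = tuple(labels)
        self.states = [tuple(map(int, s)) for s in states]
        self.index = {s: i for i, s in enumerate(self.states)}

    def __len__(self):
        return len(self.states)

    def __contains__(self, x):
        return tuple(x) in self.index

    @classmethod
    def box(cls, labels, lower, upper):
        ranges = [range(lo, hi + 1) for lo, hi in zip(lower, upper)]
        return cls(labels, list(itertools.product(*ranges)))

    @classmethod
    def simplex(cls, labels, total):
        """All non-negative integer tuples summing to ``total``."""
        dim = len(labels)

        def rec(prefix, remaining, k):
            if k == 1:
                yield prefix + (remaining,)
                return
            for v in range(remaining + 1):
                yield from rec(prefix + (v,), remaining - v, k - 1)

        return cls(labels, list(rec((), total, dim)))


@dataclass
class PopulationModel:
    demes: tuple[str, ...]
    marks: tuple[JumpMark, ...]
    occupancy: Callable[[State], tuple[int, ...]]
    p0: dict[State, float]
    state_space: StateSpace
    scheduled: tuple[ScheduledEvent, ...] = ()
    time_homogeneous: bool = True
    rate_bound: float | None = None
    name: str | None = None
    params: dict | None = None

    def mark(self, name: str) -> JumpMark:
        for m in self.marks:
            if m.name == name:
                return m
        raise KeyError(name)


def total_rate(model: PopulationModel, t: float, x: State) -> float:
    """Σ_u α_u(t, x): additive over jump marks."""
    if tuple(x) not in model.state_space:
        raise ValueError(f"state {x} outside truncation bounds")
    return float(sum(m.rate(t, x) for m in model.marks))


# ---------------------------------------------------------------------------
# builtin models
# ---------------------------------------------------------------------------

def _require(params, *names):
    missing = [n for n in names if n not in params]
    if missing:
        raise ValueError(f"missing parameters: {missing}")
    for n in names:
        if isinstance(params[n], (int, float)) and params[n] < 0:
            raise ValueError(f"negative parameter {n}")
    return [params[n] for n in names]


def _mark(name, ec, rate, update, demes, observed_only=False, **pk):
    return JumpMark(name, ec, rate, update, Participants(**pk),
                    demes=tuple(demes), observed_only=observed_only)


def _moran(params):
    mu, n = _require(params, "mu", "n")
    psi = params.get("psi", 0.0)
    n = int(n)
    demes = ("L",)
    ident = lambda x: x
    marks = [
        _mark("event", BIRTH_DEATH, lambda t, x: mu, ident, demes,
              parent="L", children=("L",), deaths=("L",)),
    ]
    if psi > 0:
        # serial sampling conditioned on its times (Poisson density factor psi)
        marks.append(_mark("sample", SAMPLE, lambda t, x: psi, ident, demes,
                           samples=("L",), observed_only=True))
    sched = ()
    m_end = params.get("terminal_samples")
    if m_end:
        sched = (ScheduledEvent("conditioned_sample", time=None, deme="L",
                                count=int(m_end)),)
    space = StateSpace(("k",), [()])
    return PopulationModel(
        demes=demes, marks=tuple(marks),
        occupancy=lambda x: (n,),
        p0={(): 1.0}, state_space=space, scheduled=sched)


def _lbd(params):
    lam, mu, psi, rho = _require(params, "lam", "mu", "psi", "rho")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be a probability")
    x0 = int(params.get("x0", 1))
    xmax = int(params.get("xmax", 60))
    demes = ("L",)
    sampled_die = bool(params.get("sampled_lineage_dies", False))
    marks = [
        _mark("birth", BIRTH, lambda t, x: lam * x[0],
              lambda x: (x[0] + 1,), demes, parent="L", children=("L",)),
        _mark("death", DEATH, lambda t, x: mu * x[0],
              lambda x: (x[0] - 1,), demes, deaths=("L",)),
    ]
    if sampled_die:
        marks.append(_mark("sample", SAMPLE_DEATH, lambda t, x: psi * x[0],
                           lambda x: (x[0] - 1,), demes, samples=("L",),
                           sampled_lineages_die=True))
    else:
        marks.append(_mark("sample", SAMPLE, lambda t, x: psi * x[0],
                           lambda x: x, demes, samples=("L",)))
    sched = ()
    if rho > 0:
        sched = (ScheduledEvent("binomial_sample", time=None, deme="L",
                                prob=rho),)
    space = StateSpace.box(("x",), (0,), (xmax,))
    return PopulationModel(
        demes=demes, marks=tuple(marks),
        occupancy=lambda x: (x[0],),
        p0={(x0,): 1.0}, state_space=space, scheduled=sched)


def _sirs(params):
    beta, gamma, psi, omega, N = _require(
        params, "beta", "gamma", "psi", "omega", "N")
    N = int(N)
    i0 = int(params.get("I0", 1))
    demes = ("I",)
    marks = (
        _mark("trans", BIRTH, lambda t, x: beta * x[0] * x[1] / N,
              lambda x: (x[0] - 1, x[1] + 1, x[2]), demes,
              parent="I", children=("I",)),
        _mark("recov", DEATH, lambda t, x: gamma * x[1],
              lambda x: (x[0], x[1] - 1, x[2] + 1), demes, deaths=("I",)),
        _mark("sample", SAMPLE, lambda t, x: psi * x[1],
              lambda x: x, demes, samples=("I",)),
        _mark("wane", NEUTRAL, lambda t, x: omega * x[2],
              lambda x: (x[0] + 1, x[1], x[2] - 1), demes),
    )
    space = StateSpace.simplex(("S", "I", "R"), N)
    return PopulationModel(
        demes=demes, marks=marks,
        occupancy=lambda x: (x[1],),
        p0={(N - i0, i0, 0): 1.0}, state_space=space)


def _seirs(params):
    beta, sigma, gamma, psi, omega, N = _require(
        params, "beta", "sigma", "gamma", "psi", "omega", "N")
    N = int(N)
    e0 = int(params.get("E0", 0))
    i0 = int(params.get("I0", 1))
    demes = ("E", "I")
    marks = (
        _mark("trans", BIRTH, lambda t, x: beta * x[0] * x[2] / N,
              lambda x: (x[0] - 1, x[1] + 1, x[2], x[3]), demes,
              parent="I", children=("E",)),
        _mark("prog", MIGRATION, lambda t, x: sigma * x[1],
              lambda x: (x[0], x[1] - 1, x[2] + 1, x[3]), demes,
              migrations=(("E", "I"),)),
        _mark("recov", DEATH, lambda t, x: gamma * x[2],
              lambda x: (x[0], x[1], x[2] - 1, x[3] + 1), demes,
              deaths=("I",)),
        _mark("sample", SAMPLE, lambda t, x: psi * x[2],
              lambda x: x, demes, samples=("I",)),
        _mark("wane", NEUTRAL, lambda t, x: omega * x[3],
              lambda x: (x[0] + 1, x[1], x[2], x[3] - 1), demes),
    )
    space = StateSpace.simplex(("S", "E", "I", "R"), N)
    return PopulationModel(
        demes=demes, marks=marks,
        occupancy=lambda x: (x[1], x[2]),
        p0={(N - e0 - i0, e0, i0, 0): 1.0}, state_space=space)


def _two_strain(params):
    (beta1, beta2, sigma1, sigma2, gamma1, gamma2,
     psi1, psi2, omega, N) = _require(
        params, "beta1", "beta2", "sigma1", "sigma2", "gamma1", "gamma2",
        "psi1", "psi2", "omega", "N")
    N = int(N)
    i1, i2 = int(params.get("I1_0", 1)), int(params.get("I2_0", 1))
    demes = ("E1", "E2", "I1", "I2")
    # state: (S, E1, E2, I1, I2, R1, R2)
    marks = (
        _mark("trans1", BIRTH, lambda t, x: beta1 * x[0] * x[3] / N,
              lambda x: (x[0] - 1, x[1] + 1, *x[2:]), demes,
              parent="I1", children=("E1",)),
        _mark("trans2", BIRTH, lambda t, x: beta2 * x[0] * x[4] / N,
              lambda x: (x[0] - 1, x[1], x[2] + 1, *x[3:]), demes,
              parent="I2", children=("E2",)),
        _mark("prog1", MIGRATION, lambda t, x: sigma1 * x[1],
              lambda x: (x[0], x[1] - 1, x[2], x[3] + 1, *x[4:]), demes,
              migrations=(("E1", "I1"),)),
        _mark("prog2", MIGRATION, lambda t, x: sigma2 * x[2],
              lambda x: (x[0], x[1], x[2] - 1, x[3], x[4] + 1, *x[5:]), demes,
              migrations=(("E2", "I2"),)),
        _mark("recov1", DEATH, lambda t, x: gamma1 * x[3],
              lambda x: (*x[:3], x[3] - 1, x[4], x[5] + 1, x[6]), demes,
              deaths=("I1",)),
        _mark("recov2", DEATH, lambda t, x: gamma2 * x[4],
              lambda x: (*x[:4], x[4] - 1, x[5], x[6] + 1), demes,
              deaths=("I2",)),
        _mark("sample1", SAMPLE, lambda t, x: psi1 * x[3],
              lambda x: x, demes, samples=("I1",)),
        _mark("sample2", SAMPLE, lambda t, x: psi2 * x[4],
              lambda x: x, demes, samples=("I2",)),
        _mark("wane1", NEUTRAL, lambda t, x: omega * x[5],
              lambda x: (x[0] + 1, *x[1:5], x[5] - 1, x[6]), demes),
        _mark("wane2", NEUTRAL, lambda t, x: omega * x[6],
              lambda x: (x[0] + 1, *x[1:6], x[6] - 1), demes),
    )
    space = StateSpace.simplex(("S", "E1", "E2", "I1", "I2", "R1", "R2"), N)
    return PopulationModel(
        demes=demes, marks=marks,
        occupancy=lambda x: (x[1], x[2], x[3], x[4]),
        p0={(N - i1 - i2, 0, 0, i1, i2, 0, 0): 1.0}, state_space=space)


def _progression(params):
    (beta_a, beta_s, sigma_a, sigma_s, gamma_a, gamma_s,
     eta, delta, psi, N) = _require(
        params, "beta_a", "beta_s", "sigma_a", "sigma_s", "gamma_a",
        "gamma_s", "eta", "delta", "psi", "N")
    N = int(N)
    e0 = int(params.get("E0", 1))
    demes = ("E", "IA", "IS")
    # state: (S, E, IA, IS, H, R); hospitalized hosts no longer carry lineages
    marks = (
        _mark("transA", BIRTH, lambda t, x: beta_a * x[0] * x[2] / N,
              lambda x: (x[0] - 1, x[1] + 1, *x[2:]), demes,
              parent="IA", children=("E",)),
        _mark("transS", BIRTH, lambda t, x: beta_s * x[0] * x[3] / N,
              lambda x: (x[0] - 1, x[1] + 1, *x[2:]), demes,
              parent="IS", children=("E",)),
        _mark("progA", MIGRATION, lambda t, x: sigma_a * x[1],
              lambda x: (x[0], x[1] - 1, x[2] + 1, *x[3:]), demes,
              migrations=(("E", "IA"),)),
        _mark("progS", MIGRATION, lambda t, x: sigma_s * x[1],
              lambda x: (x[0], x[1] - 1, x[2], x[3] + 1, *x[4:]), demes,
              migrations=(("E", "IS"),)),
        _mark("recovA", DEATH, lambda t, x: gamma_a * x[2],
              lambda x: (*x[:2], x[2] - 1, x[3], x[4], x[5] + 1), demes,
              deaths=("IA",)),
        _mark("recovS", DEATH, lambda t, x: gamma_s * x[3],
              lambda x: (*x[:3], x[3] - 1, x[4], x[5] + 1), demes,
              deaths=("IS",)),
        _mark("hosp", DEATH, lambda t, x: eta * x[3],
              lambda x: (*x[:3], x[3] - 1, x[4] + 1, x[5]), demes,
              deaths=("IS",)),
        _mark("hout", NEUTRAL, lambda t, x: delta * x[4],
              lambda x: (*x[:4], x[4] - 1, x[5] + 1), demes),
        _mark("sampleS", SAMPLE, lambda t, x: psi * x[3],
              lambda x: x, demes, samples=("IS",)),
    )
    space = StateSpace.simplex(("S", "E", "IA", "IS", "H", "R"), N)
    return PopulationModel(
        demes=demes, marks=marks,
        occupancy=lambda x: (x[1], x[2], x[3]),
        p0={(N - e0, e0, 0, 0, 0, 0): 1.0}, state_space=space)


def _superspreading(params):
    (beta_l, beta_h, sigma, p_h, w_lh, w_hl, gamma, psi, N) = _require(
        params, "beta_l", "beta_h", "sigma", "p_h", "w_lh", "w_hl",
        "gamma", "psi", "N")
    N = int(N)
    e0 = int(params.get("E0", 1))
    demes = ("E", "IL", "IH")
    # state: (S, E, IL, IH, R)
    marks = (
        _mark("transL", BIRTH, lambda t, x: beta_l * x[0] * x[2] / N,
              lambda x: (x[0] - 1, x[1] + 1, *x[2:]), demes,
              parent="IL", children=("E",)),
        _mark("transH", BIRTH, lambda t, x: beta_h * x[0] * x[3] / N,
              lambda x: (x[0] - 1, x[1] + 1, *x[2:]), demes,
              parent="IH", children=("E",)),
        _mark("progL", MIGRATION, lambda t, x: sigma * (1 - p_h) * x[1],
              lambda x: (x[0], x[1] - 1, x[2] + 1, *x[3:]), demes,
              migrations=(("E", "IL"),)),
        _mark("progH", MIGRATION, lambda t, x: sigma * p_h * x[1],
              lambda x: (x[0], x[1] - 1, x[2], x[3] + 1, x[4]), demes,
              migrations=(("E", "IH"),)),
        _mark("calm", MIGRATION, lambda t, x: w_hl * x[3],
              lambda x: (*x[:2], x[2] + 1, x[3] - 1, x[4]), demes,
              migrations=(("IH", "IL"),)),
        _mark("risk", MIGRATION, lambda t, x: w_lh * x[2],
              lambda x: (*x[:2], x[2] - 1, x[3] + 1, x[4]), demes,
              migrations=(("IL", "IH"),)),
        _mark("recovL", DEATH, lambda t, x: gamma * x[2],
              lambda x: (*x[:2], x[2] - 1, x[3], x[4] + 1), demes,
              deaths=("IL",)),
        _mark("recovH", DEATH, lambda t, x: gamma * x[3],
              lambda x: (*x[:3], x[3] - 1, x[4] + 1), demes,
              deaths=("IH",)),
        _mark("sampleL", SAMPLE, lambda t, x: psi * x[2],
              lambda x: x, demes, samples=("IL",)),
        _mark("sampleH", SAMPLE, lambda t, x: psi * x[3],
              lambda x: x, demes, samples=("IH",)),
    )
    space = StateSpace.simplex(("S", "E", "IL", "IH", "R"), N)
    return PopulationModel(
        demes=demes, marks=marks,
        occupancy=lambda x: (x[1], x[2], x[3]),
        p0={(N - e0, e0, 0, 0, 0): 1.0}, state_space=space)


_BUILTINS = {
    "moran": _moran,
    "lbd": _lbd,
    "sirs": _sirs,
    "seirs": _seirs,
    "two_strain": _two_strain,
    "progression": _progression,
    "superspreading": _superspreading,
}


def builtin_model(name: str, params: dict) -> PopulationModel:
    """Construct one of the builtin population models by name."""
    if name not in _BUILTINS:
        raise ValueError(f"unknown model {name!r}; "
                         f"choose from {sorted(_BUILTINS)}")
    model = _BUILTINS[name](dict(params))
    model.name = name
    model.params = dict(params)
    return model


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _expected_occupancy_delta(mark: JumpMark, demes) -> list[int]:
    d = [0] * len(demes)
    P = mark.participants
    idx = {dm: i for i, dm in enumerate(demes)}
    for c in P.children:
        d[idx[c]] += 1
    for dd in P.deaths:
        d[idx[dd]] -= 1
    for (i, j) in P.migrations:
        d[idx[i]] -= 1
        d[idx[j]] += 1
    if P.sampled_lineages_die:
        for sd in P.samples:
            d[idx[sd]] -= 1
    return d


def validate_model(model: PopulationModel,
                   times: Sequence[float] = (0.0, 0.5, 1.0),
                   max_states: int = 500) -> list[str]:
    """Check model invariants on a sampled grid of (t, x); report violations."""
    out: list[str] = []
    demes = model.demes
    states = model.state_space.states
    step = max(1, len(states) // max_states)
    probe = states[::step]

    for m in model.marks:
        if m.event_class not in EVENT_CLASSES:
            out.append(f"{m.name}: unknown event class {m.event_class!r}")
            continue
        try:
            r1, r2 = m.production(demes), m.production(demes)
        except Exception as e:  # noqa: BLE001 - reported, not raised
            out.append(f"{m.name}: production not computable ({e})")
            continue
        if r1 != r2 or any((not isinstance(v, int)) or v < 0 for v in r1):
            out.append(f"{m.name}: production not constant non-negative")
        if m.event_class in (DEATH, NEUTRAL) and any(v != 0 for v in r1):
            out.append(f"{m.name}: death/neutral mark has nonzero production")
        if m.event_class in (BIRTH, BIRTH_DEATH) and \
                m.participants.parent is None:
            out.append(f"{m.name}: birth-type mark lacks a parent deme")
        if m.event_class in (SAMPLE, SAMPLE_DEATH) and \
                len(set(m.participants.samples)) > 1:
            out.append(f"{m.name}: multi-deme simultaneous sampling is not "
                       "supported by the filter equations")

    for x in probe:
        n = model.occupancy(x)
        if any(v < 0 for v in n):
            out.append(f"occupancy negative at state {x}")
            break
    delta_cache = {m.name: _expected_occupancy_delta(m, demes)
                   for m in model.marks}
    for m in model.marks:
        for t in times:
            bad_rate = next((x for x in probe if m.rate(t, x) < 0), None)
            if bad_rate is not None:
                out.append(f"{m.name}: negative rate at t={t}, x={bad_rate}")
                break
        for x in probe:
            if m.rate(0.0, x) <= 0:
                continue
            x2 = tuple(m.state_update(x))
            n1, n2 = model.occupancy(x), model.occupancy(x2)
            if any(v < 0 for v in n2):
                out.append(f"{m.name}: occupancy negative after update at {x}")
                break
            if x2 not in model.state_space:
                # truncation boundary: the filters drop this transition and
                # report the leaked mass; not a model defect
                continue
            want = delta_cache[m.name]
            if [b - a for a, b in zip(n1, n2)] != want:
                out.append(f"{m.name}: occupancy change at {x} is "
                           f"{[b - a for a, b in zip(n1, n2)]}, expected {want}")
                break
    return out


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

def model_to_config(model: PopulationModel) -> str:
    if model.name is None:
        raise ValueError("only builtin models serialize to config")
    return yaml.safe_dump({"model": model.name,
                           "params": dict(model.params or {})},
                          sort_keys=True)


def model_from_config(text: str) -> PopulationModel:
    doc = yaml.safe_load(text)
    return builtin_model(doc["model"], doc.get("params", {}))
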