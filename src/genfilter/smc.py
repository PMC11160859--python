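"""Sequential Monte Carlo estimation of obscured-genealogy likelihoods.

Particles carry a population state and a hidden coloring (a deme per extant
genealogy lineage).  Between genealogical events they follow the population
process, with hidden-coloring updates proposed proportionally to the
per-event weight φ and the marginal Σφ absorbed into the particle weight
(a Rao-Blackwellised uniform proposal, which the change-of-measure theory
explicitly permits).  At each genealogical event time a singular update
forces the observed node, weighting by the total singular density.  The
weight mean is an unbiased estimator of the likelihood.

Particles are split into independent blocks; each block resamples
systematically when its effective sample size drops below a threshold, and
the reported standard error is a delete-one-block jackknife, which remains
honest in the presence of resampling."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .filters import _Engine, _is_obscured, _SAMPLE_CLASSES, _BIRTH_CLASSES
from .genealogy import Genealogy, binomial_ratio
from .models import MIGRATION, PopulationModel


def hidden_target_terms(mark, demes, occ, y_pre, l_cache=None):
    """Forward enumeration of hidden-coloring options at one free jump of
    ``mark``: list of (y_post, φ).  Mirrors the filter's regular-part gains."""
    demes = list(demes)
    nd = len(demes)

    def lvec(y):
        l = [0] * nd
        for d in y:
            l[demes.index(d)] += 1
        return l

    ec = mark.event_class
    if ec in _SAMPLE_CLASSES:
        return []
    r = mark.production(demes)
    zero = [0] * nd
    terms = [(tuple(y_pre), binomial_ratio(occ, lvec(y_pre), r, zero))]
    if ec in _BIRTH_CLASSES:
        par = mark.participants.parent
        for k, d in enumerate(y_pre):
            if d != par:
                continue
            for ji, j in enumerate(demes):
                if r[ji] < 1:
                    continue
                s = list(zero)
                s[ji] = 1
                y_post = tuple(y_pre[:k]) + (j,) + tuple(y_pre[k + 1:])
                terms.append((y_post,
                              binomial_ratio(occ, lvec(y_post), r, s)))
    elif ec == MIGRATION:
        for (src, dst) in mark.participants.migrations:
            di = demes.index(dst)
            s = list(zero)
            s[di] = 1
            e = list(s)
            for k, d in enumerate(y_pre):
                if d != src:
                    continue
                y_post = tuple(y_pre[:k]) + (dst,) + tuple(y_pre[k + 1:])
                terms.append((y_post,
                              binomial_ratio(occ, lvec(y_post), e, s)))
    return [(y, float(w)) for y, w in terms if w > 0]


@dataclass
class SMCResult:
    loglik: float
    se: float
    block_logliks: list[float]
    n_particles: int
    diagnostic: str = ""

    def __iter__(self):
        return iter((self.loglik, self.se))


def _systematic_resample(logw, rng):
    w = np.exp(logw - logw.max())
    w = w / w.sum()
    J = len(w)
    positions = (rng.uniform() + np.arange(J)) / J
    return np.searchsorted(np.cumsum(w), positions).clip(0, J - 1)


class _SMCRunner:
    def __init__(self, model, z, seed_engine=None):
        self.model = model
        self.eng = seed_engine or _Engine(model, z, hidden=True,
                                          rtol=1e-8, atol=1e-12)
        self.sched = self.eng.sched
        self.demes = self.eng.demes
        self.marks = list(model.marks)
        self.free = [(i, m) for i, m in enumerate(self.marks)
                     if m.event_class not in _SAMPLE_CLASSES
                     and not m.observed_only]
        name2dst = {m.name: dst for m, dst in self.eng.tables}
        self.free_dst = [name2dst[m.name] for _, m in self.free]
        self._rate_cache: dict = {}
        self._jump_cache: dict = {}
        self._event_cache: dict = {}
        self._B: dict = {}
        # y index per interval
        self.yspaces = [self.eng._yspace(iv) for iv in self.sched.intervals]
        self.yindex = [{y: i for i, y in enumerate(ys)}
                       for ys in self.yspaces]

    def rates(self, xi):
        if xi not in self._rate_cache:
            x = self.eng.states[xi]
            fr = np.array([m.rate(0.0, x) for _, m in self.free])
            lam_s = sum(m.rate(0.0, x) for m in self.marks
                        if m.event_class in _SAMPLE_CLASSES
                        and not m.observed_only)
            self._rate_cache[xi] = (fr, fr.sum(), lam_s)
        return self._rate_cache[xi]

    def jump_options(self, mi, xj, y_pre):
        key = (mi, xj, y_pre)
        if key not in self._jump_cache:
            _, m = self.free[mi]
            occ = tuple(int(v) for v in self.eng.occ[xj])
            terms = hidden_target_terms(m, self.demes, occ, y_pre)
            if terms:
                ys, ws = zip(*terms)
                ws = np.array(ws)
                self._jump_cache[key] = (list(ys), ws / ws.sum(), ws.sum())
            else:
                self._jump_cache[key] = ([], None, 0.0)
        return self._jump_cache[key]

    def event_options(self, ie, xi, y_pre_idx):
        key = (ie, xi, y_pre_idx)
        if key not in self._event_cache:
            if ie not in self._B:
                self._B[ie] = self.eng._event_matrix(ie).tocsc()
            ny_pre = len(self.yspaces[ie])
            col = self._B[ie].getcol(xi * ny_pre + y_pre_idx).tocoo()
            rows = col.row.astype(int)
            vals = col.data.astype(float)
            keep = vals > 0
            rows, vals = rows[keep], vals[keep]
            tot = vals.sum()
            self._event_cache[key] = (rows, vals / tot if tot > 0 else vals,
                                      tot)
        return self._event_cache[key]

    def run_block(self, J, rng, ess_threshold):
        eng = self.eng
        model = self.model
        x0s = list(model.p0)
        p0w = np.array([model.p0[x] for x in x0s])
        p0w = p0w / p0w.sum()
        ys0 = self.yspaces[0]
        xs = np.zeros(J, dtype=int)
        yi = np.zeros(J, dtype=int)
        logw = np.zeros(J)
        for j in range(J):
            x = x0s[rng.choice(len(x0s), p=p0w)]
            xi = eng.space.index[x]
            n = eng.occ[xi]
            feas = [k for k, y in enumerate(ys0)
                    if (n >= eng._lvec(y)).all()]
            if not feas:
                logw[j] = -math.inf
                continue
            xs[j] = xi
            yi[j] = feas[int(rng.integers(len(feas)))]
            logw[j] = math.log(len(feas))
        logZ = 0.0
        nseg = len(self.sched.intervals)
        for ii in range(nseg):
            iv = self.sched.intervals[ii]
            ys = self.yspaces[ii]
            for j in range(J):
                if not np.isfinite(logw[j]):
                    continue
                xi, y = int(xs[j]), ys[int(yi[j])]
                t = iv.t0
                lw = 0.0
                while True:
                    fr, tot, lam_s = self.rates(xi)
                    dt = rng.exponential(1.0 / tot) if tot > 0 else math.inf
                    t2 = min(iv.t1, t + dt)
                    lw -= lam_s * (t2 - t)
                    t = t2
                    if t >= iv.t1:
                        break
                    mi = int(rng.choice(len(fr), p=fr / tot))
                    xj = int(self.free_dst[mi][xi])
                    if xj < 0:
                        lw = -math.inf
                        break
                    opts, probs, tot_phi = self.jump_options(mi, xj, y)
                    if tot_phi <= 0:
                        lw = -math.inf
                        break
                    y = opts[int(rng.choice(len(opts), p=probs))]
                    lw += math.log(tot_phi)
                    xi = xj
                if np.isfinite(lw) and ii < nseg - 1:
                    rowsv, probs, tot = self.event_options(
                        ii, xi, self.yindex[ii][y])
                    if tot <= 0:
                        lw = -math.inf
                    else:
                        pick = int(rng.choice(len(rowsv), p=probs))
                        joint = int(rowsv[pick])
                        ny_post = len(self.yspaces[ii + 1])
                        xi, ynext = divmod(joint, ny_post)
                        lw += math.log(tot)
                        yi[j] = ynext
                        xs[j] = xi
                logw[j] = logw[j] + lw if np.isfinite(lw) else -math.inf
            if not np.isfinite(logw).any():
                return -math.inf
            if ii < nseg - 1:
                # resample within the block if weights degenerate
                finite = np.isfinite(logw)
                lsw = logsumexp(logw[finite])
                ess = math.exp(2 * lsw - logsumexp(2 * logw[finite]))
                if ess < ess_threshold * J:
                    logZ += lsw - math.log(J)
                    idx = _systematic_resample(
                        np.where(finite, logw, -np.inf), rng)
                    xs, yi = xs[idx], yi[idx]
                    logw = np.zeros(J)
        return logZ + logsumexp(logw[np.isfinite(logw)]) - math.log(J) \
            if np.isfinite(logw).any() else -math.inf


def smc_loglik(model: PopulationModel, z: Genealogy, n_particles: int,
               seed: int, ess_threshold: float = 0.5,
               n_blocks: int | None = None) -> SMCResult:
    """SMC estimate of the obscured-genealogy log-likelihood.

    Returns the log of the unbiased natural-scale estimator together with a
    delete-one-block jackknife standard error.
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    if not _is_obscured(z):
        raise ValueError("smc_loglik expects an obscured genealogy")
    if n_blocks is None:
        n_blocks = int(np.clip(n_particles // 200, 2, 25))
    J = max(2, n_particles // n_blocks)
    rng = np.random.default_rng(seed)
    runner = _SMCRunner(model, z)
    block_ll = [runner.run_block(J, np.random.default_rng(s), ess_threshold)
                for s in rng.integers(0, 2 ** 31 - 1, size=n_blocks)]
    arr = np.array(block_ll, dtype=float)
    if not np.isfinite(arr).any():
        return SMCResult(-math.inf, math.inf, block_ll, n_blocks * J,
                         diagnostic="all particles extinct")
    B = len(arr)
    comb = logsumexp(arr) - math.log(B)
    # delete-one-block jackknife on the log combined estimate
    loo = np.array([logsumexp(np.delete(arr, i)) - math.log(B - 1)
                    for i in range(B)])
    se = math.sqrt((B - 1) / B * ((loo - loo.mean()) ** 2).sum())
    return SMCResult(float(comb), float(se), block_ll, B * J)


def smc_replicates(model: PopulationModel, z: Genealogy, n_particles: int,
                   n_reps: int, seed: int,
                   ess_threshold: float = 0.5) -> np.ndarray:
    """Independent replicate SMC estimates from split seeds."""
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n_reps)
    return np.array([smc_loglik(model, z, n_particles, int(s),
                                ess_threshold).loglik for s in seeds])
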