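"""Closed-form genealogy likelihoods for two classical special cases.

* Moran model (fixed population of n lineages, compound birth/death events at
  total rate μ): the coalescent likelihood, with or without serial sampling.
* Linear birth-death model (per-capita birth λ, death μ, sampling ψ, binomial
  sampling with probability ρ at the horizon): likelihood via the G/H
  final-value ODE system.

Both serve as independent oracles for the generic filter solvers.  All
likelihoods are for *ordered* samples (simultaneous samples in a fixed
order), matching the filter convention; they differ from unordered versions
by a factorial in the number of simultaneous samples.
"""

from __future__ import annotations

import math

from scipy.integrate import solve_ivp

from .genealogy import (Genealogy, INTERNAL, SAMPLE, coalescent_intervals,
                        lineage_count)


def _classify(z: Genealogy):
    """Branch times, terminal/inline sample times (before T), tip count at T,
    and root count of a (single-deme or obscured) genealogy."""
    ch = z.children_map()
    T = z.horizon
    branches, s0, s1, n_tips = [], [], [], 0
    for nd in z.nodes.values():
        kids = ch[nd.id]
        if nd.kind == INTERNAL:
            if len(kids) == 1:
                raise ValueError("inline internal node in an obscured "
                                 "genealogy; obscure() the tree first")
            if len(kids) > 2:
                raise ValueError("closed forms require binary branch points")
            branches.append(nd.time)
        elif nd.kind == SAMPLE:
            if nd.time >= T and not kids:
                n_tips += 1
            elif kids:
                s1.append(nd.time)
            else:
                s0.append(nd.time)
    roots = [i for i in z.roots() if ch[i]]
    return branches, s0, s1, n_tips, len(roots)


def kingman_loglik(z: Genealogy, n: int, mu: float) -> float:
    """Coalescent log-likelihood of a genealogy whose samples are all
    simultaneous, under the Moran model with population size n and event
    rate μ:  |B| log(μ/C(n,2)) − (μ/C(n,2)) Σ_i C(i,2) s_i."""
    branches, s0, s1, n_tips, _ = _classify(z)
    if s0 or s1:
        raise ValueError("serial samples present; use moran_serial_loglik")
    rate = mu / math.comb(n, 2)
    ll = len(branches) * math.log(rate) if branches else 0.0
    for i, dur in coalescent_intervals(z).items():
        ll -= rate * math.comb(i, 2) * dur
    return ll


def moran_serial_loglik(z: Genealogy, n: int, mu: float,
                        psi: float) -> float:
    """Serially-sampled coalescent log-likelihood under the Moran model.

    Sampling events at total rate ψ pick one of the n lineages uniformly;
    their times are conditioned on (each contributes its Poisson density
    factor ψ).  Terminal samples contribute ψ(1−ℓ(t)/n), inline samples ψ/n,
    binary branch points μ/C(n,2), with ℓ(t) the post-event lineage count.
    """
    branches, s0, s1, n_tips, _ = _classify(z)
    if n_tips:
        s0 = s0 + [nd.time for nd in z.nodes.values()
                   if nd.kind == SAMPLE and nd.time >= z.horizon
                   and z.n_children(nd.id) == 0]
    n_samp = len(s0) + len(s1)
    ll = n_samp * math.log(psi) if n_samp else 0.0
    for t in s0:
        l_post = sum(lineage_count(z, min(t, z.horizon)).values()) if \
            t < z.horizon else 0
        if t >= z.horizon:
            # a terminal sample exactly at the horizon: count edges just after
            l_post = sum(1 for (a, b, _, _) in z.edges() if b > t)
        if l_post >= n:
            return -math.inf
        ll += math.log1p(-l_post / n)
    ll -= len(s1) * math.log(n)
    rate = mu / math.comb(n, 2)
    ll += len(branches) * math.log(rate) if branches else 0.0
    for i, dur in coalescent_intervals(z).items():
        ll -= rate * math.comb(i, 2) * dur
    return ll


# ---------------------------------------------------------------------------
# linear birth-death
# ---------------------------------------------------------------------------

def lbd_gh(lam: float, mu: float, psi: float, rho: float, T: float,
           rtol: float = 1e-10, atol: float = 1e-12):
    """Solve the final-value problem for the birth-death integrands G, H:

        G' = −λG² + (λ+μ+ψ)G − μ,            G(T) = 1−ρ,
        H' = −H·(2λG − (λ+μ+ψ)),             H(T) = 1.

    Returns a dense solution callable s ↦ (G(s), H(s)) on [0, T].
    """
    def rhs(s, v):
        G, H = v
        dG = -lam * G * G + (lam + mu + psi) * G - mu
        dH = -H * (2 * lam * G - (lam + mu + psi))
        return [dG, dH]

    sol = solve_ivp(rhs, (T, 0.0), [1.0 - rho, 1.0], method="LSODA",
                    dense_output=True, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"G/H integration failed: {sol.message}")

    def gh(s):
        G, H = sol.sol(s)
        return float(G), float(H)

    return gh


def lbd_gh_closed_form(lam: float, mu: float, psi: float, rho: float,
                       T: float):
    """Textbook closed-form G and H (via the standard transform), used as a
    cross-check of the numerical solution; requires λ > 0."""
    c1 = math.sqrt((lam - mu - psi) ** 2 + 4 * lam * psi)
    c2 = -(lam - mu - 2 * lam * rho - psi) / c1

    def gh(s):
        tau = T - s
        em = math.exp(-c1 * tau)
        G = (lam + mu + psi + c1 * (em * (1 - c2) - (1 + c2))
             / (em * (1 - c2) + (1 + c2))) / (2 * lam)
        q = (2 * (1 - c2 ** 2) + em * (1 - c2) ** 2
             + math.exp(c1 * tau) * (1 + c2) ** 2)
        H = 4.0 / q
        return G, H

    return gh


def lbd_loglik(z: Genealogy, lam: float, mu: float, psi: float,
               rho: float, x0: int, n_T: int | None = None,
               rtol: float = 1e-10) -> float:
    """Closed-form log-likelihood of an obscured genealogy under the linear
    birth-death model with x0 initial individuals.

    log ℒ = log x0!/(x0−ℓ0)! + n_T log ρ − log n_T! + (x0−ℓ0) log G(0)
            + ℓ0 log H(0) + |S1| log ψ + Σ_B log 2λH(e) + Σ_S0 log ψG(e)/H(e)
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    branches, s0, s1, tips, l0 = _classify(z)
    if n_T is None:
        n_T = tips
    if x0 < l0:
        return -math.inf
    T = z.horizon
    gh = lbd_gh(lam, mu, psi, rho, T, rtol=rtol)
    G0, H0 = gh(0.0)
    ll = math.lgamma(x0 + 1) - math.lgamma(x0 - l0 + 1)
    if n_T:
        if rho <= 0:
            return -math.inf
        ll += n_T * math.log(rho) - math.lgamma(n_T + 1)
    if x0 - l0 > 0:
        if G0 <= 0:
            return -math.inf
        ll += (x0 - l0) * math.log(G0)
    if l0 > 0:
        if H0 <= 0:
            return -math.inf
        ll += l0 * math.log(H0)
    if s1:
        ll += len(s1) * math.log(psi)
    for e in branches:
        Ge, He = gh(e)
        ll += math.log(2 * lam * He)
    for e in s0:
        Ge, He = gh(e)
        val = psi * Ge / He
        if val <= 0:
            return -math.inf
        ll += math.log(val)
    return ll
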