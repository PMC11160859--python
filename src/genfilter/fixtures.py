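"""Deterministic fixture generation: simulated genealogies for every builtin
model family plus small hand-built worked examples.

Everything is reproducible from a seed; tests and the acceptance script use
the in-memory helpers, while :func:`generate_fixtures` writes a Newick/TSV
corpus with a checksum manifest for the command line.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

from .genealogy import (Genealogy, ObscuredGenealogy, PrunedGenealogy,
                        obscure, prune, write_newick)
from .models import builtin_model, model_to_config
from .simulate import simulate_genealogy


def moran_serial_fixture(seed: int, n: int = 8, mu: float = 1.5,
                         psi: float = 1.2, horizon: float = 3.0,
                         min_samples: int = 1):
    """Moran model with serial sampling: (model, history, pruned, obscured).

    Scans seeds deterministically from ``seed`` until the genealogy carries
    at least ``min_samples`` samples.
    """
    model = builtin_model("moran", {"n": n, "mu": mu, "psi": psi})
    for s in range(seed, seed + 1000):
        h, g = simulate_genealogy(model, horizon, s)
        p = prune(g)
        if len(p.samples()) >= min_samples:
            return model, h, p, obscure(p)
    raise RuntimeError("no fixture with enough samples found")


def kingman_fixture(seed: int, n: int = 7, mu: float = 2.0,
                    m_samples: int = 4, horizon: float = 2.0):
    """Moran model with simultaneous terminal sampling (classical case)."""
    model = builtin_model("moran", {"n": n, "mu": mu,
                                    "terminal_samples": m_samples})
    h, g = simulate_genealogy(model, horizon, seed)
    p = prune(g)
    return model, h, p, obscure(p)


def lbd_fixture(seed: int, lam: float = 1.2, mu: float = 0.6,
                psi: float = 0.4, rho: float = 0.7, x0: int = 2,
                horizon: float = 2.0, xmax: int = 120,
                min_samples: int = 1):
    """Linear birth-death fixture with at least ``min_samples`` samples."""
    model = builtin_model("lbd", {"lam": lam, "mu": mu, "psi": psi,
                                  "rho": rho, "x0": x0, "xmax": xmax})
    for s in range(seed, seed + 1000):
        h, g = simulate_genealogy(model, horizon, s)
        p = prune(g)
        if len(p.samples()) >= min_samples:
            return model, h, p, obscure(p)
    raise RuntimeError("no fixture with enough samples found")


def seirs_fixture(seed: int, N: int = 20, beta: float = 3.0,
                  sigma: float = 2.0, gamma: float = 1.0, psi: float = 0.2,
                  omega: float = 0.5, I0: int = 2, horizon: float = 3.0,
                  min_samples: int = 2, max_samples: int = 4):
    """SEIRS fixture whose pruned genealogy has a bounded sample count."""
    model = builtin_model("seirs", {"N": N, "beta": beta, "sigma": sigma,
                                    "gamma": gamma, "psi": psi,
                                    "omega": omega, "I0": I0})
    for s in range(seed, seed + 2000):
        h, g = simulate_genealogy(model, horizon, s)
        p = prune(g)
        if min_samples <= len(p.samples()) <= max_samples:
            return model, h, p, obscure(p)
    raise RuntimeError("no fixture with the requested sample count found")


def worked_example_trees() -> dict[str, Genealogy]:
    """Small hand-built genealogies used in worked examples and tests."""
    out: dict[str, Genealogy] = {}
    # two samples at t=1 coalescing at t=0.5 (single deme, obscured)
    z = ObscuredGenealogy(1.0)
    r = z.add_node(0.0, "root")
    b = z.add_node(0.5, "internal", parent=r)
    z.add_node(1.0, "sample", parent=b, label="s1")
    z.add_node(1.0, "sample", parent=b, label="s2")
    out["pair_coalescent"] = z
    # colored two-deme chain with an E->I inline node and an inline sample
    p = PrunedGenealogy(2.0)
    r = p.add_node(0.0, "root")
    m = p.add_node(0.8, "internal", deme="E", parent=r)   # E -> I migration
    s1 = p.add_node(1.2, "sample", deme="I", parent=m, label="s1")
    p.add_node(2.0, "sample", deme="I", parent=s1, label="s2")
    out["colored_chain"] = p
    return out


def generate_fixtures(out_dir, seed: int) -> dict:
    """Write the fixture corpus and return (and save) its manifest."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}, "families": []}

    def save(name, text):
        path = out / name
        path.write_text(text)
        manifest["files"][name] = hashlib.sha256(
            text.encode()).hexdigest()

    def emit(family, name, model, h, p, z):
        manifest["families"].append(family)
        save(f"{name}.cfg.yaml", model_to_config(model))
        save(f"{name}.events.tsv", h.to_tsv())
        save(f"{name}.colored.nwk", write_newick(p))
        save(f"{name}.obscured.nwk", write_newick(z))

    for i in range(3):
        model, h, p, z = kingman_fixture(seed + i)
        emit("moran_kingman", f"moran_kingman_{i}", model, h, p, z)
        model, h, p, z = moran_serial_fixture(seed + 10 * i + 1)
        emit("moran_serial", f"moran_serial_{i}", model, h, p, z)
    for i, (lam, mu, psi, rho) in enumerate(
            [(1.2, 0.6, 0.4, 0.7), (1.5, 1.0, 0.5, 1.0),
             (0.8, 0.3, 0.6, 0.5)]):
        model, h, p, z = lbd_fixture(seed + i, lam=lam, mu=mu, psi=psi,
                                     rho=rho)
        emit("lbd", f"lbd_{i}", model, h, p, z)
    for N in (10, 20, 30):
        model, h, p, z = seirs_fixture(seed, N=N)
        emit("seirs", f"seirs_N{N}", model, h, p, z)
    for name, tree in worked_example_trees().items():
        manifest["families"].append("worked_example")
        save(f"{name}.nwk", write_newick(tree))
    manifest["families"] = sorted(set(manifest["families"]))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
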