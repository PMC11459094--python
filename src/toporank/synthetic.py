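"""Synthetic chemical-like graphs and property vectors for testing.

Two generators make every stage of the pipeline testable without external
data: random connected graphs with bounded degree (standing in for
hydrogen-suppressed molecules), and property vectors with an *exactly*
prescribed sample correlation against a given descriptor vector, so the
correlation -> weight -> ranking chain can be round-tripped
deterministically.

All randomness flows through a single :class:`numpy.random.Generator`
derived from one integer seed; the same seed reproduces the same outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import ConstantVectorError, InfeasibleConfigError
from .indices import index_table
from .molgraph import MolecularGraph, build_graph

__all__ = [
    "SyntheticConfig",
    "random_molecular_graph",
    "correlated_property",
    "synthetic_panel",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic molecule panel.

    ``n_atoms`` heavy atoms per molecule, degrees capped at ``max_degree``
    (4 by default — the common heavy-atom valence), ``n_molecules`` in the
    panel, and a property generated at sample correlation ``target_r``
    against the first Zagreb index column (exact when ``noise_sd`` is 0,
    else jittered).
    """

    n_atoms: int = 13
    max_degree: int = 4
    n_molecules: int = 16
    target_r: float = 0.7
    noise_sd: float = 0.0
    seed: int = 0


def _rng(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_molecular_graph(
    n_atoms: int,
    max_degree: int = 4,
    rng: int | np.random.Generator | None = None,
) -> MolecularGraph:
    """Random connected simple graph with all degrees <= ``max_degree``.

    Built as a random spanning tree (each new vertex attaches to a uniform
    choice among vertices still below the degree cap) plus a random number
    of extra degree-respecting edges, giving tree-like skeletons with a few
    rings — qualitatively like small-molecule graphs.
    """
    if n_atoms < 2:
        raise InfeasibleConfigError("need at least 2 atoms")
    if max_degree < 1 or (max_degree == 1 and n_atoms > 2):
        raise InfeasibleConfigError(
            f"max_degree={max_degree} admits no connected graph on {n_atoms} atoms"
        )
    gen = _rng(rng)
    degree = np.zeros(n_atoms, dtype=int)
    edges: list[tuple[int, int]] = []
    for v in range(1, n_atoms):
        open_slots = [u for u in range(v) if degree[u] < max_degree]
        if not open_slots:
            raise InfeasibleConfigError(
                f"cannot attach atom {v}: every placed atom is at max_degree"
            )
        u = int(gen.choice(open_slots))
        edges.append((u, v))
        degree[u] += 1
        degree[v] += 1
    # sprinkle ring-closing edges where both endpoints have spare valence
    existing = {frozenset(e) for e in edges}
    n_extra = int(gen.integers(0, max(1, n_atoms // 4) + 1))
    for _ in range(n_extra * 4):  # bounded retries
        if n_extra == 0:
            break
        candidates = np.flatnonzero(degree < max_degree)
        if candidates.size < 2:
            break
        u, v = (int(x) for x in gen.choice(candidates, size=2, replace=False))
        if frozenset((u, v)) in existing:
            continue
        edges.append((u, v))
        existing.add(frozenset((u, v)))
        degree[u] += 1
        degree[v] += 1
        n_extra -= 1
    return build_graph(edges)


def correlated_property(
    x: Sequence[float],
    target_r: float,
    rng: int | np.random.Generator | None = None,
    *,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Property vector whose sample Pearson correlation with ``x`` is ``target_r``.

    Draws a noise vector, projects it orthogonal to ``x`` (and the
    constant), standardizes both parts and blends them as
    ``r * z_x + sqrt(1 - r^2) * z_perp``, which makes the sample
    correlation *exactly* ``target_r``.  A positive ``noise_sd`` adds
    Gaussian jitter afterwards, trading exactness for realism.
    """
    gen = _rng(rng)
    xa = np.asarray(x, dtype=float)
    if xa.ndim != 1 or xa.shape[0] < 3:
        raise ValueError("x must be one-dimensional with at least 3 entries")
    if np.ptp(xa) == 0:
        raise ConstantVectorError("cannot target a correlation against a constant x")
    if not -1.0 < target_r < 1.0:
        raise ValueError(f"target_r must lie in (-1, 1), got {target_r}")
    zx = (xa - xa.mean()) / xa.std()
    for _ in range(100):
        e = gen.standard_normal(xa.shape[0])
        e = e - e.mean()
        e = e - (e @ zx) / (zx @ zx) * zx
        if e.std() > 1e-12:
            break
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("could not draw a noise vector independent of x")
    ze = e / e.std()
    y = target_r * zx + np.sqrt(1.0 - target_r**2) * ze
    if noise_sd > 0:
        y = y + noise_sd * gen.standard_normal(y.shape)
    return y


def synthetic_panel(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Index table and correlated property for a panel of random molecules.

    Returns the molecules x indices DataFrame (labels ``mol_00`` ...) and a
    property Series with sample correlation ``config.target_r`` against the
    M1 column (exact when ``config.noise_sd == 0``).
    """
    gen = np.random.default_rng(config.seed)
    graphs = {
        f"mol_{i:02d}": random_molecular_graph(
            config.n_atoms, config.max_degree, gen
        )
        for i in range(config.n_molecules)
    }
    table = index_table(graphs)
    prop = correlated_property(
        table["M1"].to_numpy(), config.target_r, gen, noise_sd=config.noise_sd
    )
    return table, pd.Series(prop, index=table.index, name="property")
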