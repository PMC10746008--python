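"""Monte-Carlo simulator of the Stable Ecotype Model.

The model: a sample of n gene lineages is distributed over ``npop`` ecotypes.
Looking backward in time, two kinds of events occur with exponential waiting
times (branch lengths are measured in expected substitutions per site):

* **periodic selection** — at rate ``sigma`` per ecotype with two or more
  surviving lineages, an adaptive sweep purges the ecotype's diversity; all of
  its lineages coalesce into one.
* **ecotype formation** (viewed backward, an ecotype *merge*) — at rate
  ``omega`` per ecotype while at least two ecotypes remain, an ecotype merges
  back into a uniformly chosen other ecotype.

The process stops at a total backward ``depth``; any surviving lineages join
at the root. A random root sequence of length L then evolves down the
genealogy under the Jukes-Cantor model, with per-branch substitution
probability p(b) = (3/4)(1 - exp(-4b/3)), and the simulated alignment is
summarised as a binning curve. The fraction of replicates whose curve matches
an observed curve (within a multiplicative tolerance band at every criterion)
is the likelihood of the parameter triple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binning import DEFAULT_CRITERIA, BinningCurve, curve_from_pdist

_SURJECTION_TRIES = 200


@dataclass
class EcosimParams:
    """The three fitted quantities of the model.

    omega
        net ecotype-formation rate (events per ecotype per unit branch
        length, substitutions/site).
    sigma
        periodic-selection rate (events per ecotype per unit branch length).
    npop
        number of ecotype (or geotype) populations, integer >= 1.
    """

    omega: float
    sigma: float
    npop: int

    def __post_init__(self) -> None:
        if self.omega < 0 or self.sigma < 0:
            raise ValueError("rates must be non-negative")
        self.npop = int(self.npop)
        if self.npop < 1:
            raise ValueError("npop must be >= 1")


@dataclass
class MatchRule:
    """How a simulated binning curve is compared with the observed one.

    A replicate matches when, at every criterion, the observed count lies in
    the nearest-integer band [round(sim/tolerance), round(sim*tolerance)].
    Rounding to nearest keeps a 10% band meaning 10%: counts below 5 must
    match exactly while a count of 20 is allowed +/-2. ``tolerance`` 1.0
    demands exact equality; ``inf`` accepts everything.
    """

    tolerance: float = 1.1
    criteria: tuple[float, ...] = DEFAULT_CRITERIA

    def __post_init__(self) -> None:
        if self.tolerance < 1.0:
            raise ValueError("tolerance must be >= 1")
        self.criteria = tuple(float(c) for c in self.criteria)


@dataclass
class Genealogy:
    """A rooted coalescent genealogy as parent/time arrays.

    Nodes 0..n_leaves-1 are the sampled lineages (backward time 0); internal
    nodes are numbered in order of creation, so a parent always has a larger
    index than its children. ``time`` is backward time in substitutions/site;
    the branch above node v has length time[parent[v]] - time[v].
    """

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def leaf_labels(self) -> list[str]:
        return [f"t{i}" for i in range(self.n_leaves)]

    def to_newick(self, labels: Sequence[str] | None = None) -> str:
        labels = list(labels) if labels is not None else self.leaf_labels()
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            children[self.parent[v]].append(v)

        def fmt(v: int) -> str:
            blen = (
                self.time[self.parent[v]] - self.time[v]
                if self.parent[v] >= 0
                else 0.0
            )
            if not children[v]:
                return f"{labels[v]}:{blen:.8g}"
            inner = ",".join(fmt(c) for c in children[v])
            return f"({inner}):{blen:.8g}" if self.parent[v] >= 0 else f"({inner})"

        return fmt(self.root) + ";"


@dataclass
class ReplicateOutcome:
    """One simulated replicate: its binning curve and genealogy."""

    curve: BinningCurve
    genealogy: Genealogy
    matched: bool | None = None


def _assign_ecotypes(n: int, npop: int, rng: np.random.Generator) -> list[list[int]]:
    """Uniform assignment of n lineages to npop ecotypes, no ecotype empty.

    Rejection-sampled from the unconditioned uniform; if the occupancy
    condition is too improbable (npop close to n), falls back to seeding each
    ecotype with one lineage of a random permutation and spreading the rest
    uniformly.
    """
    if npop > n:
        raise ValueError(f"npop ({npop}) cannot exceed sample size ({n})")
    if npop == 1:
        return [list(range(n))]
    for _ in range(_SURJECTION_TRIES):
        assign = rng.integers(0, npop, size=n)
        if len(np.unique(assign)) == npop:
            break
    else:
        assign = np.empty(n, dtype=np.int64)
        perm = rng.permutation(n)
        assign[perm[:npop]] = np.arange(npop)
        assign[perm[npop:]] = rng.integers(0, npop, size=n - npop)
    return [list(np.nonzero(assign == e)[0]) for e in range(npop)]


def simulate_genealogy(
    params: EcosimParams,
    n: int,
    depth: float,
    rng: np.random.Generator,
    assignment: Sequence[Sequence[int]] | None = None,
) -> Genealogy:
    """Simulate the backward-in-time genealogy of n sampled lineages.

    ``assignment`` optionally fixes the lineage-to-ecotype layout (a list of
    lineage-index lists, one per ecotype); by default lineages are assigned
    uniformly at random conditioned on no ecotype being empty.
    """
    if n < 2:
        raise ValueError("need at least 2 sampled lineages")
    if depth <= 0:
        raise ValueError("depth must be positive")
    parent = np.full(2 * n, -1, dtype=np.int64)
    time = np.zeros(2 * n)
    next_node = n
    if assignment is not None:
        if sorted(i for eco in assignment for i in eco) != list(range(n)):
            raise ValueError("assignment must partition lineages 0..n-1")
        ecotypes = [list(eco) for eco in assignment if eco]
    else:
        ecotypes = _assign_ecotypes(n, params.npop, rng)
    t = 0.0
    while True:
        multi = [e for e in ecotypes if len(e) >= 2]
        rate_ps = params.sigma * len(multi)
        rate_form = params.omega * len(ecotypes) if len(ecotypes) >= 2 else 0.0
        total = rate_ps + rate_form
        if total == 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= depth:
            break
        if rng.random() * total < rate_ps:
            eco = multi[rng.integers(len(multi))]
            node = next_node
            next_node += 1
            time[node] = t
            for lin in eco:
                parent[lin] = node
            eco.clear()
            eco.append(node)
            ecotypes = [e for e in ecotypes if e]
        else:
            i = int(rng.integers(len(ecotypes)))
            j = int(rng.integers(len(ecotypes) - 1))
            if j >= i:
                j += 1
            ecotypes[j].extend(ecotypes[i])
            del ecotypes[i]
    survivors = [lin for eco in ecotypes for lin in eco]
    if len(survivors) > 1:
        node = next_node
        next_node += 1
        time[node] = depth
        for lin in survivors:
            parent[lin] = node
    return Genealogy(parent=parent[:next_node], time=time[:next_node], n_leaves=n)


def _sample_distinct(L: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct site indices in [0, L), uniform without replacement."""
    if 3 * k > L:
        return rng.permutation(L)[:k]
    chosen: set[int] = set()
    while len(chosen) < k:
        for v in rng.integers(0, L, size=k - len(chosen)):
            chosen.add(int(v))
    return np.fromiter(chosen, dtype=np.int64, count=k)


def _mutation_shifts(
    genealogy: Genealogy, L: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse Jukes-Cantor evolution down the genealogy.

    Across a branch of length b each site substitutes with probability
    p(b) = (3/4)(1 - exp(-4b/3)), changing to one of the other three bases.
    A substitution is a base shift of +1..+3 (mod 4) and shifts compose
    additively along a path, so the whole realisation is captured by the
    per-node cumulative shift at the sites mutated anywhere in the tree:
    the number of mutated sites per branch is Binomial(L, p(b)), their
    positions are uniform without replacement — exactly the per-site
    Bernoulli model, but touching only mutated columns.

    Returns (site_columns, shift_matrix) where shift_matrix[v, j] is node
    v's cumulative shift (mod 4) at site site_columns[j].
    """
    n_nodes = genealogy.n_nodes
    parent, time = genealogy.parent, genealogy.time
    blen = time[parent[: n_nodes - 1]] - time[: n_nodes - 1]
    p = 0.75 * -np.expm1(-4.0 * blen / 3.0)
    ks = rng.binomial(L, p)
    total = int(ks.sum())
    pos_all = rng.integers(0, L, size=total)
    ends = np.cumsum(ks)
    starts = ends - ks
    # enforce within-branch distinctness; redraw the (rare) colliding branches
    for v in np.nonzero(ks > 1)[0]:
        a, b = int(starts[v]), int(ends[v])
        if len(np.unique(pos_all[a:b])) < b - a:
            pos_all[a:b] = _sample_distinct(L, b - a, rng)
    shifts_all = rng.integers(1, 4, size=total)
    if total == 0:
        return np.empty(0, dtype=np.int64), np.zeros((n_nodes, 0), dtype=np.int64)
    cols, inv = np.unique(pos_all, return_inverse=True)
    acc = np.zeros((n_nodes, len(cols)), dtype=np.int64)
    for v in range(n_nodes - 2, -1, -1):
        acc[v] = acc[parent[v]]
        a, b = int(starts[v]), int(ends[v])
        if b > a:
            acc[v, inv[a:b]] += shifts_all[a:b]
    return cols, acc % 4


def evolve_sequences(
    genealogy: Genealogy, L: int, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a random root sequence down the genealogy under Jukes-Cantor.

    Returns the leaf states as a (n_leaves, L) array over {0, 1, 2, 3}.
    """
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    # shifts are drawn before the root so that the stream matches the
    # curve-only fast path (which never materialises a root sequence)
    cols, acc = _mutation_shifts(genealogy, L, rng)
    root_seq = rng.integers(0, 4, size=L, dtype=np.uint8)
    n = genealogy.n_leaves
    states = np.tile(root_seq, (n, 1))
    if len(cols):
        states[:, cols] = (states[:, cols] + acc[:n]) % 4
    return states


def leaf_p_distances(leaves: np.ndarray, L: int) -> np.ndarray:
    """Pairwise p-distance matrix of simulated leaf sequences."""
    seg = (leaves != leaves[0]).any(axis=0)
    sub = leaves[:, seg]
    if sub.shape[1] == 0:
        n = leaves.shape[0]
        return np.zeros((n, n))
    diff = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
    return diff / float(L)


def states_to_strings(leaves: np.ndarray) -> list[str]:
    lut = np.frombuffer(b"ACGT", dtype="S1")
    return [arr.tobytes().decode() for arr in lut[leaves]]


def simulate_replicate(
    params: EcosimParams,
    n: int,
    depth: float,
    L: int,
    rng: np.random.Generator,
    criteria: Sequence[float] = DEFAULT_CRITERIA,
) -> ReplicateOutcome:
    """One full model replicate: genealogy, sequences, binning curve."""
    genealogy = simulate_genealogy(params, n, depth, rng)
    leaves = evolve_sequences(genealogy, L, rng)
    p = leaf_p_distances(leaves, L)
    bins = curve_from_pdist(p, criteria)
    curve = BinningCurve(tuple(float(c) for c in criteria), bins)
    return ReplicateOutcome(curve=curve, genealogy=genealogy)


def _replicate_bins(
    params: EcosimParams,
    n: int,
    depth: float,
    L: int,
    rng: np.random.Generator,
    criteria: tuple[float, ...],
) -> tuple[int, ...]:
    """Hot-path variant of :func:`simulate_replicate`: curve only.

    Skips materialising sequences: pairwise differences are read off the
    cumulative mutation shifts directly (the root sequence cancels).
    """
    genealogy = simulate_genealogy(params, n, depth, rng)
    cols, acc = _mutation_shifts(genealogy, L, rng)
    sub = acc[:n]
    if sub.shape[1] == 0:
        p = np.zeros((n, n))
    else:
        p = (sub[:, None, :] != sub[None, :, :]).sum(axis=2) / float(L)
    return curve_from_pdist(p, criteria)


def curve_matches(
    sim_bins: Sequence[int], obs_bins: Sequence[int], tolerance: float
) -> bool:
    """Multiplicative band comparison at every criterion, rounded to nearest."""
    if math.isinf(tolerance):
        return True
    for s, o in zip(sim_bins, obs_bins):
        lo = math.floor(s / tolerance + 0.5)
        hi = math.floor(s * tolerance + 0.5)
        if not lo <= o <= hi:
            return False
    return True


def likelihood_estimate(
    params: EcosimParams,
    observed: BinningCurve,
    rule: MatchRule,
    R: int,
    n: int,
    depth: float,
    L: int,
    seed: int,
) -> float:
    """Match-fraction likelihood of a parameter triple.

    Runs R independent replicates; replicate i draws from a substream seeded
    by (seed, i), so increasing R extends — never reshuffles — the replicate
    set. Returns the fraction whose binning curve matches the observed curve
    under ``rule``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if observed.criteria != rule.criteria:
        raise ValueError("observed curve and match rule use different criteria grids")
    obs = observed.n_bins
    matched = 0
    for i in range(R):
        rng = np.random.default_rng([seed, i])
        bins = _replicate_bins(params, n, depth, L, rng, rule.criteria)
        if curve_matches(bins, obs, rule.tolerance):
            matched += 1
    return matched / R
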