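"""Parameter fitting and recursive ecotype demarcation.

``fit_parameters`` optimises the three Stable-Ecotype-Model parameters
against an observed binning curve with the Nelder-Mead downhill simplex,
working in (log10 omega, log10 sigma, log10 npop) space with npop rounded to
an integer inside every likelihood evaluation. Common random numbers (a
fixed replicate seed per restart) make the match-fraction objective
deterministic in the parameters, which Nelder-Mead tolerates far better than
a re-randomised objective.

``demarcate`` walks a rooted phylogeny depth-first from the root: a clade is
demarcated as one putative ecotype exactly when the maximum-likelihood
number of ecotypes for its leaf set equals one (omega and sigma held at the
global fit; only the integer ecotype count is scanned per clade). Otherwise
the walk descends into the children, so the result is a partition of the
leaves into clades of the tree.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode
from skbio.tree import nj as _skbio_nj

from .binning import DEFAULT_CRITERIA, FINE_CRITERIA, BinningCurve, curve_from_pdist
from .ecosim import EcosimParams, MatchRule, likelihood_estimate
from .seq_core import Alignment, DistanceMatrix, distance_matrix, jc_distance

logger = logging.getLogger(__name__)

#: Relative-likelihood threshold for approximate 95% profile confidence
#: intervals: exp(-chi2_{0.95,1}/2).
CI_THRESHOLD = math.exp(-3.841459 / 2.0)


class NewickParseError(ValueError):
    """Malformed newick input (unbalanced parentheses, duplicate labels...)."""


def default_depth(corrected: np.ndarray) -> float:
    """Simulation depth (time to root) from a corrected distance matrix.

    Half the *median* off-diagonal corrected distance. In a clade of several
    diverged populations most pairs sit at the deepest split, so the median
    estimates twice the root depth without the upward bias of the maximum
    (an extreme order statistic over hundreds of binomially noisy pairs);
    in a single tight population it estimates the shared coalescence time.
    """
    n = corrected.shape[0]
    off = corrected[np.triu_indices(n, 1)]
    return max(float(np.median(off)) / 2.0, 1e-6)


@dataclass
class PhyloTree:
    """A rooted tree with leaves labelled by sequence id.

    Thin wrapper around a ``skbio.TreeNode``; branch lengths are expected
    substitutions per site, missing lengths read as 0.
    """

    tree: TreeNode

    def __post_init__(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickParseError(f"duplicate leaf labels: {dup}")
        for node in self.tree.traverse():
            if node.length is None:
                node.length = 0.0
            elif node.length < 0:
                logger.info(
                    "clamping negative branch length %.3g to 0", node.length
                )
                node.length = 0.0

    def leaf_labels(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.tips())


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a rooted tree."""
    try:
        tree = TreeNode.read(io.StringIO(text))
    except Exception as exc:  # skbio raises several parser exception types
        raise NewickParseError(f"could not parse newick: {exc}") from exc
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    buf = io.StringIO()
    tree.tree.write(buf)
    return buf.getvalue().strip()


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a (corrected) distance matrix.

    The unrooted NJ topology is midpoint-rooted; negative branch-length
    estimates are clamped to zero with the deficit logged. Two taxa are
    returned as a cherry split evenly at the midpoint.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("tree construction needs at least 2 taxa")
    if n == 2:
        d = float(dm.data[0, 1])
        a = TreeNode(name=dm.ids[0], length=d / 2)
        b = TreeNode(name=dm.ids[1], length=d / 2)
        return PhyloTree(TreeNode(children=[a, b]))
    sk = _SkbioDM(dm.data, ids=dm.ids)
    unrooted = _skbio_nj(sk)
    for node in unrooted.traverse():
        if node.length is None:
            node.length = 0.0
    try:
        rooted = unrooted.root_at_midpoint()
    except (AttributeError, ValueError):
        # degenerate (near-zero) matrices can defeat midpoint search; the
        # trifurcating NJ root is as good a root as any in that case
        logger.info("midpoint rooting failed on a degenerate tree; keeping NJ root")
        rooted = unrooted
    return PhyloTree(rooted)


def root_with_outgroup(tree: PhyloTree, outgroup: Sequence[str]) -> PhyloTree:
    """Re-root at the branch leading to the (monophyletic) outgroup taxa."""
    out = list(outgroup)
    if len(out) == 1:
        node = tree.tree.find(out[0])
    else:
        node = tree.tree.lca(out)
    return PhyloTree(tree.tree.root_at(node.parent if node.parent else node))


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    """Best-fit model parameters with likelihood and bookkeeping."""

    best: EcosimParams
    likelihood: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    evaluations: int = 0
    seed: int = 0
    non_identifiable: bool = False


def _objective_factory(observed, rule, R, n, depth, L, eval_seed, counter):
    def objective(x: np.ndarray) -> float:
        counter[0] += 1
        omega = 10.0 ** float(x[0])
        sigma = 10.0 ** float(x[1])
        npop = int(np.clip(round(10.0 ** float(x[2])), 1, n))
        params = EcosimParams(omega=omega, sigma=sigma, npop=npop)
        return -likelihood_estimate(params, observed, rule, R, n, depth, L, eval_seed)

    return objective


def fit_parameters(
    observed: BinningCurve,
    n: int,
    depth: float,
    L: int,
    rule: MatchRule | None = None,
    R: int = 200,
    restarts: int = 2,
    seed: int = 0,
    maxfev: int = 40,
) -> FitResult:
    """Fit (omega, sigma, npop) to an observed binning curve.

    Nelder-Mead over log10-parameters, best of ``restarts`` independent
    starts. The first start is heuristic — npop from the bin count at the
    0.99 criterion, sigma from the depth scale — and the rest are drawn from
    broad log-uniform ranges. Each restart evaluates the match-fraction
    likelihood with its own fixed replicate seed (common random numbers).
    """
    rule = rule or MatchRule(criteria=observed.criteria)
    if observed.criteria != rule.criteria:
        raise ValueError("observed curve and match rule use different criteria grids")
    total_evals = 0

    # stage 1: coarse lattice scan at reduced replicate count, common random
    # numbers — the match-fraction surface is mostly a zero plateau, so the
    # simplex needs to start inside (or next to) the matching region
    mid_idx = min(
        range(len(observed.criteria)),
        key=lambda i: abs(observed.criteria[i] - 0.99),
    )
    npop0 = max(1, min(observed.n_bins[mid_idx], n))
    npop_grid = sorted(
        {v for v in (1, 2, 3, 4, 6, 8, 12, npop0 - 1, npop0, npop0 + 1) if 1 <= v <= n}
    )
    sigma_grid = [
        m / depth for m in (0.3, 1.0, 3.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 1000.0)
    ]
    omega_grid = [m / depth for m in (0.01, 0.3)]
    R_scan = max(50, R // 4)
    scan_seed = _sub_seed(seed, 0x5CA)
    scored: list[tuple[float, tuple[float, float, int]]] = []
    for npop_v in npop_grid:
        for sigma_v in sigma_grid:
            for omega_v in omega_grid:
                ll = likelihood_estimate(
                    EcosimParams(omega=omega_v, sigma=sigma_v, npop=npop_v),
                    observed, rule, R_scan, n, depth, L, scan_seed,
                )
                total_evals += 1
                scored.append((ll, (omega_v, sigma_v, npop_v)))
    scored.sort(key=lambda t: -t[0])

    # stage 2: Nelder-Mead refinement from the best scan points
    starts = [
        np.array([math.log10(o), math.log10(s), math.log10(np_)])
        for _, (o, s, np_) in scored[: max(1, restarts)]
    ]
    best_x = starts[0]
    best_ll = -1.0
    for r, x0 in enumerate(starts):
        counter = [0]
        objective = _objective_factory(
            observed, rule, R, n, depth, L, _sub_seed(seed, 1 + r), counter
        )
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 0.02, "fatol": 1.0 / (2 * R)},
        )
        total_evals += counter[0]
        if -res.fun > best_ll:
            best_ll = float(-res.fun)
            best_x = res.x
    best = EcosimParams(
        omega=10.0 ** float(best_x[0]),
        sigma=10.0 ** float(best_x[1]),
        npop=int(np.clip(round(10.0 ** float(best_x[2])), 1, n)),
    )
    result = FitResult(
        best=best,
        likelihood=float(max(best_ll, 0.0)),
        evaluations=total_evals,
        seed=seed,
        non_identifiable=bool(best_ll <= 0.0),
    )
    if result.non_identifiable:
        logger.warning("all restarts returned likelihood 0; fit is unidentifiable")
    return result


def _sub_seed(seed: int, tag: int) -> int:
    """Deterministic 31-bit stream seed derived from (seed, tag)."""
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] >> 1)


def profile_ci(
    best: EcosimParams,
    parameter: str,
    observed: BinningCurve,
    R: int,
    n: int,
    depth: float,
    L: int,
    rule: MatchRule | None = None,
    grid: Sequence[float] | None = None,
    seed: int = 0,
    threshold: float = CI_THRESHOLD,
) -> tuple[float, float]:
    """Approximate 95% profile confidence interval for one parameter.

    The parameter sweeps a log-spaced grid (default: two decades around the
    best value; integers for npop) while the others stay at the best fit.
    The CI is the extremal grid span where relative likelihood
    L(theta)/L(theta_hat) >= exp(-chi2_{0.95,1}/2) ~= 0.1465, forced to
    contain the best value. A flat zero profile returns the full grid span.
    """
    if parameter not in ("omega", "sigma", "npop"):
        raise ValueError(f"unknown parameter {parameter!r}")
    center = getattr(best, parameter)
    if grid is None:
        if parameter == "npop":
            raw = center * np.logspace(-1, 1, 13)
            ints = {int(np.clip(round(v), 1, n)) for v in raw}
            ints.update({max(1, center - 1), center, min(n, center + 1)})
            grid = sorted(ints)
        else:
            c = max(center, 1e-8)
            grid = list(np.logspace(math.log10(c) - 1, math.log10(c) + 1, 9))
    grid = [float(g) for g in grid]
    rule = rule or MatchRule(criteria=observed.criteria)
    eval_seed = _sub_seed(seed, 0xC1)

    def ll_at(value: float) -> float:
        kwargs = {"omega": best.omega, "sigma": best.sigma, "npop": best.npop}
        kwargs[parameter] = int(round(value)) if parameter == "npop" else value
        return likelihood_estimate(
            EcosimParams(**kwargs), observed, rule, R, n, depth, L, eval_seed
        )

    l_hat = ll_at(center)
    if l_hat <= 0.0:
        logger.warning("profile CI unbounded: best-fit likelihood is 0 on the grid")
        return (min(grid + [center]), max(grid + [center]))
    inside = [g for g in grid if ll_at(g) / l_hat >= threshold]
    inside.append(float(center))
    return (min(inside), max(inside))


# ---------------------------------------------------------------------------
# Recursive demarcation


@dataclass
class DemarcationConfig:
    """Settings for the recursive clade walk."""

    R: int = 400
    rule: MatchRule = field(default_factory=lambda: MatchRule(criteria=FINE_CRITERIA))
    npop_cap: int = 12
    seed: int = 0
    criteria: tuple[float, ...] = FINE_CRITERIA
    #: identity level below which cluster structure counts as real population
    #: separation rather than within-population microheterogeneity
    structure_criterion: float = 0.995

    def __post_init__(self) -> None:
        self.criteria = tuple(float(c) for c in self.criteria)
        if self.rule.criteria != self.criteria:
            self.rule = MatchRule(tolerance=self.rule.tolerance, criteria=self.criteria)


@dataclass
class DemarcatedClade:
    clade_id: str
    members: list[str]
    ml_npop: int


@dataclass
class Demarcation:
    """A partition of the tree's leaves into putative ecotypes."""

    assignments: dict[str, str]
    clades: list[DemarcatedClade]

    def n_ecotypes(self) -> int:
        return len(self.clades)


def _clade_ml_npop(
    p_sub: np.ndarray,
    depth: float,
    L: int,
    omega: float,
    sigma: float,
    config: DemarcationConfig,
    node_seed: int,
) -> int:
    """ML ecotype count for one clade, omega/sigma fixed at the global fit.

    Scans integer npop from 1 up to the cap (bounded by the clade's distinct
    sequence count — more ecotypes than variants cannot improve the match).
    The single-population hypothesis wins unless it is *rejected*: npop = 1
    must fall outside the relative-likelihood band used for the 95% profile
    CIs (L(1)/L(argmax) < exp(-chi2_0.95,1/2)). A one-population clade and a
    clade of several barely diverged populations produce nearly identical
    binning curves, so a plain noisy argmax over-splits; demanding strong
    evidence against npop=1 resolves that degeneracy toward parsimony.
    """
    n = p_sub.shape[0]
    bins = curve_from_pdist(p_sub, config.criteria)
    observed = BinningCurve(config.criteria, bins)

    # resolution floor: a clade that is one bin at every criterion at or
    # below the structure criterion shows only microheterogeneity, whose
    # scale is set by the (noisily estimated) periodic-selection rate; such
    # clades are treated as single populations without simulation
    deep_idx = [
        i for i, c in enumerate(config.criteria) if c <= config.structure_criterion
    ]
    if not any(observed.n_bins[i] > 1 for i in deep_idx):
        return 1

    def ll(npop: int) -> float:
        return likelihood_estimate(
            EcosimParams(omega=omega, sigma=sigma, npop=npop),
            observed,
            config.rule,
            config.R,
            n,
            depth,
            L,
            node_seed,
        )

    n_distinct = observed.n_bins[0] if observed.criteria[0] == 1.0 else n
    cap = min(n, config.npop_cap, n_distinct + 1)
    lls = [ll(k) for k in range(1, cap + 1)]
    best_ll = max(lls)
    if best_ll <= 0.0:
        # structured, but no ecotype count explains the clade at the fitted
        # rates: signal the walk to descend rather than lump
        return 0
    if lls[0] >= CI_THRESHOLD * best_ll:
        return 1
    return int(np.argmax(lls)) + 1


def demarcate(
    tree: PhyloTree,
    aln: Alignment,
    global_fit: FitResult,
    config: DemarcationConfig | None = None,
) -> Demarcation:
    """Partition the leaves of a rooted tree into putative ecotypes.

    Depth-first from the root: a clade whose maximum-likelihood ecotype
    count equals one is demarcated whole (the walk does not descend);
    otherwise its children are visited. Singletons and clades of identical
    sequences are demarcated directly. Per-clade simulation depth is half
    the deepest corrected divergence inside the clade.
    """
    config = config or DemarcationConfig()
    leaves = tree.leaf_labels()
    missing = [l for l in leaves if l not in set(aln.ids)]
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {missing}")
    sub_aln = aln.subset(leaves)
    dm = distance_matrix(sub_aln, kind="p_distance")
    index = {rid: i for i, rid in enumerate(dm.ids)}
    L = sub_aln.length
    omega, sigma = global_fit.best.omega, global_fit.best.sigma

    clades: list[DemarcatedClade] = []
    assignments: dict[str, str] = {}
    node_counter = [0]

    def emit(members: list[str], ml_npop: int) -> None:
        cid = f"E{len(clades) + 1}"
        clades.append(DemarcatedClade(clade_id=cid, members=members, ml_npop=ml_npop))
        for m in members:
            assignments[m] = cid

    def visit(node: TreeNode) -> None:
        node_counter[0] += 1
        members = [t.name for t in node.tips()] if node.children else [node.name]
        if len(members) == 1:
            emit(members, 1)
            return
        idx = [index[m] for m in members]
        p_sub = dm.data[np.ix_(idx, idx)]
        p_max = float(p_sub.max())
        if p_max == 0.0:
            emit(members, 1)
            return
        # clade depth = deepest corrected split / 2: a k-population split
        # inside this clade would sit exactly at its deepest divergence,
        # which maximises the contrast against the one-population model
        depth = jc_distance(min(p_max, 0.7499)) / 2.0
        node_seed = _sub_seed(config.seed, node_counter[0])
        ml_npop = _clade_ml_npop(p_sub, depth, L, omega, sigma, config, node_seed)
        if ml_npop == 1:
            emit(members, 1)
        else:
            for child in node.children:
                visit(child)

    visit(tree.tree)
    return Demarcation(assignments=assignments, clades=clades)


def demarcation_to_tsv(dem: Demarcation) -> str:
    lines = ["sequence_id\tecotype_id\tml_npop"]
    by_clade = {c.clade_id: c for c in dem.clades}
    for seq_id in sorted(dem.assignments):
        cid = dem.assignments[seq_id]
        lines.append(f"{seq_id}\t{cid}\t{by_clade[cid].ml_npop}")
    return "\n".join(lines) + "\n"
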