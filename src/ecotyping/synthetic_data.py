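"""Ground-truthed synthetic inputs for every pipeline stage.

The alignment generator drives the Stable-Ecotype-Model simulator itself
(with a balanced, known lineage-to-ecotype assignment), so simulated
libraries look like real hot-spring 16S clone libraries: tight clusters of
near-identical sequences (microheterogeneity of a few nucleotides) separated
by 0.2-4% divergence. Genome pairs, clone libraries with copy-number
structure, and environmentally patterned site metadata follow the same
seed-deterministic discipline: every generator records its ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecosim import (
    EcosimParams,
    evolve_sequences,
    leaf_p_distances,
    simulate_genealogy,
    states_to_strings,
)
from .seq_core import Alignment, SequenceRecord, jc_distance

_MAX_RETRIES = 500


class GenerationInfeasibleError(RuntimeError):
    """The divergence bounds could not be realised within the retry budget."""


@dataclass
class EnvProfile:
    """Per-ecotype environmental distribution (means and spreads)."""

    temperature_mean: float
    ph_mean: float
    temperature_sd: float = 0.5
    ph_sd: float = 0.1


@dataclass
class SynthConfig:
    """Study-like conditions for the ecotype-structured alignment generator.

    Defaults mirror the regime of closely related thermophilic populations:
    within-ecotype divergence of a few tenths of a percent
    (microheterogeneity) against >= 1.5-4% separation between ecotypes.
    """

    n_ecotypes: int = 4
    seqs_per_ecotype: int = 10
    L: int = 750
    within_div: float = 0.003
    between_div: float = 0.03
    env_profile: dict[str, EnvProfile] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ecotypes < 1 or self.seqs_per_ecotype < 1 or self.L < 1:
            raise ValueError("counts and length must be >= 1")
        if self.n_ecotypes > 1 and not self.within_div < self.between_div:
            raise ValueError("within_div must be smaller than between_div")


def solve_params(cfg: SynthConfig) -> tuple[EcosimParams, float]:
    """Model parameters and depth that realise the configured divergences.

    Backward logic: with omega = 0 the ecotypes stay separate until the root
    at ``depth``, so between-ecotype p-distance concentrates near the
    divergence of two lineages separated for 2*depth. Within an ecotype, all
    lineages coalesce at its most recent periodic selection, an Exp(sigma)
    time ago, so sigma = 4/within_div puts the mean within-pair divergence at
    half the configured ceiling. Depth carries a 15% margin so the realised
    minimum between-ecotype divergence clears its acceptance bound.
    """
    sigma = 1e9 if cfg.within_div == 0 else 4.0 / cfg.within_div
    if cfg.n_ecotypes == 1:
        depth = max(cfg.within_div, 1e-4)
    else:
        target = min(cfg.between_div * 1.15, 0.70)
        depth = jc_distance(target) / 2.0
    return EcosimParams(omega=0.0, sigma=sigma, npop=cfg.n_ecotypes), depth


def simulate_ecotype_alignment(
    cfg: SynthConfig,
) -> tuple[Alignment, dict[str, str]]:
    """Generate an ecotype-structured alignment with known labels.

    Returns the alignment and the true assignment (sequence id ->
    ecotype id). The realised divergences are checked against the configured
    bounds (within <= 1.2x the ceiling, minimum between >= 0.8x the floor)
    and the draw is retried up to a fixed budget before giving up.
    """
    params, depth = solve_params(cfg)
    n = cfg.n_ecotypes * cfg.seqs_per_ecotype
    assignment = [
        list(range(e * cfg.seqs_per_ecotype, (e + 1) * cfg.seqs_per_ecotype))
        for e in range(cfg.n_ecotypes)
    ]
    labels = {}
    ids = []
    for e in range(cfg.n_ecotypes):
        for k in range(cfg.seqs_per_ecotype):
            sid = f"E{e + 1}-S{k + 1}"
            ids.append(sid)
            labels[sid] = f"E{e + 1}"
    eco_index = np.repeat(np.arange(cfg.n_ecotypes), cfg.seqs_per_ecotype)
    last_violation = "no attempts made"
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng([cfg.seed, attempt])
        genealogy = simulate_genealogy(params, n, depth, rng, assignment=assignment)
        leaves = evolve_sequences(genealogy, cfg.L, rng)
        p = leaf_p_distances(leaves, cfg.L)
        same = eco_index[:, None] == eco_index[None, :]
        off = ~np.eye(n, dtype=bool)
        within_max = float(p[same & off].max()) if (same & off).any() else 0.0
        if cfg.within_div == 0:
            within_ok = within_max == 0.0
        else:
            within_ok = within_max <= 1.2 * cfg.within_div
        if cfg.n_ecotypes == 1:
            between_ok, between_min = True, math.nan
        else:
            between_min = float(p[~same].min())
            between_ok = between_min >= 0.8 * cfg.between_div
        if within_ok and between_ok:
            seqs = states_to_strings(leaves)
            records = [
                SequenceRecord(id=ids[i], seq=seqs[i], source="synthetic")
                for i in range(n)
            ]
            return Alignment(records), labels
        last_violation = (
            f"within_max={within_max:.4f} (bound {1.2 * cfg.within_div:.4f}), "
            f"between_min={between_min:.4f} (bound {0.8 * cfg.between_div:.4f})"
        )
    raise GenerationInfeasibleError(
        f"could not satisfy divergence bounds in {_MAX_RETRIES} tries: {last_violation}"
    )


def simulate_genome_pair(
    length: int, divergence: float, seed: int = 0
) -> tuple[str, str, int]:
    """A random genome and a copy with i.i.d. substitutions.

    Each site of the copy substitutes with probability ``divergence`` to one
    of the other three bases. Returns (genome_a, genome_b,
    realised_substitution_count).
    """
    if not 0 <= divergence < 0.75:
        raise ValueError("divergence must be in [0, 0.75)")
    rng = np.random.default_rng([seed, 0xA])
    a = rng.integers(0, 4, size=length, dtype=np.uint8)
    mask = rng.random(length) < divergence
    b = a.copy()
    k = int(mask.sum())
    if k:
        b[mask] = (b[mask] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4
    sa, sb = states_to_strings(np.vstack([a, b]))
    return sa, sb, k


def simulate_clone_library(
    tally_spec: list[tuple[str, int]],
    singletons: int = 0,
    L: int = 741,
    muts_per_variant: int = 1,
    seed: int = 0,
) -> list[SequenceRecord]:
    """A clone library with prescribed copy-number structure.

    ``tally_spec`` lists (variant name, copy count); the first variant is the
    base sequence and each later variant (and each singleton) differs from it
    at its own disjoint set of ``muts_per_variant`` positions, so all
    variants are distinct and :func:`ecotyping.seq_core.clone_tally` inverts
    the library exactly. Records are emitted in shuffled order.
    """
    if not tally_spec:
        raise ValueError("tally_spec must be nonempty")
    n_variants = len(tally_spec) + singletons
    needed = (n_variants - 1) * muts_per_variant
    if needed > L:
        raise ValueError("sequence too short for the requested number of variants")
    rng = np.random.default_rng([seed, 0xC])
    base = rng.integers(0, 4, size=L, dtype=np.uint8)
    positions = rng.permutation(L)[:needed]
    variants: list[np.ndarray] = [base]
    for v in range(1, n_variants):
        arr = base.copy()
        pos = positions[(v - 1) * muts_per_variant: v * muts_per_variant]
        arr[pos] = (arr[pos] + rng.integers(1, 4, size=len(pos), dtype=np.uint8)) % 4
        variants.append(arr)
    seqs = states_to_strings(np.vstack(variants))
    records: list[SequenceRecord] = []
    for v, (name, copies) in enumerate(tally_spec):
        for c in range(copies):
            records.append(
                SequenceRecord(id=f"{name}_c{c + 1}", seq=seqs[v], source="synthetic")
            )
    for s in range(singletons):
        records.append(
            SequenceRecord(
                id=f"SGL{s + 1}", seq=seqs[len(tally_spec) + s], source="synthetic"
            )
        )
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def default_env_profile(ecotypes: list[str]) -> dict[str, EnvProfile]:
    """Distinct, hot-spring-like temperature/pH niches, one per ecotype."""
    return {
        eco: EnvProfile(
            temperature_mean=38.0 + 4.0 * i,
            ph_mean=5.4 + 0.4 * i,
            temperature_sd=0.5,
            ph_sd=0.1,
        )
        for i, eco in enumerate(sorted(ecotypes))
    }


def simulate_site_metadata(
    assignments: dict[str, str],
    env_profile: dict[str, EnvProfile] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sequence environmental metadata drawn from each ecotype's niche.

    Temperature and pH are independent normal draws with the profile's means
    and spreads; zero spreads reproduce the means exactly.
    """
    ecotypes = sorted(set(assignments.values()))
    profile = env_profile or default_env_profile(ecotypes)
    missing = [e for e in ecotypes if e not in profile]
    if missing:
        raise ValueError(f"ecotypes without an environmental profile: {missing}")
    rng = np.random.default_rng([seed, 0xE])
    rows = []
    for sid in sorted(assignments):
        eco = assignments[sid]
        p = profile[eco]
        rows.append(
            {
                "sequence_id": sid,
                "site_id": f"site-{eco}",
                "ecotype": eco,
                "temperature_c": p.temperature_mean
                + (p.temperature_sd * rng.standard_normal() if p.temperature_sd else 0.0),
                "ph": p.ph_mean + (p.ph_sd * rng.standard_normal() if p.ph_sd else 0.0),
            }
        )
    return pd.DataFrame(rows)
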