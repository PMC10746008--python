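"""Clade-by-environment association via a permutation eta-squared statistic.

Demarcated ecotypes are qualitatively expected to track environmental
parameters (temperature, pH). This module formalises that with the
between-group fraction of the total sum of squares (eta squared) and a
permutation null obtained by randomly relabelling the group assignments;
the p-value uses the add-one estimator so it is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class AssociationResult:
    """Permutation test of one environmental variable against a partition."""

    variable: str
    statistic: float        # eta squared, in [0, 1]
    p_value: float
    n_permutations: int
    seed: int


class ZeroVarianceError(ValueError):
    """The environmental variable is constant; eta squared is undefined."""


def _parse_measure(raw: str) -> tuple[float, float | None, float | None]:
    """Parse a scalar or 'low-high' ranged measurement to (midpoint, lo, hi)."""
    raw = str(raw).strip()
    if raw.upper() in ("", "NA", "NT", "NAN"):
        return (float("nan"), None, None)
    if "-" in raw[1:]:
        lo_s, hi_s = raw.split("-", 1)
        lo, hi = float(lo_s), float(hi_s)
        return ((lo + hi) / 2.0, min(lo, hi), max(lo, hi))
    v = float(raw)
    return (v, None, None)


def load_site_metadata(path: str | Path | None = None) -> pd.DataFrame:
    """Load a per-site metadata table (site_id, temperature_c, ph, sulfide_um).

    Ranged measurements like ``37-40`` are encoded by their midpoint, with
    the bounds retained in ``*_lo``/``*_hi`` columns. With no path, the
    packaged hot-spring site table ships as the default.
    """
    if path is None:
        path = resources.files("ecotyping.data").joinpath("site_metadata.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("temperature_c", "ph", "sulfide_um"):
        if col not in df.columns:
            continue
        parsed = df[col].map(_parse_measure)
        df[col] = [p[0] for p in parsed]
        df[col + "_lo"] = [p[1] for p in parsed]
        df[col + "_hi"] = [p[2] for p in parsed]
    return df


def eta_squared(values: np.ndarray, codes: np.ndarray) -> float:
    """Between-group sum of squares as a fraction of the total."""
    values = np.asarray(values, dtype=float)
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    if ss_total == 0.0:
        raise ZeroVarianceError("variable has zero total variance")
    ss_between = 0.0
    for g in np.unique(codes):
        sel = values[codes == g]
        ss_between += len(sel) * (sel.mean() - grand) ** 2
    return float(ss_between / ss_total)


def clade_env_association(
    assignments: dict[str, str],
    metadata: pd.DataFrame | dict[str, float],
    variable: str = "temperature_c",
    n_permutations: int = 999,
    seed: int = 0,
) -> AssociationResult:
    """Permutation test of ecotype partition against one environmental variable.

    ``assignments`` maps sequence id to ecotype/group id. ``metadata`` is
    either a DataFrame with a ``sequence_id`` column and the variable column,
    or a plain mapping from sequence id to value. The statistic is eta
    squared; the null redistributes values over groups uniformly at random,
    and p = (1 + #{permuted >= observed}) / (1 + n_permutations).
    """
    if isinstance(metadata, dict):
        value_of = metadata
        variable_name = variable
    else:
        if "sequence_id" not in metadata.columns:
            raise ValueError("metadata DataFrame needs a 'sequence_id' column")
        value_of = dict(zip(metadata["sequence_id"], metadata[variable]))
        variable_name = variable
    missing = [s for s in assignments if s not in value_of]
    if missing:
        raise ValueError(f"sequences without metadata: {missing}")
    seqs = sorted(assignments)
    values = np.array([value_of[s] for s in seqs], dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"missing values for variable {variable_name!r}")
    groups = [assignments[s] for s in seqs]
    _, codes = np.unique(groups, return_inverse=True)
    if len(np.unique(codes)) < 2:
        raise ValueError("association needs at least 2 groups")
    observed = eta_squared(values, codes)

    # vectorised permutation null: shuffle values, reuse fixed group layout
    rng = np.random.default_rng(seed)
    n = len(values)
    onehot = np.zeros((n, codes.max() + 1))
    onehot[np.arange(n), codes] = 1.0
    counts = onehot.sum(axis=0)
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    perm = np.tile(values, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    group_means = (perm @ onehot) / counts
    ss_between = (counts * (group_means - grand) ** 2).sum(axis=1)
    exceed = int((ss_between / ss_total >= observed - 1e-12).sum())
    p = (1 + exceed) / (1 + n_permutations)
    return AssociationResult(
        variable=variable_name,
        statistic=observed,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )
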