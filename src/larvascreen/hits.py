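"""Replicate-consensus hit calling.

A compound is a hit when its well Z-score clears a threshold in enough
replicates. The two screen presets are verbatim conventions of the assay:

* worm suppressor — Z ≥ 2.0 in 3 of 3 replicates (inclusive boundary);
* fly suppressor — Z > 2.5 in at least 2 of 3 replicates (strict);
* enhancer/toxic — Z ≤ −2.0 in 3 of 3 replicates.

An artifact-excluded or missing replicate counts as failing its rule
(conservative: exclusions can never create a hit). Hit rates are printed
as percentages with half-away-from-zero rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .doseresponse import round_half_away
from .errors import ConfigError

log = logging.getLogger(__name__)

_COMPARATORS = {"ge": np.greater_equal, "gt": np.greater, "le": np.less_equal}


@dataclass(frozen=True)
class ConsensusRule:
    """Threshold + replicate-count rule for one call direction."""

    z_threshold: float
    comparison: str  # 'ge' | 'gt' | 'le'
    min_replicates: int
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.comparison not in _COMPARATORS:
            raise ConfigError(f"unknown comparison {self.comparison!r}")
        if not 1 <= self.min_replicates <= self.n_replicates:
            raise ConfigError(
                "requires 1 <= min_replicates <= n_replicates, got "
                f"{self.min_replicates}/{self.n_replicates}"
            )

    def passes(self, z: np.ndarray) -> np.ndarray:
        """Row-wise consensus over a (n_compounds, n_replicates) Z matrix;
        NaN entries (excluded/missing replicates) fail."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        with np.errstate(invalid="ignore"):
            ok = _COMPARATORS[self.comparison](z, self.z_threshold)
        ok &= ~np.isnan(z)
        return ok.sum(axis=1) >= self.min_replicates


WORM_SUPPRESSOR = ConsensusRule(2.0, "ge", 3, 3)
FLY_SUPPRESSOR = ConsensusRule(2.5, "gt", 2, 3)
ENHANCER = ConsensusRule(-2.0, "le", 3, 3)

PRESETS = {"worm": WORM_SUPPRESSOR, "fly": FLY_SUPPRESSOR, "enhancer": ENHANCER}


class ConsensusHitCaller(BaseEstimator):
    """Stateless scikit-learn-style classifier applying consensus rules.

    ``predict`` maps a (n_compounds, n_replicates) Z-score matrix to the
    call labels ``{"suppressor", "enhancer_toxic", "none"}``. Suppressor
    and enhancer rules are evaluated independently; for any sensible rule
    pair (positive vs negative thresholds) the two cannot both fire.
    """

    def __init__(
        self,
        suppressor_rule: ConsensusRule = WORM_SUPPRESSOR,
        enhancer_rule: ConsensusRule | None = ENHANCER,
    ):
        self.suppressor_rule = suppressor_rule
        self.enhancer_rule = enhancer_rule

    def fit(self, X=None, y=None):
        return self

    def predict(self, X) -> np.ndarray:
        z = np.atleast_2d(np.asarray(X, dtype=float))
        call = np.full(z.shape[0], "none", dtype=object)
        if self.enhancer_rule is not None:
            call[self.enhancer_rule.passes(z)] = "enhancer_toxic"
        call[self.suppressor_rule.passes(z)] = "suppressor"
        return call


def call_consensus(
    z_tables: list[pd.DataFrame],
    rule: ConsensusRule,
    enhancer_rule: ConsensusRule | None = None,
) -> pd.DataFrame:
    """Consensus calls from one Z-score table per replicate.

    Each table needs ``compound_id`` and ``z`` columns (``excluded``
    optional). The compound universe is the union over replicates; a
    compound missing from a replicate fails that replicate and is logged.

    Returns one row per compound: z_1..z_n, call, n_excluded.
    """
    if len(z_tables) != rule.n_replicates:
        raise ConfigError(
            f"rule expects {rule.n_replicates} replicates, got {len(z_tables)}"
        )
    per_rep = []
    for i, tbl in enumerate(z_tables, start=1):
        t = tbl[tbl.compound_id.notna()]
        if "excluded" in t:
            t = t.assign(z=np.where(t.excluded.astype(bool), np.nan, t.z))
        s = t.groupby("compound_id", sort=True).z.first().rename(f"z_{i}")
        per_rep.append(s)
    wide = pd.concat(per_rep, axis=1)
    zcols = [f"z_{i}" for i in range(1, rule.n_replicates + 1)]
    missing = int(wide[zcols].isna().any(axis=1).sum())
    if missing:
        log.info("%d compounds have missing/excluded replicates", missing)
    z = wide[zcols].to_numpy(float)
    caller = ConsensusHitCaller(suppressor_rule=rule, enhancer_rule=enhancer_rule)
    wide["call"] = caller.predict(z)
    wide["n_excluded"] = np.isnan(z).sum(axis=1)
    return wide.reset_index().rename(columns={"index": "compound_id"})


def single_replicate_positives(z_table: pd.DataFrame, rule: ConsensusRule) -> set:
    """Compounds clearing the rule's threshold in one replicate's table
    (the per-replicate sets behind the Venn overlap)."""
    t = z_table[z_table.compound_id.notna() & z_table.z.notna()]
    with np.errstate(invalid="ignore"):
        ok = _COMPARATORS[rule.comparison](t.z.to_numpy(float), rule.z_threshold)
    return set(t.compound_id.to_numpy()[ok])


def hit_rate(n_hits: int, library_size: int, precision: int = 1) -> float:
    """Percent hit rate, rounded half away from zero to ``precision``."""
    if library_size <= 0:
        raise ConfigError("library_size must be positive")
    if not 0 <= n_hits <= library_size:
        raise ConfigError(f"n_hits {n_hits} outside [0, {library_size}]")
    return round_half_away(100.0 * n_hits / library_size, precision)


def replicate_overlap(positive_sets: list[set]) -> dict[tuple[int, ...], int]:
    """Exclusive Venn-region counts across replicate hit sets.

    Keys are tuples of the replicate indices (1-based) a region belongs
    to; e.g. for three replicates ``(1, 2, 3)`` is the triple
    intersection and ``(2,)`` the elements unique to replicate 2.
    """
    sets = [set(s) for s in positive_sets]
    if len(sets) < 2:
        raise ConfigError("replicate_overlap needs at least 2 sets")
    n = len(sets)
    counts: dict[tuple[int, ...], int] = {}
    for pattern in product([False, True], repeat=n):
        if not any(pattern):
            continue
        region = set.intersection(*(sets[i] for i in range(n) if pattern[i]))
        for i in range(n):
            if not pattern[i]:
                region -= sets[i]
        counts[tuple(i + 1 for i in range(n) if pattern[i])] = len(region)
    return counts


def venn_json(counts: dict[tuple[int, ...], int]) -> dict[str, int]:
    """Venn counts with string keys ('1&2&3') for JSON serialization."""
    return {"&".join(map(str, k)): v for k, v in sorted(counts.items())}
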