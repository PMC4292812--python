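"""Resampling enrichment and overlap significance for changing-probe sets.

Each probe carries a genomic feature (TSS1500 ... IGR) and a CpG-island
relation (Island / Shore / Shelf / None); combining the two gives every
probe a unique (epi)genomic category.  Enrichment of a target probe set
(e.g. probes reversing methylation after xenografting) over these
categories is assessed against repeated random draws of equally many probes
from the analysis universe; the overlap of changing-probe sets between
samples is assessed against a null in which each set is redrawn uniformly
at random from the universe with its size preserved.

Empirical p-values use the add-one estimator (r + 1) / (n_reps + 1), so the
smallest attainable p is 1 / (n_reps + 1) and p is never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pdxmeth import _seeds

logger = logging.getLogger(__name__)


def combined_categories(annotation: pd.DataFrame) -> pd.Series:
    """Combined '<feature>|<island_relation>' category per probe."""
    return annotation["feature"].astype(str) + "|" + annotation["island_relation"].astype(str)


@dataclass(frozen=True)
class EnrichmentResult:
    """Resampling enrichment of one combined category."""

    category: str
    observed: int
    expected_mean: float
    expected_sd: float
    fold: float
    empirical_p: float
    n_reps: int


def _drop_unannotated(
    probes: pd.Index, annotation: pd.DataFrame, what: str
) -> pd.Index:
    known = probes.intersection(annotation.index)
    missing = annotation.loc[known, ["feature", "island_relation"]].isna().any(axis=1)
    known = known[~missing.to_numpy()]
    dropped = len(probes) - len(known)
    if dropped:
        logger.info("%s: excluded %d probe(s) without annotation", what, dropped)
    return known


def resampling_enrichment(
    target: pd.Index | Sequence[str],
    universe: pd.Index | Sequence[str],
    annotation: pd.DataFrame,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Category enrichment of ``target`` against random draws from ``universe``.

    Each repetition draws ``len(target)`` probes uniformly without
    replacement from the universe (implemented exactly as a multivariate
    hypergeometric draw over category counts).  Per category the result
    reports the observed count, the resampling mean and SD, the fold change
    observed / expected_mean, and a two-sided empirical p-value (per-tail
    add-one counts, doubled and capped at 1).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    target = pd.Index(target)
    universe = pd.Index(universe)
    if not target.isin(universe).all():
        raise ValueError("target probes must be a subset of the universe")
    universe = _drop_unannotated(universe, annotation, "universe")
    target = target.intersection(universe)
    if len(target) > len(universe):
        raise ValueError("target is larger than the universe")
    if len(target) == 0:
        raise ValueError("target is empty after annotation filtering")

    cats = combined_categories(annotation.loc[universe])
    codes, labels = pd.factorize(cats, sort=True)
    n_cat = len(labels)
    universe_counts = np.bincount(codes, minlength=n_cat)
    target_mask = universe.isin(target)
    observed = np.bincount(codes[target_mask], minlength=n_cat)

    rng = _seeds.child_rng(seed, _seeds.ENRICH)
    null = rng.multivariate_hypergeometric(universe_counts, len(target), size=n_reps)

    exp_mean = null.mean(axis=0)
    exp_sd = null.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(exp_mean > 0, observed / exp_mean, np.nan)
    # two-sided: the smaller tail count is doubled and capped at n_reps,
    # then the add-one estimator applied, so min attainable p is 1/(n_reps+1)
    r_hi = (null >= observed).sum(axis=0)
    r_lo = (null <= observed).sum(axis=0)
    r = np.minimum(n_reps, 2 * np.minimum(r_hi, r_lo))
    p = (r + 1) / (n_reps + 1)

    return pd.DataFrame(
        {
            "category": labels,
            "observed": observed,
            "expected_mean": exp_mean,
            "expected_sd": exp_sd,
            "fold": fold,
            "empirical_p": p,
            "n_reps": n_reps,
        }
    )


@dataclass(frozen=True)
class OverlapResult:
    """Observed full intersection size and its resampling significance."""

    observed_shared: int
    empirical_p: float
    n_reps: int


def overlap_significance(
    sets: Sequence[pd.Index | Sequence[str]],
    universe: pd.Index | Sequence[str],
    n_reps: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Significance of the common intersection of several probe sets.

    Null model: each repetition redraws every set uniformly at random from
    the universe, preserving its size; the statistic is the size of the full
    intersection.  Because the redrawn sets are independent and uniform, the
    running intersection size after adding each set is exactly
    hypergeometric given the previous one, which is how the null is sampled
    (no explicit sets are materialised).  p = (r + 1) / (n_reps + 1) with r
    the number of repetitions whose null intersection is at least the
    observed one.
    """
    if len(sets) < 2:
        raise ValueError("at least two sets are required")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    universe = pd.Index(universe)
    idx_sets = [pd.Index(s) for s in sets]
    for i, s in enumerate(idx_sets):
        if not s.isin(universe).all():
            raise ValueError(f"set {i} is not a subset of the universe")
    inter = idx_sets[0]
    for s in idx_sets[1:]:
        inter = inter.intersection(s)
    observed = len(inter)

    rng = _seeds.child_rng(seed, _seeds.OVERLAP)
    n_u = len(universe)
    shared = np.full(n_reps, len(idx_sets[0]), dtype=np.int64)
    for s in idx_sets[1:]:
        shared = rng.hypergeometric(ngood=shared, nbad=n_u - shared, nsample=len(s))
    r = int((shared >= observed).sum())
    return OverlapResult(observed, (r + 1) / (n_reps + 1), n_reps)


def overlap_percentages(sets: Mapping[str, pd.Index | Sequence[str]]) -> dict:
    """Pairwise and full-intersection overlaps as percentages.

    The denominator for every percentage is the size of the smallest set
    (the sample with the fewest changing probes).  Returns a dict with keys
    ``denominator`` (name of the smallest set), ``denominator_size``,
    ``pairwise`` (mapping frozenset({a, b}) -> percent) and ``all``.
    """
    if len(sets) < 2:
        raise ValueError("at least two sets are required")
    idx_sets = {name: pd.Index(s) for name, s in sets.items()}
    for name, s in idx_sets.items():
        if len(s) == 0:
            raise ValueError(f"set {name!r} is empty")
    min_name = min(idx_sets, key=lambda k: len(idx_sets[k]))
    denom = len(idx_sets[min_name])
    names = list(idx_sets)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = len(idx_sets[a].intersection(idx_sets[b]))
            pairwise[frozenset((a, b))] = 100.0 * inter / denom
    full = idx_sets[names[0]]
    for name in names[1:]:
        full = full.intersection(idx_sets[name])
    return {
        "denominator": min_name,
        "denominator_size": denom,
        "pairwise": pairwise,
        "all": 100.0 * len(full) / denom,
    }
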