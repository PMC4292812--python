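"""Core fidelity statistics for patient/xenograft methylome comparison.

The central quantity is the per-probe difference
``delta beta = beta_patient - beta_xenograft``.  A probe whose absolute
difference meets or exceeds a calibrated threshold is counted as 'reversed
methylation': a change large enough to be read as a switch between the fully
unmethylated and fully methylated states.  The threshold derives from the
empirical beta-value bounds of those states — 95% of fully unmethylated
probes sit at beta <= 0.31 and fully methylated probes at beta >= 0.82, so a
difference of 0.82 - 0.31 = 0.51 is the minimum change expected for a true
state reversal.

The module also provides difference histograms, threshold-sensitivity
curves over a grid of cutoffs, per-feature beta distributions, the
delta-delta-beta concordance used to judge whether a xenograft can
substitute for its patient tumour in an inter-tumour comparison, and a
generic signed-set concordance for cross-platform validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: empirical beta-value bounds of the fully unmethylated / methylated states
DEFAULT_UNMETH_UPPER = 0.31
DEFAULT_METH_LOWER = 0.82


@dataclass(frozen=True)
class ReversalThreshold:
    """Minimum |delta beta| for a probe to count as reversing methylation.

    ``threshold = meth_lower - unmeth_upper``: the smallest difference
    compatible with a switch between the two fully committed states.
    """

    unmeth_upper: float = DEFAULT_UNMETH_UPPER
    meth_lower: float = DEFAULT_METH_LOWER

    def __post_init__(self) -> None:
        if not self.meth_lower > self.unmeth_upper:
            raise ValueError(
                "degenerate calibration: methylated lower bound "
                f"({self.meth_lower}) must exceed unmethylated upper bound "
                f"({self.unmeth_upper})"
            )

    @property
    def threshold(self) -> float:
        return self.meth_lower - self.unmeth_upper


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Type-1 (nearest-rank) quantile: smallest x with F(x) >= q."""
    s = np.sort(values)
    # epsilon guards against float fuzz in q (e.g. 1 - 0.95) tipping the rank
    k = max(1, math.ceil(q * s.size - 1e-9))
    return float(s[k - 1])


def calibrate_threshold(
    unmeth_betas: Sequence[float],
    meth_betas: Sequence[float],
    coverage: float = 0.95,
) -> ReversalThreshold:
    """Calibrate the reversal threshold from reference beta distributions.

    ``unmeth_upper`` is the ``coverage`` quantile of beta values at known
    fully unmethylated probes and ``meth_lower`` the ``1 - coverage``
    quantile at fully methylated probes (nearest-rank quantiles).  The fixed
    published bounds are available directly as ``ReversalThreshold()``.
    """
    u = np.asarray(unmeth_betas, dtype=float)
    m = np.asarray(meth_betas, dtype=float)
    if u.size == 0 or m.size == 0:
        raise ValueError("calibration vectors must be non-empty")
    if u.min() < 0 or u.max() > 1 or m.min() < 0 or m.max() > 1:
        raise ValueError("calibration beta values must lie in [0, 1]")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    return ReversalThreshold(
        unmeth_upper=_nearest_rank_quantile(u, coverage),
        meth_lower=_nearest_rank_quantile(m, 1.0 - coverage),
    )


@dataclass(frozen=True)
class PairDelta:
    """Per-probe delta beta for one (patient, xenograft) pair.

    ``delta`` is patient minus xenograft, indexed by the QC-retained probes.
    """

    patient_id: str
    xenograft_id: str
    delta: pd.Series

    @property
    def n_probes(self) -> int:
        return len(self.delta)


def delta_beta(beta: pd.DataFrame, patient_id: str, xenograft_id: str) -> PairDelta:
    """Elementwise beta difference, patient minus xenograft."""
    for sid in (patient_id, xenograft_id):
        if sid not in beta.columns:
            raise KeyError(f"sample {sid!r} not present in the beta matrix")
    delta = beta[patient_id] - beta[xenograft_id]
    delta.name = f"{patient_id}-{xenograft_id}"
    return PairDelta(patient_id, xenograft_id, delta)


@dataclass(frozen=True)
class ReversalSummary:
    """Count/percentage of probes meeting the reversal threshold, and which."""

    count: int
    percent: float
    probes: pd.Index


def _as_threshold(threshold: ReversalThreshold | float) -> float:
    t = threshold.threshold if isinstance(threshold, ReversalThreshold) else float(threshold)
    if not 0.0 < t <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {t}")
    return t


def reversed_fraction(
    pair: PairDelta, threshold: ReversalThreshold | float = ReversalThreshold()
) -> ReversalSummary:
    """Probes with |delta beta| >= threshold (boundary inclusive).

    The percentage denominator is the pair's retained probe count.
    """
    t = _as_threshold(threshold)
    mask = pair.delta.abs().to_numpy() >= t
    count = int(mask.sum())
    return ReversalSummary(
        count=count,
        percent=100.0 * count / pair.n_probes,
        probes=pair.delta.index[mask],
    )


def _bin_edges(bin_width: float, lo: float, hi: float) -> np.ndarray:
    n = (hi - lo) / bin_width
    if not math.isclose(n, round(n), abs_tol=1e-9) or bin_width <= 0:
        raise ValueError(f"bin_width {bin_width} must evenly divide [{lo}, {hi}]")
    return np.linspace(lo, hi, int(round(n)) + 1)


def delta_histogram(pair: PairDelta, bin_width: float = 0.01) -> pd.DataFrame:
    """Histogram of |delta beta| in ``bin_width`` increments over [0, 1].

    Bins are half-open [lo, hi) with the final bin closed; counts sum to the
    retained probe count.
    """
    edges = _bin_edges(bin_width, 0.0, 1.0)
    counts, _ = np.histogram(pair.delta.abs().to_numpy(), bins=edges)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )


def threshold_sensitivity(
    pairs: Sequence[PairDelta],
    thresholds: Sequence[float] = (0.51, 0.41, 0.31, 0.21),
) -> pd.DataFrame:
    """Mean percentage of changing probes across pairs at each threshold.

    Returns a DataFrame with columns ``threshold``, ``mean_percent`` and
    ``sem`` (standard error of the mean over pairs; 0 for a single pair).
    Means weakly increase as the threshold decreases.
    """
    if len(pairs) == 0:
        raise ValueError("at least one pair is required")
    rows = []
    for t in thresholds:
        percents = np.array([reversed_fraction(p, t).percent for p in pairs])
        sem = float(percents.std(ddof=1) / math.sqrt(len(percents))) if len(percents) > 1 else 0.0
        rows.append((float(t), float(percents.mean()), sem))
    return pd.DataFrame(rows, columns=["threshold", "mean_percent", "sem"])


WHOLE_GENOME = "Whole Genome"
_KNOWN_FEATURES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "IGR")
_KNOWN_ISLAND = ("Island", "Shore", "Shelf", "None")


def feature_histograms(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    bin_width: float = 0.01,
    by: str = "feature",
) -> pd.DataFrame:
    """Per-sample, per-category binned beta distributions (percentages).

    ``by`` selects the annotation column ("feature" or "island_relation");
    a "Whole Genome" category covering all probes is always included.
    Per-histogram percentages sum to 100.
    """
    if by not in ("feature", "island_relation"):
        raise ValueError(f"by must be 'feature' or 'island_relation', got {by!r}")
    known = _KNOWN_FEATURES if by == "feature" else _KNOWN_ISLAND
    ann = annotation.loc[beta.index]
    labels = ann[by]
    unknown = sorted(set(labels) - set(known))
    if unknown:
        raise ValueError(f"unknown {by} label(s) in annotation: {unknown}")
    edges = _bin_edges(bin_width, 0.0, 1.0)
    frames = []
    categories: list[tuple[str, np.ndarray]] = [(WHOLE_GENOME, np.ones(len(beta), dtype=bool))]
    categories += [(cat, (labels == cat).to_numpy()) for cat in known]
    for sample in beta.columns:
        col = beta[sample].to_numpy()
        for cat, mask in categories:
            n = int(mask.sum())
            if n == 0:
                continue
            counts, _ = np.histogram(col[mask], bins=edges)
            frames.append(
                pd.DataFrame(
                    {
                        "sample": sample,
                        "category": cat,
                        "bin_lo": edges[:-1],
                        "percent": 100.0 * counts / n,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SubstituteConcordance:
    """Delta-delta-beta comparison of a reference and a test pair.

    ``ddb = |delta_ref| - |delta_test|`` per probe; values near zero mean the
    test pair captures the same differential methylation as the reference
    pair (e.g. a xenograft substituting for its patient tumour in an
    inter-tumour comparison).
    """

    ddb: pd.Series
    histogram: pd.DataFrame
    tolerance: float
    concordant_fraction: float


def substitute_concordance(
    ref_pair: PairDelta,
    test_pair: PairDelta,
    tolerance: float = 0.1,
    bin_width: float = 0.01,
) -> SubstituteConcordance:
    """Compute per-probe ddb = |delta_ref| - |delta_test| and summarise.

    ``concordant_fraction`` is the fraction of probes with |ddb| <
    ``tolerance`` (the cutoff for 'close to zero' has no canonical value and
    is fully configurable).  The histogram bins ddb over [-1, 1].
    """
    if not ref_pair.delta.index.equals(test_pair.delta.index):
        raise ValueError("pairs are defined on different probe universes")
    ddb = ref_pair.delta.abs() - test_pair.delta.abs()
    ddb.name = "ddb"
    edges = _bin_edges(bin_width, -1.0, 1.0)
    counts, _ = np.histogram(ddb.to_numpy(), bins=edges)
    hist = pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})
    frac = float((ddb.abs() < tolerance).mean())
    return SubstituteConcordance(ddb=ddb, histogram=hist, tolerance=tolerance, concordant_fraction=frac)


def set_concordance(
    set_a: Mapping[str, int],
    set_b: Mapping[str, int],
) -> tuple[int, float | None]:
    """Shared-identifier count and directional concordance of two signed sets.

    Elements map identifier -> direction sign (+1/-1).  Returns
    ``(shared, concordance)`` where concordance is the fraction of shared
    identifiers whose signs match, or ``None`` when nothing is shared.
    """
    shared_ids = set(set_a) & set(set_b)
    if not shared_ids:
        return 0, None
    matching = sum(
        1 for k in shared_ids if np.sign(set_a[k]) == np.sign(set_b[k])
    )
    return len(shared_ids), matching / len(shared_ids)
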