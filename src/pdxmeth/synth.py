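"""Synthetic 450K-style methylome generation.

Everything the analysis consumes can be generated here with the statistical
structure the pipeline assumes: probe annotation manifests, pools of
bimodally distributed beta-value methylomes with feature-dependent modes
(CpG-island promoters low, gene bodies and open sea high), paired
patient/xenograft samples with planted tumour-specific methylation changes,
mouse cross-hybridisation detection p-values, and name-matched dual-genome
read-pair fixtures.

Beta values are built on the logit scale: each probe gets a latent state
(unmethylated / intermediate / methylated) drawn from a mixture whose weights
depend on its combined genomic/CpG-island category, a probe-level mean beta is
drawn from a state-specific Beta distribution, and per-sample Gaussian noise
is added on the logit scale before mapping back through the inverse logit.
This keeps every value strictly inside (0, 1) with no clipping artifacts.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from pdxmeth import _seeds
from pdxmeth.readfilter import ReadPairRecord

FEATURES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "IGR")
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "None")
PROMOTER_FEATURES = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
CHROMS = AUTOSOMES + ("chrX", "chrY")

#: number of probes on the full array, before any quality control
ARRAY_N_PROBES = 485_512
#: a typical post-QC analysis probe count at full scale
POSTQC_N_PROBES = 463_558
#: default probe count for desk-scale fixtures
FIXTURE_N_PROBES = 20_000

# mixture weights over (unmethylated, intermediate, methylated) per combined
# probe category; CpG-island promoters are almost always unmethylated while
# open-sea gene bodies are predominantly methylated
DEFAULT_FEATURE_MIX: Mapping[str, tuple[float, float, float]] = {
    "island_promoter": (0.94, 0.04, 0.02),
    "island_body": (0.75, 0.13, 0.12),
    "shore": (0.45, 0.25, 0.30),
    "shelf": (0.15, 0.15, 0.70),
    "opensea_promoter": (0.25, 0.20, 0.55),
    "opensea_body": (0.06, 0.10, 0.84),
}

# marginal feature frequencies and island relation conditional on feature,
# loosely shaped like the 450K manifest (promoter probes island-dense, bodies
# and intergenic probes mostly open sea)
_FEATURE_FREQ = {
    "TSS1500": 0.14,
    "TSS200": 0.13,
    "5UTR": 0.09,
    "1stExon": 0.04,
    "Body": 0.31,
    "3UTR": 0.03,
    "IGR": 0.26,
}
_ISLAND_GIVEN_FEATURE = {
    "promoter": (0.60, 0.25, 0.05, 0.10),  # Island, Shore, Shelf, None
    "body": (0.15, 0.25, 0.15, 0.45),
    "igr": (0.15, 0.20, 0.10, 0.55),
}


def probe_state_category(feature: str, island_relation: str) -> str:
    """Map a (genomic feature, island relation) pair to a mixture category."""
    promoter = feature in PROMOTER_FEATURES
    if island_relation == "Island":
        return "island_promoter" if promoter else "island_body"
    if island_relation == "Shore":
        return "shore"
    if island_relation == "Shelf":
        return "shelf"
    return "opensea_promoter" if promoter else "opensea_body"


def _check_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"MethylomeModel.{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class MethylomeModel:
    """Parameters of the synthetic beta-value generator.

    Parameters
    ----------
    n_probes:
        Number of probes per methylome.
    feature_mix:
        Per-category mixture weights over the (unmethylated, intermediate,
        methylated) probe states; each triple must sum to 1.
    unmeth_mode, meth_mode:
        Beta-distribution shape parameters ``(a, b)`` for probe-level mean
        beta in the low and high states.
    mid_mode:
        Shape parameters for the intermediate state.
    sample_noise_sd:
        Standard deviation of the per-sample noise on the logit scale.
    seed:
        Master seed; all internal randomness derives from it.
    """

    n_probes: int = FIXTURE_N_PROBES
    feature_mix: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_MIX)
    )
    unmeth_mode: tuple[float, float] = (1.5, 20.0)
    meth_mode: tuple[float, float] = (20.0, 1.5)
    mid_mode: tuple[float, float] = (3.0, 3.0)
    sample_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("MethylomeModel.n_probes must be >= 1")
        for name in ("unmeth_mode", "meth_mode", "mid_mode", "sample_noise_sd"):
            _check_finite(name, getattr(self, name))
        if self.sample_noise_sd < 0:
            raise ValueError("MethylomeModel.sample_noise_sd must be >= 0")
        for cat, weights in self.feature_mix.items():
            _check_finite(f"feature_mix[{cat!r}]", weights)
            if len(weights) != 3 or not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"MethylomeModel.feature_mix[{cat!r}] must be three weights summing to 1"
                )


@dataclass(frozen=True)
class PairPlan:
    """Plan for planting tumour-specific changes into a patient/PDX pair.

    ``frac_changing`` of the probes are shifted by at least ``min_shift`` in
    beta, emulating 'reversed methylation' events introduced by xenografting;
    ``shared_fraction`` controls how many planted probes sibling PDXs of the
    same patient tumour have in common.
    """

    frac_changing: float = 0.027
    min_shift: float = 0.51
    direction_balance: float = 0.5
    shared_fraction: float = 0.86
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_changing <= 1.0:
            raise ValueError("PairPlan.frac_changing must be in [0, 1]")
        if not 0.0 < self.min_shift <= 1.0:
            raise ValueError("PairPlan.min_shift must be in (0, 1]")
        if not 0.0 <= self.direction_balance <= 1.0:
            raise ValueError("PairPlan.direction_balance must be in [0, 1]")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("PairPlan.shared_fraction must be in [0, 1]")


def generate_annotation(
    n_probes: int,
    seed: int = 0,
    sex_fraction: float = 0.024,
) -> pd.DataFrame:
    """Generate a probe annotation manifest.

    Returns a DataFrame indexed by probe id with columns ``chrom`` (1-based
    coordinates live in ``pos``), ``pos``, ``feature`` and
    ``island_relation``.  ``sex_fraction`` of probes land on chrX/chrY
    (chrY rare), mirroring the small sex-chromosome share of the array.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if not 0.0 <= sex_fraction < 1.0:
        raise ValueError("sex_fraction must be in [0, 1)")
    rng = _seeds.child_rng(seed, _seeds.ANNOTATION)

    feats = list(_FEATURE_FREQ)
    fprobs = np.array([_FEATURE_FREQ[f] for f in feats])
    fprobs = fprobs / fprobs.sum()
    fcodes = rng.choice(len(feats), size=n_probes, p=fprobs)
    feature = np.array(feats, dtype=object)[fcodes]

    island = np.empty(n_probes, dtype=object)
    for kind, mask_feats in (
        ("promoter", PROMOTER_FEATURES),
        ("body", {"Body", "3UTR"}),
        ("igr", {"IGR"}),
    ):
        mask = np.isin(feature, list(mask_feats))
        k = int(mask.sum())
        if k:
            codes = rng.choice(4, size=k, p=_ISLAND_GIVEN_FEATURE[kind])
            island[mask] = np.array(ISLAND_RELATIONS, dtype=object)[codes]

    n_sex = int(round(sex_fraction * n_probes))
    chrom_pool = list(AUTOSOMES)
    chrom = np.array(rng.choice(chrom_pool, size=n_probes), dtype=object)
    if n_sex:
        sex_idx = rng.choice(n_probes, size=n_sex, replace=False)
        sex_chrom = np.where(rng.random(n_sex) < 0.96, "chrX", "chrY")
        chrom[sex_idx] = sex_chrom
    # unique 1-based positions per chromosome via strictly positive steps
    pos = np.empty(n_probes, dtype=np.int64)
    for c in CHROMS:
        mask = chrom == c
        k = int(mask.sum())
        if k:
            pos[mask] = np.cumsum(rng.integers(1, 5_000, size=k)) + 10_000

    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n_probes)], name="probe_id")
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "feature": feature, "island_relation": island},
        index=probe_ids,
    )


class SyntheticPool:
    """A lazily materialised pool of synthetic methylomes.

    Probe-level latent states and mean beta values are drawn once from the
    model; individual samples are realised on demand by adding per-sample
    logit-scale noise.  Columns are a pure function of (model, annotation,
    column index), so a pool of thousands of samples costs no more memory
    than the columns actually requested — the study-design simulation draws
    a handful of samples per repetition from a nominal pool of 2,000.
    """

    def __init__(
        self,
        model: MethylomeModel,
        n_samples: int,
        annotation: pd.DataFrame | None = None,
    ) -> None:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if annotation is None:
            annotation = generate_annotation(model.n_probes, seed=model.seed, sex_fraction=0.0)
        if len(annotation) != model.n_probes:
            raise ValueError(
                f"annotation covers {len(annotation)} probes, model expects {model.n_probes}"
            )
        self.model = model
        self.n_samples = int(n_samples)
        self.annotation = annotation

        rng = _seeds.child_rng(model.seed, _seeds.POOL, 0)
        cats = [
            probe_state_category(f, i)
            for f, i in zip(annotation["feature"], annotation["island_relation"])
        ]
        unknown = sorted({c for c in cats if c not in model.feature_mix})
        if unknown:
            raise ValueError(f"feature_mix missing categories: {unknown}")
        weights = np.array([model.feature_mix[c] for c in cats])
        u = rng.random(model.n_probes)
        cum = np.cumsum(weights, axis=1)
        self.states = (u[:, None] >= cum).sum(axis=1)  # 0=unmeth, 1=mid, 2=meth

        mean = np.empty(model.n_probes)
        for state, (a, b) in enumerate((model.unmeth_mode, model.mid_mode, model.meth_mode)):
            mask = self.states == state
            mean[mask] = rng.beta(a, b, size=int(mask.sum()))
        mean = np.clip(mean, 1e-6, 1.0 - 1e-6)
        self._mu = logit(mean)

    @property
    def n_probes(self) -> int:
        return self.model.n_probes

    @property
    def probe_ids(self) -> pd.Index:
        return self.annotation.index

    def column(self, j: int) -> np.ndarray:
        """Beta values of sample ``j`` (0-based), deterministic in (model, j)."""
        if not 0 <= j < self.n_samples:
            raise IndexError(f"sample index {j} out of range [0, {self.n_samples})")
        sd = self.model.sample_noise_sd
        if sd == 0:
            return expit(self._mu)
        rng = _seeds.child_rng(self.model.seed, _seeds.POOL, 1, int(j))
        return expit(self._mu + rng.normal(0.0, sd, size=self.n_probes))

    def columns(self, idx: Sequence[int]) -> np.ndarray:
        """Probes x samples array for the requested column indices."""
        return np.column_stack([self.column(int(j)) for j in idx])


def generate_pool(
    model: MethylomeModel,
    n_samples: int,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Generate a probes x samples beta matrix for ``n_samples`` methylomes.

    Deterministic in (model, annotation, n_samples); with zero sample noise
    every column equals the probe-level mean beta exactly.
    """
    pool = SyntheticPool(model, n_samples, annotation)
    data = pool.columns(range(n_samples))
    cols = [f"S{j + 1:03d}" for j in range(n_samples)]
    return pd.DataFrame(data, index=annotation.index, columns=cols)


def _plant_shifts(
    beta: np.ndarray,
    plan: PairPlan,
    rng: np.random.Generator,
    up_idx: np.ndarray,
    down_idx: np.ndarray,
) -> np.ndarray:
    """Apply feasible-direction shifts of magnitude >= min_shift; returns copy."""
    out = beta.copy()
    if up_idx.size:
        headroom = 1.0 - beta[up_idx]
        out[up_idx] = beta[up_idx] + rng.uniform(plan.min_shift, headroom)
    if down_idx.size:
        headroom = beta[down_idx]
        out[down_idx] = beta[down_idx] - rng.uniform(plan.min_shift, headroom)
    return out


def _choose_directions(
    beta: np.ndarray,
    plan: PairPlan,
    rng: np.random.Generator,
    n_up: int,
    n_down: int,
    forbidden: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint up/down probe index sets with feasible full-magnitude shifts."""
    allowed = np.ones(beta.shape[0], dtype=bool)
    if forbidden is not None:
        allowed[forbidden] = False
    up_feasible = np.flatnonzero((beta <= 1.0 - plan.min_shift) & allowed)
    if up_feasible.size < n_up:
        raise ValueError(
            f"infeasible plan: need {n_up} up-shift candidates "
            f"(beta <= {1 - plan.min_shift:.3f}), only {up_feasible.size} available"
        )
    up_idx = rng.choice(up_feasible, size=n_up, replace=False) if n_up else np.empty(0, dtype=int)
    allowed[up_idx] = False
    down_feasible = np.flatnonzero((beta >= plan.min_shift) & allowed)
    if down_feasible.size < n_down:
        raise ValueError(
            f"infeasible plan: need {n_down} down-shift candidates "
            f"(beta >= {plan.min_shift:.3f}), only {down_feasible.size} available"
        )
    down_idx = (
        rng.choice(down_feasible, size=n_down, replace=False) if n_down else np.empty(0, dtype=int)
    )
    return up_idx, down_idx


def _planted_series(index: pd.Index, up_idx: np.ndarray, down_idx: np.ndarray) -> pd.Series:
    planted = pd.Series(
        np.concatenate([np.ones(up_idx.size, dtype=int), -np.ones(down_idx.size, dtype=int)]),
        index=index[np.concatenate([up_idx, down_idx])],
        name="direction",
    )
    return planted.sort_index()


def generate_pdx_pair(
    patient: pd.Series,
    plan: PairPlan,
) -> tuple[pd.Series, pd.Series]:
    """Derive a xenograft methylome from a patient methylome.

    Exactly ``round(frac_changing * n_probes)`` probes are shifted, each by at
    least ``min_shift`` in beta, with directions chosen only where the full
    magnitude fits inside [0, 1] (up-shifts where beta <= 1 - min_shift,
    down-shifts where beta >= min_shift).  Unplanted probes are untouched, so
    the planted set is exactly recoverable by thresholding |delta beta| at
    ``min_shift``.

    Returns ``(xenograft_column, planted)`` where ``planted`` is a Series of
    +1/-1 directions indexed by the planted probe ids.
    """
    beta = np.asarray(patient, dtype=float)
    if beta.min() < 0 or beta.max() > 1:
        raise ValueError("patient beta values must lie in [0, 1]")
    rng = _seeds.child_rng(plan.seed, _seeds.PAIR, 0)
    n_changed = int(round(plan.frac_changing * beta.shape[0]))
    n_up = int(round(plan.direction_balance * n_changed))
    n_down = n_changed - n_up
    up_idx, down_idx = _choose_directions(beta, plan, rng, n_up, n_down)
    out = _plant_shifts(beta, plan, rng, up_idx, down_idx)
    xeno = pd.Series(out, index=patient.index, name=f"{patient.name or 'patient'}_PDX")
    return xeno, _planted_series(patient.index, up_idx, down_idx)


def generate_sibling_pdxs(
    patient: pd.Series,
    plan: PairPlan,
    n_siblings: int = 2,
) -> list[tuple[pd.Series, pd.Series]]:
    """Derive several sibling PDXs from one patient tumour.

    The first sibling's planted set is drawn fresh; each subsequent sibling
    reuses ``round(shared_fraction * n_changed)`` of the first sibling's
    planted probes (with directions) and fills the remainder with fresh
    probes disjoint from the first sibling's planted set, so the pairwise
    overlap of planted sets equals ``shared_fraction`` by construction.
    """
    if n_siblings < 1:
        raise ValueError("n_siblings must be >= 1")
    beta = np.asarray(patient, dtype=float)
    rng = _seeds.child_rng(plan.seed, _seeds.PAIR, 1)
    n_changed = int(round(plan.frac_changing * beta.shape[0]))
    n_up = int(round(plan.direction_balance * n_changed))
    n_down = n_changed - n_up

    first_up, first_down = _choose_directions(beta, plan, rng, n_up, n_down)
    out = []
    for s in range(n_siblings):
        if s == 0:
            up_idx, down_idx = first_up, first_down
        else:
            n_share = int(round(plan.shared_fraction * n_changed))
            share_up = rng.choice(first_up, size=min(first_up.size, int(round(plan.shared_fraction * n_up))), replace=False)
            share_down = rng.choice(
                first_down,
                size=min(first_down.size, n_share - share_up.size),
                replace=False,
            )
            forbidden = np.concatenate([first_up, first_down])
            fresh_up, fresh_down = _choose_directions(
                beta, plan, rng, n_up - share_up.size, n_down - share_down.size, forbidden
            )
            up_idx = np.concatenate([share_up, fresh_up]).astype(int)
            down_idx = np.concatenate([share_down, fresh_down]).astype(int)
        col = _plant_shifts(beta, plan, rng, up_idx, down_idx)
        name = f"{patient.name or 'patient'}_PDX{chr(ord('A') + s)}"
        out.append(
            (pd.Series(col, index=patient.index, name=name), _planted_series(patient.index, up_idx, down_idx))
        )
    return out


def generate_mouse_qc(
    n_probes: int,
    frac_cross_hyb: float,
    seed: int = 0,
    probe_ids: pd.Index | None = None,
) -> pd.Series:
    """Detection p-values of a mouse-only sample on a human array.

    Exactly ``round(frac_cross_hyb * n_probes)`` probes cross-hybridise to
    mouse DNA (detection p < 0.01); the remainder are background
    (p >= 0.01).
    """
    if not 0.0 <= frac_cross_hyb <= 1.0:
        raise ValueError("frac_cross_hyb must be in [0, 1]")
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    rng = _seeds.child_rng(seed, _seeds.MOUSE_QC)
    n_hyb = int(round(frac_cross_hyb * n_probes))
    detp = rng.uniform(0.01, 1.0, size=n_probes)
    if n_hyb:
        hyb_idx = rng.choice(n_probes, size=n_hyb, replace=False)
        detp[hyb_idx] = rng.uniform(1e-8, 0.0099, size=n_hyb)
    if probe_ids is None:
        probe_ids = pd.Index([f"cg{i:08d}" for i in range(n_probes)], name="probe_id")
    elif len(probe_ids) != n_probes:
        raise ValueError("probe_ids length does not match n_probes")
    return pd.Series(detp, index=probe_ids, name="mouse_detp")


READ_CLASSES = ("human_only", "mouse_only", "both", "neither")


def generate_read_records(
    n_pairs: int,
    class_probs: Sequence[float],
    seed: int = 0,
) -> list[ReadPairRecord]:
    """Read-pair records with multinomially drawn alignment classes.

    ``class_probs`` orders the classes as ``(human_only, mouse_only, both,
    neither)`` and must sum to 1 (tolerance 1e-9).
    """
    probs = np.asarray(class_probs, dtype=float)
    if probs.shape != (4,):
        raise ValueError("class_probs must have exactly four entries")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"class_probs sum to {probs.sum()!r}, expected 1")
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    rng = _seeds.child_rng(seed, _seeds.READS)
    counts = rng.multinomial(n_pairs, probs)
    labels = np.repeat(np.arange(4), counts)
    rng.shuffle(labels)
    flags = {
        0: (True, False),
        1: (False, True),
        2: (True, True),
        3: (False, False),
    }
    return [
        ReadPairRecord(f"pair{i:06d}", *flags[int(lbl)]) for i, lbl in enumerate(labels)
    ]


def write_read_records_sam(
    records: Sequence[ReadPairRecord],
    graft_path: str,
    host_path: str,
    seed: int = 0,
) -> None:
    """Write records as two name-matched paired-end SAM files.

    Each record becomes one read pair in each file; the pair is written as
    mapped and properly paired in a genome's file iff the record is aligned
    to that genome, otherwise as an unmapped pair (as aligners emit unmapped
    mates).  Round-trips through :func:`pdxmeth.readfilter.ingest_alignments`
    to the same classes.
    """
    import pysam

    rng = _seeds.child_rng(seed, _seeds.READS, 1)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": "chr1", "LN": 1_000_000}],
    }
    seq = "A" * 50
    qual = "I" * 50
    for path, attr in ((graft_path, "human_aligned"), (host_path, "mouse_aligned")):
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for rec in records:
                aligned = getattr(rec, attr)
                pos = int(rng.integers(0, 900_000))
                for mate in (0, 1):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = rec.read_id
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array(qual)
                    flag = 0x1  # paired
                    flag |= 0x40 if mate == 0 else 0x80
                    if aligned:
                        flag |= 0x2  # proper pair
                        if mate == 1:
                            flag |= 0x10
                        else:
                            flag |= 0x20
                        a.reference_id = 0
                        a.reference_start = pos + mate * 100
                        a.mapping_quality = 60
                        a.cigarstring = "50M"
                        a.next_reference_id = 0
                        a.next_reference_start = pos + (1 - mate) * 100
                        a.template_length = 150 if mate == 0 else -150
                    else:
                        flag |= 0x4 | 0x8  # both mates unmapped
                        a.reference_id = -1
                        a.reference_start = -1
                        a.mapping_quality = 0
                    a.flag = flag
                    out.write(a)
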