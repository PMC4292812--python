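"""Dual-genome read-pair classification for xenograft sequencing data.

Sequencing reads from a xenograft are a mixture of graft (human) tumour DNA
and host (mouse) DNA from stroma and vasculature.  The disambiguation
strategy implemented here aligns every read pair separately to the human and
mouse genomes and keeps for downstream analysis only those pairs that align
to human alone or to both genomes; pairs aligning only to mouse (host
contamination) or to neither genome are discarded.

Alignment itself is delegated to external aligners; this module ingests the
resulting name-matched SAM files, classifies each pair, applies the keep
rule, and quantifies agreement between two alternative kept sets (e.g.
against a k-mer-based classifier's output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

CLASS_NAMES = ("human_only", "mouse_only", "both", "neither")

MateMode = Literal["strict", "any"]


@dataclass(frozen=True)
class ReadPairRecord:
    """Alignment status of one read pair against graft and host genomes.

    A pair counts as aligned to a genome iff (under the default strict mate
    mode) both mates map to it, are flagged properly paired, and are neither
    duplicates nor secondary/supplementary alignments.
    """

    read_id: str
    human_aligned: bool
    mouse_aligned: bool

    @property
    def read_class(self) -> str:
        if self.human_aligned:
            return "both" if self.mouse_aligned else "human_only"
        return "mouse_only" if self.mouse_aligned else "neither"


@dataclass
class ClassificationSummary:
    """Per-class counts plus kept/discarded totals (kept = human_only + both)."""

    counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def kept(self) -> int:
        return self.counts.get("human_only", 0) + self.counts.get("both", 0)

    @property
    def discarded(self) -> int:
        return self.total - self.kept

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [(c, self.counts.get(c, 0)) for c in CLASS_NAMES]
        rows += [("kept", self.kept), ("discarded", self.discarded), ("total", self.total)]
        return rows


class _PairState:
    __slots__ = ("mates", "mapped", "proper", "duplicate")

    def __init__(self) -> None:
        self.mates: set[int] = set()
        self.mapped: dict[int, bool] = {}
        self.proper: dict[int, bool] = {}
        self.duplicate = False


def _scan_sam(path: str) -> dict[str, _PairState]:
    import pysam

    pairs: dict[str, _PairState] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for i, seg in enumerate(sam.fetch(until_eof=True), start=1):
            if seg.is_secondary or seg.is_supplementary:
                continue
            if not seg.is_paired:
                # unpaired reads are removed before classification
                continue
            name = seg.query_name
            if name is None:
                raise ValueError(f"{path}: record {i} has no read name")
            mate = 2 if seg.is_read2 else 1
            state = pairs.setdefault(name, _PairState())
            if mate in state.mates:
                raise ValueError(
                    f"{path}: read name {name!r} has two primary records for mate {mate}"
                )
            state.mates.add(mate)
            state.mapped[mate] = not seg.is_unmapped
            state.proper[mate] = seg.is_proper_pair
            state.duplicate = state.duplicate or seg.is_duplicate
    return pairs


def _pair_aligned(state: _PairState | None, mate_mode: MateMode) -> bool:
    if state is None:
        return False
    if mate_mode == "strict":
        return (
            state.mates == {1, 2}
            and all(state.mapped.values())
            and all(state.proper.values())
        )
    return any(state.mapped.values())


def ingest_alignments(
    sam_graft: str,
    sam_host: str,
    mate_mode: MateMode = "strict",
) -> list[ReadPairRecord]:
    """Build one :class:`ReadPairRecord` per read-pair name in either SAM.

    Pairs flagged duplicate in either genome are excluded entirely
    (redundant reads are removed before classification), as are unpaired
    reads.  Under ``mate_mode="strict"`` a pair is aligned to a genome only
    if both mates map and are properly paired; ``"any"`` accepts a single
    mapped mate.
    """
    if mate_mode not in ("strict", "any"):
        raise ValueError(f"mate_mode must be 'strict' or 'any', got {mate_mode!r}")
    graft = _scan_sam(sam_graft)
    host = _scan_sam(sam_host)
    records = []
    for name in sorted(set(graft) | set(host)):
        g, h = graft.get(name), host.get(name)
        if (g is not None and g.duplicate) or (h is not None and h.duplicate):
            continue
        records.append(
            ReadPairRecord(name, _pair_aligned(g, mate_mode), _pair_aligned(h, mate_mode))
        )
    return records


def classify(records: Iterable[ReadPairRecord]) -> tuple[set[str], ClassificationSummary]:
    """Apply the keep rule: human_only and both are kept, the rest discarded."""
    counts = {c: 0 for c in CLASS_NAMES}
    kept: set[str] = set()
    for rec in records:
        cls = rec.read_class
        counts[cls] += 1
        if cls in ("human_only", "both"):
            kept.add(rec.read_id)
    return kept, ClassificationSummary(counts)


@dataclass(frozen=True)
class KeepsetConcordance:
    """Agreement between two kept read sets."""

    jaccard: float
    containment_a: float
    containment_b: float


def keepset_concordance(kept_a: set[str], kept_b: set[str]) -> KeepsetConcordance | None:
    """Jaccard overlap |A∩B|/|A∪B| plus containment fractions.

    Returns ``None`` when both sets are empty (no reads to compare).
    """
    if not kept_a and not kept_b:
        return None
    inter = len(kept_a & kept_b)
    union = len(kept_a | kept_b)
    return KeepsetConcordance(
        jaccard=inter / union,
        containment_a=inter / len(kept_a) if kept_a else float("nan"),
        containment_b=inter / len(kept_b) if kept_b else float("nan"),
    )
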