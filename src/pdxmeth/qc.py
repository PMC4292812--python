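"""Probe-level quality control with host-genome masking.

Four rules, applied in a fixed order, reduce the raw probe universe to the
analysis-ready set:

1. detection filter — drop any probe for which at least one sample fails the
   detection p-value threshold (pass means p strictly below the threshold,
   i.e. signal distinguishable from background);
2. bead filter — drop probes measured with fewer than ``bead_min`` beads in
   at least ``bead_sample_frac`` of samples;
3. sex chromosomes — drop chrX/chrY probes;
4. mouse mask — drop probes detectable (p < threshold) in a mouse-only
   sample, removing host cross-hybridisation signal from xenograft data.

The final retained set is order-invariant (removal is a union); only the
per-rule attribution in the report depends on the order, with the first
removing rule claiming each probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QCThresholds:
    """Cutoffs for the probe QC rules.

    detection_p: probes pass detection when p < detection_p.
    bead_min / bead_sample_frac: remove probes with fewer than ``bead_min``
        beads in at least ``bead_sample_frac`` of samples.
    drop_sex: remove chrX/chrY probes.
    """

    detection_p: float = 0.01
    bead_min: int = 3
    bead_sample_frac: float = 0.05
    drop_sex: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_p < 1.0:
            raise ValueError("QCThresholds.detection_p must be in (0, 1)")
        if not 0.0 <= self.bead_sample_frac <= 1.0:
            raise ValueError("QCThresholds.bead_sample_frac must be in [0, 1]")
        if self.bead_min < 0:
            raise ValueError("QCThresholds.bead_min must be >= 0")


@dataclass
class QCReport:
    """Per-rule removal attribution and the retained probe set.

    ``removed_by_rule`` maps rule name to the probes *first* removed by that
    rule in application order; together with ``retained`` these partition the
    input probe universe.
    """

    removed_by_rule: dict[str, pd.Index] = field(default_factory=dict)
    retained: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def counts(self) -> dict[str, int]:
        out = {rule: len(ids) for rule, ids in self.removed_by_rule.items()}
        out["retained"] = len(self.retained)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(rule, len(ids)) for rule, ids in self.removed_by_rule.items()]
        rows.append(("retained", len(self.retained)))
        return pd.DataFrame(rows, columns=["rule", "count"])


def _check_unit_interval(df: pd.DataFrame, what: str) -> None:
    values = df.to_numpy()
    bad = (values < 0) | (values > 1) | ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{what} value {values[i, j]!r} out of [0, 1] at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )


def filter_detection(detp: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.Index:
    """Probes where at least one sample fails detection (p >= detection_p)."""
    _check_unit_interval(detp, "detection p")
    failing = (detp.to_numpy() >= thresholds.detection_p).any(axis=1)
    return detp.index[failing]


def mouse_mask(
    detp_mouse: pd.Series,
    thresholds: QCThresholds = QCThresholds(),
    universe: pd.Index | None = None,
) -> pd.Index:
    """Probes detectable in the mouse-only sample (p < detection_p).

    These cross-hybridise to host DNA and are removed from all xenografts.
    """
    if universe is not None and not detp_mouse.index.equals(universe):
        raise ValueError(
            f"mouse detection-p vector covers {len(detp_mouse)} probes, "
            f"probe universe has {len(universe)}; indexes must match"
        )
    return detp_mouse.index[detp_mouse.to_numpy() < thresholds.detection_p]


def filter_beads(beads: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.Index:
    """Probes with < bead_min beads in >= bead_sample_frac of samples."""
    values = beads.to_numpy()
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative bead count at probe {beads.index[i]!r}, sample {beads.columns[j]!r}"
        )
    frac_low = (values < thresholds.bead_min).mean(axis=1)
    return beads.index[frac_low >= thresholds.bead_sample_frac]


def sex_probes(annotation: pd.DataFrame) -> pd.Index:
    """Probes on chrX or chrY according to the annotation manifest."""
    return annotation.index[annotation["chrom"].isin(["chrX", "chrY"])]


def apply_qc(
    beta: pd.DataFrame,
    detp: pd.DataFrame | None = None,
    beads: pd.DataFrame | None = None,
    detp_mouse: pd.Series | None = None,
    annotation: pd.DataFrame | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[pd.DataFrame, QCReport]:
    """Apply all QC rules in order: detection, beads, sex chromosomes, mouse mask.

    All matrices must share the beta matrix's probe universe.  Rules whose
    input is ``None`` are skipped (sex removal additionally requires
    ``drop_sex``).  Returns the restricted beta matrix and a report whose
    per-rule sets partition the removed probes by first-removing rule.
    """
    universe = beta.index
    for name, obj in (("detp", detp), ("beads", beads), ("annotation", annotation)):
        if obj is not None and not obj.index.equals(universe):
            raise ValueError(f"{name} probe universe does not match the beta matrix")
    if detp_mouse is not None and not detp_mouse.index.equals(universe):
        raise ValueError("detp_mouse probe universe does not match the beta matrix")

    rule_sets: list[tuple[str, pd.Index]] = []
    if detp is not None:
        rule_sets.append(("detection", filter_detection(detp, thresholds)))
    if beads is not None:
        rule_sets.append(("beads", filter_beads(beads, thresholds)))
    if thresholds.drop_sex and annotation is not None:
        rule_sets.append(("sex_chromosomes", sex_probes(annotation)))
    if detp_mouse is not None:
        rule_sets.append(("mouse_mask", mouse_mask(detp_mouse, thresholds)))

    removed = pd.Index([], name=universe.name)
    report = QCReport()
    for rule, ids in rule_sets:
        newly = ids.difference(removed)
        report.removed_by_rule[rule] = newly.sort_values()
        removed = removed.union(newly)
    report.retained = universe.difference(removed).sort_values()
    # preserve original row order of retained probes
    keep_mask = ~universe.isin(removed)
    filtered = beta.loc[keep_mask]
    report.retained = filtered.index
    return filtered, report
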