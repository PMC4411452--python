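"""ROI-level R2* summaries, per-animal deltaR2*, and reference-tissue indexing.

USPIO uptake is quantified semiquantitatively: the mean R2* over the valid
voxels of a labelled region is taken at baseline and 48 h post-infusion,
their difference is the region's deltaR2*, and the graft's deltaR2* is
divided by a reference tissue's deltaR2* (native kidney, or skeletal muscle
for the clinically translatable variant) to normalise blood-pool contrast
concentration.  Records with a non-positive reference delta or too few
valid voxels are flagged rather than dropped, so a cohort survives
degenerate animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relaxometry import RelaxometryMaps

__all__ = [
    "LabelMask",
    "RoiSummary",
    "TissueMeasure",
    "AnimalRecord",
    "roi_summary",
    "delta_r2star",
    "index_ratio",
    "build_animal_record",
    "records_to_frame",
    "frame_to_records",
]

GRAFT = "graft_kidney"
NATIVE = "native_kidney"
MUSCLE = "skeletal_muscle"
SPLEEN = "spleen"

#: Tissues required to assemble a full AnimalRecord.  The spleen is never
#: summarised: its concentrated iron blooms into neighbouring tissue on
#: T2*-weighted images, so regions of interest avoid it.
REQUIRED_TISSUES = (GRAFT, NATIVE, MUSCLE)


@dataclass(frozen=True)
class LabelMask:
    """Integer-labelled ROI image with a label dictionary (0 = background)."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")
        present = set(np.unique(lab).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from dictionary")
        object.__setattr__(self, "labels", lab)

    def mask_for(self, tissue: str) -> np.ndarray:
        for value, name in self.names.items():
            if name == tissue:
                return self.labels == value
        raise KeyError(f"tissue {tissue!r} not in label dictionary")

    @property
    def tissues(self) -> list[str]:
        return [self.names[v] for v in sorted(self.names)]


@dataclass(frozen=True)
class RoiSummary:
    """Summary R2* (s^-1) over the valid voxels of one ROI."""

    value: float
    n_valid: int
    n_total: int
    flagged: bool = False
    reason: str | None = None


@dataclass
class TissueMeasure:
    """Per-tissue baseline and follow-up R2* (s^-1) for one animal."""

    r2star_baseline: float
    r2star_48h: float
    n_valid_baseline: int = 0
    n_valid_48h: int = 0
    flagged: bool = False

    @property
    def delta_r2star(self) -> float:
        return self.r2star_48h - self.r2star_baseline


@dataclass
class AnimalRecord:
    """One animal's tissue-wise R2* measures and indexed uptake ratios."""

    animal_id: str
    group: str  # "allograft" | "isograft"
    tissues: dict[str, TissueMeasure] = field(default_factory=dict)
    indexed_to_native: float | None = None
    indexed_to_muscle: dict[str, float | None] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return bool(self.flags)

    def delta(self, tissue: str) -> float:
        return self.tissues[tissue].delta_r2star


def roi_summary(maps: RelaxometryMaps, mask: LabelMask, tissue: str,
                statistic: str = "mean", min_voxels: int = 10) -> RoiSummary:
    """Summarise the R2* map over one labelled region.

    The statistic (mean by default, median optionally) is taken over valid
    voxels only.  ROIs with fewer than ``min_voxels`` valid voxels return a
    flagged summary with a NaN value instead of raising.
    """
    region = mask.mask_for(tissue)
    if region.shape != maps.spatial_shape:
        raise ValueError("mask and maps differ in spatial shape")
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown ROI statistic {statistic!r}")
    inside = region & maps.valid
    n_valid = int(np.count_nonzero(inside))
    n_total = int(np.count_nonzero(region))
    if n_valid < min_voxels:
        return RoiSummary(float("nan"), n_valid, n_total, flagged=True,
                          reason=f"only {n_valid} valid voxels (< {min_voxels})")
    vals = maps.r2star_s[inside]
    value = float(np.mean(vals) if statistic == "mean" else np.median(vals))
    return RoiSummary(value, n_valid, n_total)


def delta_r2star(baseline: float, followup: float) -> float:
    """R2* increase from baseline to follow-up; may be negative."""
    if not (np.isfinite(baseline) and np.isfinite(followup)):
        raise ValueError("both phases must be present to compute deltaR2*")
    return followup - baseline


def index_ratio(delta_target: float, delta_reference: float) -> float | None:
    """Ratio of a target tissue's deltaR2* to a reference tissue's.

    Returns ``None`` (flagged undefined) when the reference delta is not
    strictly positive — a negative or zero reference increase makes the
    normalisation meaningless rather than merely large.
    """
    if not np.isfinite(delta_reference) or delta_reference <= 0:
        return None
    return delta_target / delta_reference


def build_animal_record(animal_id: str, group: str,
                        measures: dict[str, TissueMeasure]) -> AnimalRecord:
    """Assemble an AnimalRecord from per-tissue measures, flag degeneracies.

    Requires graft, native kidney and skeletal muscle; a missing tissue or a
    non-positive reference delta produces a flagged (but retained) record.
    """
    rec = AnimalRecord(animal_id=animal_id, group=group, tissues=dict(measures))
    missing = [t for t in REQUIRED_TISSUES if t not in measures]
    if missing:
        rec.flags.append(f"missing tissues: {', '.join(missing)}")
        return rec
    for t, m in measures.items():
        if m.flagged:
            rec.flags.append(f"{t}: ROI summary flagged")
    if rec.flags:
        return rec

    d_graft = measures[GRAFT].delta_r2star
    d_native = measures[NATIVE].delta_r2star
    d_muscle = measures[MUSCLE].delta_r2star

    rec.indexed_to_native = index_ratio(d_graft, d_native)
    if rec.indexed_to_native is None:
        rec.flags.append("native-kidney reference delta <= 0")
    for t in (GRAFT, NATIVE):
        ratio = index_ratio(measures[t].delta_r2star, d_muscle)
        rec.indexed_to_muscle[t] = ratio
        if ratio is None and "muscle reference delta <= 0" not in rec.flags:
            rec.flags.append("muscle reference delta <= 0")
    return rec


def records_to_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    """Long-format cohort table: one row per animal, tissue and phase."""
    rows = []
    for r in records:
        for tissue, m in r.tissues.items():
            for phase, value in (("baseline", m.r2star_baseline),
                                 ("48h", m.r2star_48h)):
                rows.append({
                    "animal_id": r.animal_id, "group": r.group,
                    "tissue": tissue, "phase": phase, "value": value,
                })
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[AnimalRecord]:
    """Rebuild AnimalRecords (with indexing) from a long-format cohort table."""
    records = []
    for (animal_id, group), sub in frame.groupby(["animal_id", "group"], sort=True):
        measures: dict[str, TissueMeasure] = {}
        for tissue, tsub in sub.groupby("tissue"):
            by_phase = dict(zip(tsub["phase"], tsub["value"]))
            if "baseline" not in by_phase or "48h" not in by_phase:
                continue
            measures[tissue] = TissueMeasure(
                r2star_baseline=float(by_phase["baseline"]),
                r2star_48h=float(by_phase["48h"]),
            )
        records.append(build_animal_record(str(animal_id), str(group), measures))
    return records
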