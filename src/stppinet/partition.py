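"""Spatiotemporal partitioning of samples into period x region intervals.

Developmental stages (codes 1-13) are merged into non-overlapping periods
(P1-P8 by default) and anatomical structures (16 codes) into regions
(R1-R4).  Each sample lands in at most one interval; intervals with too few
samples for rank correlation are excluded with a recorded reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .datatypes import IntervalKey, SampleMeta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeriodDef:
    label: str
    stages: frozenset[int]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError(f"period {self.label} has no stages")


@dataclass(frozen=True)
class RegionDef:
    label: str
    structures: frozenset[str]

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError(f"region {self.label} has no structures")


@dataclass
class SpatioTemporalPartition:
    """Interval -> sample-id assignment plus exclusion bookkeeping."""

    intervals: dict[IntervalKey, list[str]]
    unassigned: list[str] = field(default_factory=list)
    excluded: dict[IntervalKey, str] = field(default_factory=dict)

    def retained(self) -> dict[IntervalKey, list[str]]:
        return dict(self.intervals)

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)


# Default surrogate scheme.  The 16 structure codes follow the BrainSpan
# dissection vocabulary; region contents group the structure codes by anatomy
# (R1 parietal/temporal/occipital cortex; R3 amygdala/hippocampus/striatum;
# R4 mediodorsal thalamus + cerebellar cortex; R2 the remaining frontal and
# sensorimotor cortex).  The stage->period merge is a surrogate: real-data
# runs should supply the authoritative scheme file.
DEFAULT_PERIODS: tuple[PeriodDef, ...] = (
    PeriodDef("P1", frozenset({1, 2})),
    PeriodDef("P2", frozenset({3, 4})),
    PeriodDef("P3", frozenset({5, 6})),
    PeriodDef("P4", frozenset({7})),
    PeriodDef("P5", frozenset({8})),
    PeriodDef("P6", frozenset({9, 10})),
    PeriodDef("P7", frozenset({11})),
    PeriodDef("P8", frozenset({12})),
    # stage 13 (oldest adults) intentionally unassigned
)
DEFAULT_REGIONS: tuple[RegionDef, ...] = (
    RegionDef("R1", frozenset({"IPC", "ITC", "STC", "A1C", "V1C"})),
    RegionDef("R2", frozenset({"OFC", "DFC", "VFC", "MFC", "M1C", "S1C"})),
    RegionDef("R3", frozenset({"AMY", "HIP", "STR"})),
    RegionDef("R4", frozenset({"MD", "CBC"})),
)


def _check_disjoint(items: Sequence, attr: str, kind: str) -> None:
    seen: dict = {}
    for item in items:
        for code in getattr(item, attr):
            if code in seen:
                raise ValueError(
                    f"{kind} definitions overlap: code {code!r} in both "
                    f"{seen[code]} and {item.label}"
                )
            seen[code] = item.label


def load_scheme(path: str | Path) -> tuple[list[PeriodDef], list[RegionDef]]:
    """Load a period/region scheme from a YAML file.

    Layout::

        periods:
          P1: [1, 2]
          ...
        regions:
          R1: [IPC, ITC, ...]
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "periods" not in doc or "regions" not in doc:
        raise ValueError(f"scheme file {path} must define 'periods:' and 'regions:' blocks")
    periods = [PeriodDef(str(k), frozenset(int(s) for s in v)) for k, v in doc["periods"].items()]
    regions = [RegionDef(str(k), frozenset(str(s) for s in v)) for k, v in doc["regions"].items()]
    return periods, regions


def write_scheme(periods: Sequence[PeriodDef], regions: Sequence[RegionDef],
                 path: str | Path) -> None:
    doc = {
        "periods": {p.label: sorted(p.stages) for p in periods},
        "regions": {r.label: sorted(r.structures) for r in regions},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def assign_samples(
    samples: Iterable[SampleMeta],
    periods: Sequence[PeriodDef] = DEFAULT_PERIODS,
    regions: Sequence[RegionDef] = DEFAULT_REGIONS,
) -> SpatioTemporalPartition:
    """Map each sample to its (period, region) interval.

    All period x region combinations are created as keys, possibly empty.
    Samples whose stage or structure falls outside the scheme are recorded
    as unassigned.  Overlapping period or region definitions are an error.
    """
    _check_disjoint(periods, "stages", "period")
    _check_disjoint(regions, "structures", "region")
    stage_to_period = {s: p.label for p in periods for s in p.stages}
    struct_to_region = {c: r.label for r in regions for c in r.structures}

    intervals: dict[IntervalKey, list[str]] = {
        IntervalKey(p.label, r.label): [] for p in periods for r in regions
    }
    unassigned: list[str] = []
    for sm in samples:
        period = stage_to_period.get(int(sm.stage))
        region = struct_to_region.get(str(sm.structure))
        if period is None or region is None:
            unassigned.append(sm.sample_id)
            continue
        intervals[IntervalKey(period, region)].append(sm.sample_id)
    if unassigned:
        logger.info("%d samples outside the scheme left unassigned", len(unassigned))
    return SpatioTemporalPartition(intervals=intervals, unassigned=unassigned)


def exclude_sparse_intervals(
    p: SpatioTemporalPartition, min_samples: int = 6
) -> SpatioTemporalPartition:
    """Move intervals with fewer than ``min_samples`` samples to excluded.

    Rank correlations are meaningless on a handful of observations, so
    data-poor intervals are dropped as a rule rather than case by case.
    Idempotent.
    """
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    intervals: dict[IntervalKey, list[str]] = {}
    excluded = dict(p.excluded)
    for key, ids in p.intervals.items():
        if len(ids) < min_samples:
            excluded[key] = f"insufficient samples (n={len(ids)} < {min_samples})"
        else:
            intervals[key] = list(ids)
    dropped = set(excluded) - set(p.excluded)
    if dropped:
        logger.info("excluded %d sparse intervals: %s",
                    len(dropped), ", ".join(k.label for k in sorted(dropped)))
    return SpatioTemporalPartition(intervals=intervals, unassigned=list(p.unassigned),
                                   excluded=excluded)
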