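"""Collapse redundant LC-MS lipid annotations into unique identifications.

Automated annotation of global lipidomics data produces redundant entries
for one lipid: multiple adducts, slightly shifted integrations of the same
chromatographic peak, and in-source fragments.  Within one ionization mode
and one lipid identity, a lower-abundance annotation is dropped when it
elutes within ``rt_tolerance`` minutes of a retained annotation (same peak
integrated twice) or when its abundance falls below ``intensity_fraction``
of the identity's dominant annotation (adduct/fragment satellite).  After
per-mode deduplication, the two ionization modes are merged and, for a
lipid annotated in both, only the higher-abundance mode's record is kept.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

from .nomenclature import LipidName, canonical_key, parse_lipid_name

__all__ = [
    "FeatureAnnotation",
    "CurationConfig",
    "CurationReport",
    "dedup_within_mode",
    "merge_modes",
    "curate",
]

logger = logging.getLogger(__name__)

_MODES = ("positive", "negative")


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated LC-MS feature."""

    lipid: LipidName
    mode: str
    retention_time: float  # minutes
    abundance: float  # peak area
    adduct: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.retention_time < 0:
            raise ValueError("retention_time must be >= 0")
        if not self.abundance >= 0:
            raise ValueError("abundance must be >= 0")

    @property
    def key(self) -> str:
        return canonical_key(self.lipid)


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds for redundancy filtering.

    rt_tolerance: annotations of one identity closer than this (minutes)
        are the same peak; strictly-less-than comparison.
    intensity_fraction: annotations below this fraction of the identity's
        reference abundance are satellites; strictly-less-than comparison.
    intensity_reference: ``group_max`` measures the fraction against the
        identity's single most abundant annotation; ``pairwise`` measures
        against every already-retained annotation (equivalent under the
        greedy order, kept for sensitivity analysis).
    mode_tie_break: which mode wins an exact abundance tie at the merge.
    """

    rt_tolerance: float = 0.10
    intensity_fraction: float = 0.25
    intensity_reference: str = "group_max"
    mode_tie_break: str = "positive_first"

    def __post_init__(self) -> None:
        if not self.rt_tolerance > 0:
            raise ValueError("rt_tolerance must be > 0")
        if not 0 < self.intensity_fraction < 1:
            raise ValueError("intensity_fraction must be in (0, 1)")
        if self.intensity_reference not in ("group_max", "pairwise"):
            raise ValueError("intensity_reference must be 'group_max' or 'pairwise'")
        if self.mode_tie_break not in ("positive_first", "negative_first"):
            raise ValueError("mode_tie_break must be 'positive_first' or 'negative_first'")


@dataclass
class CurationReport:
    """Counts of annotations dropped per rule."""

    dropped_rt: int = 0
    dropped_intensity: int = 0
    dropped_cross_mode: int = 0

    @property
    def total_dropped(self) -> int:
        return self.dropped_rt + self.dropped_intensity + self.dropped_cross_mode


def _group_by_key(annotations: list[FeatureAnnotation]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = defaultdict(list)
    for i, ann in enumerate(annotations):
        groups[ann.key].append(i)
    return groups


def dedup_within_mode(
    annotations: list[FeatureAnnotation],
    config: CurationConfig = CurationConfig(),
    report: CurationReport | None = None,
) -> list[FeatureAnnotation]:
    """Drop redundant annotations of identical lipids within one mode.

    Within each canonical-key group, candidates are visited in order of
    descending abundance (ties: earlier retention time, then input order)
    and greedily retained; a candidate is dropped if it elutes within
    ``rt_tolerance`` of an already retained record, or if its abundance is
    below ``intensity_fraction`` of the reference abundance.  Output
    preserves input order and is a subset of the input; the pass is
    idempotent.
    """
    modes = {a.mode for a in annotations}
    if len(modes) > 1:
        raise ValueError(f"annotations span multiple modes: {sorted(modes)}")
    keep: set[int] = set()
    for idxs in _group_by_key(annotations).values():
        order = sorted(idxs, key=lambda i: (-annotations[i].abundance, annotations[i].retention_time, i))
        group_max = annotations[order[0]].abundance
        retained: list[int] = []
        for i in order:
            cand = annotations[i]
            rt_hit = any(
                abs(cand.retention_time - annotations[j].retention_time) < config.rt_tolerance
                for j in retained
            )
            if rt_hit:
                if report is not None:
                    report.dropped_rt += 1
                continue
            if config.intensity_reference == "group_max":
                weak = cand.abundance < config.intensity_fraction * group_max
            else:
                weak = any(
                    cand.abundance < config.intensity_fraction * annotations[j].abundance
                    for j in retained
                )
            if weak:
                if report is not None:
                    report.dropped_intensity += 1
                continue
            retained.append(i)
        keep.update(retained)
    return [a for i, a in enumerate(annotations) if i in keep]


def merge_modes(
    positive: list[FeatureAnnotation],
    negative: list[FeatureAnnotation],
    config: CurationConfig = CurationConfig(),
    report: CurationReport | None = None,
) -> list[FeatureAnnotation]:
    """Merge per-mode curated lists, keeping one mode per lipid identity.

    For an identity annotated in both modes, the mode whose most abundant
    record is higher keeps all its records for that identity; the other
    mode's records are dropped.  Identities seen in one mode pass through.
    """
    pos_max: dict[str, float] = defaultdict(float)
    neg_max: dict[str, float] = defaultdict(float)
    for a in positive:
        pos_max[a.key] = max(pos_max[a.key], a.abundance)
    for a in negative:
        neg_max[a.key] = max(neg_max[a.key], a.abundance)

    def mode_wins(key: str, mode: str) -> bool:
        if key not in pos_max or key not in neg_max:
            return True
        p, n = pos_max[key], neg_max[key]
        if p != n:
            return (p > n) == (mode == "positive")
        return (config.mode_tie_break == "positive_first") == (mode == "positive")

    merged: list[FeatureAnnotation] = []
    for a in positive + negative:
        if mode_wins(a.key, a.mode):
            merged.append(a)
        elif report is not None:
            report.dropped_cross_mode += 1
    return merged


def curate(
    positive: list[FeatureAnnotation],
    negative: list[FeatureAnnotation],
    config: CurationConfig = CurationConfig(),
) -> tuple[list[FeatureAnnotation], CurationReport]:
    """Full curation: per-mode deduplication, then cross-mode merge.

    Returns the unique high-confidence identification list together with a
    :class:`CurationReport` of how many annotations each rule removed.
    """
    report = CurationReport()
    pos = dedup_within_mode(positive, config, report)
    neg = dedup_within_mode(negative, config, report)
    merged = merge_modes(pos, neg, config, report)
    logger.info(
        "curation: %d -> %d annotations (rt %d, intensity %d, cross-mode %d)",
        len(positive) + len(negative), len(merged),
        report.dropped_rt, report.dropped_intensity, report.dropped_cross_mode,
    )
    return merged, report


def annotations_from_records(records: list[dict]) -> list[FeatureAnnotation]:
    """Build annotations from plain dicts (CSV rows): lipid, mode, rt_min, abundance[, adduct]."""
    out = []
    for r in records:
        out.append(
            FeatureAnnotation(
                lipid=parse_lipid_name(r["lipid"]),
                mode=r["mode"],
                retention_time=float(r["rt_min"]),
                abundance=float(r["abundance"]),
                adduct=r.get("adduct") or None,
            )
        )
    return out
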