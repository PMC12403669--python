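"""Mutation spectra: six-class conditional rates, ts/tv, A/T bias, In/Del.

Substitution spectra are conditioned on the genomic base composition:
the per-class rate divides each class's count by the number of sites
where that class can originate (A/T sites for A:T-> classes, G/C sites
for G:C-> classes), times cell divisions.  Ratios with an empty
denominator return ``math.inf`` — the IEEE infinity is the flag — so
degenerate spectra never raise mid-pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .records import (
    ExperimentGroup,
    GenomeComposition,
    MutationClass,
    MutationRecord,
    SPECTRUM_CLASSES,
    TRANSITION_CLASSES,
    TRANSVERSION_CLASSES,
)

__all__ = [
    "SpectrumSummary",
    "spectrum_counts",
    "conditional_spectrum_rates",
    "ts_tv_ratio",
    "at_bias",
    "ins_del_ratio",
    "summarize_spectrum",
]

_AT_CLASSES = tuple(c for c in SPECTRUM_CLASSES if c.startswith("A:T"))
_GC_CLASSES = tuple(c for c in SPECTRUM_CLASSES if c.startswith("G:C"))


def spectrum_counts(mutations: Iterable[MutationRecord]) -> dict[str, int]:
    """Counts of BPS records over the six strand-collapsed classes."""
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for m in mutations:
        if m.mclass != MutationClass.BPS:
            continue
        if m.bps_subclass is None:
            raise ValueError(f"BPS record at {m.contig}:{m.position} lacks subclass")
        counts[m.bps_subclass] += 1
    return counts


def _origin_sites(cls: str, composition: GenomeComposition) -> int:
    return composition.at_sites if cls in _AT_CLASSES else composition.gc_sites


def conditional_spectrum_rates(
    group: ExperimentGroup, composition: GenomeComposition
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-class conditional rates (mean over lines) and their SEM.

    Each line's class rate is count / (origin sites x divisions), where
    origin sites are the genome's A/T or G/C sites scaled by the line's
    callable fraction (callable_sites / genome_length) when callable
    sites are recorded.  The group rate is the unweighted mean across
    lines; SEM is the sample standard deviation over sqrt(n lines)
    (0 for a single line).
    """
    if composition.at_sites == 0 or composition.gc_sites == 0:
        raise ValueError("composition must have both A/T and G/C sites")
    per_line: dict[str, list[float]] = {c: [] for c in SPECTRUM_CLASSES}
    for ln in group.lines:
        counts = spectrum_counts(group.mutations_of_line(ln.line_id))
        frac = (ln.callable_sites / composition.genome_length
                if ln.callable_sites is not None else 1.0)
        for cls in SPECTRUM_CLASSES:
            sites = _origin_sites(cls, composition) * frac
            per_line[cls].append(counts[cls] / (sites * ln.total_divisions))
    rates, sem = {}, {}
    for cls in SPECTRUM_CLASSES:
        vals = np.asarray(per_line[cls])
        rates[cls] = float(vals.mean())
        sem[cls] = float(vals.std(ddof=1) / math.sqrt(len(vals))) \
            if len(vals) > 1 else 0.0
    return rates, sem


def ts_tv_ratio(class_counts: Mapping[str, int]) -> float:
    """Transition/transversion ratio; ``inf`` when no transversions."""
    ts = sum(class_counts.get(c, 0) for c in TRANSITION_CLASSES)
    tv = sum(class_counts.get(c, 0) for c in TRANSVERSION_CLASSES)
    if tv == 0:
        return math.inf if ts > 0 else math.nan
    return ts / tv


def at_bias(class_counts: Mapping[str, int],
            composition: GenomeComposition) -> float:
    """Mutation bias in the A/T direction, conditioned on composition.

    Ratio of the conditional rate of G:C -> A/T changes (classes
    G:C->A:T and G:C->T:A, per G/C site) to the rate of A:T -> G/C
    changes (A:T->G:C and A:T->C:G, per A/T site).  The
    direction-neutral classes G:C->C:G and A:T->T:A change neither
    composition and are excluded.  ``inf`` when there are no
    A/T -> G/C events.
    """
    toward_at = class_counts.get("G:C->A:T", 0) + class_counts.get("G:C->T:A", 0)
    toward_gc = class_counts.get("A:T->G:C", 0) + class_counts.get("A:T->C:G", 0)
    if composition.gc_sites == 0 or composition.at_sites == 0:
        raise ValueError("composition must have both A/T and G/C sites")
    if toward_gc == 0:
        return math.inf if toward_at > 0 else math.nan
    return (toward_at / composition.gc_sites) / (toward_gc / composition.at_sites)


def ins_del_ratio(mutations: Iterable[MutationRecord]) -> float:
    """Insertion/deletion count ratio among small indels; ``inf`` if no deletions."""
    ins = dele = 0
    for m in mutations:
        if m.mclass == MutationClass.INSERTION:
            ins += 1
        elif m.mclass == MutationClass.DELETION:
            dele += 1
    if dele == 0:
        return math.inf if ins > 0 else math.nan
    return ins / dele


@dataclass
class SpectrumSummary:
    """Spectrum statistics of one experiment group."""

    group: str
    class_counts: dict[str, int]
    class_rates: dict[str, float]
    class_sem: dict[str, float]
    ts_tv: float
    at_bias: float
    ins_del: float

    def to_rows(self) -> list[dict]:
        """Plot-ready rows (class, count, rate, sem) for a bar chart."""
        return [
            {
                "group": self.group,
                "class": cls,
                "count": self.class_counts[cls],
                "rate": self.class_rates[cls],
                "sem": self.class_sem[cls],
            }
            for cls in SPECTRUM_CLASSES
        ]


def summarize_spectrum(
    group: ExperimentGroup, composition: GenomeComposition
) -> SpectrumSummary:
    """All spectrum statistics of a group in one pass."""
    counts = spectrum_counts(group.mutations)
    rates, sem = conditional_spectrum_rates(group, composition)
    return SpectrumSummary(
        group=group.name,
        class_counts=counts,
        class_rates=rates,
        class_sem=sem,
        ts_tv=ts_tv_ratio(counts),
        at_bias=at_bias(counts, composition),
        ins_del=ins_del_ratio(group.mutations),
    )
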