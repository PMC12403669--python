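"""Domain types for mutation-accumulation (MA) experiments.

An MA experiment propagates many independent lines of a microbe through
repeated single-colony bottlenecks, so that genetic drift overwhelms
selection and spontaneous mutations accumulate nearly neutrally.  The
atomic observation is a curated mutation call (:class:`MutationRecord`);
lines carry the exposure bookkeeping (callable sites, cell divisions)
needed to turn counts into per-site per-division rates.

Mutation classes
----------------
Calls are partitioned into four classes:

* ``BPS`` — base-pair substitution (single-nucleotide change), further
  labelled with one of six strand-collapsed substitution classes
  (e.g. a C→T and its complement G→A both read ``G:C->A:T``);
* ``INSERTION`` / ``DELETION`` — small indels, length change 1–49 bp;
* ``SV`` — structural variation, length change ≥ 50 bp or an imported
  SV call flagged as such.

Coordinates are 1-based fully closed, matching VCF convention; indels
are anchored on the base before the event.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "MutationClass",
    "MutationRecord",
    "MALine",
    "ExperimentGroup",
    "GenomeComposition",
    "SPECTRUM_CLASSES",
    "TRANSITION_CLASSES",
    "TRANSVERSION_CLASSES",
    "SV_SIZE_THRESHOLD",
    "classify_mutation",
    "bps_subclass",
    "complement",
    "InvalidAlleleError",
    "InvalidRecordError",
]

#: Length-change boundary separating small indels from structural variants.
SV_SIZE_THRESHOLD = 50

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: The six strand-collapsed base-substitution classes, ordered with the
#: A:T-origin classes first (the conventional spectrum-plot order).
SPECTRUM_CLASSES = (
    "A:T->G:C",
    "A:T->T:A",
    "A:T->C:G",
    "G:C->A:T",
    "G:C->T:A",
    "G:C->C:G",
)

#: Transition classes (purine<->purine / pyrimidine<->pyrimidine).
TRANSITION_CLASSES = ("A:T->G:C", "G:C->A:T")

#: Transversion classes.
TRANSVERSION_CLASSES = ("A:T->T:A", "A:T->C:G", "G:C->T:A", "G:C->C:G")


class InvalidAlleleError(ValueError):
    """An allele string contains characters outside {A, C, G, T}."""


class InvalidRecordError(ValueError):
    """A mutation record violates a structural invariant (e.g. ref == alt)."""


class MutationClass(str, enum.Enum):
    BPS = "BPS"
    INSERTION = "INSERTION"
    DELETION = "DELETION"
    SV = "SV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def complement(seq: str) -> str:
    """Complement of a DNA string (no reversal)."""
    try:
        return "".join(_COMPLEMENT[b] for b in seq)
    except KeyError as exc:
        raise InvalidAlleleError(f"non-ACGT base in {seq!r}") from exc


def _check_allele(name: str, seq: str) -> None:
    if not seq or any(b not in _COMPLEMENT for b in seq):
        raise InvalidAlleleError(
            f"{name} allele {seq!r} must be a non-empty string over A/C/G/T"
        )


def bps_subclass(ref: str, alt: str) -> str:
    """Strand-collapsed class of a single-base substitution.

    Substitutions are reported on the A:T / G:C pair of the reference
    base, so a mutation and its reverse-complement counterpart fall in
    the same class: ``bps_subclass("C", "T") == bps_subclass("G", "A")
    == "G:C->A:T"``.
    """
    _check_allele("ref", ref)
    _check_allele("alt", alt)
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise InvalidRecordError(f"not a single-base substitution: {ref}->{alt}")
    if ref in ("T", "C"):  # collapse onto the A/G-reference strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}:{_COMPLEMENT[ref]}->{alt}:{_COMPLEMENT[alt]}"


def classify_mutation(
    ref: str, alt: str, sv_flag: bool = False
) -> tuple[MutationClass, Optional[str]]:
    """Classify a ref/alt allele pair into (class, optional BPS subclass).

    Parameters
    ----------
    ref, alt
        Reference and alternate alleles (non-empty, A/C/G/T only).
    sv_flag
        Mark the record as an imported structural-variant call
        regardless of allele lengths (SV callers report breakends,
        not literal alleles).

    Returns
    -------
    (MutationClass, subclass)
        ``subclass`` is one of the six strand-collapsed substitution
        classes for BPS records and ``None`` otherwise.
    """
    _check_allele("ref", ref)
    _check_allele("alt", alt)
    if ref == alt:
        raise InvalidRecordError(f"ref equals alt ({ref!r}); not a mutation")
    if sv_flag:
        return MutationClass.SV, None
    delta = len(alt) - len(ref)
    if delta == 0:
        if len(ref) == 1:
            return MutationClass.BPS, bps_subclass(ref, alt)
        raise InvalidRecordError(
            f"multi-base substitution {ref}->{alt} is not a supported class; "
            "decompose into single-base records"
        )
    if abs(delta) >= SV_SIZE_THRESHOLD:
        return MutationClass.SV, None
    return (MutationClass.INSERTION if delta > 0 else MutationClass.DELETION), None


@dataclass(frozen=True)
class MutationRecord:
    """One curated mutation call in one MA line.

    ``mclass`` and ``bps_subclass`` are derived from the alleles at
    construction time when not supplied, and validated against them
    when they are.
    """

    line_id: str
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    mclass: MutationClass = None  # type: ignore[assignment]
    bps_subclass: Optional[str] = None
    coding_effect: Optional[str] = None  # nonsynonymous | synonymous | noncoding
    annotations: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise InvalidRecordError(
                f"position must be 1-based positive, got {self.position}"
            )
        sv_flag = self.mclass == MutationClass.SV
        mclass, sub = classify_mutation(self.ref, self.alt, sv_flag=sv_flag)
        if self.mclass is None:
            object.__setattr__(self, "mclass", mclass)
        elif MutationClass(self.mclass) != mclass:
            raise InvalidRecordError(
                f"declared class {self.mclass} inconsistent with alleles "
                f"{self.ref}->{self.alt} (expected {mclass})"
            )
        else:
            object.__setattr__(self, "mclass", MutationClass(self.mclass))
        if self.mclass == MutationClass.BPS:
            if self.bps_subclass is None:
                object.__setattr__(self, "bps_subclass", sub)
            elif self.bps_subclass != sub:
                raise InvalidRecordError(
                    f"declared subclass {self.bps_subclass} != derived {sub}"
                )
        elif self.bps_subclass is not None:
            raise InvalidRecordError("bps_subclass only valid for BPS records")
        if self.coding_effect is not None and self.coding_effect not in (
            "nonsynonymous",
            "synonymous",
            "noncoding",
        ):
            raise InvalidRecordError(
                f"unknown coding_effect {self.coding_effect!r}"
            )

    @property
    def is_transition(self) -> bool:
        return self.bps_subclass in TRANSITION_CLASSES


@dataclass
class MALine:
    """Per-line metadata: transfer regime, divisions, callable sites.

    ``total_divisions`` is the product of the per-transfer division
    estimate and the number of transfers; either it or the factor pair
    must be supplied.
    """

    line_id: str
    group: str
    transfers: Optional[int] = None
    divisions_per_transfer: Optional[float] = None
    total_divisions: Optional[float] = None
    callable_sites: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("transfers", "divisions_per_transfer", "total_divisions",
                     "callable_sites"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"line {self.line_id}: {name} must be positive")
        if self.transfers is not None and self.divisions_per_transfer is not None:
            product = self.divisions_per_transfer * self.transfers
            if self.total_divisions is None:
                self.total_divisions = product
            elif not math.isclose(self.total_divisions, product, rel_tol=1e-9):
                raise ValueError(
                    f"line {self.line_id}: total_divisions={self.total_divisions} "
                    f"!= divisions_per_transfer*transfers={product}"
                )
        if self.total_divisions is None:
            raise ValueError(
                f"line {self.line_id}: need total_divisions or "
                "(transfers, divisions_per_transfer)"
            )


@dataclass
class ExperimentGroup:
    """A named group of MA lines with their pooled mutation set."""

    name: str
    lines: list[MALine]
    mutations: list[MutationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [ln.line_id for ln in self.lines]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"group {self.name}: duplicate line ids {dupes}")
        known = set(ids)
        orphans = sorted({m.line_id for m in self.mutations} - known)
        if orphans:
            raise ValueError(
                f"group {self.name}: mutations reference unknown lines {orphans}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def records(self, mclass: MutationClass | str) -> list[MutationRecord]:
        mclass = MutationClass(mclass)
        return [m for m in self.mutations if m.mclass == mclass]

    def count(self, mclass: MutationClass | str) -> int:
        return len(self.records(mclass))

    def counts_by_class(self) -> dict[str, int]:
        out = {c.value: 0 for c in MutationClass}
        for m in self.mutations:
            out[m.mclass.value] += 1
        return out

    def mutations_of_line(self, line_id: str) -> list[MutationRecord]:
        return [m for m in self.mutations if m.line_id == line_id]


@dataclass
class GenomeComposition:
    """Base and site composition of the reference genome.

    ``at_sites``/``gc_sites`` condition substitution rates on the
    origin base; ``nonsyn_sites``/``syn_sites`` are fractional site
    counts (codon-degeneracy convention) used by the selection tests.
    Ambiguous bases are excluded from the A/T + G/C partition and
    tallied separately.
    """

    at_sites: int
    gc_sites: int
    genome_length: Optional[int] = None
    nonsyn_sites: Optional[float] = None
    syn_sites: Optional[float] = None
    ambiguous_sites: int = 0

    def __post_init__(self) -> None:
        if self.at_sites < 0 or self.gc_sites < 0 or self.ambiguous_sites < 0:
            raise ValueError("site counts must be non-negative")
        if self.genome_length is None:
            self.genome_length = self.at_sites + self.gc_sites
        elif self.genome_length != self.at_sites + self.gc_sites:
            raise ValueError(
                "genome_length must equal at_sites + gc_sites "
                "(ambiguous bases are tallied separately)"
            )
        for name in ("nonsyn_sites", "syn_sites"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def gc_fraction(self) -> float:
        return self.gc_sites / self.genome_length
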