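"""Shared fixtures: study-scale constants and a curated-counts experiment.

The "curated" fixture rebuilds, as input tables, the summary counts of
a two-group fission-yeast MA study (46 control / 48 treatment lines,
18/24 substitutions, 24/30 small indels, 6/13 SVs, nonsyn/syn splits
5:4 and 11:2) so the pipeline can be checked end to end against the
study's published statistics without any sequencing data.
"""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

from mastat import ExperimentGroup, GenomeComposition, MALine, MutationRecord
from mastat.records import MutationClass

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# exposures (site x division x line) and site totals of the study
G1 = 5.02822e11
G2 = 5.37022e11
NONSYN_SITES = 6_074_090
SYN_SITES = 1_641_376
GENOME_LENGTH = 12_521_788
GC_CONTENT = 0.3606


@pytest.fixture(scope="session")
def composition() -> GenomeComposition:
    gc = round(GC_CONTENT * GENOME_LENGTH)
    return GenomeComposition(
        at_sites=GENOME_LENGTH - gc,
        gc_sites=gc,
        nonsyn_sites=float(NONSYN_SITES),
        syn_sites=float(SYN_SITES),
    )


def _bps(line_id, pos, subclass, effect=None):
    """A BPS record of a given strand-collapsed class."""
    ref_alt = {
        "A:T->G:C": ("A", "G"),
        "A:T->T:A": ("A", "T"),
        "A:T->C:G": ("A", "C"),
        "G:C->A:T": ("G", "A"),
        "G:C->T:A": ("G", "T"),
        "G:C->C:G": ("G", "C"),
    }[subclass]
    return MutationRecord(line_id=line_id, contig="chr1", position=pos,
                          ref=ref_alt[0], alt=ref_alt[1], coding_effect=effect)


def _indel(line_id, pos, insertion=True, size=1):
    anchor = "A"
    tract = "C" * size
    ref, alt = (anchor, anchor + tract) if insertion else (anchor + tract, anchor)
    return MutationRecord(line_id=line_id, contig="chr1", position=pos,
                          ref=ref, alt=alt)


def _sv(line_id, pos, size=120):
    return MutationRecord(line_id=line_id, contig="chr1", position=pos,
                          ref="A", alt="A" + "G" * size,
                          mclass=MutationClass.SV)


def _build_group(name, n_lines, callable_sites, divisions_per_transfer,
                 spectrum_plan, coding_plan, n_ins, n_del, n_sv):
    """Assemble a group whose pooled counts match a published summary row.

    spectrum_plan: {subclass: count}; coding_plan: (n_nonsyn, n_syn)
    assigned to the first BPS records.
    """
    lines = [
        MALine(line_id=f"{name}_{i:03d}", group=name, transfers=46,
               divisions_per_transfer=divisions_per_transfer,
               callable_sites=callable_sites)
        for i in range(1, n_lines + 1)
    ]
    n_nonsyn, n_syn = coding_plan
    effects = (["nonsynonymous"] * n_nonsyn + ["synonymous"] * n_syn)
    classes = [c for c, k in spectrum_plan.items() for _ in range(k)]
    effects += ["noncoding"] * (len(classes) - len(effects))
    pos = itertools.count(1000, 997)  # arbitrary distinct positions
    line_cycle = itertools.cycle(ln.line_id for ln in lines)
    mutations = [
        _bps(next(line_cycle), next(pos), cls, effect)
        for cls, effect in zip(classes, effects)
    ]
    mutations += [_indel(next(line_cycle), next(pos), insertion=True)
                  for _ in range(n_ins)]
    mutations += [_indel(next(line_cycle), next(pos), insertion=False, size=2)
                  for _ in range(n_del)]
    mutations += [_sv(next(line_cycle), next(pos)) for _ in range(n_sv)]
    return ExperimentGroup(name=name, lines=lines, mutations=mutations)


@pytest.fixture(scope="session")
def curated_control() -> ExperimentGroup:
    """46 lines, 890 divisions, 18 BPS (ts/tv 2.00), 21+3 indels, 6 SVs."""
    return _build_group(
        "control", n_lines=46, callable_sites=12_282_010,
        divisions_per_transfer=890 / 46,
        spectrum_plan={"A:T->G:C": 3, "G:C->A:T": 9, "A:T->T:A": 1,
                       "A:T->C:G": 2, "G:C->T:A": 2, "G:C->C:G": 1},
        coding_plan=(5, 4), n_ins=21, n_del=3, n_sv=6,
    )


@pytest.fixture(scope="session")
def curated_treatment() -> ExperimentGroup:
    """48 lines, 911 divisions, 24 BPS (ts/tv 1.67), 28+2 indels, 13 SVs."""
    return _build_group(
        "treatment", n_lines=48, callable_sites=12_281_346,
        divisions_per_transfer=911 / 46,
        spectrum_plan={"A:T->G:C": 5, "G:C->A:T": 10, "A:T->T:A": 2,
                       "A:T->C:G": 2, "G:C->T:A": 3, "G:C->C:G": 2},
        coding_plan=(11, 2), n_ins=28, n_del=2, n_sv=13,
    )


@pytest.fixture()
def curated_tables(tmp_path, curated_control, curated_treatment):
    """The curated experiment written out as the TSV dialects the readers use."""
    from mastat import write_metadata_table, write_mutation_table

    mut = tmp_path / "mutations.tsv"
    meta = tmp_path / "metadata.tsv"
    write_mutation_table(
        curated_control.mutations + curated_treatment.mutations, mut)
    write_metadata_table(
        curated_control.lines + curated_treatment.lines, meta)
    return {"mutations": mut, "metadata": meta}
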