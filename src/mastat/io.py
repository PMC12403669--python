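"""Readers and writers for mutation tables, line metadata, VCF and FASTA.

Tables are plain tab-separated text with a header row.  The mutation
table carries one curated call per row (mandatory columns ``line_id``,
``contig``, ``position``, ``ref``, ``alt``; optional ``class`` and
``coding_effect``); unknown columns are preserved as per-record
annotations.  Records are returned in deterministic
(contig, position, line_id) order.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO

from .records import (
    ExperimentGroup,
    GenomeComposition,
    InvalidRecordError,
    MALine,
    MutationClass,
    MutationRecord,
)

__all__ = [
    "SchemaError",
    "RowError",
    "VcfFormatError",
    "read_mutation_table",
    "write_mutation_table",
    "read_metadata_table",
    "write_metadata_table",
    "read_cfu_table",
    "read_vcf_minimal",
    "scan_genome_composition",
    "load_experiment_groups",
]

MUTATION_COLUMNS = ("line_id", "contig", "position", "ref", "alt")
_OPTIONAL_COLUMNS = ("class", "bps_subclass", "coding_effect")
METADATA_COLUMNS = ("line_id", "group", "callable_sites")


class SchemaError(ValueError):
    """A table is missing mandatory columns."""


class RowError(ValueError):
    """A table row failed validation; the message names the row."""


class VcfFormatError(ValueError):
    """A VCF file could not be parsed."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_mutation_table(path: Union[str, Path]) -> list[MutationRecord]:
    """Read a tab-separated mutation table into validated records.

    Positions are 1-based.  A ``class`` column equal to ``SV`` marks
    imported structural-variant calls whatever their allele lengths;
    otherwise the class is derived from the alleles.  Row-level
    failures report the 1-based data row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, MUTATION_COLUMNS, path)
    extra_cols = [c for c in df.columns
                  if c not in MUTATION_COLUMNS and c not in _OPTIONAL_COLUMNS]
    records: list[MutationRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            position = int(row["position"])
        except (TypeError, ValueError):
            raise RowError(
                f"{path}: row {i}: unparseable position {row['position']!r}"
            ) from None
        declared = row.get("class") or None
        coding = row.get("coding_effect") or None
        annotations = {c: row[c] for c in extra_cols if row[c] != ""}
        try:
            records.append(
                MutationRecord(
                    line_id=row["line_id"],
                    contig=row["contig"],
                    position=position,
                    ref=row["ref"],
                    alt=row["alt"],
                    mclass=MutationClass(declared) if declared else None,
                    coding_effect=coding,
                    annotations=annotations,
                )
            )
        except ValueError as exc:
            raise RowError(f"{path}: row {i}: {exc}") from exc
    records.sort(key=lambda r: (r.contig, r.position, r.line_id))
    return records


def write_mutation_table(records: Iterable[MutationRecord],
                         path: Union[str, Path]) -> None:
    """Write records as the TSV dialect `read_mutation_table` consumes."""
    records = sorted(records, key=lambda r: (r.contig, r.position, r.line_id))
    extra = sorted({k for r in records for k in r.annotations})
    rows = []
    for r in records:
        row = {
            "line_id": r.line_id,
            "contig": r.contig,
            "position": r.position,
            "ref": r.ref,
            "alt": r.alt,
            "class": r.mclass.value,
            "coding_effect": r.coding_effect or "",
        }
        for k in extra:
            row[k] = r.annotations.get(k, "")
        rows.append(row)
    cols = ["line_id", "contig", "position", "ref", "alt", "class",
            "coding_effect", *extra]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_metadata_table(path: Union[str, Path]) -> list[MALine]:
    """Read per-line metadata (group, transfers, divisions, callable sites).

    Accepts either a ``divisions_per_transfer`` column or a ``cfu``
    column (colony-forming units of a colony grown from one cell), in
    which case divisions per transfer are estimated as log2(CFU).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("line_id", "group"), path)
    if "divisions_per_transfer" not in df.columns and "cfu" not in df.columns \
            and "total_divisions" not in df.columns:
        raise SchemaError(
            f"{path}: need divisions_per_transfer, cfu, or total_divisions"
        )
    lines = []
    for i, row in df.iterrows():
        kwargs = {}
        if "transfers" in df.columns and not pd.isna(row.get("transfers")):
            kwargs["transfers"] = int(row["transfers"])
        if "divisions_per_transfer" in df.columns and \
                not pd.isna(row.get("divisions_per_transfer")):
            kwargs["divisions_per_transfer"] = float(row["divisions_per_transfer"])
        elif "cfu" in df.columns and not pd.isna(row.get("cfu")):
            cfu = float(row["cfu"])
            if cfu < 1:
                raise RowError(f"{path}: row {i + 1}: CFU must be >= 1")
            kwargs["divisions_per_transfer"] = math.log2(cfu)
        if "total_divisions" in df.columns and not pd.isna(row.get("total_divisions")):
            kwargs["total_divisions"] = float(row["total_divisions"])
        if "callable_sites" in df.columns and not pd.isna(row.get("callable_sites")):
            kwargs["callable_sites"] = int(row["callable_sites"])
        try:
            lines.append(MALine(line_id=str(row["line_id"]),
                                group=str(row["group"]), **kwargs))
        except ValueError as exc:
            raise RowError(f"{path}: row {i + 1}: {exc}") from exc
    return lines


def write_metadata_table(lines: Iterable[MALine], path: Union[str, Path]) -> None:
    rows = [
        {
            "line_id": ln.line_id,
            "group": ln.group,
            "transfers": ln.transfers if ln.transfers is not None else "",
            "divisions_per_transfer": ln.divisions_per_transfer
            if ln.divisions_per_transfer is not None else "",
            "total_divisions": ln.total_divisions,
            "callable_sites": ln.callable_sites
            if ln.callable_sites is not None else "",
        }
        for ln in lines
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cfu_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CFU sampling table (columns line_id, round, cfu)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("line_id", "cfu"), path)
    return df


def load_experiment_groups(
    metadata_path: Union[str, Path],
    mutation_paths: Union[str, Path, Iterable[Union[str, Path]]],
) -> dict[str, ExperimentGroup]:
    """Assemble ExperimentGroups from a metadata table and mutation table(s).

    Every mutation's line_id must resolve to a metadata line; the
    group assignment comes from the metadata.
    """
    lines = read_metadata_table(metadata_path)
    if isinstance(mutation_paths, (str, Path)):
        mutation_paths = [mutation_paths]
    mutations: list[MutationRecord] = []
    for p in mutation_paths:
        mutations.extend(read_mutation_table(p))
    by_line = {ln.line_id: ln.group for ln in lines}
    unknown = sorted({m.line_id for m in mutations} - set(by_line))
    if unknown:
        raise RowError(f"mutations reference lines absent from metadata: {unknown}")
    groups: dict[str, ExperimentGroup] = {}
    for gname in dict.fromkeys(ln.group for ln in lines):  # stable order
        groups[gname] = ExperimentGroup(
            name=gname,
            lines=[ln for ln in lines if ln.group == gname],
            mutations=[m for m in mutations if by_line[m.line_id] == gname],
        )
    return groups


def read_vcf_minimal(
    path: Union[str, Path], default_line_id: str = "sample"
) -> tuple[list[MutationRecord], int]:
    """Convert SNVs and indels from a VCF 4.x file into mutation records.

    Multi-allelic records are split; per-sample genotypes, when
    present, assign each alternate allele to the samples carrying it
    (one MA line per sample column).  Records failing FILTER are
    skipped and counted.

    Returns
    -------
    (records, n_filtered)
    """
    import pysam

    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: malformed VCF: {exc}") from exc
    records: list[MutationRecord] = []
    n_filtered = 0
    with vf:
        samples = list(vf.header.samples)
        for rec in vf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                n_filtered += 1
                continue
            for ai, alt in enumerate(rec.alts or (), start=1):
                if alt is None or any(b not in "ACGT" for b in alt.upper()):
                    continue  # symbolic/breakend alleles need an SV table
                carriers: list[str]
                if samples:
                    carriers = [
                        s for s in samples
                        if ai in (rec.samples[s].get("GT") or ())
                    ]
                else:
                    carriers = [default_line_id]
                for line_id in carriers:
                    records.append(
                        MutationRecord(
                            line_id=line_id,
                            contig=rec.chrom,
                            position=rec.pos,
                            ref=rec.ref.upper(),
                            alt=alt.upper(),
                        )
                    )
    records.sort(key=lambda r: (r.contig, r.position, r.line_id))
    return records, n_filtered


def scan_genome_composition(fasta_path: Union[str, Path]) -> GenomeComposition:
    """Count A/T vs G/C sites over a genome FASTA, case-insensitive.

    Ambiguous bases (N and other IUPAC codes) are excluded from the
    A/T + G/C partition and tallied in ``ambiguous_sites``.
    """
    at = gc = ambiguous = 0
    n_seqs = 0
    for seq_record in SeqIO.parse(str(fasta_path), "fasta"):
        n_seqs += 1
        s = str(seq_record.seq).upper()
        at += s.count("A") + s.count("T")
        gc += s.count("G") + s.count("C")
        ambiguous += len(s) - (s.count("A") + s.count("T")
                               + s.count("G") + s.count("C"))
    if n_seqs == 0:
        raise ValueError(f"{fasta_path}: empty FASTA (no sequences)")
    return GenomeComposition(at_sites=at, gc_sites=gc, ambiguous_sites=ambiguous)
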