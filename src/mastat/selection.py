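"""Selection tests and synonymous/nonsynonymous site counting.

Whether selection biased the mutations recovered from an MA experiment
is tested by comparing observed nonsynonymous vs synonymous
substitution counts with the genome's nonsynonymous/synonymous site
ratio (goodness of fit), and the two groups with each other (2x2
table).  Both use the chi-square test with Yates' continuity
correction, with the corrected deviation floored at zero:
max(|O - E| - 0.5, 0), so near-perfect fits give exactly 0 rather
than an inflated statistic.

Site counting follows the codon-degeneracy convention: within each
codon, every position contributes (number of synonymous single-base
changes)/3 synonymous sites and the complement nonsynonymous, so each
codon contributes exactly 3 sites in total.  Changes that create a
stop codon count as nonsynonymous by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "TestResult",
    "yates_gof_test",
    "yates_2x2_test",
    "chisq_contingency",
    "codon_syn_nonsyn_fractions",
    "count_syn_nonsyn_sites",
    "cds_from_gff",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0 <= self.p_value <= 1:
            raise ValueError("invalid test result")


def yates_gof_test(
    obs_nonsyn: int, obs_syn: int, nonsyn_sites: float, syn_sites: float
) -> TestResult:
    """Goodness of fit of nonsyn/syn counts to the genomic site ratio.

    Expected counts are proportional to the site totals; the statistic
    is the Yates-corrected chi-square with 1 degree of freedom.
    """
    n = obs_nonsyn + obs_syn
    if n < 1:
        raise ValueError("need at least one observation")
    if nonsyn_sites <= 0 or syn_sites <= 0:
        raise ValueError("site totals must be positive")
    total_sites = nonsyn_sites + syn_sites
    expected = (n * nonsyn_sites / total_sites, n * syn_sites / total_sites)
    stat = sum(
        max(abs(o - e) - 0.5, 0.0) ** 2 / e
        for o, e in zip((obs_nonsyn, obs_syn), expected)
    )
    return TestResult(stat, 1, float(stats.chi2.sf(stat, 1)),
                      "chi-square goodness of fit, Yates-corrected")


def yates_2x2_test(a: int, b: int, c: int, d: int) -> TestResult:
    """Yates-corrected chi-square test of independence on a 2x2 table.

    Uses the shortcut form N(|ad - bc| - N/2)^2 / (row and column
    products), with the correction clamped: |ad - bc| <= N/2 gives 0.
    """
    N = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError("degenerate 2x2 table: a zero margin")
    dev = max(abs(a * d - b * c) - N / 2, 0.0)
    stat = N * dev ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return TestResult(stat, 1, float(stats.chi2.sf(stat, 1)),
                      "chi-square 2x2, Yates-corrected")


def chisq_contingency(
    table: Union[Sequence[Sequence[int]], np.ndarray], yates: bool = False
) -> TestResult:
    """Pearson chi-square test on an r x 2 contingency table.

    Yates correction is honoured only for 2x2 tables (df = 1), where
    it delegates to :func:`yates_2x2_test`; larger tables use the
    plain Pearson statistic with df = r - 1.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError(f"expected an r x 2 table with r >= 2, got {arr.shape}")
    if yates and arr.shape == (2, 2):
        return yates_2x2_test(*arr.astype(int).ravel())
    stat, p, df, expected = stats.chi2_contingency(arr, correction=False)
    if np.any(expected <= 0):
        raise ValueError("degenerate table: zero expected cell")
    return TestResult(float(stat), int(df), float(p), "chi-square contingency")


def codon_syn_nonsyn_fractions(
    codon: str, table_id: int = 1, stops_as_nonsyn: bool = True
) -> tuple[float, float]:
    """(nonsyn_sites, syn_sites) contributed by one sense codon.

    Enumerates the nine single-base changes; each position contributes
    n_synonymous/3 synonymous sites.  The two always sum to 3.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    code = CodonTable.unambiguous_dna_by_id[table_id]
    if codon in code.stop_codons:
        raise ValueError(f"stop codon {codon} contributes no sites")
    aa = code.forward_table[codon]
    syn = 0.0
    n_compared = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if mutant in code.stop_codons:
                if stops_as_nonsyn:
                    n_compared += 1
                # else: change excluded from the comparison entirely
                continue
            n_compared += 1
            if code.forward_table[mutant] == aa:
                syn += 1
    if stops_as_nonsyn:
        syn_sites = syn / 3.0
        return 3.0 - syn_sites, syn_sites
    # renormalise so the codon still contributes 3 sites
    if n_compared == 0:
        return 0.0, 0.0
    syn_sites = 3.0 * syn / n_compared
    return 3.0 - syn_sites, syn_sites


def count_syn_nonsyn_sites(
    cds_sequences: Iterable[str], table_id: int = 1, stops_as_nonsyn: bool = True
) -> tuple[float, float]:
    """Total (nonsyn_sites, syn_sites) over in-frame CDS sequences.

    Each CDS must have length divisible by 3 and no internal stop; a
    terminal stop codon is allowed and skipped (it contributes no
    sense sites).
    """
    nonsyn = syn = 0.0
    for si, seq in enumerate(cds_sequences):
        seq = str(seq).upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError(f"CDS {si}: length {len(seq)} not divisible by 3")
        code = CodonTable.unambiguous_dna_by_id[table_id]
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in code.stop_codons:
            codons = codons[:-1]
        for ci, codon in enumerate(codons):
            if codon in code.stop_codons:
                raise ValueError(f"CDS {si}: internal stop codon at codon {ci}")
            if any(b not in _BASES for b in codon):
                raise ValueError(f"CDS {si}: ambiguous codon {codon!r} at {ci}")
            ns, s = codon_syn_nonsyn_fractions(codon, table_id, stops_as_nonsyn)
            nonsyn += ns
            syn += s
    return nonsyn, syn


def cds_from_gff(gff_path, fasta_path) -> list[str]:
    """Extract in-frame CDS sequences from a GFF3 + genome FASTA.

    CDS features are grouped by parent (mRNA) ID, sorted by
    coordinate, stitched, and reverse-complemented on the minus
    strand.  Standard plumbing for feeding annotation into
    :func:`count_syn_nonsyn_sites`.
    """
    import gffutils
    from Bio import SeqIO
    from Bio.Seq import Seq

    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    by_parent: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.id or "cds"])
        for parent in parents:
            by_parent.setdefault(parent, []).append(cds)
    sequences = []
    for parent in sorted(by_parent):
        parts = sorted(by_parent[parent], key=lambda f: f.start)
        strand = parts[0].strand
        seq = "".join(genome[p.seqid][p.start - 1:p.end] for p in parts)
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        sequences.append(seq)
    return sequences
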