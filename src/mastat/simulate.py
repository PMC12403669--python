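"""Synthetic MA-experiment generator.

Emulates a two-group (control vs treatment) mutation-accumulation
experiment at the statistical level the downstream analysis assumes:
per-line mutation counts are Poisson with mean
mu x callable sites x total divisions; base substitutions carry one of
the six strand-collapsed classes drawn from a spectrum probability
vector, a uniform position over origin-base sites, and a coding
effect; indels and structural variants draw sizes below/above the
50 bp boundary.  No read-level error model is simulated — the
analysis starts from curated calls.

Defaults are the conditions of a fission-yeast MA study: 46 + 48
lines, ~46 transfers of ~19.35 divisions each (890 divisions per
line), a 12.52 Mb genome at 36.06% GC with ~98% of sites callable,
and rates on the 1e-11 per-site per-division scale, giving on the
order of 20 substitutions per group.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .records import (
    ExperimentGroup,
    GenomeComposition,
    MALine,
    MutationClass,
    MutationRecord,
    SPECTRUM_CLASSES,
    SV_SIZE_THRESHOLD,
    complement,
)

__all__ = [
    "SimulationConfig",
    "simulate_experiment",
    "simulate_cfu_series",
    "simulate_genome",
    "write_experiment",
]

#: Six-class spectrum used by default: ts/tv 2.0 and a ~3.7-fold
#: conditional bias toward A/T at 36% GC (order matches SPECTRUM_CLASSES).
DEFAULT_SPECTRUM = (0.22, 0.06, 0.06, 0.45, 0.14, 0.07)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic two-group MA experiment."""

    n_lines_control: int = 46
    n_lines_treatment: int = 48
    genome_length: int = 12_521_788
    gc_content: float = 0.3606
    coding_fraction: float = 0.616  # fraction of sites inside CDS
    nonsyn_syn_site_ratio: float = 3.70
    mu_bps: float = 3.58e-11
    mu_indel: float = 4.77e-11
    mu_sv: float = 1.19e-11
    treatment_fold: float = 1.0  # multiplier on every rate in the treatment
    spectrum_probs: tuple[float, ...] = DEFAULT_SPECTRUM
    ins_del_prob: float = 0.875  # fraction of indels that are insertions
    transfers: int = 46
    divisions_per_transfer: float = 19.35
    callable_fraction: float = 0.98
    cfu_log2_sigma: float = 0.2  # multiplicative noise of CFU counts
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.spectrum_probs) - 1.0) > 1e-9:
            raise ValueError("spectrum_probs must sum to 1")
        for name in ("gc_content", "coding_fraction", "ins_del_prob",
                     "callable_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("mu_bps", "mu_indel", "mu_sv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.treatment_fold < 0:
            raise ValueError("treatment_fold must be >= 0")

    @property
    def total_divisions(self) -> float:
        return self.divisions_per_transfer * self.transfers

    @property
    def callable_sites(self) -> int:
        return round(self.callable_fraction * self.genome_length)

    def composition(self) -> GenomeComposition:
        """Analytic genome composition implied by the config."""
        gc = round(self.gc_content * self.genome_length)
        coding = self.coding_fraction * self.genome_length
        r = self.nonsyn_syn_site_ratio
        return GenomeComposition(
            at_sites=self.genome_length - gc,
            gc_sites=gc,
            nonsyn_sites=coding * r / (1 + r),
            syn_sites=coding / (1 + r),
        )


def _random_base(rng: np.random.Generator, pool: str) -> str:
    return pool[rng.integers(len(pool))]


def _draw_bps(cfg: SimulationConfig, rng: np.random.Generator,
              line_id: str, comp: GenomeComposition) -> MutationRecord:
    cls = SPECTRUM_CLASSES[rng.choice(len(SPECTRUM_CLASSES),
                                      p=np.asarray(cfg.spectrum_probs))]
    # origin base: one of the two strands of the class's origin pair
    origin_pair = ("A", "T") if cls.startswith("A:T") else ("G", "C")
    ref = origin_pair[rng.integers(2)]
    target = cls.split("->")[1][0]  # e.g. "G" from "A:T->G:C"
    alt = target if ref in "AG" else complement(target)
    position = int(rng.integers(1, cfg.genome_length + 1))
    if rng.random() < cfg.coding_fraction:
        r = cfg.nonsyn_syn_site_ratio
        effect = "nonsynonymous" if rng.random() < r / (1 + r) else "synonymous"
    else:
        effect = "noncoding"
    return MutationRecord(line_id=line_id, contig="chr1", position=position,
                          ref=ref, alt=alt, coding_effect=effect)


def _draw_indel(cfg: SimulationConfig, rng: np.random.Generator,
                line_id: str) -> MutationRecord:
    # sizes concentrate at 1 bp, as real small-indel spectra do
    size = min(int(rng.geometric(0.7)), SV_SIZE_THRESHOLD - 1)
    position = int(rng.integers(1, cfg.genome_length + 1))
    anchor = _random_base(rng, "ACGT")
    tract = "".join(_random_base(rng, "ACGT") for _ in range(size))
    if rng.random() < cfg.ins_del_prob:
        ref, alt = anchor, anchor + tract
    else:
        ref, alt = anchor + tract, anchor
    return MutationRecord(line_id=line_id, contig="chr1", position=position,
                          ref=ref, alt=alt)


def _draw_sv(cfg: SimulationConfig, rng: np.random.Generator,
             line_id: str) -> MutationRecord:
    size = SV_SIZE_THRESHOLD + int(rng.geometric(0.01))
    position = int(rng.integers(1, cfg.genome_length + 1))
    anchor = _random_base(rng, "ACGT")
    tract = "".join(_random_base(rng, "ACGT") for _ in range(size))
    if rng.random() < 0.5:
        ref, alt = anchor, anchor + tract
    else:
        ref, alt = anchor + tract, anchor
    return MutationRecord(line_id=line_id, contig="chr1", position=position,
                          ref=ref, alt=alt, mclass=MutationClass.SV)


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[ExperimentGroup, ExperimentGroup, GenomeComposition, dict]:
    """Generate (control, treatment, composition, truth record).

    Each line draws from its own deterministic child stream of
    cfg.seed, so adding lines never perturbs earlier lines' draws.
    Duplicate (contig, position, line) collisions — vanishingly rare
    at these rates — are removed and counted in the truth record.
    """
    comp = cfg.composition()
    exposure_per_line = cfg.callable_sites * cfg.total_divisions
    for fold, n_lines in ((1.0, cfg.n_lines_control),
                          (cfg.treatment_fold, cfg.n_lines_treatment)):
        expected = (cfg.mu_bps + cfg.mu_indel + cfg.mu_sv) * fold \
            * exposure_per_line * n_lines
        if expected > 1e6:
            raise ValueError(
                f"expected {expected:.3g} mutations per group exceeds the "
                "desk-scale guard of 1e6; lower the rates or exposures"
            )
    root = np.random.SeedSequence(cfg.seed)
    group_streams = root.spawn(2)
    groups = []
    n_dupes = 0
    for gname, fold, n_lines, gss in (
        ("control", 1.0, cfg.n_lines_control, group_streams[0]),
        ("treatment", cfg.treatment_fold, cfg.n_lines_treatment,
         group_streams[1]),
    ):
        lines, mutations = [], []
        for li, lss in enumerate(gss.spawn(n_lines), start=1):
            rng = np.random.default_rng(lss)
            line_id = f"{gname}_{li:03d}"
            lines.append(MALine(
                line_id=line_id, group=gname, transfers=cfg.transfers,
                divisions_per_transfer=cfg.divisions_per_transfer,
                callable_sites=cfg.callable_sites,
            ))
            n_bps = rng.poisson(cfg.mu_bps * fold * exposure_per_line)
            n_indel = rng.poisson(cfg.mu_indel * fold * exposure_per_line)
            n_sv = rng.poisson(cfg.mu_sv * fold * exposure_per_line)
            for _ in range(n_bps):
                mutations.append(_draw_bps(cfg, rng, line_id, comp))
            for _ in range(n_indel):
                mutations.append(_draw_indel(cfg, rng, line_id))
            for _ in range(n_sv):
                mutations.append(_draw_sv(cfg, rng, line_id))
        seen = set()
        unique = []
        for m in mutations:
            key = (m.line_id, m.contig, m.position)
            if key in seen:
                n_dupes += 1
                continue
            seen.add(key)
            unique.append(m)
        unique.sort(key=lambda r: (r.contig, r.position, r.line_id))
        groups.append(ExperimentGroup(name=gname, lines=lines,
                                      mutations=unique))
    control, treatment = groups
    truth = {
        "config": asdict(cfg),
        "exposure_control": exposure_per_line * cfg.n_lines_control,
        "exposure_treatment": exposure_per_line * cfg.n_lines_treatment,
        "n_position_collisions_removed": n_dupes,
    }
    return control, treatment, comp, truth


def simulate_cfu_series(
    T: float, n_samples: int, sigma: float = 0.2, seed: int = 0
) -> np.ndarray:
    """CFU counts of colonies grown from one cell for T doublings.

    CFU = round(2^T x lognormal noise); log2 of the geometric mean
    recovers T with standard error sigma / (ln 2 * sqrt(n)).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if T < 0 or sigma < 0:
        raise ValueError("T and sigma must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=n_samples) \
        if sigma > 0 else np.ones(n_samples)
    return np.maximum(np.round(2.0 ** T * noise), 1.0)


def simulate_genome(
    length: int, gc_content: float, seed: int = 0, contig: str = "chr1"
) -> tuple[str, str]:
    """(name, sequence) of an i.i.d. random genome at the given GC content."""
    rng = np.random.default_rng(seed)
    p_each_gc = gc_content / 2
    p_each_at = (1 - gc_content) / 2
    bases = rng.choice(np.array(list("ACGT")), size=length,
                       p=[p_each_at, p_each_gc, p_each_gc, p_each_at])
    return contig, "".join(bases)


def write_experiment(
    cfg: SimulationConfig, out_dir, genome_fasta: bool = False
) -> dict[str, Path]:
    """Run the generator and emit the TSV/JSON (optionally FASTA) files.

    Produces ``mutations.tsv``, ``metadata.tsv`` and ``truth.json`` in
    the dialects the readers consume; ``genome.fasta`` on request.
    Byte-identical across runs with the same config.
    """
    from . import io as mio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    control, treatment, comp, truth = simulate_experiment(cfg)
    paths = {
        "mutations": out_dir / "mutations.tsv",
        "metadata": out_dir / "metadata.tsv",
        "truth": out_dir / "truth.json",
    }
    mio.write_mutation_table(control.mutations + treatment.mutations,
                             paths["mutations"])
    mio.write_metadata_table(control.lines + treatment.lines,
                             paths["metadata"])
    truth["composition"] = {
        "at_sites": comp.at_sites, "gc_sites": comp.gc_sites,
        "nonsyn_sites": comp.nonsyn_sites, "syn_sites": comp.syn_sites,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    if genome_fasta:
        name, seq = simulate_genome(cfg.genome_length, cfg.gc_content,
                                    seed=cfg.seed)
        fasta = out_dir / "genome.fasta"
        with open(fasta, "w") as fh:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
        paths["genome"] = fasta
    return paths
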