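"""Full-analysis orchestration: tables in, reproducible report out.

Composes the whole MA-experiment analysis — per-group mutation counts
and rates with exact Poisson intervals, spectrum statistics, between-
group rate comparisons, selection tests, effective population size,
and (optionally) the power analysis — into one deterministic report.
The report is a pure function of the input tables, the configuration
and the seed; identical inputs give byte-identical JSON.

Configuration is a flat YAML mapping::

    mutations: mutations.tsv        # path or list of paths
    metadata: metadata.tsv
    genome_fasta: genome.fa         # or explicit at_sites/gc_sites
    at_sites: 8006432
    gc_sites: 4515356
    nonsyn_sites: 6074090.0         # optional, enables selection tests
    syn_sites: 1641376.0
    conf_level: 0.95
    alpha: 0.05
    power: false                    # or a mapping of PowerConfig fields
    seed: 1
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import io as mio
from .popgen import effective_population_size
from .power import PowerConfig, PowerCurve, power_curve
from .rates import RateComparison, RateEstimate, estimate_rate, exposure, \
    rate_ratio_test
from .records import ExperimentGroup, GenomeComposition, MutationClass
from .selection import TestResult, yates_2x2_test, yates_gof_test
from .spectrum import SpectrumSummary, summarize_spectrum

__all__ = ["AnalysisConfigError", "AnalysisInputError", "AnalysisReport",
           "run_full_analysis", "write_report"]

RATE_SCALE = 1e-10  # Table-style rates are reported in units of 1e-10


class AnalysisConfigError(ValueError):
    """The configuration file is missing or inconsistent."""


class AnalysisInputError(ValueError):
    """An input table failed to load or validate."""


@dataclass
class GroupSummary:
    """One row of the per-group summary table."""

    name: str
    n_lines: int
    mean_divisions: float
    exposure: float
    bps: RateEstimate
    indel: RateEstimate
    sv: RateEstimate
    spectrum: SpectrumSummary
    ne: float

    def to_row(self) -> dict:
        return {
            "group": self.name,
            "lines": self.n_lines,
            "divisions": round(self.mean_divisions, 1),
            "BPSs": self.bps.count,
            "ts/tv": _fmt_ratio(self.spectrum.ts_tv),
            "AT_bias": _fmt_ratio(self.spectrum.at_bias),
            "In/Del": _fmt_ratio(self.spectrum.ins_del),
            "mu_BPS_1e-10": self.bps.mu / RATE_SCALE,
            "mu_Indel_1e-10": self.indel.mu / RATE_SCALE,
            "mu_SV_1e-10": self.sv.mu / RATE_SCALE,
            "Ne": self.ne,
        }


def _fmt_ratio(x: float) -> Union[float, str]:
    if math.isinf(x):
        return "inf"
    if math.isnan(x):
        return "NA"
    return round(x, 4)


@dataclass
class AnalysisReport:
    """Everything the analysis computes, JSON/TSV/text-serialisable."""

    groups: list[GroupSummary]
    comparisons: dict[str, RateComparison]
    selection: dict[str, TestResult]
    power: Optional[PowerCurve]
    conf_level: float
    seed: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def rate(r: RateEstimate) -> dict:
            return {"count": r.count, "mu": r.mu, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "conf_level": r.conf_level}

        out = {
            "conf_level": self.conf_level,
            "seed": self.seed,
            "groups": {
                g.name: {
                    "n_lines": g.n_lines,
                    "mean_divisions": g.mean_divisions,
                    "exposure": g.exposure,
                    "rates": {"BPS": rate(g.bps), "indel": rate(g.indel),
                              "SV": rate(g.sv)},
                    "spectrum": {
                        "counts": g.spectrum.class_counts,
                        "rates": g.spectrum.class_rates,
                        "sem": g.spectrum.class_sem,
                        "ts_tv": _fmt_ratio(g.spectrum.ts_tv),
                        "at_bias": _fmt_ratio(g.spectrum.at_bias),
                        "ins_del": _fmt_ratio(g.spectrum.ins_del),
                    },
                    "Ne": g.ne,
                }
                for g in self.groups
            },
            "comparisons": {
                k: {"rr": _fmt_ratio(c.rr), "ci_low": _fmt_ratio(c.ci_low),
                    "ci_high": _fmt_ratio(c.ci_high),
                    "p_wald": _fmt_ratio(c.p_wald),
                    "p_exact": _fmt_ratio(c.p_exact)}
                for k, c in self.comparisons.items()
            },
            "selection": {
                k: {"statistic": t.statistic, "df": t.df,
                    "p_value": t.p_value, "method": t.method}
                for k, t in self.selection.items()
            },
            "notes": self.notes,
        }
        if self.power is not None:
            out["power"] = {
                "alpha": self.power.alpha, "sided": self.power.sided,
                "reps": self.power.reps, "curve": self.power.to_rows(),
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame([g.to_row() for g in self.groups])

    def to_text(self) -> str:
        lines = ["MA-experiment analysis report", ""]
        lines.append(self.summary_table().to_string(index=False))
        lines.append("")
        for k, c in self.comparisons.items():
            lines.append(
                f"rate comparison {k}: RR = {_fmt_ratio(c.rr)} "
                f"({int(c.conf_level * 100)}% CI {_fmt_ratio(c.ci_low)}, "
                f"{_fmt_ratio(c.ci_high)}), Wald P = {_fmt_ratio(c.p_wald)}, "
                f"exact P = {_fmt_ratio(c.p_exact)}"
            )
        for k, t in self.selection.items():
            lines.append(
                f"selection {k}: chi2 = {t.statistic:.2f}, df = {t.df}, "
                f"P = {t.p_value:.2f}"
            )
        if self.power is not None:
            lines.append(
                f"power ({self.power.sided}-sided, alpha {self.power.alpha}, "
                f"{self.power.reps} reps/effect): "
                + ", ".join(f"{e:g}->{p:.3f}" for e, p in
                            zip(self.power.effects, self.power.power))
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"


def _class_rate(group: ExperimentGroup, classes, g, conf, label) -> RateEstimate:
    count = sum(group.count(c) for c in classes)
    return estimate_rate(count, g, conf=conf, mclass=label)


def _consistency_check(summary: GroupSummary, group: ExperimentGroup) -> None:
    # the report must always re-derive from the record set it claims to summarise
    counts = group.counts_by_class()
    assert summary.bps.count == counts["BPS"]
    assert summary.indel.count == counts["INSERTION"] + counts["DELETION"]
    assert summary.sv.count == counts["SV"]
    assert sum(summary.spectrum.class_counts.values()) == counts["BPS"]


def _load_config(config: Union[str, Path, dict]) -> dict:
    if isinstance(config, (str, Path)):
        try:
            cfg = yaml.safe_load(Path(config).read_text())
        except FileNotFoundError as exc:
            raise AnalysisConfigError(f"config not found: {config}") from exc
        except yaml.YAMLError as exc:
            raise AnalysisConfigError(f"config not parseable: {exc}") from exc
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict):
        raise AnalysisConfigError("config must be a mapping of flat keys")
    for key in ("mutations", "metadata"):
        if key not in cfg:
            raise AnalysisConfigError(f"config lacks mandatory key {key!r}")
    return cfg


def _composition_from_config(cfg: dict) -> GenomeComposition:
    if "genome_fasta" in cfg:
        comp = mio.scan_genome_composition(cfg["genome_fasta"])
        return GenomeComposition(
            at_sites=comp.at_sites, gc_sites=comp.gc_sites,
            nonsyn_sites=cfg.get("nonsyn_sites"),
            syn_sites=cfg.get("syn_sites"),
            ambiguous_sites=comp.ambiguous_sites,
        )
    if "at_sites" in cfg and "gc_sites" in cfg:
        return GenomeComposition(
            at_sites=int(cfg["at_sites"]), gc_sites=int(cfg["gc_sites"]),
            nonsyn_sites=cfg.get("nonsyn_sites"),
            syn_sites=cfg.get("syn_sites"),
        )
    raise AnalysisConfigError(
        "config needs either genome_fasta or explicit at_sites/gc_sites"
    )


def run_full_analysis(config: Union[str, Path, dict]) -> AnalysisReport:
    """Run the complete analysis described by a configuration mapping.

    Stages: load tables -> per-group rates (BPS, small indel, SV) with
    exact Poisson CIs -> spectrum statistics -> pairwise rate
    comparisons -> selection tests (when site totals are given) ->
    Ne -> optional power curve.  Raises
    :class:`AnalysisInputError` / :class:`AnalysisConfigError` with
    the failing stage named.
    """
    cfg = _load_config(config)
    conf = float(cfg.get("conf_level", 0.95))
    seed = int(cfg.get("seed", 0))
    notes = [
        "p-values are reported raw; no multiple-testing correction is "
        "applied across the handful of tests"
    ]
    try:
        groups = mio.load_experiment_groups(cfg["metadata"], cfg["mutations"])
    except (mio.SchemaError, mio.RowError, FileNotFoundError, ValueError) as exc:
        raise AnalysisInputError(f"stage load-tables: {exc}") from exc
    try:
        comp = _composition_from_config(cfg)
    except (ValueError, FileNotFoundError) as exc:
        if isinstance(exc, AnalysisConfigError):
            raise
        raise AnalysisInputError(f"stage composition: {exc}") from exc

    summaries = []
    exposures = {}
    for group in groups.values():
        try:
            g = exposure(group, mean_sites=cfg.get("mean_callable_sites"))
        except ValueError as exc:
            raise AnalysisInputError(f"stage exposure: {exc}") from exc
        exposures[group.name] = g
        mean_T = sum(
            ln.divisions_per_transfer for ln in group.lines
            if ln.divisions_per_transfer is not None
        ) / max(1, sum(1 for ln in group.lines
                       if ln.divisions_per_transfer is not None)) \
            if any(ln.divisions_per_transfer is not None for ln in group.lines) \
            else None
        summary = GroupSummary(
            name=group.name,
            n_lines=group.n_lines,
            mean_divisions=g.mean_divisions,
            exposure=g.value,
            bps=_class_rate(group, [MutationClass.BPS], g, conf, "BPS"),
            indel=_class_rate(group, [MutationClass.INSERTION,
                                      MutationClass.DELETION], g, conf, "indel"),
            sv=_class_rate(group, [MutationClass.SV], g, conf, "SV"),
            spectrum=summarize_spectrum(group, comp),
            ne=effective_population_size(mean_T) if mean_T is not None
            else math.nan,
        )
        _consistency_check(summary, group)
        summaries.append(summary)

    comparisons: dict[str, RateComparison] = {}
    selection: dict[str, TestResult] = {}
    if len(summaries) == 2:
        ctrl, trt = summaries
        for label, attr in (("BPS", "bps"), ("indel", "indel"), ("SV", "sv")):
            r1, r2 = getattr(ctrl, attr), getattr(trt, attr)
            if r1.count + r2.count > 0:
                comparisons[label] = rate_ratio_test(
                    r1.count, ctrl.exposure, r2.count, trt.exposure, conf=conf
                )
        if comp.nonsyn_sites and comp.syn_sites:
            obs = {}
            for group in groups.values():
                ns = sum(1 for m in group.mutations
                         if m.coding_effect == "nonsynonymous")
                s = sum(1 for m in group.mutations
                        if m.coding_effect == "synonymous")
                obs[group.name] = (ns, s)
                if ns + s >= 1:
                    selection[f"gof_{group.name}"] = yates_gof_test(
                        ns, s, comp.nonsyn_sites, comp.syn_sites
                    )
            (a, b), (c, d) = obs.values()
            if min(a + b, c + d, a + c, b + d) > 0:
                selection["between_groups_2x2"] = yates_2x2_test(a, b, c, d)

    power = None
    if cfg.get("power"):
        pkw = cfg["power"] if isinstance(cfg["power"], dict) else {}
        pkw.setdefault("seed", seed)
        if len(summaries) == 2 and "g1" not in pkw:
            pkw["g1"] = summaries[0].exposure
            pkw["g2"] = summaries[1].exposure
            pkw.setdefault("mu_control", summaries[0].bps.mu)
        if "effect_grid" in pkw:
            pkw["effect_grid"] = tuple(pkw["effect_grid"])
        try:
            power = power_curve(PowerConfig(**pkw))
        except (TypeError, ValueError) as exc:
            raise AnalysisConfigError(f"stage power: {exc}") from exc

    return AnalysisReport(groups=summaries, comparisons=comparisons,
                          selection=selection, power=power,
                          conf_level=conf, seed=seed, notes=notes)


def write_report(report: AnalysisReport, out_dir: Union[str, Path]) -> dict:
    """Emit report.json, summary.tsv, spectrum.tsv and report.txt."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out_dir / "report.json",
        "summary": out_dir / "summary.tsv",
        "spectrum": out_dir / "spectrum.tsv",
        "text": out_dir / "report.txt",
    }
    paths["json"].write_text(report.to_json())
    report.summary_table().to_csv(paths["summary"], sep="\t", index=False)
    spec_rows = [row for g in report.groups for row in g.spectrum.to_rows()]
    pd.DataFrame(spec_rows).to_csv(paths["spectrum"], sep="\t", index=False)
    paths["text"].write_text(report.to_text())
    if report.power is not None:
        paths["power"] = out_dir / "power.tsv"
        pd.DataFrame(report.power.to_rows()).to_csv(
            paths["power"], sep="\t", index=False)
    return paths
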