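"""End-to-end validation pipeline and report generation.

Runs the full psychometric validation sequence on a dataset (read from
delimited text or freshly simulated): item descriptives and outlier
screening, the three factorial-validity models with fit indices and
reliability, the measurement-invariance ladder per grouping variable with
the latent-mean comparison, and convergent validity plus percentile-rank
norms. Every stage writes one block of a structured report; a stage
failure is recorded and non-dependent stages continue.
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, descriptives, evaluation, norms
from .data import ItemDataset, read_dataset
from .invariance import invariance_ladder
from .model import CFAModel
from .simulate import GeneratorConfig, generate_dataset
from .specs import build_model

STAGES = ("descriptives", "cfa", "invariance", "norms")


@dataclass
class RunConfig:
    """Configuration of one validation run.

    Either ``input_path`` (delimited text) or ``generator`` (keyword
    overrides for :class:`~gbb8.simulate.GeneratorConfig`) supplies the
    data. Every decision threshold of the analysis is a named key here.
    """

    input_path: str | None = None
    generator: dict = field(default_factory=dict)
    covariate_cols: list[str] = field(default_factory=list)
    groupings: list[str] = field(default_factory=lambda: ["sex", "age_band"])
    models: list[str] = field(default_factory=lambda: [
        "one_factor", "correlated", "second_order"])
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    outlier_alpha: float = 0.001
    dcfi_threshold: float = 0.010
    drmsea_threshold: float = 0.015
    significance_alpha: float = 0.001
    seed: int = 0
    output_dir: str = "gbb8_report"
    verbosity: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not self.stages:
            raise ValueError("at least one analysis stage must be enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _load_data(config: RunConfig) -> ItemDataset:
    if config.input_path:
        return read_dataset(config.input_path,
                            covariate_cols=config.covariate_cols)
    gen = GeneratorConfig(seed=config.seed, **config.generator)
    return generate_dataset(gen)


def run_validation(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the structured report.

    The report is a plain JSON-serialisable dict: ``metadata`` plus one
    block per enabled stage (or an ``error`` record for a failed stage).
    Deterministic given the seed, except for the timestamp.
    """
    data = _load_data(config)
    report: dict = {
        "metadata": {
            "version": __version__,
            "seed": config.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "n": data.n,
            "n_items": data.n_items,
            "missing_fraction": round(data.missing_fraction(), 6),
            "n_dropped_all_missing": data.meta.get("n_dropped_all_missing", 0),
            "groupings": [g for g in config.groupings if g in data.group_cols],
        },
        "warnings": [],
    }

    for stage in config.stages:
        try:
            if stage == "descriptives":
                report[stage] = _stage_descriptives(data, config)
            elif stage == "cfa":
                report[stage] = _stage_cfa(data, config)
            elif stage == "invariance":
                report[stage] = _stage_invariance(data, config)
            elif stage == "norms":
                report[stage] = _stage_norms(data, config)
        except Exception as exc:  # a failed stage must not kill the run
            report[stage] = {"error": f"{type(exc).__name__}: {exc}"}
            report["warnings"].append(
                f"stage {stage} failed: {traceback.format_exc(limit=1)}")
    return report


# ----------------------------------------------------------------------
def _stage_descriptives(data: ItemDataset, config: RunConfig) -> dict:
    table = descriptives.item_descriptives(data)
    outliers = descriptives.mahalanobis_outliers(data, alpha=config.outlier_alpha)
    return {
        "items": {item: {k: _r(v, 2) for k, v in row.items()}
                  for item, row in table.round(6).to_dict("index").items()},
        "outliers": {
            "alpha": outliers.alpha,
            "n_complete": int(len(outliers.d2)),
            "n_flagged": outliers.n_flagged,
            "prop_flagged": _r(outliers.prop_flagged, 4),
            "sum_d2": _r(float(outliers.d2.sum()), 3),
        },
    }


def _stage_cfa(data: ItemDataset, config: RunConfig) -> dict:
    out = {"note": ("normal-theory maximum-likelihood statistics; "
                    "robust (scaled) variants are not computed")}
    for kind in config.models:
        spec = build_model(kind, item_names=data.item_names,
                           subscales=data.subscales)
        res = CFAModel.from_dataset(data, spec).fit()
        idx = evaluation.fit_indices(res)
        block = {k: _r(v, 3) for k, v in idx.as_dict().items()}
        block["labels"] = idx.labels
        block["converged"] = res.converged
        if res.heywood:
            block["heywood"] = [list(h) for h in res.heywood]
        if kind == "second_order":
            rel = evaluation.reliability(res)
            block["reliability"] = {
                "omega_subscale": {k: _r(v, 3)
                                   for k, v in rel.omega_subscale.items()},
                "omega_l1": _r(rel.omega_l1, 3),
                "omega_l2": _r(rel.omega_l2, 3),
            }
        out[kind] = block
    return out


def _stage_invariance(data: ItemDataset, config: RunConfig) -> dict:
    out = {}
    for grouping in config.groupings:
        if grouping not in data.group_cols:
            continue
        ladder = invariance_ladder(
            data, grouping,
            dcfi_threshold=config.dcfi_threshold,
            drmsea_threshold=config.drmsea_threshold,
        )
        rows = []
        for s in ladder.steps:
            row = {"model": s.label, "chi2": _r(s.results.chi2, 3),
                   "df": s.results.df, "cfi": _r(s.indices.cfi, 3),
                   "rmsea": _r(s.indices.rmsea, 3), "decision": s.decision}
            if s.dchi2 is not None:
                row.update({"dchi2": _r(s.dchi2, 3), "ddf": s.ddf,
                            "p": _r(s.pvalue, 3), "dcfi": _r(s.dcfi, 3),
                            "drmsea": _r(s.drmsea, 3)})
            rows.append(row)
        block = {"steps": rows, "highest_level": ladder.highest_level,
                 "aborted_at": ladder.aborted_at}
        if ladder.effect_size is not None:
            es = ladder.effect_size
            block["latent_means"] = {
                "p": _r(ladder.mean_lrt.pvalue, 3),
                "alphas": {lab: _r(a, 4)
                           for lab, a in zip(es.labels, es.alphas)},
                "psi_p": _r(es.psi_p, 4),
                "f": _r(es.f, 4),
                "r_squared": _r(es.r_squared, 4),
            }
            if len(es.alphas) == 2:
                block["latent_means"]["d"] = _r(es.d, 4)
        out[grouping] = block
    return out


def _stage_norms(data: ItemDataset, config: RunConfig) -> dict:
    table = norms.sum_scores(data)
    nt = norms.norms_table(table)
    block = {
        "percentile_ranks": {c: {int(s): int(v)
                                 for s, v in nt[c].dropna().items()}
                             for c in nt.columns},
    }
    if data.covariate_cols:
        r, p, sig = norms.convergent_correlations(
            table, data.covariates, alpha=config.significance_alpha)
        block["correlations"] = {
            "r": {a: {b: _r(r.loc[a, b], 2) for b in r.columns}
                  for a in r.index},
            "alpha": config.significance_alpha,
            "n_significant": int(sig.to_numpy().sum() - len(sig)),
        }
    return block


def _r(v, nd):
    if v is None:
        return None
    v = float(v)
    return None if np.isnan(v) else round(v, nd)


# ----------------------------------------------------------------------
def write_report(report: dict, output_dir, formats=("json", "txt")) -> list[Path]:
    """Write the structured report (JSON) and a human-readable rendering."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        path = out / "report.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True))
        written.append(path)
    if "txt" in formats:
        path = out / "report.txt"
        path.write_text(render_report(report))
        written.append(path)
    return written


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def render_report(report: dict) -> str:
    """Human-readable rendering (3 decimals for fit indices, 2 for
    descriptives, mirroring common reporting conventions)."""
    lines = ["GBB-8 validation report", "=" * 60]
    meta = report.get("metadata", {})
    lines.append(f"version {meta.get('version')}   seed {meta.get('seed')}   "
                 f"n = {meta.get('n')}   "
                 f"missing = {100 * meta.get('missing_fraction', 0):.1f}%")
    if "descriptives" in report and "items" in report.get("descriptives", {}):
        lines += ["", "Item descriptives", "-" * 60,
                  f"{'item':<14}{'M':>6}{'SD':>6}{'skew':>7}{'kurt':>7}"
                  f"{'r_sub':>7}{'r_it':>6}"]
        for item, row in report["descriptives"]["items"].items():
            lines.append(
                f"{item:<14}{row['M']:>6.2f}{row['SD']:>6.2f}"
                f"{row['skewness']:>7.2f}{row['kurtosis']:>7.2f}"
                f"{row['r_subscale']:>7.2f}{row['r_it']:>6.2f}")
        o = report["descriptives"]["outliers"]
        lines.append(f"outliers: {o['n_flagged']} of {o['n_complete']} flagged "
                     f"at alpha = {o['alpha']}")
    if "cfa" in report:
        lines += ["", "Factorial validity", "-" * 60]
        for kind in ("one_factor", "correlated", "second_order"):
            b = report["cfa"].get(kind)
            if not b or "chi2" not in b:
                continue
            lines.append(
                f"{kind:<14} chi2({b['df']}) = {b['chi2']:.3f}  p = {b['p']:.3f}  "
                f"CFI = {b['cfi']:.3f}  TLI = {b['tli']:.3f}  "
                f"RMSEA = {b['rmsea']:.3f}  SRMR = {b['srmr']:.3f}")
            if "reliability" in b:
                rel = b["reliability"]
                oms = "  ".join(f"{k} {v:.3f}"
                                for k, v in rel["omega_subscale"].items())
                lines.append(f"{'':<14} omega: {oms}")
                lines.append(f"{'':<14} omega_L1 = {rel['omega_l1']:.3f}  "
                             f"omega_L2 = {rel['omega_l2']:.3f}")
    if "invariance" in report:
        for grouping, b in report["invariance"].items():
            if "steps" not in b:
                continue
            lines += ["", f"Measurement invariance: {grouping}", "-" * 60]
            for s in b["steps"]:
                extra = ""
                if "dchi2" in s:
                    extra = (f"  dchi2 = {s['dchi2']:.3f} (ddf {s['ddf']}, "
                             f"p = {s['p']:.3f})  dCFI = {s['dcfi']:.3f}  "
                             f"dRMSEA = {s['drmsea']:.3f}  [{s['decision']}]")
                lines.append(f"{s['model']:<28} chi2({s['df']}) = "
                             f"{s['chi2']:.3f}{extra}")
            if "latent_means" in b:
                lm = b["latent_means"]
                conv = (f"d = {lm['d']:.2f}" if "d" in lm
                        else f"R^2 = {lm['r_squared']:.3f}")
                lines.append(f"latent means: p = {lm['p']:.3f}, "
                             f"f = {lm['f']:.3f}, {conv}")
    if "norms" in report and "percentile_ranks" in report.get("norms", {}):
        lines += ["", "Percentile-rank norms (scores with PR)", "-" * 60]
        for scale, table in report["norms"]["percentile_ranks"].items():
            entries = "  ".join(f"{s}:{pr}" for s, pr in table.items())
            lines.append(f"{scale:<18} {entries}")
        if "correlations" in report["norms"]:
            lines.append("convergent correlations (r with total):")
            r = report["norms"]["correlations"]["r"]
            row = r.get("total", {})
            lines.append("  " + "  ".join(
                f"{k} {v:.2f}" for k, v in row.items()
                if k != "total" and v is not None))
    return "\n".join(lines) + "\n"
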