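"""Pipeline orchestration: validate inputs, run the analysis stages in
dependency order and emit machine-readable results plus a text report.

A run is described by a YAML or JSON config mapping stage names to their
inputs.  Each stage consumes either existing CSV files or a ``synthetic``
scenario block (handed to :func:`dclkit.synth.generate`).  Supported stages:

``isotherms``   anisotropy titrations -> binding fits (-> van't Hoff when
                several temperatures are present)
``solubility``  phase-solubility diagram -> type + stability constant
``decay``       TCSPC histogram -> lifetimes
``quench``      Stern-Volmer series -> K_SV, k_q
``release``     intensity time course -> first-order k, half-life
``mtt``         dose-response plates -> IC50 (+ pairwise t-tests)

Outputs are deterministic for a fixed config and seed: results.json is
written with sorted keys and no timestamps, so re-runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as dio
from .binding import fit_binding_isotherm, select_stoichiometry
from .cytotoxicity import compare_ic50, fit_ic50
from .errors import DclkitError, ValidationError
from .formulation import fit_release_first_order
from .photophysics import fit_decay, stern_volmer_fit
from .solubility import classify_diagram, stability_constant
from .synth import generate
from .thermodynamics import vant_hoff_fit

__all__ = ["RunReport", "run_pipeline", "validate_inputs", "load_config"]

STAGE_ORDER = ("isotherms", "solubility", "decay", "quench", "release", "mtt")

_SCHEMA_BY_COLUMN = {
    "host_conc_M": ("titration", dio.load_titration),
    "cd_conc_M": ("solubility", dio.load_solubility),
    "time_ns": ("decay", dio.load_decay),
    "q_conc_M": ("quench", dio.load_quench),
    "time_min": ("release", dio.load_release),
    "dose_M": ("dose_response", dio.load_dose_response),
    "temperature_K": ("k_table", dio.load_k_table),
}


@dataclass
class RunReport:
    """Aggregated pipeline results with provenance."""

    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    failures: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {"stages": self.stages, "provenance": self.provenance,
                   "warnings": self.warnings, "failures": self.failures}
        return json.dumps(payload, indent=2, sort_keys=True, default=float)

    def to_text(self) -> str:
        lines = [f"dclkit {self.provenance.get('version', '?')} pipeline report",
                 f"seed: {self.provenance.get('seed')}", ""]
        for stage in STAGE_ORDER:
            if stage not in self.stages:
                continue
            lines.append(f"[{stage}]")
            lines.extend(_render(self.stages[stage], indent="  "))
            lines.append("")
        if self.warnings:
            lines.append("warnings:")
            lines.extend(f"  - {w}" for w in self.warnings)
        if self.failures:
            lines.append("failures:")
            lines.extend(f"  - {k}: {v}" for k, v in sorted(self.failures.items()))
        return "\n".join(lines) + "\n"


def _render(obj, indent=""):
    lines = []
    if isinstance(obj, dict):
        for key in obj:
            val = obj[key]
            if isinstance(val, (dict, list)):
                lines.append(f"{indent}{key}:")
                lines.extend(_render(val, indent + "  "))
            else:
                lines.append(f"{indent}{key}: {_fmt(val)}")
    elif isinstance(obj, list):
        for val in obj:
            if isinstance(val, (dict, list)):
                lines.extend(_render(val, indent + "  "))
            else:
                lines.append(f"{indent}- {_fmt(val)}")
    return lines


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline config file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or not cfg:
        raise ValidationError(f"{path}: empty or malformed config")
    return cfg


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _resolve_files(block: dict, outdir: Path, seed: int, scenario_default: str,
                   provenance: dict):
    """Return the list of input CSVs for a stage, generating synthetic data
    when the block asks for it."""
    if "synthetic" in block:
        syn = dict(block["synthetic"] or {})
        syn.setdefault("scenario", scenario_default)
        syn.setdefault("seed", seed)
        paths = generate(syn, outdir / "synthetic" / syn["scenario"])
        files = [p for p in paths if str(p).endswith(".csv")]
    else:
        files = [Path(f) for f in block.get("files", [])]
        if "file" in block:
            files.append(Path(block["file"]))
        for f in files:
            if not f.exists():
                raise ValidationError(f"input file not found: {f}")
    for f in files:
        # synthetic inputs are recorded relative to the run directory so a
        # re-run in another location stays byte-identical
        try:
            key = str(Path(f).relative_to(outdir))
        except ValueError:
            key = str(f)
        provenance["inputs"][key] = _sha256(f)
    return files


def _stage_isotherms(block, files, warnings_out):
    results = {"titrations": []}
    K_by_T = {}
    for f in files:
        t = dio.load_titration(f)
        mode = block.get("stoichiometry", "auto")
        if mode == "auto":
            rep = select_stoichiometry(t)
            fit = rep.fit_1to2 if rep.selected == "1:2" else rep.fit_1to1
            selected = rep.selected
        else:
            fit = fit_binding_isotherm(t, mode)
            selected = mode
        warnings_out.extend(f"{Path(f).name}: {w}" for w in fit.warnings)
        entry = {"file": Path(f).name, "temperature_K": t.temperature,
                 "medium": t.medium, "stoichiometry": selected,
                 "K": fit.K, "r_free": fit.r_free, "r_inf": fit.r_inf,
                 "K_stderr": fit.std_errors.get("K"),
                 "residual_ss": fit.residual_ss}
        if selected == "1:2":
            entry["K_sqrt"] = fit.K_sqrt
        results["titrations"].append(entry)
        K_by_T.setdefault(t.medium, {})[t.temperature] = fit.K
    for medium, kt in K_by_T.items():
        if len(kt) >= 2:
            th = vant_hoff_fit(kt)
            results.setdefault("vant_hoff", {})[medium] = {
                "dH_kJ_mol": th.dH, "dS_J_K_mol": th.dS,
                "dH_stderr": th.std_errors["dH"],
                "dS_stderr": th.std_errors["dS"],
                "dG_298K_kJ_mol": th.dG_at(298.15),
                "n_temperatures": th.n_temperatures}
    return results


def _stage_solubility(block, files, warnings_out):
    out = {}
    for f in files:
        d = dio.load_solubility(f)
        cls = classify_diagram(d)
        entry = {"type": cls.diagram_type, "slope": cls.slope,
                 "intercept_M": cls.intercept, "r_squared": cls.r_squared,
                 "S0_M": d.S0}
        if cls.diagram_type == "A_L":
            entry["K_stability"] = stability_constant(cls.slope, d.S0)
        else:
            warnings_out.append(f"{Path(f).name}: non-A_L diagram "
                                f"({cls.diagram_type}); no 1:1 constant")
        out[Path(f).name] = entry
    return out


def _stage_decay(block, files, warnings_out):
    out = {}
    for f in files:
        trace = dio.load_decay(f)
        fit = fit_decay(trace, n_components=int(block.get("n_components", 1)))
        warnings_out.extend(f"{Path(f).name}: {w}" for w in fit.warnings)
        out[Path(f).name] = {
            "lifetimes_ns": fit.lifetimes.tolist(),
            "amplitudes": fit.amplitudes.tolist(),
            "mean_lifetime_ns": fit.mean_lifetime,
            "background": fit.background,
            "reduced_chisq": fit.reduced_chisq}
    return out


def _stage_quench(block, files, warnings_out):
    out = {}
    for f in files:
        s = dio.load_quench(f)
        use = block.get("use", "intensity")
        res = stern_volmer_fit(s, use=use)
        warnings_out.extend(f"{Path(f).name}: {w}" for w in res.warnings)
        out[Path(f).name] = {
            "K_SV": res.K_SV, "k_q": res.k_q,
            "n_linear_points": int(res.linear_mask.sum()),
            "r_squared": res.r_squared, "ratios_used": use}
    return out


def _stage_release(block, files, warnings_out):
    out = {}
    for f in files:
        trace = dio.load_release(f)
        fit = fit_release_first_order(trace, mode=block.get("mode", "plateau"))
        out[Path(f).name] = {
            "stable": fit.stable, "k_per_min": fit.k,
            "tau_half_min": fit.tau_half,
            "plateau_percent": fit.plateau_percent, "pH": trace.pH}
    return out


def _stage_mtt(block, files, warnings_out):
    out = {"fits": {}}
    replicate_sets = {}
    for f in files:
        dr = dio.load_dose_response(f)
        label = dr.treatment or Path(f).stem
        pooled = fit_ic50(dr, per_replicate=False)
        warnings_out.extend(f"{Path(f).name}: {w}" for w in pooled.warnings)
        per_rep = fit_ic50(dr, per_replicate=True)
        replicate_sets[label] = per_rep
        out["fits"][label] = {
            "cell_line": dr.cell_line,
            "ic50_M": pooled.ic50, "hill": pooled.hill,
            "bottom_pct": pooled.bottom,
            "ic50_stderr": pooled.std_errors.get("ic50"),
            "replicate_ic50_M": [r.ic50 for r in per_rep]}
    for pair in block.get("compare", []):
        a, b = pair
        if a in replicate_sets and b in replicate_sets:
            res = compare_ic50(replicate_sets[a], replicate_sets[b])
            out.setdefault("comparisons", {})[f"{a}_vs_{b}"] = {
                "t": res.t_statistic, "p": res.p_value,
                "significant": res.significant}
    return out


_STAGE_HANDLERS = {
    "isotherms": (_stage_isotherms, "cmbcd_1to1"),
    "solubility": (_stage_solubility, "solubility"),
    "decay": (_stage_decay, "decay"),
    "quench": (_stage_quench, "quench"),
    "release": (_stage_release, "release"),
    "mtt": (_stage_mtt, "mtt"),
}


def run_pipeline(config, outdir, seed: int = 0) -> RunReport:
    """Execute the configured stages and write results under ``outdir``.

    ``config`` may be a path to a YAML/JSON file or an already-parsed dict.
    Writes ``results.json`` and ``report.txt``; a stage failure is recorded
    in the report's failure section without aborting later stages.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    stages_cfg = config.get("stages", config)
    known = [s for s in STAGE_ORDER if s in stages_cfg]
    if not known:
        raise ValidationError("config defines no recognized stages "
                              f"(expected any of {STAGE_ORDER})")
    seed = int(config.get("seed", seed))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(provenance={"version": __version__, "seed": seed,
                                   "inputs": {}})
    for stage in known:
        block = stages_cfg[stage] or {}
        handler, default_scenario = _STAGE_HANDLERS[stage]
        try:
            files = _resolve_files(block, outdir, seed, default_scenario,
                                   report.provenance)
            report.stages[stage] = handler(block, files, report.warnings)
        except DclkitError as exc:
            report.failures[stage] = str(exc)
    (outdir / "results.json").write_text(report.to_json() + "\n")
    (outdir / "report.txt").write_text(report.to_text())
    return report


def validate_inputs(paths) -> dict:
    """Validate each file against its (column-inferred) schema.

    Returns ``{path: {"schema": name, "status": "ok"|"error", ...}}``;
    unreadable or invalid files produce error entries without stopping the
    remaining files.
    """
    out = {}
    for p in paths:
        entry = {"schema": None, "status": "error"}
        try:
            df, _ = dio.read_csv_with_meta(p)
            loader = None
            for col, (name, fn) in _SCHEMA_BY_COLUMN.items():
                if col in df.columns:
                    entry["schema"] = name
                    loader = fn
                    break
            if loader is None:
                entry["message"] = "unrecognized schema (no known key column)"
            else:
                loader(p)
                entry["status"] = "ok"
        except Exception as exc:  # report and continue with other files
            entry["message"] = str(exc)
        out[str(p)] = entry
    return out
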