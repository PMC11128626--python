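"""Config-driven orchestration of the full study design.

Stages, in order: optional colocalization gate on the drug-target locus,
instrument selection (cis exposure set and mediator set), the five-estimator
MR panel with sensitivity suite for each outcome, and two-step mediation
through the mediator.  Every stage's result — or failure — is recorded in a
StudyReport whose numbers are re-derivable from the config and seeds alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import InputError
from . import __version__
from .coloc import coloc_abf
from .estimators import cochran_q, egger, estimator_panel, leave_one_out, mr_presso
from .instruments import LDMatrix, load_annotations, select_instruments
from .mediation import TwoStepConfig, run_two_step
from .simulate import make_study_shaped_fixture, simulate_coloc_locus
from .summary_io import harmonize, instruments_to_frame, read_summary_table


@dataclass
class AnalysisConfig:
    """All thresholds, paths and seeds for one study run."""

    # inputs: either file paths ...
    exposure_path: str | None = None
    mediator_path: str | None = None
    outcome_path: str | None = None
    secondary_outcome_paths: dict = field(default_factory=dict)  # name -> path
    ld_path: str | None = None
    annotations_path: str | None = None
    # ... or a synthetic study
    synthetic: bool = True

    # thresholds
    exposure_p_threshold: float = 1e-4
    exposure_r2_threshold: float = 0.8
    mediator_p_threshold: float = 5e-8
    mediator_r2_threshold: float = 0.001
    f_min: float | None = 10.0
    blocked_traits: tuple = ("low-density lipoprotein", "coronary artery disease")

    # colocalization gate
    coloc_gate: bool = True
    coloc_gate_threshold: float = 0.70
    coloc_shared: bool = True  # synthetic locus: does it share the causal variant?

    # estimation
    ivw_model: str = "random"
    n_boot: int = 5000
    run_presso: bool = True
    presso_n_sim: int = 5000
    interval_method: str = "monte-carlo"
    n_draws: int = 100_000
    palindrome_policy: str = "infer"

    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "blocked_traits" in raw:
            raw["blocked_traits"] = tuple(raw["blocked_traits"])
        return cls(**raw)


@dataclass
class StudyReport:
    config: dict
    stages: dict = field(default_factory=dict)
    version: str = __version__

    def as_dict(self) -> dict:
        return {"version": self.version, "config": self.config, "stages": self.stages}

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, default=_jsonable)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    return str(obj)


def _sensitivity(instruments, *, ivw_model, run_presso, presso_n_sim, seed):
    out = {}
    q = cochran_q(instruments)
    out["cochran_q"] = {"Q": q.Q, "df": q.df, "pvalue": q.pvalue}
    if len(instruments) >= 3:
        eg = egger(instruments)
        out["egger_intercept"] = {
            "intercept": eg.intercept,
            "se": eg.intercept_se,
            "pvalue": eg.intercept_pvalue,
        }
        out["leave_one_out"] = [
            {"omitted": vid, **est.as_dict()} for vid, est in leave_one_out(instruments, ivw_model)
        ]
    if run_presso and len(instruments) >= 4:
        pr = mr_presso(instruments, n_sim=presso_n_sim, seed=seed)
        out["mr_presso"] = {
            "rss_observed": pr.rss_observed,
            "global_pvalue": pr.global_pvalue,
            "outlier_indices": list(pr.outlier_indices),
            "distortion_pvalue": pr.distortion_pvalue,
            "n_simulations": pr.n_simulations,
        }
    return out


def _load_table(path):
    records, dropped = read_summary_table(path)
    return records


def run_study(config: AnalysisConfig) -> StudyReport:
    """Execute the full design and return (and optionally write) the report.

    On a stage failure the report marks the stage failed with its cause and
    skips the stages that depend on it.
    """
    report = StudyReport(config=dataclasses.asdict(config))
    stages = report.stages

    # ---- inputs -----------------------------------------------------------
    if config.synthetic:
        study = make_study_shaped_fixture(seed=config.seed)
        exposure, mediator, outcome = (
            study.exposure_stats,
            study.mediator_stats,
            study.outcome_stats,
        )
        ld = study.ld
        annotations = {k: set(v) for k, v in study.truth["annotations"].items()}
        secondary = {}
        locus = simulate_coloc_locus(shared=config.coloc_shared, seed=config.seed + 1)
    else:
        exposure = _load_table(config.exposure_path)
        mediator = _load_table(config.mediator_path)
        outcome = _load_table(config.outcome_path)
        secondary = {
            name: _load_table(path) for name, path in config.secondary_outcome_paths.items()
        }
        ld = LDMatrix.from_tsv(config.ld_path) if config.ld_path else None
        annotations = (
            load_annotations(config.annotations_path) if config.annotations_path else None
        )
        locus = None

    # ---- colocalization gate ---------------------------------------------
    gate_open = True
    if config.coloc_gate and locus is not None:
        res = coloc_abf(*locus, gate=config.coloc_gate_threshold)
        stages["coloc"] = {**res.as_dict(), "status": "ok"}
        if not res.colocalized:
            gate_open = False
            stages["coloc"]["note"] = (
                "not colocalized: exposure locus fails the gate; instrument use halted"
            )
    if not gate_open:
        for name in ("instrument_selection", "mr", "mediation"):
            stages[name] = {"status": "skipped", "cause": "colocalization gate failed"}
        _write_report(report, config.out_dir)
        return report

    # ---- instrument selection --------------------------------------------
    try:
        cis_set = select_instruments(
            exposure,
            p_threshold=config.exposure_p_threshold,
            ld=ld,
            r2_threshold=config.exposure_r2_threshold,
            f_min=config.f_min,
        )
        med_set = select_instruments(
            mediator,
            p_threshold=config.mediator_p_threshold,
            ld=ld,
            r2_threshold=config.mediator_r2_threshold,
            f_min=config.f_min,
            annotations=annotations,
            blocked_traits=config.blocked_traits,
        )
        stages["instrument_selection"] = {
            "status": "ok",
            "exposure": cis_set.log_dict(),
            "mediator": med_set.log_dict(),
            "exposure_f": cis_set.f_statistics,
            "mediator_f": med_set.f_statistics,
        }
    except InputError as exc:
        stages["instrument_selection"] = {"status": "failed", "cause": str(exc)}
        for name in ("mr", "mediation"):
            stages[name] = {"status": "skipped", "cause": "instrument selection failed"}
        _write_report(report, config.out_dir)
        return report

    # ---- MR panels per outcome -------------------------------------------
    outcomes = {"primary": outcome, **secondary}
    mr_stage: dict = {"status": "ok", "outcomes": {}}
    for name, table in outcomes.items():
        try:
            harm = harmonize(
                cis_set.instruments, table, palindrome_policy=config.palindrome_policy
            )
            panel = estimator_panel(
                harm.instruments,
                ivw_model=config.ivw_model,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            mr_stage["outcomes"][name] = {
                "estimates": [e.as_dict() for e in panel],
                "sensitivity": _sensitivity(
                    harm.instruments,
                    ivw_model=config.ivw_model,
                    run_presso=config.run_presso,
                    presso_n_sim=config.presso_n_sim,
                    seed=config.seed,
                ),
                "wald_table": instruments_to_frame(harm.instruments).to_dict("records"),
                "n_instruments": len(harm.instruments),
            }
        except InputError as exc:
            mr_stage["outcomes"][name] = {"status": "failed", "cause": str(exc)}
    stages["mr"] = mr_stage

    # ---- mediation --------------------------------------------------------
    try:
        ts_cfg = TwoStepConfig(
            mediator_p_threshold=config.mediator_p_threshold,
            r2_threshold=config.mediator_r2_threshold,
            f_min=config.f_min,
            ld=ld,
            annotations=annotations,
            blocked_traits=config.blocked_traits,
            palindrome_policy=config.palindrome_policy,
            ivw_model=config.ivw_model,
            interval_method=config.interval_method,
            n_draws=config.n_draws,
            seed=config.seed,
        )
        med = run_two_step(cis_set.instruments, mediator, outcome, ts_cfg)
        stages["mediation"] = {
            "status": "ok",
            "table1": med.table1_row(),
            "total": med.total.as_dict(),
            "direct_a": med.direct_a.as_dict(),
            "direct_b": med.direct_b.as_dict(),
            "indirect": dataclasses.asdict(med.indirect),
            "proportion": dataclasses.asdict(med.proportion),
        }
    except InputError as exc:
        stages["mediation"] = {"status": "failed", "cause": str(exc)}

    _write_report(report, config.out_dir)
    return report


def _write_report(report: StudyReport, out_dir) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    mr = report.stages.get("mr", {})
    rows = []
    for name, res in mr.get("outcomes", {}).items():
        for est in res.get("estimates", []):
            rows.append({"outcome": name, **est})
    if rows:
        pd.DataFrame(rows).to_csv(out / "estimates.tsv", sep="\t", index=False)
    med = report.stages.get("mediation", {})
    if "table1" in med:
        pd.DataFrame([med["table1"]]).to_csv(out / "mediation.tsv", sep="\t", index=False)
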