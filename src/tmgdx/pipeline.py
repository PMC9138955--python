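"""End-to-end analysis: cohort → asymmetries → diagnostic report.

:func:`run_full_analysis` simulates or ingests a bilateral cohort, computes
per-subject asymmetry scores and, for each parameter (Tc, Td, Dm) and
stratum (combined, female, male), evaluates the asymmetry score as an
injury classifier: ROC (AUC ± SE, bootstrap CIs, Youden cut-off and its
operating point), precision–recall (AUPRC, F1max, PPV/TPR), a
female-vs-male ROC comparison, a Monte-Carlo Cramér's V association test
at the Youden cut-off, and a power table.  Every stochastic step is driven
by sub-seeds spawned from the configured seed, so a config + seed pair
fixes every number in the report.
"""

from __future__ import annotations

import fnmatch
import hashlib
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__, asymmetry, metrics
from .cohort import (
    PARAM_NAMES,
    CohortConfig,
    SubjectRecord,
    cohort_to_frame,
    read_cohort_csv,
    sample_cohort,
)
from .signal import load_signal, baseline_correct, extract_twitch_params, select_supramaximal

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_full_analysis",
    "extract_directory",
    "render_report",
]

logger = logging.getLogger(__name__)

STRATA = ("all", "F", "M")
POWER_EFFECT_SIZES = (0.2, 0.5, 0.8)


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one full analysis run.

    ``mode`` selects the cohort source: ``simulate`` draws from
    ``cohort_config``; ``csv`` reads ``cohort_path``.  ``bootstrap_B`` and
    ``mc_resamples`` size the stochastic steps; ``seed`` drives all of
    them.
    """

    mode: Literal["simulate", "csv"] = "simulate"
    cohort_config: CohortConfig = field(default_factory=CohortConfig)
    cohort_path: str | None = None
    bootstrap_B: int = 1000
    mc_resamples: int = 1000
    alpha: float = 0.05
    seed: int = 0
    se_method: str = "delong"
    plots: bool = False

    def __post_init__(self) -> None:
        if self.bootstrap_B < 200:
            raise ValueError("bootstrap_B must be >= 200")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.mode == "csv" and not self.cohort_path:
            raise ValueError("mode='csv' requires cohort_path")

    def canonical_dict(self) -> dict:
        d = {
            "mode": self.mode, "cohort_path": self.cohort_path,
            "bootstrap_B": self.bootstrap_B, "mc_resamples": self.mc_resamples,
            "alpha": self.alpha, "seed": self.seed, "se_method": self.se_method,
            "plots": self.plots,
        }
        cc = self.cohort_config
        d["cohort_config"] = {
            "n_injured": cc.n_injured, "n_noninjured": cc.n_noninjured,
            "n_female_injured": cc.n_female_injured,
            "n_female_noninjured": cc.n_female_noninjured,
            "rho": cc.rho, "p_injured_left": cc.p_injured_left, "seed": cc.seed,
            "noninjured": {s: {p: list(v.__dict__.values()) for p, v in cell.items()}
                           for s, cell in cc.noninjured.items()},
            "injured": {s: {p: list(v.__dict__.values()) for p, v in cell.items()}
                        for s, cell in cc.injured.items()},
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Structured result of :func:`run_full_analysis` (JSON-serialisable)."""

    descriptives: pd.DataFrame
    asymmetry_summary: pd.DataFrame
    roc: dict
    prc: dict
    roc_comparison_f_vs_m: dict
    association: dict
    power: list
    provenance: dict
    curves: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "descriptives": self.descriptives.to_dict(orient="records"),
            "asymmetry_summary": self.asymmetry_summary.to_dict(orient="records"),
            "roc": self.roc,
            "prc": self.prc,
            "roc_comparison_f_vs_m": self.roc_comparison_f_vs_m,
            "association": self.association,
            "power": self.power,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(_json_sanitize(self.to_dict()), sort_keys=True, indent=2,
                          allow_nan=False)


def _json_sanitize(obj):
    """Make a nested structure strict-JSON-safe (±inf → strings, NaN → null)."""
    if isinstance(obj, dict):
        return {k: _json_sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        if np.isnan(f):
            return None
        if np.isinf(f):
            return "inf" if f > 0 else "-inf"
        return f
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _stratum_frame(diffs: pd.DataFrame, stratum: str) -> pd.DataFrame:
    return diffs if stratum == "all" else diffs[diffs["sex"] == stratum]


def _descriptives(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD per (group, sex + pooled, leg orientation, parameter)."""
    rows = []
    for group, sub in frame.groupby("group", sort=True):
        oriented = group == "injured"
        for sex in ("all", "F", "M"):
            cell = sub if sex == "all" else sub[sub["sex"] == sex]
            if cell.empty:
                continue
            for param in PARAM_NAMES:
                if oriented:
                    left_inj = cell["injured_side"] == "L"
                    a = np.where(left_inj, cell[f"{param}_l"], cell[f"{param}_r"])
                    b = np.where(left_inj, cell[f"{param}_r"], cell[f"{param}_l"])
                    legs = (("injured_leg", a.astype(float)), ("contralateral", b.astype(float)))
                else:
                    legs = (("left", cell[f"{param}_l"].to_numpy(float)),
                            ("right", cell[f"{param}_r"].to_numpy(float)))
                for leg, vals in legs:
                    rows.append({
                        "group": group, "sex": sex, "leg": leg, "parameter": param,
                        "mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)),
                        "n": int(vals.size),
                    })
    return pd.DataFrame(rows)


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the complete diagnostic-accuracy pipeline under ``config``."""
    ss = np.random.SeedSequence(config.seed)
    seeds = iter(int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(64))

    logger.info("stage=cohort mode=%s", config.mode)
    if config.mode == "simulate":
        cohort = sample_cohort(config.cohort_config, seed=next(seeds))
    else:
        cohort = read_cohort_csv(config.cohort_path)
        if not cohort:
            raise ValueError(f"stage=cohort: empty cohort from {config.cohort_path}")
    frame = cohort_to_frame(cohort)
    logger.info("stage=cohort subjects=%d", len(cohort))

    diffs = asymmetry.cohort_asymmetries(cohort)
    summary = asymmetry.summarize_diffs(diffs)
    descriptives = _descriptives(frame)
    logger.info("stage=asymmetry rows=%d", len(diffs))

    roc_block: dict = {}
    prc_block: dict = {}
    curves: dict = {}
    for param in PARAM_NAMES:
        roc_block[param] = {}
        prc_block[param] = {}
        curves[param] = {}
        for stratum in STRATA:
            sub = _stratum_frame(diffs, stratum)
            scores = sub[f"diff_{param}"].to_numpy()
            labels = (sub["group"] == "injured").to_numpy()
            if labels.all() or not labels.any():
                warnings.warn(f"stratum {stratum!r} lacks a class; skipped", stacklevel=2)
                continue
            roc_res = metrics.evaluate_roc(
                scores, labels, se_method=config.se_method,
                bootstrap_B=config.bootstrap_B, seed=next(seeds),
            )
            prc_res = metrics.pr_curve(scores, labels)
            roc_block[param][stratum] = roc_res.to_dict()
            prc_block[param][stratum] = prc_res.to_dict()
            curves[param][stratum] = {"roc": roc_res, "prc": prc_res}
        # evaluate the combined cut-off inside each sex stratum as well
        combined_cut = roc_block[param]["all"]["cutoff"]
        for stratum in ("F", "M"):
            if stratum not in roc_block[param]:
                continue
            sub = _stratum_frame(diffs, stratum)
            scores = sub[f"diff_{param}"].to_numpy()
            labels = (sub["group"] == "injured").to_numpy()
            pred = scores > combined_cut
            sens = float(pred[labels].mean())
            spec = float((~pred[~labels]).mean())
            roc_block[param][stratum]["sens_at_combined_cutoff"] = sens
            roc_block[param][stratum]["spec_at_combined_cutoff"] = spec
            roc_block[param][stratum]["combined_cutoff"] = combined_cut
    logger.info("stage=roc blocks=%d", sum(len(v) for v in roc_block.values()))

    comparison: dict = {}
    for param in PARAM_NAMES:
        if "F" in roc_block[param] and "M" in roc_block[param]:
            f, m = roc_block[param]["F"], roc_block[param]["M"]
            diff, se, z, p = metrics.compare_independent_rocs(
                f["auc"], f["se_auc"], m["auc"], m["se_auc"]
            )
            comparison[param] = {"auc_f": f["auc"], "auc_m": m["auc"],
                                 "difference": diff, "se_diff": se, "z": z, "p": p}

    association: dict = {}
    for param in PARAM_NAMES:
        cut = roc_block[param]["all"]["cutoff"]
        scores = diffs[f"diff_{param}"].to_numpy()
        truth = (diffs["group"] == "injured").to_numpy().astype(int)
        pred = (scores > cut).astype(int)
        try:
            res = metrics.cramers_v_mc(pred, truth, n_resamples=config.mc_resamples,
                                       seed=next(seeds))
            association[param] = {**res.to_dict(), "cutoff": cut,
                                  "construction": "dichotomised at Youden cut-off vs injury status"}
        except ValueError as exc:
            association[param] = {"error": str(exc), "cutoff": cut}
    logger.info("stage=association params=%d", len(association))

    n_power = min(config.cohort_config.n_injured, config.cohort_config.n_noninjured) \
        if config.mode == "simulate" else min(
            int((diffs["group"] == "injured").sum()),
            int((diffs["group"] == "non_injured").sum()))
    power = [
        {"d": d, "n_per_group": n_power, "alpha": config.alpha,
         "power": metrics.two_sample_t_power(d, n_power, config.alpha)}
        for d in POWER_EFFECT_SIZES
    ]

    provenance = {
        "package": "tmgdx",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "bootstrap_B": config.bootstrap_B,
        "mc_resamples": config.mc_resamples,
        "se_method": config.se_method,
        "n_subjects": len(cohort),
    }
    return AnalysisReport(
        descriptives=descriptives, asymmetry_summary=summary,
        roc=roc_block, prc=prc_block, roc_comparison_f_vs_m=comparison,
        association=association, power=power, provenance=provenance,
        curves=curves,
    )


_FNAME_RE = re.compile(
    r"^(?P<subject>.+?)_(?P<side>[LR])(?:_(?P<current>\d+(?:\.\d+)?)\s*(?:mA)?)?$",
    re.IGNORECASE,
)


def extract_directory(
    path: str | Path,
    pattern: str = "*.txt",
    baseline_window: float = 0.0,
    **extract_kwargs,
) -> pd.DataFrame:
    """Extract twitch parameters from a directory of waveform files.

    Filenames follow ``<subject>_<side>[_<current mA>]`` with side L or R;
    several currents for one (subject, side) form a stimulation ramp from
    which the supramaximal response is selected.  Subjects missing a side
    are excluded with a warning.  Returns a frame with columns
    ``subject_id, side, td, tc, dm, n_ramp, plateau_reached``.
    """
    path = Path(path)
    groups: dict[tuple[str, str], list[tuple[float, Path]]] = {}
    for f in sorted(path.iterdir()):
        if not f.is_file() or not fnmatch.fnmatch(f.name, pattern):
            continue
        m = _FNAME_RE.match(f.stem)
        if not m:
            warnings.warn(f"{f.name}: unrecognised filename; skipped", stacklevel=2)
            continue
        current = float(m.group("current")) if m.group("current") else 0.0
        groups.setdefault((m.group("subject"), m.group("side").upper()), []).append(
            (current, f))
    rows = []
    for (subject, side), entries in sorted(groups.items()):
        entries.sort(key=lambda e: e[0])
        signals = [(c, baseline_correct(load_signal(f), baseline_window))
                   for c, f in entries]
        if len(signals) > 1:
            res = select_supramaximal(signals, **extract_kwargs)
            params, n_ramp, plateau = res.params, len(signals), res.plateau_reached
        else:
            params = extract_twitch_params(signals[0][1], **extract_kwargs)
            n_ramp, plateau = 1, True
        rows.append({"subject_id": subject, "side": side, "td": params.td,
                     "tc": params.tc, "dm": params.dm, "n_ramp": n_ramp,
                     "plateau_reached": plateau})
    frame = pd.DataFrame(rows, columns=["subject_id", "side", "td", "tc", "dm",
                                        "n_ramp", "plateau_reached"])
    if not frame.empty:
        counts = frame.groupby("subject_id")["side"].nunique()
        incomplete = counts[counts < 2].index.tolist()
        if incomplete:
            warnings.warn(f"subjects missing a side excluded: {incomplete}", stacklevel=2)
            frame = frame[~frame["subject_id"].isin(incomplete)].reset_index(drop=True)
    return frame


def render_report(
    report: AnalysisReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("json", "csv"),
    plots: bool = False,
) -> list[Path]:
    """Write a report to disk as canonical JSON and/or CSV tables.

    With ``plots=True`` ROC and PRC curve figures are written as well
    (requires matplotlib).  Returns the written paths.
    """
    out_dir = Path(out_dir)
    payload = report.to_json()  # serialise before creating anything
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        p = out_dir / "report.json"
        p.write_text(payload, encoding="utf-8")
        written.append(p)
    if "csv" in formats:
        report.descriptives.to_csv(out_dir / "descriptives.csv", index=False)
        report.asymmetry_summary.to_csv(out_dir / "asymmetry_summary.csv", index=False)
        written += [out_dir / "descriptives.csv", out_dir / "asymmetry_summary.csv"]
        roc_rows = []
        for param, strata in report.roc.items():
            for stratum, block in strata.items():
                roc_rows.append({"parameter": param, "stratum": stratum,
                                 **{k: v for k, v in block.items()
                                    if not isinstance(v, (list, dict)) or k.endswith("ci95")}})
        pd.json_normalize(roc_rows).to_csv(out_dir / "roc_summary.csv", index=False)
        written.append(out_dir / "roc_summary.csv")
        prc_rows = [{"parameter": p, "stratum": s, **blk}
                    for p, strata in report.prc.items() for s, blk in strata.items()]
        pd.DataFrame(prc_rows).to_csv(out_dir / "prc_summary.csv", index=False)
        written.append(out_dir / "prc_summary.csv")
    if plots and report.curves:
        written += _plot_curves(report, out_dir)
    logger.info("stage=render files=%d dir=%s", len(written), out_dir)
    return written


def _plot_curves(report: AnalysisReport, out_dir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for kind in ("roc", "prc"):
        fig, ax = plt.subplots(figsize=(5, 5))
        for param, strata in report.curves.items():
            block = strata.get("all")
            if block is None:
                continue
            if kind == "roc":
                r = block["roc"]
                ax.plot(1 - r.spec, r.sens, label=f"{param} (AUC {r.auc:.3f})")
            else:
                r = block["prc"]
                ax.plot(r.recall, r.precision, label=f"{param} (AP {r.auprc:.3f})")
        if kind == "roc":
            ax.plot([0, 1], [0, 1], "k--", lw=0.8)
            ax.set_xlabel("1 − specificity")
            ax.set_ylabel("sensitivity")
        else:
            ax.set_xlabel("recall")
            ax.set_ylabel("precision")
        ax.legend()
        fig.tight_layout()
        p = out_dir / f"{kind}_curves.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
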