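"""End-to-end pipeline and report rendering.

``run_pipeline`` chains simulate → engine replay → feature building →
the five outcome-model fits into one reproducible artifact set (event
log, analysis tables, model JSONs, a Markdown report and a run
manifest).  Re-running with the same config and seed is byte-identical
except for the wall-clock metadata in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, load_config
from .events import write_jsonl
from .features import build_model_tables, write_tables
from .models import OutcomeLogit
from .simulate import replay_decisions, run_deployment
from .specs import ALL_SPECS

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StressSummary:
    """Mean and normal-approximation 95% CI of the momentary stress
    ratings at nudge time, pre-intervention and post-intervention."""

    at_nudge: Optional[tuple[float, float, float]]  # (mean, lo, hi)
    pre: Optional[tuple[float, float, float]]
    post: Optional[tuple[float, float, float]]
    ratings: dict[str, list[int]]  # raw vectors, density-plot ready

    def to_dict(self) -> dict:
        def tup(t):
            return None if t is None else {"mean": t[0], "ci_lower": t[1], "ci_upper": t[2]}

        return {"at_nudge": tup(self.at_nudge), "pre": tup(self.pre), "post": tup(self.post)}


def _mean_ci(values) -> Optional[tuple[float, float, float]]:
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if x.size == 0:
        return None
    m = float(x.mean())
    half = 1.959963984540054 * float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return (m, m - half, m + half)


def summarize_stress(completed: pd.DataFrame, per_nudge: pd.DataFrame) -> StressSummary:
    """Fig-2-style comparison of momentary stress ratings."""
    if completed.empty:
        warnings.warn("completed table is empty; stress summary is empty")
        return StressSummary(None, None, None, {})
    at_nudge = _mean_ci(per_nudge.get("ema_at_nudge"))
    pre = _mean_ci(completed["stress_before"])
    post = _mean_ci(completed["stress_after"])
    ratings = {
        "at_nudge": [int(v) for v in pd.Series(per_nudge.get("ema_at_nudge")).dropna()],
        "pre": [int(v) for v in completed["stress_before"].dropna()],
        "post": [int(v) for v in completed["stress_after"].dropna()],
    }
    return StressSummary(at_nudge, pre, post, ratings)


def descriptives(per_nudge: pd.DataFrame, completed: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style descriptive statistics of the analysis variables."""
    rows = []
    per_participant = per_nudge.drop_duplicates("participant_id")
    for name in ("cognitive_reappraisal", "expressive_suppression", "resilience",
                 "agreeableness", "conscientiousness", "extraversion",
                 "neuroticism", "openness", "engagement_skewness"):
        x = per_participant[name]
        rows.append({"variable": name, "level": "per-participant",
                     "mean": x.mean(), "sd": x.std(ddof=1)})
    rows.append({"variable": "nudge_probability", "level": "per-half-hour",
                 "mean": per_nudge["nudge_probability"].mean() / 100.0,
                 "sd": per_nudge["nudge_probability"].std(ddof=1) / 100.0})
    for name in ("meeting_counts", "no_meeting_minutes", "self_event_counts",
                 "email_messages_sent", "email_messages_read",
                 "chat_messages_count", "ad_hoc_call_count"):
        x = per_nudge[name]
        rows.append({"variable": name, "level": "per-nudge",
                     "mean": x.mean(), "sd": x.std(ddof=1)})
    rows.append({"variable": "number_of_attention_signals", "level": "per-nudge",
                 "mean": per_nudge["attention_signals"].mean() * 2000,
                 "sd": per_nudge["attention_signals"].std(ddof=1) * 2000})
    if not completed.empty:
        for name in ("stress_reduction", "rating", "stress_before"):
            x = completed[name].astype(float)
            rows.append({"variable": name, "level": "per-intervention",
                         "mean": x.mean(), "sd": x.std(ddof=1)})
    return pd.DataFrame(rows)


def run_pipeline(
    config: SimulationConfig | str | None = None,
    seed: int = 0,
    outdir: str | Path = "pipeline_out",
) -> dict:
    """Run simulate → replay → features → fits and write the artifact set.

    Returns the manifest dict.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(config, (str, Path)):
        cfg = load_config(str(config))
    else:
        cfg = config or SimulationConfig()

    def stage(name, fn):
        try:
            logger.info("[%s] starting", name)
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    def _simulate():
        cfg.validate()
        return run_deployment(seed=seed, config=cfg)

    events = stage("simulate", _simulate)
    stage("simulate", lambda: write_jsonl(events, outdir / "log.jsonl"))

    def _replay():
        decisions = replay_decisions(events, cfg)
        blocked = [d for d in decisions if not d.send]
        if blocked:
            raise RuntimeError(f"{len(blocked)} logged nudges fail gate replay")
        return len(decisions)

    n_nudges = stage("run-engine", _replay)

    tables = stage("build-features", lambda: build_model_tables(events))
    stage("build-features", lambda: write_tables(tables, outdir / "tables"))
    per_nudge, chosen, completed = tables

    def _fit():
        results = {}
        scoped = {"per_nudge": per_nudge, "chosen": chosen, "completed": completed}
        for spec in ALL_SPECS:
            try:
                res = OutcomeLogit(scoped[spec.scope], spec).fit()
                results[spec.name] = res
                res.to_json(outdir / f"model_{spec.name}.json")
            except Exception as exc:  # noqa: BLE001 - a model that cannot be
                # fitted on this run (separation, absent reference level on a
                # tiny cohort, ...) is reported in the bundle, not fatal
                logger.warning("model %s not fitted: %s", spec.name, exc)
                with open(outdir / f"model_{spec.name}.json", "w") as fh:
                    json.dump({"name": spec.name, "error": str(exc)}, fh)
                results[spec.name] = None
        return results

    results = stage("fit", _fit)

    def _report():
        summary = summarize_stress(completed, per_nudge)
        desc = descriptives(per_nudge, completed)
        desc.to_csv(outdir / "descriptives.csv", index=False)
        render_report(outdir / "report.md", cfg, n_nudges, tables, results, summary, desc)
        return summary

    stage("report", _report)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(repr(cfg).encode()).hexdigest(),
        "n_events": len(events),
        "n_nudges": int(n_nudges),
        "outputs": sorted(p.name for p in outdir.iterdir()),
        "wall_clock": datetime.now().isoformat(timespec="seconds"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


_CHOICE_GROUP = ("distract_chosen", "calm_chosen", "address_chosen")


def render_report(path, cfg, n_nudges, tables, results, summary, desc) -> None:
    per_nudge, chosen, completed = tables
    lines = [
        "# Deployment analysis report",
        "",
        f"Simulated cohort: {cfg.cohort.n_participants} participants, "
        f"{cfg.weeks} weeks. Nudges: {len(per_nudge)} "
        f"(engaged: {int(per_nudge['engaged'].sum())}); chosen: {len(chosen)}; "
        f"completed: {len(completed)}.",
        "",
        "## Descriptive statistics",
        "",
        "```",
        desc.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
        "```",
        "",
        "## Momentary stress ratings",
        "",
    ]
    for label, tup in (("at nudge", summary.at_nudge), ("pre-intervention", summary.pre),
                       ("post-intervention", summary.post)):
        if tup:
            lines.append(f"- {label}: mean {tup[0]:.2f} (95% CI {tup[1]:.2f}-{tup[2]:.2f})")
    lines.append("")

    def or_section(title, names):
        out = [f"## {title}", ""]
        frames = []
        for name in names:
            res = results.get(name)
            if res is None:
                out.append(f"_Model {name} could not be fitted on this run._")
                continue
            t = res.or_table()[["OR", "or_lower", "or_upper", "p", "bh_significant"]]
            t.columns = pd.MultiIndex.from_product([[name], t.columns])
            frames.append(t)
        if frames:
            merged = pd.concat(frames, axis=1)
            out += ["```",
                    merged.to_string(float_format=lambda v: f"{v:.2f}"),
                    "```"]
        out.append("")
        return out

    lines += or_section("Engagement (all nudges)", ["engaged"])
    lines += or_section("Category choice (chosen nudges)", list(_CHOICE_GROUP))
    lines += or_section("Engagement after choice", ["engaged_after_chosen"])
    lines += or_section("Intervention rating (liked)", ["liked"])
    lines += or_section("Stress improvement", ["improved"])

    Path(path).write_text("\n".join(lines))
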