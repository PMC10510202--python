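"""End-to-end analysis: descriptives, the twelve ANOVAs, post hocs,
percent differences, the +/- 2 SD audit, and four stability analyses.

The analysis program mirrors a group-level dosimetry comparison: for each
of the four protocols, (1) an omnibus ANOVA of the individual cohort
against two singleton template heads, (2) a five-group diagnosis ANOVA
with Tukey-Kramer post hocs, (3) a sex ANOVA (men, women, two templates),
then template-vs-cohort percent differences, an outlier audit at +/- 2 SD,
and a permutation point-of-stability analysis per protocol.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Diagnosis, Protocol, Sex, SubjectRecord
from .group_stats import (
    AnovaResult,
    GroupSummary,
    PairwiseComparison,
    anova_from_raw,
    anova_from_summaries,
    outliers_beyond_k_sd,
    percent_difference,
    tukey_kramer,
)
from .stability import StabilityConfig, StabilityResult, point_of_stability

__all__ = ["AnalysisReport", "run_full_analysis", "plot_group_means", "plot_stability"]

_TEMPLATE_AMBIGUITY_NOTE = (
    "Note: the two motor-TMS template values are attributed to the templates "
    "inconsistently across source tabulations; the omnibus F statistic is "
    "invariant under exchanging them, but percent differences are not."
)
_MULTIPLICITY_NOTE = (
    "No multiple-testing correction is applied across the twelve ANOVAs; "
    "each is reported at the nominal alpha."
)


@dataclass
class AnalysisReport:
    """Everything the pipeline computes, plus provenance to re-run it."""

    descriptives: pd.DataFrame
    omnibus: dict[Protocol, AnovaResult]
    diagnosis: dict[Protocol, AnovaResult]
    posthoc: dict[Protocol, list[PairwiseComparison]]
    sex: dict[Protocol, AnovaResult]
    percent_diffs: dict[str, dict[Protocol, float]]
    outlier_audit: dict[Protocol, tuple[int, list[str]]]
    stability: dict[Protocol, StabilityResult]
    conclusion: str
    alpha: float
    provenance: dict
    notes: list[str] = field(default_factory=list)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def anova_dict(a: AnovaResult) -> dict:
            return {
                "F": a.f_stat,
                "df_between": a.df_between,
                "df_within": a.df_within,
                "p": a.p_value,
                "eta_p2": a.eta_p2,
                "ss_between": a.ss_between,
                "ss_within": a.ss_within,
            }

        return {
            "descriptives": self.descriptives.to_dict(orient="records"),
            "omnibus": {p.value: anova_dict(a) for p, a in self.omnibus.items()},
            "diagnosis": {p.value: anova_dict(a) for p, a in self.diagnosis.items()},
            "posthoc": {
                p.value: [
                    {
                        "group_a": c.group_a,
                        "group_b": c.group_b,
                        "diff": c.diff,
                        "q": c.q_stat,
                        "p_adj": c.p_adj,
                        "significant": c.significant,
                    }
                    for c in comps
                ]
                for p, comps in self.posthoc.items()
            },
            "sex": {p.value: anova_dict(a) for p, a in self.sex.items()},
            "percent_diffs": {
                t: {p.value: v for p, v in d.items()} for t, d in self.percent_diffs.items()
            },
            "outlier_audit": {
                p.value: {"count": c, "subjects": labels}
                for p, (c, labels) in self.outlier_audit.items()
            },
            "stability": {
                p.value: {
                    "corridor": list(r.corridor),
                    "pos": r.pos,
                    "reached": r.reached,
                    "corridor_method": r.config.corridor_method,
                    "criterion": r.config.criterion,
                    "reps_per_size": r.config.reps_per_size,
                    "seed": r.config.seed,
                    "percentile_definition": r.percentile_definition,
                }
                for p, r in self.stability.items()
            },
            "conclusion": self.conclusion,
            "alpha": self.alpha,
            "notes": self.notes,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonable)

    # -- rendering ---------------------------------------------------------

    def render_text(self) -> str:
        """Human-readable report at conventional printed precision
        (F to 2 decimals, eta_p2 to 3, TMS V/m to 2, tES V/m to 3)."""
        lines: list[str] = []
        lines.append("Group-level E-field analysis report")
        lines.append("=" * 60)
        lines.append("")
        lines.append("Descriptives (mean (SD), V/m)")
        lines.append("-" * 60)
        table = self.descriptives.copy()
        for _, row in table.iterrows():
            proto = Protocol(row["protocol"])
            dp = 2 if proto.is_tms else 3
            sd = "" if row["n"] == 1 else f" ({row['sd']:.{dp}f})"
            lines.append(
                f"  {row['population']:<18} {proto.value:<16} n={int(row['n']):>4} "
                f"{row['mean']:.{dp}f}{sd}"
            )
        for title, block in (
            ("Omnibus ANOVAs (individuals vs. two templates)", self.omnibus),
            ("Diagnosis ANOVAs", self.diagnosis),
            ("Sex ANOVAs (men, women, two templates)", self.sex),
        ):
            lines.append("")
            lines.append(title)
            lines.append("-" * 60)
            for proto, a in block.items():
                lines.append(
                    f"  {proto.value:<16} F({a.df_between}, {a.df_within}) = "
                    f"{a.f_stat:.2f}, p = {a.p_value:.2f}, eta_p2 = {a.eta_p2:.3f}"
                )
        lines.append("")
        lines.append("Tukey-Kramer post hocs (diagnosis factor)")
        lines.append("-" * 60)
        for proto, comps in self.posthoc.items():
            sig = [c for c in comps if c.significant]
            if sig:
                for c in sig:
                    lines.append(
                        f"  {proto.value:<16} {c.group_a} vs {c.group_b}: "
                        f"diff = {c.diff:+.2f}, p_adj = {c.p_adj:.3f} *"
                    )
            else:
                lines.append(f"  {proto.value:<16} no significant pairs")
        lines.append("")
        lines.append("Template percent differences (positive = template lower)")
        lines.append("-" * 60)
        for template, diffs in self.percent_diffs.items():
            for proto, v in diffs.items():
                lines.append(f"  {template:<10} {proto.value:<16} {v:+.1f}%")
        lines.append("")
        lines.append("Outlier audit (|value - mean| > 2 SD)")
        lines.append("-" * 60)
        for proto, (count, _) in self.outlier_audit.items():
            lines.append(f"  {proto.value:<16} {count} subjects")
        lines.append("")
        lines.append("Point of stability")
        lines.append("-" * 60)
        for proto, r in self.stability.items():
            dp = 2 if Protocol(proto).is_tms else 3
            pos = str(r.pos) if r.reached else "not reached"
            lines.append(
                f"  {proto.value:<16} corridor [{r.corridor[0]:.{dp}f}, "
                f"{r.corridor[1]:.{dp}f}] ({r.config.corridor_method}), POS = {pos}"
            )
        lines.append("")
        lines.append(f"Conclusion: {self.conclusion}")
        for note in self.notes:
            lines.append(f"Note: {note}")
        lines.append("")
        lines.append(
            f"Provenance: efieldstats {self.provenance.get('version')}, "
            f"seed = {self.provenance.get('seed')}, alpha = {self.alpha}"
        )
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _efield_vector(records: Sequence[SubjectRecord], protocol: Protocol) -> np.ndarray:
    return np.array([r.efield[protocol] for r in records], dtype=float)


def run_full_analysis(
    records: Sequence[SubjectRecord],
    templates: Mapping[str, Mapping[Protocol, float]],
    alpha: float = 0.05,
    stability_config: StabilityConfig | None = None,
    seed: int = 0,
) -> AnalysisReport:
    """Run the full analysis program on a cohort.

    ``templates`` must provide a value for every template x protocol.
    ``seed`` controls the stability permutations (one derived stream per
    protocol x size); all other stages are deterministic in the data.
    """
    if not records:
        raise ValueError("empty cohort")
    if not templates:
        raise ValueError("at least one template head is required")
    for name, tvals in templates.items():
        for proto in Protocol:
            if proto not in tvals:
                raise ValueError(f"template {name!r} missing value for {proto.value}")
    if stability_config is None:
        stability_config = StabilityConfig()

    diagnoses = [d for d in Diagnosis if any(r.diagnosis == d for r in records)]

    # descriptives: templates, pooled cohort, per diagnosis, per sex
    rows = []
    for proto in Protocol:
        vals = _efield_vector(records, proto)
        for name, tvals in templates.items():
            rows.append((name, proto.value, 1, tvals[proto], 0.0))
        rows.append(("individual", proto.value, len(records), vals.mean(), vals.std(ddof=1)))
        for d in diagnoses:
            sub = np.array([r.efield[proto] for r in records if r.diagnosis == d])
            sd = sub.std(ddof=1) if sub.size > 1 else 0.0
            rows.append((d.value, proto.value, sub.size, sub.mean(), sd))
        for s in Sex:
            sub = np.array([r.efield[proto] for r in records if r.sex == s])
            if sub.size:
                sd = sub.std(ddof=1) if sub.size > 1 else 0.0
                rows.append((s.value, proto.value, sub.size, sub.mean(), sd))
    descriptives = pd.DataFrame(
        rows, columns=["population", "protocol", "n", "mean", "sd"]
    )

    omnibus: dict[Protocol, AnovaResult] = {}
    diagnosis_anovas: dict[Protocol, AnovaResult] = {}
    posthoc: dict[Protocol, list[PairwiseComparison]] = {}
    sex_anovas: dict[Protocol, AnovaResult] = {}
    percent_diffs: dict[str, dict[Protocol, float]] = {name: {} for name in templates}
    outlier_audit: dict[Protocol, tuple[int, list[str]]] = {}
    stability: dict[Protocol, StabilityResult] = {}

    ids = [r.id for r in records]
    for j, proto in enumerate(Protocol):
        vals = _efield_vector(records, proto)
        template_groups = [
            GroupSummary(label=name, n=1, mean=tvals[proto], sd=0.0)
            for name, tvals in templates.items()
        ]

        omnibus[proto] = anova_from_summaries(
            [GroupSummary.from_values("individual", vals)] + template_groups
        )

        by_diag = {
            d.value: [r.efield[proto] for r in records if r.diagnosis == d]
            for d in diagnoses
        }
        if len(by_diag) >= 2:
            diagnosis_anovas[proto] = anova_from_raw(by_diag)
            posthoc[proto] = tukey_kramer(
                [GroupSummary.from_values(lbl, v) for lbl, v in by_diag.items()],
                alpha=alpha,
            )

        by_sex = {
            s.value: [r.efield[proto] for r in records if r.sex == s] for s in Sex
        }
        sex_groups = [
            GroupSummary.from_values(lbl, v) for lbl, v in by_sex.items() if v
        ] + template_groups
        sex_anovas[proto] = anova_from_summaries(sex_groups)

        for name, tvals in templates.items():
            percent_diffs[name][proto] = percent_difference(tvals[proto], float(vals.mean()))

        outlier_audit[proto] = outliers_beyond_k_sd(vals, k=2.0, labels=ids)

        proto_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(1000 + j,)).generate_state(1)[0]
            % 2**31
        )
        stability[proto] = point_of_stability(
            vals, replace(stability_config, seed=proto_seed)
        )

    all_ns = all(a.p_value >= alpha for a in omnibus.values())
    conclusion = (
        "no significant difference between individual and template group-level E-fields"
        if all_ns
        else "significant difference detected between individual and template group-level E-fields"
    )

    report = AnalysisReport(
        descriptives=descriptives,
        omnibus=omnibus,
        diagnosis=diagnosis_anovas,
        posthoc=posthoc,
        sex=sex_anovas,
        percent_diffs=percent_diffs,
        outlier_audit=outlier_audit,
        stability=stability,
        conclusion=conclusion,
        alpha=alpha,
        provenance={
            "version": __version__,
            "seed": seed,
            "n_subjects": len(records),
            "templates": sorted(templates),
            "stability_config": {
                "reps_per_size": stability_config.reps_per_size,
                "sampling": stability_config.sampling,
                "corridor_method": stability_config.corridor_method,
                "corridor_percentiles": list(stability_config.corridor_percentiles),
                "relative_width": stability_config.relative_width,
                "criterion": stability_config.criterion,
                "band_percentiles": list(stability_config.band_percentiles),
            },
        },
        notes=[_TEMPLATE_AMBIGUITY_NOTE, _MULTIPLICITY_NOTE],
    )
    return report


# ---------------------------------------------------------------------------
# plots


def plot_group_means(report: AnalysisReport, path: str | Path) -> None:
    """Bar chart of group means +/- SD per protocol (template singletons
    shown without error bars)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(16, 4))
    pops = ["MNI-152", "Ernie", "individual"]
    for ax, proto in zip(axes, Protocol):
        sub = report.descriptives[report.descriptives["protocol"] == proto.value]
        sub = sub[sub["population"].isin(pops)].set_index("population").reindex(pops).dropna()
        ax.bar(sub.index, sub["mean"], yerr=sub["sd"], capsize=4, color="#88aacc")
        ax.set_title(proto.value)
        ax.set_ylabel("E-field magnitude (V/m)")
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_stability(result: StabilityResult, path: str | Path, title: str = "") -> None:
    """Subsample-mean band vs. size with the corridor and the POS line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    t = result.table
    ax.fill_between(t["size"], t["band_lo"], t["band_hi"], alpha=0.4, label="subsample-mean band")
    ax.plot(t["size"], t["mean_of_means"], lw=1.0, label="mean of subsample means")
    for y in result.corridor:
        ax.axhline(y, color="k", ls="--", lw=0.8)
    if result.reached:
        ax.axvline(result.pos, color="r", lw=1.2, label=f"POS = {result.pos}")
    ax.set_xlabel("subsample size")
    ax.set_ylabel("E-field magnitude (V/m)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
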