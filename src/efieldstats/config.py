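"""Configuration loading: cohort parameters and analysis defaults.

The packaged default configuration describes a transdiagnostic cohort of
195 participants in five diagnostic groups with two template-head singleton
observations per protocol; see ``data/default_cohort.yaml``.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .cohort import CohortParams, Diagnosis, Protocol, Sex
from .group_stats import GroupSummary

__all__ = [
    "CohortConfig",
    "load_config",
    "load_default_config",
    "default_config_path",
]


@dataclass
class CohortConfig:
    """Parsed configuration bundle.

    ``params`` drives cohort generation; ``transdiagnostic`` holds the
    pooled per-protocol (n, mean, sd) sufficient statistics of the cohort,
    used by summary-statistic analyses that never touch subject data.
    """

    params: CohortParams
    transdiagnostic: dict[Protocol, GroupSummary]

    def template_summaries(self, protocol: Protocol) -> list[GroupSummary]:
        """Singleton template observations for one protocol."""
        return [
            GroupSummary(label=name, n=1, mean=vals[protocol], sd=0.0)
            for name, vals in self.params.templates.items()
        ]


def _parse(doc: dict) -> CohortConfig:
    cell_moments = {
        Diagnosis(d): {Protocol(p): (float(m["mean"]), float(m["sd"])) for p, m in cells.items()}
        for d, cells in doc["cell_moments"].items()
    }
    templates = {
        name: {Protocol(p): float(v) for p, v in vals.items()}
        for name, vals in doc.get("templates", {}).items()
    }
    rmt = doc.get("rmt", {})
    params = CohortParams(
        cell_moments=cell_moments,
        group_sizes={Diagnosis(d): int(n) for d, n in doc["group_sizes"].items()},
        sex_counts={Sex(s): int(n) for s, n in doc["sex_counts"].items()},
        rmt_mean=float(rmt.get("mean_pct", 50.46)),
        rmt_sd=float(rmt.get("sd_pct", 8.91)),
        rmt_bounds=tuple(float(x) for x in rmt.get("bounds_pct", (31.0, 78.0))),
        rmt_multiplier=float(rmt.get("treatment_multiplier", 1.2)),
        max_didt=float(rmt.get("max_didt_As", 1.5e8)),
        tes_current_mA=float(doc.get("tes_current_mA", 2.0)),
        templates=templates,
        latent_loading=float(doc.get("latent_loading", 0.5)),
        mode=str(doc.get("mode", "direct")),
        seed=int(doc.get("seed", 0)),
    )
    params.validate()
    transdiagnostic = {
        Protocol(p): GroupSummary(
            label="individual", n=int(m["n"]), mean=float(m["mean"]), sd=float(m["sd"])
        )
        for p, m in doc.get("transdiagnostic_moments", {}).items()
    }
    return CohortConfig(params=params, transdiagnostic=transdiagnostic)


def load_config(path: str | Path) -> CohortConfig:
    """Load a cohort configuration from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        return _parse(yaml.safe_load(fh))


def default_config_path() -> Path:
    return Path(str(resources.files("efieldstats").joinpath("data/default_cohort.yaml")))


def load_default_config() -> CohortConfig:
    """Load the packaged default cohort configuration."""
    text = resources.files("efieldstats").joinpath("data/default_cohort.yaml").read_text()
    return _parse(yaml.safe_load(text))
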