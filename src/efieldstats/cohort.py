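"""Synthetic transdiagnostic stimulation cohorts.

Generates subject-level records for a non-invasive brain stimulation
dosimetry cohort: five diagnostic groups, individualized TMS dosing from
resting motor threshold (rMT), fixed-dose tES, and per-protocol
region-of-interest E-field magnitudes drawn to match configured
per-(diagnosis, protocol) means and standard deviations.

Two generation modes are provided.  ``direct`` draws each E-field value
from a normal distribution with the cell moments, truncated at zero.
``mechanistic`` composes a per-subject anatomical gain (V/m per unit dose,
lognormal) with the subject's dose — dI/dt at 120% rMT for TMS, a fixed
2 mA current for tES — with the gain distribution moment-matched so the
marginal cell moments are recovered.  In both modes a single shared latent
factor induces positive correlation between a subject's four protocols.
"""
from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "Protocol",
    "Diagnosis",
    "Sex",
    "SubjectRecord",
    "CohortParams",
    "CalibrationError",
    "CohortParseError",
    "rmt_to_didt",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "cohort_to_frame",
    "TMS_PROTOCOLS",
    "TES_PROTOCOLS",
    "COHORT_COLUMNS",
]


class Protocol(str, enum.Enum):
    """The four simulated stimulation protocols (site x modality)."""

    motor_TMS = "motor_TMS"
    prefrontal_TMS = "prefrontal_TMS"
    motor_tES = "motor_tES"
    prefrontal_tES = "prefrontal_tES"

    @property
    def is_tms(self) -> bool:
        return self in TMS_PROTOCOLS


TMS_PROTOCOLS: tuple[Protocol, ...] = (Protocol.motor_TMS, Protocol.prefrontal_TMS)
TES_PROTOCOLS: tuple[Protocol, ...] = (Protocol.motor_tES, Protocol.prefrontal_tES)


class Diagnosis(str, enum.Enum):
    healthy = "healthy"
    alcohol_use = "alcohol_use"
    tobacco_use = "tobacco_use"
    anxiety = "anxiety"
    depression = "depression"


#: Default diagnostic group sizes (sum to 195).
DEFAULT_GROUP_SIZES: dict[Diagnosis, int] = {
    Diagnosis.healthy: 31,
    Diagnosis.alcohol_use: 87,
    Diagnosis.tobacco_use: 31,
    Diagnosis.anxiety: 25,
    Diagnosis.depression: 21,
}


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class CalibrationError(ValueError):
    """Requested cell moments cannot be matched in mechanistic mode."""


class CohortParseError(ValueError):
    """A cohort file row failed validation; the message names the line."""


COHORT_COLUMNS = (
    "subject_id",
    "diagnosis",
    "sex",
    "rmt_pct",
    "stim_pct",
    "didt_As",
    "efield_motor_TMS",
    "efield_prefrontal_TMS",
    "efield_motor_tES",
    "efield_prefrontal_tES",
)


def rmt_to_didt(rmt_pct: float, multiplier: float = 1.2, max_didt: float = 1.5e8) -> float:
    """Convert a resting motor threshold to the delivered coil dI/dt.

    The stimulator output is ``multiplier x rmt_pct`` percent of maximum,
    capped at 100%, and the coil dI/dt scales linearly with output up to
    ``max_didt`` (A/s at 100% output).  E.g. 50% output on a machine with
    a 150e6 A/s maximum delivers 75e6 A/s.
    """
    if rmt_pct <= 0 or rmt_pct > 100:
        raise ValueError(f"rmt_pct must be in (0, 100], got {rmt_pct}")
    if multiplier <= 0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    if max_didt <= 0:
        raise ValueError(f"max_didt must be positive, got {max_didt}")
    stim_pct = min(multiplier * rmt_pct, 100.0)
    return stim_pct / 100.0 * max_didt


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: diagnosis, sex, TMS dosing, per-protocol E-fields."""

    id: str
    diagnosis: Diagnosis
    sex: Sex
    rmt_pct: float
    stim_pct: float
    didt: float  # A/s at treatment intensity
    efield: Mapping[Protocol, float]  # V/m

    def __post_init__(self) -> None:
        for proto, value in self.efield.items():
            if value <= 0:
                raise ValueError(f"E-field for {proto.value} must be positive, got {value}")


@dataclass
class CohortParams:
    """Full parameterization of a synthetic cohort.

    ``cell_moments[d][p]`` holds the (mean, sd) of the E-field magnitude in
    V/m for diagnosis ``d`` under protocol ``p``.  ``templates`` maps a
    template-head name to its per-protocol singleton E-field values.
    """

    cell_moments: dict[Diagnosis, dict[Protocol, tuple[float, float]]]
    group_sizes: dict[Diagnosis, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    sex_counts: dict[Sex, int] = field(
        default_factory=lambda: {Sex.male: 106, Sex.female: 89}
    )
    rmt_mean: float = 50.46
    rmt_sd: float = 8.91
    rmt_bounds: tuple[float, float] = (31.0, 78.0)
    rmt_multiplier: float = 1.2
    max_didt: float = 1.5e8
    tes_current_mA: float = 2.0
    templates: dict[str, dict[Protocol, float]] = field(default_factory=dict)
    latent_loading: float = 0.5
    mode: str = "direct"
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes is empty")
        for diag, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group size for {diag.value} must be >= 1, got {n}")
            cells = self.cell_moments.get(diag)
            if cells is None:
                raise ValueError(f"cell_moments missing diagnosis {diag.value}")
            for proto in Protocol:
                if proto not in cells:
                    raise ValueError(
                        f"cell_moments missing ({diag.value}, {proto.value})"
                    )
                mean, sd = cells[proto]
                if mean <= 0:
                    raise ValueError(
                        f"cell mean must be positive for ({diag.value}, {proto.value})"
                    )
                if sd < 0:
                    raise ValueError(
                        f"cell sd must be >= 0 for ({diag.value}, {proto.value})"
                    )
        if sum(self.sex_counts.values()) != self.n_subjects:
            raise ValueError(
                f"sex counts {dict(self.sex_counts)} do not sum to the "
                f"{self.n_subjects} subjects implied by group_sizes"
            )
        lo, hi = self.rmt_bounds
        if not (0 < lo < hi <= 100):
            raise ValueError(f"rmt bounds must satisfy 0 < lo < hi <= 100, got {self.rmt_bounds}")
        if self.rmt_sd < 0:
            raise ValueError("rmt_sd must be >= 0")
        if not 0 <= self.latent_loading <= 1:
            raise ValueError("latent_loading must be in [0, 1]")
        if self.mode not in ("direct", "mechanistic"):
            raise ValueError(f"unknown generation mode {self.mode!r}")
        for name, tvals in self.templates.items():
            for proto in Protocol:
                if proto not in tvals:
                    raise ValueError(f"template {name!r} missing {proto.value}")

    def with_seed(self, seed: int) -> "CohortParams":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# generation internals

# Named sub-stream offsets from the master seed; subject i always consumes
# element i of each stream, so cohort content is invariant to evaluation order.
_STREAM_RMT = 0
_STREAM_SEX = 1
_STREAM_LATENT = 2
_STREAM_EPS = 10  # + protocol index
_STREAM_REDRAW = 100  # + protocol index * 1000 + round


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _draw_rmt(params: CohortParams, n: int) -> np.ndarray:
    lo, hi = params.rmt_bounds
    if params.rmt_sd == 0:
        return np.full(n, float(np.clip(params.rmt_mean, lo, hi)))
    a = (lo - params.rmt_mean) / params.rmt_sd
    b = (hi - params.rmt_mean) / params.rmt_sd
    u = _stream(params.seed, _STREAM_RMT).random(n)
    return stats.truncnorm.ppf(u, a, b, loc=params.rmt_mean, scale=params.rmt_sd)


def _stim_pct_moments(params: CohortParams) -> tuple[float, float]:
    """First two moments of min(multiplier * rMT, 100) under the truncated
    rMT distribution, by quadrature."""
    lo, hi = params.rmt_bounds
    if params.rmt_sd == 0:
        s = min(params.rmt_multiplier * params.rmt_mean, 100.0)
        return s, s * s
    a = (lo - params.rmt_mean) / params.rmt_sd
    b = (hi - params.rmt_mean) / params.rmt_sd
    dist = stats.truncnorm(a, b, loc=params.rmt_mean, scale=params.rmt_sd)

    def f(r: float, power: int) -> float:
        return min(params.rmt_multiplier * r, 100.0) ** power * dist.pdf(r)

    m1, _ = integrate.quad(f, lo, hi, args=(1,), limit=200)
    m2, _ = integrate.quad(f, lo, hi, args=(2,), limit=200)
    return m1, m2


def _lognormal_gain_params(
    target_mean: float,
    target_sd: float,
    dose_m1: float,
    dose_m2: float,
    cell: str,
) -> tuple[float, float]:
    """Moment-match a lognormal gain g so that g x dose has the target
    moments, for a dose independent of g with raw moments (m1, m2)."""
    cv_dose_sq = dose_m2 / dose_m1**2 - 1.0
    cv_target_sq = (target_sd / target_mean) ** 2
    cv_gain_sq = (1.0 + cv_target_sq) / (1.0 + cv_dose_sq) - 1.0
    if cv_gain_sq < 0:
        raise CalibrationError(
            f"cell {cell}: requested cv {math.sqrt(cv_target_sq):.4f} is below the "
            f"dose-induced cv {math.sqrt(cv_dose_sq):.4f}; no gain distribution can "
            "match these moments given the configured rMT variability"
        )
    sigma = math.sqrt(math.log1p(cv_gain_sq))
    mu = math.log(target_mean / dose_m1) - 0.5 * sigma**2
    return mu, sigma


def _correlated_z(params: CohortParams, latent: np.ndarray, proto_idx: int) -> np.ndarray:
    lam = params.latent_loading
    eps = _stream(params.seed, _STREAM_EPS + proto_idx).standard_normal(latent.size)
    return lam * latent + math.sqrt(1.0 - lam * lam) * eps


def _redraw_nonpositive(
    params: CohortParams,
    latent: np.ndarray,
    proto_idx: int,
    mean: np.ndarray,
    sd: np.ndarray,
    values: np.ndarray,
) -> np.ndarray:
    # Rejection step of the zero-truncated normal: resample the residual of
    # any non-positive draw.  Cells sit several SD above zero, so this loop
    # effectively never runs on realistic parameters.
    lam = params.latent_loading
    resid_scale = math.sqrt(1.0 - lam * lam)
    for round_ in range(1000):
        bad = np.flatnonzero(values <= 0)
        if bad.size == 0:
            return values
        if resid_scale == 0 or np.all(sd[bad] == 0):
            raise ValueError(
                "cannot truncate at zero: cell mean non-positive with zero residual variance"
            )
        rng = _stream(params.seed, _STREAM_REDRAW + proto_idx * 1000 + round_)
        eps = rng.standard_normal(values.size)[bad]
        z = lam * latent[bad] + resid_scale * eps
        values[bad] = mean[bad] + sd[bad] * z
    raise RuntimeError("zero-truncation resampling did not converge")


def generate_cohort(params: CohortParams) -> list[SubjectRecord]:
    """Generate the cohort described by ``params``.

    Deterministic given ``params.seed``; returns exactly
    ``sum(params.group_sizes.values())`` records in a fixed order
    (diagnoses in enum order, subjects numbered within diagnosis).
    """
    params.validate()
    n = params.n_subjects

    diag_order = [d for d in Diagnosis if d in params.group_sizes]
    diagnoses: list[Diagnosis] = []
    for d in diag_order:
        diagnoses.extend([d] * params.group_sizes[d])

    sex_pool = np.array(
        [0] * params.sex_counts.get(Sex.male, 0) + [1] * params.sex_counts.get(Sex.female, 0)
    )
    sex_idx = _stream(params.seed, _STREAM_SEX).permutation(sex_pool)

    rmt = _draw_rmt(params, n)
    stim = np.minimum(params.rmt_multiplier * rmt, 100.0)
    didt = stim / 100.0 * params.max_didt
    latent = _stream(params.seed, _STREAM_LATENT).standard_normal(n)

    mean_arr = {p: np.empty(n) for p in Protocol}
    sd_arr = {p: np.empty(n) for p in Protocol}
    for p in Protocol:
        offset = 0
        for d in diag_order:
            m, s = params.cell_moments[d][p]
            k = params.group_sizes[d]
            mean_arr[p][offset : offset + k] = m
            sd_arr[p][offset : offset + k] = s
            offset += k

    efields: dict[Protocol, np.ndarray] = {}
    if params.mode == "direct":
        for j, p in enumerate(Protocol):
            z = _correlated_z(params, latent, j)
            vals = mean_arr[p] + sd_arr[p] * z
            efields[p] = _redraw_nonpositive(params, latent, j, mean_arr[p], sd_arr[p], vals)
    else:  # mechanistic
        stim_m1, stim_m2 = _stim_pct_moments(params)
        for j, p in enumerate(Protocol):
            if p.is_tms:
                dose = didt
                dose_m1 = stim_m1 / 100.0 * params.max_didt
                dose_m2 = stim_m2 / 100.0**2 * params.max_didt**2
            else:
                dose = np.full(n, params.tes_current_mA)
                dose_m1 = params.tes_current_mA
                dose_m2 = params.tes_current_mA**2
            z = _correlated_z(params, latent, j)
            vals = np.empty(n)
            offset = 0
            for d in diag_order:
                m, s = params.cell_moments[d][p]
                k = params.group_sizes[d]
                if s == 0 and not p.is_tms:
                    vals[offset : offset + k] = m
                else:
                    mu, sigma = _lognormal_gain_params(
                        m, s, dose_m1, dose_m2, f"({d.value}, {p.value})"
                    )
                    gain = np.exp(mu + sigma * z[offset : offset + k])
                    vals[offset : offset + k] = gain * dose[offset : offset + k]
                offset += k
            efields[p] = vals

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                id=f"S{i + 1:0{width}d}",
                diagnosis=diagnoses[i],
                sex=Sex.female if sex_idx[i] else Sex.male,
                rmt_pct=float(rmt[i]),
                stim_pct=float(stim[i]),
                didt=float(didt[i]),
                efield={p: float(efields[p][i]) for p in Protocol},
            )
        )
    return records


# ---------------------------------------------------------------------------
# cohort file I/O


def cohort_to_frame(records: Sequence[SubjectRecord]):
    """Tabulate records as a pandas DataFrame with the cohort file columns."""
    import pandas as pd

    rows = [
        (
            r.id,
            r.diagnosis.value,
            r.sex.value,
            r.rmt_pct,
            r.stim_pct,
            r.didt,
            r.efield[Protocol.motor_TMS],
            r.efield[Protocol.prefrontal_TMS],
            r.efield[Protocol.motor_tES],
            r.efield[Protocol.prefrontal_tES],
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write a UTF-8 comma-delimited cohort file (full float precision)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.diagnosis.value,
                    r.sex.value,
                    repr(r.rmt_pct),
                    repr(r.stim_pct),
                    repr(r.didt),
                    repr(r.efield[Protocol.motor_TMS]),
                    repr(r.efield[Protocol.prefrontal_TMS]),
                    repr(r.efield[Protocol.motor_tES]),
                    repr(r.efield[Protocol.prefrontal_tES]),
                ]
            )


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort file, validating every row.

    Raises :class:`CohortParseError` naming the offending line for unknown
    diagnosis/sex labels, non-numeric fields, or wrong column counts.
    """
    records: list[SubjectRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortParseError(f"{path}: empty file (missing header)") from None
        if tuple(header) != COHORT_COLUMNS:
            raise CohortParseError(
                f"{path}: line 1: unexpected header {header!r}; expected {list(COHORT_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(COHORT_COLUMNS):
                raise CohortParseError(
                    f"{path}: line {lineno}: expected {len(COHORT_COLUMNS)} fields, got {len(row)}"
                )
            try:
                diagnosis = Diagnosis(row[1])
            except ValueError:
                raise CohortParseError(
                    f"{path}: line {lineno}: unknown diagnosis label {row[1]!r}"
                ) from None
            try:
                sex = Sex(row[2])
            except ValueError:
                raise CohortParseError(
                    f"{path}: line {lineno}: unknown sex label {row[2]!r}"
                ) from None
            try:
                nums = [float(x) for x in row[3:]]
            except ValueError as exc:
                raise CohortParseError(f"{path}: line {lineno}: {exc}") from None
            records.append(
                SubjectRecord(
                    id=row[0],
                    diagnosis=diagnosis,
                    sex=sex,
                    rmt_pct=nums[0],
                    stim_pct=nums[1],
                    didt=nums[2],
                    efield={
                        Protocol.motor_TMS: nums[3],
                        Protocol.prefrontal_TMS: nums[4],
                        Protocol.motor_tES: nums[5],
                        Protocol.prefrontal_tES: nums[6],
                    },
                )
            )
    return records
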