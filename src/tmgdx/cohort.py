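"""Synthetic twitch waveforms and bilateral cohorts.

The study population this package targets — athletes with an acutely
injured biceps femoris versus non-injured controls — has no public raw
data, so this module generates both levels of synthetic input:

* :func:`make_twitch_waveform` builds a smooth unimodal twitch whose
  extracted (Td, Tc, Dm) hit prescribed targets exactly (up to sampling);
* :func:`sample_cohort` draws whole bilateral cohorts whose per-leg
  parameter distributions follow configurable means/SDs, with an
  interlimb correlation controlling bilateral symmetry.

The defaults encode the reference condition: 53 injured and 53 non-injured
athletes (22 F + 31 M each); non-injured legs nearly symmetric
(Td ≈ 22.8 ms, Tc ≈ 24.5 ms, Dm ≈ 4.6–4.8 mm); in injured subjects the
injured leg shows prolonged Tc (32.9 ± 8.5 ms) and Td (25.0 ± 3.6 ms) with
essentially unchanged Dm, while the contralateral leg matches the healthy
distribution.  Parameters are drawn from bivariate normals truncated at
zero, pairing the two legs with correlation ``rho``.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .signal import TMGSignal, TwitchParams

__all__ = [
    "GenerationError",
    "CohortSchemaError",
    "LegPair",
    "CohortConfig",
    "SubjectRecord",
    "default_cohort_config",
    "make_twitch_waveform",
    "sample_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("td", "tc", "dm")

COHORT_COLUMNS = [
    "subject_id", "sex", "group", "injured_side",
    "td_l", "tc_l", "dm_l", "td_r", "tc_r", "dm_r",
]


class GenerationError(ValueError):
    """Raised when a waveform target is unreachable for the template family."""


class CohortSchemaError(ValueError):
    """Raised for cohort CSV files violating the schema."""


# ---------------------------------------------------------------------------
# Waveform generation
# ---------------------------------------------------------------------------

def _template(u: np.ndarray, p: float) -> np.ndarray:
    """Unimodal rise template g(u) = u^p exp(p(1-u)); g(1) = 1 at the peak."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = u[pos] ** p * np.exp(p * (1.0 - u[pos]))
    return out


def _rise_fraction_inverse(frac: float, p: float) -> float:
    """u in (0, 1) with g(u) = frac on the rising branch (bisection via brentq)."""
    return float(brentq(lambda u: u**p * np.exp(p * (1.0 - u)) - frac, 1e-12, 1.0,
                        xtol=1e-9))


def make_twitch_waveform(
    target: TwitchParams,
    duration: float = 500.0,
    sampling_interval: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    shape: float = 2.0,
) -> TMGSignal:
    """Generate a twitch waveform with prescribed (Td, Tc, Dm).

    The waveform is ``y(t) = Dm · g((t − t0)/s)`` with the fixed template
    ``g(u) = u^p · exp(p(1 − u))`` (peak 1 at u = 1, default p = 2); ``t0``
    and ``s`` are solved from the template's 10 % / 90 % rise points so that
    threshold-crossing extraction recovers the targets.  Optional additive
    Gaussian noise of standard deviation ``noise_sd`` mm.
    """
    if target.tc <= 0 or target.td <= 0 or target.dm <= 0:
        raise GenerationError("targets must be positive")
    u10 = _rise_fraction_inverse(0.10, shape)
    u90 = _rise_fraction_inverse(0.90, shape)
    s = target.tc / (u90 - u10)
    t0 = target.td - s * u10
    t_peak = t0 + s
    if t_peak >= duration:
        raise GenerationError(
            f"duration {duration} ms too short: peak falls at {t_peak:.1f} ms"
        )
    n = int(round(duration / sampling_interval)) + 1
    t = np.arange(n) * sampling_interval
    y = target.dm * _template((t - t0) / s, shape)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return TMGSignal(time=t, displacement=y, meta={
        "synthetic": True, "target_td": target.td, "target_tc": target.tc,
        "target_dm": target.dm, "noise_sd": noise_sd,
    })


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LegPair:
    """Means/SDs (ms or mm) for the two legs of one parameter in one cell.

    For non-injured subjects the pair is (left, right); for injured subjects
    it is (injured leg, contralateral leg).
    """

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float

    def __post_init__(self) -> None:
        if self.sd_a <= 0 or self.sd_b <= 0:
            raise ValueError("SDs must be > 0")


def _noninjured_defaults() -> dict:
    # (left, right) legs of healthy athletes; Dm differs by sex.
    base = {
        "td": LegPair(22.8, 2.4, 22.8, 2.1),
        "tc": LegPair(24.5, 4.7, 24.5, 4.5),
    }
    return {
        "F": {**base, "dm": LegPair(4.1, 1.3, 4.2, 1.2)},
        "M": {**base, "dm": LegPair(5.0, 2.0, 5.1, 1.9)},
    }


def _injured_defaults() -> dict:
    # (injured leg, contralateral leg) of acutely injured athletes.
    cell = {
        "td": LegPair(25.0, 3.6, 23.1, 2.3),
        "tc": LegPair(32.9, 8.5, 24.6, 5.1),
        "dm": LegPair(5.0, 1.9, 4.9, 1.8),
    }
    return {"F": dict(cell), "M": dict(cell)}


def _default_rho() -> dict:
    # Interlimb correlation per parameter, calibrated so healthy-side
    # bilateral asymmetry matches the reference means (half-normal moment
    # match on |L - R|; see docs/methods.md for the derivation).
    return {"td": 0.884, "tc": 0.944, "dm": 0.942}


@dataclass(frozen=True)
class CohortConfig:
    """Sampling design of a synthetic bilateral cohort.

    ``rho`` is the interlimb correlation of each parameter's leg pair —
    either a single float for all parameters or a ``{param: rho}`` mapping.
    It governs bilateral symmetry and hence the spread of percentage
    differences (and the downstream AUC).  ``p_injured_left`` is the
    probability that an injured subject's injured side is the left.
    """

    n_injured: int = 53
    n_noninjured: int = 53
    n_female_injured: int = 22
    n_female_noninjured: int = 22
    rho: float | dict = field(default_factory=_default_rho)
    p_injured_left: float = 0.5
    noninjured: dict = field(default_factory=_noninjured_defaults)
    injured: dict = field(default_factory=_injured_defaults)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_injured, self.n_noninjured) < 1:
            raise ValueError("group sizes must be >= 1")
        if not (0 <= self.n_female_injured <= self.n_injured):
            raise ValueError("n_female_injured out of range")
        if not (0 <= self.n_female_noninjured <= self.n_noninjured):
            raise ValueError("n_female_noninjured out of range")
        for p in PARAM_NAMES:
            r = self.rho_for(p)
            if not (0 <= r < 1):
                raise ValueError(f"rho[{p}] must be in [0, 1), got {r}")
        if not (0 <= self.p_injured_left <= 1):
            raise ValueError("p_injured_left must be a probability")

    def rho_for(self, param: str) -> float:
        if isinstance(self.rho, dict):
            return float(self.rho[param])
        return float(self.rho)


def default_cohort_config(**overrides) -> CohortConfig:
    """The reference cohort design (53/53 subjects, 22 F + 31 M per group)."""
    return replace(CohortConfig(), **overrides) if overrides else CohortConfig()


@dataclass(frozen=True)
class SubjectRecord:
    """One athlete: sex, injury group, injured side and bilateral parameters."""

    subject_id: str
    sex: Literal["F", "M"]
    group: Literal["injured", "non_injured"]
    injured_side: Literal["L", "R", "none"]
    left: TwitchParams
    right: TwitchParams

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.group not in ("injured", "non_injured"):
            raise ValueError(f"invalid group {self.group!r}")
        if self.group == "non_injured" and self.injured_side != "none":
            raise ValueError("non-injured subjects must have injured_side 'none'")
        if self.group == "injured" and self.injured_side not in ("L", "R"):
            raise ValueError("injured subjects must have injured_side 'L' or 'R'")

    @property
    def injured_leg(self) -> TwitchParams | None:
        if self.group != "injured":
            return None
        return self.left if self.injured_side == "L" else self.right

    @property
    def contralateral_leg(self) -> TwitchParams | None:
        if self.group != "injured":
            return None
        return self.right if self.injured_side == "L" else self.left


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def _draw_truncated_pair(
    rng: np.random.Generator, pair: LegPair, rho: float, n: int
) -> np.ndarray:
    """n draws of a correlated leg pair from a bivariate normal truncated at 0.

    Truncation is by rejection (redraw rows with a non-positive component);
    with means several SDs above zero the acceptance rate is ≈ 1 and the
    bias is negligible.
    """
    mean = np.array([pair.mean_a, pair.mean_b])
    cov = np.array([
        [pair.sd_a**2, rho * pair.sd_a * pair.sd_b],
        [rho * pair.sd_a * pair.sd_b, pair.sd_b**2],
    ])
    out = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    bad = np.nonzero((out <= 0).any(axis=1))[0]
    while bad.size:
        out[bad] = rng.multivariate_normal(mean, cov, size=bad.size, method="cholesky")
        bad = bad[(out[bad] <= 0).any(axis=1)]
    return out


def sample_cohort(config: CohortConfig | None = None, seed: int | None = None) -> list[SubjectRecord]:
    """Draw a full bilateral cohort under ``config`` (reproducible by seed).

    Non-injured subjects draw (left, right) pairs; injured subjects draw
    (injured leg, contralateral leg) pairs with the injured side assigned
    Bernoulli(``p_injured_left``).  ``seed`` overrides ``config.seed``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[SubjectRecord] = []
    counter = 0

    plan = [
        ("injured", "F", config.n_female_injured),
        ("injured", "M", config.n_injured - config.n_female_injured),
        ("non_injured", "F", config.n_female_noninjured),
        ("non_injured", "M", config.n_noninjured - config.n_female_noninjured),
    ]
    for group, sex, n in plan:
        if n == 0:
            continue
        cell = (config.injured if group == "injured" else config.noninjured)[sex]
        draws = {p: _draw_truncated_pair(rng, cell[p], config.rho_for(p), n)
                 for p in PARAM_NAMES}
        if group == "injured":
            left_is_injured = rng.random(n) < config.p_injured_left
        for i in range(n):
            counter += 1
            a = TwitchParams(**{p: float(draws[p][i, 0]) for p in PARAM_NAMES})
            b = TwitchParams(**{p: float(draws[p][i, 1]) for p in PARAM_NAMES})
            if group == "injured":
                if left_is_injured[i]:
                    side, left, right = "L", a, b
                else:
                    side, left, right = "R", b, a
            else:
                side, left, right = "none", a, b
            records.append(SubjectRecord(
                subject_id=f"S{counter:04d}", sex=sex, group=group,
                injured_side=side, left=left, right=right,
            ))
    logger.info("sampled cohort: %d subjects (%d injured, %d non-injured)",
                len(records), config.n_injured, config.n_noninjured)
    return records


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def cohort_to_frame(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": r.subject_id, "sex": r.sex, "group": r.group,
            "injured_side": "NA" if r.injured_side == "none" else r.injured_side,
            "td_l": r.left.td, "tc_l": r.left.tc, "dm_l": r.left.dm,
            "td_r": r.right.td, "tc_r": r.right.tc, "dm_r": r.right.dm,
        }
        for r in cohort
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> list[SubjectRecord]:
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing columns: {missing}")
    extra = [c for c in frame.columns if c not in COHORT_COLUMNS]
    if extra:
        raise CohortSchemaError(f"unexpected columns: {extra}")
    records = []
    for _, row in frame.iterrows():
        side = row["injured_side"]
        if pd.isna(side) or side == "NA":
            side = "none"
        if side not in ("L", "R", "none"):
            raise CohortSchemaError(f"invalid injured_side value {side!r}")
        if row["sex"] not in ("F", "M"):
            raise CohortSchemaError(f"invalid sex value {row['sex']!r}")
        if row["group"] not in ("injured", "non_injured"):
            raise CohortSchemaError(f"invalid group value {row['group']!r}")
        try:
            records.append(SubjectRecord(
                subject_id=str(row["subject_id"]), sex=row["sex"], group=row["group"],
                injured_side=side,
                left=TwitchParams(td=row["td_l"], tc=row["tc_l"], dm=row["dm_l"]),
                right=TwitchParams(td=row["td_r"], tc=row["tc_r"], dm=row["dm_r"]),
            ))
        except ValueError as exc:
            raise CohortSchemaError(f"subject {row['subject_id']!r}: {exc}") from exc
    return records


def write_cohort_csv(cohort: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write a cohort as CSV with round-trip (repr) float precision."""
    buf = io.StringIO()
    buf.write(",".join(COHORT_COLUMNS) + "\n")
    for r in cohort:
        side = "NA" if r.injured_side == "none" else r.injured_side
        nums = ",".join(repr(float(v)) for v in (
            r.left.td, r.left.tc, r.left.dm, r.right.td, r.right.tc, r.right.dm))
        buf.write(f"{r.subject_id},{r.sex},{r.group},{side},{nums}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    frame = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=False,
                        na_values=[""], float_precision="round_trip")
    if frame.empty:
        warnings.warn(f"{path}: empty cohort file", stacklevel=2)
        return []
    for col in ("td_l", "tc_l", "dm_l", "td_r", "tc_r", "dm_r"):
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
            if frame[col].isna().any():
                raise CohortSchemaError(f"non-numeric values in column {col!r}")
    return frame_to_cohort(frame)
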