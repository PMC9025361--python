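"""Synthetic pH-monitoring datasets with the study's generative structure.

The default :class:`StudyDesign` mirrors the industrial monitoring campaign
the model was built for: 10 production batches, a full factorial of three
potassium-lactate doses (0, 1, 2 % w/w) and three packaging atmospheres
(Air, 70%O2-30%CO2, 50%CO2-50%N2), sampled on storage days 2, 8, 15 and 22 —
360 observations in all, one averaged pH value per (batch, condition, day).

Generation follows the hierarchical model exactly: one initial pH per batch,
shared across all of that batch's conditions, then independent Gaussian
measurement noise around the two-phase mean curve.  The drawn latent values
are retained on the returned dataset (and can be written to a sidecar file)
so that recovery tests can compare estimates against the generating truth;
the fitting pipeline itself never reads them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    ATMOSPHERES,
    Atmosphere,
    Condition,
    Observation,
    ParameterState,
    acidification_rate,
)

__all__ = ["StudyDesign", "Dataset", "generate_dataset"]

DATASET_COLUMNS = ("batch_id", "lactate_pct", "atmosphere", "day", "pH")


@dataclass(frozen=True)
class StudyDesign:
    """Factorial monitoring design: batches x lactate doses x atmospheres x days."""

    n_batches: int = 10
    lactate_doses: tuple[float, ...] = (0.0, 1.0, 2.0)
    atmospheres: tuple[Atmosphere, ...] = ATMOSPHERES
    sampling_days: tuple[float, ...] = (2.0, 8.0, 15.0, 22.0)
    replicates_per_point: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "lactate_doses", tuple(float(x) for x in self.lactate_doses))
        object.__setattr__(
            self, "atmospheres", tuple(Atmosphere.parse(a) for a in self.atmospheres)
        )
        object.__setattr__(self, "sampling_days", tuple(float(d) for d in self.sampling_days))
        if self.n_batches < 1 or self.replicates_per_point < 1:
            raise ValueError("n_batches and replicates_per_point must be >= 1")
        if not self.lactate_doses or not self.atmospheres or not self.sampling_days:
            raise ValueError("design factor lists must be non-empty")
        if any(x < 0 for x in self.lactate_doses):
            raise ValueError("lactate doses must be >= 0")
        days = self.sampling_days
        if any(d < 0 for d in days) or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling_days must be strictly increasing and >= 0")

    @property
    def conditions(self) -> tuple[Condition, ...]:
        return tuple(
            Condition(lactate=l, atmosphere=a)
            for l, a in itertools.product(self.lactate_doses, self.atmospheres)
        )

    @property
    def batch_ids(self) -> tuple[str, ...]:
        width = max(2, len(str(self.n_batches)))
        return tuple(f"B{i + 1:0{width}d}" for i in range(self.n_batches))

    @property
    def n_observations(self) -> int:
        return (self.n_batches * len(self.conditions)
                * len(self.sampling_days) * self.replicates_per_point)


_ATM_INDEX = {a: i for i, a in enumerate(ATMOSPHERES)}


class Dataset:
    """A collection of pH observations with cached numeric views.

    Wraps a tidy DataFrame with columns (batch_id, lactate_pct, atmosphere,
    day, pH) and exposes aligned numpy arrays (``pH``, ``day``, ``lactate``,
    ``atm_idx``, ``batch_idx``) used by the likelihood and the sampler.
    ``batch_ids`` preserves order of first appearance.
    """

    def __init__(self, frame: pd.DataFrame, design: StudyDesign | None = None,
                 truth_pH0: dict[str, float] | None = None):
        frame = frame.reset_index(drop=True).copy()
        missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset frame missing columns: {missing}")
        frame["atmosphere"] = [Atmosphere.parse(a).value for a in frame["atmosphere"]]
        frame["lactate_pct"] = frame["lactate_pct"].astype(float)
        frame["day"] = frame["day"].astype(float)
        frame["pH"] = frame["pH"].astype(float)
        frame["batch_id"] = frame["batch_id"].astype(str)
        if (frame["day"] < 0).any():
            raise ValueError("storage days must be >= 0")
        if (frame["lactate_pct"] < 0).any():
            raise ValueError("lactate doses must be >= 0")
        if not np.isfinite(frame["pH"]).all():
            raise ValueError("pH values must be finite")
        self.frame = frame
        self.design = design
        self.truth_pH0 = dict(truth_pH0) if truth_pH0 is not None else None

        self.batch_ids: tuple[str, ...] = tuple(pd.unique(frame["batch_id"]))
        index = {b: i for i, b in enumerate(self.batch_ids)}
        self.pH = frame["pH"].to_numpy()
        self.day = frame["day"].to_numpy()
        self.lactate = frame["lactate_pct"].to_numpy()
        self.atm_idx = np.array(
            [_ATM_INDEX[Atmosphere(a)] for a in frame["atmosphere"]], dtype=np.intp
        )
        self.batch_idx = np.array([index[b] for b in frame["batch_id"]], dtype=np.intp)

    # -- constructors -------------------------------------------------------

    @classmethod
    def empty(cls) -> "Dataset":
        return cls(pd.DataFrame({c: [] for c in DATASET_COLUMNS}))

    @classmethod
    def from_observations(cls, observations: Iterable[Observation],
                          design: StudyDesign | None = None) -> "Dataset":
        rows = [
            {
                "batch_id": o.batch_id,
                "lactate_pct": o.condition.lactate,
                "atmosphere": o.condition.atmosphere.value,
                "day": o.day,
                "pH": o.pH,
            }
            for o in observations
        ]
        frame = pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
        return cls(frame, design=design)

    # -- views --------------------------------------------------------------

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def n_batches(self) -> int:
        return len(self.batch_ids)

    @property
    def observations(self) -> list[Observation]:
        return [
            Observation(
                batch_id=row.batch_id,
                condition=Condition(lactate=row.lactate_pct, atmosphere=row.atmosphere),
                day=row.day,
                pH=row.pH,
            )
            for row in self.frame.itertuples(index=False)
        ]

    def __len__(self) -> int:
        return self.n_obs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.frame.equals(other.frame)


def generate_dataset(design: StudyDesign, truth: ParameterState, seed: int) -> Dataset:
    """Simulate one dataset under the hierarchical two-phase model.

    Each batch r gets a single initial pH draw ``pH0_r ~ N(mu_pH0, sigma_pH0)``
    shared across all of its conditions; each (batch, condition, day,
    replicate) then receives ``pH ~ N(mean_pH(...), sigma_pH)``.  Reproducible
    for a given (design, truth, seed); the latent draws are stored on the
    returned dataset as ``truth_pH0``.
    """
    if not isinstance(design, StudyDesign):
        raise TypeError("design must be a StudyDesign")
    rng = np.random.default_rng(seed)
    batch_ids = design.batch_ids
    pH0 = truth.mu_pH0 + truth.sigma_pH0 * rng.standard_normal(design.n_batches)

    # Per-condition rates; non-finite rates mean the truth cannot generate
    # this design (e.g. zero lactate with n <= 0).
    betas = {}
    for cond in design.conditions:
        beta = acidification_rate(truth.lam, truth.n, truth.delta_for(cond.atmosphere),
                                  cond.lactate)
        if not np.isfinite(beta):
            raise ValueError(
                f"non-finite acidification rate for condition {cond}; invalid truth"
            )
        betas[cond] = beta

    days = np.asarray(design.sampling_days)
    eff_days = np.minimum(days, truth.theta)
    rows = []
    for r, batch in enumerate(batch_ids):
        for cond in design.conditions:
            means = pH0[r] - betas[cond] * eff_days
            for day, m in zip(days, means):
                for _ in range(design.replicates_per_point):
                    rows.append(
                        (batch, cond.lactate, cond.atmosphere.value, day,
                         m + truth.sigma_pH * rng.standard_normal())
                    )
    frame = pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
    truth_map = {b: float(v) for b, v in zip(batch_ids, pH0)}
    return Dataset(frame, design=design, truth_pH0=truth_map)
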