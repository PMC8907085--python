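"""Synthetic first-trimester case-control cohorts.

The reference study design is a 1:1 retrospective case-control cohort
(40 trisomy-21 pregnancies, 40 euploid controls) for which only group
summaries are published: per-variable medians with 2.5th-97.5th
percentiles.  This module turns those three printed numbers per variable
into a sampling distribution and generates cohorts with the same
statistical structure, so the whole risk pipeline can be exercised and
stress-tested without access to per-subject data.

Distribution family
-------------------
Marker MoM values are simulated from a *two-piece (split) log-normal*:
on the log scale the density is Gaussian with location ``log(median)``
and a different standard deviation on each side, chosen so that the
2.5th and 97.5th percentiles match the printed interval exactly
(``sigma = |log(percentile) - log(median)| / 1.959964``).  The printed
intervals are visibly asymmetric on the log scale, which a single
log-normal cannot represent; a pooled single-sigma log-normal is
available via ``family="pooled"``.

Maternal age, weight and gestational age use the same two-piece
mechanism on the natural scale (their intervals are near-symmetric) and
are truncated to plausibility bounds (age 15-50 y, weight 30-150 kg,
GA 77-97 d); truncation is logged.

Dependence between markers is introduced by a Gaussian copula on the
log scale.  The default correlation is the identity -- no inter-marker
correlations are published for this panel -- but any positive
semi-definite correlation matrix can be supplied.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .markers import (
    AFFECTED_LABEL,
    CONTROL_LABEL,
    PANEL,
    mom_column,
    raw_column,
)

logger = logging.getLogger(__name__)

#: Standard-normal 97.5th percentile used to convert a printed
#: 2.5th/97.5th percentile into a per-side sigma.
Z_975 = 1.959964

#: Plausibility bounds applied to the demographic variables.
DEMOGRAPHIC_BOUNDS = {
    "maternal_age_years": (15.0, 50.0),
    "maternal_weight_kg": (30.0, 150.0),
    "ga_days": (77.0, 97.0),
}


@dataclass(frozen=True)
class PercentileSpec:
    """A variable summarized as median (2.5th-97.5th percentile)."""

    median: float
    p_low: float
    p_high: float

    def validate(self, name: str = "variable", positive: bool = True) -> None:
        if positive and not (self.p_low > 0 and self.median > 0 and self.p_high > 0):
            raise ValueError(
                f"{name}: median and percentiles must be strictly positive, "
                f"got median={self.median}, p_low={self.p_low}, p_high={self.p_high}"
            )
        if not (self.p_low <= self.median <= self.p_high):
            raise ValueError(
                f"{name}: percentiles must satisfy p_low <= median <= p_high, "
                f"got {self.p_low} / {self.median} / {self.p_high}"
            )


@dataclass(frozen=True)
class GroupSpec:
    """Sampling specification for one outcome group."""

    n: int
    age: PercentileSpec
    weight: PercentileSpec
    ga_days: PercentileSpec
    markers: dict[str, PercentileSpec]
    label: str

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"group {self.label!r}: n must be >= 0, got {self.n}")
        unknown = set(self.markers) - set(PANEL)
        if unknown:
            raise ValueError(
                f"group {self.label!r}: unknown marker names {sorted(unknown)}; "
                f"panel is {list(PANEL)}"
            )
        self.age.validate(f"group {self.label!r} age")
        self.weight.validate(f"group {self.label!r} weight")
        self.ga_days.validate(f"group {self.label!r} ga_days")
        for m, spec in self.markers.items():
            spec.validate(f"group {self.label!r} marker {m!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Full two-group cohort specification.

    ``correlation`` is the Gaussian-copula correlation matrix over the
    markers of the affected group, in panel order; ``family`` selects
    the marker distribution family (``"two_piece"`` or ``"pooled"``).
    """

    affected: GroupSpec
    control: GroupSpec
    correlation: np.ndarray | None = None
    seed: int = 0
    family: str = "two_piece"

    def marker_names(self) -> list[str]:
        return [m for m in PANEL if m in self.affected.markers]

    def validate(self) -> None:
        self.affected.validate()
        self.control.validate()
        if set(self.affected.markers) != set(self.control.markers):
            raise ValueError(
                "affected and control groups must model the same marker set"
            )
        if self.family not in ("two_piece", "pooled"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            k = len(self.marker_names())
            if corr.shape != (k, k):
                raise ValueError(
                    f"correlation must be {k}x{k} for {k} markers, got {corr.shape}"
                )
            if not np.allclose(corr, corr.T, atol=1e-10):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
                raise ValueError("correlation matrix diagonal must be 1")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.correlation is not None:
            d["correlation"] = np.asarray(self.correlation, dtype=float).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        def _pspec(x) -> PercentileSpec:
            if isinstance(x, PercentileSpec):
                return x
            return PercentileSpec(**x)

        def _gspec(x) -> GroupSpec:
            if isinstance(x, GroupSpec):
                return x
            x = dict(x)
            x["age"] = _pspec(x["age"])
            x["weight"] = _pspec(x["weight"])
            x["ga_days"] = _pspec(x["ga_days"])
            x["markers"] = {m: _pspec(s) for m, s in x["markers"].items()}
            return GroupSpec(**x)

        corr = d.get("correlation")
        return cls(
            affected=_gspec(d["affected"]),
            control=_gspec(d["control"]),
            correlation=None if corr is None else np.asarray(corr, dtype=float),
            seed=int(d.get("seed", 0)),
            family=d.get("family", "two_piece"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class TwoPieceDistribution:
    """Split-normal distribution on the natural or log scale.

    A standard normal draw ``z`` maps to ``loc + sigma_low * z`` when
    ``z < 0`` and ``loc + sigma_high * z`` otherwise; with ``log_scale``
    the result is exponentiated.  The median is ``loc`` (or
    ``exp(loc)``) because the two pieces carry equal probability mass.
    """

    loc: float
    sigma_low: float
    sigma_high: float
    log_scale: bool = True

    def transform(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        x = self.loc + np.where(z < 0, self.sigma_low, self.sigma_high) * z
        return np.exp(x) if self.log_scale else x

    def ppf(self, q) -> np.ndarray:
        from scipy.stats import norm

        return self.transform(norm.ppf(q))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.transform(rng.standard_normal(n))


def fit_two_piece_lognormal(
    spec: PercentileSpec, name: str = "variable", family: str = "two_piece"
) -> TwoPieceDistribution:
    """Calibrate a split log-normal to a printed median and 2.5/97.5 band.

    The log-median equals ``log(median)`` and each printed percentile is
    matched exactly: ``sigma_low = (log median - log p_low) / 1.959964``
    and ``sigma_high = (log p_high - log median) / 1.959964``.  With
    ``family="pooled"`` both sides share the pooled sigma
    ``(log p_high - log p_low) / (2 * 1.959964)`` and only the median is
    matched exactly.
    """
    spec.validate(name, positive=True)
    mu = math.log(spec.median)
    s_lo = (mu - math.log(spec.p_low)) / Z_975
    s_hi = (math.log(spec.p_high) - mu) / Z_975
    if family == "pooled":
        s_lo = s_hi = (math.log(spec.p_high) - math.log(spec.p_low)) / (2 * Z_975)
    elif family != "two_piece":
        raise ValueError(f"unknown distribution family {family!r}")
    return TwoPieceDistribution(mu, s_lo, s_hi, log_scale=True)


def fit_two_piece_normal(
    spec: PercentileSpec, name: str = "variable"
) -> TwoPieceDistribution:
    """Calibrate a split normal (natural scale) to a percentile summary."""
    spec.validate(name, positive=False)
    s_lo = (spec.median - spec.p_low) / Z_975
    s_hi = (spec.p_high - spec.median) / Z_975
    return TwoPieceDistribution(spec.median, s_lo, s_hi, log_scale=False)


def _correlation_factor(corr: np.ndarray | None, k: int) -> np.ndarray | None:
    if corr is None:
        return None
    corr = np.asarray(corr, dtype=float)
    if np.allclose(corr, np.eye(k)):
        return None
    # eigen factor tolerates PSD-singular matrices, unlike Cholesky
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        raise ValueError("correlation matrix must be positive semi-definite")
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _generate_group(
    group: GroupSpec,
    markers: list[str],
    factor: np.ndarray | None,
    family: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = group.n
    cols: dict[str, np.ndarray] = {}
    for col, pspec in (
        ("maternal_age_years", group.age),
        ("maternal_weight_kg", group.weight),
        ("ga_days", group.ga_days),
    ):
        dist = fit_two_piece_normal(pspec, col)
        values = dist.rvs(n, rng)
        lo, hi = DEMOGRAPHIC_BOUNDS[col]
        n_trunc = int(np.sum((values < lo) | (values > hi)))
        if n_trunc:
            logger.info(
                "group %s: truncated %d/%d %s values to [%g, %g]",
                group.label, n_trunc, n, col, lo, hi,
            )
        cols[col] = np.clip(values, lo, hi)

    z = rng.standard_normal((n, len(markers)))
    if factor is not None:
        z = z @ factor.T
    for j, m in enumerate(markers):
        dist = fit_two_piece_lognormal(group.markers[m], m, family=family)
        cols[mom_column(m)] = dist.transform(z[:, j])

    frame = pd.DataFrame(cols)
    frame.insert(0, "group", group.label)
    return frame


def generate_cohort(
    spec: CohortSpec,
    seed: int | None = None,
    emit_raw: bool = False,
    median_models: dict | None = None,
) -> pd.DataFrame:
    """Simulate one cohort; deterministic given the seed.

    Returns a DataFrame with one row per pregnancy: ``subject_id``,
    ``group``, demographics, and one ``<marker>_mom`` column per panel
    marker.  With ``emit_raw=True`` additional ``<marker>_raw`` columns
    hold pseudo-raw concentrations obtained by multiplying each MoM by
    the gestational-age and maternal-weight median curves, so the
    normalization stage can be exercised end-to-end (round trip:
    normalizing the raw columns with the same median models recovers
    the MoM columns exactly).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    markers = spec.marker_names()
    factor = _correlation_factor(spec.correlation, len(markers))

    parts = []
    for group in (spec.affected, spec.control):
        if group.n > 0:
            parts.append(_generate_group(group, markers, factor, spec.family, rng))
    frame = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    if frame.empty:
        raise ValueError("cohort spec generates zero records")
    frame.insert(0, "subject_id", [f"S{i:05d}" for i in range(len(frame))])

    if emit_raw:
        from . import mom as mom_mod

        models = median_models or mom_mod.default_median_models()
        for m in markers:
            ga_model, wt_model = models[m]
            med = ga_model.median(frame["ga_days"].to_numpy()) * wt_model.median(
                frame["maternal_weight_kg"].to_numpy()
            )
            frame[raw_column(m)] = frame[mom_column(m)].to_numpy() * med
    return frame


def default_cohort_spec(n_per_group: int = 40, seed: int = 20211108) -> CohortSpec:
    """The reference case-control setting for this marker panel.

    Group sizes, demographic summaries and per-marker MoM summaries are
    the published values for the 40-case / 40-control first-trimester
    cohort this package models; the correlation defaults to the
    identity because no inter-marker correlations are published.
    """
    control = GroupSpec(
        n=n_per_group,
        age=PercentileSpec(28.44, 20.35, 33.86),
        weight=PercentileSpec(50.10, 42.90, 63.00),
        ga_days=PercentileSpec(89.00, 80.05, 97.00),
        markers={
            "PAPP-A": PercentileSpec(0.88, 0.20, 3.74),
            "free beta-hCG": PercentileSpec(1.02, 0.33, 3.98),
            "NT": PercentileSpec(0.87, 0.59, 1.15),
            "AFP-L2": PercentileSpec(1.00, 0.39, 2.12),
        },
        label=CONTROL_LABEL,
    )
    affected = GroupSpec(
        n=n_per_group,
        age=PercentileSpec(29.92, 24.11, 37.79),
        weight=PercentileSpec(53.30, 39.13, 74.73),
        ga_days=PercentileSpec(87.00, 69.10, 96.98),
        markers={
            "PAPP-A": PercentileSpec(0.37, 0.04, 1.65),
            "free beta-hCG": PercentileSpec(1.76, 0.15, 6.95),
            "NT": PercentileSpec(1.17, 0.59, 2.10),
            "AFP-L2": PercentileSpec(1.59, 0.61, 3.61),
        },
        label=AFFECTED_LABEL,
    )
    return CohortSpec(
        affected=affected,
        control=control,
        correlation=np.eye(4),
        seed=seed,
    )
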