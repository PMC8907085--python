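"""Multiple-of-the-median (MoM) normalization.

Serum marker concentrations vary strongly with gestational age and
maternal weight, so screening works on MoM values: the raw
concentration divided by the expected median for a comparable
pregnancy.  This module implements the median-curve convention used by
the risk model:

* raw MoM        = concentration / population median
* GA median      = 10 ** (quartic polynomial in gestational age, days)
* weight median  = a - b / weight_kg  (reciprocal-weight hyperbola)
* adjusted MoM   = MoM / (GA median * weight median)

The adjusted-MoM formula divides a MoM by the *product* of the two
median terms, which is the convention this model family prints; the
more common pipeline (divide the raw concentration by the GA median,
then weight-correct) is available via ``MoMTransformer(
convention="sequential")`` and off by default.

Only the AFP-L2 gestational-age coefficients are published for this
panel, so :func:`default_median_models` assigns the identity GA model
(median = 1) to the other markers; per-marker coefficient tables can be
supplied through the config file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .markers import PANEL, adjusted_column, mom_column, raw_column

#: Supported gestational-age range, days (11 to 13+6 weeks).
GA_RANGE = (77.0, 97.0)
#: Supported maternal weight range, kg.
WEIGHT_RANGE = (30.0, 150.0)

#: Published gestational-age median coefficients for AFP-L2
#: (c0..c4 of the base-10 quartic, GA in days).
AFP_L2_GA_COEFFICIENTS = (-261.9, 8.09, -0.09277, 0.0004694, -0.0000008842)

#: Published maternal-weight median parameters (a, b).
DEFAULT_WEIGHT_PARAMS = (0.8852, 9.465)


@dataclass(frozen=True)
class GAMedianModel:
    """Gestational-age median curve ``10**(c0 + c1*GA + ... + c4*GA**4)``.

    The quartic's terms at the published coefficient magnitudes are
    individually of order 1e5-1e6 near GA = 90 d and nearly cancel, so
    the polynomial is evaluated by Horner's scheme; float64 carries
    ~16 significant digits, ample for the ~6 digits lost to
    cancellation (verified against extended-precision evaluation).
    """

    coefficients: tuple[float, float, float, float, float]

    def exponent(self, ga_days) -> np.ndarray:
        ga = np.asarray(ga_days, dtype=float)
        c = self.coefficients
        acc = np.full_like(ga, c[4])
        for coef in (c[3], c[2], c[1], c[0]):
            acc = acc * ga + coef
        return acc

    def median(self, ga_days) -> np.ndarray:
        """Evaluate the median curve; warns outside the supported GA range."""
        ga = np.asarray(ga_days, dtype=float)
        if np.any((ga < GA_RANGE[0]) | (ga > GA_RANGE[1])):
            warnings.warn(
                f"gestational age outside supported range {GA_RANGE} days; "
                "median curve extrapolated",
                stacklevel=2,
            )
        out = np.power(10.0, self.exponent(ga))
        if not np.all(np.isfinite(out)):
            raise ValueError(f"GA median not finite at ga_days={ga_days!r}")
        return out


@dataclass(frozen=True)
class WeightMedianModel:
    """Maternal-weight median correction ``a - b / weight_kg``."""

    a: float = DEFAULT_WEIGHT_PARAMS[0]
    b: float = DEFAULT_WEIGHT_PARAMS[1]

    def median(self, weight_kg) -> np.ndarray:
        w = np.asarray(weight_kg, dtype=float)
        if np.any(w <= 0):
            raise ValueError("maternal weight must be strictly positive")
        out = self.a - self.b / w
        # 1e-9 floor treats the exact root w = b/a as non-positive despite
        # float rounding of the division
        if np.any(out <= 1e-9):
            bad = float(np.min(w))
            raise ValueError(
                f"weight median correction non-positive at weight={bad:g} kg "
                f"(requires weight > b/a = {self.b / self.a:.4g} kg)"
            )
        return out


#: Identity GA model: median identically 1 (no GA correction).
IDENTITY_GA_MODEL = GAMedianModel((0.0, 0.0, 0.0, 0.0, 0.0))


def default_median_models() -> dict[str, tuple[GAMedianModel, WeightMedianModel]]:
    """Per-marker (GA model, weight model) pairs.

    AFP-L2 uses the published quartic; the other markers, whose
    coefficients are not published, use the identity GA model.  All
    markers share the published weight hyperbola.
    """
    wt = WeightMedianModel()
    models = {m: (IDENTITY_GA_MODEL, wt) for m in PANEL}
    models["AFP-L2"] = (GAMedianModel(AFP_L2_GA_COEFFICIENTS), wt)
    return models


def identity_median_models() -> dict[str, tuple[GAMedianModel, WeightMedianModel]]:
    """Median models that leave MoM values unchanged (median = 1)."""
    ident_wt = WeightMedianModel(a=1.0, b=0.0)
    return {m: (IDENTITY_GA_MODEL, ident_wt) for m in PANEL}


# -- scalar operations --------------------------------------------------


def raw_mom(concentration, population_median) -> np.ndarray:
    """Raw MoM: concentration divided by the population median."""
    c = np.asarray(concentration, dtype=float)
    m = np.asarray(population_median, dtype=float)
    if np.any(c <= 0) or np.any(m <= 0):
        raise ValueError("concentration and population median must be > 0")
    return c / m


def ga_median(ga_days, model: GAMedianModel) -> np.ndarray:
    """Gestational-age median from the base-10 quartic curve."""
    return model.median(ga_days)


def weight_median(weight_kg, model: WeightMedianModel | None = None) -> np.ndarray:
    """Maternal-weight median correction ``a - b/weight``."""
    return (model or WeightMedianModel()).median(weight_kg)


def adjusted_mom(mom, ga_med, weight_med) -> np.ndarray:
    """Adjusted MoM: ``mom / (ga_med * weight_med)``."""
    mom = np.asarray(mom, dtype=float)
    g = np.asarray(ga_med, dtype=float)
    w = np.asarray(weight_med, dtype=float)
    if np.any(mom <= 0) or np.any(g <= 0) or np.any(w <= 0):
        raise ValueError("mom, ga_med and weight_med must all be > 0")
    return mom / (g * w)


def ga_days_from_weeks(weeks: int, days: int = 0) -> float:
    """Convenience converter: gestational age in completed weeks + days."""
    return 7.0 * weeks + float(days)


class MoMTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer adding MoM / adjusted-MoM columns to a cohort.

    Parameters
    ----------
    median_models:
        Mapping marker name -> (GAMedianModel, WeightMedianModel);
        defaults to :func:`default_median_models`.
    population_medians:
        Marker -> population median used for the raw-MoM division when
        raw columns are present (default 1.0, i.e. raw values are
        already on a median-1 scale).
    convention:
        ``"product"`` (default) divides the MoM by the product of the
        two median terms; ``"sequential"`` divides the raw
        concentration by the GA median first, then applies the weight
        correction -- algebraically identical here but kept explicit
        because the two conventions diverge when medians are fitted per
        stage.
    """

    def __init__(
        self,
        median_models: dict | None = None,
        population_medians: dict | None = None,
        convention: str = "product",
    ):
        self.median_models = median_models
        self.population_medians = population_medians
        self.convention = convention

    def fit(self, X: pd.DataFrame, y=None):
        if self.convention not in ("product", "sequential"):
            raise ValueError(f"unknown convention {self.convention!r}")
        self.median_models_ = self.median_models or default_median_models()
        self.population_medians_ = self.population_medians or {}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "median_models_")
        out = X.copy()
        for marker, (ga_model, wt_model) in self.median_models_.items():
            rc, mc = raw_column(marker), mom_column(marker)
            if mc not in out.columns and rc in out.columns:
                pop_med = self.population_medians_.get(marker, 1.0)
                out[mc] = raw_mom(out[rc].to_numpy(), pop_med)
            if mc not in out.columns:
                continue
            g = ga_model.median(out["ga_days"].to_numpy())
            w = wt_model.median(out["maternal_weight_kg"].to_numpy())
            if self.convention == "product":
                out[adjusted_column(marker)] = adjusted_mom(
                    out[mc].to_numpy(), g, w
                )
            else:
                out[adjusted_column(marker)] = raw_mom(
                    raw_mom(out[mc].to_numpy(), g), w
                )
        return out
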