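"""Relative-probability prediction surfaces and weighted model averaging.

Each cell's covariates are summarized over a moving disc of the season's
buffer radius (the same operators used to build the training data), the fixed
effects form the linear predictor with the random intercept at its mean (0),
and the logistic function maps it to a relative probability of presence in
[0, 1].  Surfaces from the 95% confidence set are combined cell-wise by their
renormalized Akaike weights; a convex combination of logistic outputs, so the
average stays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .covariates import covariate_grid
from .fitting import FittedModel, ModelSet
from .grid import Raster
from .layers import EnergyLayers, LandscapeStack


@dataclass
class PredictionSurface:
    """Raster of relative probability of presence in [0, 1]."""

    grid: Raster
    season: str | None
    provenance: list[tuple[str, float]] = field(default_factory=list)  # (formula, weight)

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def predict_surface(fit: FittedModel, landscape: LandscapeStack, radius_m: float,
                    energy: EnergyLayers | None = None,
                    covariate_rasters: dict[str, Raster] | None = None,
                    link: str = "logistic") -> PredictionSurface:
    """Wall-to-wall prediction surface for one fitted model.

    ``covariate_rasters`` can carry precomputed moving-window rasters so a
    model set shares one extraction pass.  ``link='logistic'`` returns
    exp(eta)/(1+exp(eta)) (the relative-probability convention used here);
    ``link='exp'`` exposes the classical exponential RSF form instead.
    """
    if covariate_rasters is None:
        covariate_rasters = covariate_grid(landscape, radius_m, energy=energy)
    missing = [c for c in fit.covariates if c not in covariate_rasters]
    if missing:
        raise KeyError(f"covariates missing from the layer stack: {missing}")
    template = landscape.vegetation
    eta = np.full(template.values.shape, float(fit.beta["intercept"]))
    for c in fit.covariates:
        eta = eta + fit.beta[c] * covariate_rasters[c].values
    if link == "logistic":
        vals = special.expit(eta)
    elif link == "exp":
        vals = np.exp(eta)
    else:
        raise ValueError(f"unknown link '{link}'")
    return PredictionSurface(grid=template.copy_with(vals), season=fit.season,
                             provenance=[(fit.formula, 1.0)])


def average_surfaces(surfaces: list[PredictionSurface], weights) -> PredictionSurface:
    """Cell-wise weighted average of aligned surfaces (weights sum to 1)."""
    if not surfaces:
        raise ValueError("no surfaces to average")
    w = np.asarray(list(weights), dtype=float)
    if len(w) != len(surfaces):
        raise ValueError("one weight per surface required")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()!r}, expected 1")
    base = surfaces[0].grid
    acc = np.zeros(base.values.shape)
    prov = []
    for s, wi in zip(surfaces, w):
        if not s.grid.same_grid(base):
            raise ValueError("surfaces are not on a shared grid")
        acc += wi * s.grid.values
        prov.extend((f, float(wi * pw)) for f, pw in s.provenance)
    return PredictionSurface(grid=base.copy_with(acc), season=surfaces[0].season,
                             provenance=prov)


def model_averaged_surface(model_set: ModelSet, landscape: LandscapeStack,
                           radius_m: float, energy: EnergyLayers | None = None,
                           link: str = "logistic") -> PredictionSurface:
    """Average the 95%-set surfaces by renormalized Akaike weights."""
    pairs = model_set.confidence_models()
    needed = sorted({c for m, _ in pairs for c in m.covariates})
    rasters = covariate_grid(landscape, radius_m, energy=energy) if needed else {}
    surfaces, weights = [], []
    for fit, wr in pairs:
        surfaces.append(predict_surface(fit, landscape, radius_m, energy=energy,
                                        covariate_rasters=rasters, link=link))
        weights.append(wr)
    return average_surfaces(surfaces, weights)
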