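"""Thermodynamic model of the lac-promoter input function.

The lac operon integrates two environmental signals: cAMP (acting through
the CRP activator) and an inducer such as IPTG (acting through the LacI
repressor).  Expression measured over a two-dimensional cAMP x IPTG grid
defines the strain's regulatory input function.  This module implements a
statistical-mechanics promoter-occupancy model of that function,

    G(C, I) = gamma + alpha * P_act(C) * F_rep(I)

where ``P_act`` is the equilibrium probability that RNA polymerase occupies
the promoter given the cAMP-CRP occupancy state and ``F_rep`` is the
probability that the promoter is free of repressor.  CRP activity follows a
Hill function of cAMP, A(C) = C^n / (Km_cAMP^n + C^n); LacI activity (the
fraction of repressor not bound to IPTG) is R(I) = 1 / (1 + (I/Km_IPTG)^m).
The polymerase term enumerates the four promoter states (empty, RNAP only,
CRP only, RNAP+CRP with fold-stabilization eta):

    P_act = (a + a*d*eta*A) / (1 + a + d*A + a*d*eta*A)

and repression is a simple occupancy factor F_rep = 1 / (1 + b*R).
DNA looping by LacI tetramers is deliberately omitted.

Downstream of the forward model the module derives logic phenotypes
(pi1/pi2/pi3, single-inducer fractions, synergy), Euclidean distances
between max-normalized landscapes, and average-linkage clustering of
strains by landscape shape.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryParams",
    "InducerGrid",
    "ExpressionLandscape",
    "LogicPhenotype",
    "PAPER_CAMP_LEVELS_MM",
    "PAPER_IPTG_LEVELS_UM",
    "paper_grid",
    "crp_activity",
    "laci_activity",
    "predict_expression",
    "predict_landscape",
    "logic_phenotype",
    "landscape_distance",
    "cluster_landscapes",
    "Dendrogram",
]

#: Standard assay concentrations: 8 cAMP levels (mM) and 10 IPTG levels (uM).
PAPER_CAMP_LEVELS_MM: tuple[float, ...] = (0.0, 0.625, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0)
PAPER_IPTG_LEVELS_UM: tuple[float, ...] = (
    0.0, 0.78, 1.56, 3.125, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0,
)
#: Alternative 6-level IPTG series used for some strains.
PAPER_IPTG_LEVELS_6_UM: tuple[float, ...] = (0.0, 6.25, 12.5, 25.0, 50.0, 100.0)

#: Order of parameters in vector form (used by fitting and exports).
PARAM_NAMES: tuple[str, ...] = (
    "alpha", "gamma", "a", "b", "d", "eta", "n", "m", "Km_cAMP", "Km_IPTG",
)


class ModelError(ValueError):
    """Base class for model-domain errors."""


class GridMismatchError(ModelError):
    """Two landscapes do not share an inducer grid."""


class DegenerateLandscapeError(ModelError):
    """Landscape carries no usable signal (e.g. all zero)."""


@dataclass(frozen=True)
class RegulatoryParams:
    """The ten parameters of the promoter-occupancy model.

    alpha : maximum expression rate (AFU), > 0
    gamma : basal expression rate (AFU), >= 0
    a     : RNAP binding weight without cAMP-CRP (dimensionless), > 0
    b     : LacI binding weight (dimensionless), >= 0
    d     : cAMP-CRP binding weight (dimensionless), >= 0
    eta   : fold-stabilization of RNAP binding by bound cAMP-CRP, > 0
    n     : cAMP-CRP Hill cooperativity, > 0
    m     : IPTG-LacI Hill cooperativity, > 0
    Km_cAMP : half-saturation of CRP by cAMP (mM), > 0
    Km_IPTG : dissociation constant of IPTG from LacI (uM), > 0
    """

    alpha: float
    gamma: float
    a: float
    b: float
    d: float
    eta: float
    n: float
    m: float
    Km_cAMP: float
    Km_IPTG: float

    def __post_init__(self) -> None:
        strict = {"alpha": self.alpha, "a": self.a, "eta": self.eta,
                  "n": self.n, "m": self.m,
                  "Km_cAMP": self.Km_cAMP, "Km_IPTG": self.Km_IPTG}
        for name, v in strict.items():
            if not (np.isfinite(v) and v > 0):
                raise ModelError(f"parameter {name} must be finite and > 0, got {v}")
        for name, v in {"gamma": self.gamma, "b": self.b, "d": self.d}.items():
            if not (np.isfinite(v) and v >= 0):
                raise ModelError(f"parameter {name} must be finite and >= 0, got {v}")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "RegulatoryParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_NAMES),):
            raise ModelError(f"expected {len(PARAM_NAMES)} parameters, got {vec.shape}")
        return cls(**dict(zip(PARAM_NAMES, vec.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "RegulatoryParams":
        return cls(**{k: float(d[k]) for k in PARAM_NAMES})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "RegulatoryParams":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class InducerGrid:
    """Ordered cAMP (mM) and IPTG (uM) concentration axes of an assay grid."""

    camp_levels: tuple[float, ...]
    iptg_levels: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, axis in (("camp_levels", self.camp_levels),
                           ("iptg_levels", self.iptg_levels)):
            arr = np.asarray(axis, dtype=float)
            if arr.size < 2:
                raise ModelError(f"{name} needs at least 2 levels")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ModelError(f"{name} must be finite and non-negative")
            if np.any(np.diff(arr) <= 0):
                raise ModelError(f"{name} must be strictly increasing")
        object.__setattr__(self, "camp_levels", tuple(float(x) for x in self.camp_levels))
        object.__setattr__(self, "iptg_levels", tuple(float(x) for x in self.iptg_levels))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.camp_levels), len(self.iptg_levels))


def paper_grid(iptg_levels: int = 10) -> InducerGrid:
    """The standard 8 cAMP x 10 (or 6) IPTG assay grid."""
    iptg = PAPER_IPTG_LEVELS_UM if iptg_levels == 10 else PAPER_IPTG_LEVELS_6_UM
    return InducerGrid(PAPER_CAMP_LEVELS_MM, iptg)


@dataclass
class ExpressionLandscape:
    """Mean expression (AFU) of one strain over an inducer grid.

    ``values`` is indexed [camp][iptg].  Missing cells are NaN (fitting
    masks them).  Negative background-subtracted values are clamped to 0
    at load time by the CSV reader, not here.
    """

    strain_id: str
    grid: InducerGrid
    values: np.ndarray
    n_replicates: np.ndarray | None = None
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ModelError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise ModelError("landscape values must be >= 0 (clamp at load)")

    @property
    def max_value(self) -> float:
        return float(np.nanmax(self.values))

    def normalized(self) -> np.ndarray:
        """Values divided by the landscape maximum."""
        mx = self.max_value
        if not mx > 0:
            raise DegenerateLandscapeError(
                f"landscape {self.strain_id!r} has no positive values")
        return self.values / mx


@dataclass(frozen=True)
class LogicPhenotype:
    """Shape summary of an input function.

    pi1/pi2/pi3 are ratios of log10 expression at the (lowI,lowC),
    (highI,lowC) and (lowI,highC) corners to the (highI,highC) corner after
    rescaling the landscape maximum to 100 (values clamped to >= 1 before
    the log).  Low pi everywhere means AND-type logic.  f_iptg and f_camp
    are the single-inducer corner expressions as fractions of the both-high
    corner; synergy = 1 - (f_iptg + f_camp - f_iptg*f_camp) is the share of
    maximal expression unexplained by Bliss-independent combination.
    """

    pi1: float
    pi2: float
    pi3: float
    f_iptg: float
    f_camp: float
    synergy: float

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    def to_vector(self) -> np.ndarray:
        return np.array([self.pi1, self.pi2, self.pi3,
                         self.f_iptg, self.f_camp, self.synergy])


# ---------------------------------------------------------------------------
# forward model


def crp_activity(camp, params: RegulatoryParams):
    """Fraction of CRP bound to cAMP: A = C^n / (Km^n + C^n)."""
    camp = np.asarray(camp, dtype=float)
    if np.any(camp < 0):
        raise ModelError("cAMP concentration must be >= 0")
    cn = np.power(camp, params.n)
    out = cn / (params.Km_cAMP ** params.n + cn)
    return out if out.ndim else float(out)


def laci_activity(iptg, params: RegulatoryParams):
    """Fraction of LacI not bound to IPTG: R = 1 / (1 + (I/Km)^m)."""
    iptg = np.asarray(iptg, dtype=float)
    if np.any(iptg < 0):
        raise ModelError("IPTG concentration must be >= 0")
    out = 1.0 / (1.0 + np.power(iptg / params.Km_IPTG, params.m))
    return out if out.ndim else float(out)


def _pact(A, params: RegulatoryParams):
    a, d, eta = params.a, params.d, params.eta
    act = a * d * eta * A
    return (a + act) / (1.0 + a + d * A + act)


def _frep(R, params: RegulatoryParams):
    return 1.0 / (1.0 + params.b * R)


def predict_expression(camp, iptg, params: RegulatoryParams):
    """Expression G(C, I) = gamma + alpha * P_act(C) * F_rep(I), in AFU.

    Bounded in [gamma, gamma + alpha]; non-decreasing in both inducers
    when eta >= 1.
    """
    A = crp_activity(camp, params)
    R = laci_activity(iptg, params)
    out = params.gamma + params.alpha * _pact(A, params) * _frep(R, params)
    return out if np.ndim(out) else float(out)


def predict_landscape(grid: InducerGrid, params: RegulatoryParams,
                      strain_id: str = "model") -> ExpressionLandscape:
    """Evaluate the model on every grid cell."""
    camp = np.asarray(grid.camp_levels)[:, None]
    iptg = np.asarray(grid.iptg_levels)[None, :]
    values = predict_expression(camp, iptg, params)
    return ExpressionLandscape(strain_id=strain_id, grid=grid, values=values)


# ---------------------------------------------------------------------------
# logic phenotype


def logic_phenotype(landscape: ExpressionLandscape) -> LogicPhenotype:
    """Derive the logic phenotype from the landscape's corner conditions.

    "Low" and "high" are the minimum and maximum concentrations present on
    each axis.  The landscape is rescaled so its maximum is 100; pi_i =
    log10(max(E_i, 1)) / log10(100) at the three non-maximal corners, and
    the single-inducer fractions are ratios to the both-high corner.
    """
    vals = landscape.values
    if not np.all(np.isfinite(vals[[0, -1]][:, [0, -1]])):
        raise DegenerateLandscapeError("corner cells are missing")
    mx = np.nanmax(vals)
    if not mx > 0:
        raise DegenerateLandscapeError(
            f"landscape {landscape.strain_id!r} is all zero")
    scaled = vals * (100.0 / mx)
    e_ll = scaled[0, 0]     # low IPTG, low cAMP
    e_hl = scaled[0, -1]    # high IPTG, low cAMP
    e_lh = scaled[-1, 0]    # low IPTG, high cAMP
    e_hh = scaled[-1, -1]   # high IPTG, high cAMP

    def _pi(e: float) -> float:
        return math.log10(max(e, 1.0)) / math.log10(100.0)

    if e_hh <= 0:
        raise DegenerateLandscapeError("both-high corner is zero")
    f_iptg = e_hl / e_hh
    f_camp = e_lh / e_hh
    synergy = 1.0 - (f_iptg + f_camp - f_iptg * f_camp)
    return LogicPhenotype(pi1=_pi(e_ll), pi2=_pi(e_hl), pi3=_pi(e_lh),
                          f_iptg=f_iptg, f_camp=f_camp, synergy=synergy)


# ---------------------------------------------------------------------------
# landscape comparison


def landscape_distance(ls1: ExpressionLandscape, ls2: ExpressionLandscape) -> float:
    """Euclidean distance between max-normalized landscapes.

    Normalization makes the comparison one of shape, not absolute AFU
    scale (strains differ in reporter brightness).
    """
    if ls1.grid != ls2.grid:
        raise GridMismatchError(
            f"grids differ: {ls1.strain_id!r} vs {ls2.strain_id!r}")
    d = ls1.normalized() - ls2.normalized()
    return float(np.sqrt(np.nansum(d * d)))


@dataclass
class Dendrogram:
    """Average-linkage dendrogram over strains.

    ``linkage_matrix`` is in scipy format; ``merge_order`` lists, for each
    merge, the set of strain labels joined and the merge height.
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    distance_matrix: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def first_merge_pair(self) -> frozenset[str]:
        i, j = int(self.linkage_matrix[0, 0]), int(self.linkage_matrix[0, 1])
        return frozenset({self.labels[i], self.labels[j]})


def cluster_landscapes(landscapes: Sequence[ExpressionLandscape]) -> Dendrogram:
    """Average-linkage hierarchical clustering on landscape distances."""
    if len(landscapes) < 2:
        raise ModelError("need at least 2 landscapes to cluster")
    labels = [ls.strain_id for ls in landscapes]
    k = len(landscapes)
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dm[i, j] = dm[j, i] = landscape_distance(landscapes[i], landscapes[j])
    Z = linkage(squareform(dm, checks=False), method="average")
    return Dendrogram(labels=labels, linkage_matrix=Z, distance_matrix=dm)
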