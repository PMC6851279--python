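"""Synthetic study generator with known ground truth.

Emulates the design of the lac input-function study end to end so every
pipeline stage can be exercised and validated without measured data:
regulatory parameters drawn from documented realistic ranges, expression
landscapes on the standard 8 cAMP x 10 IPTG grid with multiplicative
lognormal measurement noise and replicate averaging, a pure-birth strain
phylogeny with traits evolved at a chosen Pagel's lambda, bi-allelic SNP
matrices with planted causal sites plus exact-copy linked sites, and
Gompertz growth curves whose true lag is a linear function of the strain's
log a and log eta (the two parameters the growth analysis targets).

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .growth import GrowthCurve, gompertz
from .model import (
    ExpressionLandscape,
    InducerGrid,
    RegulatoryParams,
    paper_grid,
    predict_landscape,
)
from .phylo import TraitVector, phylo_covariance

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "sample_params", "simulate_landscape",
           "simulate_study_landscapes", "simulate_tree_and_traits",
           "simulate_snp_matrix", "snp_matrix_to_alignment",
           "simulate_growth_panel", "true_lags", "params_to_table",
           "transform_params_table", "SAMPLING_RANGES", "LOG_SCALE_PARAMS"]

#: Log-uniform sampling ranges for realistic lac regulatory parameters.
#: Chosen (within the fitting search bounds) so that sampled landscapes
#: show the AND-to-OR morphological range seen across natural isolates:
#: half-saturation constants inside the measured concentration decades,
#: appreciable repression (b) and CRP activation (d, eta).
SAMPLING_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (2e3, 5e4),      # AFU
    "gamma": (20.0, 500.0),   # AFU
    "a": (0.05, 5.0),
    "b": (10.0, 1000.0),
    "d": (1.0, 100.0),
    "eta": (5.0, 200.0),
    "n": (1.0, 4.0),
    "m": (1.0, 4.0),
    "Km_cAMP": (0.5, 20.0),   # mM; grid spans 0-40
    "Km_IPTG": (2.0, 100.0),  # uM; grid spans 0-200
}


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic generators.

    Defaults mirror the measured design: the 8 x 10 inducer grid, 5%
    multiplicative noise CV, 3 replicates, OD450 read every 3 min for 24 h.
    The lag model lag = beta0 + beta_a * z(log a) + beta_eta * z(log eta)
    + noise uses a negative a coefficient and positive eta coefficient,
    the directions the growth analysis is designed to detect.
    """

    seed: int = 0
    n_strains: int = 20
    grid: InducerGrid = field(default_factory=paper_grid)
    noise_cv: float = 0.05
    n_replicates: int = 3
    correlate_a_eta: bool = False
    lambda_true: float = 1.0
    # SNP generator
    n_sites: int = 300
    n_causal: int = 2
    n_linked: int = 3          # exact-copy linked sites per causal site
    effect_size: float = 3.0   # separation (SD units) of the causal latent
    # growth / lag generator
    beta0: float = 300.0       # min
    beta_a: float = -60.0      # min per SD of log10(a)
    beta_eta: float = 60.0     # min per SD of log10(eta)
    sigma_eps: float = 20.0    # min
    od_noise_sd: float = 0.002
    growth_duration_min: float = 1440.0
    growth_step_min: float = 3.0

    def __post_init__(self) -> None:
        if self.n_strains < 0 or self.n_replicates < 1 or self.n_sites < 0:
            raise ValueError("counts must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    """Independent stream per stage, all derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def sample_params(config: SimulationConfig) -> dict[str, RegulatoryParams]:
    """Draw labelled parameter sets from the documented log-uniform ranges.

    With ``correlate_a_eta`` a shared latent imposes the negative a-eta
    correlation seen across strains (strains with strong basal RNAP binding
    show weaker CRP stabilization).
    """
    rng = _rng(config, 1)
    out: dict[str, RegulatoryParams] = {}
    for i in range(config.n_strains):
        draws = {}
        u = {k: rng.uniform() for k in SAMPLING_RANGES}
        if config.correlate_a_eta:
            z = rng.uniform()
            u["a"] = np.clip(0.75 * z + 0.25 * u["a"], 0.0, 1.0)
            u["eta"] = np.clip(0.75 * (1.0 - z) + 0.25 * u["eta"], 0.0, 1.0)
        for k, (lo, hi) in SAMPLING_RANGES.items():
            draws[k] = float(np.exp(np.log(lo) + u[k] * (np.log(hi) - np.log(lo))))
        out[f"S{i:03d}"] = RegulatoryParams(**draws)
    return out


def simulate_landscape(params: RegulatoryParams, config: SimulationConfig,
                       strain_id: str = "sim", rng: np.random.Generator | None = None
                       ) -> tuple[ExpressionLandscape, ExpressionLandscape]:
    """(observed replicate-averaged landscape, noiseless truth).

    Each replicate cell is truth * LogNormal(0, sigma) with sigma chosen so
    the multiplicative CV equals ``noise_cv``.
    """
    rng = rng if rng is not None else _rng(config, 2)
    truth = predict_landscape(config.grid, params, strain_id=strain_id)
    if config.noise_cv == 0:
        obs = ExpressionLandscape(strain_id=strain_id, grid=config.grid,
                                  values=truth.values.copy(),
                                  n_replicates=np.full(truth.values.shape,
                                                       config.n_replicates),
                                  sd=np.zeros_like(truth.values))
        return obs, truth
    sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
    reps = truth.values[None] * rng.lognormal(
        mean=0.0, sigma=sigma,
        size=(config.n_replicates,) + truth.values.shape)
    obs = ExpressionLandscape(
        strain_id=strain_id, grid=config.grid, values=reps.mean(axis=0),
        n_replicates=np.full(truth.values.shape, config.n_replicates),
        sd=reps.std(axis=0, ddof=1) if config.n_replicates > 1 else None)
    return obs, truth


def simulate_study_landscapes(config: SimulationConfig
                              ) -> tuple[dict[str, ExpressionLandscape],
                                         dict[str, ExpressionLandscape],
                                         dict[str, RegulatoryParams]]:
    """Convenience: parameters plus observed and noiseless landscapes."""
    params = sample_params(config)
    rng = _rng(config, 2)
    observed, truths = {}, {}
    for sid, p in params.items():
        obs, truth = simulate_landscape(p, config, strain_id=sid, rng=rng)
        observed[sid] = obs
        truths[sid] = truth
    return observed, truths, params


def simulate_tree_and_traits(config: SimulationConfig, n_traits: int = 1
                             ) -> tuple[dendropy.Tree, list[TraitVector]]:
    """Pure-birth tree scaled to unit depth plus traits evolved with
    covariance sigma^2 * C(lambda_true)."""
    if config.n_strains < 3:
        raise ValueError("need at least 3 strains for a tree")
    rng = _rng(config, 3)
    pyrng = random.Random(int(rng.integers(2**31 - 1)))
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=config.n_strains,
        rng=pyrng)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"S{i:03d}"
    # the process stops exactly at the n-th speciation, leaving the last
    # cherry with zero-length tips; observe the tree a further exponential
    # waiting time (to the next birth event) so tips are distinct
    extra = float(rng.exponential(1.0 / config.n_strains))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # scale to unit root-to-tip depth
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(l.root_distance for l in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    labels, C = phylo_covariance(tree, config.lambda_true)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(labels)))
    traits = [TraitVector(tip_labels=labels,
                          values=L @ rng.standard_normal(len(labels)))
              for _ in range(n_traits)]
    return tree, traits


def simulate_snp_matrix(params_table: pd.DataFrame, config: SimulationConfig
                        ) -> tuple["SnpMatrix", dict]:
    """Bi-allelic SNP matrix with planted causal and linked-copy sites.

    Causal sites threshold the chosen parameter at its median and then
    apply label noise: each strain's allele flips with probability
    Phi(-effect_size), so effect_size = 0 gives purely random labels and
    effect_size = 3 an essentially clean split (3-SD separation on the
    probit scale).  Each causal site is followed by ``n_linked`` exact
    copies (the linkage signature: linked sites carry identical MI).
    Remaining sites are neutral with SFS-distributed frequencies; every
    site is polymorphic.  Returns (matrix, registry of planted sites).
    """
    from scipy.stats import norm

    from .assoc import SnpMatrix

    strains = list(params_table.index)
    n = len(strains)
    if n < 6:
        raise ValueError("need at least 6 strains")
    rng = _rng(config, 4)
    cols: list[np.ndarray] = []
    registry: dict[int, dict] = {}
    pnames = list(params_table.columns)
    causal_block = config.n_causal * (1 + config.n_linked)
    if causal_block > config.n_sites:
        raise ValueError("n_sites too small for the requested causal block")
    p_flip = float(norm.cdf(-config.effect_size))
    for c in range(config.n_causal):
        pname = pnames[c % len(pnames)]
        x = params_table[pname].to_numpy(dtype=float)
        z = (x - x.mean()) / (x.std() or 1.0)
        allele = (z > np.median(z)).astype(np.int8)
        allele ^= (rng.uniform(size=n) < p_flip).astype(np.int8)
        while len(np.unique(allele)) < 2:  # keep the site polymorphic
            allele[rng.integers(n)] ^= 1
        first = len(cols)
        for _ in range(1 + config.n_linked):
            registry[len(cols)] = {"causal_site": first, "parameter": pname,
                                   "linked": len(cols) != first}
            cols.append(allele.copy())
    # neutral sites: minor-allele counts follow the folded neutral site
    # frequency spectrum, P(j) ~ 1/j + 1/(n-j), so most sites are rare
    # variants as in real alignments
    js = np.arange(1, n // 2 + 1)
    sfs = 1.0 / js + 1.0 / (n - js)
    sfs /= sfs.sum()
    while len(cols) < config.n_sites:
        j = int(rng.choice(js, p=sfs))
        carriers = rng.choice(n, size=j, replace=False)
        allele = np.zeros(n, dtype=np.int8)
        allele[carriers] = 1
        cols.append(allele)
    alleles = np.column_stack(cols)
    positions = np.arange(1, alleles.shape[1] + 1) * 17 + 3  # spread coords
    snps = SnpMatrix(strain_labels=strains, site_positions=positions,
                     alleles=alleles)
    registry_by_pos = {int(positions[i]): info for i, info in registry.items()}
    return snps, registry_by_pos


def snp_matrix_to_alignment(snps, rng: np.random.Generator | None = None,
                            length: int | None = None) -> dict[str, str]:
    """Render a SnpMatrix as aligned sequences (A/G alleles on a C
    background) so the FASTA reader path can be exercised."""
    rng = rng or np.random.default_rng(0)
    length = length or int(snps.site_positions.max()) + 5
    base = np.full(length, "C")
    seqs = {}
    lut = np.array(["A", "G", "T", "-"])
    for i, label in enumerate(snps.strain_labels):
        s = base.copy()
        s[snps.site_positions - 1] = lut[snps.alleles[i] % 4]
        seqs[label] = "".join(s)
    return seqs


def true_lags(params_table: pd.DataFrame, config: SimulationConfig,
              rng: np.random.Generator | None = None) -> pd.Series:
    """Ground-truth lag per strain: linear in z(log10 a) and z(log10 eta),
    floored at zero."""
    rng = rng if rng is not None else _rng(config, 5)
    la = np.log10(params_table["a"].to_numpy(dtype=float))
    le = np.log10(params_table["eta"].to_numpy(dtype=float))
    za = (la - la.mean()) / (la.std() or 1.0)
    ze = (le - le.mean()) / (le.std() or 1.0)
    lag = (config.beta0 + config.beta_a * za + config.beta_eta * ze
           + config.sigma_eps * rng.standard_normal(len(params_table)))
    return pd.Series(np.maximum(lag, 0.0), index=params_table.index,
                     name="true_lag_min")


def simulate_growth_panel(params_table: pd.DataFrame, config: SimulationConfig
                          ) -> tuple[list[GrowthCurve], pd.Series]:
    """Replicate growth curves per strain with lag set by the lag model.

    Curves follow the modified Gompertz with fixed plate-typical amplitude
    and rate, plus Gaussian OD noise; three replicates per strain.
    """
    rng = _rng(config, 5)
    lags = true_lags(params_table, config, rng=rng)
    t = np.arange(0.0, config.growth_duration_min + 1e-9,
                  config.growth_step_min)
    curves: list[GrowthCurve] = []
    for sid in params_table.index:
        for rep in range(config.n_replicates):
            a_max = 0.45 * rng.uniform(0.9, 1.1)
            mu = 0.0015 * rng.uniform(0.9, 1.1)
            base = 0.05
            od = gompertz(t, a_max, mu, float(lags[sid]), base)
            od = od + rng.normal(0.0, config.od_noise_sd, size=t.size)
            curves.append(GrowthCurve(well_id=f"{sid}_r{rep}", strain_id=sid,
                                      times=t.copy(), od=od))
    return curves, lags


def params_to_table(params: dict[str, RegulatoryParams]) -> pd.DataFrame:
    """Strain x parameter DataFrame from labelled parameter sets."""
    return pd.DataFrame({sid: p.to_dict() for sid, p in params.items()}).T


#: Parameters entered into MI / PLS on log10 scale; Hill exponents linear.
LOG_SCALE_PARAMS = ("alpha", "gamma", "a", "b", "d", "eta",
                    "Km_cAMP", "Km_IPTG")


def transform_params_table(table: pd.DataFrame) -> pd.DataFrame:
    """log10-transform scale parameters for association analyses."""
    out = table.copy()
    for c in out.columns:
        if c in LOG_SCALE_PARAMS:
            out[c] = np.log10(out[c].astype(float))
    return out
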