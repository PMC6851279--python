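"""Genotype-phenotype association statistics.

Two analyses relate fitted regulatory parameters to other strain data:

* a mutual-information (MI) scan of polymorphic sites in the lacI-ZYA
  alignment against each parameter, with family-wise significance from a
  max-statistic permutation null (the maximum MI across sites is recorded
  for each permutation of the parameter values, so linked sites sharing an
  allele pattern receive identical MI and near-identical corrected p); and

* partial least-squares (PLS1/NIPALS) regression of lag time on the
  standardized parameter matrix, reporting per-component variance in lag
  explained and per-parameter contribution shares, with significance by
  permutation of the response.

MI uses plug-in estimation with equal-frequency discretization of the
continuous parameter (2 bins for small panels), which also makes it
invariant to monotone transforms of the parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["SnpMatrix", "MIScanResult", "PLSResult",
           "mutual_information", "mi_scan", "pls_fit",
           "pls_permutation_test", "param_lag_correlations",
           "equal_frequency_bins", "snp_matrix_from_alignment"]


class AssocError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SNP matrix


@dataclass
class SnpMatrix:
    """Strains x polymorphic-site allele matrix.

    ``alleles`` holds one categorical code (small int) per strain and site;
    gaps are their own category.  ``site_positions`` are 1-based alignment
    coordinates, strictly increasing.
    """

    strain_labels: list[str]
    site_positions: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.site_positions = np.asarray(self.site_positions, dtype=int)
        self.alleles = np.asarray(self.alleles)
        n, s = self.alleles.shape
        if len(self.strain_labels) != n or self.site_positions.size != s:
            raise AssocError("inconsistent SnpMatrix dimensions")
        if np.any(np.diff(self.site_positions) <= 0):
            raise AssocError("site positions must be strictly increasing")
        for j in range(s):
            if len(np.unique(self.alleles[:, j])) < 2:
                raise AssocError(f"site at position {self.site_positions[j]} "
                                 "is monomorphic")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


def snp_matrix_from_alignment(records: dict[str, str]) -> SnpMatrix:
    """Extract polymorphic columns from an aligned set of sequences.

    ``records`` maps strain label -> aligned sequence (equal lengths, '-'
    for gaps).  Every retained site has >= 2 allele classes among the
    strains; gap is a legitimate class (indel polymorphism retained).
    """
    labels = list(records)
    seqs = [records[l].upper() for l in labels]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AssocError("sequences are not aligned (unequal lengths)")
    arr = np.array([list(s) for s in seqs])
    positions, codes = [], []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        uniq = np.unique(col)
        if len(uniq) >= 2:
            positions.append(j + 1)  # 1-based coordinates
            lut = {c: k for k, c in enumerate(uniq)}
            codes.append([lut[c] for c in col])
    if not positions:
        raise AssocError("no polymorphic sites in alignment")
    return SnpMatrix(strain_labels=labels,
                     site_positions=np.array(positions),
                     alleles=np.array(codes).T)


# ---------------------------------------------------------------------------
# mutual information


def equal_frequency_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize a continuous vector into equal-frequency bins (0..n-1).

    Rank-based, so any strictly monotone transform of ``values`` yields the
    same bin labels.  Ties are broken by stable order.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, dtype=np.int64)
    bins[order] = (np.arange(n) * n_bins) // n
    return bins


def _mi_from_codes(x: np.ndarray, y: np.ndarray, kx: int, ky: int) -> float:
    """Plug-in MI (bits) between two integer-coded vectors."""
    joint = np.zeros((kx, ky))
    np.add.at(joint, (x, y), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] /
                                            np.outer(px, py)[nz])))


def default_n_bins(n_strains: int) -> int:
    """2 equal-frequency bins for small panels (n < 24), else 3."""
    return 2 if n_strains < 24 else 3


def mutual_information(param_values: np.ndarray, alleles: np.ndarray,
                       n_bins: int | None = None) -> float:
    """Plug-in MI (bits) between an allele category and a discretized
    continuous parameter.

    A constant parameter yields 0 bits with a warning; a monomorphic site
    is an error (it should have been filtered upstream).
    """
    param_values = np.asarray(param_values, dtype=float)
    alleles = np.asarray(alleles)
    if param_values.size != alleles.size:
        raise AssocError("parameter and allele vectors differ in length")
    if param_values.size < 6:
        raise AssocError("need at least 6 strains")
    uniq, codes = np.unique(alleles, return_inverse=True)
    if len(uniq) < 2:
        raise AssocError("monomorphic site reached mutual_information")
    if np.allclose(param_values, param_values[0]):
        logger.warning("constant parameter: MI = 0")
        return 0.0
    n_bins = n_bins or default_n_bins(param_values.size)
    bins = equal_frequency_bins(param_values, n_bins)
    return _mi_from_codes(codes, bins, len(uniq), n_bins)


@dataclass
class MIScanResult:
    """Per-site MI and family-wise-corrected permutation p for one scan."""

    parameter: str
    site_positions: np.ndarray
    mi: np.ndarray
    p_corrected: np.ndarray
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p_corrected <= self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.parameter,
                             "position": self.site_positions,
                             "mi_bits": self.mi,
                             "p_corrected": self.p_corrected,
                             "significant": self.significant})


def _scan_one(bins: np.ndarray, allele_codes: np.ndarray,
              n_classes: np.ndarray, n_bins: int) -> np.ndarray:
    """MI of one binned parameter against every site, vectorized."""
    n, s = allele_codes.shape
    kmax = int(n_classes.max())
    # joint counts per site via one flat bincount
    flat = (np.arange(s)[None, :] * (kmax * n_bins)
            + allele_codes * n_bins + bins[:, None])
    counts = np.bincount(flat.ravel(), minlength=s * kmax * n_bins)
    joint = counts.reshape(s, kmax, n_bins).astype(float) / n
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / (px * py))
    return np.nansum(term, axis=(1, 2))


def mi_scan(params_table: pd.DataFrame, snps: SnpMatrix,
            n_perm: int = 999, n_bins: int | None = None,
            seed: int = 0, alpha: float = 0.05) -> list[MIScanResult]:
    """MI of every parameter against every polymorphic site with
    max-statistic family-wise permutation correction.

    For each parameter the null records, per permutation of the parameter
    values across strains, the maximum MI over all sites;
    p_corrected(site) = (#{max_perm >= mi_obs} + 1) / (n_perm + 1).

    With few strains the plug-in MI is heavily tied (identical contingency
    tables give identical values), which would make the ">=" rule very
    conservative; ties between the observed MI and a permutation maximum
    are therefore broken by auxiliary uniform draws (a randomized test,
    exactly calibrated and still deterministic given the seed).
    """
    if n_perm < 199:
        raise AssocError("n_perm must be >= 199")
    common = [s for s in params_table.index if s in set(snps.strain_labels)]
    if len(common) < 6:
        raise AssocError("fewer than 6 strains shared between parameters "
                         "and SNP matrix")
    if len(common) < len(params_table.index) or len(common) < len(snps.strain_labels):
        logger.info("mi_scan: restricting to %d shared strains", len(common))
    row = {s: i for i, s in enumerate(snps.strain_labels)}
    alleles = snps.alleles[[row[s] for s in common]]
    # recode per site over the retained strains; sites may become monomorphic
    keep, codes_cols, n_classes = [], [], []
    for j in range(alleles.shape[1]):
        uniq, inv = np.unique(alleles[:, j], return_inverse=True)
        if len(uniq) >= 2:
            keep.append(j)
            codes_cols.append(inv)
            n_classes.append(len(uniq))
    if not keep:
        raise AssocError("no polymorphic sites among shared strains")
    allele_codes = np.column_stack(codes_cols)
    n_classes = np.array(n_classes)
    positions = snps.site_positions[keep]
    n = len(common)
    n_bins = n_bins or default_n_bins(n)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    results = []
    for pname in params_table.columns:
        y = params_table.loc[common, pname].to_numpy(dtype=float)
        u_obs = rng.uniform()               # tie-break draw for the observed scan
        u_perm = rng.uniform(size=n_perm)   # and one per permutation
        if np.allclose(y, y[0]):
            logger.warning("parameter %s constant: MI = 0 everywhere", pname)
            mi_obs = np.zeros(len(keep))
            p_corr = np.ones(len(keep))
        else:
            bins = equal_frequency_bins(y, n_bins)
            mi_obs = _scan_one(bins, allele_codes, n_classes, n_bins)
            max_null = np.empty(n_perm)
            for k in range(n_perm):
                max_null[k] = _scan_one(bins[perms[k]], allele_codes,
                                        n_classes, n_bins).max()
            diff = max_null[None, :] - mi_obs[:, None]
            beats = (diff > 1e-12) | ((np.abs(diff) <= 1e-12)
                                      & (u_perm[None, :] >= u_obs))
            p_corr = (beats.sum(axis=1) + 1) / (n_perm + 1)
        results.append(MIScanResult(parameter=pname, site_positions=positions,
                                    mi=mi_obs, p_corrected=p_corr, alpha=alpha))
    return results


# ---------------------------------------------------------------------------
# partial least squares (PLS1, NIPALS)


@dataclass
class PLSResult:
    """PLS1 decomposition of lag time on regulatory parameters.

    ``y_variance_explained`` is percent of response variance captured by
    each component (reduction in residual sum of squares); contributions
    are 100 * w_j^2 / sum_k w_k^2 per component.
    """

    variable_names: list[str]
    n_components: int
    x_weights: np.ndarray                 # variables x components
    y_variance_explained: np.ndarray      # per component, percent
    contributions: np.ndarray             # variables x components, percent
    dropped_variables: list[str] = field(default_factory=list)
    permutation_p: float | None = None

    @property
    def cumulative_variance_explained(self) -> np.ndarray:
        return np.cumsum(self.y_variance_explained)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for h in range(self.n_components):
            for j, v in enumerate(self.variable_names):
                recs.append({"component": h + 1, "variable": v,
                             "weight": self.x_weights[j, h],
                             "contribution_pct": self.contributions[j, h],
                             "component_y_variance_pct":
                                 self.y_variance_explained[h]})
        return pd.DataFrame(recs)


def _standardize_X(X: np.ndarray, names: list[str]
                   ) -> tuple[np.ndarray, list[str], list[str]]:
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.warning("PLS: dropping constant columns %s", dropped)
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Xs, [n for n, k in zip(names, keep) if k], dropped


def _pls1_components(Xs: np.ndarray, yc: np.ndarray, n_components: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """NIPALS PLS1: returns (weights variables x H, percent y variance per
    component)."""
    ss_total = float(yc @ yc)
    X = Xs.copy()
    y = yc.copy()
    p_vars = Xs.shape[1]
    W = np.zeros((p_vars, n_components))
    var_pct = np.zeros(n_components)
    for h in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm <= 1e-300:
            break
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            break
        p_load = X.T @ t / tt
        q = float(t @ y) / tt
        ss_before = float(y @ y)
        y = y - q * t
        X = X - np.outer(t, p_load)
        W[:, h] = w
        var_pct[h] = 100.0 * (ss_before - float(y @ y)) / ss_total
    return W, var_pct


def pls_fit(X: pd.DataFrame, y: np.ndarray | pd.Series,
            n_components: int = 4) -> PLSResult:
    """Fit PLS1 of a response on standardized predictors.

    X columns are z-scored internally (constant columns dropped with a
    warning); y is centered.  A constant y is an error.
    """
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if Xm.shape[0] != yv.size:
        raise AssocError("X and y disagree on the number of strains")
    if Xm.shape[0] < n_components + 2:
        raise AssocError("need at least n_components + 2 strains")
    if np.std(yv) == 0:
        raise AssocError("constant response")
    Xs, kept, dropped = _standardize_X(Xm, names)
    n_components = min(n_components, Xs.shape[1])
    yc = yv - yv.mean()
    W, var_pct = _pls1_components(Xs, yc, n_components)
    contrib = 100.0 * W ** 2  # columns of W are unit vectors
    return PLSResult(variable_names=kept, n_components=n_components,
                     x_weights=W, y_variance_explained=var_pct,
                     contributions=contrib, dropped_variables=dropped)


def pls_permutation_test(X: pd.DataFrame, y: np.ndarray | pd.Series,
                         n_perm: int = 999, seed: int = 0,
                         n_components: int = 4) -> dict:
    """Permutation significance of the PLS decomposition.

    Permutes the response across strains and records (i) component-1
    variance explained and (ii) the summed component-1 contribution of the
    two variables that contribute most in the observed fit.  p-values are
    (#{perm >= observed} + 1) / (n_perm + 1).
    """
    if n_perm < 199:
        raise AssocError("n_perm must be >= 199")
    obs = pls_fit(X, y, n_components=n_components)
    yv = np.asarray(y, dtype=float)
    Xs, kept, _ = _standardize_X(X.to_numpy(dtype=float), list(X.columns))
    top2 = np.argsort(obs.contributions[:, 0])[-2:]
    obs_var1 = float(obs.y_variance_explained[0])
    obs_top2 = float(obs.contributions[top2, 0].sum())
    rng = np.random.default_rng(seed)
    count_var = count_top2 = 0
    for _ in range(n_perm):
        yp = yv[rng.permutation(yv.size)]
        yc = yp - yp.mean()
        W, var_pct = _pls1_components(Xs, yc, 1)
        if var_pct[0] >= obs_var1 - 1e-12:
            count_var += 1
        if float(100.0 * (W[top2, 0] ** 2).sum()) >= obs_top2 - 1e-12:
            count_top2 += 1
    return {
        "observed_component1_variance_pct": obs_var1,
        "p_component1_variance": (count_var + 1) / (n_perm + 1),
        "top2_variables": [kept[i] for i in top2[::-1]],
        "observed_top2_contribution_pct": obs_top2,
        "p_top2_contribution": (count_top2 + 1) / (n_perm + 1),
        "n_perm": n_perm,
        "result": obs,
    }


# ---------------------------------------------------------------------------
# simple correlations


def param_lag_correlations(params_table: pd.DataFrame,
                           lags: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each parameter with lag time.

    No multiplicity correction is applied; the number of tests is logged.
    Zero-variance inputs yield NaN r with an ``undefined`` flag.
    """
    common = [s for s in params_table.index if s in lags.index
              and np.isfinite(lags[s])]
    if len(common) < 4:
        raise AssocError("need at least 4 paired observations")
    out = []
    for pname in params_table.columns:
        x = params_table.loc[common, pname].to_numpy(dtype=float)
        yv = lags.loc[common].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(yv) == 0:
            out.append({"parameter": pname, "r": np.nan, "p": np.nan,
                        "n": len(common), "undefined": True})
            continue
        r, p = stats.pearsonr(x, yv)
        out.append({"parameter": pname, "r": float(r), "p": float(p),
                    "n": len(common), "undefined": False})
    logger.info("param_lag_correlations: %d tests, no multiplicity correction",
                len(out))
    return pd.DataFrame(out).set_index("parameter")
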