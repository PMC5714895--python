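"""Five independent regulator -> module edge-scoring algorithms.

The inference target is the stacked regulator + module expression matrix:
rows are differentially expressed transcription factors followed by module
mean profiles; columns are (genotype, stage) conditions.  Candidate edges
are all (regulator, module) pairs.  Each engine returns a real-valued
score matrix in which larger means stronger evidence:

* ARACNE   - pairwise mutual information with data-processing-inequality
             triplet pruning of the weakest edge in each triangle.
* CLR      - mutual information z-scored against each endpoint's MI
             background, combined as sqrt(z_i^2 + z_j^2).
* GENIE3-style random-forest importance: per target module, the total
             variance-reduction importance of each regulator in a
             random-forest regression, normalized to sum 1.
* TIGRESS-style stability selection: selection frequency of each regulator
             in least-angle regressions over subsampled, randomly
             reweighted designs.
* Shrinkage partial correlation: |pcor| from the inverse of a
             Ledoit-Wolf-style shrunken correlation matrix (identity
             target, analytic shrinkage intensity).

Mutual information uses a plug-in estimator on a BxB discretization,
default B = ceil(sqrt(n)) with equal-width bins; an equal-frequency (rank)
option makes the MI-based engines invariant to monotone per-row
transforms.  With few conditions the plug-in estimator has a positive
bias of roughly (B-1)^2 / (2n) nats under independence; CLR's background
standardization and ARACNE's relative pruning are insensitive to this
shared offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lars

METHODS = ("aracne", "clr", "genie3", "tigress", "pcor")


@dataclass
class RegulatorModuleMatrix:
    """Stacked regulators + module means over identical condition columns."""

    data: pd.DataFrame
    regulators: list[str]
    modules: list[str]

    @property
    def n_regulators(self) -> int:
        return len(self.regulators)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def n_candidate_edges(self) -> int:
        return self.n_regulators * self.n_modules

    def regulator_data(self) -> pd.DataFrame:
        return self.data.loc[self.regulators]

    def module_data(self) -> pd.DataFrame:
        return self.data.loc[self.modules]


@dataclass
class ScoreMatrix:
    """Regulator x module edge scores from one inference method."""

    method: str
    scores: pd.DataFrame  # index = regulators, columns = modules

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError(f"{self.method}: non-finite scores")

    def long(self) -> pd.DataFrame:
        out = self.scores.stack().rename("score").reset_index()
        out.columns = ["regulator", "module", "score"]
        return out


def build_regulator_module_matrix(
    tf_expr: pd.DataFrame,
    module_means: pd.DataFrame,
    de_tfs: Sequence[str] | set[str] | None = None,
) -> RegulatorModuleMatrix:
    """Stack DE-TF expression profiles on top of module mean profiles.

    Constant regulator rows carry no information for any engine and are
    dropped with a warning naming the gene.
    """
    if list(tf_expr.columns) != list(module_means.columns):
        raise ValueError("condition columns differ between TF and module matrices")
    if de_tfs is not None:
        keep = [g for g in tf_expr.index if g in set(de_tfs)]
        tf_expr = tf_expr.loc[keep]
    const = tf_expr.index[tf_expr.std(axis=1) == 0].tolist()
    if const:
        warnings.warn(f"dropping constant regulator rows: {const}")
        tf_expr = tf_expr.drop(index=const)
    modules = [str(m) for m in module_means.index]
    mm = module_means.copy()
    mm.index = modules
    data = pd.concat([tf_expr, mm])
    if data.index.duplicated().any():
        raise ValueError("regulator and module row IDs collide")
    return RegulatorModuleMatrix(data=data, regulators=list(tf_expr.index), modules=modules)


# ---------------------------------------------------------------------------
# mutual information


def _discretize(x: np.ndarray, bins: int, strategy: str) -> np.ndarray:
    if strategy == "width":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros(len(x), dtype=int)
        edges = np.linspace(lo, hi, bins + 1)
        idx = np.searchsorted(edges[1:-1], x, side="right")
        return idx
    if strategy == "frequency":
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x), dtype=int)
        ranks[order] = np.arange(len(x))
        return (ranks * bins) // len(x)
    raise ValueError(f"unknown discretization strategy {strategy!r}")


def mutual_information(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    bins: int | None = None,
    strategy: str = "width",
) -> float:
    """Plug-in MI (nats) on a bins x bins discretization of (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    B = bins if bins is not None else int(np.ceil(np.sqrt(n)))
    ix = _discretize(x, B, strategy)
    iy = _discretize(y, B, strategy)
    joint = np.zeros((B, B))
    np.add.at(joint, (ix, iy), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())
    return max(mi, 0.0)


def mi_matrix(
    data: pd.DataFrame, bins: int | None = None, strategy: str = "width"
) -> pd.DataFrame:
    """Symmetric all-pairs MI over the rows of ``data`` (diagonal = 0)."""
    vals = data.to_numpy(dtype=float)
    n_rows, n = vals.shape
    B = bins if bins is not None else int(np.ceil(np.sqrt(n)))
    disc = np.stack([_discretize(vals[i], B, strategy) for i in range(n_rows)])
    # joint histograms via flat codes: pair (i,j) -> code disc_i * B + disc_j
    out = np.zeros((n_rows, n_rows))
    logn = np.log(n)
    marg = np.stack([np.bincount(disc[i], minlength=B) for i in range(n_rows)]).astype(float)
    for i in range(n_rows):
        codes_i = disc[i] * B
        for j in range(i + 1, n_rows):
            counts = np.bincount(codes_i + disc[j], minlength=B * B).astype(float)
            nz = counts > 0
            joint = counts[nz] / n
            pij = (np.outer(marg[i], marg[j]).ravel()[nz]) / (n * n)
            mi = float((joint * np.log(joint / pij)).sum())
            out[i, j] = out[j, i] = max(mi, 0.0)
    return pd.DataFrame(out, index=data.index, columns=data.index)


def dpi_prune(mi: pd.DataFrame | np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    """Data-processing-inequality mask: True where the edge survives.

    For every triplet (i, j, k) the edge (i, j) is removed when
    MI_ij < min(MI_ik, MI_jk) * (1 - epsilon); all comparisons use the
    original MI matrix, so pruning order does not matter.
    """
    W = np.asarray(mi, dtype=float)
    n = W.shape[0]
    keep = np.ones((n, n), dtype=bool)
    for k in range(n):
        col = W[:, k]
        thresh = np.minimum.outer(col, col) * (1.0 - epsilon)
        bad = W < thresh
        bad[k, :] = False
        bad[:, k] = False
        keep &= ~bad
    np.fill_diagonal(keep, False)
    return keep


def aracne_scores(
    M: RegulatorModuleMatrix,
    dpi_epsilon: float = 0.1,
    bins: int | None = None,
    strategy: str = "width",
    mi: pd.DataFrame | None = None,
) -> ScoreMatrix:
    """ARACNE: MI with DPI triplet pruning; pruned pairs score 0."""
    if mi is None:
        mi = mi_matrix(M.data, bins=bins, strategy=strategy)
    keep = dpi_prune(mi, epsilon=dpi_epsilon)
    pruned = mi.to_numpy() * keep
    full = pd.DataFrame(pruned, index=mi.index, columns=mi.columns)
    return ScoreMatrix("aracne", full.loc[M.regulators, M.modules])


def clr_scores(
    M: RegulatorModuleMatrix,
    bins: int | None = None,
    strategy: str = "width",
    mi: pd.DataFrame | None = None,
) -> ScoreMatrix:
    """Context likelihood of relatedness from the all-pairs MI matrix."""
    if mi is None:
        mi = mi_matrix(M.data, bins=bins, strategy=strategy)
    W = mi.to_numpy(dtype=float).copy()
    n = W.shape[0]
    offdiag = ~np.eye(n, dtype=bool)
    means = np.array([W[i, offdiag[i]].mean() for i in range(n)])
    sds = np.array([W[i, offdiag[i]].std() for i in range(n)])
    z = np.zeros_like(W)
    rows_ok = sds > 0
    z[rows_ok] = np.maximum(0.0, (W[rows_ok] - means[rows_ok, None]) / sds[rows_ok, None])
    clr = np.sqrt(z**2 + z.T**2)
    full = pd.DataFrame(clr, index=mi.index, columns=mi.columns)
    return ScoreMatrix("clr", full.loc[M.regulators, M.modules])


# ---------------------------------------------------------------------------
# regression-based engines


def genie3_scores(
    M: RegulatorModuleMatrix,
    n_trees: int = 1000,
    seed: int = 0,
    max_features: str | float = "sqrt",
) -> ScoreMatrix:
    """Random-forest importance of each regulator for each module profile."""
    if M.n_regulators < 2:
        raise ValueError("need at least 2 regulators")
    X = M.regulator_data().to_numpy(dtype=float).T  # conditions x regulators
    out = np.zeros((M.n_regulators, M.n_modules))
    for t, mod in enumerate(M.modules):
        y = M.data.loc[mod].to_numpy(dtype=float)
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=seed + t,
            n_jobs=1,
        ).fit(X, y)
        imp = rf.feature_importances_
        s = imp.sum()
        out[:, t] = imp / s if s > 0 else 0.0
    return ScoreMatrix("genie3", pd.DataFrame(out, index=M.regulators, columns=M.modules))


def tigress_scores(
    M: RegulatorModuleMatrix,
    n_resamples: int = 200,
    alpha_noise: float = 0.2,
    L_steps: int = 5,
    seed: int = 0,
) -> ScoreMatrix:
    """Stability-selection frequency of each regulator under LARS.

    Each resample takes half the conditions without replacement, multiplies
    every regulator column by an independent Uniform(alpha_noise, 1)
    weight, and runs least-angle regression for L_steps; the score is the
    fraction of resamples in which the regulator enters the path.
    """
    n_cond = M.data.shape[1]
    if n_cond < 6:
        raise ValueError("need at least 6 conditions for half-subsampling")
    rng = np.random.default_rng(seed)
    X_full = M.regulator_data().to_numpy(dtype=float).T
    Y = M.module_data().to_numpy(dtype=float)
    half = n_cond // 2
    counts = np.zeros((M.n_regulators, M.n_modules))
    for _ in range(n_resamples):
        idx = rng.choice(n_cond, size=half, replace=False)
        w = rng.uniform(alpha_noise, 1.0, size=M.n_regulators)
        Xs = X_full[idx] * w
        for t in range(M.n_modules):
            y = Y[t, idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = Lars(n_nonzero_coefs=L_steps).fit(Xs, y)
            counts[model.coef_ != 0, t] += 1
    return ScoreMatrix(
        "tigress", pd.DataFrame(counts / n_resamples, index=M.regulators, columns=M.modules)
    )


# ---------------------------------------------------------------------------
# shrinkage partial correlation


def shrinkage_intensity(data: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the identity correlation target.

    lambda* = sum_{i<j} Var_hat(r_ij) / sum_{i<j} r_ij^2, clipped to [0, 1]
    (the Schafer-Strimmer estimator for the identity target).
    """
    p, n = data.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    x = data - data.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    xs = x / sd[:, None]
    r = (xs @ xs.T) / (n - 1)
    # Var_hat(r_ij) = n / (n-1)^3 * sum_k (w_kij - mean_k w_kij)^2
    num = 0.0
    den = 0.0
    for i in range(p):
        w = xs[i][None, :] * xs[i + 1 :]  # (p - i - 1) x n products
        wbar = w.mean(axis=1)
        var = n / (n - 1) ** 3 * ((w - wbar[:, None]) ** 2).sum(axis=1)
        num += var.sum()
        den += (r[i, i + 1 :] ** 2).sum()
    if den == 0:
        return 1.0
    return float(np.clip(num / den, 0.0, 1.0))


def partial_correlations(data: np.ndarray, lam: float | None = None) -> np.ndarray:
    """Partial correlations from a shrunken correlation matrix.

    R* = lam * I + (1 - lam) * R; pcor_ij = -Omega_ij / sqrt(Omega_ii
    Omega_jj) with Omega = (R*)^-1.  lam=None selects the analytic
    intensity.
    """
    x = np.asarray(data, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    xs = x / sd[:, None]
    n = x.shape[1]
    R = (xs @ xs.T) / (n - 1)
    np.fill_diagonal(R, 1.0)
    if lam is None:
        lam = shrinkage_intensity(np.asarray(data, dtype=float))
    Rstar = lam * np.eye(R.shape[0]) + (1.0 - lam) * R
    try:
        omega = np.linalg.inv(Rstar)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "shrunken correlation matrix is singular; use analytic shrinkage (lam=None)"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def pcor_scores(M: RegulatorModuleMatrix, lam: float | None = None) -> ScoreMatrix:
    """|shrinkage partial correlation| on regulator -> module pairs."""
    if M.data.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    pcor = partial_correlations(M.data.to_numpy(dtype=float), lam=lam)
    full = pd.DataFrame(np.abs(pcor), index=M.data.index, columns=M.data.index)
    return ScoreMatrix("pcor", full.loc[M.regulators, M.modules])


# ---------------------------------------------------------------------------
# orchestration


def rank_normalize(sm: ScoreMatrix) -> ScoreMatrix:
    """Min-max normalized ranks of the flattened scores (ties averaged)."""
    flat = sm.scores.to_numpy(dtype=float).ravel()
    ranks = pd.Series(flat).rank(method="average").to_numpy()
    span = ranks.max() - ranks.min()
    ranks = (ranks - ranks.min()) / span if span > 0 else np.zeros_like(ranks)
    out = pd.DataFrame(
        ranks.reshape(sm.scores.shape), index=sm.scores.index, columns=sm.scores.columns
    )
    return ScoreMatrix(sm.method, out)


def run_all_methods(
    M: RegulatorModuleMatrix,
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    bins: int | None = None,
    strategy: str = "width",
    dpi_epsilon: float = 0.1,
    n_trees: int = 1000,
    n_resamples: int = 200,
    L_steps: int = 5,
    alpha_noise: float = 0.2,
    normalize: bool = True,
) -> dict[str, ScoreMatrix]:
    """Run the requested engines, sharing one MI matrix between ARACNE and CLR."""
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    mi = None
    if "aracne" in methods or "clr" in methods:
        mi = mi_matrix(M.data, bins=bins, strategy=strategy)
    out: dict[str, ScoreMatrix] = {}
    for method in methods:
        if method == "aracne":
            sm = aracne_scores(M, dpi_epsilon=dpi_epsilon, mi=mi)
        elif method == "clr":
            sm = clr_scores(M, mi=mi)
        elif method == "genie3":
            sm = genie3_scores(M, n_trees=n_trees, seed=seed)
        elif method == "tigress":
            sm = tigress_scores(
                M, n_resamples=n_resamples, alpha_noise=alpha_noise, L_steps=L_steps, seed=seed
            )
        else:
            sm = pcor_scores(M)
        out[method] = rank_normalize(sm) if normalize else sm
    return out
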