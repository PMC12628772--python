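"""The diversity-to-function statistical core.

Principal coordinates of Bray-Curtis dissimilarities, standardized multiple
linear regression of a process rate on composition axes or alpha-diversity
metrics across community slices and correlation cutoffs, time-lagged
variants, random-forest permutation importance, and distance-based
redundancy analysis with forward AIC selection and hierarchical
partitioning of the constrained variance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg
from sklearn.tree import DecisionTreeRegressor

from .diversity import alpha_diversity, bray_curtis
from .subcommunity import SubcommunitySet, subset_table

log = logging.getLogger("nitrilink")

_EIG_TOL = 1e-9


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinate scores with the full eigenvalue spectrum."""

    scores: pd.DataFrame          # samples x retained positive axes
    eigenvalues: np.ndarray       # all eigenvalues, sorted descending
    proportion_explained: np.ndarray  # per retained axis, over positive sum


@dataclass(frozen=True)
class RegressionSummary:
    response: str
    predictors: tuple
    coefficients: tuple          # standardized
    r2: float
    adj_r2: float
    model_p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.model_p < 0.05


@dataclass(frozen=True)
class ImportanceTable:
    importances: pd.Series       # permutation increase in OOB MSE
    ranks: pd.Series             # 1 = most important
    oob_r2: float
    best_mtry: int


@dataclass(frozen=True)
class PartitionResult:
    individual: pd.Series        # per-variable individual effect
    total_constrained: float


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1); may be negative."""
    if n - p - 1 <= 0:
        raise ValueError("need n > p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def pcoa(distance: pd.DataFrame, n_axes: int = 3) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Gower double-centering B = -1/2 J (D o D) J followed by an
    eigendecomposition; sample scores are eigenvectors scaled by sqrt of
    their (positive) eigenvalues.  Negative eigenvalues are retained in the
    reported spectrum but excluded from the scores.
    """
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > _EIG_TOL * max(1.0, abs(eigval[0]))
    n_pos = int(positive.sum())
    if n_pos < n_axes:
        log.warning(
            "only %d positive eigenvalue(s) available (requested %d axes)",
            n_pos, n_axes,
        )
    m = min(n_axes, n_pos)
    scores = eigvec[:, :m] * np.sqrt(eigval[:m])
    pos_sum = eigval[positive].sum()
    prop = eigval[:m] / pos_sum if pos_sum > 0 else np.zeros(m)
    return OrdinationResult(
        pd.DataFrame(
            scores,
            index=distance.index,
            columns=[f"PCo{i + 1}" for i in range(m)],
        ),
        eigval,
        prop,
    )


def _standardize_columns(x: pd.DataFrame):
    """Z-score columns (ddof=1); zero-variance columns dropped with warning."""
    sds = x.std(ddof=1)
    keep = sds > 0
    dropped = list(x.columns[~keep])
    if dropped:
        log.warning("dropping zero-variance predictor(s): %s", dropped)
    z = (x.loc[:, keep] - x.loc[:, keep].mean()) / sds[keep]
    return z, dropped


def fit_mlr(y, x: pd.DataFrame, response: str = "rate") -> RegressionSummary:
    """Ordinary least squares on standardized response and predictors.

    Both sides are centered to mean 0 and scaled to unit variance, so the
    coefficients are standardized (comparable across predictors).  Reports
    R-squared, adjusted R-squared, and the overall F-test p-value.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=x.index)
    n, p = len(x), x.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if x.isna().any().any() or y.isna().any():
        raise ValueError("missing values in the design")
    z, _ = _standardize_columns(x)
    if z.shape[1] < x.shape[1] and z.shape[1] == 0:
        raise CollinearityError(f"all predictors constant: {list(x.columns)}")
    rank = np.linalg.matrix_rank(z.to_numpy())
    if rank < z.shape[1]:
        _, _, piv = linalg.qr(z.to_numpy(), pivoting=True)
        culprits = [z.columns[i] for i in piv[rank:]]
        raise CollinearityError(f"collinear predictor columns: {culprits}")
    ysd = y.std(ddof=1)
    yz = (y - y.mean()) / ysd if ysd > 0 else y - y.mean()
    model = sm.OLS(yz.to_numpy(), sm.add_constant(z.to_numpy())).fit()
    r2 = float(model.rsquared)
    p_eff = z.shape[1]
    pval = float(model.f_pvalue)
    if not np.isfinite(pval):
        pval = 0.0 if r2 > 1.0 - 1e-12 else 1.0
    return RegressionSummary(
        response=response,
        predictors=tuple(z.columns),
        coefficients=tuple(float(c) for c in model.params[1:]),
        r2=r2,
        adj_r2=adjusted_r2(r2, n, p_eff),
        model_p=pval,
        n=n,
    )


def composition_model(
    rate, counts: pd.DataFrame, n_axes: int = 3, response: str = "rate"
) -> RegressionSummary:
    """Bray-Curtis -> PCoA -> regression of the rate on the leading axes."""
    ord_res = pcoa(bray_curtis(counts), n_axes=n_axes)
    return fit_mlr(rate, ord_res.scores, response=response)


def composition_models(
    rate,
    counts: pd.DataFrame,
    sets_per_cutoff: dict,
    nitrifiers: SubcommunitySet | None = None,
    n_axes: int = 3,
) -> pd.DataFrame:
    """Per-cutoff composition regressions plus the two baselines.

    Returns one record per (community slice, cutoff): slices are the swept
    associated subcommunities, the total community, and (when ``nitrifiers``
    is given) the nitrifier subcommunity.  Empty or too-small sets are
    skipped with a record carrying NaN statistics.
    """
    records = []

    def run(slice_name, cutoff, table):
        if table.shape[1] == 0:
            log.info("skipping empty slice %s at cutoff %s", slice_name, cutoff)
            return dict(
                community_slice=slice_name, cutoff=cutoff, n=len(table),
                n_taxa=0, r2=np.nan, adj_r2=np.nan, p_model=np.nan,
                significant=False,
            )
        summ = composition_model(rate, table, n_axes=n_axes)
        return dict(
            community_slice=slice_name, cutoff=cutoff, n=summ.n,
            n_taxa=table.shape[1], r2=summ.r2, adj_r2=summ.adj_r2,
            p_model=summ.model_p, significant=summ.significant,
        )

    records.append(run("total", np.nan, counts))
    if nitrifiers is not None:
        records.append(
            run("nitrifier", np.nan, subset_table(counts, nitrifiers))
        )
    for cutoff, sub in sorted(sets_per_cutoff.items()):
        records.append(run("associated", cutoff, subset_table(counts, sub)))
    return pd.DataFrame(records)


def diversity_models(rate, alpha_by_slice: dict) -> pd.DataFrame:
    """One three-predictor model (richness/shannon/simpson) per slice."""
    rows = []
    for slice_name, alpha in alpha_by_slice.items():
        predictors = alpha.loc[:, ["richness", "shannon", "simpson"]]
        cond = np.linalg.cond(
            (predictors - predictors.mean()).to_numpy()
            / np.maximum(predictors.std(ddof=1).to_numpy(), 1e-12)
        )
        if cond > 1e6:
            log.warning(
                "alpha metrics nearly collinear in slice %s (cond=%.3g)",
                slice_name, cond,
            )
        summ = fit_mlr(rate, predictors)
        rows.append(
            dict(
                community_slice=slice_name,
                n=summ.n,
                predictors=",".join(summ.predictors),
                coefficients=",".join(f"{c:.4f}" for c in summ.coefficients),
                r2=summ.r2,
                adj_r2=summ.adj_r2,
                p_model=summ.model_p,
            )
        )
    return pd.DataFrame(rows)


def lag_models(
    rate: pd.Series,
    scores: pd.DataFrame,
    dates: pd.Series,
    lags=(0, 2, 4, 6, 8),
) -> pd.DataFrame:
    """Composition at day t regressed against the rate at day t + L.

    ``dates`` maps each sample to its calendar day.  Unmatched days are
    dropped; the per-lag n is reported.  Models with fewer than p + 2
    matched pairs are skipped with a NaN record.
    """
    dates = pd.to_datetime(pd.Series(dates, index=scores.index))
    date_to_sample = pd.Series(dates.index.values, index=dates.values)
    rows = []
    for lag in lags:
        target_dates = dates + pd.Timedelta(days=int(lag))
        matched = target_dates.isin(date_to_sample.index)
        x = scores.loc[matched.values]
        pair = date_to_sample.loc[target_dates[matched.values]].values
        y = rate.loc[pair].to_numpy()
        if len(x) < x.shape[1] + 2:
            log.warning("lag %d: too few matched pairs (%d)", lag, len(x))
            rows.append(dict(lag=lag, n=len(x), r2=np.nan, adj_r2=np.nan,
                             p_model=np.nan))
            continue
        summ = fit_mlr(y, x)
        rows.append(dict(lag=lag, n=summ.n, r2=summ.r2, adj_r2=summ.adj_r2,
                         p_model=summ.model_p))
    return pd.DataFrame(rows)


def rf_importance(
    rate,
    predictors: pd.DataFrame,
    n_trees: int = 1000,
    seed: int = 0,
    mtry_grid=None,
) -> ImportanceTable:
    """Random-forest permutation importance with out-of-bag tuning.

    A bagged ensemble of regression trees is grown for each candidate
    number of per-split predictors (mtry); the grid value minimizing the
    out-of-bag mean squared error is kept.  Importance of a variable is the
    mean over trees of the increase in out-of-bag MSE when that variable is
    permuted; the overall fit is the out-of-bag R-squared.
    """
    y = np.asarray(rate, dtype=float)
    x = predictors.to_numpy(dtype=float)
    n, p = x.shape
    if n < 10:
        raise ValueError("need at least 10 samples for out-of-bag estimation")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in the design")
    if mtry_grid is None:
        mtry_grid = sorted(
            {1, max(1, p // 3), max(1, int(math.sqrt(p))), max(1, p // 2), p}
        )
    rng = np.random.default_rng(seed)

    def grow(mtry, forest_rng):
        trees = []
        for _ in range(n_trees):
            idx = forest_rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeRegressor(
                max_features=mtry,
                random_state=int(forest_rng.integers(2**31)),
            )
            tree.fit(x[idx], y[idx])
            trees.append((tree, oob))
        return trees

    def oob_mse(trees):
        pred_sum = np.zeros(n)
        pred_cnt = np.zeros(n)
        for tree, oob in trees:
            if oob.any():
                pred_sum[oob] += tree.predict(x[oob])
                pred_cnt[oob] += 1
        seen = pred_cnt > 0
        resid = y[seen] - pred_sum[seen] / pred_cnt[seen]
        return float(np.mean(resid**2))

    best = None
    for mtry in mtry_grid:
        trees = grow(mtry, np.random.default_rng(rng.integers(2**63)))
        mse = oob_mse(trees)
        if best is None or mse < best[0]:
            best = (mse, mtry, trees)
    best_mse, best_mtry, trees = best

    increases = np.zeros(p)
    perm_rng = np.random.default_rng(rng.integers(2**63))
    for tree, oob in trees:
        if not oob.any():
            continue
        base = np.mean((y[oob] - tree.predict(x[oob])) ** 2)
        xo = x[oob]
        for j in range(p):
            xp = xo.copy()
            xp[:, j] = perm_rng.permutation(xp[:, j])
            increases[j] += np.mean((y[oob] - tree.predict(xp)) ** 2) - base
    increases /= len(trees)
    imp = pd.Series(increases, index=predictors.columns, name="importance")
    ranks = imp.rank(ascending=False, method="first").astype(int)
    oob_r2 = 1.0 - best_mse / np.var(y)
    return ImportanceTable(imp, ranks, float(oob_r2), int(best_mtry))


# ---------------------------------------------------------------------------
# distance-based redundancy analysis


def _response_coordinates(distance: pd.DataFrame) -> np.ndarray:
    """All positive-eigenvalue PCoA axes, as the db-RDA response."""
    ord_res = pcoa(distance, n_axes=len(distance))
    return ord_res.scores.to_numpy()


def _standardize_env(env: pd.DataFrame) -> np.ndarray:
    sds = env.std(ddof=1)
    bad = list(env.columns[sds <= 0])
    if bad:
        raise CollinearityError(f"constant environmental columns: {bad}")
    return ((env - env.mean()) / sds).to_numpy()


def _constrained_fraction(y: np.ndarray, e: np.ndarray) -> float:
    """Fraction of total response trace captured by the fitted values."""
    if e.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(e, y, rcond=None)
    fitted = e @ beta
    total = np.sum(y**2)
    return float(np.sum(fitted**2) / total) if total > 0 else 0.0


def dbrda(distance: pd.DataFrame, env: pd.DataFrame):
    """Distance-based redundancy analysis.

    Regresses all positive PCoA axes of the distance matrix on the
    standardized environmental table.  Returns the constrained fraction of
    variance, constrained axis scores, and per-axis eigenvalues.
    """
    y = _response_coordinates(distance)
    e = _standardize_env(env)
    n = y.shape[0]
    if n <= e.shape[1]:
        raise ValueError("need more samples than environmental variables")
    if np.linalg.matrix_rank(e) < e.shape[1]:
        _, _, piv = linalg.qr(e, pivoting=True)
        rank = np.linalg.matrix_rank(e)
        raise CollinearityError(
            f"collinear environmental columns: "
            f"{[env.columns[i] for i in piv[rank:]]}"
        )
    beta, *_ = np.linalg.lstsq(e, y, rcond=None)
    fitted = e @ beta
    fraction = float(np.sum(fitted**2) / np.sum(y**2))
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    n_axes = int(np.sum(s**2 > _EIG_TOL * max(1.0, s[0] ** 2 if len(s) else 1)))
    scores = pd.DataFrame(
        (u[:, :n_axes] * s[:n_axes]),
        index=distance.index,
        columns=[f"dbRDA{i + 1}" for i in range(n_axes)],
    )
    eigenvalues = s[:n_axes] ** 2
    return fraction, scores, eigenvalues


def aic_select(
    distance: pd.DataFrame, env: pd.DataFrame, direction: str = "forward"
) -> list:
    """Greedy forward selection of environmental variables by AIC.

    AIC = n ln(RSS/n) + 2k on the residual trace of the multivariate fit,
    with k = number of selected variables + 1.  Selection stops when no
    addition lowers the AIC; the path is deterministic.
    """
    if direction != "forward":
        raise ValueError("only forward selection is implemented")
    y = _response_coordinates(distance)
    e = _standardize_env(env)
    n = y.shape[0]
    total = np.sum(y**2)

    def aic(cols):
        frac = _constrained_fraction(y, e[:, cols]) if cols else 0.0
        rss = total * (1.0 - frac)
        return n * np.log(max(rss, 1e-300) / n) + 2.0 * (len(cols) + 1)

    selected: list = []
    current = aic(selected)
    remaining = list(range(e.shape[1]))
    while remaining:
        scores = [(aic(selected + [j]), j) for j in remaining]
        best_aic, best_j = min(scores)
        if best_aic >= current - 1e-12:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        current = best_aic
    return [env.columns[j] for j in selected]


def hierarchical_partition(
    distance: pd.DataFrame, env: pd.DataFrame
) -> PartitionResult:
    """Individual effects of each variable, averaged over all orderings.

    The individual effect of variable v is the Chevan-Sutherland weighted
    sum over subsets S not containing v of fraction(S + v) - fraction(S),
    with weights |S|! (p - |S| - 1)! / p!.  The effects sum exactly to the
    full-model constrained fraction.
    """
    p = env.shape[1]
    if p > 15:
        raise ValueError(
            "hierarchical partitioning enumerates 2^p subsets; pre-select "
            "variables to at most 15"
        )
    y = _response_coordinates(distance)
    e = _standardize_env(env)
    fractions = {}
    for r in range(p + 1):
        for subset in itertools.combinations(range(p), r):
            fractions[subset] = _constrained_fraction(y, e[:, list(subset)])
    effects = np.zeros(p)
    fact = [math.factorial(i) for i in range(p + 1)]
    for v in range(p):
        others = [j for j in range(p) if j != v]
        for r in range(p):
            w = fact[r] * fact[p - r - 1] / fact[p]
            for subset in itertools.combinations(others, r):
                with_v = tuple(sorted(subset + (v,)))
                effects[v] += w * (fractions[with_v] - fractions[subset])
    return PartitionResult(
        pd.Series(effects, index=env.columns, name="individual_effect"),
        fractions[tuple(range(p))],
    )


def plot_cutoff_curve(results: pd.DataFrame, path) -> None:
    """SVG of adjusted R-squared across the cutoff sweep with baselines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    assoc = results[results["community_slice"] == "associated"].dropna(
        subset=["adj_r2"]
    )
    sig = assoc["significant"].astype(bool)
    ax.plot(assoc["cutoff"], assoc["adj_r2"], color="tab:blue", zorder=1)
    ax.scatter(
        assoc.loc[sig, "cutoff"], assoc.loc[sig, "adj_r2"],
        color="tab:blue", zorder=2, label="associated (p < 0.05)",
    )
    ax.scatter(
        assoc.loc[~sig, "cutoff"], assoc.loc[~sig, "adj_r2"],
        facecolors="none", edgecolors="tab:blue", zorder=2,
        label="associated (p >= 0.05)",
    )
    for slice_name, color in (("total", "gray"), ("nitrifier", "goldenrod")):
        row = results[results["community_slice"] == slice_name]
        if len(row):
            ax.axhline(
                row["adj_r2"].iloc[0], ls="--", color=color, label=slice_name
            )
    ax.set_xlabel("correlation cutoff")
    ax.set_ylabel("adjusted $R^2$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
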