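"""Statistical analysis of ammonia-oxidation drivers.

Four tools, matching common practice in seasonal limnology studies:

* seasonal group comparison — Kruskal–Wallis omnibus test plus pairwise Dunn
  z-tests with Holm correction and a compact letter display;
* paired t-tests for depth and diel contrasts;
* forward-selection least-squares multiple regression (partial-F entry rule)
  of rates on environmental covariates;
* a univariate regression tree (binary recursive partitioning, cost-complexity
  pruning, tree size chosen at the lowest seeded k-fold cross-validation
  error) to expose non-linear thresholds, with factors handled by exhaustive
  subset search.

Plus the Pearson correlation used for the nitrification product
(NO₃⁻ + NO₂⁻), which is excluded from the regressions as a response-coupled
variable.
"""

from __future__ import annotations

import copy
import datetime as _dt
import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SeasonalSample",
    "GroupComparison",
    "MLRModel",
    "TreeModel",
    "compare_groups",
    "paired_test",
    "forward_mlr",
    "fit_urt",
    "correlate",
    "transform_covariates",
]


@dataclass
class SeasonalSample:
    """One date × depth × diel environmental observation."""

    date: _dt.date
    season: str  # {winter, spring, summer, autumn}
    depth_label: str  # {top, bottom}
    diel: str  # {day, night}
    nh4: float  # µmol L⁻¹
    no3no2: float  # µmol L⁻¹
    o2: float  # mg L⁻¹
    temp: float  # °C
    light_fraction: float  # I_z/I_0 in [0, 1]
    under_ice: bool
    chla: Optional[float] = None  # µg L⁻¹
    ao_rate: Optional[float] = None  # nmol L⁻¹ d⁻¹
    delta_n2o: Optional[float] = None  # nmol L⁻¹

    def __post_init__(self) -> None:
        if self.season not in ("winter", "spring", "summer", "autumn"):
            raise ValueError(f"bad season {self.season!r}")
        if not 0 <= self.light_fraction <= 1:
            raise ValueError("light_fraction must be in [0, 1]")
        if self.under_ice and self.light_fraction != 0:
            raise ValueError("light_fraction must be 0 under ice")


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, z, p_raw, p_adj
    letters: dict  # group -> compact letter display string
    alpha: float


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's z statistics on joint ranks with tie correction."""
    n = values.size
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    groups = list(dict.fromkeys(labels))  # preserve order of appearance
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int(np.sum(labels == g)) for g in groups}
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[g1] + 1.0 / sizes[g2])
        )
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_raw": p})
    return pd.DataFrame(rows)


def _compact_letters(groups: Sequence, significant: set, alpha: float) -> dict:
    """Compact letter display: groups sharing a letter are not significantly
    different. Letters are the maximal all-non-significant cliques."""
    groups = list(groups)
    cliques = []
    for r in range(len(groups), 0, -1):
        for subset in itertools.combinations(groups, r):
            if any(
                frozenset((a, b)) in significant
                for a, b in itertools.combinations(subset, 2)
            ):
                continue
            if any(set(subset) <= set(c) for c in cliques):
                continue
            cliques.append(subset)
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return letters


def compare_groups(values: Sequence[float], groups: Sequence, alpha: float = 0.05) -> GroupComparison:
    """Kruskal–Wallis omnibus test with Dunn/Holm pairwise follow-up.

    Returns the H statistic and p-value, a pairwise table with raw and
    Holm-adjusted p-values, and a compact letter display at ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    names = list(dict.fromkeys(labels))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [values[labels == g] for g in names]
    if any(len(v) < 2 for v in by_group):
        raise ValueError("need at least 2 values per group")
    if np.ptp(values) == 0:
        raise ValueError("degenerate: all observations tied")
    h, p = stats.kruskal(*by_group)
    pw = _dunn_pairwise(values, labels)
    pw["p_adj"] = multipletests(pw["p_raw"].to_numpy(), method="holm")[1]
    significant = {
        frozenset((r.group1, r.group2))
        for r in pw.itertuples()
        if r.p_adj < alpha
    }
    letters = _compact_letters(names, significant, alpha)
    return GroupComparison(float(h), float(p), pw, letters, alpha)


def paired_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test on the differences a−b; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return 0.0, 1.0
        raise ValueError("degenerate: constant nonzero difference, zero variance")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def correlate(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation coefficient and p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 pairs of equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# forward-selection multiple linear regression
# ---------------------------------------------------------------------------


@dataclass
class MLRModel:
    selected: list  # variable names in order of entry
    coefficients: dict  # standardized-scale slopes + "const"
    r2: float
    entry_pvalues: dict  # partial-F p at entry
    transform_log: dict = field(default_factory=dict)  # var -> offset used


def transform_covariates(table: pd.DataFrame, skew_threshold: float = 1.0):
    """Normality-improving transform: right-skewed non-negative columns get
    log₁₀(x + half the minimum positive value); others pass through.

    Returns the transformed table and a metadata dict ``{column: offset}`` for
    the columns that were transformed.
    """
    out = table.copy()
    meta: dict = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if np.any(x < 0) or np.ptp(x) == 0:
            continue
        if stats.skew(x) > skew_threshold:
            positive = x[x > 0]
            if positive.size == 0:
                continue
            offset = 0.5 * positive.min()
            out[col] = np.log10(x + offset)
            meta[col] = offset
    return out, meta


def forward_mlr(
    response: Sequence[float],
    covariates: pd.DataFrame,
    entry_alpha: float = 0.05,
) -> MLRModel:
    """Greedy forward selection: at each step the candidate with the smallest
    partial-F p-value enters if p < ``entry_alpha``.

    Covariates are standardized internally (zero mean, unit SD), so the
    reported coefficients are on the standardized scale. Collinear candidates
    that make the design singular are skipped.
    """
    y = np.asarray(response, dtype=float)
    if y.size < 8:
        raise ValueError("need at least 8 samples")
    X = covariates.copy()
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        X[col] = (x - x.mean()) / sd if sd > 0 else 0.0

    selected: list = []
    entry_p: dict = {}
    n = y.size
    rss_current = float(np.sum((y - y.mean()) ** 2))
    while True:
        best = None
        for cand in X.columns:
            if cand in selected:
                continue
            cols = selected + [cand]
            design = sm.add_constant(X[cols].to_numpy())
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue  # collinear candidate
            fit = sm.OLS(y, design).fit()
            rss_new = float(fit.ssr)
            k = design.shape[1]
            dof = n - k
            if dof <= 0 or rss_new <= 0:
                continue
            f = (rss_current - rss_new) / (rss_new / dof)
            p = float(stats.f.sf(f, 1, dof))
            if best is None or p < best[1]:
                best = (cand, p, rss_new)
        if best is None or best[1] >= entry_alpha:
            break
        selected.append(best[0])
        entry_p[best[0]] = best[1]
        rss_current = best[2]

    if selected:
        design = sm.add_constant(X[selected].to_numpy())
        fit = sm.OLS(y, design).fit()
        coefs = {"const": float(fit.params[0])}
        coefs.update({v: float(c) for v, c in zip(selected, fit.params[1:])})
        r2 = float(fit.rsquared)
    else:
        coefs = {"const": float(y.mean())}
        r2 = 0.0
    return MLRModel(selected=selected, coefficients=coefs, r2=r2, entry_pvalues=entry_p)


# ---------------------------------------------------------------------------
# univariate regression tree
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    value: float
    n: int
    sse: float
    var: Optional[str] = None
    threshold: Optional[float] = None  # numeric: x <= threshold goes left
    subset: Optional[frozenset] = None  # factor: x in subset goes left
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class TreeModel:
    """A fitted, pruned regression tree.

    ``splits`` lists (variable, threshold-or-subset) for every internal node
    (pre-order); ``leaf_means`` the response mean of each leaf; ``cv_error``
    the relative cross-validated error for each candidate tree size.
    """

    root: _Node
    splits: list
    leaf_means: list
    r2: float
    cv_error: pd.DataFrame  # columns: n_leaves, alpha, cv_relative_error
    chosen_size: int

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(table), dtype=float)
        for i, (_, row) in enumerate(table.iterrows()):
            out[i] = _predict_row(self.root, row)
        return out


def _predict_row(node: _Node, row) -> float:
    while not node.is_leaf:
        x = row[node.var]
        if node.threshold is not None:
            go_left = x <= node.threshold
        else:
            go_left = x in node.subset
        node = node.left if go_left else node.right
    return node.value


def _sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0


def _best_numeric_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = y.size
    csum = np.cumsum(ys)
    csum2 = np.cumsum(ys**2)
    total, total2 = csum[-1], csum2[-1]
    best = None
    for i in range(min_leaf - 1, n - min_leaf):
        if xs[i] == xs[i + 1]:
            continue  # not a boundary between distinct values
        nl = i + 1
        nr = n - nl
        sse_l = csum2[i] - csum[i] ** 2 / nl
        sse_r = (total2 - csum2[i]) - (total - csum[i]) ** 2 / nr
        score = sse_l + sse_r
        if best is None or score < best[0]:
            best = (score, 0.5 * (xs[i] + xs[i + 1]))
    return best  # (child SSE, midpoint threshold) or None


def _best_factor_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    levels = sorted(set(x))
    if len(levels) < 2:
        return None
    if len(levels) > 8:
        raise ValueError("factor splits support at most 8 levels")
    best = None
    # fix levels[0] on the left to avoid mirrored duplicates
    rest = levels[1:]
    for r in range(len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            left_levels = frozenset((levels[0],) + combo)
            mask = np.isin(x, list(left_levels))
            nl = int(mask.sum())
            if nl < min_leaf or (y.size - nl) < min_leaf:
                continue
            score = _sse(y[mask]) + _sse(y[~mask])
            if best is None or score < best[0]:
                best = (score, left_levels)
    return best


def _grow(table: pd.DataFrame, y: np.ndarray, min_leaf: int, min_split: int) -> _Node:
    node = _Node(value=float(y.mean()), n=int(y.size), sse=_sse(y))
    if y.size < min_split or node.sse <= 1e-12:
        return node
    best = None  # (child_sse, var, threshold, subset)
    for col in table.columns:
        series = table[col]
        if pd.api.types.is_numeric_dtype(series) and not isinstance(
            series.dtype, pd.CategoricalDtype
        ):
            res = _best_numeric_split(series.to_numpy(dtype=float), y, min_leaf)
            if res is not None and (best is None or res[0] < best[0]):
                best = (res[0], col, res[1], None)
        else:
            res = _best_factor_split(series.to_numpy(), y, min_leaf)
            if res is not None and (best is None or res[0] < best[0]):
                best = (res[0], col, None, res[1])
    if best is None or node.sse - best[0] <= 1e-12:
        return node
    _, var, threshold, subset = best
    if threshold is not None:
        mask = table[var].to_numpy(dtype=float) <= threshold
    else:
        mask = np.isin(table[var].to_numpy(), list(subset))
    node.var, node.threshold, node.subset = var, threshold, subset
    node.left = _grow(table[mask], y[mask], min_leaf, min_split)
    node.right = _grow(table[~mask], y[~mask], min_leaf, min_split)
    return node


def _leaves(node: _Node) -> list:
    if node.is_leaf:
        return [node]
    return _leaves(node.left) + _leaves(node.right)


def _internal(node: _Node) -> list:
    if node.is_leaf:
        return []
    return [node] + _internal(node.left) + _internal(node.right)


def _subtree_sse(node: _Node) -> float:
    return sum(leaf.sse for leaf in _leaves(node))


def _prune_path(root: _Node):
    """Weakest-link cost-complexity pruning sequence.

    Returns a list of (alpha, tree) with alpha increasing; the first entry is
    (0, full tree) and the last a single leaf.
    """
    tree = copy.deepcopy(root)
    path = [(0.0, copy.deepcopy(tree))]
    while not tree.is_leaf:
        links = []
        for node in _internal(tree):
            n_sub = len(_leaves(node))
            g = (node.sse - _subtree_sse(node)) / (n_sub - 1)
            links.append((g, node))
        alpha = min(g for g, _ in links)
        for g, node in links:
            if g <= alpha + 1e-12 * (1 + abs(alpha)):
                node.var = node.threshold = node.subset = None
                node.left = node.right = None
        path.append((float(alpha), copy.deepcopy(tree)))
    return path


def _prune_at(root: _Node, alpha: float) -> _Node:
    """The subtree of ``root`` optimal at complexity ``alpha`` (largest path
    alpha not exceeding it)."""
    path = _prune_path(root)
    chosen = path[0][1]
    for a, tree in path:
        if a <= alpha:
            chosen = tree
        else:
            break
    return chosen


def fit_urt(
    response: Sequence[float],
    covariates: pd.DataFrame,
    cv_folds: int = 10,
    seed: int = 0,
    min_leaf: int = 3,
) -> TreeModel:
    """Univariate regression tree with cross-validated size selection.

    The tree is grown by binary recursive partitioning (numeric splits at
    midpoints between sorted distinct values; factor splits by exhaustive
    subset search, ≤ 8 levels), pruned by weakest-link cost-complexity
    pruning, and its final size chosen at the global minimum of the seeded
    k-fold cross-validation error (ties resolved toward the smaller tree).
    """
    y = np.asarray(response, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 samples")
    if len(covariates) != y.size:
        raise ValueError("response and covariates must align")
    table = covariates.reset_index(drop=True)
    full = _grow(table, y, min_leaf, 2 * min_leaf)
    tss = _sse(y)

    path = _prune_path(full)
    alphas = [a for a, _ in path]
    # snapshot i is optimal for complexity in [alpha_i, alpha_{i+1}); use the
    # geometric mean of that interval as its representative candidate, with
    # +inf for the final single-leaf snapshot
    candidates = []
    for i, a in enumerate(alphas):
        if i + 1 < len(alphas):
            a_next = alphas[i + 1]
            candidates.append(float(np.sqrt(a * a_next)) if a > 0 else 0.0)
        else:
            candidates.append(float("inf"))

    rng = np.random.default_rng(seed)
    folds = np.repeat(np.arange(cv_folds), int(np.ceil(y.size / cv_folds)))[: y.size]
    rng.shuffle(folds)
    cv_sse = np.zeros(len(candidates))
    if tss > 0 and len(candidates) > 1:
        for k in range(cv_folds):
            test = folds == k
            if test.sum() == 0 or (~test).sum() < 2 * min_leaf:
                continue
            sub = _grow(table[~test], y[~test], min_leaf, 2 * min_leaf)
            sub_path = _prune_path(sub)
            test_tbl = table[test]
            for i, alpha in enumerate(candidates):
                pruned = sub_path[0][1]
                for a, tree_snap in sub_path:
                    if a <= alpha:
                        pruned = tree_snap
                    else:
                        break
                pred = np.array(
                    [_predict_row(pruned, row) for _, row in test_tbl.iterrows()]
                )
                cv_sse[i] += float(np.sum((y[test] - pred) ** 2))
    cv_rel = cv_sse / tss if tss > 0 else np.ones(len(candidates))

    # lowest CV error; on ties prefer the smaller (later in path) tree
    best_val = float(np.min(cv_rel))
    best_i = max(
        i for i in range(len(candidates)) if cv_rel[i] <= best_val + 1e-12
    )
    chosen = path[best_i][1] if tss > 0 else path[-1][1]

    splits = [
        (n.var, n.threshold if n.threshold is not None else set(n.subset))
        for n in _internal(chosen)
    ]
    leaf_means = [leaf.value for leaf in _leaves(chosen)]
    r2 = 1.0 - _subtree_sse(chosen) / tss if tss > 0 else 0.0
    cv_table = pd.DataFrame(
        {
            "n_leaves": [len(_leaves(t)) for _, t in path],
            "alpha": candidates,
            "cv_relative_error": cv_rel,
        }
    )
    return TreeModel(
        root=chosen,
        splits=splits,
        leaf_means=leaf_means,
        r2=float(r2),
        cv_error=cv_table,
        chosen_size=len(leaf_means),
    )
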