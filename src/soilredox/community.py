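"""Microbial community statistics, implemented from first principles.

The analyses mirror the standard 16S amplicon workflow for a designed
incubation experiment:

* **alpha diversity** per sample: ACE, Chao1, Simpson (1 - sum p_i^2) and
  Shannon (-sum p_i ln p_i);
* **generalized UniFrac**, the phylogenetic beta-diversity family with
  moderation parameter ``alpha`` in [0, 1] (alpha=1 recovers weighted
  normalized UniFrac); the study convention is alpha = 0.5;
* **NMDS** (non-metric multidimensional scaling) minimising Kruskal's
  stress-1 by alternating monotone (isotonic) regression with a Guttman
  transform, initialised from classical metric scaling plus jittered
  random restarts;
* **PERMANOVA** with a permutation p-value on the pseudo-F obtained from
  Gower-centred distance partitioning;
* **taxa aggregation** to a rank with an "other" pool below a dominance
  threshold;
* **Spearman associations** between dominant taxa and environmental
  variables, with matrix-wide Benjamini-Hochberg adjustment.

Distance matrices travel as :class:`skbio.DistanceMatrix`; trees as
:class:`skbio.TreeNode`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "OtuTable",
    "RANKS",
    "alpha_diversity",
    "generalized_unifrac",
    "NmdsResult",
    "nmds",
    "PermanovaResult",
    "permanova",
    "aggregate_taxa",
    "spearman",
    "benjamini_hochberg",
    "associate",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class OtuTable:
    """OTU count table: integer counts, OTUs x samples, optional taxonomy.

    ``taxonomy`` maps otu_id -> semicolon-ranked lineage string
    (domain;phylum;class;order;family;genus); missing trailing ranks are
    tolerated.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        empty = np.flatnonzero(self.counts.sum(axis=0) == 0)
        if empty.size:
            bad = [self.sample_ids[i] for i in empty]
            raise ValueError(f"all-zero samples not allowed: {bad}")

    @property
    def relative_abundance(self) -> np.ndarray:
        """Column-normalised proportions (OTUs x samples)."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def _shannon(c: np.ndarray) -> float:
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def _simpson(c: np.ndarray) -> float:
    p = c / c.sum()
    return float(1.0 - (p**2).sum())


def _chao1(c: np.ndarray) -> float:
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _ace(c: np.ndarray, rare_cutoff: int = 10) -> float:
    c = c[c > 0]
    rare = c[c <= rare_cutoff]
    abund = c[c > rare_cutoff]
    s_rare, s_abund = len(rare), len(abund)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if n_rare == f1:
        # all rare taxa are singletons; the ACE coverage estimate is
        # undefined, fall back to Chao1 as is conventional
        return _chao1(c)
    c_ace = 1.0 - f1 / n_rare
    fis = np.array([(rare == i).sum() for i in range(1, rare_cutoff + 1)])
    i_arr = np.arange(1, rare_cutoff + 1)
    gamma2 = max(
        s_rare / c_ace * (i_arr * (i_arr - 1) * fis).sum()
        / (n_rare * (n_rare - 1.0)) - 1.0,
        0.0,
    )
    return float(s_abund + s_rare / c_ace + f1 / c_ace * gamma2)


def alpha_diversity(table: OtuTable, rare_cutoff: int = 10) -> pd.DataFrame:
    """Per-sample richness and evenness estimators.

    Returns a DataFrame indexed by sample id with columns ``observed``,
    ``ace``, ``chao1``, ``simpson``, ``shannon``.
    """
    rows = {}
    for j, sid in enumerate(table.sample_ids):
        c = table.counts[:, j]
        if c.sum() == 0:
            raise ValueError(f"sample {sid!r} is empty")
        rows[sid] = {
            "observed": int((c > 0).sum()),
            "ace": _ace(c, rare_cutoff),
            "chao1": _chao1(c),
            "simpson": _simpson(c),
            "shannon": _shannon(c),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# generalized UniFrac
# ---------------------------------------------------------------------------

def _branch_proportions(table: OtuTable, tree: TreeNode):
    """Per-branch lengths and subtended sample proportions.

    Returns (lengths, P) where ``lengths`` is (n_branches,) and ``P`` is
    (n_branches, n_samples): the fraction of each sample's reads carried by
    the subtree below each branch.  The root branch is excluded (its
    subtended proportion is 1 for every sample and carries no signal; a
    root length would cancel in the normalised form anyway).
    """
    missing = set(table.otu_ids) - {t.name for t in tree.tips()}
    if missing:
        raise ValueError(
            f"OTUs absent from the tree: {sorted(missing)}"
        )
    idx = {otu: i for i, otu in enumerate(table.otu_ids)}
    prop = table.relative_abundance
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    # postorder accumulation of subtended proportions
    node_sum: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            v = (
                prop[idx[node.name]]
                if node.name in idx
                else np.zeros(prop.shape[1])
            )
        else:
            v = np.zeros(prop.shape[1])
            for child in node.children:
                v = v + node_sum[id(child)]
        node_sum[id(node)] = v
        if node.parent is not None and node.length is not None:
            lengths.append(float(node.length))
            rows.append(v)
    return np.asarray(lengths), np.vstack(rows)


def generalized_unifrac(
    table: OtuTable, tree: TreeNode, alpha: float = 0.5
) -> DistanceMatrix:
    """Generalized UniFrac distance matrix between all sample pairs.

    For samples A and B with branch-subtended proportions p_A, p_B and
    branch lengths b::

        d(A,B) = sum_b b (p_A+p_B)^alpha |p_A-p_B|/(p_A+p_B)
                 / sum_b b (p_A+p_B)^alpha

    restricted to branches with p_A + p_B > 0.  ``alpha`` in [0, 1]
    moderates the weight placed on abundant lineages; alpha=1 is weighted
    normalized UniFrac.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    lengths, P = _branch_proportions(table, tree)
    n = len(table.sample_ids)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pa, pb = P[:, i], P[:, j]
        tot = pa + pb
        mask = tot > 0
        if not mask.any():
            continue
        w = lengths[mask] * tot[mask] ** alpha
        num = (w * np.abs(pa[mask] - pb[mask]) / tot[mask]).sum()
        den = w.sum()
        dm[i, j] = dm[j, i] = num / den if den > 0 else 0.0
    return DistanceMatrix(dm, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    """Non-metric MDS embedding with its Kruskal stress-1."""

    coordinates: pd.DataFrame  # samples x k
    stress: float
    k: int
    converged: bool
    seed: int | None
    stress_history: list[float] = field(default_factory=list, repr=False)


def _kruskal_stress(d: np.ndarray, dhat: np.ndarray) -> float:
    return float(np.sqrt(((d - dhat) ** 2).sum() / (d**2).sum()))


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def _nmds_single(
    D: np.ndarray, X0: np.ndarray, max_iter: int, tol: float, patience: int
):
    diss = squareform(D, checks=False)
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression(increasing=True)
    n = D.shape[0]
    X = X0.copy()
    history = []
    best = np.inf
    best_X = X.copy()
    stall = 0
    for _ in range(max_iter):
        d = pdist(X)
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
        # rescale disparities so the Guttman transform keeps the scale of d
        s = np.sqrt((d**2).sum() / max((dhat**2).sum(), 1e-300))
        dhat_s = dhat * s
        stress = _kruskal_stress(d, dhat_s)
        if stress < best - tol:
            best, best_X, stall = stress, X.copy(), 0
        else:
            stall += 1
        history.append(best)
        if stall >= patience or best < 1e-12:
            break
        # Guttman transform with disparities dhat_s
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat_s / d, 0.0)
        R = squareform(ratio, checks=False)
        B = -R
        np.fill_diagonal(B, R.sum(axis=1))
        X = B @ X / n
        X -= X.mean(axis=0)
    return best_X, best, history


def nmds(
    dist: DistanceMatrix,
    k: int = 4,
    seed: int | None = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    patience: int = 10,
) -> NmdsResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    The first start is the classical (Torgerson) metric-scaling solution;
    the remaining ``n_restarts - 1`` starts jitter it with Gaussian noise.
    Iteration alternates isotonic regression of configuration distances on
    dissimilarity ranks with a Guttman transform, and stops when the best
    stress has not improved by ``tol`` over ``patience`` iterations.
    """
    D = np.asarray(dist.data, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if k >= n:
        raise ValueError(f"k={k} requires more than {k} samples")
    rng = np.random.default_rng(seed)
    X_init = _classical_mds(D, k)
    scale = max(X_init.std(), 1e-6)
    best = (None, np.inf, [])
    for r in range(max(n_restarts, 1)):
        X0 = X_init if r == 0 else X_init + rng.normal(0, 0.3 * scale, X_init.shape)
        X, stress, hist = _nmds_single(D, X0, max_iter, tol, patience)
        if stress < best[1]:
            best = (X, stress, hist)
    X, stress, hist = best
    coords = pd.DataFrame(
        X, index=list(dist.ids), columns=[f"MDS{i + 1}" for i in range(k)]
    )
    return NmdsResult(coords, stress, k, converged=len(hist) < max_iter,
                      seed=seed, stress_history=hist)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    """Pseudo-F and permutation p-value for a one-factor design."""

    pseudo_F: float
    p_value: float
    permutations: int
    factor: str


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    dist: DistanceMatrix,
    grouping,
    permutations: int = 999,
    seed: int | None = 0,
    factor: str = "grouping",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``grouping`` is a sequence of labels aligned with ``dist.ids``.  The
    p-value is ``(1 + #{F_perm >= F_obs}) / (1 + permutations)``.
    """
    labels = np.asarray(list(grouping))
    if labels.size != len(dist.ids):
        raise ValueError("grouping length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes == 1).any():
        import warnings

        warnings.warn(
            "singleton group present; the permutation distribution is restricted",
            stacklevel=2,
        )
    d2 = np.asarray(dist.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, codes, uniq.size)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, uniq.size) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return PermanovaResult(float(f_obs), float(p), permutations, factor)


# ---------------------------------------------------------------------------
# taxa aggregation
# ---------------------------------------------------------------------------

def _lineage_at_rank(lineage: str | None, rank_index: int) -> str:
    parts = [p.strip() for p in (lineage or "").split(";")]
    parts = [p for p in parts if p != ""]
    if len(parts) > rank_index and parts[rank_index]:
        return parts[rank_index]
    parent = parts[-1] if parts else "root"
    return f"unclassified_{parent}"


def aggregate_taxa(
    table: OtuTable,
    rank: str = "family",
    min_mean_relative_abundance: float = 0.02,
    other_label: str = "other",
) -> pd.DataFrame:
    """Relative abundance per lineage at ``rank``, pooling minor taxa.

    Lineages whose across-sample mean relative abundance falls below the
    threshold are pooled into ``other``.  Columns (samples) each sum to 1.
    """
    if table.taxonomy is None:
        raise ValueError("OTU table has no taxonomy; cannot aggregate")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    ridx = RANKS.index(rank)
    prop = table.relative_abundance
    frame = pd.DataFrame(prop, index=table.otu_ids, columns=table.sample_ids)
    labels = [
        _lineage_at_rank(table.taxonomy.get(otu), ridx) for otu in table.otu_ids
    ]
    agg = frame.groupby(pd.Index(labels, name=rank)).sum()
    keep = agg.mean(axis=1) >= min_mean_relative_abundance
    dominant = agg.loc[keep]
    dominant = dominant.loc[dominant.mean(axis=1).sort_values(ascending=False).index]
    other = agg.loc[~keep].sum(axis=0)
    if (other > 0).any() or (~keep).any():
        dominant = pd.concat([dominant, other.to_frame(other_label).T])
    return dominant


# ---------------------------------------------------------------------------
# Spearman + Benjamini-Hochberg
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _exact_s_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of S = sum d_i^2 over all rank permutations (no ties)."""
    perms = np.array(list(itertools.permutations(range(n))))
    base = np.arange(n)
    s = ((perms - base) ** 2).sum(axis=1)
    vals, counts = np.unique(s, return_counts=True)
    return vals, counts


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho with average ranks for ties, plus a two-sided p-value.

    For n <= ``exact_max_n`` and tie-free data the p-value comes from the
    exact permutation distribution of S = sum d^2; otherwise from the
    t-approximation with n-2 degrees of freedom.  Constant input yields
    (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= exact_max_n and not ties:
        s_obs = ((rx - ry) ** 2).sum()
        vals, counts = _exact_s_distribution(n)
        total = counts.sum()
        # |rho_perm| >= |rho_obs|  <=>  S in either symmetric tail
        s_max = (n**3 - n) / 3.0  # S at rho = -1
        s_ref = min(s_obs, s_max - s_obs)
        p = (
            counts[vals <= s_ref].sum() + counts[vals >= s_max - s_ref].sum()
        ) / total
        p = min(1.0, float(p))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (NaN entries are passed through).

    Monotone by construction: p_adj[(i)] = min_{j>=i} m/j * p[(j)], capped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def associate(
    taxa: pd.DataFrame,
    env: pd.DataFrame,
    adjust_scope: str = "matrix",
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Spearman associations between taxa and environmental variables.

    ``taxa`` is taxa x samples (relative abundances of the dominant taxa);
    ``env`` is samples x variables.  Samples are aligned on the shared ids.
    BH adjustment is applied across the whole taxa-by-variable matrix
    (``adjust_scope='matrix'``) or within each variable
    (``'per_variable'``).  ``significant`` flags adjusted (or raw, when
    ``use_adjusted=False``) p < ``alpha``.
    """
    shared = [s for s in taxa.columns if s in env.index]
    if len(shared) < 4:
        raise ValueError("need at least 4 paired samples")
    if adjust_scope not in ("matrix", "per_variable"):
        raise ValueError(f"unknown adjust_scope {adjust_scope!r}")
    t = taxa[shared]
    e = env.loc[shared]
    rows = []
    for taxon in t.index:
        for var in e.columns:
            y = e[var].to_numpy(dtype=float)
            if np.isnan(y).any():
                continue
            rho, p = spearman(t.loc[taxon].to_numpy(dtype=float), y)
            rows.append({"taxon": taxon, "variable": var,
                         "spearman_rho": rho, "p_raw": p})
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    if adjust_scope == "matrix":
        res["p_adjusted"] = benjamini_hochberg(res["p_raw"].to_numpy())
    else:
        res["p_adjusted"] = np.nan
        for var in res["variable"].unique():
            mask = res["variable"] == var
            res.loc[mask, "p_adjusted"] = benjamini_hochberg(
                res.loc[mask, "p_raw"].to_numpy()
            )
    which = "p_adjusted" if use_adjusted else "p_raw"
    res["significant"] = res[which] < alpha
    return res
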