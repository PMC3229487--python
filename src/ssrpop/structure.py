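"""Population-structure inference and comparison.

The panel is encoded as a varieties x alleles matrix of within-variety
allele frequencies (0 / 0.5 / 1 per allele of a diploid call), the shared
geometry behind PCA, principal coordinate analysis on modified Rogers
distances, Laplacian (spectral) embedding, and Gaussian-mixture
clustering with BIC model selection over the number of subgroups.

Also here: the Evanno second-difference statistic (delta-K) on replicated
clustering log-likelihoods, membership-threshold vs maximum-probability
assignment, optimal-matching correspondence between labelings,
neighbor-joining trees and Ward clustering of morphological scores.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.linalg
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA as _SKPCA
from sklearn.mixture import GaussianMixture

from ._encoding import copy_matrix
from .panel import SSRPanel

logger = logging.getLogger(__name__)

#: Gaussian-mixture covariance families examined during model selection
DEFAULT_FAMILIES = ("spherical", "diag", "tied", "full")
ADMIXED_LABEL = "AD"


@dataclass
class EncodedMatrix:
    """Varieties x (locus, allele) within-variety frequency matrix.

    Within each locus's column block a row sums to 1; originally-missing
    calls are mean-filled (panel-wide allele frequencies) and flagged in
    ``missing_mask``.
    """

    matrix: np.ndarray
    variety_ids: list[str]
    columns: list[tuple[str, int]]
    locus_ids: list[str]
    starts: np.ndarray
    missing_mask: np.ndarray


def encode(panel: SSRPanel) -> EncodedMatrix:
    """One column per (locus, allele): heterozygote 0.5/0.5, homozygote 1."""
    cm = copy_matrix(panel)
    x = cm.counts.astype(float) / 2.0
    # mean-fill missing locus blocks with the panel-wide mean frequencies
    for j in range(len(panel.locus_ids)):
        sl = cm.block(j)
        rows = ~cm.valid[:, j]
        if rows.any():
            mean = x[cm.valid[:, j], sl].mean(axis=0)
            x[np.ix_(rows, range(sl.start, sl.stop))] = mean
    return EncodedMatrix(x, list(panel.variety_ids), cm.columns,
                         list(panel.locus_ids), cm.starts, ~cm.valid)


@dataclass
class Ordination:
    coordinates: pd.DataFrame       # varieties x axes
    proportion: np.ndarray          # variance proportion per axis
    eigenvalues: np.ndarray | None = None


def pca(encoded: EncodedMatrix, n_components: int = 10) -> Ordination:
    """Principal components of the column-centred encoded matrix."""
    x = encoded.matrix
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 varieties")
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if n_components > max_rank:
        warnings.warn(f"n_components truncated from {n_components} to rank "
                      f"{max_rank}")
        n_components = max_rank
    model = _SKPCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(x)
    df = pd.DataFrame(coords, index=encoded.variety_ids,
                      columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    return Ordination(df, model.explained_variance_ratio_.copy())


def pcoa(distances, n_axes: int = 10) -> Ordination:
    """Principal coordinate analysis (Gower double-centring).

    Negative eigenvalues (non-Euclidean distances) are reported but not
    used for coordinates; proportions are over the positive eigenvalues.
    """
    if isinstance(distances, pd.DataFrame):
        ids = distances.index.tolist()
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        ids = [str(i) for i in range(d.shape[0])]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("PCoA needs a symmetric distance matrix")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("PCoA needs a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = scipy.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    k = min(n_axes, int(pos.sum()))
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    prop = evals[:k] / evals[pos].sum()
    df = pd.DataFrame(coords, index=ids,
                      columns=[f"PCo{i + 1}" for i in range(k)])
    return Ordination(df, prop, evals)


def laplacian_embed(encoded: EncodedMatrix, eps: float = 0.8,
                    n_axes: int = 2) -> Ordination:
    """Spectral embedding of the thresholded variety-correlation graph.

    Edge weight is the Pearson correlation between variety rows where it
    is >= ``eps``, else 0; the symmetric normalised Laplacian is
    eigendecomposed and, after dropping the trivial constant direction,
    the leading eigenvectors are returned as lapvectors.  Isolated
    varieties keep a self-loop of weight 1 (with a warning).  Each
    lapvector's "proportion" is the share of the encoded matrix's total
    variance its direction explains.
    """
    if not (0.0 < eps <= 1.0):
        raise ValueError("eps must be in (0, 1]")
    x = encoded.matrix
    r = np.corrcoef(x)
    w = np.where(r >= eps, r, 0.0)
    np.fill_diagonal(w, 0.0)
    deg = w.sum(axis=1)
    isolated = deg <= 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} isolated varieties in the "
                      f"eps={eps} correlation graph; kept with self-loops")
        w[isolated, isolated] = 1.0
        deg = w.sum(axis=1)
    dmh = 1.0 / np.sqrt(deg)
    lap = np.eye(len(deg)) - (dmh[:, None] * w * dmh[None, :])
    evals, evecs = scipy.linalg.eigh(lap)
    vecs = evecs[:, 1:n_axes + 1]           # drop the trivial direction
    xc = x - x.mean(axis=0)
    total = np.sum(xc ** 2)
    prop = np.array([np.sum((v @ xc) ** 2) / (np.sum(v ** 2) * total)
                     for v in vecs.T])
    df = pd.DataFrame(vecs, index=encoded.variety_ids,
                      columns=[f"LAP{i + 1}" for i in range(vecs.shape[1])])
    return Ordination(df, prop, evals[1:n_axes + 1])


@dataclass
class MembershipMatrix:
    """Varieties x K membership probabilities (rows sum to 1)."""

    probabilities: pd.DataFrame

    def __post_init__(self):
        p = self.probabilities.to_numpy()
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")

    @property
    def k(self) -> int:
        return self.probabilities.shape[1]


@dataclass
class ModelSelection:
    """BIC model-selection table over (K, covariance family)."""

    table: pd.DataFrame     # columns: k, family, bic, loglik
    best_k: int
    best_family: str
    membership: MembershipMatrix
    model: GaussianMixture


def fit_mixture(x, k_range=range(1, 31), families=DEFAULT_FAMILIES,
                seed: int | None = None, n_init: int = 2,
                variety_ids=None, reg_covar: float = 1e-6) -> ModelSelection:
    """Gaussian-mixture clustering with BIC selection of K and family.

    BIC uses the larger-is-better convention (2 log L - params log n); the
    (K, family) pair attaining the maximum is selected and its membership
    probabilities returned.  Families whose fit fails (singular
    covariance) are skipped for that K with a log entry.
    """
    x = np.asarray(x, dtype=float)
    if variety_ids is None:
        variety_ids = [str(i) for i in range(x.shape[0])]
    k_range = [k for k in k_range if k <= x.shape[0]]
    if not k_range:
        raise ValueError("no feasible K (more clusters than rows)")
    rows, models = [], {}
    rng = np.random.default_rng(seed)
    for k in k_range:
        for fam in families:
            gm = GaussianMixture(n_components=k, covariance_type=fam,
                                 n_init=n_init, reg_covar=reg_covar,
                                 random_state=int(rng.integers(2 ** 31)))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gm.fit(x)
                if not np.all(np.isfinite(gm.lower_bound_)):
                    raise ValueError("non-finite likelihood")
            except Exception as exc:   # singular fits are skipped, not fatal
                logger.info("mixture fit failed (K=%d, %s): %s", k, fam, exc)
                continue
            # identifiability guard: a component collapsed onto too few
            # points gets unbounded likelihood from the covariance floor
            min_size = x.shape[1] + 1 if fam == "full" else 2.0
            if k > 1 and gm.weights_.min() * x.shape[0] < min_size:
                logger.info("mixture fit degenerate (K=%d, %s): smallest "
                            "component below %g points", k, fam, min_size)
                continue
            bic = -gm.bic(x)           # larger is better
            loglik = gm.score(x) * x.shape[0]
            rows.append({"k": k, "family": fam, "bic": bic, "loglik": loglik})
            models[(k, fam)] = gm
    if not rows:
        raise RuntimeError("all mixture fits failed")
    table = pd.DataFrame(rows)
    best = table.loc[table["bic"].idxmax()]
    best_k, best_family = int(best["k"]), str(best["family"])
    gm = models[(best_k, best_family)]
    probs = pd.DataFrame(gm.predict_proba(x), index=variety_ids,
                         columns=[f"SG{i + 1}" for i in range(best_k)])
    return ModelSelection(table, best_k, best_family,
                          MembershipMatrix(probs), gm)


def replicate_logliks(x, k_range, n_replicates: int = 5,
                      family: str = "diag", seed: int | None = None,
                      reg_covar: float = 1e-6) -> pd.DataFrame:
    """Replicated mixture log-likelihoods per K, for the delta-K statistic.

    Each replicate refits the K-component mixture from a different random
    initialisation; the returned frame has columns (k, replicate, loglik).
    """
    x = np.asarray(x, dtype=float)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_replicates * len(list(k_range))) % (2 ** 31)
    rows = []
    i = 0
    for k in k_range:
        for rep in range(n_replicates):
            gm = GaussianMixture(n_components=k, covariance_type=family,
                                 n_init=1, init_params="random_from_data",
                                 reg_covar=reg_covar,
                                 random_state=int(seeds[i]))
            i += 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(x)
            rows.append({"k": k, "replicate": rep,
                         "loglik": gm.score(x) * x.shape[0]})
    return pd.DataFrame(rows)


def delta_k(stats: pd.DataFrame) -> pd.DataFrame:
    """Evanno's second-difference statistic on replicated log-likelihoods.

    ``stats`` has columns (k, replicate, loglik) over consecutive K with
    >= 2 replicates each.  For interior K:
    delta_K = mean_reps |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd_reps L(K).
    K values with zero replicate spread get NaN and ``undefined=True``.
    """
    ks = sorted(stats["k"].unique())
    if len(ks) < 3:
        raise ValueError("delta-K needs at least 3 consecutive K values")
    if list(ks) != list(range(min(ks), max(ks) + 1)):
        raise ValueError("K values must be consecutive")
    pivot = stats.pivot_table(index="replicate", columns="k", values="loglik")
    if pivot.isna().any().any() or len(pivot) < 2:
        raise ValueError("need >= 2 replicates at every K")
    rows = []
    for k in ks[1:-1]:
        second = (pivot[k + 1] - 2 * pivot[k] + pivot[k - 1]).abs().mean()
        sd = pivot[k].std(ddof=1)
        undefined = sd == 0
        rows.append({"k": k,
                     "delta_k": np.nan if undefined else second / sd,
                     "undefined": undefined})
    return pd.DataFrame(rows)


def delta_k_argmax(stats: pd.DataFrame) -> int:
    """Inferred subgroup number: K attaining the maximal delta-K."""
    curve = delta_k(stats)
    ok = curve[~curve["undefined"]]
    if ok.empty:
        raise ValueError("delta-K undefined at every K")
    return int(ok.loc[ok["delta_k"].idxmax(), "k"])


def assign(membership: MembershipMatrix, rule: str = "threshold",
           threshold: float = 0.80) -> pd.Series:
    """Subgroup labels from membership probabilities.

    ``threshold`` rule: a variety is labelled by its argmax subgroup when
    the maximum membership probability is >= threshold (inclusive),
    otherwise it goes to the admixed group (AD).  ``max`` rule: always the
    argmax.  Argmax ties go to the lowest-index subgroup (logged).
    """
    if rule not in ("threshold", "max"):
        raise ValueError(f"unknown rule {rule!r}")
    probs = membership.probabilities
    arr = probs.to_numpy()
    idx = arr.argmax(axis=1)
    ties = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    for v in probs.index[ties]:
        logger.info("membership tie for %s broken toward lowest subgroup", v)
    labels = probs.columns.to_numpy()[idx].astype(object)
    if rule == "threshold":
        labels[arr.max(axis=1) < threshold] = ADMIXED_LABEL
    return pd.Series(labels, index=probs.index, name="label")


def correspondence(labels_a, labels_b) -> float:
    """Agreement fraction under the best injective relabeling.

    The smaller label alphabet is matched injectively into the larger by
    maximising the confusion-matrix diagonal (optimal assignment);
    unmatched labels count as disagreement.  The admixed label is a label
    like any other.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b):
        raise ValueError("labelings have different sizes")
    positional = (isinstance(a.index, pd.RangeIndex)
                  or isinstance(b.index, pd.RangeIndex))
    if not positional and not a.index.equals(b.index):
        common = a.index.intersection(b.index)
        if len(common) == 0:
            raise ValueError("labelings share no varieties")
        if len(common) != len(a):
            raise ValueError("labelings cover different variety sets")
        b = b.loc[a.index]
    conf = pd.crosstab(a.to_numpy(), b.to_numpy()).to_numpy()
    ri, ci = linear_sum_assignment(conf, maximize=True)
    return float(conf[ri, ci].sum() / conf.sum())


def correspondence_bruteforce(labels_a, labels_b) -> float:
    """Exhaustive-permutation correspondence (oracle; <= 5 labels/side)."""
    a = pd.Series(labels_a)
    b = pd.Series(labels_b).loc[pd.Series(labels_a).index]
    la, lb = sorted(a.unique()), sorted(b.unique())
    if len(la) > 5 or len(lb) > 5:
        raise ValueError("brute force limited to 5 labels")
    small, large = (la, lb) if len(la) <= len(lb) else (lb, la)
    swap = len(la) > len(lb)
    best = 0
    for perm in itertools.permutations(large, len(small)):
        mapping = dict(zip(small, perm))
        if swap:
            agree = sum(mapping.get(y) == x for x, y in zip(a, b))
        else:
            agree = sum(mapping.get(x) == y for x, y in zip(a, b))
        best = max(best, agree)
    return best / len(a)


def nj_tree(distances, ids=None) -> str:
    """Neighbor-joining tree from a distance matrix, as Newick text.

    Standard Saitou-Nei agglomeration.  A negative branch length is
    clamped to zero and its deficit moved to the sister branch of the same
    join, preserving the pair's path length.  The tree is unrooted (final
    trifurcation).
    """
    if isinstance(distances, pd.DataFrame):
        ids = distances.index.tolist()
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        if ids is None:
            ids = [f"t{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("NJ needs a symmetric matrix")
    d = d.copy()
    nodes = [str(x) for x in ids]
    active = list(range(n))

    def clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return la, max(lb, 0.0)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        tot = sub.sum(axis=1)
        q = (r - 2) * sub - tot[:, None] - tot[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        i, j = active[i_], active[j_]
        dij = d[i, j]
        li = 0.5 * dij + (tot[i_] - tot[j_]) / (2 * (r - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        new = np.array([0.5 * (d[i, k] + d[j, k] - dij)
                        for k in active if k not in (i, j)])
        label = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        d = np.pad(d, ((0, 1), (0, 1)))
        rest = [k for k in active if k not in (i, j)]
        d[-1, rest] = new
        d[rest, -1] = new
        nodes.append(label)
        active = rest + [len(nodes) - 1]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    li = max(li, 0.0)
    lj = max(lj, 0.0)
    lk = max(lk, 0.0)
    return (f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},"
            f"{nodes[k]}:{lk:.10g});")


def ward_cluster(scores: pd.DataFrame, n_clusters: int = 2):
    """Ward-linkage clustering of the 6 trait scores + index matrix.

    Returns the scipy linkage matrix and flat cluster labels (1..n) from a
    maxclust cut.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 varieties")
    x = scores.to_numpy(dtype=float)
    z = sch.linkage(x, method="ward")
    labels = sch.fcluster(z, t=n_clusters, criterion="maxclust")
    return z, pd.Series(labels, index=scores.index, name="cluster")


def structure_pipeline(panel: SSRPanel, n_pcs: int = 10,
                       k_range=range(1, 31), families=DEFAULT_FAMILIES,
                       seed: int | None = None) -> tuple[ModelSelection, Ordination]:
    """Encode -> PCA -> mixture model selection, the standard chain.

    Clustering operates on the leading principal components of the
    encoded matrix rather than the raw allele space (n varieties is far
    below the column count, so full-covariance families would be
    singular there).
    """
    enc = encode(panel)
    ord_ = pca(enc, n_components=n_pcs)
    sel = fit_mixture(ord_.coordinates.to_numpy(), k_range=k_range,
                      families=families, seed=seed,
                      variety_ids=panel.variety_ids)
    return sel, ord_
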