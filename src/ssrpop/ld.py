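"""Multiallelic linkage disequilibrium on an inbred SSR panel.

Because the panel is selfing and nearly fully homozygous, each variety
contributes one haplotype: homozygous calls project to a single allele and
the rare heterozygotes are treated as missing (no phase modelling).  For a
locus pair with joint haplotype frequencies x_ij and marginals p_i, q_j:

    D_ij  = x_ij - p_i q_j
    D'    = sum_ij p_i q_j |D_ij| / Dmax_ij        (weighted D')
    r^2   = sum_ij p_i q_j D_ij^2 / (p_i(1-p_i) q_j(1-q_j))

For biallelic pairs r^2 reduces exactly to the classical squared allele
correlation.  Significance is a two-sided Fisher exact test for 2x2
tables and a seeded Monte-Carlo permutation test (table chi-square
statistic, add-one correction) otherwise.

Summaries mirror the standard core-collection workflow: percentage of
significant pairs split by linked (same chromosome) vs unlinked, their
ratio, LD decay against the 75th percentile of unlinked r^2, and LD
blocks (maximal runs of map-adjacent loci whose every consecutive pair is
significant).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .panel import MISSING, GeneticMap, SSRPanel

logger = logging.getLogger(__name__)

OTHER_CLASS = -2  # pooled rare-allele code


def haploid_calls(panel: SSRPanel, het_policy: str = "missing") -> pd.DataFrame:
    """Project diploid calls to one haplotype per variety.

    Homozygotes keep their allele; heterozygotes become missing under the
    default policy ("missing"; the "drop" alias behaves identically in the
    downstream complete-case pair analysis).  Loci left with fewer than
    two distinct alleles are reported via :func:`eligible_loci`.
    """
    if het_policy not in ("missing", "drop"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    a, b = panel.calls[..., 0], panel.calls[..., 1]
    out = np.where(a == b, a, MISSING).astype(np.int32)
    return pd.DataFrame(out, index=panel.variety_ids, columns=panel.locus_ids)


def pool_rare_alleles(calls: np.ndarray, min_count: int = 2) -> np.ndarray:
    """Pool alleles observed fewer than ``min_count`` times into one class."""
    out = calls.copy()
    obs = calls[calls != MISSING]
    sizes, counts = np.unique(obs, return_counts=True)
    rare = set(sizes[counts < min_count].tolist())
    if rare:
        out[np.isin(out, list(rare))] = OTHER_CLASS
    return out


def eligible_loci(haploid: pd.DataFrame, min_count: int = 2,
                  pool_rare: bool = True) -> list[str]:
    """Loci with >= 2 distinct (post-pooling) alleles among non-missing calls."""
    keep = []
    for locus in haploid.columns:
        col = haploid[locus].to_numpy()
        if pool_rare:
            col = pool_rare_alleles(col, min_count)
        k = np.unique(col[col != MISSING]).size
        if k >= 2:
            keep.append(locus)
        else:
            logger.info("locus %s excluded from LD (<2 alleles)", locus)
    return keep


@dataclass
class LDPairResult:
    locus_a: str
    locus_b: str
    r2: float
    dprime: float
    p_value: float
    n: int                       # gene (haplotype) count used
    linked: bool | None = None
    distance_cm: float = float("nan")


def _ld_statistics(table: np.ndarray) -> tuple[float, float]:
    """Weighted D' and r^2 from a joint haplotype count table."""
    x = table / table.sum()
    p = x.sum(axis=1)
    q = x.sum(axis=0)
    d = x - np.outer(p, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        dmax = np.where(d < 0,
                        np.minimum(np.outer(p, q), np.outer(1 - p, 1 - q)),
                        np.minimum(np.outer(p, 1 - q), np.outer(1 - p, q)))
        dprime_ij = np.abs(d) / dmax
        r2_ij = d ** 2 / np.outer(p * (1 - p), q * (1 - q))
    w = np.outer(p, q)
    dprime = float(np.nansum(w * dprime_ij))
    r2 = float(np.nansum(w * r2_ij))
    return min(dprime, 1.0), min(r2, 1.0)


def _perm_pvalue(a_codes: np.ndarray, b_codes: np.ndarray, ka: int, kb: int,
                 n_shuffles: int, rng: np.random.Generator) -> float:
    """Monte-Carlo permutation p-value, chi-square table statistic."""
    nc = a_codes.size
    a1 = np.zeros((nc, ka), dtype=np.float32)
    a1[np.arange(nc), a_codes] = 1.0
    b1 = np.zeros((nc, kb), dtype=np.float32)
    b1[np.arange(nc), b_codes] = 1.0
    obs = a1.T @ b1
    row, col = obs.sum(axis=1), obs.sum(axis=0)
    expect = np.outer(row, col) / nc
    chi_obs = float(np.sum((obs - expect) ** 2 / expect))
    perm = np.argsort(rng.random((n_shuffles, nc)), axis=1)
    stacked = b1[perm].transpose(1, 0, 2).reshape(nc, n_shuffles * kb)
    tables = (a1.T @ stacked).reshape(ka, n_shuffles, kb).transpose(1, 0, 2)
    chi = np.sum((tables - expect) ** 2 / expect, axis=(1, 2))
    return float((1 + np.sum(chi >= chi_obs - 1e-9)) / (1 + n_shuffles))


def pair_ld(calls_a, calls_b, n_shuffles: int = 10_000,
            seed: int | None = None, locus_a: str = "A", locus_b: str = "B",
            rng: np.random.Generator | None = None) -> LDPairResult:
    """LD statistics and significance for one locus pair.

    ``calls_a``/``calls_b`` are haploid integer call vectors with
    :data:`~ssrpop.panel.MISSING` for absent calls; only varieties with
    both calls present enter.  Degenerate pairs (under 2 varieties or
    under 2 alleles on either side) return NaN statistics with p = 1.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    nc = a.size
    nan = LDPairResult(locus_a, locus_b, float("nan"), float("nan"),
                       float("nan"), nc)
    if nc < 2:
        return nan
    ua, a_codes = np.unique(a, return_inverse=True)
    ub, b_codes = np.unique(b, return_inverse=True)
    ka, kb = ua.size, ub.size
    if ka < 2 or kb < 2:
        return nan
    table = np.zeros((ka, kb))
    np.add.at(table, (a_codes, b_codes), 1.0)
    dprime, r2 = _ld_statistics(table)
    if ka == 2 and kb == 2:
        p = float(fisher_exact(table.astype(int))[1])
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        p = _perm_pvalue(a_codes, b_codes, ka, kb, n_shuffles, rng)
    return LDPairResult(locus_a, locus_b, r2, dprime, p, nc)


def ld_scan(panel: SSRPanel, gmap: GeneticMap, varieties=None,
            n_shuffles: int = 10_000, seed: int | None = None,
            pool_rare: bool = True, min_count: int = 2) -> pd.DataFrame:
    """All unordered locus-pair LD tests for (a subset of) the panel.

    Returns one row per pair of eligible loci with columns locus_a,
    locus_b, chrom_a, chrom_b, linked, distance_cm (same-chromosome only),
    r2, dprime, p_value, n.
    """
    if varieties is not None:
        panel = panel.subset_varieties(list(varieties))
    unmapped = [l for l in panel.locus_ids if l not in gmap.table.index]
    if unmapped:
        raise ValueError(f"loci missing from map: {unmapped[:5]}")
    hap = haploid_calls(panel)
    loci = eligible_loci(hap, min_count=min_count, pool_rare=pool_rare)
    cols = {}
    for locus in loci:
        col = hap[locus].to_numpy()
        cols[locus] = pool_rare_alleles(col, min_count) if pool_rare else col
    rng = np.random.default_rng(seed)
    rows = []
    for la, lb in itertools.combinations(loci, 2):
        res = pair_ld(cols[la], cols[lb], n_shuffles=n_shuffles,
                      locus_a=la, locus_b=lb, rng=rng)
        ca, cb = gmap.chromosome_of(la), gmap.chromosome_of(lb)
        linked = ca == cb
        rows.append({"locus_a": la, "locus_b": lb, "chrom_a": ca,
                     "chrom_b": cb, "linked": linked,
                     "distance_cm": gmap.distance(la, lb) if linked
                     else float("nan"),
                     "r2": res.r2, "dprime": res.dprime,
                     "p_value": res.p_value, "n": res.n})
    return pd.DataFrame(rows)


@dataclass
class LDGroupSummary:
    group: str
    n_varieties: int
    pct_linked: float
    pct_unlinked: float
    pct_total: float
    ratio: float


def summarise_pairs(pairs: pd.DataFrame, alpha: float = 0.05,
                    group: str = "all", n_varieties: int = 0) -> LDGroupSummary:
    """Percent significant pairs by linkage category and their ratio."""
    ok = pairs[np.isfinite(pairs["p_value"])]
    sig = ok["p_value"] < alpha

    def pct(mask) -> float:
        return float(100.0 * sig[mask].mean()) if mask.any() else float("nan")

    linked = ok["linked"].to_numpy()
    pl, pu = pct(linked), pct(~linked)
    pt = float(100.0 * sig.mean()) if len(ok) else float("nan")
    ratio = pl / pu if pu and np.isfinite(pu) and pu > 0 else float("nan")
    return LDGroupSummary(group, n_varieties, pl, pu, pt, ratio)


def ld_summary(panel: SSRPanel, gmap: GeneticMap, grouping=None,
               alpha: float = 0.05, n_shuffles: int = 10_000,
               seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Per-group LD significance summary (Table-5 style).

    ``grouping`` maps variety -> group; None analyses the whole panel as
    one group "all".  Groups with fewer than 2 varieties are skipped with
    a warning.  Returns the summary frame and the per-group pair scans.
    """
    import warnings as _warnings
    if grouping is None:
        grouping = pd.Series("all", index=panel.variety_ids)
    elif isinstance(grouping, dict):
        grouping = pd.Series(grouping)
    rows, scans = [], {}
    rng = np.random.default_rng(seed)
    for g in sorted(grouping.unique()):
        members = grouping.index[grouping == g].tolist()
        if len(members) < 2:
            _warnings.warn(f"group {g!r} has fewer than 2 varieties; skipped")
            continue
        pairs = ld_scan(panel, gmap, varieties=members,
                        n_shuffles=n_shuffles,
                        seed=int(rng.integers(2 ** 31)))
        scans[g] = pairs
        s = summarise_pairs(pairs, alpha=alpha, group=g,
                            n_varieties=len(members))
        rows.append(vars(s))
    return pd.DataFrame(rows), scans


@dataclass
class DecayResult:
    threshold: float             # the unlinked-r^2 quantile
    decay_cm: float              # inf when never below threshold
    curve: pd.DataFrame          # window left edge, mean r^2, n pairs


def decay_distance(pairs: pd.DataFrame, quantile: float = 0.75,
                   window: float = 5.0, step: float = 1.0) -> DecayResult:
    """LD decay distance against the unlinked-r^2 quantile threshold.

    The threshold is the (linear-interpolation) ``quantile`` of r^2 over
    inter-chromosomal pairs.  Linked pairs are averaged in sliding cM
    windows; the decay distance is the left edge of the first window whose
    mean r^2 falls below the threshold with every later non-empty window
    also below (0 when even the first window is below; inf when no such
    window exists).
    """
    unlinked = pairs.loc[~pairs["linked"], "r2"].dropna()
    linked = pairs.loc[pairs["linked"], ["distance_cm", "r2"]].dropna()
    if unlinked.empty or linked.empty:
        raise ValueError("need at least one linked and one unlinked pair")
    threshold = float(np.quantile(unlinked.to_numpy(), quantile))
    max_d = float(linked["distance_cm"].max())
    edges = np.arange(0.0, max(max_d - window, 0.0) + step, step)
    means, counts = [], []
    d = linked["distance_cm"].to_numpy()
    r = linked["r2"].to_numpy()
    for left in edges:
        mask = (d >= left) & (d < left + window)
        counts.append(int(mask.sum()))
        means.append(float(r[mask].mean()) if mask.any() else float("nan"))
    curve = pd.DataFrame({"window_left_cm": edges, "mean_r2": means,
                          "n_pairs": counts})
    below = [(np.isnan(m) or m < threshold) for m in means]
    decay = float("inf")
    for i in range(len(edges)):
        if not np.isnan(means[i]) and means[i] < threshold and all(below[i:]):
            decay = float(edges[i])
            break
    return DecayResult(threshold, decay, curve)


@dataclass
class LDBlock:
    chromosome: int
    loci: list[str]
    span_cm: float

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def find_blocks(pairs: pd.DataFrame, gmap: GeneticMap, alpha: float = 0.05,
                min_loci: int = 2) -> list[LDBlock]:
    """Maximal runs of map-adjacent loci with every consecutive pair
    significant at ``alpha``.

    Only loci present in the pair scan participate; an untested adjacent
    pair breaks a run.
    """
    tested = set(pairs["locus_a"]).union(pairs["locus_b"])
    pval = {}
    for row in pairs.itertuples(index=False):
        pval[frozenset((row.locus_a, row.locus_b))] = row.p_value
    blocks = []
    for chrom in sorted(gmap.table["chromosome"].unique()):
        loci = [l for l in gmap.loci_on(int(chrom)) if l in tested]
        run = [loci[0]] if loci else []
        for prev, cur in zip(loci, loci[1:]):
            p = pval.get(frozenset((prev, cur)), float("nan"))
            if np.isfinite(p) and p < alpha:
                run.append(cur)
            else:
                if len(run) >= min_loci:
                    blocks.append(_mk_block(int(chrom), run, gmap))
                run = [cur]
        if len(run) >= min_loci:
            blocks.append(_mk_block(int(chrom), run, gmap))
    return blocks


def _mk_block(chrom: int, run: list[str], gmap: GeneticMap) -> LDBlock:
    span = gmap.position_of(run[-1]) - gmap.position_of(run[0])
    return LDBlock(chrom, list(run), float(span))


def block_summary(blocks: list[LDBlock], n_chromosomes: int = 12) -> dict:
    """Per-chromosome block counts / mean spans and the two group means.

    The group mean span is reported both ways the per-chromosome means can
    be averaged: over chromosomes that have blocks, and over all
    chromosomes with blockless ones entering as 0.
    """
    per = {}
    for c in range(1, n_chromosomes + 1):
        spans = [b.span_cm for b in blocks if b.chromosome == c]
        per[c] = {"n_blocks": len(spans),
                  "mean_span_cm": float(np.mean(spans)) if spans else 0.0}
    chrom_means = [per[c]["mean_span_cm"] for c in per if per[c]["n_blocks"]]
    all_means = [per[c]["mean_span_cm"] for c in per]
    return {
        "per_chromosome": per,
        "total_blocks": sum(per[c]["n_blocks"] for c in per),
        "mean_span_nonzero_chromosomes": (float(np.mean(chrom_means))
                                          if chrom_means else 0.0),
        "mean_span_all_chromosomes": float(np.mean(all_means)),
    }
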