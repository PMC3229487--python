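"""Allele-frequency accounting and diversity / divergence statistics.

Statistics implemented for multiallelic co-dominant markers:

* gene diversity (expected heterozygosity)  He = 1 - sum p_i^2
* polymorphism information content          PIC = He - sum_{i<j} 2 p_i^2 p_j^2
* modified Rogers distance between groups   MRD = sqrt( sum_l sum_a (p_a - q_a)^2 / (2 m) )
* Nei's coefficient of gene differentiation Gst = (Ht - Hs) / Ht

Frequencies count allele copies (two per variety; heterozygotes contribute
both alleles) with pairwise deletion of missing calls, and the gene count
behind every frequency vector is kept for audit.  The genome scan computes
per-locus gene diversity per group and per-locus between-group MRD, each
with a bootstrap standard error from resampling varieties within groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._encoding import CopyMatrix, copy_matrix
from .panel import SSRPanel


@dataclass
class LocusFreqs:
    """Allele sizes, frequencies and the gene count behind them."""

    alleles: np.ndarray
    freqs: np.ndarray
    gene_count: int


class AlleleFreqTable:
    """(group, locus) -> allele-frequency vector with gene counts."""

    def __init__(self, groups, loci, data):
        self.groups = list(groups)
        self.loci = list(loci)
        self._data = data  # dict group -> dict locus -> LocusFreqs

    def freqs(self, group: str, locus: str) -> LocusFreqs:
        return self._data[group][locus]

    def group(self, group: str) -> dict[str, LocusFreqs]:
        return self._data[group]

    def present(self, group: str, locus: str) -> bool:
        """False when every call at this locus is missing in the group."""
        return self._data[group][locus].gene_count > 0


def _normalise_grouping(panel: SSRPanel, grouping) -> pd.Series:
    if isinstance(grouping, dict):
        grouping = pd.Series(grouping)
    grouping = grouping.astype(str)
    unknown = [v for v in grouping.index if v not in panel.variety_ids]
    if unknown:
        raise ValueError(f"grouping names unknown varieties: {unknown[:5]}")
    return grouping


def allele_frequencies(panel: SSRPanel, grouping) -> AlleleFreqTable:
    """Per-group, per-locus allele frequencies over non-missing copies.

    ``grouping`` maps variety id -> group name; every group must be
    non-empty.  Loci with no non-missing call in a group get an empty
    frequency vector with gene count 0 (flagged absent).
    """
    grouping = _normalise_grouping(panel, grouping)
    cm = copy_matrix(panel)
    vindex = {v: i for i, v in enumerate(panel.variety_ids)}
    data: dict[str, dict[str, LocusFreqs]] = {}
    groups = sorted(grouping.unique())
    for g in groups:
        rows = np.array([vindex[v] for v in grouping.index[grouping == g]])
        counts = cm.counts[rows].sum(axis=0).astype(float)
        genes = 2 * cm.valid[rows].sum(axis=0)
        per_locus = {}
        for j, locus in enumerate(panel.locus_ids):
            sl = cm.block(j)
            c = counts[sl]
            n_genes = int(genes[j])
            sizes = np.array([a for (_, a) in cm.columns[sl]])
            if n_genes == 0:
                per_locus[locus] = LocusFreqs(sizes, np.zeros_like(c), 0)
            else:
                per_locus[locus] = LocusFreqs(sizes, c / n_genes, n_genes)
        data[g] = per_locus
    return AlleleFreqTable(groups, panel.locus_ids, data)


def _check_freqs(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must be non-negative and sum to 1")
    return p


def gene_diversity(freqs) -> float:
    """Nei's gene diversity He = 1 - sum p_i^2."""
    p = _check_freqs(freqs)
    return float(1.0 - np.sum(p ** 2))


def pic(freqs) -> float:
    """Botstein's polymorphism information content.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2, always <= He.
    """
    p = _check_freqs(freqs)
    s2 = np.sum(p ** 2)
    s4 = np.sum(p ** 4)
    return float(1.0 - s2 - (s2 ** 2 - s4))


def mrd(freqs_a, freqs_b, loci=None) -> float:
    """Modified Rogers distance between two groups' frequency tables.

    ``freqs_a`` / ``freqs_b`` map locus -> :class:`LocusFreqs` (e.g. from
    :meth:`AlleleFreqTable.group`).  Alleles absent in one group enter with
    frequency zero.
    """
    if loci is None:
        loci = [l for l in freqs_a if freqs_a[l].gene_count > 0
                and l in freqs_b and freqs_b[l].gene_count > 0]
    loci = list(loci)
    if not loci:
        raise ValueError("empty locus set for MRD")
    total = 0.0
    for locus in loci:
        fa, fb = freqs_a[locus], freqs_b[locus]
        sizes = np.union1d(fa.alleles, fb.alleles)
        pa = np.zeros(sizes.size)
        pb = np.zeros(sizes.size)
        pa[np.searchsorted(sizes, fa.alleles)] = fa.freqs
        pb[np.searchsorted(sizes, fb.alleles)] = fb.freqs
        total += np.sum((pa - pb) ** 2)
    return float(np.sqrt(total / (2.0 * len(loci))))


def gst(table: AlleleFreqTable, groups=None) -> float:
    """Nei's Gst = (Ht - Hs)/Ht over the table's loci.

    Per locus, groups are weighted by their gene counts; Hs is the weighted
    mean within-group diversity and Ht the diversity of the pooled
    frequencies; both are averaged over loci before the ratio.  Returns NaN
    when Ht is zero (all groups monomorphic for the same allele).
    """
    groups = list(groups) if groups is not None else table.groups
    if len(groups) < 2:
        raise ValueError("Gst requires at least two groups")
    hs_vals, ht_vals = [], []
    for locus in table.loci:
        lfs = [table.freqs(g, locus) for g in groups]
        lfs = [lf for lf in lfs if lf.gene_count > 0]
        if len(lfs) < 2:
            continue
        w = np.array([lf.gene_count for lf in lfs], dtype=float)
        w /= w.sum()
        sizes = lfs[0].alleles  # all groups share the panel-wide allele list
        mat = np.vstack([lf.freqs for lf in lfs])
        hs = np.sum(w * (1.0 - np.sum(mat ** 2, axis=1)))
        pooled = w @ mat
        ht = 1.0 - np.sum(pooled ** 2)
        hs_vals.append(hs)
        ht_vals.append(ht)
    ht_bar = float(np.mean(ht_vals))
    hs_bar = float(np.mean(hs_vals))
    if ht_bar <= 0:
        return float("nan")
    return (ht_bar - hs_bar) / ht_bar


def pairwise_mrd(panel: SSRPanel) -> pd.DataFrame:
    """Variety x variety MRD matrix.

    Each variety's within-variety allele frequencies (0 / 0.5 / 1 per
    allele) act as a frequency vector; loci missing in either variety of a
    pair are dropped from that pair (pairwise deletion).
    """
    cm = copy_matrix(panel)
    n = panel.n_varieties
    d2 = np.zeros((n, n))
    m_shared = np.zeros((n, n))
    for j in range(panel.n_loci):
        sl = cm.block(j)
        x = cm.counts[:, sl].astype(float) / 2.0
        v = cm.valid[:, j].astype(float)
        x = x * v[:, None]
        g = x @ x.T
        s = np.diag(g)
        contrib = s[:, None] + s[None, :] - 2 * g
        vv = np.outer(v, v)
        d2 += contrib * vv
        m_shared += vv
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(d2 / (2.0 * m_shared))
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=panel.variety_ids, columns=panel.variety_ids)


@dataclass
class DiversitySummary:
    """Genome-scan and per-group summary of diversity statistics."""

    per_locus: pd.DataFrame
    per_group: pd.DataFrame
    mrd: float
    mrd_groups: tuple[str, str] | None
    gst: float
    n_bootstrap: int
    seed: int | None = None


def _he_per_locus(counts: np.ndarray, genes: np.ndarray,
                  starts: np.ndarray) -> np.ndarray:
    """He per locus from allele counts (…, A) and gene counts (…, m)."""
    sq = np.add.reduceat(counts.astype(float) ** 2, starts, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        he = 1.0 - sq / (genes.astype(float) ** 2)
    return he


def diversity_scan(panel: SSRPanel, grouping, n_bootstrap: int = 1000,
                   seed: int | None = None,
                   mrd_groups: tuple[str, str] | None = None,
                   ) -> DiversitySummary:
    """Per-locus diversity scan with bootstrap standard errors.

    For every locus and group: allele count, gene diversity, PIC and a
    bootstrap SE of the gene diversity (resampling varieties within the
    group with replacement).  When the grouping has exactly two groups (or
    ``mrd_groups`` names two), per-locus MRD between them is scanned with
    its own bootstrap SE.  Unique alleles are alleles observed in exactly
    one group.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    grouping = _normalise_grouping(panel, grouping)
    groups = sorted(grouping.unique())
    if mrd_groups is None and len(groups) == 2:
        mrd_groups = (groups[0], groups[1])
    if mrd_groups is not None and (len(mrd_groups) != 2
                                   or any(g not in groups for g in mrd_groups)):
        raise ValueError(f"MRD scan needs two known groups, got {mrd_groups}")
    if mrd_groups is None and len(groups) > 2:
        raise ValueError("MRD scan requires exactly 2 groups; pass mrd_groups")

    rng = np.random.default_rng(seed)
    cm = copy_matrix(panel)
    vindex = {v: i for i, v in enumerate(panel.variety_ids)}
    m = panel.n_loci
    starts = cm.starts

    rows = {g: np.array([vindex[v] for v in grouping.index[grouping == g]])
            for g in groups}
    counts = {g: cm.counts[rows[g]].sum(axis=0).astype(float) for g in groups}
    genes = {g: 2.0 * cm.valid[rows[g]].sum(axis=0) for g in groups}

    # bootstrap replicates: multinomial variety weights per group
    boots_counts, boots_genes = {}, {}
    for g in groups:
        ng = rows[g].size
        w = rng.multinomial(ng, np.full(ng, 1.0 / ng), size=n_bootstrap)
        boots_counts[g] = w @ cm.counts[rows[g]].astype(float)
        boots_genes[g] = 2.0 * (w @ cm.valid[rows[g]].astype(float))

    per_locus = pd.DataFrame(index=pd.Index(panel.locus_ids, name="locus"))
    presence = {}
    for g in groups:
        he = _he_per_locus(counts[g], genes[g], starts)
        he_boot = _he_per_locus(boots_counts[g], boots_genes[g], starts)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = {j: counts[g][cm.block(j)] / genes[g][j] if genes[g][j] > 0
                    else None for j in range(m)}
        n_alleles = np.array([0 if freq[j] is None
                              else int(np.count_nonzero(freq[j] > 0))
                              for j in range(m)])
        pics = np.array([np.nan if freq[j] is None
                         else pic(freq[j]) for j in range(m)])
        presence[g] = [counts[g][cm.block(j)] > 0 for j in range(m)]
        per_locus[f"allele_count_{g}"] = n_alleles
        per_locus[f"he_{g}"] = he
        per_locus[f"pic_{g}"] = pics
        per_locus[f"he_se_{g}"] = np.nanstd(he_boot, axis=0, ddof=1)

    widths = np.diff(np.append(starts, cm.counts.shape[1]))
    if mrd_groups is not None:
        a, b = mrd_groups
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = counts[a] / np.repeat(genes[a], widths)
            pb = counts[b] / np.repeat(genes[b], widths)
        sq = np.add.reduceat((pa - pb) ** 2, starts)
        per_locus["mrd"] = np.sqrt(sq / 2.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ba = boots_counts[a] / np.repeat(boots_genes[a], widths, axis=1)
            bb = boots_counts[b] / np.repeat(boots_genes[b], widths, axis=1)
        bsq = np.add.reduceat((ba - bb) ** 2, starts, axis=1)
        per_locus["mrd_se"] = np.nanstd(np.sqrt(bsq / 2.0), axis=0, ddof=1)

    # unique alleles: observed in exactly one group
    unique_counts = {g: 0 for g in groups}
    for j in range(m):
        block = np.vstack([presence[g][j] for g in groups])
        n_groups_with = block.sum(axis=0)
        for gi, g in enumerate(groups):
            unique_counts[g] += int(np.sum(block[gi] & (n_groups_with == 1)))

    per_group = pd.DataFrame(index=pd.Index(groups, name="group"))
    for g in groups:
        ac = per_locus[f"allele_count_{g}"]
        ok = ac > 0
        per_group.loc[g, "n_varieties"] = rows[g].size
        per_group.loc[g, "mean_allele_count"] = ac[ok].mean()
        per_group.loc[g, "mean_allele_frequency"] = (1.0 / ac[ok]).mean()
        per_group.loc[g, "unique_alleles"] = unique_counts[g]
        per_group.loc[g, "mean_gene_diversity"] = per_locus[f"he_{g}"][ok].mean()

    table = allele_frequencies(panel, grouping)
    whole_mrd = (mrd(table.group(mrd_groups[0]), table.group(mrd_groups[1]))
                 if mrd_groups is not None else float("nan"))
    g_st = gst(table) if len(groups) >= 2 else float("nan")
    return DiversitySummary(per_locus, per_group, whole_mrd, mrd_groups,
                            g_st, n_bootstrap, seed)


def scan_to_tsv(summary: DiversitySummary, gmap, path) -> None:
    """Write the per-locus scan with map coordinates as a TSV."""
    out = summary.per_locus.copy()
    out.insert(0, "chromosome", [gmap.chromosome_of(l) for l in out.index])
    out.insert(1, "position_cm", [gmap.position_of(l) for l in out.index])
    out.to_csv(path, sep="\t")
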