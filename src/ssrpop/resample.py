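"""Marker-number sufficiency analysis by subset resampling.

How many markers does the panel need before the inferred population
structure and the pairwise genetic distances stop improving?  Marker
subsets of growing size are drawn either uniformly at random or
stratified (per-chromosome quotas proportional to chromosome marker
counts, then spacing-uniform picks within each chromosome); for each
subset the mixture clustering is refitted and compared against the
full-marker assignment, and the coefficient of variation of pairwise
modified Rogers distances across repetitions is tracked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import pairwise_mrd
from .panel import GeneticMap, SSRPanel
from .structure import DEFAULT_FAMILIES, assign, correspondence, structure_pipeline

STRATEGIES = ("random", "stratified")


def _largest_remainder_quotas(counts: np.ndarray, n: int) -> np.ndarray:
    """Integer per-chromosome quotas summing to n, proportional to counts."""
    share = n * counts / counts.sum()
    base = np.floor(share).astype(int)
    base = np.minimum(base, counts)
    remainder = share - base
    free = counts - base
    order = np.argsort(-remainder, kind="stable")
    short = n - base.sum()
    for idx in order:
        if short == 0:
            break
        if free[idx] > 0:
            base[idx] += 1
            free[idx] -= 1
            short -= 1
    # spill over if some chromosomes saturated
    while base.sum() < n:
        for idx in np.argsort(-free, kind="stable"):
            if free[idx] > 0:
                base[idx] += 1
                free[idx] -= 1
                break
    return base


def subsample_markers(gmap: GeneticMap, n: int, strategy: str = "random",
                      seed: int | None = None) -> list[str]:
    """Pick ``n`` loci from the map.

    ``random``: uniform without replacement.  ``stratified``: quotas per
    chromosome by largest-remainder proportional rounding, then the
    chromosome's map-ordered loci are cut into that many contiguous
    equal-count segments and one locus is drawn uniformly from each, so
    picks spread evenly along the map while repetitions still vary.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    loci = gmap.loci
    if not (1 <= n <= len(loci)):
        raise ValueError(f"n must be in 1..{len(loci)}, got {n}")
    rng = np.random.default_rng(seed)
    if strategy == "random":
        return sorted(rng.choice(loci, size=n, replace=False).tolist())
    chroms = sorted(gmap.table["chromosome"].unique())
    counts = np.array([len(gmap.loci_on(c)) for c in chroms])
    quotas = _largest_remainder_quotas(counts, n)
    picked: list[str] = []
    for chrom, q in zip(chroms, quotas):
        if q == 0:
            continue
        ordered = gmap.loci_on(int(chrom))
        if q >= len(ordered):
            picked.extend(ordered)
            continue
        bounds = np.linspace(0, len(ordered), q + 1).round().astype(int)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            picked.append(ordered[int(rng.integers(lo, hi))])
    return sorted(picked)


@dataclass
class ResamplingCurve:
    strategy: str
    table: pd.DataFrame   # size, mean_correspondence, se_correspondence, mean_cv
    n_repetitions: int
    seed: int | None
    plateau_size: int | None   # smallest size with mean correspondence >= 0.95


def sufficiency_curves(panel: SSRPanel, gmap: GeneticMap,
                       grid=None, reps: int = 100,
                       strategies=STRATEGIES, seed: int | None = None,
                       n_pcs: int = 10, k_range=None,
                       families=DEFAULT_FAMILIES,
                       plateau_threshold: float = 0.95,
                       ) -> dict[str, ResamplingCurve]:
    """Correspondence and MRD-CV curves over marker-subset sizes.

    The full-marker mixture assignment (max-probability rule) is the
    reference.  For every grid size, strategy and repetition the mixture
    is refitted on the subset (at the reference K) and its labels compared
    to the reference; pairwise MRD on the subset feeds a per-pair CV
    across repetitions, averaged over pairs (zero-mean pairs excluded).
    Per-repetition seeds derive deterministically from the master seed.
    """
    if grid is None:
        grid = list(range(12, len(gmap) + 1, 12))
    grid = sorted(grid)
    if grid[-1] > len(gmap):
        warnings.warn(f"grid truncated to the {len(gmap)} mapped loci")
        grid = [g for g in grid if g <= len(gmap)]
    ss = np.random.SeedSequence(seed)
    ref_seed, *rep_seeds = [int(s) for s in
                            ss.generate_state(1 + reps) % (2 ** 31)]
    sel, _ = structure_pipeline(panel, n_pcs=n_pcs,
                                k_range=k_range or range(1, 11),
                                families=families, seed=ref_seed)
    ref_labels = assign(sel.membership, rule="max")
    k_ref = sel.best_k

    out = {}
    for strategy in strategies:
        rows = []
        for size in grid:
            corr = np.empty(reps)
            mrds = np.empty((reps, panel.n_varieties * (panel.n_varieties - 1) // 2))
            iu = np.triu_indices(panel.n_varieties, k=1)
            for rep in range(reps):
                rseed = (rep_seeds[rep] + size * 7919) % (2 ** 31)
                loci = subsample_markers(gmap, size, strategy, seed=rseed)
                sub = panel.subset_loci(loci)
                ssel, _ = structure_pipeline(
                    sub, n_pcs=min(n_pcs, size),
                    k_range=[k_ref], families=families, seed=rseed)
                corr[rep] = correspondence(assign(ssel.membership, "max"),
                                           ref_labels)
                mrds[rep] = pairwise_mrd(sub).to_numpy()[iu]
            mean_pair = mrds.mean(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cv_pair = mrds.std(axis=0) / mean_pair
            cv_pair = cv_pair[mean_pair > 0]
            rows.append({"size": size,
                         "mean_correspondence": corr.mean(),
                         "se_correspondence": corr.std(ddof=1) / np.sqrt(reps),
                         "mean_cv": float(np.nanmean(cv_pair))})
        table = pd.DataFrame(rows)
        plateau = table.loc[table["mean_correspondence"]
                            >= plateau_threshold, "size"]
        out[strategy] = ResamplingCurve(
            strategy, table, reps, seed,
            int(plateau.min()) if not plateau.empty else None)
    return out
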