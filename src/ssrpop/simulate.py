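"""Synthetic two-subpopulation SSR panels with matching trait tables.

The generator emulates a selfing (inbred) rice panel split into two
diverged subpopulations plus a small admixed fraction:

* per locus, an ancestral allele-frequency vector is drawn from a flat
  Dirichlet over the allele simplex;
* each subpopulation's frequencies are drawn around the ancestral vector
  from a Balding-Nichols-style Dirichlet with concentration (1-F)/F, so
  the divergence parameter F in [0, 1) controls how far the two
  subpopulations drift apart;
* each variety draws one allele per locus from its (possibly
  admixture-weighted) frequency vector and is homozygous with the
  configured selfing rate, otherwise draws a second independent allele;
* missing calls are injected uniformly at random.

Defaults mirror the study panel this package is designed around:
150 varieties (111 / 20 / 19 in subpopulation 1 / 2 / admixed), 274 loci
spread over 12 chromosomes with the per-chromosome locus counts and mean
inter-locus spacings of the published map, 2-12 alleles per locus
averaging ~3.9, homozygosity 0.95.  ``calibrate_divergence`` finds by
bisection the F whose realized between-subpopulation modified Rogers
distance matches a target (the study's indica/japonica MRD is 0.443).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import MISSING, GeneticMap, SSRPanel, validate_traits
from .diversity import allele_frequencies, mrd

SUBPOP1 = "subpop1"   # indica-like
SUBPOP2 = "subpop2"   # japonica-like
ADMIXED = "admixed"

#: per-chromosome locus counts of the reference 274-marker map
DEFAULT_LOCI_PER_CHROMOSOME = (23, 25, 24, 22, 21, 22, 21, 25, 23, 24, 23, 21)
#: per-chromosome mean inter-locus spacing (cM) of the reference map
DEFAULT_SPACING_CM = (7.5, 8.2, 9.4, 7.4, 7.1, 6.3, 5.8, 5.4, 5.2, 4.7, 5.6, 5.3)


@dataclass
class SimConfig:
    """Parameters of the synthetic panel generator (seed mandatory)."""

    seed: int
    n_subpop1: int = 111
    n_subpop2: int = 20
    n_admixed: int = 19
    loci_per_chromosome: tuple = DEFAULT_LOCI_PER_CHROMOSOME
    mean_spacing_cm: tuple = DEFAULT_SPACING_CM
    min_alleles: int = 2
    max_alleles: int = 12
    mean_extra_alleles: float = 1.9   # alleles/locus ~ min + Poisson, mean ~3.9
    divergence: float = 0.33          # F; default near the MRD~0.44 calibration
    admix_low: float = 0.2
    admix_high: float = 0.8
    homozygosity: float = 0.95
    missing_rate: float = 0.02
    trait_p_indica: float = 0.12      # per-trait score ~ Binomial(4, p)
    trait_p_japonica: float = 0.88

    def __post_init__(self):
        if len(self.loci_per_chromosome) != 12:
            raise ValueError("expected 12 per-chromosome locus counts")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence F must be in [0, 1)")
        for name in ("homozygosity", "missing_rate", "admix_low", "admix_high",
                     "trait_p_indica", "trait_p_japonica"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_alleles < 2 or self.max_alleles < self.min_alleles:
            raise ValueError("need 2 <= min_alleles <= max_alleles")

    @property
    def n_loci(self) -> int:
        return int(sum(self.loci_per_chromosome))

    @property
    def n_varieties(self) -> int:
        return self.n_subpop1 + self.n_subpop2 + self.n_admixed


@dataclass
class SimResult:
    panel: SSRPanel
    genetic_map: GeneticMap
    labels: pd.Series            # variety -> subpop1 / subpop2 / admixed
    admixture: pd.Series         # variety -> subpopulation-1 ancestry fraction


def simulate_panel(config: SimConfig) -> SimResult:
    """Draw a panel, its genetic map and the truth labels/ancestries."""
    rng = np.random.default_rng(config.seed)
    F = config.divergence
    if F == 0.0 and config.n_subpop1 > 0 and config.n_subpop2 > 0:
        warnings.warn("F=0: subpopulations are exchangeable (no divergence)")
    n = config.n_varieties
    m = config.n_loci

    labels = ([SUBPOP1] * config.n_subpop1 + [SUBPOP2] * config.n_subpop2
              + [ADMIXED] * config.n_admixed)
    q1 = np.concatenate([
        np.ones(config.n_subpop1),
        np.zeros(config.n_subpop2),
        rng.uniform(config.admix_low, config.admix_high, config.n_admixed),
    ])

    variety_ids = [f"V{i + 1:03d}" for i in range(n)]
    locus_ids, chroms, positions = [], [], []
    for c, (count, spacing) in enumerate(zip(config.loci_per_chromosome,
                                             config.mean_spacing_cm), start=1):
        gaps = rng.exponential(spacing, size=count)
        pos = np.concatenate([[0.0], np.cumsum(gaps[1:])])
        for i in range(count):
            locus_ids.append(f"M{c:02d}_{i + 1:02d}")
            chroms.append(c)
            positions.append(round(float(pos[i]), 3))

    calls = np.empty((n, m, 2), dtype=np.int32)
    hom = rng.random((n, m)) < config.homozygosity
    for j in range(m):
        k = min(config.min_alleles + rng.poisson(config.mean_extra_alleles),
                config.max_alleles)
        ancestral = rng.dirichlet(np.ones(k))
        if F > 0:
            conc = (1.0 - F) / F
            p1 = rng.dirichlet(np.maximum(ancestral * conc, 1e-9))
            p2 = rng.dirichlet(np.maximum(ancestral * conc, 1e-9))
        else:
            p1 = p2 = ancestral
        p_eff = q1[:, None] * p1[None, :] + (1.0 - q1)[:, None] * p2[None, :]
        cum = np.cumsum(p_eff, axis=1)
        a1 = (rng.random(n)[:, None] > cum[:, :-1]).sum(axis=1)
        a2 = (rng.random(n)[:, None] > cum[:, :-1]).sum(axis=1)
        a2 = np.where(hom[:, j], a1, a2)
        base = int(rng.integers(80, 300))
        sizes = base + 2 * np.arange(k)
        calls[:, j, 0] = sizes[a1]
        calls[:, j, 1] = sizes[a2]

    miss = rng.random((n, m)) < config.missing_rate
    # keep the panel invariant: every locus retains >= 1 non-missing call
    for j in np.flatnonzero(miss.all(axis=0)):
        miss[rng.integers(n), j] = False
    calls[miss] = MISSING

    panel = SSRPanel(variety_ids, locus_ids, calls)
    gmap = GeneticMap(pd.DataFrame(
        {"chromosome": chroms, "position": positions},
        index=pd.Index(locus_ids, name="locus")))
    labels = pd.Series(labels, index=variety_ids, name="label")
    admixture = pd.Series(q1, index=variety_ids, name="q_subpop1")
    return SimResult(panel, gmap, labels, admixture)


def realized_mrd(result: SimResult) -> float:
    """Between-subpopulation MRD of a simulated panel (admixed excluded)."""
    core = result.labels[result.labels != ADMIXED]
    sub = result.panel.subset_varieties(core.index.tolist())
    table = allele_frequencies(sub, core)
    return mrd(table.group(SUBPOP1), table.group(SUBPOP2))


def calibrate_divergence(config: SimConfig, target_mrd: float = 0.443,
                         tol: float = 0.005, max_iter: int = 30,
                         lo: float = 1e-3, hi: float = 0.95) -> SimConfig:
    """Bisect F so the realized between-subpopulation MRD hits a target.

    Finite-allele sampling makes the F -> MRD map configuration-dependent,
    so the calibration simulates at the config's own seed and sizes.
    """
    def realized(f: float) -> float:
        return realized_mrd(simulate_panel(replace(config, divergence=f)))

    f_lo, f_hi = lo, hi
    if realized(f_hi) < target_mrd:
        warnings.warn("target MRD not reachable below F=%.2f; using it" % hi)
        return replace(config, divergence=f_hi)
    for _ in range(max_iter):
        mid = 0.5 * (f_lo + f_hi)
        val = realized(mid)
        if abs(val - target_mrd) < tol:
            return replace(config, divergence=mid)
        if val < target_mrd:
            f_lo = mid
        else:
            f_hi = mid
    return replace(config, divergence=0.5 * (f_lo + f_hi))


def _numeric_from_score(trait: str, score: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw a measurement that scores back to the intended ordinal level."""
    if trait == "rachis_cm":
        bins = [(1.0, 2.0), (2.05, 2.5), (2.55, 3.0), (3.05, 3.5), (3.55, 4.5)]
    else:  # grain_lw: reverse-scored (round japonica grains -> high score)
        bins = [(3.55, 4.3), (3.1, 3.5), (2.6, 3.05), (2.1, 2.55), (1.4, 2.05)]
    lo = np.array([bins[s][0] for s in score])
    hi = np.array([bins[s][1] for s in score])
    return np.round(rng.uniform(lo, hi), 2)


def simulate_traits(labels: pd.Series, config: SimConfig,
                    admixture: pd.Series | None = None) -> pd.DataFrame:
    """Class-conditional six-trait table for simulated varieties.

    Each trait score is Binomial(4, p) with p near ``trait_p_indica`` for
    subpopulation 1, near ``trait_p_japonica`` for subpopulation 2, and
    interpolated by ancestry for admixed varieties, so the summed index
    concentrates in the typical-indica / typical-japonica / intermediate
    ranges respectively.  The two measured traits are drawn inside the
    scoring bin of their intended ordinal level.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if admixture is None:
        admixture = labels.map({SUBPOP1: 1.0, SUBPOP2: 0.0, ADMIXED: 0.5})
    q1 = admixture.loc[labels.index].to_numpy(dtype=float)
    p = config.trait_p_indica + (config.trait_p_japonica
                                 - config.trait_p_indica) * (1.0 - q1)
    n = len(labels)
    scores = rng.binomial(4, p[:, None], size=(n, 6))
    table = pd.DataFrame(index=labels.index.copy())
    table.index.name = "variety"
    table["glume_hair"] = scores[:, 0]
    table["phenol_reaction"] = scores[:, 1]
    table["rachis_cm"] = _numeric_from_score("rachis_cm", scores[:, 2], rng)
    table["glume_color"] = scores[:, 3]
    table["leaf_hair"] = scores[:, 4]
    table["grain_lw"] = _numeric_from_score("grain_lw", scores[:, 5], rng)
    return validate_traits(table)
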