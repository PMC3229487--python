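"""Internal allele-copy encoding shared by diversity and structure code."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import MISSING, SSRPanel


@dataclass
class CopyMatrix:
    """Allele-copy counts per variety.

    ``counts`` is (n_varieties, n_alleles_total) with entries 0/1/2 (copies
    of each allele carried), zero on missing calls; ``valid`` is
    (n_varieties, n_loci) with True where the call is present.  Columns are
    grouped by locus, alleles in ascending bp order; ``starts`` gives the
    first column of each locus block (usable with ``np.add.reduceat``).
    """

    counts: np.ndarray
    valid: np.ndarray
    columns: list[tuple[str, int]]
    locus_ids: list[str]
    starts: np.ndarray

    def block(self, j: int) -> slice:
        end = (self.starts[j + 1] if j + 1 < len(self.starts)
               else self.counts.shape[1])
        return slice(int(self.starts[j]), int(end))


def copy_matrix(panel: SSRPanel) -> CopyMatrix:
    n, m = panel.n_varieties, panel.n_loci
    columns: list[tuple[str, int]] = []
    starts = np.zeros(m, dtype=int)
    allele_index: list[dict[int, int]] = []
    for j, locus in enumerate(panel.locus_ids):
        starts[j] = len(columns)
        alleles = panel.alleles_at(locus)
        allele_index.append({int(a): len(columns) + i
                             for i, a in enumerate(alleles)})
        columns.extend((locus, int(a)) for a in alleles)
    counts = np.zeros((n, len(columns)), dtype=np.int8)
    valid = panel.calls[..., 0] != MISSING
    for j in range(m):
        idx = allele_index[j]
        for i in range(n):
            if valid[i, j]:
                a, b = panel.calls[i, j]
                counts[i, idx[int(a)]] += 1
                counts[i, idx[int(b)]] += 1
    return CopyMatrix(counts, valid, columns, list(panel.locus_ids), starts)
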