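"""Genotype panels, genetic maps and morphological trait tables.

An SSR (simple sequence repeat, microsatellite) panel stores diploid
allele-size calls (fragment lengths in base pairs) for a set of varieties
at a set of mapped loci.  These are multiallelic co-dominant markers: a
call is an unordered pair of sizes, e.g. ``120/124``, with homozygotes
written either ``120/120`` or by the shorthand ``120``.

File dialects
-------------
* genotype table: TSV/CSV, varieties as rows, loci as columns, first
  column the variety id; missing calls written as ``NA``, ``-9`` or empty.
* genetic map: TSV with columns ``locus``, ``chromosome`` (1-12),
  ``position`` (cM).
* trait table: CSV with the six subspecies-diagnostic trait columns
  (four pre-scored ordinals 0-4 plus two numeric measurements).
* STRUCTURE numeric export: two rows per individual, alleles recoded to
  consecutive integers per locus, missing as -9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
DEFAULT_MISSING_TOKENS = ("NA", "-9", "")

#: ordinal trait columns (pre-scored 0-4) and numeric trait columns
ORDINAL_TRAITS = ("glume_hair", "phenol_reaction", "glume_color", "leaf_hair")
NUMERIC_TRAITS = ("rachis_cm", "grain_lw")
TRAIT_COLUMNS = ("glume_hair", "phenol_reaction", "rachis_cm",
                 "glume_color", "leaf_hair", "grain_lw")


class PanelFormatError(ValueError):
    """Structural problem in an input table (duplicate ids, bad header...)."""


class CallParseError(ValueError):
    """A genotype call that cannot be parsed; carries row/column context."""

    def __init__(self, message: str, row: str | None = None,
                 column: str | None = None):
        self.row, self.column = row, column
        loc = ""
        if row is not None or column is not None:
            loc = f" (row={row!r}, column={column!r})"
        super().__init__(message + loc)


@dataclass
class SSRPanel:
    """Varieties x loci diploid allele-size calls.

    ``calls`` has shape (n_varieties, n_loci, 2) with allele sizes in bp;
    both entries are ``MISSING`` (-1) for a missing call and each stored
    pair is sorted so comparison is order-insensitive.
    """

    variety_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.variety_ids = list(map(str, self.variety_ids))
        self.locus_ids = list(map(str, self.locus_ids))
        if len(set(self.variety_ids)) != len(self.variety_ids):
            raise PanelFormatError("duplicate variety ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise PanelFormatError("duplicate locus ids")
        calls = np.asarray(self.calls, dtype=np.int32)
        if calls.shape != (len(self.variety_ids), len(self.locus_ids), 2):
            raise PanelFormatError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.variety_ids)} varieties x {len(self.locus_ids)} loci")
        miss = calls == MISSING
        if np.any(miss[..., 0] != miss[..., 1]):
            raise PanelFormatError("half-missing call: both alleles must be "
                                   "present or both missing")
        if np.any((calls <= 0) & ~miss):
            raise PanelFormatError("allele sizes must be strictly positive")
        calls = np.sort(calls, axis=2)
        dead = np.all(miss[..., 0], axis=0)
        if np.any(dead):
            bad = [self.locus_ids[i] for i in np.flatnonzero(dead)]
            raise PanelFormatError(f"loci with no non-missing call: {bad}")
        self.calls = calls

    @property
    def n_varieties(self) -> int:
        return len(self.variety_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """(n_varieties, n_loci) boolean, True where the call is missing."""
        return self.calls[..., 0] == MISSING

    def locus_index(self, locus: str) -> int:
        return self.locus_ids.index(locus)

    def subset_loci(self, loci: list[str]) -> "SSRPanel":
        idx = [self.locus_ids.index(l) for l in loci]
        return SSRPanel(self.variety_ids, list(loci), self.calls[:, idx, :])

    def subset_varieties(self, varieties: list[str]) -> "SSRPanel":
        idx = [self.variety_ids.index(v) for v in varieties]
        return SSRPanel(list(varieties), self.locus_ids, self.calls[idx])

    def alleles_at(self, locus: str) -> np.ndarray:
        """Sorted distinct observed allele sizes at a locus."""
        j = self.locus_index(locus)
        col = self.calls[:, j, :].ravel()
        return np.unique(col[col != MISSING])

    def __eq__(self, other) -> bool:
        return (isinstance(other, SSRPanel)
                and self.variety_ids == other.variety_ids
                and self.locus_ids == other.locus_ids
                and np.array_equal(self.calls, other.calls))


@dataclass
class GeneticMap:
    """locus -> (chromosome 1-12, position in cM)."""

    table: pd.DataFrame  # index locus_id; columns: chromosome (int), position (float)

    def __post_init__(self):
        t = self.table
        if list(t.columns[:2]) != ["chromosome", "position"]:
            t = t[["chromosome", "position"]]
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise PanelFormatError(f"duplicate locus rows in map: {dups}")
        chrom = t["chromosome"].to_numpy()
        if not np.issubdtype(np.asarray(chrom).dtype, np.integer):
            raise PanelFormatError("chromosome must be integer")
        if chrom.min() < 1 or chrom.max() > 12:
            bad = sorted(set(chrom[(chrom < 1) | (chrom > 12)].tolist()))
            raise PanelFormatError(f"chromosome outside 1-12: {bad}")
        if (t["position"] < 0).any():
            raise PanelFormatError("map positions must be >= 0 cM")
        self.table = t.astype({"chromosome": int, "position": float})

    def __len__(self) -> int:
        return len(self.table)

    @property
    def loci(self) -> list[str]:
        return self.table.index.tolist()

    def chromosome_of(self, locus: str) -> int:
        return int(self.table.at[locus, "chromosome"])

    def position_of(self, locus: str) -> float:
        return float(self.table.at[locus, "position"])

    def loci_on(self, chromosome: int) -> list[str]:
        """Loci on one chromosome ordered by cM position (stable on ties)."""
        sub = self.table[self.table["chromosome"] == chromosome]
        return sub.sort_values("position", kind="stable").index.tolist()

    def same_chromosome(self, a: str, b: str) -> bool:
        return self.chromosome_of(a) == self.chromosome_of(b)

    def distance(self, a: str, b: str) -> float:
        """|cM difference|; only meaningful on the same chromosome."""
        return abs(self.position_of(a) - self.position_of(b))

    def check_panel(self, panel: SSRPanel) -> list[str]:
        """Warn about (and return) panel loci absent from the map."""
        unmapped = [l for l in panel.locus_ids if l not in self.table.index]
        if unmapped:
            warnings.warn(f"{len(unmapped)} panel loci not in map: "
                          f"{unmapped[:10]}{'...' if len(unmapped) > 10 else ''}")
        return unmapped


def _parse_call(token: str, missing_tokens, row: str, col: str):
    tok = token.strip()
    if tok in missing_tokens:
        return (MISSING, MISSING)
    parts = tok.split("/")
    if len(parts) == 1:
        parts = [parts[0], parts[0]]  # homozygote shorthand
    if len(parts) != 2:
        raise CallParseError(f"cannot parse call {token!r}", row, col)
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError:
        raise CallParseError(f"non-integer allele in {token!r}", row, col) from None
    return (a, b)


def _sep_for(path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_panel(path, dialect: str | None = None,
               missing_tokens=DEFAULT_MISSING_TOKENS) -> SSRPanel:
    """Read a genotype table (varieties as rows, loci as columns)."""
    sep = _sep_for(path, dialect)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    loci = header[1:]
    seen = {l for l in loci if loci.count(l) > 1}
    if seen:
        raise PanelFormatError(f"duplicate locus header: {sorted(seen)}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    variety_ids = df.iloc[:, 0].tolist()
    if len(set(variety_ids)) != len(variety_ids):
        dups = sorted({v for v in variety_ids if variety_ids.count(v) > 1})
        raise PanelFormatError(f"duplicate variety ids: {dups}")
    calls = np.empty((len(variety_ids), len(loci), 2), dtype=np.int32)
    for i, vid in enumerate(variety_ids):
        for j, locus in enumerate(loci):
            calls[i, j] = _parse_call(df.iat[i, j + 1], missing_tokens, vid, locus)
    return SSRPanel(variety_ids, loci, calls)


def write_panel(panel: SSRPanel, path, dialect: str | None = None,
                missing_token: str = "NA") -> None:
    sep = _sep_for(path, dialect)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["variety"] + panel.locus_ids) + "\n")
        for i, vid in enumerate(panel.variety_ids):
            row = [vid]
            for j in range(panel.n_loci):
                a, b = panel.calls[i, j]
                row.append(missing_token if a == MISSING else f"{a}/{b}")
            fh.write(sep.join(row) + "\n")


def read_map(path) -> GeneticMap:
    """Read a three-column (locus, chromosome, position-cM) map TSV."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    for col in ("locus", "chromosome", "position"):
        if col not in df.columns:
            raise PanelFormatError(f"map file missing column {col!r}")
    try:
        chrom = df["chromosome"].astype(int)
    except ValueError:
        raise PanelFormatError("non-integer chromosome in map") from None
    table = pd.DataFrame({"chromosome": chrom.to_numpy(),
                          "position": df["position"].astype(float).to_numpy()},
                         index=pd.Index(df["locus"].astype(str), name="locus"))
    return GeneticMap(table)


def write_map(gmap: GeneticMap, path) -> None:
    df = gmap.table.reset_index()
    df.columns = ["locus", "chromosome", "position"]
    df.to_csv(path, sep="\t", index=False)


def read_traits(path) -> pd.DataFrame:
    """Read a trait CSV into a validated table indexed by variety id.

    Columns: four ordinal scores (0-4) plus rachis-internode length (cm)
    and grain length/width ratio (both > 0).
    """
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "variety"
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"trait table missing columns {missing}")
    df = df[list(TRAIT_COLUMNS)]
    return validate_traits(df)


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    for c in ORDINAL_TRAITS:
        v = df[c]
        if not ((v >= 0) & (v <= 4) & (v == v.astype(int))).all():
            raise PanelFormatError(f"ordinal trait {c!r} outside {{0..4}}")
    for c in NUMERIC_TRAITS:
        if not (df[c] > 0).all():
            raise PanelFormatError(f"numeric trait {c!r} must be > 0")
    out = df.copy()
    out[list(ORDINAL_TRAITS)] = out[list(ORDINAL_TRAITS)].astype(int)
    out[list(NUMERIC_TRAITS)] = out[list(NUMERIC_TRAITS)].astype(float)
    return out


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index=True)


def allele_recoding(panel: SSRPanel) -> dict[str, dict[int, int]]:
    """Per locus, bijective map allele size (bp) -> consecutive code 1..k."""
    return {locus: {int(a): i + 1 for i, a in enumerate(panel.alleles_at(locus))}
            for locus in panel.locus_ids}


def write_structure_format(panel: SSRPanel, path) -> Path:
    """Export in STRUCTURE numeric layout: two rows per individual.

    Alleles are recoded per locus to consecutive integers (1..k, by
    ascending bp size); missing becomes -9.  The recoding table is written
    alongside as ``<path>.alleles.tsv`` and maps codes back to sizes.
    """
    codes = allele_recoding(panel)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["variety"] + panel.locus_ids) + "\n")
        for i, vid in enumerate(panel.variety_ids):
            for k in range(2):
                row = [vid]
                for j, locus in enumerate(panel.locus_ids):
                    a = int(panel.calls[i, j, k])
                    row.append("-9" if a == MISSING else str(codes[locus][a]))
                fh.write("\t".join(row) + "\n")
    side = path.with_name(path.name + ".alleles.tsv")
    with open(side, "w", encoding="utf-8") as fh:
        fh.write("locus\tcode\tsize_bp\n")
        for locus, mapping in codes.items():
            for size, code in mapping.items():
                fh.write(f"{locus}\t{code}\t{size}\n")
    return side
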