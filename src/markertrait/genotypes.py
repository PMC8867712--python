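"""Genotype containers, I/O and quality control.

Genotypes are biallelic SNP calls coded as copies of the alternate allele
(0, 1, 2) with ``NaN`` for missing.  The container keeps per-sample metadata
(species, population, family, site, block) alongside the call matrix so that
downstream stages (kinship, association, prediction) can subset by named
sample groups without re-plumbing identifiers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["species", "population", "family", "site", "block"]

__all__ = [
    "GenotypeMatrix",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "filter_samples_by_call_rate",
    "compute_maf",
    "classify_maf",
    "locus_class_by_species",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be decoded."""


@dataclass
class GenotypeMatrix:
    """Samples x loci call matrix with sample metadata.

    Parameters
    ----------
    calls
        Float array of shape ``(n_samples, n_loci)`` with values in
        {0, 1, 2, NaN}.
    sample_ids, locus_ids
        Unique string identifiers for rows and columns.
    sample_meta
        Optional DataFrame indexed by sample id; recognised columns are
        ``species``, ``population``, ``family``, ``site`` and ``block``.
    """

    calls: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    sample_meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes: {bad!r}")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        else:
            self.sample_meta = self.sample_meta.copy()
            self.sample_meta.index = pd.Index([str(i) for i in self.sample_meta.index],
                                              name="sample_id")
            missing = [s for s in self.sample_ids if s not in self.sample_meta.index]
            if missing:
                raise ValueError(f"sample_meta lacks entries for {missing[:5]}")
            self.sample_meta = self.sample_meta.loc[self.sample_ids]

    # -- basic queries ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per sample."""
        return 1.0 - np.isnan(self.calls).mean(axis=1)

    def locus_call_rate(self, samples: list[str] | None = None) -> np.ndarray:
        sub = self if samples is None else self.take_samples(samples)
        return 1.0 - np.isnan(sub.calls).mean(axis=0)

    def sample_indexer(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[str(s)] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def locus_indexer(self, locus_ids) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.locus_ids)}
        try:
            return np.array([pos[str(l)] for l in locus_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown locus id {exc.args[0]!r}") from None

    def take_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = self.sample_indexer(sample_ids)
        return GenotypeMatrix(self.calls[idx], [self.sample_ids[i] for i in idx],
                              list(self.locus_ids), self.sample_meta.iloc[idx])

    def take_loci(self, locus_ids) -> "GenotypeMatrix":
        idx = self.locus_indexer(locus_ids)
        return GenotypeMatrix(self.calls[:, idx], list(self.sample_ids),
                              [self.locus_ids[i] for i in idx], self.sample_meta)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (self.sample_ids == other.sample_ids
                and self.locus_ids == other.locus_ids
                and np.array_equal(self.calls, other.calls, equal_nan=True)
                and self.sample_meta.fillna("").astype(str).equals(
                    other.sample_meta.fillna("").astype(str)))


# -- I/O -------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, path, format: str = "table") -> None:
    """Write a genotype matrix as a delimited table or minimal GT-only VCF."""
    if format == "table":
        meta = g.sample_meta.reindex(columns=[c for c in META_COLUMNS
                                              if c in g.sample_meta.columns])
        calls = pd.DataFrame(g.calls, index=meta.index, columns=g.locus_ids)
        out = pd.concat([meta, calls], axis=1)
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%g")
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_genotypes(path, format: str = "table") -> GenotypeMatrix:
    if format == "table":
        return _read_table(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_table(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows, ids = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise GenotypeParseError(
                    f"{path}: line {lineno}: expected {ncol} fields, got {len(parts)}")
            ids.append(parts[0])
            rows.append(parts[1:])
    meta_cols = [c for c in header[1:] if c in META_COLUMNS]
    n_meta = len(meta_cols)
    locus_ids = header[1 + n_meta:]
    meta = pd.DataFrame([r[:n_meta] for r in rows], index=ids, columns=meta_cols)
    meta = meta.replace("NA", np.nan)
    calls = np.empty((len(rows), len(locus_ids)))
    decode = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan, "": np.nan, "nan": np.nan}
    for i, r in enumerate(rows):
        for j, v in enumerate(r[n_meta:]):
            try:
                calls[i, j] = decode[v]
            except KeyError:
                raise GenotypeParseError(
                    f"{path}: line {i + 2}: bad genotype code {v!r} "
                    f"at locus {locus_ids[j]}") from None
    return GenotypeMatrix(calls, ids, locus_ids, meta if n_meta else None)


def _write_vcf(g: GenotypeMatrix, path) -> None:
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j, locus in enumerate(g.locus_ids):
            col = g.calls[:, j]
            gts = "\t".join("./." if np.isnan(v) else gt_of[v] for v in col)
            fh.write(f"1\t{j + 1}\t{locus}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    locus_ids, cols = [], []
    # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
    decode = np.array([0.0, 1.0, np.nan, 2.0])
    for i, var in enumerate(vcf):
        locus_ids.append(var.ID if var.ID not in (None, ".")
                         else f"{var.CHROM}_{var.POS}")
        cols.append(decode[np.asarray(var.gt_types)])
    calls = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(calls, sample_ids, locus_ids)


# -- filtering and MAF -----------------------------------------------------

def filter_samples_by_call_rate(g: GenotypeMatrix, threshold: float = 0.80
                                ) -> tuple[GenotypeMatrix, list[str]]:
    """Remove samples whose call rate is strictly below ``threshold``.

    Mirrors the QC rule "remove all those with a call rate <80%": a sample at
    exactly the threshold is retained.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cr = g.sample_call_rate()
    keep = cr >= threshold
    removed = [s for s, k in zip(g.sample_ids, keep) if not k]
    kept = [s for s, k in zip(g.sample_ids, keep) if k]
    return g.take_samples(kept), removed


def compute_maf(g: GenotypeMatrix, samples: list[str] | None = None) -> pd.Series:
    """Per-locus minor allele frequency over non-missing calls in a subset.

    A locus with no calls in the subset gets ``NaN``.
    """
    sub = g if samples is None else g.take_samples(samples)
    if sub.n_samples == 0:
        raise ValueError("empty sample subset")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(sub.calls, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    return pd.Series(maf, index=g.locus_ids, name="maf")


def classify_maf(maf) -> pd.Series:
    """Classify loci as 'common' (MAF >= 0.05) or 'rare' (MAF < 0.05).

    The boundary is assigned to 'common' because the association filter
    excludes strictly MAF < 0.05.
    """
    maf = pd.Series(maf)
    out = pd.Series(pd.NA, index=maf.index, dtype="object", name="maf_class")
    out[maf >= 0.05] = "common"
    out[maf < 0.05] = "rare"
    return out


# -- per-species locus classification (Table-1 style accounting) ----------

CLASS_ORDER = ["CR<80", "Mono", "Poly"]


def _classify_subset(g: GenotypeMatrix, sample_ids, cr_threshold: float) -> pd.Series:
    sub = g.take_samples(sample_ids)
    cr = 1.0 - np.isnan(sub.calls).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mn = np.nanmin(sub.calls, axis=0)
        mx = np.nanmax(sub.calls, axis=0)
    cls = np.where(cr < cr_threshold, "CR<80",
                   np.where(mn == mx, "Mono", "Poly"))
    # all-missing loci have cr == 0 < threshold already
    return pd.Series(cls, index=g.locus_ids)


def locus_class_by_species(g: GenotypeMatrix, subsets: dict[str, list[str]],
                           cr_threshold: float = 0.80,
                           combos: list[tuple[str, ...]] | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each locus per named sample subset and count shared classes.

    Per subset a locus is ``CR<80`` when its within-subset call rate is below
    ``cr_threshold``; otherwise ``Mono`` when a single genotype class
    segregates, else ``Poly`` (precedence CR<80 > Mono > Poly).  A class is
    shared by a subset combination only when every member subset assigns that
    class, mirroring the "shared among species" rows of the array summary.

    Returns
    -------
    classes : DataFrame
        loci x subsets table of class labels.
    counts : DataFrame
        One row per subset and per combination, with CR<80/Mono/Poly counts.
    """
    if not subsets:
        raise ValueError("no subsets given")
    for name, ids in subsets.items():
        if len(ids) == 0:
            raise ValueError(f"empty subset {name!r}")
    classes = pd.DataFrame({name: _classify_subset(g, ids, cr_threshold)
                            for name, ids in subsets.items()})
    names = list(subsets)
    if combos is None:
        combos = [c for r in range(2, len(names) + 1)
                  for c in itertools.combinations(names, r)]
    rows = []
    for name in names:
        vc = classes[name].value_counts()
        rows.append({"subset": name, **{c: int(vc.get(c, 0)) for c in CLASS_ORDER}})
    for combo in combos:
        label = " and ".join(combo)
        sub = classes[list(combo)]
        counts = {c: int((sub == c).all(axis=1).sum()) for c in CLASS_ORDER}
        rows.append({"subset": label, **counts})
    return classes, pd.DataFrame(rows).set_index("subset")
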