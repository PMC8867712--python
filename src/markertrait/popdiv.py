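"""Per-SNP-set diversity statistics across populations.

Nei/Chesser estimators with the small-sample correction: per locus the
observed heterozygosity H_O is the mean within-population heterozygote
frequency, H_S the corrected mean within-population gene diversity, H_T
the overall gene diversity, and from these F_IS = 1 - H_O/H_S and
F_ST = (H_T - H_S)/H_T.  Overall values are ratios of locus averages
(ratio-of-averages, the convention of the reference estimators).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["DiversityStats", "basic_stats"]


@dataclass
class DiversityStats:
    snpset_name: str
    H_O: float
    H_S: float
    H_T: float
    F_IS: float
    F_ST: float
    per_locus: pd.DataFrame = None
    n_excluded_monomorphic: int = 0


def basic_stats(g: GenotypeMatrix, populations: pd.Series | None = None,
                loci: list[str] | None = None,
                snpset_name: str = "all") -> DiversityStats:
    """Nei diversity statistics over populations for a set of loci.

    Per locus, populations with at least one typed individual contribute;
    loci monomorphic overall have undefined F_ST and are excluded from the
    overall ratios (their count is reported).  Requires >= 2 populations
    with >= 2 typed individuals each.
    """
    sub = g if loci is None else g.take_loci(loci)
    if populations is None:
        if "population" not in sub.sample_meta.columns:
            raise ValueError("no population labels available")
        populations = sub.sample_meta["population"]
    pops = populations.reindex(sub.sample_ids)
    labels = [l for l in pd.unique(pops) if pd.notna(l)]
    sizes = [(pops == l).sum() for l in labels]
    if sum(s >= 2 for s in sizes) < 2:
        raise ValueError("need >= 2 populations with >= 2 typed individuals")
    calls = sub.calls
    npop = len(labels)
    L = sub.n_loci
    p_pop = np.full((npop, L), np.nan)     # allele frequency per pop
    ho_pop = np.full((npop, L), np.nan)    # observed het per pop
    n_pop = np.zeros((npop, L))            # typed individuals per pop
    for i, lab in enumerate(labels):
        rows = calls[(pops == lab).to_numpy()]
        typed = ~np.isnan(rows)
        cnt = typed.sum(axis=0)
        n_pop[i] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p_pop[i] = np.nansum(rows, axis=0) / (2.0 * cnt)
            ho_pop[i] = np.nansum(rows == 1, axis=0) / cnt
    ok = n_pop >= 1
    with np.errstate(invalid="ignore", divide="ignore"):
        # harmonic mean of per-pop sample sizes over contributing pops
        k = ok.sum(axis=0).astype(float)
        n_harm = k / np.where(ok, 1.0 / np.where(n_pop > 0, n_pop, np.nan), 0.0).sum(axis=0)
        ho = np.nanmean(np.where(ok, ho_pop, np.nan), axis=0)
        het_exp = 2.0 * p_pop * (1.0 - p_pop)            # per-pop HWE diversity
        hs_plug = np.nanmean(np.where(ok, het_exp, np.nan), axis=0)
        hs = n_harm / (n_harm - 1.0) * (hs_plug - ho / (2.0 * n_harm))
        p_bar = np.nanmean(np.where(ok, p_pop, np.nan), axis=0)
        ht_plug = 2.0 * p_bar * (1.0 - p_bar)
        ht = ht_plug + hs / (n_harm * k) - ho / (2.0 * n_harm * k)
        fis = 1.0 - ho / hs
        fst = (ht - hs) / ht
    per_locus = pd.DataFrame({"H_O": ho, "H_S": hs, "H_T": ht,
                              "F_IS": fis, "F_ST": fst},
                             index=pd.Index(sub.locus_ids, name="locus_id"))
    poly = ht > 0
    n_mono = int((~poly).sum())
    usable = per_locus[poly]
    H_O, H_S, H_T = (float(usable[c].mean()) for c in ("H_O", "H_S", "H_T"))
    return DiversityStats(
        snpset_name=snpset_name, H_O=H_O, H_S=H_S, H_T=H_T,
        F_IS=float(1.0 - H_O / H_S) if H_S > 0 else np.nan,
        F_ST=float((H_T - H_S) / H_T) if H_T > 0 else np.nan,
        per_locus=per_locus, n_excluded_monomorphic=n_mono)
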