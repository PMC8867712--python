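"""End-to-end orchestration: simulate -> qc -> ... -> select, with manifests.

Each stage reads the delimited artifacts of earlier stages from the output
directory, writes its own tables, and records a JSON manifest (stage name,
parameters, seed, SHA-256 of every output).  Re-running with an identical
configuration reproduces identical hashes, which is the pipeline's
end-to-end determinism contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import phenotypes as pheno_mod
from . import popdiv, predict, relatedness, varcomp
from .genotypes import (GenotypeMatrix, filter_samples_by_call_rate,
                        locus_class_by_species, read_genotypes, write_genotypes)
from .simulate import SimConfig, simulate_independent_sites, simulate_trial

log = logging.getLogger("markertrait.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "load_config", "run", "STAGES"]

DEFAULT_THRESHOLDS = {
    "call_rate": 0.80, "maf": 0.05, "fdr": 0.05, "mlmm_steps": 10,
    "train_fraction": 0.60, "selection_k": 10, "n_pcs": 5,
}
DEFAULT_TRAITS = ["BS2010", "BB2011", "H2013", "I2013"]


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    sim: dict = dataclasses.field(default_factory=dict)
    thresholds: dict = dataclasses.field(default_factory=dict)
    traits: list = dataclasses.field(default_factory=lambda: list(DEFAULT_TRAITS))

    def __post_init__(self):
        th = dict(DEFAULT_THRESHOLDS)
        th.update(self.thresholds)
        self.thresholds = th
        for key, lo, hi in (("call_rate", 0, 1), ("maf", 0, 0.5), ("fdr", 0, 1),
                            ("train_fraction", 0, 1)):
            v = th[key]
            if not lo < v <= hi:
                raise PipelineError(f"threshold {key}={v} outside ({lo}, {hi}]")

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def digest(self) -> str:
        payload = json.dumps({"seed": self.seed, "sim": self.sim,
                              "thresholds": self.thresholds,
                              "traits": self.traits}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_df(df: pd.DataFrame, path: Path, index=True):
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g", index=index)


def _require(outdir: Path, filenames, stage: str, needed_by: str):
    for fn in filenames:
        if not (outdir / fn).exists():
            raise PipelineError(
                f"stage {needed_by!r} needs {fn} - run stage {stage!r} first")


# -- stages ---------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[str]:
    sim = cfg.sim_config()
    g, pheno, truth = simulate_trial(sim)
    write_genotypes(g, outdir / "assoc_genotypes.tsv")
    _write_df(pheno, outdir / "assoc_phenotypes.tsv")
    _write_df(truth.qtl_effects, outdir / "truth_qtl.tsv", index=False)
    _write_df(truth.breeding_values, outdir / "truth_breeding_values.tsv")
    (outdir / "truth_realized_h2.json").write_text(
        json.dumps({k: round(float(v), 10) for k, v in truth.realized_h2.items()},
                   sort_keys=True))
    gi, pheno_by_cohort, truth_i = simulate_independent_sites(sim)
    write_genotypes(gi, outdir / "indep_genotypes.tsv")
    for cohort, df in pheno_by_cohort.items():
        _write_df(df, outdir / f"indep_phenotypes_{cohort}.tsv")
    _write_df(truth_i.breeding_values, outdir / "indep_truth_breeding_values.tsv")
    out = ["assoc_genotypes.tsv", "assoc_phenotypes.tsv", "truth_qtl.tsv",
           "truth_breeding_values.tsv", "truth_realized_h2.json",
           "indep_genotypes.tsv", "indep_truth_breeding_values.tsv"]
    out += [f"indep_phenotypes_{c}.tsv" for c in pheno_by_cohort]
    return out


def _species_datasets(g: GenotypeMatrix) -> dict[str, list[str]]:
    meta = g.sample_meta
    out = {}
    species = list(dict.fromkeys(meta["species"]))
    for sp in species:
        out[sp] = list(meta.index[meta["species"] == sp])
    if len(species) > 1:
        non_first = [s for sp in species[1:] for s in out[sp]]
        if len(species) > 2:
            out["-".join(species[1:])] = non_first
        out["-".join(species)] = list(meta.index)
    return out


def _stage_qc(cfg: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, ["assoc_genotypes.tsv"], "simulate", "qc")
    g = read_genotypes(outdir / "assoc_genotypes.tsv")
    filtered, removed = filter_samples_by_call_rate(
        g, cfg.thresholds["call_rate"])
    write_genotypes(filtered, outdir / "qc_genotypes.tsv")
    removed_df = pd.DataFrame({"sample_id": removed})
    if removed:
        removed_df["species"] = g.sample_meta.loc[removed, "species"].to_numpy()
    _write_df(removed_df, outdir / "qc_removed_samples.tsv", index=False)
    subsets = {sp: ids for sp, ids in _species_datasets(filtered).items()
               if "-" not in sp}
    _, counts = locus_class_by_species(filtered, subsets,
                                       cfg.thresholds["call_rate"])
    _write_df(counts, outdir / "qc_locus_classes.tsv")
    return ["qc_genotypes.tsv", "qc_removed_samples.tsv", "qc_locus_classes.tsv"]


def _stage_kinship(cfg: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, ["qc_genotypes.tsv"], "qc", "kinship")
    g = read_genotypes(outdir / "qc_genotypes.tsv")
    out = []
    for label, ids in _species_datasets(g).items():
        K = relatedness.centered_ibs_kinship(g.take_samples(ids))
        fn = f"kinship_{label}.tsv"
        _write_df(K.to_frame(), outdir / fn)
        out.append(fn)
    return out


def _stage_h2(cfg: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, ["qc_genotypes.tsv", "assoc_phenotypes.tsv"], "qc", "h2")
    g = read_genotypes(outdir / "qc_genotypes.tsv")
    pheno = pd.read_csv(outdir / "assoc_phenotypes.tsv", sep="\t",
                        index_col=0)
    rows = []
    for label, ids in _species_datasets(g).items():
        sub = g.take_samples(ids)
        K = relatedness.centered_ibs_kinship(sub)
        for trait in cfg.traits:
            y = pheno[trait].reindex(ids).to_numpy()
            ok = ~np.isnan(y)
            est = varcomp.greml(y[ok], K.align(np.asarray(ids)[ok]))
            rows.append({"dataset_label": label, "trait_label": trait,
                         "h2": est.h2, "se": est.se_h2, "n": est.n,
                         "boundary": est.boundary})
    _write_df(pd.DataFrame(rows), outdir / "h2.tsv", index=False)
    return ["h2.tsv"]


def _stage_assoc(cfg: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, ["qc_genotypes.tsv", "assoc_phenotypes.tsv"], "qc", "assoc")
    g = read_genotypes(outdir / "qc_genotypes.tsv")
    pheno = pd.read_csv(outdir / "assoc_phenotypes.tsv", sep="\t", index_col=0)
    datasets = _species_datasets(g)
    out = []
    for tag, maf_filter in (("nofilter", False), ("maf", True)):
        res = assoc_mod.run_association_suite(
            g, pheno, datasets, cfg.traits, maf_filter=maf_filter,
            n_pcs=cfg.thresholds["n_pcs"], fdr_threshold=cfg.thresholds["fdr"])
        for (label, trait), tab in res["tables"].items():
            fn = f"assoc_{tag}_{label}_{trait}.tsv"
            _write_df(tab, outdir / fn)
            out.append(fn)
        fn = f"assoc_summary_{tag}.tsv"
        _write_df(res["summary"], outdir / fn, index=False)
        out.append(fn)
    return out


def _stage_mlmm(cfg: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, ["qc_genotypes.tsv", "assoc_phenotypes.tsv"], "qc", "mlmm")
    g = read_genotypes(outdir / "qc_genotypes.tsv")
    pheno = pd.read_csv(outdir / "assoc_phenotypes.tsv", sep="\t", index_col=0)
    label, ids = list(_species_datasets(g).items())[-1]  # combined dataset
    sub = g.take_samples(ids)
    K = relatedness.centered_ibs_kinship(sub)
    rows = []
    for trait in cfg.traits:
        res = assoc_mod.mlmm(sub, pheno[trait], K,
                             max_steps=cfg.thresholds["mlmm_steps"])
        for locus in res.selected_model:
            rows.append({"dataset_label": label, "trait_label": trait,
                         "locus_id": locus, "criterion": res.criterion,
                         "m": res.m})
        if not res.selected_model:
            rows.append({"dataset_label": label, "trait_label": trait,
                         "locus_id": "NONE", "criterion": res.criterion,
                         "m": res.m})
    _write_df(pd.DataFrame(rows), outdir / "mlmm_selected.tsv", index=False)
    return ["mlmm_selected.tsv"]


def _stage_power(cfg: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, ["qc_genotypes.tsv"], "qc", "power")
    g = read_genotypes(outdir / "qc_genotypes.tsv")
    lam_grid = np.round(np.geomspace(0.1, 10.0, 9), 6)
    parts = []
    for label, ids in _species_datasets(g).items():
        df = assoc_mod.power_estimate(len(ids), qtl_size=0.05, alpha=0.05,
                                      lam=lam_grid)
        df.insert(0, "dataset_label", label)
        parts.append(df)
    _write_df(pd.concat(parts, ignore_index=True), outdir / "power.tsv",
              index=False)
    return ["power.tsv"]


def _main_species(g: GenotypeMatrix) -> str:
    return list(dict.fromkeys(g.sample_meta["species"]))[0]


def _load_predict_inputs(cfg: PipelineConfig, outdir: Path):
    g = read_genotypes(outdir / "qc_genotypes.tsv")
    pheno = pd.read_csv(outdir / "assoc_phenotypes.tsv", sep="\t", index_col=0)
    gi = read_genotypes(outdir / "indep_genotypes.tsv")
    sites = [s for s in dict.fromkeys(gi.sample_meta["site"]) if s != "GH"]
    site_g = {s: gi.take_samples(list(gi.sample_meta.index[gi.sample_meta["site"] == s]))
              for s in sites}
    tables = []
    for fn in sorted(outdir.glob("assoc_nofilter_*.tsv")):
        if "summary" in fn.name:
            continue
        tab = pd.read_csv(fn, sep="\t", index_col=0)
        tables.append(tab)
    return g, pheno, site_g, tables


def _stage_predict(cfg: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, ["qc_genotypes.tsv", "assoc_phenotypes.tsv",
                      "indep_genotypes.tsv"], "assoc", "predict")
    if not list(outdir.glob("assoc_nofilter_*.tsv")):
        raise PipelineError("stage 'predict' needs association tables - "
                            "run stage 'assoc' first")
    g, pheno, site_g, tables = _load_predict_inputs(cfg, outdir)
    main_sp = _main_species(g)
    main_ids = list(g.sample_meta.index[g.sample_meta["species"] == main_sp])
    g_main = g.take_samples(main_ids)
    targets = {main_sp: g_main, **site_g}
    out = []
    growth_tabs = [t for t in tables if t["trait_label"].iloc[0] in ("H2013", "I2013")]
    try:
        snpset = predict.build_snp_set(growth_tabs, targets, name="growth")
    except ValueError:
        snpset = None
    models = {}
    y = pheno["H2013"].reindex(main_ids)
    if snpset is not None and len(snpset) + 1 < len(main_ids):
        models["growth_ols"] = predict.fit_prediction_ols(
            g_main, y, snpset, training_trait="H2013")
    models["all_snps_ridge"] = predict.fit_prediction_ridge(
        g_main, y, training_trait="H2013")
    for name, model in models.items():
        fn = f"model_{name}.tsv"
        coef = model.coefficients.rename("coefficient").to_frame()
        _write_df(coef, outdir / fn)
        intercept = float(model.intercept)
        if model.train_means is not None:
            # fold the centring means into the intercept so the stored
            # coefficient table applies to raw allele counts
            intercept -= float(model.train_means @ model.coefficients)
        side = {"method": model.method, "training_trait": model.training_trait,
                "intercept": intercept,
                "snpset": model.snpset_name,
                "shrinkage": float(model.shrinkage),
                "seed": cfg.seed}
        (outdir / f"model_{name}.yaml").write_text(yaml.safe_dump(side,
                                                                  sort_keys=True))
        out += [fn, f"model_{name}.yaml"]
    if snpset is not None:
        _write_df(snpset.provenance, outdir / "snpset_growth.tsv", index=False)
        _write_df(snpset.dropped, outdir / "snpset_growth_dropped.tsv", index=False)
        out += ["snpset_growth.tsv", "snpset_growth_dropped.tsv"]
        div = popdiv.basic_stats(g_main, loci=snpset.loci, snpset_name="growth")
        _write_df(pd.DataFrame([{"snpset": div.snpset_name, "H_O": div.H_O,
                                 "H_S": div.H_S, "F_IS": div.F_IS,
                                 "F_ST": div.F_ST}]),
                  outdir / "snpset_diversity.tsv", index=False)
        out.append("snpset_diversity.tsv")
    return out


def _stage_evaluate(cfg: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, ["qc_genotypes.tsv", "assoc_phenotypes.tsv",
                      "model_all_snps_ridge.tsv", "indep_genotypes.tsv"],
             "predict", "evaluate")
    g, pheno, site_g, _ = _load_predict_inputs(cfg, outdir)
    main_sp = _main_species(g)
    main_ids = list(g.sample_meta.index[g.sample_meta["species"] == main_sp])
    g_main = g.take_samples(main_ids)
    y = pheno["H2013"].reindex(main_ids)
    rows = []
    seed = cfg.seed + 1000
    res = predict.internal_assessment(
        g_main, y, method="ridge", seed=seed,
        train_fraction=cfg.thresholds["train_fraction"], trait_label="H2013")
    rows.append({"model": "all_snps_ridge", "site": "internal",
                 "trait_label": "H2013", "pearson_r": res.pearson_r,
                 "p_value": res.p_value, "n": res.n})
    snp_fn = outdir / "snpset_growth.tsv"
    model = _load_model(outdir, "all_snps_ridge")
    if snp_fn.exists():
        prov = pd.read_csv(snp_fn, sep="\t")
        loci = list(dict.fromkeys(prov["locus_id"]))
        sset = predict.SNPSet("growth", loci, prov)
        if len(loci) + 1 < int(len(main_ids) * cfg.thresholds["train_fraction"]):
            res = predict.internal_assessment(
                g_main, y, snpset=sset, method="ols", seed=seed,
                train_fraction=cfg.thresholds["train_fraction"],
                trait_label="H2013")
            rows.append({"model": "growth_ols", "site": "internal",
                         "trait_label": "H2013", "pearson_r": res.pearson_r,
                         "p_value": res.p_value, "n": res.n})
    for site, gs in site_g.items():
        ph = pd.read_csv(outdir / f"indep_phenotypes_{site}.tsv", sep="\t",
                         index_col=0)
        ext = predict.external_assessment(model, gs, ph, site_label=site)
        for _, r in ext.iterrows():
            rows.append({"model": "all_snps_ridge", "site": site,
                         "trait_label": r["trait_label"],
                         "pearson_r": r["pearson_r"],
                         "p_value": r["p_value"], "n": r["n"]})
    _write_df(pd.DataFrame(rows), outdir / "evaluation.tsv", index=False)
    return ["evaluation.tsv"]


def _load_model(outdir: Path, name: str) -> predict.PredictionModel:
    coef = pd.read_csv(outdir / f"model_{name}.tsv", sep="\t", index_col=0)
    side = yaml.safe_load((outdir / f"model_{name}.yaml").read_text())
    # stored intercepts already absorb any centring means (raw-count scale)
    means = None
    return predict.PredictionModel(
        intercept=side["intercept"], coefficients=coef["coefficient"],
        method=side["method"], training_trait=side["training_trait"],
        snpset_name=side["snpset"], shrinkage=side["shrinkage"],
        train_means=means)


def _stage_select(cfg: PipelineConfig, outdir: Path) -> list[str]:
    _require(outdir, ["indep_genotypes.tsv", "model_all_snps_ridge.tsv"],
             "predict", "select")
    gi = read_genotypes(outdir / "indep_genotypes.tsv")
    model = _load_model(outdir, "all_snps_ridge")
    k = cfg.thresholds["selection_k"]
    rows = []
    for site in [s for s in dict.fromkeys(gi.sample_meta["site"]) if s != "GH"]:
        ids = list(gi.sample_meta.index[gi.sample_meta["site"] == site])
        gs = gi.take_samples(ids)
        ph = pd.read_csv(outdir / f"indep_phenotypes_{site}.tsv", sep="\t",
                         index_col=0)
        pred = model.predict(gs)
        comp = predict.selection_comparison(pred, ph["H_early"], ph["H_final"],
                                            k=min(k, len(ids)), site=site)
        for method, st in comp.methods.items():
            rows.append({"site": site, "method": method,
                         "mean_final": st["mean_final"], "cv": st["cv"],
                         "overlap_with_top_k": st["overlap_with_top_k"],
                         "site_mean": comp.site_mean_final,
                         "selected": ";".join(st["selected"])})
    _write_df(pd.DataFrame(rows), outdir / "selection.tsv", index=False)
    return ["selection.tsv"]


STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "kinship": _stage_kinship,
    "h2": _stage_h2,
    "assoc": _stage_assoc,
    "mlmm": _stage_mlmm,
    "power": _stage_power,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
    "select": _stage_select,
}


def run(config: PipelineConfig, stages: list[str] | None = None,
        outdir="pipeline_out") -> dict:
    """Execute the requested stages in canonical order; return the manifests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages {unknown}")
    ordered = [s for s in STAGES if s in stages]
    manifests = {}
    for stage in ordered:
        t0 = time.time()
        outputs = STAGES[stage](config, outdir)
        manifest = {
            "stage": stage,
            "config_digest": config.digest(),
            "seed": config.seed,
            "thresholds": config.thresholds,
            "outputs": {fn: _sha256(outdir / fn) for fn in sorted(outputs)},
        }
        (outdir / f"manifest_{stage}.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        manifests[stage] = manifest
        log.info("stage %s: %d outputs in %.1fs", stage, len(outputs),
                 time.time() - t0)
    return manifests
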