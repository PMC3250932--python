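"""End-to-end orchestration: QC -> deregression -> folds -> training -> validation.

`run_trait_pipeline` executes the whole analysis for one trait on in-memory
inputs and returns every intermediate product; `run_pipeline` wraps it with
file I/O, per-stage logging and provenance headers so the same analysis can be
driven from a config file or the command line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayesc import BayesCConfig, fold_config, predict_dgv, preliminary_variances, train
from .deregress import deregress_table
from .genotype_qc import MarkerMatrix, filter_animals, filter_loci, impute_missing, read_dosages
from .partition import PartitionScheme, age_split, cv_plan, kmeans_folds, random_folds
from .pedigree import Pedigree, amax_diagnostics, build_A, dissimilarity, read_pedigree
from .validate import bias_slope, blend_gebv, genetic_variance, pooled_accuracy

__all__ = ["RunConfig", "run_pipeline", "run_trait_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (one trait)."""

    pedigree_path: str = ""
    genotype_path: str = ""
    trait_path: str = ""
    trait: str = "trait"
    h2: float = 0.5
    c: float = 0.5
    scheme: str = "kmeans"  # kmeans | random | age
    k: int = 5
    n_start: int = 25
    replicate: int = 0
    valid_fraction: float = 0.20
    min_animal_call: float = 0.95
    min_locus_call: float = 0.90
    min_maf: float = 0.01
    max_hwe_chi2: float = 300.0
    bayes: BayesCConfig = field(default_factory=BayesCConfig)
    run_bivariate: bool = False
    outdir: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _partition(cfg: RunConfig, dis, ids, birth_years) -> PartitionScheme:
    if cfg.scheme == "kmeans":
        return kmeans_folds(dis, K=cfg.k, n_start=cfg.n_start, seed=cfg.seed)
    if cfg.scheme == "random":
        return random_folds(ids, K=cfg.k, replicate=cfg.replicate, seed=cfg.seed)
    if cfg.scheme == "age":
        return age_split(ids, birth_years, valid_fraction=cfg.valid_fraction)
    raise ValueError(f"unknown partition scheme {cfg.scheme!r}")


def run_trait_pipeline(
    ped: Pedigree,
    M: MarkerMatrix,
    trait_records: pd.DataFrame,
    cfg: RunConfig,
) -> dict:
    """Full analysis for one trait on in-memory inputs.

    Returns a dict with the QC'd marker matrix, deregressed records, the
    partition, per-animal DGV, accuracy/bias/blending statistics and (when
    requested) the bivariate REML fit.
    """
    # --- genotype QC
    M1, animal_log = filter_animals(M, cfg.min_animal_call)
    M2, locus_report = filter_loci(M1, cfg.min_locus_call, cfg.min_maf, cfg.max_hwe_chi2)
    M3 = impute_missing(M2)

    # --- deregression; keep animals with genotypes, a usable DEBV and a weight
    dereg = deregress_table(trait_records, h2=cfg.h2, c=cfg.c)
    usable = dereg[dereg["flag"].isin(["", "no_parent_info"])].dropna(subset=["debv", "weight"])
    keep = [a for a in M3.animal_ids if a in set(usable["animal"])]
    idx = [list(M3.animal_ids).index(a) for a in keep]
    M_t = MarkerMatrix(np.array(keep, dtype=object), M3.locus_ids.copy(), M3.Z[idx])
    rec = usable.set_index("animal").loc[keep]

    # --- relationship structure over the analyzed animals
    rel = build_A(ped, subset=keep)
    dis = dissimilarity(rel)
    years = ped.birth_year[ped.index_of(keep)]

    # --- folds
    parts = _partition(cfg, dis, np.array(keep, dtype=object), years)
    folds = cv_plan(parts)

    # --- preliminary full-data chain: variance priors and sigma_p^2
    sg2_hat, se2_hat, sp2_hat = preliminary_variances(M_t, rec, replace(cfg.bayes, seed=cfg.seed))
    bcfg = fold_config(cfg.bayes, sg2_hat, se2_hat, M_t.Z)

    # --- per-fold training and prediction
    dgv = pd.Series(index=keep, dtype=float)
    posteriors = []
    id_to_row = {a: i for i, a in enumerate(M_t.animal_ids)}
    for f, (train_ids, valid_ids) in enumerate(folds):
        tr_idx = [id_to_row[a] for a in train_ids]
        va_idx = [id_to_row[a] for a in valid_ids]
        M_tr = MarkerMatrix(M_t.animal_ids[tr_idx], M_t.locus_ids, M_t.Z[tr_idx])
        M_va = MarkerMatrix(M_t.animal_ids[va_idx], M_t.locus_ids, M_t.Z[va_idx])
        post = train(M_tr, rec, replace(bcfg, seed=cfg.seed + 1000 + f))
        posteriors.append(post)
        dgv[list(valid_ids)] = predict_dgv(M_va, post)

    # --- validation statistics, over animals with an out-of-fold prediction
    # (all animals for K-fold schemes; the young set for an age split)
    sg2 = genetic_variance(cfg.h2, sp2_hat)
    predicted = [a for a in keep if not np.isnan(dgv[a])]
    pred_pos = [keep.index(a) for a in predicted]
    rec_all, years_all = rec, years
    rec = rec.loc[predicted]
    years = years_all[pred_pos]
    debv = rec["debv"].to_numpy()
    dgv_arr = dgv.loc[predicted].to_numpy()
    groups = np.array([parts.assignment()[a] for a in predicted])
    acc_pooled = pooled_accuracy(debv, dgv_arr, years, sg2)
    per_group_acc = {}
    for g in np.unique(groups):
        sel = groups == g
        try:
            per_group_acc[int(g)] = pooled_accuracy(debv[sel], dgv_arr[sel], years[sel], sg2)
        except Exception:
            per_group_acc[int(g)] = np.nan
    slope = bias_slope(debv, dgv_arr)

    blend = None
    has_pa = rec["pa_adj"].notna()
    if has_pa.sum() >= 10:
        sel = has_pa.to_numpy()
        try:
            blend = blend_gebv(
                debv[sel],
                rec["pa_adj"].to_numpy()[sel],
                dgv_arr[sel],
                groups[sel],
                years[sel],
                sg2=sg2,
            )
        except Exception:
            blend = None

    bivar = None
    if cfg.run_bivariate:
        from .bivar_reml import BivariateModelSpec, fit_bivariate

        A_pred = rel.A[np.ix_(pred_pos, pred_pos)]
        spec = BivariateModelSpec(debv, dgv_arr, rec["weight"].to_numpy(), groups, A_pred)
        bivar = fit_bivariate(spec)

    amax_per_animal, amax_summary = amax_diagnostics(rel, parts.assignment())

    return {
        "trait": cfg.trait,
        "markers": M_t,
        "records": rec,
        "relationship": rel,
        "partition": parts,
        "folds": folds,
        "posteriors": posteriors,
        "dgv": dgv,
        "sigma_p2": sp2_hat,
        "sigma_g2": sg2,
        "accuracy": acc_pooled,
        "per_group_accuracy": per_group_acc,
        "bias_slope": slope,
        "blend": blend,
        "bivariate": bivar,
        "amax_summary": amax_summary,
        "qc": {"animals_removed": animal_log, "locus_report": locus_report},
    }


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig):
    with open(path, "w") as fh:
        fh.write(f"# kinfold {__version__}; seed={cfg.seed}; config={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """File-driven end-to-end run; writes artifacts under ``cfg.outdir``."""
    ped = read_pedigree(cfg.pedigree_path, validate_years=False)
    M = read_dosages(cfg.genotype_path)
    traits = pd.read_csv(cfg.trait_path, sep="\t")
    result = run_trait_pipeline(ped, M, traits, cfg)
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        dgv_df = pd.DataFrame(
            {
                "animal": result["dgv"].index,
                "dgv": result["dgv"].to_numpy(),
                "group": [result["partition"].assignment()[a] for a in result["dgv"].index],
            }
        )
        _write_tsv(dgv_df, out / f"dgv_{cfg.trait}_{cfg.scheme}.tsv", cfg)
        _write_tsv(result["amax_summary"], out / f"amax_{cfg.trait}_{cfg.scheme}.tsv", cfg)
        summary = {
            "trait": cfg.trait,
            "scheme": cfg.scheme,
            "seed": cfg.seed,
            "config": cfg.config_hash(),
            "sigma_p2": result["sigma_p2"],
            "sigma_g2": result["sigma_g2"],
            "accuracy": result["accuracy"],
            "per_group_accuracy": result["per_group_accuracy"],
            "bias_slope": result["bias_slope"],
        }
        if result["blend"]:
            summary["blend_b1"] = result["blend"]["b1"]
            summary["blend_b2"] = result["blend"]["b2"]
            summary["corr_pa_dgv"] = result["blend"]["corr_pa_dgv"]
        if result["bivariate"]:
            fit = result["bivariate"]
            summary["rg"] = fit.rg
            summary["rg_se"] = fit.rg_se
            summary["h2_dgv"] = fit.h2_dgv
            summary["h2_t"] = fit.h2_t
        with open(out / f"summary_{cfg.trait}_{cfg.scheme}.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return result
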