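"""Genotype quality control and deregression of the trait records.

Reads the bundle written by 01_simulate_population.py (regenerating it if
absent), applies the animal/locus filters and mean imputation, deregresses the
EPD/BIF table, and writes per-stage counts plus the deregression summary.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from kinfold.deregress import deregress_table  # noqa: E402
from kinfold.genotype_qc import filter_animals, filter_loci, impute_missing, read_dosages  # noqa: E402
from kinfold.synthdata import make_fixture  # noqa: E402

SEED = 0
H2 = 0.5


def main():
    data = ROOT / "scratch" / "data"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    if not (data / "genotypes.tsv").exists():
        make_fixture("tiny", seed=SEED, outdir=data)

    M = read_dosages(data / "genotypes.tsv")
    M1, animal_log = filter_animals(M, 0.95)
    M2, locus_report = filter_loci(M1, 0.90, 0.01, 300.0)
    M3 = impute_missing(M2)
    counts = {
        "animals_in": M.n_animals,
        "animals_removed_call_rate": len(animal_log),
        "loci_in": M.n_loci,
        "loci_fail_call_rate": int(locus_report["fail_call_rate"].sum()),
        "loci_fail_maf": int(locus_report["fail_maf"].sum()),
        "loci_fail_hwe": int(locus_report["fail_hwe"].sum()),
        "loci_removed_total": int(locus_report["removed"].sum()),
        "loci_out": M3.n_loci,
    }
    print("QC:", counts)
    locus_report.to_csv(results / "02_locus_qc.tsv", sep="\t", index=False)

    records = pd.read_csv(data / "trait_records.tsv", sep="\t")
    dereg = deregress_table(records, h2=H2, c=0.5)
    dereg.to_csv(results / "02_deregressed.tsv", sep="\t", index=False)
    kept = dereg["flag"].isin(["", "no_parent_info"])
    print(
        f"deregression: {kept.sum()}/{len(dereg)} records usable "
        f"(mean r2* = {dereg.loc[kept, 'r2_star'].mean():.3f}, "
        f"mean weight = {dereg.loc[kept, 'weight'].mean():.3f})"
    )
    pd.DataFrame([counts]).to_csv(results / "02_qc_counts.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
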