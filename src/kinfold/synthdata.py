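"""Synthetic pedigreed, genotyped population with the structure the analysis assumes.

Real beef-cattle evaluation data are proprietary, so this module generates a
stand-in population with the features the pipeline exploits:

* a multi-generation pedigree dominated by large patrilineal half-sib
  families, organized in weakly connected sire lines (so relationship-aware
  clustering has real structure to find);
* one small closed line bred within itself for many generations, reaching a
  mean inbreeding coefficient around 0.10 — the analogue of a herd closed to
  outside germplasm decades ago;
* linkage disequilibrium from founder haplotypes built as mosaics of a small
  ancestral haplotype pool, then Mendelian inheritance with Poisson crossovers
  (1 Morgan per chromosome, Haldane model, no interference);
* true breeding values from a sparse set of QTL among the markers, and
  EBV/EPD records built by the forward model that deregression inverts.

For an animal with no parental information the published EBV is the shrunk
estimate

    EBV_i = r2_i * (TBV_i + e_i),    Var(e_i) = sigma_g^2 (1 - r2_i)/r2_i,

which has corr(EBV, TBV) = r_i and Var(EBV) = r2_i * sigma_g^2 — the moments
BLUP shrinkage delivers.  When parents carry information, the published EBV
blends the animal's own (deregressed-scale) information x_i = TBV_i + e_i
with the parent average g_PA = (EBV_s + EBV_d)/2, exactly as the
two-equation deregression model assumes:

    EBV_i = (Z'Z_i * x_i + 2*lambda * g_PA) / (Z'Z_i + 2*lambda),

with Z'Z_i solved from the target reliabilities (see `deregress`) and
Var(e_i) = lambda * sigma_g^2 / Z'Z_i.  Deregressing such a record recovers
x_i exactly, so synthetic DEBV are true breeding values plus
reliability-calibrated noise, free of de-shrinkage outliers.  EPD = EBV/2 and
BIF = 1 - sqrt(1 - r2).  Parent records are generated recursively the same
way (parents before offspring); multi-generation EBV consistency beyond the
immediate parent average remains approximate because each animal's own
information is drawn independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_qc import MarkerMatrix
from .pedigree import Pedigree, pedigree_from_records

__all__ = ["SimConfig", "SimTruth", "simulate_population", "simulate_ebv", "resample_trait", "make_fixture"]


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults describe the "tiny" scale used throughout the test-suite:
    one interconnected mainstream population (patrilineal half-sib families,
    ~666 genotyped animals over the youngest three generations) plus a small
    closed inbred herd of distinct ancestry, on a 1 000-marker panel with
    400 hidden QTL.
    """

    n_founders: int = 60
    n_lines: int = 1
    n_generations: int = 5
    sires_per_line: int = 10
    offspring_per_line: int = 192
    cross_line_dam_prob: float = 0.40
    cross_line_sire_prob: float = 0.15  # matings sired from another main line
    new_dam_prob: float = 0.35  # matings using a fresh unrelated founder dam
    closed_size: int = 30
    closed_founders: int = 12  # importation bottleneck founding the closed herd
    closed_generations: int = 10
    n_chr: int = 10
    markers_per_chr: int = 100
    ancestral_haplotypes: int = 32
    mosaic_segments: float = 8.0  # mean pool-switch events per chromosome in founders
    n_qtl: int = 400
    h2: float = 0.5
    sg2: float = 1.0  # target variance of TBV among genotyped animals
    reliability_mean: float = 0.7
    reliability_sd: float = 0.15
    missing_rate: float = 0.0045
    birth_year_start: int = 1985
    years_per_generation: int = 4
    genotyped_generations: int = 3  # youngest generations of each line enter the panel
    seed: int = 0

    @property
    def n_markers(self) -> int:
        return self.n_chr * self.markers_per_chr


@dataclass
class SimTruth:
    """Ground truth for one simulated trait."""

    animal_ids: np.ndarray  # all simulated animals, pedigree order
    tbv: np.ndarray  # aligned to animal_ids
    genotyped_ids: np.ndarray
    qtl_flags: np.ndarray  # per marker
    qtl_effects: np.ndarray  # per marker (0 off-QTL), on the rescaled TBV scale
    sg2: float
    h2: float
    extras: dict = field(default_factory=dict)


def _founder_haplotypes(rng, pool, n, cfg) -> np.ndarray:
    """Founder gametes as mosaics of the ancestral pool (induces LD)."""
    m = pool.shape[2]
    out = np.empty((n, 2, cfg.n_chr, m), dtype=np.uint8)
    for i in range(n):
        for h in range(2):
            for c in range(cfg.n_chr):
                n_seg = 1 + rng.poisson(cfg.mosaic_segments)
                bounds = np.sort(rng.integers(0, m, n_seg - 1)) if n_seg > 1 else np.array([], int)
                src = rng.integers(0, pool.shape[0], n_seg)
                hap = np.empty(m, dtype=np.uint8)
                start = 0
                for s, b in zip(src, list(bounds) + [m]):
                    hap[start:b] = pool[s, c, start:b]
                    start = b
                out[i, h, c] = hap
    return out


def _meiosis(rng, haps, positions) -> np.ndarray:
    """One gamete from a parent's (2, n_chr, m) haplotypes; Poisson crossovers
    on a 1-Morgan chromosome (Haldane)."""
    n_chr, m = haps.shape[1], haps.shape[2]
    gamete = np.empty((n_chr, m), dtype=np.uint8)
    for c in range(n_chr):
        n_x = rng.poisson(1.0)
        phase = rng.integers(0, 2)
        if n_x == 0:
            gamete[c] = haps[phase, c]
            continue
        xpos = np.sort(rng.random(n_x))
        segment = np.searchsorted(xpos, positions[c], side="right")
        choose = (segment + phase) % 2
        gamete[c] = np.where(choose == 0, haps[0, c], haps[1, c])
    return gamete


def simulate_population(cfg: SimConfig) -> tuple[Pedigree, MarkerMatrix, SimTruth]:
    """Generate pedigree, genotypes for the panel animals, and trait truth."""
    if cfg.n_qtl > cfg.n_markers:
        raise SimulationError("more QTL than markers")
    if cfg.closed_size < 4:
        raise SimulationError("closed line too small to sustain matings")
    rng = np.random.default_rng(cfg.seed)
    # QTL are hidden loci interleaved with the panel markers: the panel tags
    # them only through LD, as a commercial SNP chip does
    q = cfg.n_qtl // cfg.n_chr
    if q * cfg.n_chr != cfg.n_qtl:
        raise SimulationError("n_qtl must divide evenly over chromosomes")
    m = cfg.markers_per_chr + q
    positions = [np.linspace(0, 1, m, endpoint=False) for _ in range(cfg.n_chr)]
    qtl_cols = np.concatenate(
        [c * m + np.sort(rng.choice(m, q, replace=False)) for c in range(cfg.n_chr)]
    )
    panel_cols = np.setdiff1d(np.arange(cfg.n_chr * m), qtl_cols)
    freqs = rng.uniform(0.1, 0.9, (1, cfg.n_chr, m))
    pool = (rng.random((cfg.ancestral_haplotypes, cfg.n_chr, m)) < freqs).astype(np.uint8)
    # the closed herd descends from distinct (native-origin) ancestry: its
    # ancestral haplotypes are private, so its marker-QTL LD phase differs
    # from the mainstream population even at matched allele frequencies
    pool_closed = (
        rng.random((cfg.ancestral_haplotypes, cfg.n_chr, m)) < freqs
    ).astype(np.uint8)

    haplo: dict[str, np.ndarray] = {}
    rows: list[tuple] = []  # (animal, sire, dam, year)
    line_of: dict[str, int] = {}

    def add_founder(aid, line, year, founder_pool=None):
        haplo[aid] = _founder_haplotypes(rng, pool if founder_pool is None else founder_pool, 1, cfg)[0]
        rows.append((aid, "0", "0", year))
        line_of[aid] = line

    def add_offspring(aid, sire, dam, line, year):
        gam_s = _meiosis(rng, haplo[sire], positions)
        gam_d = _meiosis(rng, haplo[dam], positions)
        haplo[aid] = np.stack([gam_s, gam_d])
        rows.append((aid, sire, dam, year))
        line_of[aid] = line

    # main population: founders split over sire lines
    per_line = cfg.n_founders // cfg.n_lines
    line_members: dict[int, list[str]] = {ln: [] for ln in range(cfg.n_lines)}
    for ln in range(cfg.n_lines):
        for i in range(per_line):
            aid = f"L{ln}F{i}"
            add_founder(aid, ln, cfg.birth_year_start)
            line_members[ln].append(aid)

    year = cfg.birth_year_start
    generation_of: dict[str, int] = {a: 0 for a in haplo}
    for gen in range(1, cfg.n_generations + 1):
        year = cfg.birth_year_start + gen * cfg.years_per_generation
        new_members: dict[int, list[str]] = {ln: [] for ln in range(cfg.n_lines)}
        for ln in range(cfg.n_lines):
            prev = line_members[ln]
            sires = list(rng.choice(prev, size=min(cfg.sires_per_line, len(prev)), replace=False))
            for i in range(cfg.offspring_per_line):
                sire = sires[i % len(sires)]  # large patrilineal half-sib families
                if rng.random() < cfg.cross_line_sire_prob and cfg.n_lines > 1:
                    # AI sires serve herds outside their own line
                    other = int(rng.choice([x for x in range(cfg.n_lines) if x != ln]))
                    prev_other = line_members[other]
                    sire = str(prev_other[int(rng.integers(len(prev_other))) % len(prev_other)])
                if rng.random() < cfg.new_dam_prob:
                    # an unrelated dam entering the registered population
                    dam = f"L{ln}D{gen}_{i}"
                    add_founder(dam, ln, year - cfg.years_per_generation)
                    generation_of[dam] = gen - 1
                elif rng.random() < cfg.cross_line_dam_prob and cfg.n_lines > 1:
                    other = int(rng.choice([x for x in range(cfg.n_lines) if x != ln]))
                    dam = str(rng.choice([a for a in line_members[other] if a != sire]))
                else:
                    dam = str(rng.choice([a for a in prev if a != sire]))
                aid = f"L{ln}G{gen}N{i}"
                add_offspring(aid, sire, dam, ln, year)
                generation_of[aid] = gen
                new_members[ln].append(aid)
        line_members = new_members

    # closed line: bred within itself, sires reused across half-sib families
    closed_line_label = cfg.n_lines
    closed = []
    for i in range(cfg.closed_founders):
        aid = f"CF{i}"
        add_founder(
            aid,
            closed_line_label,
            cfg.birth_year_start - cfg.closed_generations * 2,
            founder_pool=pool_closed,
        )
        generation_of[aid] = 0
        closed.append(aid)
    for gen in range(1, cfg.closed_generations + 1):
        cyear = (
            cfg.birth_year_start
            - cfg.closed_generations * 2
            + gen * cfg.years_per_generation // 2 * 2
        )
        sires = list(rng.choice(closed, size=max(3, cfg.closed_size // 3), replace=False))
        new_closed = []
        for i in range(cfg.closed_size):
            sire = sires[i % len(sires)]
            dam = str(rng.choice([a for a in closed if a != sire]))
            aid = f"CG{gen}N{i}"
            add_offspring(aid, sire, dam, closed_line_label, cyear)
            generation_of[aid] = gen
            new_closed.append(aid)
        closed = new_closed

    ped = pedigree_from_records(rows, validate_years=False)

    # the genotyped panel: youngest generations of each line + last closed gens
    has_sire = {a: s >= 0 for a, s in zip(ped.ids, ped.sire)}
    genotyped = [
        a
        for a in ped.ids
        if has_sire[a]
        and (
            (
                line_of[a] < cfg.n_lines
                and generation_of[a] > cfg.n_generations - cfg.genotyped_generations
            )
            or (
                line_of[a] == closed_line_label
                and generation_of[a] > cfg.closed_generations - cfg.genotyped_generations
            )
        )
    ]
    genotyped = np.array(genotyped, dtype=object)

    locus_ids = np.array([f"chr{c // m + 1}_m{c % m}" for c in panel_cols], dtype=object)

    def dosages(aid):
        return haplo[aid].sum(axis=0).reshape(-1).astype(float)

    Z = np.stack([dosages(a) for a in genotyped])[:, panel_cols]
    if cfg.missing_rate > 0:
        mask = rng.random(Z.shape) < cfg.missing_rate
        Z = np.where(mask, np.nan, Z)
    M = MarkerMatrix(genotyped.copy(), locus_ids, Z)

    # trait truth over ALL animals (parents need TBV for their own records)
    effects = rng.standard_normal(cfg.n_qtl)
    Z_all = np.stack([dosages(a) for a in ped.ids])
    tbv_raw = Z_all[:, qtl_cols] @ effects
    geno_idx = ped.index_of(genotyped)
    sd = tbv_raw[geno_idx].std(ddof=1)
    if sd == 0:
        raise SimulationError("degenerate trait: no QTL variance among genotyped animals")
    scale = np.sqrt(cfg.sg2) / sd
    center = tbv_raw[geno_idx].mean()
    tbv = (tbv_raw - center) * scale
    truth = SimTruth(
        animal_ids=ped.ids.copy(),
        tbv=tbv,
        genotyped_ids=genotyped,
        qtl_flags=np.zeros(len(panel_cols), dtype=bool),  # QTL are off-panel
        qtl_effects=np.zeros(len(panel_cols)),
        sg2=cfg.sg2,
        h2=cfg.h2,
        extras={
            "line_of": line_of,
            "generation_of": generation_of,
            "closed_line": closed_line_label,
            "qtl_effects_hidden": effects * scale,
            "hidden_dosages": Z_all[:, qtl_cols],
        },
    )
    return ped, M, truth


def resample_trait(truth: SimTruth, seed: int, h2: float | None = None, sg2: float | None = None) -> SimTruth:
    """A new trait on the same population: fresh effects on the hidden QTL loci.

    Shares pedigree, genotypes and QTL positions with ``truth``; only the
    effect sizes (and optionally h2 / sigma_g^2) change, the way different
    recorded traits share one genotyped population.
    """
    rng = np.random.default_rng(seed)
    hidden = truth.extras["hidden_dosages"]
    h2 = truth.h2 if h2 is None else h2
    sg2 = truth.sg2 if sg2 is None else sg2
    effects = rng.standard_normal(hidden.shape[1])
    tbv_raw = hidden @ effects
    pos = {a: i for i, a in enumerate(truth.animal_ids)}
    geno_idx = np.array([pos[a] for a in truth.genotyped_ids])
    sd = tbv_raw[geno_idx].std(ddof=1)
    if sd == 0:
        raise SimulationError("degenerate trait resample")
    tbv = (tbv_raw - tbv_raw[geno_idx].mean()) * (np.sqrt(sg2) / sd)
    extras = dict(truth.extras)
    extras["qtl_effects_hidden"] = effects * (np.sqrt(sg2) / sd)
    return SimTruth(
        animal_ids=truth.animal_ids,
        tbv=tbv,
        genotyped_ids=truth.genotyped_ids,
        qtl_flags=truth.qtl_flags,
        qtl_effects=truth.qtl_effects,
        sg2=sg2,
        h2=h2,
        extras=extras,
    )


def simulate_ebv(
    truth: SimTruth,
    ped: Pedigree,
    reliability_mean: float = 0.6,
    reliability_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """EPD/BIF records for the genotyped animals and their parents.

    Per-animal target reliabilities are drawn from a normal clipped to
    (0.05, 0.95).  EBV are produced by the forward BLUP-blending model the
    deregression machinery inverts (see module docstring): parents' records
    are generated first, an offspring's EBV blends its own
    reliability-calibrated information with the parent average of the
    generated parental EBVs, and its reliability always exceeds the
    parent-average reliability.
    """
    from .deregress import solve_information

    rng = np.random.default_rng(seed)
    sg2 = truth.sg2
    h2 = truth.h2
    lam = (1.0 - h2) / h2
    tbv_of = dict(zip(truth.animal_ids, truth.tbv))

    records: dict[str, tuple[float, float]] = {}  # animal -> (ebv, r2)

    def one_record(aid, sire, dam):
        draw = float(np.clip(rng.normal(reliability_mean, reliability_sd), 0.05, 0.95))
        r2_pa = 0.0
        g_pa = 0.0
        known = [p for p in (sire, dam) if p is not None and p in records]
        if known:
            r2_pa = sum(records[p][1] for p in known) / 4.0
            g_pa = sum(records[p][0] for p in known) / 2.0
        if r2_pa <= 0.0:
            r2 = draw
            x = tbv_of[aid] + np.sqrt(sg2 * (1.0 - r2) / r2) * rng.standard_normal()
            return r2 * x, r2
        r2 = float(min(max(draw, r2_pa + 0.05), 0.95))
        _, zz_i, _ = solve_information(r2_pa, r2, h2)
        x = tbv_of[aid] + np.sqrt(lam * sg2 / zz_i) * rng.standard_normal()
        return (zz_i * x + 2.0 * lam * g_pa) / (zz_i + 2.0 * lam), r2

    needed = set(truth.genotyped_ids)
    parent_of = {}
    for aid in truth.genotyped_ids:
        i = ped.index_of([aid])[0]
        s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else None
        d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else None
        parent_of[aid] = (s, d)
        needed.update(x for x in (s, d) if x is not None)
    pos = {a: i for i, a in enumerate(truth.animal_ids)}
    for aid in sorted(needed, key=pos.__getitem__):  # parents precede offspring
        i = ped.index_of([aid])[0]
        s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else None
        d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else None
        records[aid] = one_record(aid, s, d)

    def as_epd_bif(rec):
        ebv, r2 = rec
        return ebv / 2.0, 1.0 - np.sqrt(1.0 - r2)

    out = []
    for aid in truth.genotyped_ids:
        s, d = parent_of[aid]
        epd, bif = as_epd_bif(records[aid])
        s_epd, s_bif = as_epd_bif(records[s]) if s else (np.nan, np.nan)
        d_epd, d_bif = as_epd_bif(records[d]) if d else (np.nan, np.nan)
        out.append(
            {
                "animal": aid,
                "epd": epd,
                "bif_acc": bif,
                "sire_epd": s_epd,
                "sire_bif": s_bif,
                "dam_epd": d_epd,
                "dam_bif": d_bif,
            }
        )
    return pd.DataFrame(out)


def _dosage_frame(M: MarkerMatrix) -> pd.DataFrame:
    df = pd.DataFrame(M.Z, columns=M.locus_ids)
    df.insert(0, "IID", M.animal_ids)
    df.insert(0, "FID", "SIM")
    return df


def make_fixture(scale: str = "tiny", seed: int = 0, outdir: str | Path | None = None):
    """Generate a complete on-disk dataset bundle (or return it in memory).

    ``tiny``: ~300 genotyped animals x 1 000 markers — test-suite scale.
    ``paper_like``: ~3 500 genotyped animals x 45 000 markers in 5 latent
    subpopulations with birth years spread over five decades.
    """
    if scale == "tiny":
        cfg = SimConfig(seed=seed)
    elif scale == "paper_like":
        cfg = SimConfig(
            n_founders=400,
            n_lines=1,
            n_generations=10,
            sires_per_line=24,
            offspring_per_line=680,
            closed_size=80,
            closed_generations=12,
            n_chr=29,
            markers_per_chr=1552,
            ancestral_haplotypes=32,
            n_qtl=300,
            birth_year_start=1955,
            years_per_generation=5,
            genotyped_generations=5,
            seed=seed,
        )
    else:
        raise SimulationError(f"unknown fixture scale {scale!r}")
    ped, M, truth = simulate_population(cfg)
    traits = simulate_ebv(truth, ped, cfg.reliability_mean, cfg.reliability_sd, seed=cfg.seed + 1)
    bundle = {"config": cfg, "pedigree": ped, "markers": M, "truth": truth, "traits": traits}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ped.to_frame().to_csv(outdir / "pedigree.csv", index=False)
        _dosage_frame(M).to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
        traits.to_csv(outdir / "trait_records.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"animal": truth.animal_ids, "tbv": truth.tbv}
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return bundle
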