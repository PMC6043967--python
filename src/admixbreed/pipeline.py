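"""Config-driven end-to-end run: simulate -> qc -> stats -> roh -> ancestry
-> dating -> outliers, with a machine-readable report.

A single global seed fans out deterministically to per-stage seeds
(child = (seed * 1000003 + stage index) mod 2^31) so any stage can be rerun
in isolation; the report carries every stage's parameters and headline
numbers (F_ST matrix, H_o, F_ROH means, ancestry proportions, N_E
trajectory, dating estimates, panel counts).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import dating, outliers, qc, roh, stats
from .containers import GeneticMap, HaplotypeSet
from .pedigree import coi_all, cor, expected_ancestry_fraction
from .sim import (FounderModel, cwd_schedule, inject_missingness, simulate_breed)

_STAGES = ("simulate", "missingness", "qc", "stats", "roh", "ancestry",
           "dating", "outliers")


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000003 + _STAGES.index(stage)) % (2 ** 31)


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    seed: int = 0
    out_dir: str | None = None
    # simulation
    n_sites: int = 2000
    n_chromosomes: int = 5
    chrom_length: int = 50_000_000
    divergence_fst: float = 0.35
    n_generations: int = 18
    census_start: int = 40
    census_end: int = 20
    sire_concentration: float = 1.0
    missing_rate: float = 0.03
    # qc
    qc_enabled: bool = True
    call_rate: float = 0.95
    ld_window: int = 50
    ld_step: int = 5
    ld_r2: float = 0.2
    # roh
    roh_min_snps: int = 25
    roh_min_kb: float = 500.0
    # ancestry
    block_size: int = 10
    hmm_generations: float = 10.0
    call_threshold: float = 0.8
    # dating
    t_range: tuple = (1, 20)
    # outliers
    aim_fraction: float = 0.01
    flank_bp: int = 50_000

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if not (0 <= cfg.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if cfg.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        return cfg

    def founder_model(self) -> FounderModel:
        return FounderModel(
            n_sites=self.n_sites,
            chrom_lengths={str(c): self.chrom_length
                           for c in range(1, self.n_chromosomes + 1)},
            divergence_fst=self.divergence_fst,
            seed=stage_seed(self.seed, "simulate"),
        )


def _subset_haplotypes(hs: HaplotypeSet, gm_sub) -> HaplotypeSet:
    """Restrict a haplotype set to the sites surviving in ``gm_sub``."""
    key = pd.MultiIndex.from_frame(hs.sites[["chrom", "pos"]])
    want = pd.MultiIndex.from_frame(gm_sub.sites[["chrom", "pos"]])
    idx = key.get_indexer(want)
    if (idx < 0).any():
        raise ValueError("filtered sites not present in haplotype set")
    return HaplotypeSet(sample_ids=list(hs.sample_ids),
                        sites=gm_sub.sites.reset_index(drop=True),
                        haplotypes=hs.haplotypes[:, idx])


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the run report (JSON-safe dict)."""
    report: dict = {"config": asdict(config), "stages": {}}
    gmap = GeneticMap()
    try:
        # -- simulate ------------------------------------------------------
        model = config.founder_model()
        schedule = cwd_schedule(config.n_generations, config.census_start,
                                config.census_end, config.sire_concentration)
        sim = simulate_breed(model, schedule, gmap,
                             seed=stage_seed(config.seed, "simulate"))
        breed_ids = sim.breed_sample_ids()
        report["stages"]["simulate"] = {
            "seed": stage_seed(config.seed, "simulate"),
            "n_breed": len(breed_ids),
            "mean_truth_q": float(np.mean([sim.truth_q[s] for s in breed_ids])),
            "sampling_year": sim.schedule.sampling_year(),
        }

        # -- missingness + qc ---------------------------------------------
        gm = inject_missingness(sim.genotypes, config.missing_rate,
                                seed=stage_seed(config.seed, "missingness"))
        if config.qc_enabled:
            gm_q, qc_report = qc.qc_cascade(
                gm, call_rate=config.call_rate, drop_sex=True,
                ld_window=config.ld_window, ld_step=config.ld_step,
                ld_r2=config.ld_r2)
            # quality-pruned (pre-LD) matrix for LD-aware analyses
            gm_quality = qc.filter_call_rate(qc.drop_sex_chromosomes(gm),
                                             config.call_rate)
        else:
            gm_q = gm_quality = gm
            qc_report = {"skipped": True}
        report["stages"]["qc"] = qc_report

        # -- summary statistics -------------------------------------------
        _ho_sample, ho_group = stats.observed_heterozygosity(gm_quality)
        f_sample = stats.inbreeding_f(gm_quality)
        fst = stats.pairwise_fst(gm_quality,
                                 ["breed", "wild_parent", "dom_parent"])
        coords, evf = stats.pca(gm_quality, n_components=2)
        pc1 = {g: float(coords["PC1"][gm_quality.groups == g].mean())
               for g in ("breed", "wild_parent", "dom_parent")}
        report["stages"]["stats"] = {
            "H_o": {k: float(v) for k, v in ho_group.items()},
            "F_mean": {g: float(f_sample[gm_quality.groups == g].mean())
                       for g in ("breed", "wild_parent", "dom_parent")},
            "fst_matrix": json.loads(fst.matrix.to_json()),
            "pca_explained": [float(x) for x in evf],
            "pc1_group_means": pc1,
        }

        # -- ROH -----------------------------------------------------------
        params = roh.ROHParams(min_snps=config.roh_min_snps,
                               min_kb=config.roh_min_kb)
        rohset = roh.detect_roh(gm_quality, params)
        fr = roh.froh_all(rohset, gm_quality)
        groups_map = dict(zip(gm_quality.sample_ids, gm_quality.groups))
        summary = roh.roh_summary(rohset, groups_map)
        froh_mean = {g: float(fr[[s for s in gm_quality.sample_ids
                                  if groups_map[s] == g]].mean())
                     for g in ("breed", "wild_parent", "dom_parent")}
        coi_map = coi_all(sim.pedigree)
        breed_present = [s for s in breed_ids if s in gm_quality.sample_ids]
        froh_vs_coi = float(np.corrcoef(
            [fr[s] for s in breed_present],
            [coi_map[s] for s in breed_present])[0, 1]) if len(breed_present) > 2 else float("nan")
        report["stages"]["roh"] = {
            "froh_mean": froh_mean,
            "summary": summary.drop(columns="histogram").to_dict("records"),
            "froh_coi_correlation": froh_vs_coi,
        }

        # -- local ancestry -------------------------------------------------
        gm_complete = qc.remove_missing_sites(gm_quality)
        haps = _subset_haplotypes(sim.haplotypes, gm_complete)
        panel_groups = {s: g for s, g in zip(gm_complete.sample_ids,
                                             gm_complete.groups)
                        if g in ("wild_parent", "dom_parent")}
        parent_idx = [haps.sample_ids.index(s) for s in panel_groups]
        parent_rows = np.sort(np.concatenate(
            [[2 * i, 2 * i + 1] for i in parent_idx]))
        panel = HaplotypeSet(
            sample_ids=[haps.sample_ids[i] for i in parent_idx],
            sites=haps.sites, haplotypes=haps.haplotypes[parent_rows])
        ref = anc.build_reference(panel, panel_groups,
                                  block_size=config.block_size)
        breed_idx = [haps.sample_ids.index(s) for s in breed_ids
                     if s in gm_complete.sample_ids]
        breed_rows = np.sort(np.concatenate(
            [[2 * i, 2 * i + 1] for i in breed_idx]))
        query = HaplotypeSet(
            sample_ids=[haps.sample_ids[i] for i in breed_idx],
            sites=haps.sites, haplotypes=haps.haplotypes[breed_rows])
        track = anc.deconvolve(query, ref, smooth=True,
                               hmm_generations=config.hmm_generations,
                               call_threshold=config.call_threshold, gmap=gmap)
        qdf = anc.genome_wide_ancestry(track)
        switches = anc.count_switches(track)
        wolf_fixed, dog_fixed = anc.fixed_ancestry_blocks(track)
        p_wolf = stats.allele_freq(gm_complete, "wild_parent")
        p_dog = stats.allele_freq(gm_complete, "dom_parent")
        q_sup = anc.supervised_q(gm_complete, p_wolf, p_dog,
                                 samples=list(qdf.index))
        truth_q = pd.Series({s: sim.truth_q[s] for s in qdf.index})
        exp_frac = expected_ancestry_fraction(sim.pedigree, "wolf")
        report["stages"]["ancestry"] = {
            "mean_q_blocks": float(qdf["q"].mean()),
            "sd_q_blocks": float(qdf["q"].std()),
            "mean_q_supervised": float(q_sup.mean()),
            "mean_truth_q": float(truth_q.mean()),
            "mean_pedigree_expected_q": float(np.mean(
                [exp_frac[s] for s in qdf.index])),
            "mean_abs_q_error": float((qdf["q"] - truth_q).abs().mean()),
            "mean_switches": float(switches.mean()),
            "n_wolf_fixed_blocks": int(wolf_fixed.sum()),
            "n_dog_fixed_blocks": int(dog_fixed.sum()),
        }

        # -- dating ---------------------------------------------------------
        traj = dating.ne_trajectory(gm_quality, gmap, group="breed",
                                    t_range=tuple(config.t_range))
        ald = dating.admixture_ld_decay(
            gm_quality, stats.allele_freq(gm_quality, "wild_parent"),
            stats.allele_freq(gm_quality, "dom_parent"), gmap,
            seed=stage_seed(config.seed, "dating"))
        genome_l = sum(gmap.chrom_length_morgans(c, l) for c, l in
                       model.chrom_lengths.items())
        sw = dating.switch_dating_cohort(switches.astype(float),
                                         qdf["q"], genome_l)
        years = dating.generations_to_years(
            ald.estimate, (ald.estimate - ald.ci[0], ald.ci[1] - ald.estimate),
            schedule.generation_time_years, schedule.sampling_year()) \
            if np.isfinite(ald.estimate) else None
        report["stages"]["dating"] = {
            "ne_trajectory": traj.bins.to_dict("records"),
            "weighted_ld_generations": ald.estimate,
            "weighted_ld_ci": list(ald.ci),
            "weighted_ld_years": years,
            "switch_dating_median": float(sw["generations"].median()),
            "generations_since_last_admixture_truth":
                config.n_generations - schedule.last_admixture_generation() + 1,
        }

        # -- outlier panels --------------------------------------------------
        fixed = outliers.fixed_diff_sites(gm_quality)
        chrom_lengths = model.chrom_lengths
        panel_dict = {}
        if len(fixed):
            sel = outliers.aim_select(gm_quality, fixed,
                                      fraction=config.aim_fraction)
            panel_dict["fst_snp_wolf"] = (
                outliers.expand_intervals(gm_quality, site_indices=sel["wolf_like"],
                                          flank_bp=config.flank_bp,
                                          chrom_lengths=chrom_lengths), "wolf_like")
            panel_dict["fst_snp_dog"] = (
                outliers.expand_intervals(gm_quality, site_indices=sel["dog_like"],
                                          flank_bp=config.flank_bp,
                                          chrom_lengths=chrom_lengths), "dog_like")
        for name, mask, direction in (("pcadmix_wolf", wolf_fixed, "wolf_like"),
                                      ("pcadmix_dog", dog_fixed, "dog_like")):
            spans = [(track.blocks.loc[k, "chrom"],
                      track.blocks.loc[k, "start_bp"],
                      track.blocks.loc[k, "end_bp"])
                     for k in np.flatnonzero(mask)]
            if spans:
                panel_dict[name] = (
                    outliers.expand_intervals(gm_quality, block_spans=spans,
                                              flank_bp=config.flank_bp,
                                              chrom_lengths=chrom_lengths),
                    direction)
        shared = roh.shared_roh_regions(
            rohset, [s for s in breed_ids if s in gm_quality.sample_ids])
        if len(shared):
            panel_dict["shared_roh"] = (shared, "dog_like")
        table = outliers.consolidate(panel_dict)
        report["stages"]["outliers"] = {
            "n_fixed_diff_sites": int(len(fixed)),
            "n_wolf_like_regions": int((table["direction"] == "wolf_like").sum())
            if len(table) else 0,
            "n_dog_like_regions": int((table["direction"] == "dog_like").sum())
            if len(table) else 0,
            "n_multi_method_regions": int((table["n_methods"] > 1).sum())
            if len(table) else 0,
        }
    except Exception as err:  # annotate failures with the stage reached
        done = list(report["stages"])
        raise RuntimeError(
            f"pipeline failed after stages {done}: {err}") from err

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report


__all__ = ["RunConfig", "run_pipeline", "stage_seed"]
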