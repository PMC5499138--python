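"""End-to-end in-silico rapid-cycling genomic selection experiment.

One call runs the whole program from a config and a master seed: founder
panel -> half-diallel -> bulk-pollen intermating -> selfing to the
ear-to-row training cycle (C0) -> family-bulk genotyping and multi-location
testcross phenotyping -> phenotypic selection into C1 -> GBLUP-ranked
recombination cycles C2 and C3 (predictions from the model trained on C0)
-> an ungenotyped final cycle C4 -> a two-location evaluation trial of all
cycles with benchmark checks -> gain, diversity, marker-status and
ordination reports.

Every stage draws from its own generator seeded by a stable hash of
(master seed, stage name), so inserting a stage does not perturb the
streams of the others and a run is reproducible byte-for-byte from
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import breeding, diversity, founders, gains, gblup, io, traits
from .breeding import CyclePlan, Population, SelectionPlan, scaled_plan
from .genome import GenotypeTable

logger = logging.getLogger(__name__)

#: ratio of plants intermated to training families selected from them
#: (4800 intermated plants yielded the 1000-family training cycle).
S1_PER_C0_FAMILY = 4.8


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from (master seed, stage name)."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))


@dataclass
class ExperimentConfig:
    """All knobs of the simulated breeding program.

    Defaults are the desk-scale study conditions: a 10-chromosome maize
    genome with 2000 markers, 18 inbred founders, grain yield with
    entry-mean heritability 0.34 in a 4-location training trial, and the
    published selection plan scaled down tenfold.
    """

    n_chrom: int = 10
    markers_per_chrom: int = 200
    chrom_length_cM: float = 150.0
    chrom_length_bp: int = 230_000_000

    n_parents: int = 18
    missing_rate: float = 0.05
    maf_spectrum: dict | None = None

    n_qtl: int = 40
    target_h2_entry: float = 0.34
    mu: float = 8.5
    genetic_sd: float = 0.5

    plan: SelectionPlan = field(default_factory=scaled_plan)
    f1_plants_per_family: int = 3
    bulk_plants: int = 15

    training_locations: int = 4
    training_reps: int = 1
    eval_locations: int = 2
    eval_reps: int = 2
    eval_entries_per_cycle: int = 5

    cv_k: int = 5
    cv_reps: int = 10
    run_cv: bool = True

    mono_band: tuple = (0.05, 0.95)
    cluster_max_gap_bp: int = 1000
    cluster_min_size: int = 3
    shift_threshold: float = 0.15

    selection_criterion: str | None = None  # override: 'random' for null runs
    seed: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["plan"] = {
            "cycles": {k: asdict(v) for k, v in self.plan.cycles.items()},
            "final_ears": self.plan.final_ears,
            "final_entries_evaluated": self.plan.final_entries_evaluated,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "plan" in d and isinstance(d["plan"], dict):
            p = d["plan"]
            d["plan"] = SelectionPlan(
                cycles={k: CyclePlan(**v) for k, v in p["cycles"].items()},
                final_ears=p["final_ears"],
                final_entries_evaluated=p.get("final_entries_evaluated"),
            )
        if "mono_band" in d:
            d["mono_band"] = tuple(d["mono_band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ExperimentResult:
    """Artifacts of one experiment run (populations, tables, reports)."""

    config: ExperimentConfig
    arch: "traits.TraitArchitecture"
    populations: dict
    bulk_tables: dict
    gebv_tables: dict
    training_records: pd.DataFrame
    eval_records: pd.DataFrame
    gain_report: pd.DataFrame
    h2_report: pd.DataFrame
    diversity_report: pd.DataFrame
    status_by_chrom: pd.DataFrame
    clusters: pd.DataFrame
    shift_summary: dict
    mds_coords: pd.DataFrame
    cv: dict | None
    log: list

    def slope(self, scope: str = "combined", from_cycle: str = "C1") -> float:
        means = self.cycle_means(scope)
        labels = [c for c in means.index if gains.cycle_index(c) >= gains.cycle_index(from_cycle)]
        return gains.regress_gain(means, labels)

    def cycle_means(self, scope: str = "combined") -> pd.Series:
        rep = self.gain_report
        sub = rep[(rep["scope"] == scope) & rep["cycle"].str.fullmatch(r"C\d+")]
        return sub.set_index("cycle")["entry_mean"]

    def census_cycle_means(self) -> pd.Series:
        """Mean true (simulated) testcross value over every family of each
        cycle — the genetic trend free of trial measurement noise."""
        out = {}
        for cyc in [*self.config.plan.labels(), "C4"]:
            vals = traits.entry_values(self.populations[cyc], self.arch)
            out[cyc] = float(vals["genetic_value"].mean())
        return pd.Series(out)

    def census_slope(self, from_cycle: str = "C1") -> float:
        """OLS slope of the genetic trend on cycle index."""
        means = self.census_cycle_means()
        labels = [c for c in means.index if gains.cycle_index(c) >= gains.cycle_index(from_cycle)]
        return gains.regress_gain(means, labels)

    def heterozygosity(self, group: str) -> float:
        d = self.diversity_report.set_index("group")
        return float(d.at[group, "heterozygosity"])

    def pedigree(self) -> pd.DataFrame:
        return pd.concat(
            [p.meta for p in self.populations.values()], ignore_index=True
        )[["id", "mother", "father", "family", "cycle"]]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        io.write_report(self.gain_report, out / "gain_report.tsv")
        io.write_report(self.h2_report, out / "h2_report.tsv")
        io.write_report(self.diversity_report, out / "diversity_report.tsv")
        io.write_report(self.status_by_chrom.reset_index(), out / "status_changes.tsv")
        io.write_report(self.clusters, out / "status_clusters.tsv")
        io.write_report(self.mds_coords.reset_index(names="sample"), out / "mds_coordinates.tsv")
        io.write_report(self.pedigree(), out / "pedigree.tsv")
        io.write_phenotypes(self.eval_records, out / "evaluation_phenotypes.csv")
        io.write_phenotypes(self.training_records, out / "training_phenotypes.csv")
        for cyc, tab in self.gebv_tables.items():
            io.write_report(tab, out / f"gebv_{cyc}.tsv")
        with open(out / "shift_summary.json", "w") as fh:
            json.dump(self.shift_summary, fh, indent=1)
        if self.cv is not None:
            with open(out / "cross_validation.json", "w") as fh:
                json.dump(
                    {k: v for k, v in self.cv.items() if k != "correlations"}, fh, indent=1
                )
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=1)


def adjusted_entry_means(records: pd.DataFrame, trait: str = "GY") -> pd.Series:
    """Location-adjusted entry means: subtract location means, average plots."""
    df = records.loc[~records["is_check"]].copy()
    df[trait] = df[trait] - df.groupby("location")[trait].transform("mean")
    return df.groupby("entry")[trait].mean()


def _family_subpop(pop: Population, fams: list) -> Population:
    idx = np.flatnonzero(pop.meta["family"].isin(fams).to_numpy())
    return pop.subset(idx)


def _bulk_table(pop: Population, cfg: ExperimentConfig, rng) -> GenotypeTable:
    """Family-bulk genotyping of every family, with missing-call injection."""
    fams = pop.families()
    rows = []
    for fam, idx in fams.items():
        rows.append(breeding.bulk_family_genotype(pop.subset(idx), rng, cfg.bulk_plants))
    dosage = np.vstack(rows)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan
    return GenotypeTable(list(fams), pop.map, dosage)


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResult:
    """Run the full simulated RCGS program; see the module docstring.

    Writes the report files to ``out_dir`` when given. Any stage failure
    raises a RuntimeError naming the stage (artifacts produced by earlier
    stages are still written when ``out_dir`` is set).
    """
    cfg = config
    log: list = []
    state: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                info = fn(stage_rng(cfg.seed, name)) or {}
            except Exception as err:
                if out_dir is not None:
                    _write_partial(state, cfg, out_dir)
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
            log.append(
                {
                    "stage": name,
                    "seed": stage_seed(cfg.seed, name),
                    "elapsed_s": round(time.perf_counter() - t0, 3),
                    **info,
                }
            )

        return deco

    @stage("map_and_founders")
    def _(rng):
        state["map"] = founders.simulate_map(
            cfg.n_chrom,
            cfg.markers_per_chrom,
            cfg.chrom_length_cM,
            cfg.chrom_length_bp,
            seed=stage_seed(cfg.seed, "map"),
        )
        state["founders"] = founders.simulate_founders(
            state["map"],
            cfg.n_parents,
            maf_spectrum=cfg.maf_spectrum,
            missing_rate=cfg.missing_rate,
            seed=stage_seed(cfg.seed, "founders"),
        )
        return {"n_markers": state["map"].n_markers, "n_parents": cfg.n_parents}

    @stage("architecture")
    def _(rng):
        tester = founders.simulate_founders(
            state["map"], 2, missing_rate=0.0, seed=stage_seed(cfg.seed, "tester")
        ).population
        state["arch"] = traits.assign_architecture(
            state["map"],
            state["founders"],
            n_qtl=cfg.n_qtl,
            target_h2_entry=cfg.target_h2_entry,
            n_locations=cfg.training_locations,
            n_reps=cfg.training_reps,
            seed=stage_seed(cfg.seed, "architecture"),
            mu=cfg.mu,
            genetic_sd=cfg.genetic_sd,
            tester=tester,
        )
        return {"n_qtl": cfg.n_qtl}

    @stage("training_population")
    def _(rng):
        plan0 = cfg.plan.cycles["C0"]
        f1 = breeding.half_diallel(state["founders"].population, cfg.f1_plants_per_family, rng)
        n_s1 = int(round(S1_PER_C0_FAMILY * plan0.families_sown))
        s1 = breeding.bulk_intermate(f1, n_s1, rng, progeny_per_ear=1, cycle="S1")
        chosen = rng.choice(s1.n, size=plan0.families_sown, replace=False)
        c0 = breeding.ear_to_row_families(
            s1, sorted(chosen), plan0.plants_per_family, rng, prefix="C0_f", cycle="C0"
        )
        state["populations"] = {"F1": f1, "S1": s1, "C0": c0}
        return {"n_f1_families": len(f1.families()), "n_s1": s1.n, "n_c0_families": plan0.families_sown}

    @stage("c0_genotyping")
    def _(rng):
        state["bulks"] = {"C0": _bulk_table(state["populations"]["C0"], cfg, rng)}
        qc_idx = founders.marker_qc(state["bulks"]["C0"])
        if qc_idx.size == 0:
            raise ValueError("no markers pass QC in the training population")
        state["qc_idx"] = qc_idx
        return {"n_markers_qc": int(qc_idx.size)}

    @stage("c0_trial")
    def _(rng):
        state["training_records"] = traits.simulate_trial(
            state["populations"]["C0"],
            state["arch"],
            cfg.training_locations,
            cfg.training_reps,
            rng,
        )
        state["y_train"] = adjusted_entry_means(state["training_records"])
        return {"n_entries": state["y_train"].size}

    @stage("gblup_training")
    def _(rng):
        tab = state["bulks"]["C0"].subset_markers(state["qc_idx"])
        state["grm_train"] = gblup.compute_grm(tab)
        state["fit"] = gblup.fit_gblup(state["y_train"], state["grm_train"])
        cv = None
        if cfg.run_cv:
            cv = gblup.cross_validate(
                state["y_train"],
                state["grm_train"],
                k=cfg.cv_k,
                reps=cfg.cv_reps,
                seed=stage_seed(cfg.seed, "cv"),
            )
            cv = {"mean": cv["mean"], "sd": cv["sd"], "k": cfg.cv_k, "reps": cfg.cv_reps}
        state["cv"] = cv
        return {"lambda": state["fit"].lam, "cv_mean": None if cv is None else round(cv["mean"], 4)}

    @stage("selection_cycles")
    def _(rng):
        pops, bulks = state["populations"], state["bulks"]
        gebvs = {}
        labels = cfg.plan.labels()
        selected = {}
        for n, cyc in enumerate(labels):
            plan_c = cfg.plan.cycles[cyc]
            pop = pops[cyc]
            criterion = cfg.selection_criterion or plan_c.criterion
            fams = list(pop.families())
            if criterion == "phenotype":
                scores = state["y_train"].reindex(fams)
            elif criterion == "gebv":
                if cyc not in bulks:
                    bulks[cyc] = _bulk_table(pop, cfg, rng)
                cand = bulks[cyc].subset_markers(state["qc_idx"])
                train = state["bulks"]["C0"].subset_markers(state["qc_idx"])
                combined = GenotypeTable(
                    list(train.samples) + list(cand.samples),
                    train.map,
                    np.vstack([train.dosage, cand.dosage]),
                )
                grm = gblup.compute_grm(combined)
                scores = gblup.predict_gebv(state["fit"], grm, fams)
                gebvs[cyc] = (
                    scores.rename("gebv")
                    .rename_axis("family")
                    .reset_index()
                    .assign(rank=lambda d: d["gebv"].rank(ascending=False).astype(int))
                )
            elif criterion == "random":
                scores = pd.Series(rng.random(len(fams)), index=fams)
            else:
                raise ValueError(f"unknown selection criterion {criterion!r}")
            keep = breeding.select_families(scores, plan_c.families_selected)
            selected[cyc] = keep
            sub = _family_subpop(pop, keep)
            nxt = labels[n + 1] if n + 1 < len(labels) else "C4"
            ears = plan_c.ears_selected if nxt != "C4" else cfg.plan.final_ears
            ppf = cfg.plan.cycles[nxt].plants_per_family if nxt != "C4" else plan_c.plants_per_family
            pops[nxt] = breeding.bulk_intermate(sub, ears, rng, progeny_per_ear=ppf, cycle=nxt)
        state["gebvs"] = gebvs
        state["selected"] = selected
        return {cyc: len(v) for cyc, v in selected.items()}

    @stage("evaluation_trial")
    def _(rng):
        pops = state["populations"]
        frames = []
        for cyc in [*cfg.plan.labels(), "C4"]:
            pop = pops[cyc]
            vals = traits.entry_values(pop, state["arch"])
            if cyc == "C0":
                keep = state["selected"]["C0"]  # the best training families
            else:
                if cyc == "C4":
                    n_eval = cfg.plan.final_entries_evaluated or cfg.eval_entries_per_cycle
                else:
                    n_eval = cfg.eval_entries_per_cycle
                fams = list(vals["family"])
                n_eval = min(n_eval, len(fams))
                keep = sorted(rng.choice(fams, size=n_eval, replace=False))
            frames.append(vals[vals["family"].isin(keep)])
        entries = pd.concat(frames, ignore_index=True)
        parent_vals = traits.entry_values(
            state["founders"].population, state["arch"], by_family=False
        )["genetic_value"]
        base = float(parent_vals.mean())
        checks = {
            "check_baseline": base,
            "check_local1": base + float(cfg.genetic_sd * rng.standard_normal()),
            "check_local2": base + float(cfg.genetic_sd * rng.standard_normal()),
            "check_commercial": base + float(cfg.genetic_sd * rng.standard_normal()),
        }
        state["eval_records"] = traits.simulate_trial(
            entries,
            state["arch"],
            cfg.eval_locations,
            cfg.eval_reps,
            rng,
            checks=checks,
            location_names=["loc_A", "loc_B"],
        )
        return {"n_entries": len(entries), "n_records": len(state["eval_records"])}

    @stage("gain_analysis")
    def _(rng):
        rec = state["eval_records"]
        state["gain_report"] = gains.gain_table(rec)
        rows = []
        for cyc, grp in rec[~rec["is_check"]].groupby("cycle"):
            vc = traits.estimate_variance_components(grp)
            g = grp["entry"].nunique()
            ell, r = vc["n_locations"], vc["n_reps"]
            rows.append(
                {
                    "cycle": cyc,
                    "h2_entry_mean": vc["h2_entry_mean"],
                    "lsd05": gains.lsd(
                        r * vc["sigma2_ge"] + vc["sigma2_e"],
                        max((g - 1) * (ell - 1), 1),
                        ell * r,
                    ),
                }
            )
        state["h2_report"] = pd.DataFrame(rows).sort_values("cycle").reset_index(drop=True)

    @stage("diversity_analysis")
    def _(rng):
        pops, bulks = state["populations"], state["bulks"]
        parents_gt = state["founders"].genotypes
        tables = [parents_gt]
        groups = {"parents": list(parents_gt.samples)}
        for cyc in cfg.plan.labels():
            if cyc not in bulks:
                bulks[cyc] = _bulk_table(pops[cyc], cfg, rng)
            tables.append(bulks[cyc])
            groups[cyc] = list(bulks[cyc].samples)
            groups[f"{cyc}_selected"] = state["selected"][cyc]
        combined = GenotypeTable(
            sum((list(t.samples) for t in tables), []),
            state["map"],
            np.vstack([t.dosage for t in tables]),
        )
        state["diversity_report"] = diversity.diversity_report(combined, groups)
        dist = diversity.ibs_distance(combined)
        coords, _ = diversity.classical_mds(dist, dims=3)
        state["mds_coords"] = coords

        prof1 = diversity.allele_frequencies(parents_gt, label="parents")
        prof2 = diversity.allele_frequencies(bulks["C3"], label="C3")
        report = diversity.classify_marker_status(prof1, prof2, cfg.mono_band)
        state["status_by_chrom"] = report.per_chromosome(state["map"])
        state["clusters"] = diversity.cluster_changed_snps(
            report, state["map"], cfg.cluster_max_gap_bp, cfg.cluster_min_size
        )
        state["shift_summary"] = diversity.frequency_shift_summary(
            prof1, prof2, cfg.shift_threshold, cfg.mono_band
        )
        return {"n_groups": len(groups), "n_changed": int(state["status_by_chrom"]["total_changed"].sum())}

    result = ExperimentResult(
        config=cfg,
        arch=state["arch"],
        populations=state["populations"],
        bulk_tables=state["bulks"],
        gebv_tables=state["gebvs"],
        training_records=state["training_records"],
        eval_records=state["eval_records"],
        gain_report=state["gain_report"],
        h2_report=state["h2_report"],
        diversity_report=state["diversity_report"],
        status_by_chrom=state["status_by_chrom"],
        clusters=state["clusters"],
        shift_summary=state["shift_summary"],
        mds_coords=state["mds_coords"],
        cv=state["cv"],
        log=log,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def training_population_analog(
    seed: int,
    n_families: int = 1000,
    markers_per_chrom: int = 200,
    target_h2_entry: float = 0.34,
    n_locations: int = 4,
    bulk_plants: int = 15,
) -> dict:
    """Synthetic analogue of the full-size genomic-prediction training cycle.

    Builds the 18-founder panel, crosses and intermates it, selfs to
    ``n_families`` ear-to-row families, genotypes each as a 15-plant bulk,
    runs the multi-location testcross trial, and returns the
    location-adjusted entry means with the QC'd GRM — the inputs of the
    prediction-accuracy cross-validation.

    Returns a dict with ``y``, ``grm``, ``arch``, ``h2_realized``,
    ``n_markers_qc``.
    """
    cfg = ExperimentConfig(
        markers_per_chrom=markers_per_chrom,
        target_h2_entry=target_h2_entry,
        training_locations=n_locations,
        bulk_plants=bulk_plants,
        seed=seed,
    )
    gmap = founders.simulate_map(
        cfg.n_chrom, cfg.markers_per_chrom, cfg.chrom_length_cM, cfg.chrom_length_bp,
        seed=stage_seed(seed, "map"),
    )
    panel = founders.simulate_founders(
        gmap, cfg.n_parents, missing_rate=cfg.missing_rate, seed=stage_seed(seed, "founders")
    )
    tester = founders.simulate_founders(
        gmap, 2, missing_rate=0.0, seed=stage_seed(seed, "tester")
    ).population
    arch = traits.assign_architecture(
        gmap, panel, n_qtl=cfg.n_qtl, target_h2_entry=target_h2_entry,
        n_locations=n_locations, n_reps=cfg.training_reps,
        seed=stage_seed(seed, "architecture"), mu=cfg.mu, genetic_sd=cfg.genetic_sd,
        tester=tester,
    )
    rng = stage_rng(seed, "training_population")
    f1 = breeding.half_diallel(panel.population, cfg.f1_plants_per_family, rng)
    s1 = breeding.bulk_intermate(
        f1, int(round(S1_PER_C0_FAMILY * n_families)), rng, progeny_per_ear=1, cycle="S1"
    )
    chosen = rng.choice(s1.n, size=n_families, replace=False)
    c0 = breeding.ear_to_row_families(
        s1, sorted(chosen), bulk_plants, rng, prefix="C0_f", cycle="C0"
    )
    bulk = _bulk_table(c0, cfg, stage_rng(seed, "c0_genotyping"))
    qc_idx = founders.marker_qc(bulk)
    rec = traits.simulate_trial(
        c0, arch, n_locations, cfg.training_reps, stage_rng(seed, "c0_trial")
    )
    y = adjusted_entry_means(rec)
    grm = gblup.compute_grm(bulk.subset_markers(qc_idx))
    vc = traits.estimate_variance_components(rec)
    return {
        "y": y,
        "grm": grm,
        "arch": arch,
        "h2_realized": vc["h2_entry_mean"],
        "n_markers_qc": int(qc_idx.size),
        "population": c0,
    }


def _write_partial(state: dict, cfg: ExperimentConfig, out_dir) -> None:
    """Retain artifacts of completed stages after a failure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    for key in ("gain_report", "diversity_report", "status_by_chrom", "clusters"):
        if key in state:
            io.write_report(
                state[key].reset_index() if key == "status_by_chrom" else state[key],
                out / f"{key}.tsv",
            )
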