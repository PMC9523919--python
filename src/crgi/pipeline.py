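"""End-to-end orchestration of the pipeline stages.

Each stage consumes and produces only files under the output directory, so
stages can be rerun individually with identical results; a manifest JSON
per stage records the thresholds, seed, config hash and the funnel counts
(tested pairs → candidates → consensus → drug-confirmed).  Reruns with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as crgi_io
from .cohort import (
    differential_features,
    GroupSplit,
    pairwise_correlation,
    pathway_enrichment,
    score_shift_test,
    split_by_target_median,
)
from .datatypes import InteractionType, Orientation, ResponseMetric, ScreenDataset, \
    DrugResponseDataset, Cohort, MutationCatalog
from .drugsim import compare_groups, drug_pair_table
from .network import (
    build_network,
    cancer_gene_enrichment,
    degree_table,
    gene_gene_edges,
    network_summary,
    ppi_overlap_test,
)
from .pharmaco import aggregate_drug_evidence, drug_response_test, map_interactions_to_drugs
from .screens import consensus, scan_candidates
from .simulate import SimulationConfig, write_bundle
from .survival import (
    ActivationRule,
    build_module,
    burden_groups,
    count_activated,
    module_carrier_split,
    single_pair_survival,
    SurvivalComparison,
    survival_of_groups,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_stage", "STAGES"]

STAGES = (
    "simulate", "screen-gi", "drug-filter", "network",
    "drugsim", "validate", "survival", "run-all",
)


@dataclass
class PipelineConfig:
    """Thresholds and simulation overrides for one pipeline run."""

    seed: int = 0
    alpha: float = 0.05
    alpha_combined: float = 0.05
    min_support: int = 2
    fdr: float = 0.1
    min_tissue_lines: int = 4
    min_group: int = 3
    min_mut_freq: float = 0.10
    n_perm: int = 1000
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_combined", "fdr", "min_mut_freq"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.min_support < 1 or self.min_group < 1 or self.min_tissue_lines < 1:
            raise ValueError("minimum counts must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.sim)


def _write_manifest(out_dir: Path, stage: str, cfg: PipelineConfig, counts: dict) -> None:
    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "thresholds": {
            "alpha": cfg.alpha, "alpha_combined": cfg.alpha_combined,
            "min_support": cfg.min_support, "fdr": cfg.fdr,
            "min_tissue_lines": cfg.min_tissue_lines, "min_group": cfg.min_group,
            "min_mut_freq": cfg.min_mut_freq, "n_perm": cfg.n_perm,
        },
        "counts": counts,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# bundle loading

def _load_screens(bundle: Path):
    with open(bundle / "manifest.json") as fh:
        meta = json.load(fh)
    lineages = crgi_io.read_lineages(bundle / "lineages.tsv")
    screens, catalogs = [], {}
    for s in meta["screens"]:
        scores = crgi_io.read_matrix(bundle / f"{s['name']}_scores.tsv", "score")
        screens.append(ScreenDataset(name=s["name"], orientation=Orientation(s["orientation"]),
                                     scores=scores, lineages=lineages))
        catalogs[s["name"]] = crgi_io.read_mutations(bundle / f"{s['name']}_mutations.tsv")
    return meta, screens, catalogs


def _load_pharmaco(bundle: Path, meta):
    lineages = crgi_io.read_lineages(bundle / "lineages.tsv")
    datasets = []
    for d in meta["pharmaco"]:
        resp = crgi_io.read_matrix(bundle / f"{d['name']}_responses.tsv", "response")
        datasets.append(DrugResponseDataset(name=d["name"], metric=ResponseMetric(d["metric"]),
                                            responses=resp, lineages=lineages))
    mutations = crgi_io.read_mutations(bundle / "pharmaco_mutations.tsv")
    return datasets, mutations


def _load_cohort(bundle: Path, cancer_type: str) -> Cohort:
    cdir = bundle / "cohort"
    surv = pd.read_csv(cdir / "survival.tsv", sep="\t", index_col="sample")
    return Cohort(
        cancer_type=cancer_type,
        expression=crgi_io.read_matrix(cdir / "expression.tsv", "expression"),
        methylation=crgi_io.read_matrix(cdir / "methylation.tsv", "methylation"),
        mutations=crgi_io.read_mutations(cdir / "mutations.tsv"),
        survival=surv,
        sample_scores=crgi_io.read_matrix(cdir / "sample_scores.tsv", "score"),
    )


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig, out_dir: Path) -> dict:
    bundle = out_dir / "bundle"
    manifest = write_bundle(cfg.sim_config(), bundle)
    counts = {"screens": len(manifest["screens"]),
              "pharmaco_datasets": len(manifest["pharmaco"]),
              "planted_csl": len(manifest["planted_csl"]),
              "planted_csv": len(manifest["planted_csv"])}
    return counts


def stage_screen(cfg: PipelineConfig, out_dir: Path) -> dict:
    bundle = out_dir / "bundle"
    meta, screens, catalogs = _load_screens(bundle)
    cr_genes = crgi_io.read_gene_list(bundle / "cr_genes.txt")
    targets = crgi_io.read_gene_list(bundle / "targets.txt")
    pairs = None
    design_path = bundle / "pair_design.tsv"
    if design_path.exists():
        design = pd.read_csv(design_path, sep="\t", dtype=str)
        pairs = list(zip(design["target"], design["partner"]))
    table = scan_candidates(
        screens, catalogs, cr_genes, targets, pairs=pairs,
        alpha=cfg.alpha, min_lines=cfg.min_tissue_lines, min_group=cfg.min_group,
    )
    sdir = out_dir / "screen-gi"
    sdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(sdir / "pair_tests.tsv", sep="\t", index=False)
    records, conflicts = consensus(table, min_support=cfg.min_support,
                                   alpha_combined=cfg.alpha_combined)
    crgi_io.write_results(records, sdir / "consensus.tsv",
                          metadata={"seed": cfg.seed, "screens": [s["name"] for s in meta["screens"]],
                                    "alpha": cfg.alpha, "alpha_combined": cfg.alpha_combined})
    crgi_io.write_results(conflicts, sdir / "conflicts.tsv", metadata={"seed": cfg.seed})
    counts = {
        "tested_pairs": int(len(table)),
        "candidate_lethal": int(table["sig_lethal"].sum()) if len(table) else 0,
        "candidate_viable": int(table["sig_viable"].sum()) if len(table) else 0,
        "consensus": len(records),
        "consensus_csl": sum(r.itype is InteractionType.CSL for r in records),
        "consensus_csv": sum(r.itype is InteractionType.CSV for r in records),
        "conflict_pairs": len(conflicts) // 2,
    }
    _write_manifest(sdir, "screen-gi", cfg, counts)
    return counts


def stage_drug_filter(cfg: PipelineConfig, out_dir: Path) -> dict:
    bundle = out_dir / "bundle"
    with open(bundle / "manifest.json") as fh:
        meta = json.load(fh)
    records = crgi_io.read_results(out_dir / "screen-gi" / "consensus.tsv")
    datasets, mutations = _load_pharmaco(bundle, meta)
    dtm = crgi_io.read_drug_targets(bundle / "drug_targets.tsv")
    pairs = map_interactions_to_drugs(records, dtm)
    kept, rejected = [], []
    for ds in datasets:
        for pair in pairs:
            res = drug_response_test(pair, ds, mutations,
                                     min_group=cfg.min_group,
                                     min_tissue_lines=cfg.min_tissue_lines,
                                     alpha=cfg.alpha)
            (kept if hasattr(res, "drug_p") else rejected).append(res)
    ddir = out_dir / "drug-filter"
    ddir.mkdir(parents=True, exist_ok=True)
    crgi_io.write_results(kept, ddir / "drug_records.tsv",
                          metadata={"seed": cfg.seed, "datasets": [d.name for d in datasets]})
    aggregate_drug_evidence(kept).to_csv(ddir / "evidence.tsv", sep="\t", index=False)
    counts = {
        "interaction_drug_pairs": len(pairs),
        "tests": len(pairs) * len(datasets),
        "retained": len(kept),
        "retained_interactions": len({(r.interaction.pair, r.interaction.tissue) for r in kept}),
    }
    _write_manifest(ddir, "drug-filter", cfg, counts)
    return counts


def stage_network(cfg: PipelineConfig, out_dir: Path) -> dict:
    bundle = out_dir / "bundle"
    records = crgi_io.read_results(out_dir / "drug-filter" / "drug_records.tsv")
    ppi = crgi_io.read_ppi(bundle / "ppi.tsv")
    cancer = crgi_io.read_gene_list(bundle / "cancer_genes.txt")
    cr_genes = crgi_io.read_gene_list(bundle / "cr_genes.txt")
    ndir = out_dir / "network"
    ndir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for itype in (InteractionType.CSL, InteractionType.CSV):
        subset = [r for r in records if r.interaction.itype is itype]
        if not subset:
            summary[itype.value] = {"empty": True}
            continue
        net = build_network(subset)
        info = network_summary(net)
        deg = degree_table(net)
        deg.rename("degree").to_csv(ndir / f"{itype.value.lower()}_degrees.tsv", sep="\t",
                                    index_label="node")
        edges = pd.DataFrame(
            [{"a": a, "b": b, **d} for a, b, d in net.edges(data=True)]
        ).sort_values(["a", "b"]).reset_index(drop=True)
        edges.to_csv(ndir / f"{itype.value.lower()}_edges.tsv", sep="\t", index=False)
        observed, emp_p = ppi_overlap_test(net, ppi, n_perm=cfg.n_perm, seed=cfg.seed)
        info["ppi_overlap_rate"] = observed
        info["ppi_empirical_p"] = emp_p
        net_crs = {g for e in gene_gene_edges(net) for g in e} & cr_genes
        if net_crs:
            enr = cancer_gene_enrichment(net_crs, cr_genes, cancer)
            info["cancer_enrichment_stat"] = enr.statistic
            info["cancer_enrichment_p"] = enr.p_value
        summary[itype.value] = info
    with open(ndir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    counts = {k: v.get("n_gene_gene_edges", 0) for k, v in summary.items()}
    _write_manifest(ndir, "network", cfg, counts)
    return counts


def stage_drugsim(cfg: PipelineConfig, out_dir: Path) -> dict:
    bundle = out_dir / "bundle"
    records = crgi_io.read_results(out_dir / "drug-filter" / "drug_records.tsv")
    atc = crgi_io.read_atc(bundle / "atc.tsv")
    sdir = out_dir / "drugsim"
    sdir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for itype in (InteractionType.CSL, InteractionType.CSV):
        partners: dict = {}
        for r in records:
            if r.interaction.itype is itype:
                partners.setdefault(r.drug, set()).add(r.interaction.partner)
        table = drug_pair_table(partners, atc=atc, alpha=cfg.alpha)
        table.to_csv(sdir / f"{itype.value.lower()}_drug_pairs.tsv", sep="\t", index=False)
        counts[f"{itype.value}_pairs"] = int(len(table))
        counts[f"{itype.value}_similar"] = int(table["similar"].sum()) if len(table) else 0
        scored = table.dropna(subset=["atc_jaccard"])
        sim = scored.loc[scored["similar"], "atc_jaccard"]
        oth = scored.loc[~scored["similar"], "atc_jaccard"]
        if len(sim) >= 2 and len(oth) >= 2:
            res = compare_groups(sim.to_numpy(), oth.to_numpy())
            counts[f"{itype.value}_atc_t_p"] = res.p_value
    _write_manifest(sdir, "drugsim", cfg, counts)
    return counts


def stage_validate(cfg: PipelineConfig, out_dir: Path) -> dict:
    bundle = out_dir / "bundle"
    with open(bundle / "manifest.json") as fh:
        meta = json.load(fh)
    records = crgi_io.read_results(out_dir / "screen-gi" / "consensus.tsv")
    cohort = _load_cohort(bundle, meta["config"].get("cancer_type", "NA"))
    pathways = crgi_io.read_gmt(bundle / "pathways.gmt")
    vdir = out_dir / "validate"
    vdir.mkdir(parents=True, exist_ok=True)
    pairs = sorted({(r.target, r.partner) for r in records})
    corr_e = pairwise_correlation(cohort.expression, pairs, kind="expression")
    corr_m = pairwise_correlation(cohort.methylation, pairs, kind="methylation")
    pd.concat([corr_e, corr_m]).to_csv(vdir / "correlations.tsv", sep="\t", index=False)
    rows = []
    for rec in sorted(records, key=lambda r: (r.target, r.partner, r.tissue)):
        split = split_by_target_median(cohort, rec, min_mut_freq=cfg.min_mut_freq)
        row = {"target": rec.target, "partner": rec.partner, "itype": rec.itype.value}
        if not isinstance(split, GroupSplit):
            row.update(status="skipped", reason=split.reason)
            rows.append(row)
            continue
        if len(split.low_group) < 3 or len(split.high_group) < 3:
            row.update(status="skipped", reason="split group too small")
            rows.append(row)
            continue
        up_e, down_e = differential_features(cohort.expression, split, fdr=cfg.fdr)
        up_m, down_m = differential_features(cohort.methylation, split, fdr=cfg.fdr)
        hrd = score_shift_test(cohort.sample_scores.loc["HRD"], split, alpha=cfg.alpha)
        row.update(
            status="ok", reason="",
            n_low=len(split.low_group), n_high=len(split.high_group),
            expr_up=len(up_e), expr_down=len(down_e),
            meth_up=len(up_m), meth_down=len(down_m),
            hrd_direction=hrd["direction"],
            hrd_p=hrd["result"].p_value if hrd["result"] else None,
            hrd_significant=hrd["significant"],
        )
        rows.append(row)
    report = pd.DataFrame(rows)
    report.to_csv(vdir / "validation.tsv", sep="\t", index=False)
    cr_genes = crgi_io.read_gene_list(bundle / "cr_genes.txt")
    partners = sorted({r.partner for r in records} - cr_genes) or sorted(
        {r.partner for r in records}
    )
    universe = sorted(cohort.expression.index)
    enrich = pathway_enrichment(set(partners) & set(universe), pathways,
                                set(universe), fdr=cfg.fdr)
    enrich.to_csv(vdir / "pathway_enrichment.tsv", sep="\t", index=False)
    ok = report[report["status"] == "ok"] if len(report) else report
    counts = {
        "interactions": len(records),
        "validated": int(len(ok)),
        "deregulating_expression": int(((ok["expr_up"] + ok["expr_down"]) > 0).sum()) if len(ok) else 0,
        "significant_pathways": int(enrich["significant"].sum()) if len(enrich) else 0,
    }
    _write_manifest(vdir, "validate", cfg, counts)
    return counts


def _comparison_entry(comp) -> dict:
    if isinstance(comp, str):
        return {"status": "skipped", "reason": comp}
    return {
        "status": "ok",
        "statistic": comp.result.statistic,
        "p": comp.result.p_value,
        "degenerate": comp.degenerate,
        "group_sizes": {k: int(len(v[0])) for k, v in comp.groups.items()},
    }


def stage_survival(cfg: PipelineConfig, out_dir: Path) -> dict:
    bundle = out_dir / "bundle"
    with open(bundle / "manifest.json") as fh:
        meta = json.load(fh)
    records = crgi_io.read_results(out_dir / "screen-gi" / "consensus.tsv")
    drug_records = crgi_io.read_results(out_dir / "drug-filter" / "drug_records.tsv")
    cohort = _load_cohort(bundle, meta["config"].get("cancer_type", "NA"))
    rule = ActivationRule()
    sdir = out_dir / "survival"
    sdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"activation_rule": {"expression_side": rule.expression_side,
                                        "require_expression": rule.require_expression,
                                        "note": "activation = partner mutation AND "
                                                "target expression on the configured "
                                                "side of the cohort median"}}
    single = {}
    for rec in sorted(records, key=lambda r: (r.target, r.partner, r.tissue)):
        comp = single_pair_survival(cohort, rec, min_mut_freq=cfg.min_mut_freq)
        single[f"{rec.target}~{rec.partner}"] = _comparison_entry(comp)
    report["single_pair"] = single
    burden = {}
    for itype in (InteractionType.CSL, InteractionType.CSV):
        subset = [r for r in records if r.itype is itype]
        if not subset:
            continue
        counts_s = count_activated(cohort, subset, rule)
        labels = burden_groups(counts_s)
        groups = {
            lab: tuple(labels.index[labels == lab]) for lab in ("none", "fewer", "more")
        }
        groups = {k: v for k, v in groups.items() if v}
        entry: dict = {"group_sizes": {k: len(v) for k, v in groups.items()}}
        if len(groups) >= 2:
            comp = survival_of_groups(cohort, groups)
            entry.update(statistic=comp.result.statistic, p=comp.result.p_value,
                         degenerate=comp.degenerate)
        burden[itype.value] = entry
    report["burden"] = burden
    modules = {}
    by_key: dict = {}
    for r in drug_records:
        by_key.setdefault((r.interaction.target, r.interaction.tissue,
                           r.interaction.itype), []).append(r)
    for (target, tissue, itype), group in sorted(
        by_key.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
    ):
        try:
            module = build_module(group, target, tissue)
        except ValueError:
            continue
        split = module_carrier_split(cohort, module, rule)
        entry = {"itype": itype.value,
                 "partners": sorted(module.partners),
                 "drugs": sorted(module.drugs),
                 "group_sizes": {k: len(v) for k, v in split.items()}}
        nonempty = {k: v for k, v in split.items() if v}
        if len(nonempty) >= 2:
            comp = survival_of_groups(cohort, nonempty)
            entry.update(statistic=comp.result.statistic, p=comp.result.p_value,
                         degenerate=comp.degenerate)
        modules[f"{target}@{tissue}"] = entry
    report["modules"] = modules
    with open(sdir / "survival.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    counts = {
        "single_pair_tested": sum(1 for v in single.values() if v["status"] == "ok"),
        "single_pair_skipped": sum(1 for v in single.values() if v["status"] != "ok"),
        "modules": len(modules),
    }
    _write_manifest(sdir, "survival", cfg, counts)
    return counts


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "screen-gi": stage_screen,
    "drug-filter": stage_drug_filter,
    "network": stage_network,
    "drugsim": stage_drugsim,
    "validate": stage_validate,
    "survival": stage_survival,
}


def run_stage(stage: str, cfg: PipelineConfig, out_dir) -> dict:
    """Run one stage (or ``run-all``) and return its funnel counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stage == "run-all":
        all_counts = {}
        for name in ("simulate", "screen-gi", "drug-filter", "network",
                     "drugsim", "validate", "survival"):
            log.info("running stage %s", name)
            all_counts[name] = _STAGE_FUNCS[name](cfg, out_dir)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump({"seed": cfg.seed, "config_hash": cfg.digest(),
                       "counts": all_counts}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return all_counts
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    return _STAGE_FUNCS[stage](cfg, out_dir)
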