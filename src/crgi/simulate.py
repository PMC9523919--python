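"""Synthetic data generation for every input the pipeline consumes.

The generator emulates the shapes of the real resources — multiple
perturbation screens over a shared cell-line panel with tissue labels and
per-screen mutation calls, correlated drug-response matrices, and a
TCGA-like cohort (expression, methylation, mutations, survival, per-sample
scores) — with effects planted at configurable sizes so every pipeline
stage can be exercised and power-tested without any download.

Planted-effect semantics (all shifts in units of the noise σ):

* CSL pair: in viability orientation, partner-mutant lines' target scores
  are shifted down by δσ; CSV pairs up.  Identical pair semantics across
  screens with independent noise; the raw matrix is negated for screens
  declared LOW_IS_VIABLE.
* Drug response: partner-mutant lines of a planted CSL pair shift down
  (sensitive) by the drug shift, CSV up (resistant).
* Cohort: planted pairs get bivariate-normal expression/methylation
  correlation ρ; survival is exponential with the hazard divided by HR for
  CSL-activated patients (better prognosis) and multiplied by HR for
  CSV-activated ones (worse); HRD and one immune score are shifted in
  activated patients of planted pairs.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AtcCatalog,
    Cohort,
    DrugResponseDataset,
    DrugTargetMap,
    MutationCatalog,
    Orientation,
    PathwayCollection,
    PPIGraph,
    ResponseMetric,
    ScreenDataset,
)
from . import io as crgi_io

__all__ = [
    "SimulationConfig",
    "generate_screens",
    "generate_pharmaco",
    "generate_cohort",
    "generate_side_data",
    "planted_feature_matrix",
    "write_bundle",
]

_ALTERING = ("missense", "nonsense", "frameshift", "splice")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study, with defaults matching the planted
    design the pipeline is validated against: 20 CSL + 10 CSV pairs at a
    2σ viability shift, one tissue of 100 cell lines with a 0.3 partner
    mutation rate (≈30 mutant / 70 wild-type), three screens (one
    CERES-like LOW_IS_VIABLE, two fitness-like HIGH_IS_VIABLE)."""

    seed: int = 0
    # pair design: planted pairs plus independent null pairs; pair i joins
    # target T{i} (a chromatin regulator) with partner P{i}, so each pair is
    # an independent hypothesis (cross-pairing planted targets with other
    # mutated genes would contaminate null pairs through chance overlap of
    # mutation masks — a known confounder of marginal association tests)
    n_csl: int = 20
    n_csv: int = 10
    n_null_pairs: int = 100
    # cell-line panel
    tissues: dict = field(default_factory=lambda: {"lung": 100})
    # screens
    n_screens: int = 3
    orientations: tuple = (
        Orientation.LOW_IS_VIABLE,
        Orientation.HIGH_IS_VIABLE,
        Orientation.HIGH_IS_VIABLE,
    )
    noise_sigma: float = 1.0
    delta: float = 2.0  # planted viability shift, in σ units
    mutation_rate: float = 0.3
    mutation_flip_rate: float = 0.0  # per-screen annotation discordance
    # pharmacogenomic datasets
    n_pharmaco: int = 2
    drug_shift: float = 2.0
    # cohort
    n_patients: int = 200
    cancer_type: str = "LUAD"
    expression_rho: float = 0.8
    cohort_mutation_rate: float = 0.3
    hazard_ratio: float = 2.5
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censoring_rate: float = 0.2
    score_shift: float = 1.0
    n_response_genes: int = 20  # genes deregulated by the first planted pair
    # side data
    n_pathways: int = 10
    ppi_edge_prob: float = 0.02
    ppi_planted_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.orientations = tuple(Orientation(o) for o in self.orientations)[: self.n_screens]
        if len(self.orientations) < self.n_screens:
            extra = self.n_screens - len(self.orientations)
            self.orientations = self.orientations + (Orientation.HIGH_IS_VIABLE,) * extra
        for rate in (self.mutation_rate, self.cohort_mutation_rate,
                     self.censoring_rate, self.mutation_flip_rate,
                     self.ppi_planted_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")

    # -- derived naming ----------------------------------------------------
    @property
    def n_pairs(self) -> int:
        return self.n_csl + self.n_csv + self.n_null_pairs

    @property
    def targets(self) -> list[str]:
        return [f"T{i:03d}" for i in range(self.n_pairs)]

    @property
    def partners(self) -> list[str]:
        return [f"P{i:03d}" for i in range(self.n_pairs)]

    @property
    def cr_genes(self) -> set:
        return set(self.targets)

    @property
    def pair_design(self) -> list[tuple[str, str]]:
        """The designed (target, partner) hypotheses, planted first."""
        return list(zip(self.targets, self.partners))

    @property
    def planted_csl(self) -> list[tuple[str, str]]:
        return self.pair_design[: self.n_csl]

    @property
    def planted_csv(self) -> list[tuple[str, str]]:
        return self.pair_design[self.n_csl : self.n_csl + self.n_csv]

    @property
    def cell_lines(self) -> list[str]:
        return [f"CL{i:04d}" for i in range(sum(self.tissues.values()))]

    @property
    def lineages(self) -> pd.Series:
        labels = []
        for tissue, n in self.tissues.items():
            labels.extend([tissue] * n)
        return pd.Series(labels, index=self.cell_lines, name="tissue")

    @property
    def drug_target_map(self) -> DrugTargetMap:
        """One drug per target; drugs of unplanted targets carry no planted
        response shift and serve as the null arm of the drug filter."""
        return DrugTargetMap(pairs={f"drug_{t}": {t} for t in self.targets})


def _mutation_truth(config: SimulationConfig) -> pd.DataFrame:
    """Shared cell-line × partner mutation status (boolean), one draw per run."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    status = rng.random((len(config.cell_lines), len(config.partners))) < config.mutation_rate
    return pd.DataFrame(status, index=config.cell_lines, columns=config.partners)


def _catalog_from_status(status: pd.DataFrame, rng: np.random.Generator) -> MutationCatalog:
    rows = []
    for gene in status.columns:
        for sample in status.index[status[gene]]:
            cls = _ALTERING[rng.integers(0, len(_ALTERING))]
            rows.append({"sample": sample, "gene": gene, "mutation_class": cls})
    df = pd.DataFrame(rows, columns=["sample", "gene", "mutation_class"])
    return MutationCatalog(records=df)


def generate_screens(config: SimulationConfig):
    """Perturbation screens plus per-screen mutation catalogs.

    Baseline scores are i.i.d. normal(0, σ); planted pairs shift the target
    score of partner-mutant lines by ∓δσ (CSL down, CSV up) in viability
    orientation, then the matrix is negated for LOW_IS_VIABLE screens.
    """
    truth = _mutation_truth(config)
    genes = config.targets + config.partners
    lines = config.cell_lines
    screens, catalogs = [], {}
    for si in range(config.n_screens):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20 + si]))
        scores = rng.normal(0.0, config.noise_sigma, size=(len(genes), len(lines)))
        scores = pd.DataFrame(scores, index=genes, columns=lines)
        for sign, pairs in ((-1.0, config.planted_csl), (+1.0, config.planted_csv)):
            for target, partner in pairs:
                if target not in scores.index or partner not in truth.columns:
                    raise ValueError(f"planted pair ({target}, {partner}) references unknown gene")
                mut_lines = truth.index[truth[partner]]
                scores.loc[target, mut_lines] += sign * config.delta * config.noise_sigma
        orientation = config.orientations[si]
        if orientation is Orientation.LOW_IS_VIABLE:
            scores = -scores
        name = f"screen{si + 1}"
        screens.append(
            ScreenDataset(name=name, orientation=orientation, scores=scores,
                          lineages=config.lineages)
        )
        # per-screen annotation, optionally degraded by a flip rate
        status = truth.copy()
        if config.mutation_flip_rate > 0:
            flips = rng.random(status.shape) < config.mutation_flip_rate
            status = status ^ flips
        catalogs[name] = _catalog_from_status(status, rng)
    return screens, catalogs


def generate_pharmaco(config: SimulationConfig):
    """Drug-response datasets with planted partner-mutant shifts.

    Responses are normal around a per-drug baseline; for drugs targeting a
    planted pair's target, partner-mutant lines shift down (CSL, sensitive)
    or up (CSV, resistant).  Independent noise per dataset.
    """
    truth = _mutation_truth(config)
    dtm = config.drug_target_map
    drugs = sorted(dtm.pairs)
    lines = config.cell_lines
    metric_cycle = (ResponseMetric.AUC, ResponseMetric.IC50)
    planted = {t: (-1.0, p) for t, p in config.planted_csl}
    planted.update({t: (+1.0, p) for t, p in config.planted_csv})
    datasets = []
    for di in range(config.n_pharmaco):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 40 + di]))
        baselines = rng.normal(5.0, 1.0, size=len(drugs))
        resp = rng.normal(0.0, config.noise_sigma, size=(len(drugs), len(lines)))
        resp = pd.DataFrame(resp, index=drugs, columns=lines)
        resp = resp.add(baselines, axis=0)
        for drug in drugs:
            (target,) = dtm.pairs[drug]
            if target in planted:
                sign, partner = planted[target]
                mut_lines = truth.index[truth[partner]]
                resp.loc[drug, mut_lines] += sign * config.drug_shift * config.noise_sigma
        datasets.append(
            DrugResponseDataset(
                name=f"pharmaco{di + 1}",
                metric=metric_cycle[di % 2],
                responses=resp,
                lineages=config.lineages,
            )
        )
    return datasets


_IMMUNE_SCORES = ("Macrophages_M1", "Macrophages_M2", "Plasma_cells", "Tregs")


def generate_cohort(config: SimulationConfig) -> Cohort:
    """TCGA-like patient bundle with interaction-linked effects.

    Expression/methylation: standard normal per gene, with each planted pair
    drawn bivariate-normal at correlation ρ.  Partner mutations are
    Bernoulli at the cohort rate.  Survival is exponential; CSL-activated
    patients (partner mutated, target expression below the cohort median)
    have hazard / HR, CSV-activated hazard × HR.  Censoring replaces the
    event with a uniform earlier time for a configured fraction.  HRD and
    M2-macrophage scores shift in activated patients of planted pairs;
    response genes of the first planted pair shift in its activated
    patients.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 60]))
    patients = [f"PT{i:04d}" for i in range(config.n_patients)]
    response_genes = [f"RG{i:03d}" for i in range(config.n_response_genes)]
    genes = config.targets + config.partners + response_genes

    def correlated_matrix() -> pd.DataFrame:
        mat = pd.DataFrame(
            rng.normal(0.0, 1.0, size=(len(genes), len(patients))),
            index=genes, columns=patients,
        )
        rho = config.expression_rho
        for target, partner in config.planted_csl + config.planted_csv:
            shared = rng.normal(0.0, 1.0, size=len(patients))
            for g in (target, partner):
                noise = rng.normal(0.0, 1.0, size=len(patients))
                mat.loc[g] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        return mat

    expression = correlated_matrix()
    methylation = correlated_matrix()

    mut_rows = []
    mut_status = {}
    for partner in config.partners:
        carriers = rng.random(len(patients)) < config.cohort_mutation_rate
        mut_status[partner] = np.array(patients)[carriers]
        for sample in mut_status[partner]:
            cls = _ALTERING[rng.integers(0, len(_ALTERING))]
            mut_rows.append({"sample": sample, "gene": partner, "mutation_class": cls})
    mutations = MutationCatalog(
        records=pd.DataFrame(mut_rows, columns=["sample", "gene", "mutation_class"])
    )

    def activated(target: str, partner: str) -> set:
        expr = expression.loc[target]
        low = set(expr.index[expr <= float(expr.median())])
        return set(mut_status[partner]) & low

    log_hr = np.zeros(len(patients))
    idx = {p: i for i, p in enumerate(patients)}
    for target, partner in config.planted_csl:
        for s in activated(target, partner):
            log_hr[idx[s]] -= np.log(config.hazard_ratio)
    for target, partner in config.planted_csv:
        for s in activated(target, partner):
            log_hr[idx[s]] += np.log(config.hazard_ratio)
    # per-pair contributions would compound; cap at one net pair effect
    log_hr = np.clip(log_hr, -np.log(config.hazard_ratio), np.log(config.hazard_ratio))
    hazard = config.baseline_hazard * np.exp(log_hr)
    times = rng.exponential(1.0 / hazard)
    events = np.ones(len(patients), dtype=int)
    censored = rng.random(len(patients)) < config.censoring_rate
    times = np.where(censored, times * rng.random(len(patients)), times)
    events[censored] = 0
    survival = pd.DataFrame(
        {"time": np.round(times, 1), "event": events}, index=patients
    )
    survival.index.name = "sample"

    scores = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(1 + len(_IMMUNE_SCORES), len(patients))),
        index=["HRD"] + list(_IMMUNE_SCORES), columns=patients,
    )
    for target, partner in config.planted_csl + config.planted_csv:
        act = sorted(activated(target, partner))
        scores.loc["HRD", act] += config.score_shift
        scores.loc["Macrophages_M2", act] -= config.score_shift
    if config.planted_csl:
        target, partner = config.planted_csl[0]
        act = sorted(activated(target, partner))
        half = len(response_genes) // 2
        expression.loc[response_genes[:half], act] += config.score_shift
        expression.loc[response_genes[half:], act] -= config.score_shift

    return Cohort(
        cancer_type=config.cancer_type,
        expression=expression,
        methylation=methylation,
        mutations=mutations,
        survival=survival,
        sample_scores=scores,
    )


def generate_side_data(config: SimulationConfig):
    """PPI graph, pathway collection, ATC catalog and cancer gene set.

    The PPI is an Erdős–Rényi graph over the gene universe plus guaranteed
    edges for a configured fraction of planted pairs; one pathway contains
    the planted partners; drugs of planted CSL targets share an ATC code.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 80]))
    genes = config.targets + config.partners
    edges = set()
    n = len(genes)
    rand = rng.random((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rand[i, j] < config.ppi_edge_prob:
                edges.add((genes[i], genes[j]))
    planted = config.planted_csl + config.planted_csv
    for target, partner in planted:
        if rng.random() < config.ppi_planted_fraction:
            edges.add((target, partner))
    ppi = PPIGraph(edges=edges)

    sets = {}
    for pi in range(config.n_pathways):
        size = min(int(rng.integers(8, 20)), len(genes))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"PW{pi:02d}"] = set(members)
    sets["PW_PLANTED"] = {p for _, p in planted}
    pathways = PathwayCollection(sets=sets)

    dtm = config.drug_target_map
    csl_targets = {t for t, _ in config.planted_csl}
    codes = {}
    for di, drug in enumerate(sorted(dtm.pairs)):
        (target,) = dtm.pairs[drug]
        own = {f"X{di:02d}AA01"}
        if target in csl_targets:
            own.add("L01XX01")
        codes[drug] = own
    atc = AtcCatalog(codes=codes)

    cancer = set(rng.choice(config.targets, size=max(2, config.n_pairs // 4),
                            replace=False))
    cancer |= {t for t, _ in planted[: config.n_csl // 2]}
    return ppi, pathways, atc, cancer


def planted_feature_matrix(
    seed: int,
    n_features: int = 500,
    n_planted: int = 50,
    n_low: int = 30,
    n_high: int = 30,
    shift: float = 2.0,
):
    """Feature × sample matrix with the first ``n_planted`` features shifted
    up (by ``shift``·σ) in the low/reference group; returns
    ``(matrix, low_samples, high_samples, planted_features)``."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_low + n_high)]
    low, high = samples[:n_low], samples[n_low:]
    feats = [f"F{i:03d}" for i in range(n_features)]
    mat = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_features, len(samples))),
        index=feats, columns=samples,
    )
    mat.loc[feats[:n_planted], low] += shift
    return mat, tuple(low), tuple(high), set(feats[:n_planted])


def write_bundle(config: SimulationConfig, out_dir) -> dict:
    """Generate everything and write the full TSV/GMT bundle + manifest.

    Layout: screens (scores + mutations per screen), lineages, pharmaco
    matrices, drug targets, side data, cohort tables, the planted truth and
    a manifest with the config.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    screens, catalogs = generate_screens(config)
    for screen in screens:
        crgi_io.write_matrix(screen.scores, out / f"{screen.name}_scores.tsv")
        crgi_io.write_mutations(catalogs[screen.name], out / f"{screen.name}_mutations.tsv")
    crgi_io.write_lineages(config.lineages, out / "lineages.tsv")

    pharmaco = generate_pharmaco(config)
    for ds in pharmaco:
        crgi_io.write_matrix(ds.responses, out / f"{ds.name}_responses.tsv")
    crgi_io.write_drug_targets(config.drug_target_map, out / "drug_targets.tsv")
    # mutation annotation accompanying the pharmacogenomic panels
    rng_ph = np.random.default_rng(np.random.SeedSequence([config.seed, 45]))
    crgi_io.write_mutations(
        _catalog_from_status(_mutation_truth(config), rng_ph),
        out / "pharmaco_mutations.tsv",
    )

    ppi, pathways, atc, cancer = generate_side_data(config)
    crgi_io.write_ppi(ppi, out / "ppi.tsv")
    crgi_io.write_gmt(pathways, out / "pathways.gmt")
    crgi_io.write_atc(atc, out / "atc.tsv")
    crgi_io.write_gene_list(cancer, out / "cancer_genes.txt")
    crgi_io.write_gene_list(config.cr_genes, out / "cr_genes.txt")
    crgi_io.write_gene_list(config.targets, out / "targets.txt")
    pd.DataFrame(config.pair_design, columns=["target", "partner"]).to_csv(
        out / "pair_design.tsv", sep="\t", index=False
    )

    cohort = generate_cohort(config)
    cdir = out / "cohort"
    cdir.mkdir(exist_ok=True)
    crgi_io.write_matrix(cohort.expression, cdir / "expression.tsv")
    crgi_io.write_matrix(cohort.methylation, cdir / "methylation.tsv")
    crgi_io.write_mutations(cohort.mutations, cdir / "mutations.tsv")
    surv = cohort.survival.reset_index()
    surv.to_csv(cdir / "survival.tsv", sep="\t", index=False)
    crgi_io.write_matrix(cohort.sample_scores, cdir / "sample_scores.tsv")

    screen_meta = [
        {"name": s.name, "orientation": s.orientation.value} for s in screens
    ]
    pharmaco_meta = [{"name": d.name, "metric": d.metric.value} for d in pharmaco]
    manifest = {
        "seed": config.seed,
        "screens": screen_meta,
        "pharmaco": pharmaco_meta,
        "planted_csl": config.planted_csl,
        "planted_csv": config.planted_csv,
        "tissues": config.tissues,
        "config": {
            k: v for k, v in asdict(config).items()
            if not isinstance(v, (Orientation, tuple))
        },
    }
    manifest["config"]["orientations"] = [o.value for o in config.orientations]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
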