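"""Domain types for the chromatin-regulator genetic-interaction pipeline.

A *target* is the perturbed gene (knocked out/down in a screen, or inhibited
by a drug); a *partner* is the mutated gene conditioning the effect.  A pair
is CSL (synthetic lethal) when partner mutation makes target knockout more
lethal, CSV (synthetic viable) when it enhances viability.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Orientation",
    "InteractionType",
    "Direction",
    "ResponseMetric",
    "ALTERING_CLASSES",
    "MUTATION_CLASSES",
    "ScreenDataset",
    "MutationCatalog",
    "DrugResponseDataset",
    "DrugTargetMap",
    "InteractionRecord",
    "DrugInteractionRecord",
    "Cohort",
    "PPIGraph",
    "PathwayCollection",
    "AtcCatalog",
    "ModuleDefinition",
]


class Orientation(enum.Enum):
    HIGH_IS_VIABLE = "high_is_viable"
    LOW_IS_VIABLE = "low_is_viable"


class InteractionType(enum.Enum):
    CSL = "CSL"
    CSV = "CSV"


class Direction(enum.Enum):
    SENSITIVE = "SENSITIVE"
    RESISTANT = "RESISTANT"


class ResponseMetric(enum.Enum):
    IC50 = "IC50"
    AUC = "AUC"


MUTATION_CLASSES = ("missense", "nonsense", "frameshift", "splice", "other", "silent")
#: mutation classes counted as gene-altering by default (silent excluded)
ALTERING_CLASSES = frozenset(c for c in MUTATION_CLASSES if c != "silent")


def _check_lineages(scores: pd.DataFrame, lineages: pd.Series) -> pd.Series:
    lineages = pd.Series(lineages)
    missing = [c for c in scores.columns if c not in lineages.index]
    if missing:
        raise ValueError(f"cell lines without tissue label: {missing[:5]}")
    return lineages


@dataclass
class ScreenDataset:
    """One perturbation screen: gene × cell-line dependency scores.

    ``orientation`` declares which direction of the raw score means "more
    viable": CERES-style scores are LOW_IS_VIABLE (lower = more essential),
    fitness/viability scores are HIGH_IS_VIABLE.
    """

    name: str
    orientation: Orientation
    scores: pd.DataFrame  # genes × cell lines; NaN = missing
    lineages: pd.Series  # cell line → tissue

    def __post_init__(self) -> None:
        if not isinstance(self.orientation, Orientation):
            self.orientation = Orientation(self.orientation)
        self.lineages = _check_lineages(self.scores, self.lineages)
        vals = self.scores.to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise ValueError(f"screen {self.name}: infinite score entries")

    @property
    def cell_lines(self) -> pd.Index:
        return self.scores.columns

    def tissue_lines(self, tissue: str) -> list[str]:
        in_tissue = self.lineages[self.lineages == tissue].index
        return [c for c in self.scores.columns if c in set(in_tissue)]


@dataclass
class MutationCatalog:
    """Per-sample mutation calls with class labels.

    ``records`` has columns (sample, gene, mutation_class); duplicates are
    dropped.  "silent" records are retained but excluded from alteration
    calls unless ``altering_classes`` says otherwise.
    """

    records: pd.DataFrame
    altering_classes: frozenset = ALTERING_CLASSES

    def __post_init__(self) -> None:
        req = ["sample", "gene", "mutation_class"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"mutation table missing columns {missing}")
        df = self.records[req].astype(str)
        if (df["gene"].str.len() == 0).any():
            raise ValueError("empty gene symbol in mutation table")
        self.records = df.drop_duplicates().reset_index(drop=True)

    def altered_samples(self, gene: str) -> set[str]:
        df = self.records
        m = (df["gene"] == gene) & df["mutation_class"].isin(self.altering_classes)
        return set(df.loc[m, "sample"])

    def altering_records(self) -> pd.DataFrame:
        return self.records[self.records["mutation_class"].isin(self.altering_classes)]

    @property
    def genes(self) -> list[str]:
        return sorted(self.altering_records()["gene"].unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DrugResponseDataset:
    """Drug × cell-line response matrix (IC50 or AUC; lower = more sensitive)."""

    name: str
    metric: ResponseMetric
    responses: pd.DataFrame  # drugs × cell lines; NaN = missing
    lineages: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.metric, ResponseMetric):
            self.metric = ResponseMetric(self.metric)
        self.lineages = _check_lineages(self.responses, self.lineages)

    @property
    def drugs(self) -> pd.Index:
        return self.responses.index


@dataclass
class DrugTargetMap:
    """drug → set of target genes."""

    pairs: dict

    def __post_init__(self) -> None:
        self.pairs = {d: set(ts) for d, ts in self.pairs.items()}
        empty = [d for d, ts in self.pairs.items() if not ts]
        if empty:
            raise ValueError(f"drugs with no target: {empty[:5]}")

    def drugs_for_target(self, gene: str) -> list[str]:
        return sorted(d for d, ts in self.pairs.items() if gene in ts)


@dataclass
class InteractionRecord:
    """A candidate or consensus CSL/CSV pair with per-screen and combined p."""

    target: str
    partner: str
    tissue: str
    itype: InteractionType
    per_dataset_p: dict  # screen name → directional p in (0, 1]
    n_mut: int
    n_wt: int
    combined_p: float
    support: frozenset  # screens with nominal significance
    conflict: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.itype, InteractionType):
            self.itype = InteractionType(self.itype)
        self.support = frozenset(self.support)
        if not (0.0 < self.combined_p <= 1.0):
            raise ValueError(f"combined_p {self.combined_p} outside (0, 1]")
        for s, p in self.per_dataset_p.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"per-dataset p for {s} outside (0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.target, self.partner)


@dataclass
class DrugInteractionRecord:
    """An interaction promoted to a drug-response biomarker.

    CSL pairs must show partner-mutant sensitivity (lower IC50/AUC), CSV
    pairs resistance; the invariant is enforced at construction.
    """

    interaction: InteractionRecord
    drug: str
    pharmaco_dataset: str
    drug_p: float
    direction: Direction
    n_mut: int = 0
    n_wt: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.direction, Direction):
            self.direction = Direction(self.direction)
        if not (0.0 < self.drug_p <= 1.0):
            raise ValueError("drug_p outside (0, 1]")
        want = (
            Direction.SENSITIVE
            if self.interaction.itype is InteractionType.CSL
            else Direction.RESISTANT
        )
        if self.direction is not want:
            raise ValueError(
                f"{self.interaction.itype.value} record must be {want.value}"
            )


@dataclass
class Cohort:
    """TCGA-like patient bundle.

    All tables are indexed by feature (rows) × sample (columns) except
    ``survival`` (per-sample rows: time in days, event 0/1).
    """

    cancer_type: str
    expression: pd.DataFrame
    methylation: pd.DataFrame
    mutations: MutationCatalog
    survival: pd.DataFrame  # index sample; columns time, event
    sample_scores: pd.DataFrame  # score name × sample
    feature_matrix: pd.DataFrame | None = None  # e.g. ATAC peaks × sample

    def __post_init__(self) -> None:
        surv = self.survival
        if not {"time", "event"}.issubset(surv.columns):
            raise ValueError("survival table needs 'time' and 'event' columns")
        if (surv["time"] < 0).any():
            raise ValueError("negative survival time")
        if not surv["event"].isin((0, 1)).all():
            raise ValueError("event must be 0/1")
        ref = set(self.expression.columns)
        for name, tab in [
            ("methylation", self.methylation),
            ("sample_scores", self.sample_scores),
        ]:
            extra = set(tab.columns) - ref
            if extra:
                raise ValueError(f"{name} has samples absent from expression: {sorted(extra)[:5]}")
        if not set(surv.index).issubset(ref):
            raise ValueError("survival has samples absent from expression")

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns


class PPIGraph:
    """Undirected protein–protein interaction edge set (no self-loops)."""

    def __init__(self, edges) -> None:
        clean = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on {a}")
            clean.add((a, b) if a <= b else (b, a))
        self.edges = frozenset(clean)
        self._adj: dict = {}
        for a, b in self.edges:
            self._adj.setdefault(a, set()).add(b)
            self._adj.setdefault(b, set()).add(a)

    @property
    def genes(self) -> set:
        return set(self._adj)

    def has_edge(self, a: str, b: str) -> bool:
        key = (a, b) if a <= b else (b, a)
        return key in self.edges

    def neighbors(self, g: str) -> set:
        return self._adj.get(g, set())

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class PathwayCollection:
    """Named gene sets (e.g. KEGG pathways)."""

    sets: dict

    def __post_init__(self) -> None:
        self.sets = {name: set(genes) for name, genes in self.sets.items()}
        empty = [n for n, g in self.sets.items() if not g]
        if empty:
            raise ValueError(f"empty pathways: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class AtcCatalog:
    """drug → set of ATC classification codes."""

    codes: dict

    def __post_init__(self) -> None:
        self.codes = {d: set(cs) for d, cs in self.codes.items()}
        for d, cs in self.codes.items():
            for c in cs:
                if not c or not c.isalnum() or c != c.upper():
                    raise ValueError(f"malformed ATC code {c!r} for {d}")


@dataclass
class ModuleDefinition:
    """Union of partner genes sharing one drug target in one tissue."""

    target: str
    tissue: str
    partners: frozenset
    drugs: frozenset
    itype: InteractionType

    def __post_init__(self) -> None:
        if not isinstance(self.itype, InteractionType):
            self.itype = InteractionType(self.itype)
        self.partners = frozenset(self.partners)
        self.drugs = frozenset(self.drugs)
        if not self.partners:
            raise ValueError("module has no partners")
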