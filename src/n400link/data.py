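"""Trial-level N400 data model, IO, and the two regression recipes.

A trial is one (subject, item) presentation with its single-trial N400
amplitude (mean voltage over centro-parietal electrodes in the N400 window,
in microvolts) plus whatever covariates the dataset convention carries:
lab, pre-stimulus baseline voltage, concreteness, log word frequency,
orthographic neighborhood (OLD20) and sentence position.

Two preset regression recipes cover the dataset conventions analyzed:

``lab_random_subject``
    baselined amplitude ~ metric + lab, random intercept per subject
    (multi-lab replication-style datasets).

``baseline_covariates``
    raw amplitude ~ baseline + concreteness + log_frequency + old20 +
    sentence_position + metric, with baseline slopes (and intercepts) for
    subject and item.  Crossed subject/item components are modelled as
    independent variance components; ``subject_slope_only=True`` restricts
    the subject term to the baseline slope.

All numeric variables entering a design — including, by default, the
dependent variable — are z-scored on the analyzed trial set.  AIC and
likelihood-ratio comparisons between metrics are unaffected by the common
affine DV transform (a property the test-suite asserts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DesignError, InvalidInputError, SchemaError
from .metrics import zscore

__all__ = [
    "CANONICAL_COLUMNS",
    "RegressionRecipe",
    "RandomTerm",
    "Dataset",
    "ModelFrame",
    "preset_recipe",
    "load_trials",
    "write_trials",
    "build_design",
]

logger = logging.getLogger(__name__)

#: canonical trial-table columns; the first three are always required
CANONICAL_COLUMNS = (
    "subject_id", "item_id", "amplitude", "lab", "baseline",
    "concreteness", "log_frequency", "old20", "sentence_position",
)

_NUMERIC_COVARIATES = ("baseline", "concreteness", "log_frequency",
                       "old20", "sentence_position")


@dataclass(frozen=True)
class RandomTerm:
    """One random-effects term: grouping factor, slope columns, intercept."""

    factor: str
    slopes: Tuple[str, ...] = ()
    intercept: bool = True


@dataclass(frozen=True)
class RegressionRecipe:
    """Named fixed + random effects specification."""

    name: str
    dv: str  # "raw_amplitude" | "baselined_amplitude"
    fixed_terms: Tuple[str, ...]
    random_terms: Tuple[RandomTerm, ...]

    def __post_init__(self):
        if self.dv not in ("raw_amplitude", "baselined_amplitude"):
            raise InvalidInputError(f"unknown dependent variable {self.dv!r}")


def preset_recipe(name: str, subject_slope_only: bool = False) -> RegressionRecipe:
    """Return one of the two preset recipes (see module docstring)."""
    if name == "lab_random_subject":
        return RegressionRecipe(
            name=name,
            dv="baselined_amplitude",
            fixed_terms=("metric", "lab"),
            random_terms=(RandomTerm("subject_id"),),
        )
    if name == "baseline_covariates":
        subject_term = RandomTerm("subject_id", slopes=("baseline",),
                                  intercept=not subject_slope_only)
        return RegressionRecipe(
            name=name,
            dv="raw_amplitude",
            fixed_terms=("baseline", "concreteness", "log_frequency",
                         "old20", "sentence_position", "metric"),
            random_terms=(subject_term,
                          RandomTerm("item_id", slopes=("baseline",))),
        )
    raise InvalidInputError(f"unknown preset recipe {name!r}")


@dataclass
class Dataset:
    """A named collection of trials plus its analysis recipe."""

    name: str
    trials: pd.DataFrame
    recipe: Optional[RegressionRecipe] = None
    stimuli: Optional[pd.DataFrame] = None
    n_dropped: int = 0
    drop_log: List[str] = field(default_factory=list)

    def __post_init__(self):
        for col in ("subject_id", "item_id", "amplitude"):
            if col not in self.trials.columns:
                raise SchemaError(f"trial table lacks required column {col!r}")
        if self.stimuli is not None:
            known = set(self.stimuli["item_id"])
            orphan = sorted(set(self.trials["item_id"]) - known)
            if orphan:
                raise SchemaError(
                    f"trials reference items absent from stimuli: {orphan[:10]}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def load_trials(path: Union[str, Path],
                schema: Optional[Mapping[str, object]] = None,
                name: Optional[str] = None,
                recipe: Optional[RegressionRecipe] = None) -> Dataset:
    """Read a trial table from CSV/TSV.

    ``schema`` may carry ``columns`` (mapping canonical name -> file column)
    and ``required`` (list of canonical names; defaults to subject_id,
    item_id, amplitude plus everything the recipe needs).  Rows missing a
    required field are dropped and counted.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep)

    schema = dict(schema or {})
    colmap: Dict[str, str] = dict(schema.get("columns", {}))
    required = list(schema.get("required", ["subject_id", "item_id", "amplitude"]))
    if recipe is not None:
        needed = [t for t in recipe.fixed_terms if t != "metric"]
        required = list(dict.fromkeys(required + needed))

    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = colmap.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
    df = raw.rename(columns=rename)

    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")

    keep = [c for c in CANONICAL_COLUMNS if c in df.columns]
    df = df[keep].copy()
    for col in ("subject_id", "item_id", "lab"):
        if col in df.columns:
            df[col] = df[col].astype(str)

    before = len(df)
    mask = df[required].notna().all(axis=1)
    if "amplitude" in required:
        mask &= np.isfinite(df["amplitude"].astype(float))
    df = df.loc[mask].reset_index(drop=True)
    n_dropped = before - len(df)
    drop_log = []
    if n_dropped:
        msg = f"{path.name}: dropped {n_dropped} row(s) with missing required fields"
        drop_log.append(msg)
        logger.info(msg)

    return Dataset(name=name or path.stem, trials=df, recipe=recipe,
                   n_dropped=n_dropped, drop_log=drop_log)


def write_trials(dataset: Dataset, path: Union[str, Path]) -> None:
    """Write the analyzed trial fields back out (round-trips exactly)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    dataset.trials.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# model frames


@dataclass
class RandomStructure:
    """Realized random term: integer codes plus level labels."""

    factor: str
    codes: np.ndarray
    levels: List[str]
    slopes: Tuple[str, ...] = ()
    intercept: bool = True

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def signature(self) -> str:
        parts = ["1"] if self.intercept else []
        parts += list(self.slopes)
        return f"({'+'.join(parts)}|{self.factor})"


@dataclass
class ModelFrame:
    """Response vector, fixed design and random structure, ready to fit."""

    y: np.ndarray
    X: pd.DataFrame
    random: List[RandomStructure]
    data: pd.DataFrame            # z-scored analysis columns (for slopes)
    dataset_name: str = ""
    drop_log: List[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def random_signature(self) -> str:
        return "+".join(r.signature() for r in self.random)

    def subset(self, fixed_columns: Sequence[str]) -> "ModelFrame":
        """Same response and random structure, a subset of fixed columns.

        ``Intercept`` is always retained.  Used to fit nested fixed-effect
        sets against an identical response for likelihood-ratio tests.
        """
        cols = ["Intercept"] + [c for c in self.X.columns
                                if c != "Intercept" and c in fixed_columns]
        missing = [c for c in fixed_columns if c not in self.X.columns]
        if missing:
            raise DesignError(f"fixed column(s) {missing} not in design")
        return ModelFrame(y=self.y, X=self.X[cols], random=self.random,
                          data=self.data, dataset_name=self.dataset_name,
                          drop_log=list(self.drop_log))

    def with_metric(self, values_by_item: Mapping[str, float],
                    column: str = "metric") -> "ModelFrame":
        """Swap the (z-scored) metric column for new item-level values."""
        items = self.data["item_id"]
        raw = items.map(values_by_item)
        if raw.isna().any():
            missing = sorted(items[raw.isna()].unique())
            raise DesignError(f"metric values missing for items {missing[:10]}")
        z = zscore(raw.to_numpy(dtype=float))
        X = self.X.copy()
        X[column] = z
        data = self.data.copy()
        data[column] = z
        return ModelFrame(y=self.y, X=X, random=self.random, data=data,
                          dataset_name=self.dataset_name,
                          drop_log=list(self.drop_log))


def build_design(dataset: Dataset,
                 metric: Union[str, Mapping[str, float], pd.Series, np.ndarray],
                 recipe: Optional[RegressionRecipe] = None,
                 zscore_dv: bool = True,
                 extra_metrics: Optional[Mapping[str, Mapping[str, float]]] = None,
                 ) -> ModelFrame:
    """Assemble the model frame for one dataset/metric/recipe combination.

    Parameters
    ----------
    metric
        Either a column name already present in the trial table, a mapping
        ``item_id -> value``, or a trial-aligned vector.
    extra_metrics
        Additional item-level metric columns (name -> mapping) added to the
        fixed design; used for variance-partitioning fits where several
        metrics enter one model against the same response.

    Rows with missing required fields are dropped and logged, never silently.
    """
    recipe = recipe or dataset.recipe or preset_recipe("lab_random_subject")
    df = dataset.trials.copy().reset_index(drop=True)

    # resolve the metric column
    if isinstance(metric, str):
        if metric not in df.columns:
            raise DesignError(f"metric column {metric!r} not in trial table")
        df["metric"] = df[metric].astype(float)
    elif isinstance(metric, Mapping) or isinstance(metric, pd.Series):
        mapping = dict(metric) if not isinstance(metric, Mapping) else metric
        df["metric"] = df["item_id"].map(mapping).astype(float)
    else:
        arr = np.asarray(metric, dtype=float)
        if arr.shape[0] != len(df):
            raise DesignError("trial-aligned metric vector has wrong length")
        df["metric"] = arr
    for name, mapping in (extra_metrics or {}).items():
        df[name] = df["item_id"].map(mapping).astype(float)

    extra_names = list(extra_metrics or {})
    needed = set(recipe.fixed_terms) | set(extra_names) | {"subject_id", "item_id"}
    for rt in recipe.random_terms:
        needed.add(rt.factor)
        needed.update(rt.slopes)
    needed.discard("metric")
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"recipe {recipe.name!r} needs column(s) {sorted(missing_cols)}")

    check_cols = sorted((needed | {"metric", "amplitude"}) & set(df.columns))
    before = len(df)
    mask = df[check_cols].notna().all(axis=1)
    df = df.loc[mask].reset_index(drop=True)
    drop_log = list(dataset.drop_log)
    if before - len(df):
        msg = (f"{dataset.name}: design dropped {before - len(df)} trial(s) "
               f"with missing values in {check_cols}")
        drop_log.append(msg)
        logger.info(msg)
    if len(df) < 3:
        raise DesignError(f"{dataset.name}: too few usable trials ({len(df)})")

    # z-score every numeric variable on the analyzed trial set
    numeric_terms = [t for t in recipe.fixed_terms if t != "lab"] + extra_names
    slope_terms = {s for rt in recipe.random_terms for s in rt.slopes}
    for col in dict.fromkeys(list(numeric_terms) + sorted(slope_terms)):
        try:
            df[col] = zscore(df[col].to_numpy(dtype=float))
        except DegenerateInputError:
            raise DegenerateInputError(
                f"{dataset.name}: term {col!r} is constant on the analyzed trials")
    y = df["amplitude"].to_numpy(dtype=float)
    if zscore_dv:
        y = zscore(y)

    # fixed design, deterministic column order
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for term in list(recipe.fixed_terms) + extra_names:
        if term == "lab":
            levels = sorted(df["lab"].unique())
            if len(levels) < 2:
                raise DesignError(
                    f"{dataset.name}: categorical term 'lab' has a single level")
            for lev in levels[1:]:
                X[f"lab[{lev}]"] = (df["lab"] == lev).astype(float)
        else:
            X[term] = df[term].to_numpy()

    random: List[RandomStructure] = []
    for rt in recipe.random_terms:
        codes, levels = pd.factorize(df[rt.factor], sort=True)
        if len(levels) < 2:
            raise DesignError(
                f"{dataset.name}: grouping factor {rt.factor!r} has a single level")
        random.append(RandomStructure(factor=rt.factor,
                                      codes=np.asarray(codes),
                                      levels=[str(l) for l in levels],
                                      slopes=rt.slopes,
                                      intercept=rt.intercept))

    return ModelFrame(y=y, X=X, random=random, data=df,
                      dataset_name=dataset.name, drop_log=drop_log)
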