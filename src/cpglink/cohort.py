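"""Domain types, validation and tabular I/O for methylation cohorts.

A cohort bundles a participant-level phenotype table (exposure = CTQ-SF
childhood-maltreatment total, outcome = BDI-II depressive-symptom total,
plus candidate confounders), a participants x CpG-units percent-methylation
matrix, and the analysis configuration.  All file I/O is delimited text
(TSV by default, comma accepted); missing methylation is an empty cell or
"NA" on read and written back as "NA".  Participant order is canonicalized
by sorted ID on load so downstream results never depend on file row order.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGUnit",
    "MethylationMatrix",
    "AnalysisConfig",
    "Cohort",
    "CohortError",
    "CohortInconsistencyError",
    "ValueDomainError",
    "AnnotationError",
    "InsufficientDataError",
    "CollinearDesignError",
    "AllUnitsRemovedError",
    "DependencyError",
    "read_cohort",
    "write_cohort",
    "write_report",
    "PHENOTYPE_COLUMNS",
]

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class CohortError(Exception):
    """Base class for cohort validation and analysis errors."""


class CohortInconsistencyError(CohortError):
    """Participant ID sets of phenotype and methylation tables disagree."""


class ValueDomainError(CohortError):
    """A value lies outside its permitted domain (e.g. methylation > 100%)."""


class AnnotationError(CohortError):
    """CpG-unit annotation is malformed (duplicate IDs, bad coordinates...)."""


class InsufficientDataError(CohortError):
    """Too few complete observations for the requested computation."""


class CollinearDesignError(CohortError):
    """Design matrix is rank deficient; names the offending terms."""


class AllUnitsRemovedError(CohortError):
    """A QC filter removed every CpG unit."""


class DependencyError(CohortError):
    """A pipeline stage was invoked before the stage it depends on."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: Phenotype columns required on read, in canonical order.
PHENOTYPE_COLUMNS = (
    "maltreatment",
    "depression",
    "age",
    "drug_use",
    "smoking",
    "alcohol",
    "bmi",
)


@dataclass(frozen=True)
class CpGUnit:
    """One measured methylation unit covering >= 1 adjacent CpG positions.

    EpiTYPER-style assays report a single percent-methylation value per
    cleavage fragment, which may span several CpG dinucleotides; ``positions``
    holds the 1-based GRCh37 coordinates of every CpG in the unit, strictly
    increasing, all on ``chrom``.
    """

    unit_id: str
    gene: str
    chrom: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.unit_id:
            raise AnnotationError("unit_id must be a non-empty string")
        pos = tuple(int(p) for p in self.positions)
        if len(pos) == 0:
            raise AnnotationError(f"unit {self.unit_id!r}: positions must be non-empty")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise AnnotationError(
                f"unit {self.unit_id!r}: positions must be strictly increasing, got {pos}"
            )
        object.__setattr__(self, "positions", pos)

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1]


class MethylationMatrix:
    """Participants x CpG-units percent-methylation matrix (0-100, NaN = missing).

    Wraps a :class:`pandas.DataFrame` (index = participant IDs, columns =
    unit IDs) together with the unit annotation.  Construction validates the
    value domain and the ID/annotation correspondence.
    """

    def __init__(self, values: pd.DataFrame, units: Sequence[CpGUnit]):
        unit_ids = [u.unit_id for u in units]
        if len(set(unit_ids)) != len(unit_ids):
            dupes = sorted({u for u in unit_ids if unit_ids.count(u) > 1})
            raise AnnotationError(f"duplicate unit_id in annotation: {dupes}")
        if list(values.columns) != unit_ids:
            missing = set(unit_ids) ^ set(values.columns)
            if missing:
                raise AnnotationError(
                    f"matrix columns and annotation disagree on units: {sorted(missing)}"
                )
            values = values[unit_ids]
        arr = values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 100)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueDomainError(
                f"methylation value {arr[i, j]!r} for participant "
                f"{values.index[i]!r}, unit {values.columns[j]!r} outside [0, 100]"
            )
        if values.index.has_duplicates:
            raise CohortInconsistencyError("duplicate participant IDs in methylation matrix")
        self.values = values.astype(float)
        self.units = list(units)
        self._unit_map = {u.unit_id: u for u in self.units}

    # -- container conveniences -------------------------------------------
    @property
    def participants(self) -> list[str]:
        return list(self.values.index)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def unit(self, unit_id: str) -> CpGUnit:
        return self._unit_map[unit_id]

    def subset(self, unit_ids: Sequence[str]) -> "MethylationMatrix":
        """New matrix restricted to ``unit_ids`` (order preserved)."""
        units = [self._unit_map[u] for u in unit_ids]
        return MethylationMatrix(self.values[list(unit_ids)].copy(), units)

    def sorted_by_participant(self) -> "MethylationMatrix":
        return MethylationMatrix(self.values.sort_index(), self.units)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationMatrix):
            return NotImplemented
        return self.units == other.units and self.values.equals(other.values)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the whole pipeline (defaults mirror the study design).

    winsor_k
        Scores beyond mean +- k*SD are winsorized (k = 3).
    missing_frac_max, zero_frac_min
        QC cascade: drop units with > 20% missing values, then units whose
        non-missing values are > 80% exactly zero.
    duplicate_r_tol
        Units within a gene correlated at r >= 1 - tol are collapsed
        (floating-point r of exact duplicates can miss 1.0 by ulps).
    region_r_min, region_window_bp
        Same-gene units correlated at r >= 0.50 and within 500 bp are
        averaged into a region.
    screen_alpha, confounder_alpha, fdr_q
        Nominal screen significance (0.05), the p < 0.10 confounder-retention
        rule, and the FDR threshold (0.20) used for the BH-corrected column.
    n_mediation_sims
        Monte-Carlo draws for mediation confidence intervals (1,000).
    slope_sd_offset
        Simple slopes are evaluated at the moderator mean +- this many SDs.
    """

    winsor_k: float = 3.0
    missing_frac_max: float = 0.20
    zero_frac_min: float = 0.80
    duplicate_r_tol: float = 1e-9
    region_r_min: float = 0.50
    region_window_bp: int = 500
    screen_alpha: float = 0.05
    confounder_alpha: float = 0.10
    fdr_q: float = 0.20
    n_mediation_sims: int = 1000
    slope_sd_offset: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_frac_max", "zero_frac_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in (
            "winsor_k",
            "region_r_min",
            "region_window_bp",
            "screen_alpha",
            "confounder_alpha",
            "fdr_q",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_mediation_sims < 1:
            raise ValueError("n_mediation_sims must be >= 1")
        if self.duplicate_r_tol < 0:
            raise ValueError("duplicate_r_tol must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    def with_seed(self, seed: int) -> "AnalysisConfig":
        return replace(self, rng_seed=int(seed))


@dataclass
class Cohort:
    """Phenotypes + methylation + config, keyed by participant ID."""

    phenotypes: pd.DataFrame
    methylation: MethylationMatrix
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ph = self.phenotypes
        if ph.index.name != "participant_id":
            if "participant_id" in ph.columns:
                ph = ph.set_index("participant_id")
            else:
                raise CohortInconsistencyError("phenotype table lacks participant_id")
        if ph.index.has_duplicates:
            raise CohortInconsistencyError("duplicate participant IDs in phenotype table")
        ph = ph.sort_index()
        ph.index = ph.index.astype(str)
        meth = self.methylation.sorted_by_participant()
        meth.values.index = meth.values.index.astype(str)
        ph_ids, m_ids = set(ph.index), set(meth.values.index)
        if ph_ids != m_ids:
            only_ph = sorted(ph_ids - m_ids)
            only_m = sorted(m_ids - ph_ids)
            raise CohortInconsistencyError(
                "cohort inconsistency: participant ID sets differ "
                f"(phenotypes only: {only_ph}, methylation only: {only_m})"
            )
        missing_cols = [c for c in ("maltreatment", "depression") if c not in ph.columns]
        if missing_cols:
            raise CohortInconsistencyError(f"phenotype table lacks columns {missing_cols}")
        if (ph["maltreatment"].dropna() < 25).any():
            raise ValueDomainError("maltreatment (CTQ total) below theoretical minimum 25")
        if (ph["depression"].dropna() < 0).any():
            raise ValueDomainError("depression (BDI-II total) below 0")
        if "age" in ph.columns and (ph["age"].dropna() <= 0).any():
            raise ValueDomainError("age must be > 0")
        if "bmi" in ph.columns and (ph["bmi"].dropna() <= 0).any():
            raise ValueDomainError("bmi must be > 0 where present")
        self.phenotypes = ph
        self.methylation = meth

    @property
    def participants(self) -> list[str]:
        return list(self.phenotypes.index)

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    def exposure(self) -> pd.Series:
        return self.phenotypes["maltreatment"].astype(float)

    def outcome(self) -> pd.Series:
        return self.phenotypes["depression"].astype(float)

    def with_methylation(self, matrix: MethylationMatrix) -> "Cohort":
        return Cohort(self.phenotypes.copy(), matrix, self.config, dict(self.meta))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NA_VALUES = ["", "NA"]


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table; TSV default, comma accepted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(
        path, sep=sep, na_values=_NA_VALUES, keep_default_na=False, dtype={0: str}
    )


def _parse_annotation(df: pd.DataFrame) -> list[CpGUnit]:
    required = {"unit_id", "gene", "chrom", "positions"}
    if not required <= set(df.columns):
        raise AnnotationError(
            f"annotation must declare columns {sorted(required)}, got {list(df.columns)}"
        )
    if df["unit_id"].duplicated().any():
        dupes = sorted(df.loc[df["unit_id"].duplicated(), "unit_id"].unique())
        raise AnnotationError(f"duplicate unit_id in annotation: {dupes}")
    units = []
    for row in df.itertuples(index=False):
        try:
            positions = tuple(int(p) for p in re.split(r"[;,]", str(row.positions)))
        except ValueError as exc:
            raise AnnotationError(
                f"unit {row.unit_id!r}: cannot parse positions {row.positions!r}"
            ) from exc
        units.append(
            CpGUnit(str(row.unit_id), str(row.gene), str(row.chrom), positions)
        )
    return units


def read_cohort(
    phenotype_path: str | Path,
    methylation_path: str | Path,
    annotation_path: str | Path,
    config: AnalysisConfig | None = None,
) -> Cohort:
    """Load and validate a cohort from three delimited-text files.

    Raises
    ------
    CohortInconsistencyError
        if phenotype and methylation participant ID sets differ.
    ValueDomainError
        for methylation outside [0, 100] or impossible phenotype scores.
    AnnotationError
        for duplicate unit IDs or malformed coordinates.
    """
    ph = _read_table(phenotype_path)
    if "participant_id" not in ph.columns:
        raise CohortInconsistencyError("phenotype file lacks a participant_id column")
    ph["participant_id"] = ph["participant_id"].astype(str)

    meth = _read_table(methylation_path)
    if "participant_id" not in meth.columns:
        raise CohortInconsistencyError("methylation file lacks a participant_id column")
    meth["participant_id"] = meth["participant_id"].astype(str)
    meth = meth.set_index("participant_id")

    units = _parse_annotation(_read_table(annotation_path))
    unit_ids = [u.unit_id for u in units]
    missing_units = set(unit_ids) ^ set(meth.columns)
    if missing_units:
        raise AnnotationError(
            f"methylation columns and annotation units disagree: {sorted(missing_units)}"
        )
    matrix = MethylationMatrix(meth[unit_ids].astype(float), units)
    return Cohort(ph, matrix, config or AnalysisConfig())


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write phenotypes/methylation/annotation as TSV; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": out / "phenotypes.tsv",
        "methylation": out / "methylation.tsv",
        "annotation": out / "annotation.tsv",
    }
    cohort.phenotypes.reset_index().to_csv(paths["phenotypes"], sep="\t", index=False, na_rep="NA")
    cohort.methylation.values.reset_index(names="participant_id").to_csv(
        paths["methylation"], sep="\t", index=False, na_rep="NA"
    )
    ann = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in cohort.methylation.units],
            "gene": [u.gene for u in cohort.methylation.units],
            "chrom": [u.chrom for u in cohort.methylation.units],
            "positions": [";".join(map(str, u.positions)) for u in cohort.methylation.units],
        }
    )
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    return paths


def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    run_summary: Mapping | None = None,
) -> dict[str, Path]:
    """Write one deterministic TSV per analysis family plus a JSON run summary.

    ``tables`` maps a family name (e.g. ``"screen_exposure"``) to its result
    table; an empty table yields a header-only file.  Floats are rendered with
    ``repr`` round-trip precision so identical inputs give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=None)
        written[name] = path
    if run_summary is not None:
        path = out / "run_summary.json"
        with open(path, "w") as fh:
            json.dump(run_summary, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        written["run_summary"] = path
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
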