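"""Shared fixtures: small hand-checkable cohorts built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cpglink import AnalysisConfig, Cohort, CpGUnit, MethylationMatrix


def make_units(spec: dict[str, tuple[str, str, tuple[int, ...]]]) -> list[CpGUnit]:
    """spec: unit_id -> (gene, chrom, positions)."""
    return [CpGUnit(uid, g, c, pos) for uid, (g, c, pos) in spec.items()]


def make_cohort(
    meth: dict[str, list[float]],
    units: list[CpGUnit] | None = None,
    maltreatment: list[float] | None = None,
    depression: list[float] | None = None,
    extra_phenotypes: dict[str, list[float]] | None = None,
    config: AnalysisConfig | None = None,
) -> Cohort:
    """Small cohort from explicit columns; units default to one gene, 100 bp apart."""
    n = len(next(iter(meth.values())))
    ids = [f"P{i:03d}" for i in range(1, n + 1)]
    if units is None:
        units = [
            CpGUnit(uid, "GENE1", "chr1", (1000 + 100 * k,))
            for k, uid in enumerate(meth)
        ]
    values = pd.DataFrame(meth, index=pd.Index(ids, name="participant_id"), dtype=float)
    matrix = MethylationMatrix(values, units)
    ph = pd.DataFrame(
        {
            "participant_id": ids,
            "maltreatment": maltreatment if maltreatment is not None else np.linspace(25, 75, n),
            "depression": depression if depression is not None else np.linspace(0, 30, n),
        }
    )
    for name, vals in (extra_phenotypes or {}).items():
        ph[name] = vals
    return Cohort(ph, matrix, config or AnalysisConfig())


@pytest.fixture
def tiny_cohort() -> Cohort:
    """3 participants x 2 units, no missing values."""
    return make_cohort(
        {"GENE1_1_CpG_1": [10.0, 20.0, 30.0], "GENE1_1_CpG_2": [5.0, 5.0, 80.0]},
        maltreatment=[25, 40, 60],
        depression=[0, 10, 20],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
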