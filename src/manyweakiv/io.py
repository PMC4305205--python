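"""File I/O: delimited-text readers, fixture generation and result writers.

The on-disk interface is deliberately minimal: a phenotype table (one row
per individual) and a genotype table of 0/1/2 allele counts (individuals as
rows, header row of variant IDs), both comma- or tab-delimited, plus an
optional two-column weights file (variant_id, weight).  VCF/PLINK conversion
is upstream of this package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import IVData
from .exceptions import DataValidationError
from .scores import GenotypeMatrix

log = logging.getLogger("manyweakiv")

__all__ = ["AnalysisConfig", "read_table", "read_dataset", "read_weights",
           "make_fixture", "write_json"]


@dataclass
class AnalysisConfig:
    """Configuration of one estimation run (file paths and column mappings)."""

    phenotype_path: str
    genotype_path: str | None = None
    weights_path: str | None = None
    outcome: str = "outcome"
    exposures: list = field(default_factory=lambda: ["exposure"])
    instruments: list | None = None       # explicit instrument column names
    instrument_prefix: str | None = None  # ... or every column with this prefix
    id_column: str | None = None
    estimators: list = field(default_factory=lambda: ["tsls", "liml", "cue"])
    alpha: float = 0.05
    include_intercept: bool = True
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("exposures"), str):
            raw["exposures"] = [raw["exposures"]]
        return cls(**raw)


def read_table(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, sniffing the delimiter."""
    return pd.read_csv(path, sep=None, engine="python")


def read_weights(path, variant_ids=None) -> np.ndarray:
    """Read a (variant_id, weight) file, aligned to ``variant_ids`` if given."""
    w = read_table(path)
    if w.shape[1] < 2:
        raise DataValidationError("weights file needs columns (variant_id, weight)")
    ser = pd.Series(w.iloc[:, 1].to_numpy(dtype=float),
                    index=w.iloc[:, 0].astype(str))
    if variant_ids is None:
        return ser.to_numpy()
    missing = [v for v in variant_ids if v not in ser.index]
    if missing:
        raise DataValidationError(f"weights missing for variants: {missing[:5]}")
    return ser.loc[list(variant_ids)].to_numpy()


def read_dataset(config: AnalysisConfig):
    """Load and validate one analysis dataset.

    Returns ``(IVData, GenotypeMatrix)``.  Rows with any missing value in
    the used columns are dropped (complete-case analysis) and the exclusion
    count is logged.
    """
    pheno = read_table(config.phenotype_path)
    cols = [config.outcome, *config.exposures]
    missing = [c for c in cols if c not in pheno.columns]
    if missing:
        raise DataValidationError(
            f"phenotype table lacks columns {missing}; has {list(pheno.columns)}")

    if config.genotype_path is None:
        raise DataValidationError("no genotype table configured")
    geno = read_table(config.genotype_path)
    if config.instruments is not None:
        inst_cols = list(config.instruments)
        miss = [c for c in inst_cols if c not in geno.columns]
        if miss:
            raise DataValidationError(f"genotype table lacks columns {miss}")
    elif config.instrument_prefix is not None:
        inst_cols = [c for c in geno.columns
                     if c.startswith(config.instrument_prefix)]
        if not inst_cols:
            raise DataValidationError(
                f"no genotype columns start with {config.instrument_prefix!r}")
    else:
        inst_cols = [c for c in geno.columns if c != config.id_column]

    if config.id_column and config.id_column in pheno.columns \
            and config.id_column in geno.columns:
        merged = pheno[[config.id_column, *cols]].merge(
            geno[[config.id_column, *inst_cols]], on=config.id_column)
    else:
        if len(pheno) != len(geno):
            raise DataValidationError(
                f"phenotype ({len(pheno)}) and genotype ({len(geno)}) tables "
                "have different lengths and no shared id column")
        merged = pd.concat([pheno[cols].reset_index(drop=True),
                            geno[inst_cols].reset_index(drop=True)], axis=1)

    n_total = len(merged)
    complete = merged.dropna(subset=[*cols, *inst_cols])
    n_dropped = n_total - len(complete)
    if n_dropped:
        log.info("read_dataset: excluded %d of %d rows with missing values "
                 "(complete-case)", n_dropped, n_total)
    if complete.empty:
        raise DataValidationError("no complete-case rows remain")

    Graw = complete[inst_cols].to_numpy()
    if not np.all(np.isin(Graw, (0, 1, 2))):
        bad = np.argwhere(~np.isin(Graw, (0, 1, 2)))[0]
        raise DataValidationError(
            f"genotype entry {Graw[tuple(bad)]!r} at row {bad[0]}, column "
            f"{inst_cols[bad[1]]!r} is not in {{0, 1, 2}}")
    weights = None
    if config.weights_path:
        weights = read_weights(config.weights_path, inst_cols)
    gm = GenotypeMatrix(Graw.astype(np.int64), inst_cols, weights)
    data = IVData(complete[config.outcome].to_numpy(dtype=float),
                  complete[list(config.exposures)].to_numpy(dtype=float),
                  gm.G.astype(float),
                  include_intercept=config.include_intercept)
    log.info("read_dataset: n=%d individuals, l=%d exposure(s), J=%d variants",
             data.n, data.l, data.J)
    return data, gm


def make_fixture(outdir, n: int = 50, J: int = 5, kind: str = "dgp",
                 seed: int = 0) -> dict:
    """Write a small synthetic dataset (phenotype/genotype/weights CSVs).

    ``kind="dgp"`` draws from the simulation DGP with the first-stage
    coefficient scaled so the concentration parameter matches the standard
    study value.  ``kind="alspac_like"`` emulates the *shape* of a cohort
    analysis -- many variants with heterogeneous small effects plus an
    external-weights file -- without reproducing any cohort data.
    """
    from .simulate import SIGMA_V2, SimulationDesign, simulate_dataset

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ids = np.arange(1, n + 1)
    variant_ids = [f"v{j+1}" for j in range(J)]

    if kind == "dgp":
        maf = 0.3
        sigma_z2 = 2 * maf * (1 - maf)
        pi = float(np.sqrt(56.70 * SIGMA_V2 / (n * J * sigma_z2)))
        design = SimulationDesign(n=n, J=J, pi_z=pi, maf=maf, reps=1, seed=seed)
        data = simulate_dataset(design, rng)
        G = data.Z_raw.astype(int)
        y, x = data.y_raw, data.X_raw[:, 0]
        weights = None
    elif kind == "alspac_like":
        mafs = rng.uniform(0.1, 0.5, size=J)
        weights = np.abs(rng.normal(0.02, 0.015, size=J)) + 0.002
        u = rng.random((n, J))
        p0 = (1 - mafs) ** 2
        p01 = p0 + 2 * mafs * (1 - mafs)
        G = ((u >= p0).astype(int) + (u >= p01).astype(int))
        conf = rng.standard_normal(n)
        x = (G @ weights) * 3.0 + conf + rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)
        y = 0.45 * x + 0.5 * conf + rng.standard_normal(n) * 0.8
        y = (y - y.mean()) / y.std(ddof=1)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    paths = {}
    pheno = pd.DataFrame({"id": ids, "outcome": y, "exposure": x})
    paths["phenotypes"] = outdir / "phenotypes.csv"
    pheno.to_csv(paths["phenotypes"], index=False)
    geno = pd.DataFrame(G, columns=variant_ids)
    geno.insert(0, "id", ids)
    paths["genotypes"] = outdir / "genotypes.csv"
    geno.to_csv(paths["genotypes"], index=False)
    if weights is not None:
        wdf = pd.DataFrame({"variant_id": variant_ids, "weight": weights})
        paths["weights"] = outdir / "weights.csv"
        wdf.to_csv(paths["weights"], index=False)
    log.info("make_fixture: wrote %s fixture (n=%d, J=%d, seed=%d) to %s",
             kind, n, J, seed, outdir)
    return {k: str(v) for k, v in paths.items()}


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
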