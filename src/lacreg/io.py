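"""Readers and writers for the study's file formats.

Long-format expression CSV (strain, camp_mM, iptg_uM, replicate, afu) is
the canonical exchange format for landscapes; concentration units are
fixed in the column names to prevent silent unit drift.  Growth curves
travel as (well, strain, time_min, od450) CSV, trees as Newick, the
lacI-ZYA region as aligned FASTA, parameters and reports as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .growth import GrowthCurve
from .model import ExpressionLandscape, InducerGrid

logger = logging.getLogger(__name__)

__all__ = ["read_expression_csv", "write_expression_csv",
           "read_growth_csv", "write_growth_csv",
           "read_alignment_fasta", "write_alignment_fasta",
           "read_distance_csv", "write_distance_csv",
           "write_params_json", "read_params_json"]

EXPRESSION_COLUMNS = ["strain", "camp_mM", "iptg_uM", "replicate", "afu"]


class SchemaError(ValueError):
    pass


def read_expression_csv(path) -> list[ExpressionLandscape]:
    """Load landscapes from long-format CSV, averaging replicates.

    Negative background-subtracted AFU values are clamped to 0 (one
    warning with the count).  Strains with incomplete grids are accepted:
    missing cells are NaN and fitting masks them.  Duplicate
    (strain, camp, iptg, replicate) rows and non-numeric afu are errors
    that name the offending location.
    """
    df = pd.read_csv(path)
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    afu = pd.to_numeric(df["afu"], errors="coerce")
    bad = df.index[afu.isna() & df["afu"].notna()]
    if len(bad):
        raise SchemaError(
            f"{path}: non-numeric afu at row {int(bad[0]) + 2} "
            f"(value {df.loc[bad[0], 'afu']!r})")
    df = df.assign(afu=afu)
    dup = df.duplicated(subset=["strain", "camp_mM", "iptg_uM", "replicate"])
    if dup.any():
        i = int(df.index[dup][0])
        raise SchemaError(f"{path}: duplicate measurement row at line {i + 2} "
                          f"({df.loc[i, 'strain']}, camp={df.loc[i, 'camp_mM']}, "
                          f"iptg={df.loc[i, 'iptg_uM']}, rep={df.loc[i, 'replicate']})")
    n_neg = int((df["afu"] < 0).sum())
    if n_neg:
        logger.warning("%s: clamped %d negative afu value(s) to 0", path, n_neg)
        df.loc[df["afu"] < 0, "afu"] = 0.0

    landscapes = []
    for strain, g in df.groupby("strain", sort=True):
        camp = np.sort(g["camp_mM"].unique())
        iptg = np.sort(g["iptg_uM"].unique())
        grid = InducerGrid(tuple(camp), tuple(iptg))
        agg = g.groupby(["camp_mM", "iptg_uM"])["afu"].agg(["mean", "count", "std"])
        values = np.full(grid.shape, np.nan)
        n_rep = np.zeros(grid.shape)
        sd = np.full(grid.shape, np.nan)
        ci = {c: i for i, c in enumerate(camp)}
        ii = {c: i for i, c in enumerate(iptg)}
        for (c, i), row in agg.iterrows():
            values[ci[c], ii[i]] = row["mean"]
            n_rep[ci[c], ii[i]] = row["count"]
            sd[ci[c], ii[i]] = row["std"]
        n_missing = int(np.isnan(values).sum())
        if n_missing:
            logger.warning("%s: strain %s has %d missing grid cell(s)",
                           path, strain, n_missing)
        landscapes.append(ExpressionLandscape(
            strain_id=str(strain), grid=grid, values=values,
            n_replicates=n_rep, sd=sd))
    return landscapes


def write_expression_csv(path, replicates: pd.DataFrame) -> None:
    """Write a long-format expression table (columns EXPRESSION_COLUMNS)."""
    missing = [c for c in EXPRESSION_COLUMNS if c not in replicates.columns]
    if missing:
        raise SchemaError(f"cannot write expression CSV, missing {missing}")
    replicates[EXPRESSION_COLUMNS].to_csv(path, index=False)


def landscape_replicate_frame(strain_id: str, grid: InducerGrid,
                              replicate_values: np.ndarray) -> pd.DataFrame:
    """Long-format frame from a (replicate, camp, iptg) value array."""
    rows = []
    for r in range(replicate_values.shape[0]):
        for i, c in enumerate(grid.camp_levels):
            for j, ipt in enumerate(grid.iptg_levels):
                rows.append({"strain": strain_id, "camp_mM": c, "iptg_uM": ipt,
                             "replicate": r + 1,
                             "afu": replicate_values[r, i, j]})
    return pd.DataFrame(rows)


def read_growth_csv(path) -> list[GrowthCurve]:
    """Load growth curves from (well, strain, time_min, od450) CSV."""
    df = pd.read_csv(path)
    required = ["well", "strain", "time_min", "od450"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    curves = []
    for (well, strain), g in df.groupby(["well", "strain"], sort=True):
        g = g.sort_values("time_min")
        curves.append(GrowthCurve(well_id=str(well), strain_id=str(strain),
                                  times=g["time_min"].to_numpy(dtype=float),
                                  od=g["od450"].to_numpy(dtype=float)))
    return curves


def write_growth_csv(path, curves: list[GrowthCurve]) -> None:
    frames = [pd.DataFrame({"well": c.well_id, "strain": c.strain_id,
                            "time_min": c.times, "od450": c.od})
              for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_alignment_fasta(path) -> dict[str, str]:
    """Aligned FASTA -> {label: sequence}; unequal lengths are an error."""
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise SchemaError(f"{path}: no FASTA records")
    if len({len(s) for s in records.values()}) != 1:
        raise SchemaError(f"{path}: sequences are not aligned")
    return records


def write_alignment_fasta(path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=label, description="")
            for label, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_distance_csv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{path}: row and column labels differ")
    return list(df.index), df.to_numpy(dtype=float)


def write_distance_csv(path, labels: list[str], matrix: np.ndarray) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path)


def write_params_json(path, fits: dict[str, dict]) -> None:
    """One record per strain; values are FitResult.to_dict() payloads."""
    Path(path).write_text(json.dumps(fits, indent=2, sort_keys=True) + "\n")


def read_params_json(path) -> dict[str, dict]:
    return json.loads(Path(path).read_text())


def params_records_to_csv(path, fits: dict[str, dict]) -> None:
    """Flat per-strain CSV of fitted parameters and rmse."""
    rows = []
    for sid, rec in sorted(fits.items()):
        row = {"strain": sid, **rec["params"], "rmse": rec["rmse"]}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
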