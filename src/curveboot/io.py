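"""Table readers/writers and run configuration.

Input is a long-format CSV/TSV with columns ``chemical_id``, ``assay_id``,
``logc`` (log10 µM) and ``resp`` (normalized response), one row per
measurement — rows sharing an exactly-equal ``logc`` within a series are
replicates. Outputs are CSV (floats at 17 significant digits, so
determinism is byte-testable) plus JSON, and every CLI run writes a
machine-readable manifest with the resolved configuration and seed.

Cutoffs may be absolute response values or strings like ``"3*bmad"``,
resolved per assay after bmad estimation.
"""

from __future__ import annotations

import json
import re
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .data import ConcRespSeries

__all__ = [
    "RunConfig",
    "read_series_table",
    "resolve_cutoff",
    "write_fits_table",
    "write_bootstrap_tables",
    "write_scores_table",
    "write_manifest",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.17g"

REQUIRED_COLUMNS = ("chemical_id", "assay_id", "logc", "resp")


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    input: str = ""
    cutoff: str = "3*bmad"          # absolute number or "k*bmad"
    B: int = 1000
    seed: int = 0
    quantiles: tuple = (0.025, 0.975)
    gain_only: bool = True
    reference_chemical: str = ""
    outdir: str = "."

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        q = tuple(self.quantiles)
        if not (0 < q[0] < q[1] < 1):
            raise ValueError("quantiles must be ordered and inside (0, 1)")
        self.quantiles = q

    @classmethod
    def from_toml(cls, path, **overrides):
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "quantiles" in raw:
            raw["quantiles"] = tuple(raw["quantiles"])
        return cls(**raw)


def resolve_cutoff(cutoff, bmad: float) -> float:
    """Resolve an absolute cutoff or a ``"k*bmad"`` multiplier string."""
    if isinstance(cutoff, (int, float)):
        return float(cutoff)
    text = str(cutoff).strip().lower().replace(" ", "")
    m = re.fullmatch(r"([0-9.]+)\*bmad", text)
    if m:
        return float(m.group(1)) * float(bmad)
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"cannot parse cutoff {cutoff!r}: use a number or 'k*bmad'"
        ) from None


def read_series_table(path) -> list:
    """Read a long-format table into one ConcRespSeries per (chemical, assay).

    Row order within a series is preserved; duplicate (chemical, assay,
    logc) rows are replicates. Malformed numeric cells are reported with
    their (1-based, header-inclusive) line numbers.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty and df.columns.size == 0:
        raise ValueError(f"{path}: empty file")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    out = {}
    for col in ("logc", "resp"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()] + 2  # header + 1-base
        allbad = df.index[values.isna()] + 2
        if len(allbad):
            which = list(bad if len(bad) else allbad)[:5]
            raise ValueError(
                f"{path}: non-numeric or missing {col!r} at line(s) {which}")
        df[col] = values
    for (chem, assay), grp in df.groupby(["chemical_id", "assay_id"],
                                         sort=True):
        out[(chem, assay)] = ConcRespSeries(
            str(chem), str(assay),
            grp["logc"].to_numpy(float), grp["resp"].to_numpy(float))
    return list(out.values())


def read_cutoff_column(path) -> dict:
    """Per-series cutoffs from an optional ``cutoff`` column.

    Returns ``{(chemical_id, assay_id): cutoff_spec}`` (absolute values or
    ``"k*bmad"`` strings, first row per series); empty when the column is
    absent.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "cutoff" not in df.columns:
        return {}
    first = df.groupby(["chemical_id", "assay_id"], sort=True).first()
    return {(str(c), str(a)): v
            for (c, a), v in first["cutoff"].items() if pd.notna(v)}


def _fit_row(result) -> dict:
    row = {
        "chemical_id": result.series.chemical_id,
        "assay_id": result.series.assay_id,
        "winner": result.winner,
        "hitc": result.hitc,
        "cutoff": result.cutoff,
        "max_median": result.max_median,
        "bmad": result.bmad,
        "fitted_nonconstant": result.fitted_nonconstant,
    }
    for model in ("cnst", "hill", "gnls"):
        fit = result.fits.get(model)
        fields = {
            "cnst": ("er", "loglik", "aic"),
            "hill": ("tp", "ga", "gw", "er", "loglik", "aic"),
            "gnls": ("tp", "ga", "gw", "la", "lw", "er", "loglik", "aic"),
        }[model]
        for f in fields:
            row[f"{model}_{f}"] = getattr(fit, f) if fit is not None else np.nan
        row[f"{model}_converged"] = (bool(fit.converged)
                                     if fit is not None else False)
    return row


def _write_csv_json(df: pd.DataFrame, stem: Path):
    df.to_csv(stem.with_suffix(".csv"), index=False,
              float_format=FLOAT_FORMAT)
    # pandas serializes NaN as null, keeping the JSON strictly valid;
    # the CSV is the full-precision (17 significant digits) record
    df.to_json(stem.with_suffix(".json"), orient="records", indent=1,
               double_precision=15)
    return stem.with_suffix(".csv")


def write_fits_table(results, stem) -> Path:
    """One row per series: winner, hit call, cutoff context and all
    per-model parameters/loglik/AIC. Writes ``<stem>.csv`` and ``.json``."""
    return _write_csv_json(pd.DataFrame([_fit_row(r) for r in results]),
                           Path(stem))


def write_bootstrap_tables(entries, stem) -> Path:
    """Per-sample long table + one-row-per-series summary.

    ``entries`` is a list of ``(series, BootstrapRun, BootstrapSummary)``.
    Writes ``<stem>_samples.csv`` and ``<stem>_summary.csv``/``.json``.
    """
    stem = Path(stem)
    sample_frames = []
    summary_rows = []
    for series, run, summ in entries:
        df = run.to_dataframe()
        df.insert(0, "assay_id", series.assay_id)
        df.insert(0, "chemical_id", series.chemical_id)
        sample_frames.append(df)
        row = {
            "chemical_id": series.chemical_id,
            "assay_id": series.assay_id,
            "B": summ.B,
            "seed": summ.seed,
            "quantile_rule": "linear (type 7)",
            "hit_probability": summ.hit_probability,
            "n_param_samples": summ.n_param_samples,
            "n_gnls_samples": summ.n_gnls_samples,
        }
        for m in ("cnst", "hill", "gnls"):
            row[f"freq_{m}"] = summ.model_freq[m]
        for p, q in summ.param_quantiles.items():
            row[f"{p}_q025"], row[f"{p}_q50"], row[f"{p}_q975"] = (
                q if q is not None else (np.nan,) * 3)
        summary_rows.append(row)
    pd.concat(sample_frames, ignore_index=True).to_csv(
        f"{stem}_samples.csv", index=False, float_format=FLOAT_FORMAT)
    return _write_csv_json(pd.DataFrame(summary_rows),
                           Path(f"{stem}_summary"))


def write_scores_table(dists, drivers, stem) -> Path:
    """Per-chemical score table plus per-assay driver table."""
    stem = Path(stem)
    rows = []
    for d in dists:
        rows.append({
            "chemical_id": d.chemical_id,
            "point_score": d.point_score,
            "q025": d.ci[0],
            "q975": d.ci[1],
            **{k: v for k, v in d.flags.items()},
        })
    out = _write_csv_json(pd.DataFrame(rows), stem)
    if drivers:
        driver_rows = []
        for chem, table in drivers.items():
            for rank, row in enumerate(table):
                driver_rows.append({"chemical_id": chem, "rank": rank, **row})
        pd.DataFrame(driver_rows).to_csv(
            f"{stem}_drivers.csv", index=False, float_format=FLOAT_FORMAT)
    return out


def write_manifest(path, command: str, config: dict):
    """Machine-readable provenance record for one run."""
    manifest = {
        "tool": "curveboot",
        "version": _pkg_version,
        "command": command,
        "config": config,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return Path(path)
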