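"""File formats, configuration and run manifests.

All interchange formats are delimited text: a genotype table (one row per
fish, one column per locus, alleles written "171/175", apparent homozygotes
"171/171", unscored loci empty), a sample-metadata table, a daily-fecundity
table, and comma-separated report tables.  Readers validate strictly and
name the offending row and column; writers round-trip exactly through the
readers.  Capture dates finer than a year are truncated to the year (the
model's resolution) with a logged note.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinship import MISSING, Comparisons, ExclusionTable, GenotypePanel

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_metadata",
    "write_metadata",
    "read_fecundity",
    "RunConfig",
    "write_report",
    "write_manifest",
    "ValidationError",
]

log = logging.getLogger("ckmrkit")

_ALLELE_RE = re.compile(r"^(\d+)/(\d+)$")
_SEX_CODES = {"F", "M", ""}


class ValidationError(ValueError):
    """Malformed input file; message names the line and column."""


def read_genotypes(path) -> GenotypePanel:
    """Read a genotype table; strict validation with line-numbered errors."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if not header or header[0] != "fish_id":
            raise ValidationError(f"{path.name} line 1: header must start "
                                  "with 'fish_id'")
        loci = header[1:]
        if not loci:
            raise ValidationError(f"{path.name} line 1: no locus columns")
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != len(header):
                raise ValidationError(
                    f"{path.name} line {lineno}: expected {len(header)} "
                    f"fields, got {len(parts)}")
            ids.append(parts[0])
            calls = np.full((len(loci), 2), MISSING, dtype=np.int32)
            for j, cell in enumerate(parts[1:]):
                if cell == "":
                    continue
                m = _ALLELE_RE.match(cell)
                if not m:
                    raise ValidationError(
                        f"{path.name} line {lineno}, column {loci[j]}: "
                        f"malformed allele field {cell!r}")
                calls[j] = (int(m.group(1)), int(m.group(2)))
            rows.append(calls)
    return GenotypePanel(fish_ids=np.asarray(ids), loci=loci,
                         alleles=np.stack(rows) if rows
                         else np.empty((0, len(loci), 2), dtype=np.int32))


def write_genotypes(panel: GenotypePanel, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(["fish_id"] + list(panel.loci)) + "\n")
        for i, fid in enumerate(panel.fish_ids):
            cells = []
            for j in range(len(panel.loci)):
                a, b = panel.alleles[i, j]
                cells.append("" if a < 0 else f"{a}/{b}")
            fh.write(",".join([str(fid)] + cells) + "\n")


_META_COLS = ["fish_id", "stage", "capture_year", "length", "sex", "age",
              "birth_year"]


def _parse_year(cell: str, where: str) -> int:
    """Years may arrive as dates; anything finer than a year is truncated."""
    if re.fullmatch(r"\d{4}", cell):
        return int(cell)
    m = re.fullmatch(r"(\d{4})-\d{2}(-\d{2})?", cell)
    if m:
        log.info("%s: date %r truncated to year %s", where, cell, m.group(1))
        return int(m.group(1))
    raise ValidationError(f"{where}: cannot parse year {cell!r}")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata; validates stages, sex codes and juvenile birth years."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header != _META_COLS:
            raise ValidationError(f"{path.name} line 1: header must be "
                                  f"{','.join(_META_COLS)}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != len(header):
                raise ValidationError(f"{path.name} line {lineno}: expected "
                                      f"{len(header)} fields, got {len(parts)}")
            fid, stage, cy, length, sex, age, by = parts
            where = f"{path.name} line {lineno}"
            if stage not in ("adult", "juvenile"):
                raise ValidationError(f"{where}: unknown stage {stage!r}")
            if sex not in _SEX_CODES:
                raise ValidationError(f"{where}: unknown sex code {sex!r}")
            if stage == "juvenile" and by == "":
                raise ValidationError(f"{where}: juvenile missing birth year")
            rows.append({
                "fish_id": fid, "stage": stage,
                "capture_year": _parse_year(cy, where),
                "length": float(length) if length else None,
                "sex": sex or None,
                "age": int(age) if age else None,
                "birth_year": _parse_year(by, where) if by else None,
            })
    df = pd.DataFrame(rows, columns=_META_COLS)
    df["age"] = df["age"].astype("Int64")
    df["birth_year"] = df["birth_year"].astype("Int64")
    return df


def write_metadata(samples: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(_META_COLS) + "\n")
        for row in samples.itertuples(index=False):
            d = row._asdict()
            cells = [str(d["fish_id"]), d["stage"], str(int(d["capture_year"]))]
            cells.append("" if d["length"] is None or pd.isna(d["length"])
                         else f"{float(d['length']):.2f}")
            cells.append("" if d["sex"] is None or pd.isna(d["sex"]) else str(d["sex"]))
            cells.append("" if d["age"] is None or pd.isna(d["age"])
                         else str(int(d["age"])))
            cells.append("" if d["birth_year"] is None or pd.isna(d["birth_year"])
                         else str(int(d["birth_year"])))
            fh.write(",".join(cells) + "\n")


def read_fecundity(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ["length", "daily_output"]:
        raise ValidationError(f"{Path(path).name}: columns must be "
                              "length,daily_output")
    if (df.daily_output <= 0).any():
        bad = int(df.index[df.daily_output <= 0][0]) + 2
        raise ValidationError(f"{Path(path).name} line {bad}: nonpositive "
                              "daily output")
    return df


@dataclass
class RunConfig:
    """Validated run settings for the command-line interface."""

    genotypes: str | None = None
    metadata: str | None = None
    fecundity: str | None = None
    out_dir: str = "ckmr_out"
    fp_budget_fraction: float = 0.01
    length_bin_width: float = 1.0
    ess_factor: float = 0.1
    share_selectivity: bool = True
    estimate_sigma_r: bool = True
    seed: int = 0
    simulate: dict = field(default_factory=dict)

    _KNOWN = ("genotypes", "metadata", "fecundity", "out_dir",
              "fp_budget_fraction", "length_bin_width", "ess_factor",
              "share_selectivity", "estimate_sigma_r", "seed", "simulate")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls._KNOWN)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if not (0 < cfg.fp_budget_fraction < 1):
            raise ValidationError("fp_budget_fraction must be in (0, 1)")
        if cfg.length_bin_width < 0:
            raise ValidationError("length_bin_width must be nonnegative")
        for key in ("genotypes", "metadata", "fecundity"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"config path {key}={p!r} does not exist")
        return cfg

    def digest(self) -> str:
        blob = yaml.safe_dump({k: getattr(self, k) for k in self._KNOWN},
                              sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(out_dir, config: RunConfig, seed: int, extra=None) -> Path:
    """Record everything needed to reproduce the run byte-for-byte."""
    import ckmrkit
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_sha256": config.digest(),
        "seed": int(seed),
        "versions": {
            "ckmrkit": ckmrkit.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_report(results, out_dir) -> list:
    """Write comparison / exclusion-table / fit outputs as delimited text.

    ``results`` may contain a :class:`Comparisons`, :class:`ExclusionTable`
    objects, or a fit result; each becomes one or more CSV files plus a
    human-readable summary.
    """
    from .inference import FitResult

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for item in results:
        if isinstance(item, Comparisons):
            p = out / "comparisons.csv"
            item.df.to_csv(p, index=False)
            written.append(p)
            s = out / "comparisons_summary.txt"
            s.write_text(
                f"candidate comparisons: {item.n_candidates}\n"
                f"retained: {int(item.df.retained.sum())}\n"
                f"POPs called: {item.n_pops}\n"
                f"near-misses flagged for re-examination: "
                f"{int(item.df.near_miss.sum())}\n"
                f"expected false positives among retained: "
                f"{item.expected_false_positives:.4g}\n")
            written.append(s)
        elif isinstance(item, ExclusionTable):
            p = out / f"exclusion_table_{item.label.replace('-', '_')}.csv"
            item.to_frame().to_csv(p, index=False)
            written.append(p)
        elif isinstance(item, FitResult):
            p1 = out / "fit_parameters.csv"
            item.params.to_csv(p1, index=False)
            p2 = out / "fit_derived.csv"
            item.derived.to_csv(p2, index=False)
            written.extend([p1, p2])
        else:
            raise TypeError(f"cannot write report for {type(item)}")
    return written
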