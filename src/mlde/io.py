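"""File formats: delimited tables, FASTA, structured YAML documents.

Fixed dialect throughout: comma delimiter, "." decimal point, mandatory
header rows.  Variant names are the single source of identity across
files; full sequences are derived from them on demand.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assay import ActivityRecord, KineticTrace, PlateNormalization
from .gp import CVReport
from .synthetic import TRACE_TIMES, SyntheticLandscape
from .variants import ProteinVariant

ACTIVITY_COLUMNS = ("plate", "well", "variant_name", "slope")


def read_parent_fasta(path) -> tuple[str, str]:
    """Read the parent protein: returns (name, sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def write_library_fasta(
    variants: Iterable[ProteinVariant], parent_sequence: str, path
) -> None:
    """Full mutated protein sequences derived from the parent."""
    records = [
        SeqRecord(Seq(v.apply(parent_sequence)), id=v.name, description="")
        for v in variants
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class TableErrors:
    """Malformed rows collected during table parsing."""

    rows: list[tuple[int, str]] = field(default_factory=list)

    def add(self, line_no: int, message: str) -> None:
        self.rows.append((line_no, message))

    def __len__(self) -> int:
        return len(self.rows)


def read_activity_table(path) -> tuple[list[ActivityRecord], TableErrors]:
    """Read a well-per-row activity table, collecting malformed rows.

    Mandatory columns: plate, well, variant_name, slope.  Optional:
    fiop, fiowt, flagged.  Rows with non-numeric slopes are excluded and
    reported with their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ACTIVITY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"activity table missing mandatory column {col!r}")
    records: list[ActivityRecord] = []
    errors = TableErrors()
    for i, row in df.iterrows():
        line_no = int(i) + 2  # header is line 1
        try:
            slope = float(row["slope"])
        except ValueError:
            errors.add(line_no, f"non-numeric slope {row['slope']!r}")
            continue
        def _opt(col):
            val = row.get(col, "")
            return float(val) if col in df.columns and val != "" else None
        try:
            records.append(
                ActivityRecord(
                    variant_name=row["variant_name"],
                    plate=row["plate"],
                    well=row["well"],
                    slope=slope,
                    fiop=_opt("fiop"),
                    fiowt=_opt("fiowt"),
                    flagged=row.get("flagged", "") in ("True", "true", "1"),
                )
            )
        except ValueError as exc:
            errors.add(line_no, str(exc))
    return records, errors


def write_activity_table(records: Sequence[ActivityRecord], path) -> None:
    df = pd.DataFrame(
        {
            "plate": [r.plate for r in records],
            "well": [r.well for r in records],
            "variant_name": [r.variant_name for r in records],
            "slope": [r.slope for r in records],
            "fiop": [r.fiop if r.fiop is not None else "" for r in records],
            "fiowt": [r.fiowt if r.fiowt is not None else "" for r in records],
            "flagged": [r.flagged for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_trace_table(traces: Sequence[KineticTrace], path) -> None:
    """One well per row: plate, well, variant_name, then the trace values."""
    cols = [f"t{int(t)}" for t in TRACE_TIMES]
    rows = []
    for tr in traces:
        if tr.times.size != TRACE_TIMES.size or not np.allclose(tr.times, TRACE_TIMES):
            raise ValueError("trace table requires the standard 0-80 min grid")
        rows.append([tr.plate, tr.well, tr.variant_name, *tr.absorbance.tolist()])
    pd.DataFrame(rows, columns=["plate", "well", "variant_name", *cols]).to_csv(
        path, index=False
    )


def read_trace_table(path) -> list[KineticTrace]:
    df = pd.read_csv(path)
    time_cols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    if len(time_cols) < 4:
        raise ValueError("trace table needs >= 4 time-point columns (t0, t5, ...)")
    times = np.array([float(c[1:]) for c in time_cols])
    order = np.argsort(times)
    times = times[order]
    time_cols = [time_cols[i] for i in order]
    return [
        KineticTrace(
            times=times.copy(),
            absorbance=row[time_cols].to_numpy(dtype=float),
            well=str(row["well"]),
            plate=str(row["plate"]),
            variant_name=str(row["variant_name"]),
        )
        for _, row in df.iterrows()
    ]


def write_normalization_report(report: Sequence[PlateNormalization], path) -> None:
    pd.DataFrame(
        {
            "plate": [r.plate for r in report],
            "parent_mean_slope": [r.parent_mean_slope for r in report],
            "n_parent_wells": [r.n_parent_wells for r in report],
            "n_flagged": [r.n_flagged for r in report],
        }
    ).to_csv(path, index=False)


def save_landscape(landscape: SyntheticLandscape, path) -> None:
    doc = {
        "sites": list(landscape.sites),
        "alphabets": {int(s): landscape.alphabets[s] for s in landscape.sites},
        "parent_residues": {int(s): landscape.parent_residues[s] for s in landscape.sites},
        "intercept": landscape.intercept,
        "site_effects": {
            f"{site}:{res}": float(val)
            for (site, res), val in sorted(landscape.site_effects.items())
        },
        "epistasis_terms": {
            f"{a[0]}:{a[1]}|{b[0]}:{b[1]}": float(val)
            for (a, b), val in sorted(landscape.epistasis_terms.items())
        },
        "noise_sd": landscape.noise_sd,
        "seed": landscape.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_landscape(path) -> SyntheticLandscape:
    doc = yaml.safe_load(Path(path).read_text())

    def _key(text: str) -> tuple[int, str]:
        site, res = text.split(":")
        return int(site), res

    return SyntheticLandscape(
        sites=tuple(int(s) for s in doc["sites"]),
        alphabets={int(s): a for s, a in doc["alphabets"].items()},
        parent_residues={int(s): r for s, r in doc["parent_residues"].items()},
        intercept=float(doc["intercept"]),
        site_effects={_key(k): float(v) for k, v in doc["site_effects"].items()},
        epistasis_terms={
            tuple(_key(part) for part in k.split("|")): float(v)
            for k, v in doc["epistasis_terms"].items()
        },
        noise_sd=float(doc["noise_sd"]),
        seed=int(doc["seed"]),
    )


def write_cv_report(report: CVReport, path) -> None:
    doc = {
        "seed": report.seed,
        "n_folds": report.n_folds,
        "mean_r_squared": None if np.isnan(report.mean_r2) else float(report.mean_r2),
        "fold_r_squared": [
            None if np.isnan(r) else float(r) for r in report.fold_r2
        ],
        "fold_assignments": [list(f) for f in report.assignments],
        "flags": list(report.flags),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration loaded from YAML."""

    parent_fasta: str
    parent_name: str
    sites: tuple[int, ...]
    property_table: str | None = None
    cv_folds: int = 10
    gp_restarts: int = 5
    seed: int = 0
    n_top: int = 24
    n_explore: int = 6
    molar_absorptivity: float = 6220.0
    path_length: float = 0.56

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sites):
            raise ValueError("sites must be positive 1-based integers")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    cfg = RunConfig(
        parent_fasta=doc["parent_fasta"],
        parent_name=doc.get("parent_name", "WT"),
        sites=tuple(int(s) for s in doc["sites"]),
        property_table=doc.get("property_table"),
        cv_folds=int(doc.get("cv_folds", 10)),
        gp_restarts=int(doc.get("gp_restarts", 5)),
        seed=int(doc.get("seed", 0)),
        n_top=int(doc.get("n_top", 24)),
        n_explore=int(doc.get("n_explore", 6)),
        molar_absorptivity=float(doc.get("molar_absorptivity", 6220.0)),
        path_length=float(doc.get("path_length", 0.56)),
    )
    base = Path(path).parent
    for ref in (cfg.parent_fasta, cfg.property_table):
        if ref is not None and not (base / ref).exists() and not Path(ref).exists():
            raise ValueError(f"referenced path does not exist: {ref}")
    return cfg


def config_hash(params: dict) -> str:
    """Short stable hash of a parameter mapping, for run logs."""
    canon = repr(sorted(params.items())).encode()
    return hashlib.sha256(canon).hexdigest()[:12]
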