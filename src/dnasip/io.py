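"""File formats and run manifests.

All interchange formats are plain text: fraction CSV, OTU TSV, isotope
CSV, FASTA, newick and JSON.  Densities are written with at least four
decimals so a 12-fraction 1.687–1.770 g mL⁻¹ gradient stays resolvable.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .community import VALID_ROLES, OtuTable
from .gradient import FractionSet
from .isotope import Treatment

FRACTION_CSV_COLUMNS = [
    "tube_id",
    "treatment",
    "timepoint_days",
    "fraction",
    "density_g_ml",
    "dna_conc",
    "failed",
]

OTU_META_COLUMNS = ["sample", "role", "treatment", "timepoint_days"]

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def read_fraction_table(path: str | Path) -> list[FractionSet]:
    """Read a fraction CSV into one FractionSet per tube.

    Columns: tube_id, treatment, timepoint_days, fraction, density_g_ml,
    dna_conc, failed.  Densities in any other order than heavy-first are
    re-sorted with a warning; duplicate (tube, fraction) pairs are
    parse errors reported with their line number.
    """
    df = pd.read_csv(path, dtype=str)
    missing = set(FRACTION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    seen: dict[tuple[str, int], int] = {}
    rows = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            frac = int(row["fraction"])
            density = float(row["density_g_ml"])
            conc = float(row["dna_conc"])
        except (TypeError, ValueError) as e:
            raise ValueError(f"{path}:{line}: non-numeric field ({e})") from None
        key = (row["tube_id"], frac)
        if key in seen:
            raise ValueError(
                f"{path}:{line}: duplicate fraction {frac} for tube {row['tube_id']!r} "
                f"(first at line {seen[key]})"
            )
        seen[key] = line
        failed = str(row["failed"]).strip().lower()
        if failed not in _BOOL:
            raise ValueError(f"{path}:{line}: failed must be boolean, got {row['failed']!r}")
        rows.append(
            {
                "tube_id": row["tube_id"],
                "treatment": row["treatment"],
                "timepoint_days": float(row["timepoint_days"]),
                "fraction": frac,
                "density_g_ml": density,
                "dna_conc": conc,
                "failed": _BOOL[failed],
            }
        )
    out = []
    frame = pd.DataFrame(rows)
    for tube, grp in frame.groupby("tube_id", sort=False):
        out.append(
            FractionSet.from_frame(
                grp,
                treatment=Treatment(grp["treatment"].iloc[0]),
                timepoint=float(grp["timepoint_days"].iloc[0]),
                tube_id=str(tube),
            )
        )
    return out


def write_fraction_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a fraction table (columns as FRACTION_CSV_COLUMNS)."""
    out = frame[FRACTION_CSV_COLUMNS].copy()
    out["density_g_ml"] = out["density_g_ml"].map(lambda v: f"{v:.5f}")
    out.to_csv(path, index=False)


def read_otu_table(path: str | Path) -> OtuTable:
    """Read an OTU TSV: metadata columns sample, role, treatment,
    timepoint_days, then one integer count column per OTU."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(OTU_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    otu_cols = [c for c in df.columns if c not in OTU_META_COLUMNS]
    bad_roles = set(df["role"]) - VALID_ROLES
    if bad_roles:
        hints = {"heavy": "H", "light": "L", "insitu": "in-situ", "is": "in-situ"}
        hint = "; ".join(
            f"did you mean {hints[r]!r}?" for r in bad_roles if r in hints
        )
        raise ValueError(f"{path}: unknown roles {sorted(bad_roles)} {hint}".strip())
    counts = df[otu_cols].copy()
    for col in otu_cols:
        as_float = pd.to_numeric(counts[col], errors="raise")
        if (as_float < 0).any() or not np.allclose(as_float, np.round(as_float)):
            raise ValueError(f"{path}: column {col!r} has negative or fractional counts")
        counts[col] = as_float.astype(np.int64)
    counts.index = pd.Index(df["sample"], name="sample")
    meta = df[["role", "treatment", "timepoint_days"]].copy()
    meta["timepoint_days"] = pd.to_numeric(meta["timepoint_days"])
    meta.index = counts.index
    return OtuTable(counts=counts, sample_meta=meta)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    meta = table.sample_meta[["role", "treatment", "timepoint_days"]]
    out = pd.concat([meta, table.counts], axis=1)
    out.insert(0, "sample", out.index)
    out.to_csv(path, sep="\t", index=False)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, inputs: list[str | Path] = ()) -> None:
    """Record everything needed to reproduce a run bit-identically."""
    manifest = {
        "config": config,
        "inputs": {str(p): file_digest(p) for p in inputs if Path(p).exists()},
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))


def derive_seeds(master_seed: int, stages: list[str]) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(stages))
    return {
        stage: int(child.generate_state(1)[0] % 2**31)
        for stage, child in zip(stages, children)
    }
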