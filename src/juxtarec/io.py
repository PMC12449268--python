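"""Tabular I/O for count tables, per-plant Rf tables and segment files.

All tables are plain TSV.  Output tables carry comment headers recording
the tool version, a config hash and the seed, so that a run can be tied
back to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .boundary import IndividualGenotype
from .rf_estimators import (
    BackcrossCounts,
    F2PhenotypeCounts,
    SeedCounts,
    rf_from_backcross,
    rf_from_f2_ml,
    rf_from_seed_counts,
)

COUNT_COLUMNS = ["sample_id", "cross_id", "design", "a", "b", "c", "d", "g", "r", "n", "sex"]


def config_hash(config: dict[str, Any]) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, *, seed: int | None = None,
                cfg_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# juxtarec {__version__}")
        if cfg_hash is not None:
            fh.write(f"\tconfig={cfg_hash}")
        if seed is not None:
            fh.write(f"\tseed={seed}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_counts_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = {"sample_id", "design"} - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def estimate_counts_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the appropriate estimator to each row of a counts table."""
    rows = []
    for _, row in df.iterrows():
        design = row["design"]
        if design == "seed":
            est = rf_from_seed_counts(
                SeedCounts(g=int(row["g"]), r=int(row["r"]), n=int(row["n"]))
            )
        elif design == "bc":
            est = rf_from_backcross(
                BackcrossCounts(a=int(row["a"]), b=int(row["b"]),
                                c=int(row["c"]), d=int(row["d"]))
            )
        elif design == "f2":
            est = rf_from_f2_ml(
                F2PhenotypeCounts(a=int(row["a"]), b=int(row["b"]),
                                  c=int(row["c"]), d=int(row["d"]))
            )
        else:
            raise ValueError(f"unknown design {design!r} for sample {row['sample_id']!r}")
        rows.append({
            "sample_id": row["sample_id"],
            "method": est.method,
            "rf": est.rf,
            "se": est.se,
            "theta": est.theta,
            "n_total": est.n,
            "flags": ";".join(est.flags),
        })
    return pd.DataFrame(rows)


def read_individuals(segments_path: str | Path, rf_path: str | Path,
                     interval: tuple[int, int]) -> list[IndividualGenotype]:
    """Assemble per-individual genotypes from a segments table
    (sample_id, start, end, state) and an Rf table (sample_id, rf)."""
    seg_df = read_table(segments_path)
    rf_df = read_table(rf_path).set_index("sample_id")
    individuals = []
    for sample_id, sub in seg_df.groupby("sample_id", sort=False):
        if sample_id not in rf_df.index:
            continue
        segs = tuple(
            (int(r.start), int(r.end), str(r.state))
            for r in sub.sort_values("start").itertuples()
        )
        individuals.append(IndividualGenotype(
            sample_id=str(sample_id), segments=segs, interval=interval,
            rf=float(rf_df.loc[sample_id, "rf"]),
        ))
    return individuals
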