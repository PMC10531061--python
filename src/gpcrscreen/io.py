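"""Plain-TSV input/output with companion schema files.

Every table is TSV with a one-line header, genes as row keys and samples
as column keys where applicable, and missing values as empty cells —
diffable and auditable with any text tool.  ``write_table`` drops a
``<name>.schema.json`` next to each table documenting its columns.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .ddpcr import DropletWell
from .errors import ValidationError

__all__ = [
    "write_table",
    "read_matrix",
    "read_lengths",
    "read_samples",
    "read_droplets",
    "wells_to_frame",
    "read_echo",
    "sha256_of",
]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    index_label: str | None = "gene",
    schema: dict[str, str] | None = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)
    if schema is not None:
        meta = {"columns": schema}
        if index_label is not None:
            meta["index"] = index_label
        with open(path.with_suffix(path.suffix + ".schema.json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return path


def _require(path: str | Path, what: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{what} file not found: {path}")
    return path


def read_matrix(path: str | Path, index_col: str = "gene") -> pd.DataFrame:
    """Genes x samples matrix (counts, TPM or copies/uL)."""
    path = _require(path, "matrix")
    df = pd.read_csv(path, sep="\t")
    if index_col not in df.columns:
        raise ValidationError(f"{path}: missing index column {index_col!r}")
    return df.set_index(index_col)


def read_lengths(path: str | Path) -> pd.Series:
    path = _require(path, "gene lengths")
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "length"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return df.set_index("gene")["length"]


def read_samples(path: str | Path) -> pd.Series:
    """Sample sheet: columns ``sample`` and ``group``."""
    path = _require(path, "sample sheet")
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return df.set_index("sample")["group"]


def wells_to_frame(wells: list[DropletWell], truth_saturated: pd.DataFrame | None = None) -> pd.DataFrame:
    rows = []
    for w in wells:
        flag = ""
        if truth_saturated is not None and bool(truth_saturated.loc[w.gene, w.sample]):
            flag = "simulated_saturation"
        rows.append(
            {"gene": w.gene, "sample": w.sample, "n_droplets": w.n_droplets,
             "n_positive": w.n_positive, "droplet_volume_ul": w.droplet_volume_ul,
             "flags": flag}
        )
    return pd.DataFrame(rows)


def read_droplets(path: str | Path) -> list[DropletWell]:
    """Droplet table: gene, sample, n_droplets, n_positive[, droplet_volume_ul]."""
    path = _require(path, "droplets")
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "sample", "n_droplets", "n_positive"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    has_vol = "droplet_volume_ul" in df.columns
    return [
        DropletWell(
            gene=str(r.gene), sample=str(r.sample),
            n_droplets=int(r.n_droplets), n_positive=int(r.n_positive),
            **({"droplet_volume_ul": float(r.droplet_volume_ul)} if has_vol else {}),
        )
        for r in df.itertuples()
    ]


def read_echo(path: str | Path) -> pd.DataFrame:
    path = _require(path, "echo measurements")
    return pd.read_csv(path, sep="\t")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
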