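"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinate conventions
----------------------
Per-cytosine tables ("allc-style" TSV) use **1-based** positions, following
the convention of single-cytosine methylation callers.  All interval files
(BED, BED12) are **0-based half-open**.  A cytosine at 1-based position
``pos`` therefore occupies the interval ``[pos - 1, pos)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

#: Canonical column order for per-cytosine count tables.
ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc_count", "total_count", "assay"]

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

_ALLC_DTYPES = {
    "chrom": str,
    "pos": "int64",
    "strand": str,
    "context": str,
    "mc_count": "int64",
    "total_count": "int64",
}


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


def read_allc(path) -> pd.DataFrame:
    """Read an allc-style TSV (with header) of per-cytosine counts."""
    df = pd.read_csv(path, sep="\t", dtype=_ALLC_DTYPES)
    missing = [c for c in ALLC_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing allc columns {missing}")
    return df


def write_allc(df: pd.DataFrame, path) -> None:
    cols = [c for c in ALLC_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_bed(path, extra_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a headerless BED file; ``extra_cols`` names columns beyond the sixth."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = BED6_COLUMNS[: min(df.shape[1], 6)] + list(extra_cols)
    if df.shape[1] < len(names):
        raise FormatError(f"{path}: expected at least {len(names)} columns")
    df = df.iloc[:, : len(names)]
    df.columns = names
    return df


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in df.columns]
    df.to_csv(path, sep="\t", index=False, header=False, columns=cols)


def genes_to_bed12(genes: pd.DataFrame) -> pd.DataFrame:
    """Render a gene table as single-exon BED12 records."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["name"],
            "score": 0,
            "strand": genes["strand"],
            "thickStart": genes["start"],
            "thickEnd": genes["end"],
            "itemRgb": "0,0,0",
            "blockCount": 1,
            "blockSizes": (genes["end"] - genes["start"]).astype(str) + ",",
            "blockStarts": "0,",
        }
    )
    return out


def write_genes_bed12(genes: pd.DataFrame, path) -> None:
    genes_to_bed12(genes).to_csv(path, sep="\t", index=False, header=False)


def read_genes(path) -> pd.DataFrame:
    """Read genes from BED6/BED12 and derive the strand-aware TSS coordinate.

    The TSS is reported as the 0-based coordinate of the first transcribed
    base: ``start`` for plus-strand genes and ``end - 1`` for minus-strand.
    """
    df = read_bed(path)
    if "strand" not in df.columns:
        raise FormatError(f"{path}: gene BED needs at least 6 columns (strand)")
    df = df[BED6_COLUMNS].copy()
    df["tss"] = tss_coordinates(df)
    return df


def tss_coordinates(genes: pd.DataFrame) -> pd.Series:
    minus = genes["strand"] == "-"
    return genes["start"].where(~minus, genes["end"] - 1)


def read_counts(path) -> pd.DataFrame:
    """Gene-by-sample integer count matrix, first column gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "region", "condition"):
        if col not in df.columns:
            raise FormatError(f"{path}: sample sheet missing column '{col}'")
    return df.set_index("sample", drop=False)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def load_config(path):
    """Load a :class:`~methylaxis.simulate.SimConfig` from YAML."""
    from .simulate import SimConfig

    data = yaml.safe_load(Path(path).read_text()) or {}
    return SimConfig(**data)


def dump_config(config, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
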