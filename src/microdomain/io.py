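"""Text-format readers and writers.

Supported formats: pairs-style contact TSV, chrom.sizes, BED3/BED6,
narrowPeak, GFF3 gene models, bedGraph, and a two-file sparse matrix
container (pixels + bins TSVs) used to chain CLI steps.

Coordinate conventions: BED/bedGraph/narrowPeak are read as-is (already
0-based half-open); GFF3 is 1-based closed and converted on ingest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .regions import RegionSet
from .tracks import SignalTrack

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "iter_pairs",
    "write_pairs",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bedgraph",
    "write_bedgraph",
    "write_matrix",
    "read_matrix",
    "write_json",
]

PAIRS_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2"]


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chrom_sizes(genome: BinnedGenome, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{chrom}\t{length}\n")


def iter_pairs(path, chunksize: int = 2_000_000):
    """Yield (chrom1, pos1, chrom2, pos2) frames from a pairs-style TSV.

    Accepts 4 or 6 columns; optional strand columns are ignored. Lines
    starting with '#' are comments.
    """
    for chunk in pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        chunksize=chunksize,
        dtype={0: str, 2: str},
    ):
        chunk = chunk.iloc[:, :4]
        chunk.columns = PAIRS_COLUMNS
        chunk["pos1"] = chunk["pos1"].astype(np.int64)
        chunk["pos2"] = chunk["pos2"].astype(np.int64)
        yield chunk


def write_pairs(df: pd.DataFrame, path) -> None:
    df[PAIRS_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# -- region formats ------------------------------------------------------

_BED6 = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> RegionSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = _BED6[: df.shape[1]] + list(df.columns[6:])
    return RegionSet(df)


def write_bed(regions: RegionSet, path, extra_cols: list[str] | None = None) -> None:
    df = regions.df
    cols = [c for c in _BED6 if c in df.columns]
    if extra_cols:
        cols += [c for c in extra_cols if c in df.columns]
    # BED requires name/score before strand; fill defaults when strand present
    if "strand" in cols and "name" not in cols:
        df = df.assign(name=".")
        cols.insert(3, "name")
    if "strand" in cols and "score" not in cols:
        df = df.assign(score=0)
        cols.insert(4, "score")
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path) -> RegionSet:
    """Read ENCODE narrowPeak; exposes a ``summit`` column in absolute bp."""
    names = _BED6 + ["signalValue", "pValue", "qValue", "peak"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=names, dtype={0: str})
    summit_off = df["peak"].astype(int)
    df["summit"] = np.where(summit_off >= 0, df["start"] + summit_off, (df["start"] + df["end"]) // 2)
    return RegionSet(df)


def read_gff3_genes(path, feature: str = "gene") -> RegionSet:
    """Extract gene-level records from GFF3, converting to 0-based half-open.

    The ``ID`` attribute becomes the ``name`` column; all other attributes
    are kept in ``attributes`` untouched.
    """
    names = ["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=names, dtype={0: str})
    df = df[df["type"] == feature].copy()
    df["start"] = df["start"].astype(np.int64) - 1  # 1-based closed -> 0-based half-open
    df["end"] = df["end"].astype(np.int64)
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    fallback = pd.Series([f"{feature}_{i}" for i in range(len(df))], index=df.index)
    df["name"] = ids.fillna(fallback)
    return RegionSet(df[["chrom", "start", "end", "name", "strand", "attributes"]])


def write_gff3_genes(regions: RegionSet, path, source: str = "microdomain") -> None:
    df = regions.df
    strand = df["strand"] if "strand" in df.columns else "."
    name = df["name"] if "name" in df.columns else [f"gene_{i}" for i in range(len(df))]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "source": source,
            "type": "gene",
            "start": df["start"] + 1,  # back to 1-based closed
            "end": df["end"],
            "score": ".",
            "strand": strand,
            "phase": ".",
            "attributes": "ID=" + pd.Series(name, index=df.index).astype(str),
        }
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# -- 1D signal -----------------------------------------------------------


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={0: str},
    )
    return df


def write_bedgraph(track_or_df, path, precision: int = 6) -> None:
    df = track_or_df.to_frame() if isinstance(track_or_df, SignalTrack) else track_or_df
    df.to_csv(path, sep="\t", header=False, index=False, float_format=f"%.{precision}g")


# -- matrix container ----------------------------------------------------


def write_matrix(matrix, prefix) -> None:
    """Write a ContactMatrix as <prefix>.pixels.tsv + <prefix>.bins.tsv.

    Pixels are the upper-triangle sparse triplets (chrom, bin_i, bin_j,
    value); bins carry balancing weights and the validity mask.
    """
    prefix = str(prefix)
    pix = []
    binrows = []
    for chrom in matrix.genome.chrom_names:
        coo = matrix.pixels[chrom]
        pix.append(
            pd.DataFrame({"chrom": chrom, "bin_i": coo.row, "bin_j": coo.col, "value": coo.data})
        )
        n = matrix.genome.n_bins(chrom)
        w = matrix.weights[chrom] if matrix.weights is not None else np.full(n, np.nan)
        binrows.append(
            pd.DataFrame(
                {"chrom": chrom, "bin": np.arange(n), "weight": w, "masked": (~matrix.mask[chrom]).astype(int)}
            )
        )
    pd.concat(pix, ignore_index=True).to_csv(
        prefix + ".pixels.tsv", sep="\t", index=False, float_format="%.10g"
    )
    pd.concat(binrows, ignore_index=True).to_csv(
        prefix + ".bins.tsv", sep="\t", index=False, float_format="%.10g"
    )


def read_matrix(prefix, genome: BinnedGenome):
    from .contact import ContactMatrix

    prefix = str(prefix)
    pix = pd.read_csv(prefix + ".pixels.tsv", sep="\t", dtype={"chrom": str})
    bins = pd.read_csv(prefix + ".bins.tsv", sep="\t", dtype={"chrom": str})
    pixels = {}
    mask = {}
    weights = {}
    any_weight = bins["weight"].notna().any()
    from scipy.sparse import coo_matrix

    for chrom in genome.chrom_names:
        n = genome.n_bins(chrom)
        sub = pix[pix["chrom"] == chrom]
        pixels[chrom] = coo_matrix(
            (sub["value"].to_numpy(float), (sub["bin_i"].to_numpy(int), sub["bin_j"].to_numpy(int))),
            shape=(n, n),
        )
        bsub = bins[bins["chrom"] == chrom].sort_values("bin")
        mask[chrom] = bsub["masked"].to_numpy(int) == 0
        weights[chrom] = bsub["weight"].to_numpy(float)
    return ContactMatrix(genome, pixels, weights=weights if any_weight else None, mask=mask)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
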