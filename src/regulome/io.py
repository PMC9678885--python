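"""Readers and writers for the formats shared by all stages.

Peak sets travel as BED3/BED6 or ENCODE narrowPeak (10 tab-separated
columns, summit offset in column 10 with -1 meaning "no summit"); gene
models, DE tables, meta-score tables and results as TSV; gene sets as GMT;
CyTOF events as wide CSV with ``meta_``-prefixed metadata columns.  Every
writer emits files the matching reader reproduces bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .intervals import GenomicInterval, GeneModel, PeakSet, ValidationError


# ------------------------------------------------------------------- peaks

def read_peaks(path, fmt: str | None = None, set_id: str | None = None) -> PeakSet:
    """Read a BED3/BED6 or narrowPeak file into a PeakSet.

    ``fmt`` in {"bed", "narrowPeak"}; inferred from the extension when None.
    """
    path = Path(path)
    if fmt is None:
        fmt = "narrowPeak" if path.suffix == ".narrowPeak" else "bed"
    if fmt not in ("bed", "narrowPeak"):
        raise ValidationError(f"read_peaks: unknown format {fmt!r}")
    want = 10 if fmt == "narrowPeak" else (3, 6)
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if fmt == "narrowPeak" and len(f) != want:
                raise ValidationError(f"{path}:{lineno}: expected 10 columns, got {len(f)}")
            if fmt == "bed" and len(f) not in want:
                raise ValidationError(f"{path}:{lineno}: expected 3 or 6 columns, got {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise ValidationError(f"{path}:{lineno}: non-numeric coordinate") from e
            name = f[3] if len(f) > 3 and f[3] != "." else f"peak_{lineno}"
            signal = 0.0
            summit = None
            if fmt == "narrowPeak":
                signal = float(f[6])
                s = int(f[9])
                summit = None if s == -1 else s
            elif len(f) == 6:
                signal = float(f[4])
            ivs.append(GenomicInterval(f[0], start, end, name, signal, summit))
    return PeakSet(set_id or path.stem, ivs)


def write_peaks(peaks: PeakSet, path, fmt: str = "narrowPeak") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for iv in peaks.sorted():
            if fmt == "narrowPeak":
                summit = -1 if iv.summit_offset is None else iv.summit_offset
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.peak_id}\t0\t.\t"
                    f"{iv.signal:g}\t-1\t-1\t{summit}\n"
                )
            elif fmt == "bed":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.peak_id}\t{iv.signal:g}\t.\n")
            else:
                raise ValidationError(f"write_peaks: unknown format {fmt!r}")


# -------------------------------------------------------------- gene models

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end"]


def read_genes(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"read_genes: missing columns {sorted(missing)}")
    return [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def write_genes(genes, path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.body_start, g.body_end) for g in genes],
        columns=GENE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ tables

def read_table(path) -> pd.DataFrame:
    """TSV table with a comment-header convention: leading '# key=value'
    lines are parsed into .attrs['params']."""
    params = {}
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                params[k.strip()] = v.strip()
            n_comment += 1
    df = pd.read_csv(path, sep="\t", skiprows=n_comment)
    df.attrs["params"] = params
    return df


def write_table(df: pd.DataFrame, path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


# --------------------------------------------------------------------- GMT

def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> member..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[f[0]] = [g for g in f[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ------------------------------------------------------------------- events

def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------- config/report

def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
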