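"""Readers and writers for the pipeline's TSV dialects.

All tables are tab-separated with a header row.  Floats are written with
Python's shortest round-trip repr, so write -> read is lossless.

Dialects
--------
counts.tsv      gene_id, then one column per sample (integer counts)
lengths.tsv     gene_id, length_bp
samples.tsv     sample_id, treatment{FBZ|FLU|UNT}, breed{D|H|L|Y}, sex{F|CM}, batch{1..}
traits.tsv      sample_id, T12, AUC, CL, MRT, VDSS, CMAX, TMAX (cells may be empty)
annotation.tsv  gene_id, term_id, term_name (one row per pair)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datasets import CountDataset, PK_TRAITS


class DataIOError(RuntimeError):
    """I/O failure that names the offending path and pipeline stage."""


def _read_tsv(path: Path, stage: str, **kw) -> pd.DataFrame:
    if not path.exists():
        raise DataIOError(f"[{stage}] missing input file: {path}")
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except Exception as exc:  # pragma: no cover - parser-specific messages
        raise DataIOError(f"[{stage}] failed to parse {path}: {exc}") from exc


def read_counts(path) -> pd.DataFrame:
    df = _read_tsv(Path(path), "counts", index_col=0)
    df.index.name = "gene_id"
    df.columns.name = "sample_id"
    return df


def read_lengths(path) -> pd.Series:
    df = _read_tsv(Path(path), "lengths", index_col=0)
    s = df.iloc[:, 0]
    s.name = "length_bp"
    s.index.name = "gene_id"
    return s


def read_samples(path) -> pd.DataFrame:
    df = _read_tsv(Path(path), "samples", index_col=0, dtype={"batch": int})
    df.index.name = "sample_id"
    return df


def read_traits(path) -> pd.DataFrame:
    df = _read_tsv(Path(path), "traits", index_col=0)
    df.index.name = "sample_id"
    return df[[c for c in PK_TRAITS if c in df.columns]]


def read_annotation(path) -> pd.DataFrame:
    return _read_tsv(Path(path), "annotation", dtype=str)


def read_dataset(directory) -> CountDataset:
    """Load a full dataset bundle written by :func:`write_dataset`."""
    directory = Path(directory)
    counts = read_counts(directory / "counts.tsv")
    lengths = read_lengths(directory / "lengths.tsv").loc[counts.index]
    samples = read_samples(directory / "samples.tsv").loc[counts.columns]
    traits_path = directory / "traits.tsv"
    traits = read_traits(traits_path) if traits_path.exists() else None
    if traits is not None:
        traits = traits.reindex(counts.columns)
    ann_path = directory / "annotation.tsv"
    annotation = read_annotation(ann_path) if ann_path.exists() else None
    return CountDataset(counts=counts, gene_lengths=lengths, samples=samples,
                        traits=traits, annotation=annotation)


def write_dataset(dataset: CountDataset, directory) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, frame, **kw) -> None:
        path = directory / name
        try:
            frame.to_csv(path, sep="\t", **kw)
        except OSError as exc:
            raise DataIOError(f"[write_dataset] cannot write {path}: {exc}") from exc
        paths[name.removesuffix(".tsv")] = path

    _write("counts.tsv", dataset.counts)
    _write("lengths.tsv", dataset.gene_lengths.to_frame())
    _write("samples.tsv", dataset.samples)
    if dataset.traits is not None:
        _write("traits.tsv", dataset.traits)
    if dataset.annotation is not None:
        _write("annotation.tsv", dataset.annotation, index=False)
    return paths


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    """Write an output table in the shared TSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path
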