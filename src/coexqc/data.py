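"""Core data containers and plain-text I/O.

The pipeline passes three kinds of objects around: raw count datasets
(integer gene x sample matrices with per-sample batch and biology labels),
real-valued expression matrices carrying a processing provenance trail, and
gene-set annotations in GMT form.  Everything serializes to TSV/GMT/JSON so
that intermediate results remain inspectable with standard shell tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountDataset",
    "ExpressionMatrix",
    "read_counts_tsv",
    "read_metadata_tsv",
    "read_dataset",
    "read_expression_tsv",
    "read_gmt",
    "write_gmt",
]


@dataclass
class CountDataset:
    """A gene x sample integer count matrix with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, columns are sample ids, values are
        non-negative integers (mapped read counts).
    batch_of
        Series mapping sample id -> batch id (here a batch is the study
        that produced the sample, the unit of technical variation).
    biology_of
        Series mapping sample id -> biological label (cell type / tissue).
    name, species
        Free-form dataset identifier and species tag, used as covariates
        by the workflow analysis.
    """

    counts: pd.DataFrame
    batch_of: pd.Series
    biology_of: pd.Series
    name: str = ""
    species: str = "human"

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        self.batch_of = pd.Series(self.batch_of)
        self.biology_of = pd.Series(self.biology_of)
        missing = [s for s in self.counts.columns if s not in self.batch_of.index]
        if missing:
            raise ValueError(f"samples without batch label: {missing[:5]}")
        missing = [s for s in self.counts.columns if s not in self.biology_of.index]
        if missing:
            raise ValueError(f"samples without biology label: {missing[:5]}")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("count matrix contains non-finite values")
        if (vals < 0).any():
            raise ValueError("count matrix contains negative values")
        self.counts.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_batches(self) -> int:
        return self.batch_of.loc[self.sample_ids].nunique()

    def metadata(self) -> pd.DataFrame:
        """Sample metadata table (sample_id, batch_id, biology_id)."""
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "batch_id": self.batch_of.loc[self.sample_ids].to_numpy(),
                "biology_id": self.biology_of.loc[self.sample_ids].to_numpy(),
            }
        )

    def write(self, outdir: str | Path) -> None:
        """Write counts.tsv and metadata.tsv into *outdir*."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        counts = self.counts.copy()
        counts.index.name = "gene_id"
        counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.metadata().to_csv(outdir / "metadata.tsv", sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """A real-valued genes x samples matrix with processing provenance.

    ``provenance`` is the ordered list of processing steps applied so far
    (e.g. ``["normalize:UQ", "log2(pseudocount=0.31)"]``).  ``is_log``
    marks matrices already on a log-like scale, which the pseudocount log
    transform refuses to re-log.
    """

    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    pseudocount: float | None = None
    is_log: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame, step: str, **changes) -> "ExpressionMatrix":
        """Return a copy holding *values* with *step* appended to provenance."""
        kwargs = dict(
            provenance=self.provenance + [step],
            pseudocount=self.pseudocount,
            is_log=self.is_log,
        )
        kwargs.update(changes)
        return ExpressionMatrix(values, **kwargs)

    def write(self, path: str | Path) -> None:
        """TSV with ``#`` provenance header lines."""
        path = Path(path)
        with open(path, "w") as fh:
            for step in self.provenance:
                fh.write(f"# {step}\n")
            if self.pseudocount is not None:
                fh.write(f"# pseudocount: {self.pseudocount!r}\n")
            fh.write(f"# is_log: {self.is_log}\n")
            vals = self.values.copy()
            vals.index.name = "gene_id"
            vals.to_csv(fh, sep="\t")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    provenance: list[str] = []
    pseudocount = None
    is_log = False
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            text = line[1:].strip()
            if text.startswith("pseudocount:"):
                pseudocount = float(text.split(":", 1)[1])
            elif text.startswith("is_log:"):
                is_log = text.split(":", 1)[1].strip() == "True"
            else:
                provenance.append(text)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        values = pd.read_csv(fh, sep="\t", index_col=0)
    return ExpressionMatrix(values, provenance=provenance, pseudocount=pseudocount, is_log=is_log)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV (first column gene ids, header sample ids)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return counts


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "batch_id", "biology_id"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def read_dataset(counts_path: str | Path, metadata_path: str | Path, **kwargs) -> CountDataset:
    counts = read_counts_tsv(counts_path)
    meta = read_metadata_tsv(metadata_path).set_index("sample_id")
    return CountDataset(
        counts=counts,
        batch_of=meta["batch_id"],
        biology_of=meta["biology_id"],
        **kwargs,
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term <tab> description <tab> gene...

    Returns term -> gene set; the description column is dropped.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term = parts[0]
            if term in sets:
                raise ValueError(f"duplicate term in GMT: {term}")
            sets[term] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sets:
            genes = sorted(sets[term])
            desc = descriptions.get(term, "na")
            fh.write("\t".join([term, desc] + genes) + "\n")


def write_ground_truth_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
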