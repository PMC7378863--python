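"""Count-table handling: I/O, rarefaction, filtering, aggregation, diversity.

The universal container is :class:`CountMatrix` — a non-negative integer
taxa x samples table with optional per-sample metadata.  All normalisation
and filtering steps used upstream of network inference live here:

* rarefaction (without-replacement subsampling to a common depth),
* relative abundance,
* taxonomy-bootstrap filtering (keep taxa classified with confidence >= 0.80
  at a chosen rank),
* a minimum relative-abundance filter (keep genera reaching >= 1% in at
  least one sample, or in mean across samples),
* aggregation of OTUs to a taxonomic rank,
* alpha diversity (observed richness, bias-corrected Chao1, Shannon in nats,
  Gini-Simpson).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1 as _chao1
from skbio.diversity.alpha import shannon as _shannon
from skbio.diversity.alpha import simpson as _simpson

from .errors import FormatError, ParameterError

__all__ = [
    "CountMatrix",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_taxonomy",
    "rarefy",
    "relative_abundance",
    "filter_by_bootstrap",
    "filter_min_relabund",
    "aggregate_to_rank",
    "alpha_diversity",
]


@dataclass
class CountMatrix:
    """Taxa x samples integer count table with optional sample metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].tolist()
            raise FormatError(f"duplicate taxon IDs: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample IDs: {dup}")
        if (c.to_numpy() < 0).any():
            r, s = np.argwhere(c.to_numpy() < 0)[0]
            raise FormatError(f"negative count at taxon {c.index[r]!r}, sample {c.columns[s]!r}")
        if self.metadata is not None:
            missing = c.columns.difference(self.metadata.index)
            if len(missing):
                raise FormatError(f"metadata missing for samples: {missing.tolist()}")

    @property
    def taxa(self) -> list:
        return self.counts.index.tolist()

    @property
    def samples(self) -> list:
        return self.counts.columns.tolist()

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def with_counts(self, counts: pd.DataFrame) -> "CountMatrix":
        meta = self.metadata.loc[counts.columns] if self.metadata is not None else None
        return CountMatrix(counts, meta)


def read_count_table(path: str | Path, metadata: str | Path | None = None) -> CountMatrix:
    """Read a TSV count table (taxa in column 1, samples across) as integers."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = {h for h in header if header.count(h) > 1}
    if dup:  # pandas silently renames duplicate columns, so check the raw header
        raise FormatError(f"duplicate sample IDs: {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if arr.dtype.kind == "f":
        if not np.all(arr == np.floor(arr)):
            r, s = np.argwhere(arr != np.floor(arr))[0]
            raise FormatError(
                f"non-integer count at taxon {df.index[r]!r}, sample {df.columns[s]!r}"
            )
        df = df.astype(np.int64)
    elif arr.dtype.kind not in "iu":
        raise FormatError(f"non-numeric entries in count table {path}")
    meta = read_metadata(metadata) if metadata is not None else None
    return CountMatrix(df, meta)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype={"replicate": "Int64"})


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0)
    conf_cols = [c for c in tax.columns if c.endswith("_conf")]
    bad = [(c, v) for c in conf_cols for v in tax[c] if not 0 <= v <= 1]
    if bad:
        raise FormatError(f"bootstrap confidence outside [0, 1]: {bad[0]}")
    return tax


def rarefy(cm: CountMatrix, depth: int | None = None, seed=None) -> CountMatrix:
    """Subsample every library without replacement to a common depth.

    ``depth=None`` uses the smallest library.  The draw per sample is
    multivariate hypergeometric, i.e. exact subsampling of the observed reads;
    each column of the result sums to ``depth``.
    """
    sizes = cm.library_sizes
    if depth is None:
        depth = int(sizes.min())
    if depth < 1:
        raise ParameterError("rarefaction depth must be >= 1")
    short = sizes.index[sizes < depth].tolist()
    if short:
        raise ParameterError(f"depth {depth} exceeds library size of samples: {short}")
    rng = np.random.default_rng(seed)
    out = {
        s: rng.multivariate_hypergeometric(cm.counts[s].to_numpy(), depth)
        for s in cm.samples
    }
    return cm.with_counts(pd.DataFrame(out, index=cm.counts.index))


def relative_abundance(counts: pd.DataFrame | CountMatrix) -> pd.DataFrame:
    """Column-normalise to proportions; every column then sums to one."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = df.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ParameterError(f"all-zero samples cannot be normalised: {zero}")
    return df / totals


def filter_by_bootstrap(
    cm: CountMatrix,
    taxonomy: pd.DataFrame,
    rank: str = "genus",
    min_conf: float = 0.80,
) -> tuple[CountMatrix, dict]:
    """Drop taxa whose classification confidence at ``rank`` is below ``min_conf``.

    The boundary is inclusive: confidence exactly at ``min_conf`` is kept.
    Returns the filtered table and a report with the discarded taxa and the
    fraction of total reads they held.
    """
    col = f"{rank}_conf"
    if col not in taxonomy.columns:
        raise ParameterError(f"taxonomy has no confidence column for rank {rank!r}")
    missing = pd.Index(cm.taxa).difference(taxonomy.index)
    if len(missing):
        raise ParameterError(f"taxonomy does not cover taxa: {missing.tolist()}")
    conf = taxonomy.loc[cm.taxa, col]
    keep = conf[conf >= min_conf].index
    dropped = conf[conf < min_conf].index
    total = cm.counts.to_numpy().sum()
    lost = cm.counts.loc[dropped].to_numpy().sum()
    report = {
        "rank": rank,
        "min_conf": min_conf,
        "n_discarded": int(len(dropped)),
        "discarded_taxa": dropped.tolist(),
        "discarded_fraction": float(lost / total) if total else 0.0,
    }
    return cm.with_counts(cm.counts.loc[keep]), report


def filter_min_relabund(
    relab: pd.DataFrame,
    threshold: float = 0.01,
    scope: str = "any_sample",
) -> pd.DataFrame:
    """Keep taxa reaching ``threshold`` relative abundance (inclusive).

    ``scope="any_sample"`` keeps a taxon if it reaches the threshold in at
    least one sample; ``scope="mean"`` requires the across-sample mean to
    reach it.  Remaining rows are *not* renormalised: downstream regression
    receives proportions of the original community.
    """
    if not 0 < threshold < 1:
        raise ParameterError("threshold must lie strictly between 0 and 1")
    if scope == "any_sample":
        keep = relab.max(axis=1) >= threshold
    elif scope == "mean":
        keep = relab.mean(axis=1) >= threshold
    else:
        raise ParameterError(f"unknown scope {scope!r}")
    return relab.loc[keep]


def aggregate_to_rank(
    cm: CountMatrix,
    taxonomy: pd.DataFrame,
    rank: str = "genus",
    unclassified_label: str = "unclassified",
) -> CountMatrix:
    """Sum counts of taxa sharing a label at ``rank``; totals are conserved.

    Taxa without a label at the rank fall into a single "unclassified" row.
    """
    if rank not in taxonomy.columns:
        raise ParameterError(f"taxonomy has no rank column {rank!r}")
    missing = pd.Index(cm.taxa).difference(taxonomy.index)
    if len(missing):
        raise ParameterError(f"taxonomy does not cover taxa: {missing.tolist()}")
    labels = taxonomy.loc[cm.taxa, rank].fillna(unclassified_label)
    grouped = cm.counts.groupby(labels.to_numpy()).sum()
    grouped.index.name = rank
    return cm.with_counts(grouped.sort_index())


def alpha_diversity(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample alpha diversity.

    observed
        number of taxa with nonzero count;
    chao1
        bias-corrected Chao1 richness, S_obs + F1 (F1 - 1) / (2 (F2 + 1))
        with F1/F2 the singleton/doubleton counts;
    shannon
        H = -sum p_i ln p_i (natural log);
    simpson
        Gini-Simpson D = 1 - sum p_i^2.
    """
    rows = []
    for s in cm.samples:
        v = cm.counts[s].to_numpy()
        if v.sum() == 0:
            raise ParameterError(f"sample {s!r} is empty")
        rows.append(
            {
                "sample_id": s,
                "observed": int(np.count_nonzero(v)),
                "chao1": float(_chao1(v, bias_corrected=True)),
                "shannon": float(_shannon(v, base=np.e)),
                "simpson": float(_simpson(v)),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
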