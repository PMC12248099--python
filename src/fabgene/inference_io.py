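"""Multiple-testing adjustment, delimited-text I/O, and result tables.

File conventions: everything is delimited text (comma or tab, sniffed).
Profile matrices have a header row of gene IDs and one observation per row;
embedding files have a gene-ID first column and numeric embedding columns;
panel tables are tidy per-gene tables.  Data and embeddings are aligned by
an order-preserving inner join on gene IDs, with dropped genes logged.
"""

from __future__ import annotations

import hashlib
import io
import logging
from datetime import datetime, timezone

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .embeddings import EmbeddingMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "bh_adjust",
    "discoveries",
    "read_embedding",
    "read_profile_matrix",
    "read_panel",
    "align_genes",
    "write_results",
    "read_results",
]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Missing entries (NaN) propagate as missing and do not count toward the
    number of tests.  Values are monotone after sorting by p and capped at 1.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    bad = np.where(ok & ((p < 0) | (p > 1)))[0]
    if bad.size:
        raise ValueError(
            f"p-value outside [0, 1] at index {bad[0]}: {p[bad[0]]}"
        )
    if ok.sum() == 0:
        return q
    q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def discoveries(q, fdr: float) -> np.ndarray:
    """Indices whose q-value is at or below the FDR threshold."""
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must lie in (0, 1)")
    q = np.asarray(q, dtype=float).ravel()
    with np.errstate(invalid="ignore"):
        return np.where(~np.isnan(q) & (q <= fdr))[0]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_embedding(path, genes=None) -> EmbeddingMatrix:
    """Read an embedding file: first column gene ID, remaining columns
    numeric coordinates; optional header.  If ``genes`` is given, the result
    is inner-joined to it (order-preserving) and unmatched genes logged."""
    sep = _sniff_sep(path)
    probe = pd.read_csv(path, sep=sep, header=None, nrows=2)
    has_header = False
    if probe.shape[0] > 1:
        try:
            probe.iloc[0, 1:].astype(float)
        except (ValueError, TypeError):
            has_header = True
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    emb = EmbeddingMatrix(gene_ids, values)
    if genes is not None:
        have = set(emb.gene_ids)
        matched = [g for g in genes if g in have]
        dropped = [g for g in genes if g not in have]
        if dropped:
            logger.warning(
                "%d gene(s) without embeddings dropped: %s",
                len(dropped),
                ", ".join(map(str, dropped[:10])),
            )
        if len(matched) < 2:
            raise ValueError(
                "fewer than 2 genes shared between data and embeddings"
            )
        emb = emb.subset(matched)
    return emb


def read_profile_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a samples-by-genes matrix with a header row of gene IDs."""
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, header=0)
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"malformed numeric entry in {path}: {exc}") from exc
    return [str(c) for c in df.columns], values


def read_panel(path) -> pd.DataFrame:
    """Read a per-gene panel table.

    Accepts either a precomputed panel (columns gene, y, sigma_hat, n1, n2)
    or a long-format replicate table (gene, condition, replicate, value),
    which is condensed via ``difference_scores``-equivalent aggregation.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=0)
    cols = {c.lower() for c in df.columns}
    if {"gene", "y", "sigma_hat", "n1", "n2"} <= cols:
        df.columns = [c.lower() for c in df.columns]
        return df
    if {"gene", "condition", "replicate", "value"} <= cols:
        df.columns = [c.lower() for c in df.columns]
        return _condense_long(df)
    raise ValueError(
        "panel file must have columns (gene, y, sigma_hat, n1, n2) or "
        "(gene, condition, replicate, value)"
    )


def _condense_long(df: pd.DataFrame) -> pd.DataFrame:
    conds = sorted(df["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    rows = []
    for gene, sub in df.groupby("gene", sort=False):
        g1 = sub.loc[sub["condition"] == conds[0], "value"].to_numpy(float)
        g2 = sub.loc[sub["condition"] == conds[1], "value"].to_numpy(float)
        n1, n2 = g1.size, g2.size
        if n1 < 2 or n2 < 2:
            raise ValueError(f"gene {gene}: need >= 2 replicates per condition")
        ss = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        rows.append(
            {
                "gene": str(gene),
                "y": g2.mean() - g1.mean(),
                "sigma_hat": np.sqrt(ss / (n1 + n2 - 2)),
                "n1": n1,
                "n2": n2,
            }
        )
    return pd.DataFrame(rows)


def align_genes(
    data_genes: list[str], emb: EmbeddingMatrix
) -> tuple[list[int], EmbeddingMatrix]:
    """Order-preserving inner join of data gene IDs with an embedding.

    Returns the column indices of the data matrix to keep and the embedding
    subset in matching order.
    """
    have = set(emb.gene_ids)
    keep = [i for i, g in enumerate(data_genes) if g in have]
    dropped = [g for g in data_genes if g not in have]
    if dropped:
        logger.warning(
            "%d data gene(s) lack embeddings: %s",
            len(dropped),
            ", ".join(map(str, dropped[:10])),
        )
    if len(keep) < 2:
        raise ValueError("fewer than 2 genes shared between data and embeddings")
    return keep, emb.subset([data_genes[i] for i in keep])


def _config_hash(config) -> str:
    blob = repr(sorted((config or {}).items())).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(
    df: pd.DataFrame, path, seed=None, config=None, timestamp: bool = True
) -> None:
    """Write a results table as TSV with a commented provenance header."""
    buf = io.StringIO()
    from . import __version__

    buf.write(f"# fabgene {__version__}\n")
    buf.write(f"# seed: {seed}\n")
    buf.write(f"# config_hash: {_config_hash(config)}\n")
    if timestamp:
        buf.write(f"# written: {datetime.now(timezone.utc).isoformat()}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_results(path) -> pd.DataFrame:
    """Read back a results TSV, skipping provenance comments."""
    return pd.read_csv(path, sep="\t", comment="#")
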