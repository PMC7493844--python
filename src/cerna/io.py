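"""TSV readers/writers and sample alignment.

File formats (all UTF-8, tab-separated, one header row):

* expression:  ``feature_id\\t<sample ids...>`` then one feature per row
* biotype map: ``feature_id\\tbiotype``
* catalog:     ``mirna_id\\ttarget_id\\ttarget_biotype\\tsource``

Identifier matching is exact string equality throughout; alias/id-version
resolution is a data-preparation concern, not handled here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ALL_BIOTYPES,
    ExpressionMatrix,
    InteractionCatalog,
    ValidationError,
)

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = ["mirna_id", "target_id", "target_biotype", "source"]


def read_expression(
    path: str | Path,
    biotype_map: str | Path | None = None,
    default_biotype: str | None = None,
    log2: bool = False,
) -> ExpressionMatrix:
    """Read a features x samples expression TSV.

    Biotypes come either from a ``biotype`` column in the file, from a
    separate two-column map file, or from ``default_biotype``. Features
    with no known biotype are rejected.

    Parameters
    ----------
    log2
        Apply log2(x+1). Default off: inputs are assumed already on a
        log-normalized scale.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected feature_id plus sample columns")
    df = df.set_index(df.columns[0])
    df.index.name = "feature_id"

    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate feature id {dup!r}")

    biotype: pd.Series
    if "biotype" in df.columns:
        biotype = df.pop("biotype").astype(str)
    elif biotype_map is not None:
        bmap = pd.read_csv(
            biotype_map, sep="\t", dtype=str, names=["feature_id", "biotype"],
            header=0,
        ).set_index("feature_id")["biotype"]
        missing = df.index.difference(bmap.index)
        if len(missing) and default_biotype is None:
            raise ValidationError(
                f"{path}: features with unknown biotype: {list(missing[:5])}"
            )
        biotype = bmap.reindex(df.index).fillna(default_biotype or "")
    elif default_biotype is not None:
        biotype = pd.Series(default_biotype, index=df.index)
    else:
        raise ValidationError(
            f"{path}: no biotype column, biotype map or default biotype given"
        )

    if df.empty or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty expression matrix")
    try:
        values = df.astype(float)
    except ValueError as exc:
        # locate the offending cell for the error message
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValidationError(
                    f"{path}: non-numeric value at feature {row!r}, sample {col!r}"
                ) from exc
        raise ValidationError(f"{path}: non-numeric expression values") from exc

    em = ExpressionMatrix(values, biotype)
    if log2:
        em = em.log2_transform()
    return em


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression TSV with a trailing biotype column (lossless round-trip)."""
    out = em.data.copy()
    out["biotype"] = em.biotype
    out.to_csv(path, sep="\t", index=True, index_label="feature_id")


def read_catalog(path: str | Path) -> InteractionCatalog:
    """Read a miRNA-target edge list; duplicate edges collapse with merged sources."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")

    edges: set[tuple[str, str]] = set()
    target_biotype: dict[str, str] = {}
    source: dict[tuple[str, str], str] = {}
    for rec in df.itertuples(index=False):
        edge = (rec.mirna_id, rec.target_id)
        bt = rec.target_biotype
        prev = target_biotype.get(rec.target_id)
        if prev is not None and prev != bt:
            raise ValidationError(
                f"{path}: conflicting biotypes for target {rec.target_id!r}: {prev} vs {bt}"
            )
        target_biotype[rec.target_id] = bt
        if edge in edges:
            tags = set(source[edge].split(";")) | {rec.source}
            source[edge] = ";".join(sorted(tags))
        else:
            edges.add(edge)
            source[edge] = rec.source
    if not edges:
        raise ValidationError(f"{path}: catalog has no edges")
    return InteractionCatalog(edges=edges, target_biotype=target_biotype, source=source)


def write_catalog(catalog: InteractionCatalog, path: str | Path) -> None:
    rows = [
        {
            "mirna_id": m,
            "target_id": t,
            "target_biotype": catalog.target_biotype[t],
            "source": catalog.source.get((m, t), ""),
        }
        for (m, t) in sorted(catalog.edges)
    ]
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def align_samples(
    gene_expr: ExpressionMatrix, mirna_expr: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to shared samples, in gene-matrix order.

    Alignment is by exact sample-id intersection; the gene matrix's column
    order is preserved so the operation is deterministic and idempotent.
    """
    shared = [s for s in gene_expr.sample_ids if s in set(mirna_expr.sample_ids)]
    if not shared:
        raise ValidationError("gene and miRNA matrices share no samples")
    logger.info(
        "aligned samples: %d shared of %d gene / %d miRNA",
        len(shared), len(gene_expr.sample_ids), len(mirna_expr.sample_ids),
    )
    return gene_expr.subset_samples(shared), mirna_expr.subset_samples(shared)


def validate_biotypes(labels: pd.Series) -> None:
    bad = set(labels.unique()) - set(ALL_BIOTYPES)
    if bad:
        raise ValidationError(f"unknown biotype(s): {sorted(bad)}")
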