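"""Domain containers shared by all pipeline stages.

Expression values are assumed to be log-scale normalized abundances;
all downstream statistics are correlation-based, so any monotone
variance-stabilised scale works. Biotypes partition features into
protein-coding genes, lncRNAs, pseudogenes and miRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_BIOTYPES = ("protein_coding", "lncRNA", "pseudogene")
ALL_BIOTYPES = GENE_BIOTYPES + ("miRNA",)

#: biotypes eligible to act as a sponge partner (ceRNA-B)
SPONGE_BIOTYPES = frozenset(GENE_BIOTYPES)


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Features x samples expression with one biotype label per feature.

    ``data`` is indexed by feature id with sample ids as columns;
    ``biotype`` is aligned to ``data.index``.
    """

    data: pd.DataFrame
    biotype: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if len(idx) == 0 or len(cols) == 0:
            raise ValidationError("expression matrix is empty")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if not self.biotype.index.equals(idx):
            raise ValidationError("biotype labels do not align with features")
        bad = set(self.biotype.unique()) - set(ALL_BIOTYPES)
        if bad:
            raise ValidationError(
                f"unknown biotype(s) {sorted(bad)}; allowed: {list(ALL_BIOTYPES)}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def vector(self, feature_id: str) -> np.ndarray:
        try:
            return self.data.loc[feature_id].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in expression matrix")

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, sample_ids], self.biotype.copy())

    def drop_constant_features(self) -> "ExpressionMatrix":
        """Remove zero-variance features (correlations are undefined for them)."""
        sd = self.data.std(axis=1, ddof=0)
        keep = sd > 0
        if not keep.all():
            dropped = list(self.data.index[~keep])
            warnings.warn(
                f"dropping {len(dropped)} constant feature(s): {dropped[:5]}...",
                stacklevel=2,
            )
            return ExpressionMatrix(self.data.loc[keep], self.biotype.loc[keep])
        return self

    def log2_transform(self) -> "ExpressionMatrix":
        """Optional log2(x+1); off by default, for raw-scale inputs."""
        return ExpressionMatrix(np.log2(self.data + 1.0), self.biotype.copy())


@dataclass
class InteractionCatalog:
    """Bipartite miRNA -> target edge set with target biotypes and sources.

    ``mirna_universe`` houses N, the total number of available miRNAs used
    by the hypergeometric overlap test.
    """

    edges: set[tuple[str, str]]
    target_biotype: dict[str, str]
    source: dict[tuple[str, str], str] = field(default_factory=dict)
    mirna_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        edge_mirnas = {m for m, _ in self.edges}
        if not self.mirna_universe:
            self.mirna_universe = set(edge_mirnas)
        elif not edge_mirnas <= self.mirna_universe:
            raise ValidationError("mirna_universe must cover all edge miRNAs")
        missing = {t for _, t in self.edges} - set(self.target_biotype)
        if missing:
            raise ValidationError(
                f"targets without biotype: {sorted(missing)[:5]}"
            )
        bad = set(self.target_biotype.values()) - set(GENE_BIOTYPES)
        if bad:
            raise ValidationError(
                f"target biotype(s) {sorted(bad)} outside allowed set {list(GENE_BIOTYPES)}"
            )

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.edges}

    def mirnas_of(self, target_id: str) -> set[str]:
        if target_id not in self.targets:
            raise KeyError(f"target {target_id!r} not in catalog")
        return {m for m, t in self.edges if t == target_id}

    def neighborhoods(self) -> dict[str, set[str]]:
        """target id -> set of regulating miRNA ids."""
        nb: dict[str, set[str]] = {}
        for m, t in self.edges:
            nb.setdefault(t, set()).add(m)
        return nb


@dataclass
class TissueDataset:
    """Per-tissue inputs: aligned gene/miRNA expression plus the catalog."""

    gene_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    catalog: InteractionCatalog
    tissue_label: str = "unspecified"
    condition: str = "normal"

    def __post_init__(self) -> None:
        if self.gene_expr.sample_ids != self.mirna_expr.sample_ids:
            raise ValidationError(
                "gene and miRNA matrices must share an identical ordered sample list; "
                "run align_samples first"
            )
        if "miRNA" in set(self.gene_expr.biotype):
            raise ValidationError("gene matrix must not contain miRNA features")
        if set(self.mirna_expr.biotype) - {"miRNA"}:
            raise ValidationError("miRNA matrix must contain only miRNA features")
        if self.condition not in ("normal", "tumour"):
            raise ValidationError(
                f"condition must be 'normal' or 'tumour', got {self.condition!r}"
            )
        if not (self.catalog.targets & set(self.gene_expr.feature_ids)):
            raise ValidationError(
                "catalog targets and gene expression features are disjoint"
            )

    @property
    def n_samples(self) -> int:
        return self.gene_expr.n_samples
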