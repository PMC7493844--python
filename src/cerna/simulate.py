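"""Synthetic expression and catalog generator with planted ceRNA structure.

The generator emulates log-scale normalized expression under a Gaussian
linear model: miRNA profiles are i.i.d. normal across samples, and each
planted ceRNA pair consists of two targets repressed by the same shared
miRNAs,

    target = base - beta * sum_j m_j + noise,

so the pair is positively correlated through the miRNAs (population
correlation s*beta^2*sigma_m^2 / (s*beta^2*sigma_m^2 + sigma_eps^2) for s
shared miRNAs) while being conditionally independent given them — exactly
the signature the pipeline is built to detect. Decoy pairs share catalog
edges with the same topology but have no expression coupling; remaining
background genes are pure noise, and background catalog edges are
sprinkled at a configurable density so the overlap test has non-trivial
rejection behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import cycle

import numpy as np
import pandas as pd

from .sponge import CeRnaInteraction
from .types import ExpressionMatrix, InteractionCatalog, TissueDataset, ValidationError


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic tissue.

    Defaults are the standard benchmark scenario: 200 samples, 5 planted
    triplets with 2 shared miRNAs each at repression strength beta = 0.8,
    20 decoy pairs, unit noise.
    """

    n_samples: int = 200
    n_mirnas: int = 150
    n_coding: int = 60
    n_lncrna: int = 30
    n_pseudo: int = 20
    n_true_triplets: int = 5
    n_decoy_pairs: int = 20
    beta: float = 0.8
    noise_sd: float = 1.0
    mirna_mean: float = 0.0
    mirna_sd: float = 1.0
    shared_per_triplet: int = 2
    base_expression: float = 8.0
    background_edge_density: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_mirnas, self.n_coding) <= 0:
            raise ValidationError("sample, miRNA and coding-gene counts must be positive")
        if self.beta < 0 or self.noise_sd <= 0 or self.mirna_sd <= 0:
            raise ValidationError("beta must be >= 0 and spreads positive")
        if self.shared_per_triplet < 1:
            raise ValidationError("shared_per_triplet must be >= 1")
        n_pairs = self.n_true_triplets + self.n_decoy_pairs
        if n_pairs * self.shared_per_triplet > self.n_mirnas:
            raise ValidationError("not enough miRNAs for the requested pairs")
        if n_pairs > self.n_coding:
            raise ValidationError("not enough coding genes for ceRNA-A slots")
        if 2 * n_pairs > self.n_coding + self.n_lncrna + self.n_pseudo:
            raise ValidationError("not enough features for the requested pairs")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    true_pairs: set[frozenset] = field(default_factory=set)
    true_repressive_edges: set[tuple[str, str]] = field(default_factory=set)
    decoy_pairs: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.true_pairs & self.decoy_pairs:
            raise ValidationError("a pair cannot be both true and decoy")


def generate_dataset(spec: GeneratorSpec) -> tuple[TissueDataset, GroundTruth]:
    """Generate one synthetic tissue with planted ceRNA pairs and decoys.

    Fully reproducible from ``spec.seed``: identical specs give identical
    matrices, catalogs and ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    mirna_ids = [f"hsa-miR-{i + 1}" for i in range(spec.n_mirnas)]
    sample_ids = [f"s{i + 1}" for i in range(n)]
    mirna_values = rng.normal(spec.mirna_mean, spec.mirna_sd, (spec.n_mirnas, n))
    mirna_df = pd.DataFrame(mirna_values, index=mirna_ids, columns=sample_ids)

    coding = [f"GENE{i + 1}" for i in range(spec.n_coding)]
    lncrna = [f"LNC{i + 1}" for i in range(spec.n_lncrna)]
    pseudo = [f"PSG{i + 1}" for i in range(spec.n_pseudo)]
    biotype = pd.Series(
        {**{g: "protein_coding" for g in coding},
         **{g: "lncRNA" for g in lncrna},
         **{g: "pseudogene" for g in pseudo}}
    )

    gene_df = pd.DataFrame(
        spec.base_expression + rng.normal(0.0, spec.noise_sd, (len(biotype), n)),
        index=list(biotype.index),
        columns=sample_ids,
    )

    # pools of unused ids, consumed as pairs are planted
    free_coding = list(coding)
    free_b = {"lncRNA": list(lncrna), "pseudogene": list(pseudo),
              "protein_coding": None}  # coding Bs drawn from free_coding
    free_mirnas = list(mirna_ids)
    b_biotypes = cycle(["lncRNA", "pseudogene", "protein_coding"])

    edges: set[tuple[str, str]] = set()
    source: dict[tuple[str, str], str] = {}
    truth = GroundTruth()

    def next_pair() -> tuple[str, str]:
        a = free_coding.pop(0)
        for _ in range(3):
            bt = next(b_biotypes)
            pool = free_coding if bt == "protein_coding" else free_b[bt]
            if pool:
                return a, pool.pop(0)
        raise ValidationError("exhausted feature pools while planting pairs")

    def plant(coupled: bool) -> tuple[str, str, list[str]]:
        a, b = next_pair()
        shared = [free_mirnas.pop(0) for _ in range(spec.shared_per_triplet)]
        for m in shared:
            for t in (a, b):
                edges.add((m, t))
                source[(m, t)] = "validated"
        if coupled:
            drive = spec.beta * mirna_df.loc[shared].sum(axis=0).to_numpy()
            for t in (a, b):
                gene_df.loc[t] = (
                    spec.base_expression - drive + rng.normal(0, spec.noise_sd, n)
                )
            truth.true_pairs.add(frozenset((a, b)))
            truth.true_repressive_edges.update((m, t) for m in shared for t in (a, b))
        else:
            truth.decoy_pairs.add(frozenset((a, b)))
        return a, b, shared

    for _ in range(spec.n_true_triplets):
        plant(coupled=True)
    for _ in range(spec.n_decoy_pairs):
        plant(coupled=False)

    # background catalog edges at the requested density, attached only to
    # genes outside planted pairs so planted overlap counts stay exactly
    # the configured shared sets
    paired_genes = {g for pair in truth.true_pairs | truth.decoy_pairs for g in pair}
    background_genes = [g for g in biotype.index if g not in paired_genes]
    for m in mirna_ids:
        hits = rng.random(len(background_genes)) < spec.background_edge_density
        for g in np.asarray(background_genes)[hits]:
            e = (m, str(g))
            edges.add(e)
            source[e] = "predicted"

    catalog = InteractionCatalog(
        edges=edges,
        target_biotype={t: biotype[t] for _, t in edges},
        source=source,
        mirna_universe=set(mirna_ids),
    )
    dataset = TissueDataset(
        gene_expr=ExpressionMatrix(gene_df, biotype),
        mirna_expr=ExpressionMatrix(
            mirna_df, pd.Series("miRNA", index=mirna_df.index)
        ),
        catalog=catalog,
        tissue_label="synthetic",
        condition="normal",
    )
    return dataset, truth


def evaluate_recovery(
    predicted: list[CeRnaInteraction], truth: GroundTruth
) -> tuple[float, float]:
    """Precision and recall of predicted pairs against the planted truth.

    Pair matching is orientation-insensitive. Precision of an empty
    prediction set is defined as 1 (nothing asserted, nothing wrong).
    """
    pred_pairs = {p.pair for p in predicted}
    if not pred_pairs:
        precision = 1.0
    else:
        precision = len(pred_pairs & truth.true_pairs) / len(pred_pairs)
    if not truth.true_pairs:
        recall = 1.0
    else:
        recall = len(pred_pairs & truth.true_pairs) / len(truth.true_pairs)
    return precision, recall
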