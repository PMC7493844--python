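"""Step A in isolation: the hypergeometric shared-miRNA overlap test.

Out of N available miRNAs, ceRNA-A interacts with K of them and ceRNA-B
with O; x are shared. The p-value is the probability of seeing an overlap
at least that large if the two regulator sets were drawn independently.
"""

from cerna import InteractionCatalog, OverlapCounts, hypergeom_pvalue, shared_mirnas

catalog = InteractionCatalog(
    edges={
        ("hsa-miR-373", "STOML1"), ("hsa-miR-372", "STOML1"),
        ("hsa-miR-373", "RP11-290F5.22"), ("hsa-miR-372", "RP11-290F5.22"),
        ("hsa-miR-17", "STOML1"), ("hsa-miR-98", "AASDHPPT"),
    },
    target_biotype={
        "STOML1": "protein_coding",
        "AASDHPPT": "protein_coding",
        "RP11-290F5.22": "lncRNA",
    },
    mirna_universe={f"hsa-miR-{i}" for i in range(1, 97)}
    | {"hsa-miR-372", "hsa-miR-373", "hsa-miR-98", "hsa-miR-17"},
)

shared = shared_mirnas(catalog, "STOML1", "RP11-290F5.22")
counts = OverlapCounts(
    N=len(catalog.mirna_universe),
    K=len(catalog.mirnas_of("STOML1")),
    O=len(catalog.mirnas_of("RP11-290F5.22")),
    x=len(shared),
)
p = hypergeom_pvalue(counts)
print(f"shared miRNAs: {'; '.join(sorted(shared))}")
print(f"N={counts.N} K={counts.K} O={counts.O} x={counts.x} -> p = {p:.3e}")
# a small p means the two transcripts share far more regulators than chance
# predicts, making them a candidate sponge pair.
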