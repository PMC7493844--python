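"""Pipeline orchestration: steps A -> B -> C per tissue/condition.

Outputs per run directory:

* ``candidates.tsv``   step-A candidate pairs with overlap counts
* ``edge_tests.tsv``   step-B per-edge negative-correlation tests
* ``interactions.tsv`` final table, exactly the six canonical columns
* ``report.json``      survivor counts per stage plus provenance
* ``config.lock``      the resolved run configuration (YAML)

Runs are deterministic: one master seed in the config, with per-stage
seeds derived by hashing the stage name, so identical inputs and seed
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .anticorr import MiRnaTargetTest, filter_negative_edges
from .hypergeom import CandidateTriplet, enumerate_candidates
from .sponge import CeRnaInteraction, NullModel, score_candidates
from .types import TissueDataset, ValidationError

logger = logging.getLogger(__name__)

#: canonical output header of the final interaction table
RESULT_COLUMNS = [
    "ceRNA-A",
    "ceRNA-B",
    "shared miRNAs",
    "list of shared miRNAs",
    "mscor",
    "p-value",
]
EXTENDED_COLUMNS = RESULT_COLUMNS + ["cor", "pcor", "tissue", "condition"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All tunables of one pipeline run."""

    alpha_hyper: float = 0.05
    alpha_gt: float = 0.05
    alpha_mscor: float = 0.05
    min_shared: int = 1
    n_perm: int = 1000
    null_draws: int = 10_000
    adjust_hyper: str = "bh"
    joint_global_test: bool = False
    extended_columns: bool = False
    seed: int = 0
    tissue_label: str = "unspecified"
    condition: str = "normal"

    def __post_init__(self) -> None:
        for name in ("alpha_hyper", "alpha_gt", "alpha_mscor"):
            a = getattr(self, name)
            if not (0 < a <= 1):
                raise ValidationError(f"{name} must be in (0, 1]")

    def stage_seed(self, stage: str) -> int:
        h = zlib.crc32(stage.encode())
        return (self.seed * 1_000_003 + h) % (2**31 - 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# table serialization
# ---------------------------------------------------------------------------

def candidates_frame(candidates: list[CandidateTriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cerna_a": c.cerna_a,
                "cerna_b": c.cerna_b,
                "n_shared": c.counts.x,
                "shared_mirnas": "; ".join(c.shared_mirnas),
                "N": c.counts.N,
                "K": c.counts.K,
                "O": c.counts.O,
                "p_hyper": c.p_hyper,
                "p_hyper_adj": c.p_hyper_adj,
            }
            for c in candidates
        ],
        columns=[
            "cerna_a", "cerna_b", "n_shared", "shared_mirnas",
            "N", "K", "O", "p_hyper", "p_hyper_adj",
        ],
    )


def edge_tests_frame(tests: list[MiRnaTargetTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": t.mirna_id,
                "target_id": t.target_id,
                "r": t.r,
                "Q": t.Q,
                "p_gt": t.p_gt,
                "retained": t.retained,
            }
            for t in tests
        ],
        columns=["mirna_id", "target_id", "r", "Q", "p_gt", "retained"],
    )


def interactions_frame(
    interactions: list[CeRnaInteraction],
    extended: bool = False,
    condition: str = "normal",
) -> pd.DataFrame:
    rows = []
    for it in interactions:
        row = {
            "ceRNA-A": it.cerna_a,
            "ceRNA-B": it.cerna_b,
            "shared miRNAs": it.n_shared,
            "list of shared miRNAs": "; ".join(it.shared_mirnas),
            "mscor": it.mscor,
            "p-value": it.p_emp,
        }
        if extended:
            row.update(
                cor=it.cor_ab, pcor=it.pcor_ab,
                tissue=it.tissue_label, condition=condition,
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=EXTENDED_COLUMNS if extended else RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    dataset: TissueDataset,
    config: RunConfig,
    out_dir: str | Path | None = None,
    null_model: NullModel | None = None,
) -> tuple[list[CeRnaInteraction], dict]:
    """Execute steps A -> B -> C and optionally write all artifacts.

    Step B tests only the edges touched by some step-A candidate
    (result-equivalent to testing the whole catalog, and much cheaper).
    Returns the final interactions and the run report.
    """
    written: list[Path] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _abort(stage: str, exc: Exception):
        for f in written:
            f.unlink(missing_ok=True)
        raise StageError(f"step {stage} failed: {exc}") from exc

    # step A: hypergeometric candidate enumeration
    try:
        candidates = enumerate_candidates(
            dataset,
            min_shared=config.min_shared,
            alpha=config.alpha_hyper,
            adjust=config.adjust_hyper,
        )
    except Exception as exc:  # noqa: BLE001
        _abort("A (hypergeometric filter)", exc)
    logger.info("step A: %d candidate pair(s)", len(candidates))

    # step B: negative-correlation filter on the edges the candidates use
    edges = sorted(
        {
            (m, t)
            for c in candidates
            for m in c.shared_mirnas
            for t in (c.cerna_a, c.cerna_b)
        }
    )
    try:
        tests = filter_negative_edges(
            dataset,
            edges=edges,
            alpha=config.alpha_gt,
            n_perm=config.n_perm,
            seed=config.stage_seed("global_test"),
            joint=config.joint_global_test,
        )
    except Exception as exc:  # noqa: BLE001
        _abort("B (negative-correlation filter)", exc)
    n_retained = sum(t.retained for t in tests)
    logger.info("step B: %d of %d edge(s) retained", n_retained, len(tests))

    # step C: mscor scoring against the stratified null
    if null_model is None:
        null_model = NullModel(
            n_samples=dataset.n_samples,
            n_draws=config.null_draws,
            seed=config.stage_seed("null_model"),
        )
    try:
        interactions = score_candidates(
            dataset, candidates, tests, null_model, alpha=config.alpha_mscor
        )
    except Exception as exc:  # noqa: BLE001
        _abort("C (mscor scoring)", exc)
    logger.info("step C: %d interaction(s)", len(interactions))

    cfg = config.to_dict()
    report = {
        "tissue": config.tissue_label,
        "condition": config.condition,
        "seed": config.seed,
        "counts": {
            "candidates": len(candidates),
            "edges_tested": len(tests),
            "edges_retained": int(n_retained),
            "interactions": len(interactions),
        },
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }

    if out is not None:
        try:
            p = out / "candidates.tsv"
            candidates_frame(candidates).to_csv(p, sep="\t", index=False)
            written.append(p)
            p = out / "edge_tests.tsv"
            edge_tests_frame(tests).to_csv(p, sep="\t", index=False)
            written.append(p)
            p = out / "interactions.tsv"
            interactions_frame(
                interactions, extended=config.extended_columns,
                condition=config.condition,
            ).to_csv(p, sep="\t", index=False)
            written.append(p)
            p = out / "report.json"
            p.write_text(json.dumps(report, indent=2, sort_keys=True))
            written.append(p)
            p = out / "config.lock"
            p.write_text(yaml.safe_dump(cfg, sort_keys=True))
            written.append(p)
        except Exception as exc:  # noqa: BLE001
            _abort("output", exc)

    return interactions, report


# ---------------------------------------------------------------------------
# result store and queries
# ---------------------------------------------------------------------------

@dataclass
class ResultStore:
    """Per-(tissue, condition) result tables loaded from run directories."""

    runs: dict[tuple[str, str], dict] = field(default_factory=dict)

    @classmethod
    def load(cls, root: str | Path) -> "ResultStore":
        """Scan a directory tree for run outputs (directories holding report.json)."""
        root = Path(root)
        store = cls()
        reports = sorted(root.rglob("report.json"))
        if (root / "report.json").exists():
            reports = [root / "report.json"] + [
                r for r in reports if r != root / "report.json"
            ]
        for rep_path in reports:
            d = rep_path.parent
            report = json.loads(rep_path.read_text())
            key = (report["tissue"], report["condition"])
            store.runs[key] = {
                "dir": d,
                "report": report,
                "interactions": pd.read_csv(d / "interactions.tsv", sep="\t"),
                "candidates": pd.read_csv(d / "candidates.tsv", sep="\t"),
                "edge_tests": pd.read_csv(d / "edge_tests.tsv", sep="\t"),
            }
        if not store.runs:
            raise ValidationError(f"no run outputs found under {root}")
        return store

    @property
    def tissues(self) -> list[str]:
        return sorted({t for t, _ in self.runs})

    def _runs_for(self, tissues: list[str] | None) -> list[tuple[str, str]]:
        if tissues is None:
            return sorted(self.runs)
        unknown = set(tissues) - {t for t, _ in self.runs}
        if unknown:
            raise ValidationError(
                f"unknown tissue(s) {sorted(unknown)}; available: {self.tissues}"
            )
        return sorted(k for k in self.runs if k[0] in set(tissues))


def _removal_stage(run: dict, a: str, b: str) -> str:
    """Which stage removed a pair that is absent from the final table."""
    cand = run["candidates"]
    hit = cand[
        ((cand.cerna_a == a) & (cand.cerna_b == b))
        | ((cand.cerna_a == b) & (cand.cerna_b == a))
    ]
    if hit.empty:
        return "step_A"
    shared = str(hit.iloc[0]["shared_mirnas"]).split("; ")
    et = run["edge_tests"]
    retained = {
        (r.mirna_id, r.target_id) for r in et.itertuples() if r.retained
    }
    if any((m, a) in retained and (m, b) in retained for m in shared):
        return "step_C"
    return "step_B"


def query_pair(
    store: ResultStore,
    cerna_a: str,
    cerna_b: str | None = None,
    tissues: list[str] | None = None,
) -> pd.DataFrame:
    """Look a ceRNA pair (or all partners of one gene) up across tissues.

    Returns one row per (tissue, condition, pair): matching final-table
    rows, or an absence marker annotated with the stage at which the pair
    was removed. ``cross_tissue_count`` counts the tissues where the pair
    appears in the final table.
    """
    rows = []
    for key in store._runs_for(tissues):
        run = store.runs[key]
        df = run["interactions"]
        if cerna_b is None:
            hit = df[(df["ceRNA-A"] == cerna_a) | (df["ceRNA-B"] == cerna_a)]
            hit = hit.sort_values("p-value")
        else:
            hit = df[
                ((df["ceRNA-A"] == cerna_a) & (df["ceRNA-B"] == cerna_b))
                | ((df["ceRNA-A"] == cerna_b) & (df["ceRNA-B"] == cerna_a))
            ]
        if hit.empty:
            rows.append(
                {
                    "tissue": key[0],
                    "condition": key[1],
                    "ceRNA-A": cerna_a,
                    "ceRNA-B": cerna_b,
                    "present": False,
                    "removed_at": (
                        _removal_stage(run, cerna_a, cerna_b)
                        if cerna_b is not None
                        else "no_partner"
                    ),
                }
            )
        else:
            for _, r in hit.iterrows():
                rows.append(
                    {
                        "tissue": key[0],
                        "condition": key[1],
                        **r.to_dict(),
                        "present": True,
                        "removed_at": "",
                    }
                )
    out = pd.DataFrame(rows)
    if not out.empty and cerna_b is not None:
        out["cross_tissue_count"] = int(
            out.loc[out["present"], "tissue"].nunique()
        )
    return out


def annotate_mirna_targets(
    store: ResultStore, mirna_id: str, tissue: str
) -> pd.DataFrame:
    """All step-B-retained targets of one miRNA in one tissue, with r and p_gt."""
    keys = [k for k in store.runs if k[0] == tissue]
    if not keys:
        raise ValidationError(
            f"unknown tissue {tissue!r}; available: {store.tissues}"
        )
    frames = []
    for key in sorted(keys):
        et = store.runs[key]["edge_tests"]
        hit = et[(et.mirna_id == mirna_id) & (et.retained)]
        if not hit.empty:
            hit = hit.assign(tissue=key[0], condition=key[1])
            frames.append(hit)
    if not frames:
        logger.warning("miRNA %r has no retained targets in tissue %r", mirna_id, tissue)
        return pd.DataFrame(
            columns=["mirna_id", "target_id", "r", "Q", "p_gt", "retained",
                     "tissue", "condition"]
        )
    return pd.concat(frames, ignore_index=True)
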