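"""End-to-end study orchestration.

Reads every input, builds trait seeds, scores each QTL, optionally runs
the permutation null, applies BH over per-QTL minimum p-values and writes
one TSV row per (QTL, member gene) plus a reproducibility log.  Skipping
the permutation step changes no score increase — it only leaves the p
columns empty.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import (EvidencePolicy, build_trait_seeds, parse_chebi_xrefs,
                          parse_gaf, parse_trait_map, SOURCE_CHEBI, SOURCE_GOA)
from .ontology import parse_obo
from .orthology import parse_orthoxml
from .propagation import PropagationParams
from .qtl_scoring import (gene_to_tree_map, genes_in_qtl, load_gene_loci,
                          load_qtl_table, score_qtl)
from .significance import ResampleParams, bh_adjust, empirical_null, empirical_pvalue

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

OUTPUT_COLUMNS = ["qtl_id", "trait_id", "gene_id", "S0", "S1", "delta", "p", "p_bh_qtl"]


@dataclass
class RunConfig:
    """Declarative configuration of one study run.

    Defaults mirror the method's published operating point: 20% per-edge
    decay with the squared paralogy penalty, evidence scores 1.0
    (experimental) / 0.95 (trusted electronic) / 1.0 (ChEBI xref), and 1000
    resamples when significance is enabled.
    """

    genes: str = ""
    hogs: str = ""
    go_obo: str = ""
    chebi_obo: str = ""
    gaf: str = ""
    chebi_xrefs: str = ""
    trait_map: str = ""
    qtl: str = ""
    output: str = "results.tsv"

    decay: float = 0.2
    paralog_mode: str = "squared_decay"
    experimental_score: float = 1.0
    trusted_electronic_score: float = 0.95
    xref_score: float = 1.0
    trusted_iea_references: list[str] = field(default_factory=list)
    trusted_iea_assigned_by: list[str] = field(default_factory=list)
    chebi_closure: bool = False
    significance: bool = True
    n_resamples: int = 1000
    null_pooling: str = "pooled"
    smoothing: bool = True
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def propagation_params(self) -> PropagationParams:
        return PropagationParams(decay=self.decay, paralog_mode=self.paralog_mode)

    def evidence_policy(self) -> EvidencePolicy:
        policy = EvidencePolicy(
            experimental_score=self.experimental_score,
            trusted_electronic_score=self.trusted_electronic_score,
            xref_score=self.xref_score,
        )
        if self.trusted_iea_references or self.trusted_iea_assigned_by:
            policy = dataclasses.replace(
                policy,
                trusted_references=frozenset(self.trusted_iea_references),
                trusted_assigned_by=frozenset(self.trusted_iea_assigned_by),
            )
        return policy

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run the full prioritization study described by ``config``.

    Returns the results table (one row per QTL member gene, sorted by QTL
    then score increase descending) and writes it to ``config.output``
    atomically — on any reader error nothing is written.  Per-QTL skip
    reasons (unmapped trait, empty interval, window too wide to resample)
    are logged, not fatal.
    """
    logger.info("qtlprio %s | seed=%d | config=%s",
                __version__, config.rng_seed, config.config_hash())

    index = load_gene_loci(config.genes)
    with open(config.hogs) as fh:
        forest, _catalogue = parse_orthoxml(fh)
    gene_to_tree = gene_to_tree_map(forest)
    dags = {}
    if config.go_obo:
        with open(config.go_obo) as fh:
            dags[SOURCE_GOA] = parse_obo(fh)
    if config.chebi_obo:
        with open(config.chebi_obo) as fh:
            dags[SOURCE_CHEBI] = parse_obo(fh)
    annotations = []
    if config.gaf:
        with open(config.gaf) as fh:
            annotations += parse_gaf(fh)
    if config.chebi_xrefs:
        with open(config.chebi_xrefs) as fh:
            annotations += parse_chebi_xrefs(fh)
    with open(config.trait_map) as fh:
        trait_map = parse_trait_map(fh)
    qtls = load_qtl_table(config.qtl)

    seeds_by_trait = build_trait_seeds(
        annotations, trait_map, dags, config.evidence_policy(),
        closure_by_source={SOURCE_GOA: True, SOURCE_CHEBI: config.chebi_closure},
    )
    params = config.propagation_params()
    resample_params = ResampleParams(
        n_resamples=config.n_resamples, pooling=config.null_pooling,
        smoothing=config.smoothing,
    )
    rng = np.random.default_rng(config.rng_seed)

    rows: list[dict] = []
    qtl_min_p: dict[str, float] = {}
    for qtl in qtls:
        if qtl.trait_id not in seeds_by_trait:
            logger.warning("QTL %s skipped: trait %s has no mapped terms",
                           qtl.qtl_id, qtl.trait_id)
            continue
        members = genes_in_qtl(index, qtl.chromosome, qtl.start, qtl.end)
        if not members:
            logger.warning("QTL %s skipped: no genes in interval", qtl.qtl_id)
            continue
        trait_seeds = seeds_by_trait[qtl.trait_id]
        scores = score_qtl(qtl, index, trait_seeds, gene_to_tree, params)
        p_values: list[float | None] = [None] * len(scores)
        if config.significance:
            try:
                null = empirical_null(qtl, index, trait_seeds, gene_to_tree,
                                      params, resample_params, rng,
                                      k=len(members))
            except ValueError as exc:
                logger.warning("QTL %s: null skipped (%s)", qtl.qtl_id, exc)
            else:
                p_values = [empirical_pvalue(c.delta, null, config.smoothing)
                            for c in scores]
                finite = [p for p in p_values if p is not None and p > 0]
                if finite:
                    qtl_min_p[qtl.qtl_id] = min(finite)
        for score, p in zip(scores, p_values):
            rows.append({
                "qtl_id": qtl.qtl_id, "trait_id": qtl.trait_id,
                "gene_id": score.gene_id, "S0": score.S0, "S1": score.S1,
                "delta": score.delta, "p": p, "p_bh_qtl": None,
            })

    if qtl_min_p:
        qtl_ids = sorted(qtl_min_p)
        adjusted = bh_adjust([qtl_min_p[q] for q in qtl_ids])
        p_bh = dict(zip(qtl_ids, adjusted))
        for row in rows:
            row["p_bh_qtl"] = p_bh.get(row["qtl_id"])

    frame = pd.DataFrame(rows, columns=OUTPUT_COLUMNS)
    out = Path(config.output)
    out.parent.mkdir(parents=True, exist_ok=True)
    tmp = out.with_suffix(out.suffix + ".tmp")
    frame.to_csv(tmp, sep="\t", index=False, float_format="%.6g")
    tmp.replace(out)
    logger.info("wrote %d candidate rows for %d QTL to %s",
                len(frame), frame["qtl_id"].nunique() if len(frame) else 0, out)
    return frame


def main_guard(func, *args, **kwargs):
    """Run ``func`` and exit non-zero with a message on any fatal error."""
    try:
        return func(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        logger.error("fatal: %s", exc)
        sys.exit(1)
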