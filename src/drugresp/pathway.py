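"""Gene-set enrichment filtering of the core signature and the final model.

The core signature is tested for over-representation in a GMT pathway
collection with the one-sided hypergeometric tail (population = the
post-reduction gene universe that entered feature selection); genes on
pathways passing the raw p < 0.01 gate form the pathway-based "functional"
signature, which is refit as a 2-component PLSR on the full retained panel
and calibrated with a data-driven score cutoff on the re-predicted panel
scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import ExpressionMatrix, PipelineError, ResponsePanel
from .plsr import PLSRModel, ScoreCutoff, design_matrix, fit_plsr, predict, response_cutoff

logger = logging.getLogger("drugresp")


@dataclass
class PathwayCollection:
    """Named gene sets: pathway id -> (description, member gene symbols)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        cleaned = {}
        for name, (desc, genes) in self.sets.items():
            members = sorted({g.upper() for g in genes})
            if not members:
                raise PipelineError(f"pathway {name!r} is empty")
            cleaned[name] = (desc, members)
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> set[str]:
        return set(self.sets[name][1])


def read_gmt(path) -> PathwayCollection:
    """Read a GMT file (tab-separated: id, description, member genes...)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise PipelineError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return PathwayCollection(sets)


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    lines = [
        "\t".join([name, desc] + list(genes)) for name, (desc, genes) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def enrich_pathways(
    core_genes, background_genes, pathways: PathwayCollection
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of the core genes per pathway.

    P(overlap >= observed) with population = |background|, successes =
    |pathway n background|, draws = |core|.  Pathways with no background
    member are skipped (logged).  BH-adjusted values are reported
    alongside, but the downstream gate is on raw p.
    """
    core = {g.upper() for g in core_genes}
    background = {g.upper() for g in background_genes}
    if not core <= background:
        raise PipelineError("core genes must be a subset of the background")
    rows = []
    for name in pathways.sets:
        in_bg = pathways.members(name) & background
        if not in_bg:
            logger.info("pathway %s shares no genes with the background; skipped", name)
            continue
        overlap = len(in_bg & core)
        p = float(hypergeom.sf(overlap - 1, len(background), len(in_bg), len(core)))
        rows.append((name, len(in_bg), overlap, p))
    table = pd.DataFrame(rows, columns=["pathway", "pathway_size", "overlap", "p"])
    if not table.empty:
        from .feature_selection import bh_adjust

        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)


def select_functional_genes(
    core_genes,
    enrichment: pd.DataFrame,
    pathways: PathwayCollection,
    consensus_weights: pd.Series | None = None,
    p_cutoff: float = 0.01,
) -> list[str]:
    """Union of core genes on significantly enriched pathways.

    Ordered by |consensus weight| descending when weights are given (core
    order otherwise).  Falls back to the full core signature when no
    pathway is significant (logged).
    """
    significant = enrichment[enrichment["p"] < p_cutoff]["pathway"].tolist()
    core_upper = {g.upper(): g for g in core_genes}
    selected: set[str] = set()
    for name in significant:
        selected |= {core_upper[g] for g in pathways.members(name) & set(core_upper)}
    if not selected:
        logger.warning(
            "no pathway passes p < %g; falling back to the full core signature", p_cutoff
        )
        selected = set(core_genes)
    if consensus_weights is not None:
        order = consensus_weights.abs().sort_values(ascending=False, kind="mergesort").index
        return [g for g in order if g in selected]
    return [g for g in core_genes if g in selected]


@dataclass
class FunctionalSignature:
    """The pathway-filtered signature with its calibrated final model."""

    genes: list[str]
    directions: pd.Series  # 'sensitivity' (r<0) or 'resistance' (r>0) per gene
    pathways: pd.DataFrame  # significant pathway ids + p-values
    model: PLSRModel
    cutoff: ScoreCutoff
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "genes": self.genes,
            "directions": self.directions.to_dict(),
            "pathways": self.pathways.to_dict(orient="records"),
            "model": json.loads(self.model.to_json()),
            "cutoff": {"value": self.cutoff.value, "method": self.cutoff.method},
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FunctionalSignature":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            genes=d["genes"],
            directions=pd.Series(d["directions"]),
            pathways=pd.DataFrame(d["pathways"]),
            model=PLSRModel.from_json(json.dumps(d["model"])),
            cutoff=ScoreCutoff(**d["cutoff"]),
            provenance=d.get("provenance", {}),
        )


def fit_final_model(
    signature_genes,
    expr: ExpressionMatrix,
    resp: ResponsePanel,
    feature_stats: pd.DataFrame,
    enrichment: pd.DataFrame | None = None,
    cutoff_method: str = "auto",
    manual_cutoff: float | None = None,
    n_components: int = 2,
    provenance: dict | None = None,
) -> FunctionalSignature:
    """Refit the signature on the full retained panel and calibrate its cutoff.

    The score cutoff is derived from the distribution of re-predicted panel
    scores (median/valley per its shape, or a manual override), so it can
    be carried to cohorts normalized against this panel.  Direction labels
    come from the feature-selection correlation signs.
    """
    signature_genes = list(signature_genes)
    if not signature_genes:
        raise PipelineError("empty signature")
    missing = [g for g in signature_genes if g not in set(expr.feature_ids)]
    if missing:
        raise PipelineError(f"signature genes absent from panel: {missing[:10]}")
    samples = expr.sample_ids.intersection(resp.sample_ids)
    model = fit_plsr(
        design_matrix(expr, samples, signature_genes),
        resp.ic50_log2.loc[samples],
        n_components,
    )
    scores = predict(model, design_matrix(expr, samples, signature_genes))
    cutoff = response_cutoff(
        scores.to_numpy(), method="manual" if manual_cutoff is not None else cutoff_method,
        manual_value=manual_cutoff,
    )
    directions = feature_stats["direction"].reindex(signature_genes)
    return FunctionalSignature(
        genes=signature_genes,
        directions=directions,
        pathways=enrichment if enrichment is not None else pd.DataFrame(),
        model=model,
        cutoff=cutoff,
        provenance=provenance or {},
    )
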