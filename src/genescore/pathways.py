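"""Pathway scoring with meta-gene fusion.

Gene scores of neighbouring genes are correlated through shared LD, so member
genes whose (windowed) regions overlap are fused into a single "meta-gene"
scored on the union of their SNPs.  The gene p-values of the resulting
scoring units are rank-transformed against a genome-wide background to
chi-square(1) variables, summed, and the pathway is tested against a
chi-square distribution with as many degrees of freedom as scoring units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .genes import (
    DEFAULT_WINDOW,
    GeneDef,
    PrecisionPolicy,
    SnpAssignment,
    SummaryStats,
    score_gene,
    map_snps_to_gene,
)
from .refpanel import PanelStore, correlation_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pathway:
    name: str
    members: frozenset
    description: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pathway {self.name}: empty membership")


@dataclass
class MetaGene:
    """Fusion of mutually proximal member genes into one scoring unit."""

    constituent_ids: List[str]
    chrom: str
    start: int  # fused region, window included
    end: int

    @property
    def unit_id(self) -> str:
        return "+".join(sorted(self.constituent_ids))


@dataclass
class PathwayResult:
    name: str
    n_members: int
    n_units: int
    statistic: float
    p: float
    fused_composition: List[List[str]]
    n_unscorable: int = 0


def fuse_genes(
    members: Sequence[GeneDef], window: int = DEFAULT_WINDOW
) -> List[List[GeneDef]]:
    """Partition member genes by transitive closure of window overlap.

    Two genes are proximal when their ``[start - window, end + window]``
    intervals overlap on the same chromosome; the transitive closure of that
    relation partitions the members into scoring units (singletons or fused
    blocks).  Every member appears in exactly one unit.
    """
    units: List[List[GeneDef]] = []
    by_chrom: Dict[str, List[GeneDef]] = {}
    for g in sorted(members, key=lambda g: (g.chrom, g.start, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, genes in sorted(by_chrom.items()):
        current: List[GeneDef] = []
        reach = -1
        for g in genes:  # sorted by start: sweep merges transitively
            lo, hi = g.start - window, g.end + window
            if current and lo <= reach:
                current.append(g)
                reach = max(reach, hi)
            else:
                if current:
                    units.append(current)
                current = [g]
                reach = hi
        if current:
            units.append(current)
    return units


def rank_transform(pvalues: Mapping[str, float]) -> Dict[str, float]:
    """Map gene p-values to chi-square(1) variables via genome-wide ranks.

    Each p becomes its rank-based uniform score ``u = rank / (M + 1)``
    (ascending, average ranks on ties) and then the chi-square(1) quantile at
    ``1 - u``.  Needs a background of at least two genes.
    """
    ids = list(pvalues)
    if len(ids) < 2:
        raise ValueError("rank transform needs a background of >= 2 genes")
    p = np.array([pvalues[i] for i in ids], dtype=float)
    ranks = sps.rankdata(p, method="average")
    u = ranks / (len(ids) + 1.0)
    chi = special.chdtri(1, u)  # chi2_1 quantile at 1 - u
    return dict(zip(ids, chi))


def _score_unit(
    unit: List[GeneDef],
    window: int,
    stats: SummaryStats,
    store: PanelStore,
    policy: Optional[PrecisionPolicy],
    method: str,
) -> Optional[float]:
    """Gene p-value of a fused unit, scored on the union of member SNP sets."""
    seen: Set[str] = set()
    records = []
    for g in sorted(unit, key=lambda g: (g.start, g.gene_id)):
        lo = max(1, g.start - window)
        for r in store.query_range(g.chrom, lo, g.end + window):
            if r.variant_id not in seen and r.variant_id in stats:
                seen.add(r.variant_id)
                records.append(r)
    if not records:
        return None
    records.sort(key=lambda r: r.pos)
    sigma, kept = correlation_matrix(records)
    if kept.size == 0:
        return None
    records = [records[i] for i in kept]
    from .genes import transform_pvalue

    fused = MetaGene(
        [g.gene_id for g in unit],
        unit[0].chrom,
        min(g.start for g in unit) - window,
        max(g.end for g in unit) + window,
    )
    meta_def = GeneDef(fused.unit_id, fused.unit_id, fused.chrom, max(1, fused.start), fused.end)
    z = np.array([transform_pvalue(stats[r.variant_id].p) for r in records])
    a = SnpAssignment(meta_def, [r.variant_id for r in records], z, sigma)
    res = score_gene(a, policy, method)
    return None if res is None else res.p


def score_pathway(
    pathway: Pathway,
    gene_pvalues: Mapping[str, float],
    annotation: Mapping[str, GeneDef],
    store: PanelStore,
    stats: SummaryStats,
    policy: Optional[PrecisionPolicy] = None,
    method: str = "auto",
    window: int = DEFAULT_WINDOW,
    fusion_window: Optional[int] = None,
) -> Optional[PathwayResult]:
    """Score one pathway against chi^2_N after meta-gene fusion.

    ``gene_pvalues`` is the genome-wide background of scored genes (gene_id
    -> p).  Members missing from the annotation or unscorable are excluded
    from both the statistic and the degrees of freedom, but counted.  For a
    fused unit the meta-gene is rescored on the union SNP set and replaces
    its constituents in the ranking background for this pathway's test.
    Returns ``None`` when no member is scorable.
    """
    if fusion_window is None:
        fusion_window = window
    resolved = []
    for gid in sorted(pathway.members):
        g = annotation.get(gid)
        if g is None:
            logger.warning("pathway %s: member %s not in annotation", pathway.name, gid)
        else:
            resolved.append(g)
    if not resolved:
        return None
    units = fuse_genes(resolved, fusion_window)
    background = dict(gene_pvalues)
    unit_ids: List[str] = []
    composition: List[List[str]] = []
    n_unscorable = 0
    for unit in units:
        member_ids = [g.gene_id for g in unit]
        if len(unit) == 1 and member_ids[0] in background:
            unit_ids.append(member_ids[0])
            composition.append(member_ids)
            continue
        p = _score_unit(unit, window, stats, store, policy, method)
        if p is None:
            n_unscorable += len(unit)
            continue
        uid = "+".join(sorted(member_ids))
        # the meta-gene replaces its constituents in the ranking background
        for gid in member_ids:
            background.pop(gid, None)
        background[uid] = p
        unit_ids.append(uid)
        composition.append(member_ids)
    if not unit_ids:
        return None
    chi = rank_transform(background)
    s = float(sum(chi[u] for u in unit_ids))
    n_units = len(unit_ids)
    p_path = float(sps.chi2.sf(s, n_units))
    return PathwayResult(
        name=pathway.name,
        n_members=len(pathway.members),
        n_units=n_units,
        statistic=s,
        p=p_path,
        fused_composition=composition,
        n_unscorable=n_unscorable,
    )


def score_pathways(
    pathways: Sequence[Pathway],
    gene_scores: pd.DataFrame,
    annotation: Sequence[GeneDef],
    store: PanelStore,
    stats: SummaryStats,
    **kwargs,
) -> pd.DataFrame:
    """Score many pathways; returns a table sorted by pathway name."""
    ann = {g.gene_id: g for g in annotation}
    scored = gene_scores.dropna(subset=["p"])
    background = dict(zip(scored["gene_id"], scored["p"]))
    rows = []
    for pw in sorted(pathways, key=lambda p: p.name):
        res = score_pathway(pw, background, ann, store, stats, **kwargs)
        if res is None:
            rows.append(
                dict(
                    name=pw.name,
                    n_members=len(pw.members),
                    n_units=0,
                    S=np.nan,
                    p=np.nan,
                    fused_composition="",
                )
            )
        else:
            rows.append(
                dict(
                    name=res.name,
                    n_members=res.n_members,
                    n_units=res.n_units,
                    S=res.statistic,
                    p=res.p,
                    fused_composition=";".join(
                        "+".join(sorted(u)) for u in res.fused_composition
                    ),
                )
            )
    return pd.DataFrame(rows).sort_values("name", kind="mergesort").reset_index(drop=True)
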