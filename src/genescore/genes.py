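"""LD-aware gene scoring from GWAS summary statistics.

A gene's score is ``T_G = sum_i v_i z_i^2`` over the SNPs mapped to the gene
region, where ``z_i = Phi^-1(1 - p_i/2)`` is the two-sided inverse-normal
transform of the SNP p-value and ``v_i`` optional non-negative SNP weights.
Under the null ``z ~ N(0, Sigma_G)`` (``Sigma_G`` the SNP-SNP correlation
matrix from a reference panel), ``T_G`` follows a linear combination of
chi-square(1) variables with coefficients the eigenvalues of ``Sigma_G``
(of ``D_v^{1/2} Sigma_G D_v^{1/2}`` in the weighted case), so the gene
p-value is the survival function of that combination at ``T_G``.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import special

from .lincomb import LinCombSpec, PrecisionPolicy, SFResult, sf_auto
from .refpanel import PanelStore, correlation_matrix

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # p-values at or below this are clipped (with a warning)
EIG_RTOL = 1e-8  # drop eigenvalues below EIG_RTOL * lambda_max
DEFAULT_WINDOW = 50_000  # bp on each side of the transcript


@dataclass(frozen=True)
class GeneDef:
    """A gene region in 1-based inclusive coordinates."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass(frozen=True)
class SnpStat:
    """Per-variant summary statistics from one GWAS."""

    p: float
    beta: Optional[float] = None
    a1: Optional[str] = None  # effect allele
    a2: Optional[str] = None  # other allele


class SummaryStats:
    """Sanitized variant_id -> (p, optional signed effect, optional alleles)."""

    def __init__(self, records: Mapping[str, SnpStat]):
        self._records = dict(records)
        self.n_clipped = 0

    @classmethod
    def from_records(cls, items, clip_floor: float = P_FLOOR) -> "SummaryStats":
        """Build from (variant_id, SnpStat) pairs with first-wins duplicates."""
        records: Dict[str, SnpStat] = {}
        n_dup = n_clip = 0
        for vid, stat in items:
            if vid in records:
                n_dup += 1
                continue
            p = stat.p
            if not math.isfinite(p) or p > 1.0:
                raise ValueError(f"{vid}: p-value {p} outside (0, 1]")
            if p <= clip_floor:
                p = clip_floor
                n_clip += 1
            records[vid] = SnpStat(p, stat.beta, stat.a1, stat.a2)
        if n_dup:
            logger.warning("summary stats: %d duplicate variant ids (first wins)", n_dup)
        if n_clip:
            logger.warning("summary stats: %d p-values clipped to %g", n_clip, clip_floor)
        obj = cls(records)
        obj.n_clipped = n_clip
        return obj

    def __contains__(self, vid: str) -> bool:
        return vid in self._records

    def __getitem__(self, vid: str) -> SnpStat:
        return self._records[vid]

    def __len__(self) -> int:
        return len(self._records)

    def ids(self) -> Set[str]:
        return set(self._records)


@dataclass
class SnpAssignment:
    """The SNPs mapped to one gene, with transformed scores and local LD."""

    gene: GeneDef
    variant_ids: List[str]
    z: np.ndarray
    sigma: np.ndarray
    weights: Optional[np.ndarray] = None
    ref_alleles: Optional[List[str]] = None
    alt_alleles: Optional[List[str]] = None

    def __post_init__(self):
        n = len(self.variant_ids)
        if n < 1:
            raise ValueError("assignment needs at least one SNP")
        if len(self.z) != n or self.sigma.shape != (n, n):
            raise ValueError("inconsistent assignment dimensions")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != n:
                raise ValueError("weights length mismatch")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)


@dataclass
class GeneScoreResult:
    gene_id: str
    symbol: str
    n_snps: int
    T: float
    eigenvalues: np.ndarray
    p: float
    log10p: float
    method: str
    digits: int
    flagged: bool = False


def transform_pvalue(p: float, clip_floor: float = P_FLOOR) -> float:
    """Two-sided inverse-normal transform: z = Phi^-1(1 - p/2) >= 0.

    ``z^2`` is then the chi-square(1) quantile at 1-p.  p = 1 maps to 0;
    p <= 0 (or below the floor) is clipped to the floor.
    """
    if not math.isfinite(p) or p > 1.0:
        raise ValueError(f"p-value {p} outside (0, 1]")
    p = max(p, clip_floor)
    # chdtri(1, p) is the chi2_1 quantile at 1 - p; sqrt gives |z|
    return float(math.sqrt(special.chdtri(1, p)))


def map_snps_to_gene(
    gene: GeneDef,
    window: int,
    stats: SummaryStats,
    store: PanelStore,
    linking: Optional[Mapping[str, Set[str]]] = None,
    weights: Optional[Mapping[str, float]] = None,
) -> Optional[SnpAssignment]:
    """Select the SNPs scoring a gene and assemble their z-scores and LD.

    Without a linking table, SNPs with position in ``[start - window, end +
    window]`` present in both the summary statistics and the panel are used;
    with one, exactly the linked variant ids (intersected with stats and
    panel) are used regardless of position.  Returns ``None`` when no SNP
    qualifies or all are monomorphic (unscorable gene).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if linking is not None:
        linked = {v for v, genes in linking.items() if gene.gene_id in genes}
        records = store.query_ids(gene.chrom, linked & stats.ids())
    else:
        lo = max(1, gene.start - window)
        records = [
            r
            for r in store.query_range(gene.chrom, lo, gene.end + window)
            if r.variant_id in stats
        ]
    if not records:
        return None
    sigma, kept = correlation_matrix(records)
    if kept.size == 0:
        return None
    records = [records[i] for i in kept]
    ids = [r.variant_id for r in records]
    z = np.array([transform_pvalue(stats[v].p) for v in ids])
    w = None
    if weights is not None:
        w = np.array([float(weights.get(v, 1.0)) for v in ids])
    return SnpAssignment(
        gene,
        ids,
        z,
        sigma,
        weights=w,
        ref_alleles=[r.ref_allele for r in records],
        alt_alleles=[r.alt_allele for r in records],
    )


def null_coefficients(sigma: np.ndarray, weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Eigenvalues of (weighted) Sigma_G, clipped and pruned.

    Small negatives (floating-point PSD violations) are clipped to zero and
    eigenvalues below ``EIG_RTOL * lambda_max`` are dropped.
    """
    m = np.atleast_2d(np.asarray(sigma, dtype=float))
    if weights is not None:
        d = np.sqrt(np.asarray(weights, dtype=float))
        m = m * d[:, None] * d[None, :]
    eig = np.linalg.eigvalsh(m)
    eig = np.clip(eig, 0.0, None)
    if eig.size == 0 or eig.max() == 0.0:
        return np.array([])
    return eig[eig > EIG_RTOL * eig.max()]


def score_gene(
    assignment: SnpAssignment,
    policy: Optional[PrecisionPolicy] = None,
    method: str = "auto",
) -> Optional[GeneScoreResult]:
    """Score one gene: T = sum v_i z_i^2 against the eigenvalue null.

    ``method`` is the hint passed to the tail evaluator: ``saddle`` (fast
    approximation), ``exact`` (escalating exact evaluation), or ``auto``
    (saddle with exact fallback for extreme tails).  Returns ``None`` when no
    eigenvalue survives pruning (unscorable).
    """
    if policy is None:
        policy = PrecisionPolicy()
    v = assignment.weights
    z2 = assignment.z**2
    t = float(np.sum(z2 if v is None else v * z2))
    lam = null_coefficients(assignment.sigma, v)
    if lam.size == 0:
        return None
    res: SFResult = sf_auto(LinCombSpec(lam), t, policy, method_hint=method)
    return GeneScoreResult(
        gene_id=assignment.gene.gene_id,
        symbol=assignment.gene.symbol,
        n_snps=assignment.n_snps,
        T=t,
        eigenvalues=lam,
        p=res.p,
        log10p=res.log10p,
        method=res.method,
        digits=res.digits,
        flagged=res.flagged,
    )


def _score_one(args):
    gene, window, stats, store, linking, weights, policy, method = args
    try:
        a = map_snps_to_gene(gene, window, stats, store, linking, weights)
        if a is None:
            return (gene, None, "no scorable SNPs")
        r = score_gene(a, policy, method)
        if r is None:
            return (gene, None, "degenerate LD matrix")
        return (gene, r, "")
    except Exception as exc:  # per-gene failures must not abort the run
        logger.warning("gene %s failed: %s", gene.gene_id, exc)
        return (gene, None, f"error: {exc}")


def score_all_genes(
    annotation: Sequence[GeneDef],
    stats: SummaryStats,
    store: PanelStore,
    window: int = DEFAULT_WINDOW,
    policy: Optional[PrecisionPolicy] = None,
    method: str = "auto",
    linking: Optional[Mapping[str, Set[str]]] = None,
    weights: Optional[Mapping[str, float]] = None,
    workers: int = 1,
) -> pd.DataFrame:
    """Score every annotated gene; one row per gene, sorted by gene id.

    The result is identical for any ``workers`` count (genes are scored
    independently and the table is assembled in sorted order); unscorable
    genes are kept as rows with NaN p and a note.
    """
    genes = sorted(annotation, key=lambda g: g.gene_id)
    tasks = [
        (g, window, stats, store, linking, weights, policy, method) for g in genes
    ]
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_score_one, tasks, chunksize=16))
    else:
        results = [_score_one(t) for t in tasks]
    rows = []
    for gene, res, note in results:
        if res is None:
            rows.append(
                dict(
                    gene_id=gene.gene_id,
                    symbol=gene.symbol,
                    n_snps=0,
                    T=np.nan,
                    p=np.nan,
                    log10p=np.nan,
                    method="",
                    digits=0,
                    note=note,
                )
            )
        else:
            rows.append(
                dict(
                    gene_id=res.gene_id,
                    symbol=res.symbol,
                    n_snps=res.n_snps,
                    T=res.T,
                    p=res.p,
                    log10p=res.log10p,
                    method=res.method,
                    digits=res.digits,
                    note="flagged" if res.flagged else "",
                )
            )
    df = pd.DataFrame(rows)
    n_skipped = int(df["p"].isna().sum())
    if n_skipped:
        logger.info("score_all_genes: %d of %d genes unscorable", n_skipped, len(df))
    return df.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
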