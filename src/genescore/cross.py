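"""Cross-GWAS gene coherence and ratio tests.

Given signed SNP scores ``z`` and ``w`` from two GWAS (both ``N(0, Sigma_G)``
under the null, independent of each other), two directional statistics detect
shared association structure:

* coherence: ``X_G = sum_i z_i w_i`` — large positive values indicate
  effect directions that agree across the two studies, large negative values
  anti-coherent effects;
* ratio: ``R_G = sum_i z_i w_i / sum_i z_i^2`` — a coherence signal
  normalized by the first study's own signal strength.

Both nulls are linear combinations of chi-square(1) variables with positive
AND negative coefficients (the product-normal construction), so tail
probabilities go through the CF-inversion backend.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .genes import SnpAssignment, SummaryStats, transform_pvalue, null_coefficients
from .lincomb import LinCombSpec, PrecisionPolicy, sf_davies
from .refpanel import correlation_matrix

logger = logging.getLogger(__name__)

_PALINDROMIC = ({"A", "T"}, {"C", "G"})


class HarmonizationError(ValueError):
    pass


@dataclass
class HarmonizedPair:
    """Signed scores of two GWAS on a shared, allele-aligned SNP set."""

    gene: object
    variant_ids: list
    z: np.ndarray  # GWAS 1, signed, alt-allele oriented
    w: np.ndarray  # GWAS 2, signed, alt-allele oriented
    sigma: np.ndarray
    n_dropped: int = 0

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)


@dataclass
class CrossScoreResult:
    gene_id: str
    n_snps: int
    statistic: float
    p_coherent: Optional[float] = None
    p_anticoherent: Optional[float] = None
    p_ratio: Optional[float] = None


def _signed_score(p: float, beta: float) -> float:
    return math.copysign(transform_pvalue(p), beta) if beta != 0 else 0.0


def harmonize(
    stats1: SummaryStats,
    stats2: SummaryStats,
    assignment: SnpAssignment,
    drop_palindromic: bool = True,
) -> Optional[HarmonizedPair]:
    """Align both GWAS to the panel's alt allele and build signed scores.

    Per variant, ``z = sign(effect) * Phi^-1(1 - p/2)`` with the sign flipped
    when the GWAS effect allele is the panel's ref allele.  Variants whose
    allele pair does not match the panel, and (under the default strict
    policy) strand-ambiguous A/T and C/G variants, are dropped and counted.
    Returns ``None`` if no variant survives.
    """
    if assignment.ref_alleles is None or assignment.alt_alleles is None:
        raise HarmonizationError("assignment lacks panel allele information")
    ids, zs, ws, keep_idx = [], [], [], []
    n_dropped = 0
    for i, vid in enumerate(assignment.variant_ids):
        s1, s2 = stats1[vid], stats2[vid]
        if s1.beta is None or s2.beta is None:
            raise HarmonizationError(
                "cross-scoring needs signed effect sizes in both GWAS"
            )
        ref, alt = assignment.ref_alleles[i], assignment.alt_alleles[i]
        if drop_palindromic and {ref, alt} in _PALINDROMIC:
            n_dropped += 1
            continue
        pair = []
        ok = True
        for s in (s1, s2):
            if s.a1 == alt and (s.a2 is None or s.a2 == ref):
                pair.append(1.0)
            elif s.a1 == ref and (s.a2 is None or s.a2 == alt):
                pair.append(-1.0)
            else:
                ok = False
                break
        if not ok:
            n_dropped += 1
            continue
        ids.append(vid)
        zs.append(pair[0] * _signed_score(s1.p, s1.beta))
        ws.append(pair[1] * _signed_score(s2.p, s2.beta))
        keep_idx.append(i)
    if not ids:
        return None
    keep = np.asarray(keep_idx)
    sigma = assignment.sigma[np.ix_(keep, keep)]
    return HarmonizedPair(
        assignment.gene, ids, np.asarray(zs), np.asarray(ws), sigma, n_dropped
    )


def pair_from_records(gene, records, stats1, stats2, **kw) -> Optional[HarmonizedPair]:
    """Convenience: harmonize directly from panel records."""
    sigma, kept = correlation_matrix(records)
    if kept.size == 0:
        return None
    records = [records[i] for i in kept]
    ids = [r.variant_id for r in records]
    a = SnpAssignment(
        gene,
        ids,
        np.zeros(len(ids)),
        sigma,
        ref_alleles=[r.ref_allele for r in records],
        alt_alleles=[r.alt_allele for r in records],
    )
    return harmonize(stats1, stats2, a, **kw)


def coherence_null(sigma: np.ndarray) -> LinCombSpec:
    """Null coefficients of X_G = sum z_i w_i for independent z, w ~ N(0, Sigma).

    From ``z_i w_i = ((z_i + w_i)^2 - (z_i - w_i)^2) / 4`` each eigenvalue
    ``lambda_i`` of Sigma contributes the pair ``{+lambda_i/2, -lambda_i/2}``;
    the coefficients sum to zero exactly.
    """
    lam = null_coefficients(sigma)
    if lam.size == 0:
        raise ValueError("no eigenvalue survives pruning (unscorable)")
    return LinCombSpec(np.concatenate([lam / 2.0, -lam / 2.0]))


def score_coherence(
    pair: HarmonizedPair,
    policy: Optional[PrecisionPolicy] = None,
    tail: str = "both",
) -> CrossScoreResult:
    """Coherence test: X = z . w against the product-normal mixture null.

    ``tail`` selects which directional p-values to report: ``coherent`` is
    ``P(Xi > X)``, ``anticoherent`` is ``P(Xi < X) = P(Xi > -X)`` by symmetry
    of the null, ``both`` reports both (they sum to one).
    """
    if tail not in ("coherent", "anticoherent", "both"):
        raise ValueError("tail must be coherent, anticoherent or both")
    if policy is None:
        policy = PrecisionPolicy()
    x = float(np.dot(pair.z, pair.w))
    spec = coherence_null(pair.sigma)
    digits = policy.initial_digits
    p_coh = p_anti = None
    if tail in ("coherent", "both"):
        p_coh = float(sf_davies(spec, x, digits=digits))
    if tail in ("anticoherent", "both"):
        p_anti = float(sf_davies(spec, -x, digits=digits))
    return CrossScoreResult(
        gene_id=pair.gene.gene_id,
        n_snps=pair.n_snps,
        statistic=x,
        p_coherent=p_coh,
        p_anticoherent=p_anti,
    )


def ratio_null(sigma: np.ndarray, r: float) -> LinCombSpec:
    """Null coefficients for P(R > r) expressed as P(q' A q > 0).

    With ``q ~ N(0, I_2N)``, ``M = blockdiag(Sigma^1/2, Sigma^1/2)`` and
    ``B(r) = [[-r I, I/2], [I/2, 0]]``, the event ``R > r`` equals
    ``q' M B(r) M q > 0``; the coefficients are the eigenvalues of
    ``A = [[-r Sigma, Sigma/2], [Sigma/2, 0]]`` (a similarity transform of
    ``M B M`` with the same spectrum).
    """
    if not math.isfinite(r):
        raise ValueError("ratio threshold must be finite")
    s = np.atleast_2d(np.asarray(sigma, dtype=float))
    n = s.shape[0]
    # eig(M B M) = eig(B M^2): the square root of Sigma never needs forming,
    # and the resulting block matrix is symmetric.
    a = np.block([[-r * s, s / 2.0], [s / 2.0, np.zeros((n, n))]])
    eig = np.linalg.eigvalsh(a)
    eig = eig[np.abs(eig) > 1e-12 * max(np.abs(eig).max(), 1e-30)]
    if eig.size == 0:
        raise ValueError("degenerate ratio null (unscorable)")
    return LinCombSpec(eig)


def score_ratio(
    pair: HarmonizedPair,
    policy: Optional[PrecisionPolicy] = None,
    direction: str = "z_over",
) -> CrossScoreResult:
    """Ratio test at the observed ratio (plug-in).

    ``direction='z_over'`` tests ``R = sum z_i w_i / sum z_i^2``;
    ``'w_over'`` swaps the roles of the two GWAS.  The p-value is
    ``P(Xi(r*) > 0)`` with the mixed-sign null built at the observed ``r*``.
    """
    if direction not in ("z_over", "w_over"):
        raise ValueError("direction must be z_over or w_over")
    if policy is None:
        policy = PrecisionPolicy()
    num = float(np.dot(pair.z, pair.w))
    den_vec = pair.z if direction == "z_over" else pair.w
    den = float(np.dot(den_vec, den_vec))
    if den == 0.0:
        logger.warning("gene %s: zero denominator in ratio test", pair.gene.gene_id)
        return CrossScoreResult(pair.gene.gene_id, pair.n_snps, math.nan, p_ratio=None)
    rstar = num / den
    # swapping the roles of z and w permutes the blocks of A, which leaves
    # the spectrum unchanged, so one construction serves both directions
    spec = ratio_null(pair.sigma, rstar)
    p = float(sf_davies(spec, 0.0, digits=policy.initial_digits))
    return CrossScoreResult(
        gene_id=pair.gene.gene_id,
        n_snps=pair.n_snps,
        statistic=rstar,
        p_ratio=p,
    )
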