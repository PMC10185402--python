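"""Synthetic reference panels and GWAS summary statistics.

The generator emulates the statistical structure the scoring methods assume:
block-structured LD in the panel (latent exchangeable-correlation Gaussians
thresholded to genotypes at allele-frequency-matched cutpoints) and null
summary statistics with ``z ~ N(0, Sigma)`` drawn from the panel's own
correlation matrix.  Everything is deterministic under the design seed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .genes import GeneDef, SnpStat, SummaryStats
from .pathways import Pathway
from .refpanel import MISSING, PanelStore

DEFAULT_MAF_RANGE = (0.1, 0.5)


@dataclass(frozen=True)
class LdBlockDesign:
    """Design of a synthetic one-chromosome reference panel.

    ``blocks`` is a list of ``(n_snps, rho)`` pairs: each block draws its
    SNPs from a latent Gaussian with exchangeable correlation ``rho`` (LD is
    attenuated by genotype thresholding; see docs).  Blocks are separated by
    ``block_gap`` bp, SNPs within a block by ``intra_spacing`` bp.
    """

    n_samples: int
    blocks: Tuple[Tuple[int, float], ...]
    chrom: str = "1"
    start_pos: int = 10_000
    intra_spacing: int = 100
    block_gap: int = 20_000
    maf_range: Tuple[float, float] = DEFAULT_MAF_RANGE
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        object.__setattr__(self, "blocks", tuple((int(n), float(r)) for n, r in self.blocks))
        for n, r in self.blocks:
            if not (0.0 <= r < 1.0):
                raise ValueError("block correlation must lie in [0, 1)")
            if n < 1:
                raise ValueError("blocks need at least one SNP")

    def positions(self) -> List[List[int]]:
        out, pos = [], self.start_pos
        for n, _ in self.blocks:
            out.append([pos + i * self.intra_spacing for i in range(n)])
            pos = out[-1][-1] + self.block_gap
        return out

    @property
    def n_snps(self) -> int:
        return sum(n for n, _ in self.blocks)


def _latent_block(rng, n_samples: int, n_snps: int, rho: float) -> np.ndarray:
    shared = rng.standard_normal(n_samples)
    noise = rng.standard_normal((n_snps, n_samples))
    return math.sqrt(rho) * shared[None, :] + math.sqrt(1.0 - rho) * noise


def simulate_panel(design: LdBlockDesign) -> Tuple[str, np.ndarray]:
    """Generate VCF text plus the design's latent (target) correlation matrix.

    Genotypes are the latent Gaussian thresholded at the cutpoints
    ``Phi^-1((1-f)^2)`` and ``Phi^-1(1-f^2)`` for allele frequency ``f``
    (Hardy-Weinberg genotype frequencies).  The returned matrix is the
    block-diagonal latent correlation; empirical genotype LD is attenuated
    relative to it.
    """
    rng = np.random.default_rng(design.seed)
    positions = design.positions()
    samples = [f"S{i:04d}" for i in range(design.n_samples)]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={design.chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    blocks_sigma = []
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    snp_idx = 0
    for (n_snps, rho), pos_list in zip(design.blocks, positions):
        latent = _latent_block(rng, design.n_samples, n_snps, rho)
        freqs = rng.uniform(*design.maf_range, size=n_snps)
        sigma = np.full((n_snps, n_snps), rho)
        np.fill_diagonal(sigma, 1.0)
        blocks_sigma.append(sigma)
        for j in range(n_snps):
            f = freqs[j]
            c1 = sps.norm.ppf((1.0 - f) ** 2)
            c2 = sps.norm.ppf(1.0 - f**2)
            geno = np.digitize(latent[j], [c1, c2])
            fields = [
                design.chrom,
                str(pos_list[j]),
                f"rs{snp_idx + 1}",
                "A",
                "G",
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt_strings[int(g)] for g in geno]
            lines.append("\t".join(fields))
            snp_idx += 1
    target = _block_diag(blocks_sigma) if blocks_sigma else np.empty((0, 0))
    return "\n".join(lines) + "\n", target


def _block_diag(blocks: List[np.ndarray]) -> np.ndarray:
    n = sum(b.shape[0] for b in blocks)
    out = np.zeros((n, n))
    i = 0
    for b in blocks:
        k = b.shape[0]
        out[i : i + k, i : i + k] = b
        i += k
    return out


def write_panel_vcf(design: LdBlockDesign, path: str) -> np.ndarray:
    text, target = simulate_panel(design)
    with open(path, "w") as fh:
        fh.write(text)
    return target


def _chrom_chunks(store: PanelStore, chrom: str, gap: int = 5_000):
    """Contiguous runs of panel variants (split at position gaps > gap)."""
    pos = store.variant_positions(chrom)
    if pos.size == 0:
        return
    breaks = np.where(np.diff(pos) > gap)[0]
    start = 0
    for b in list(breaks) + [pos.size - 1]:
        yield int(pos[start]), int(pos[b])
        start = b + 1


def _draw_block_z(rng, sigma: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(sigma)
    w = np.clip(w, 0.0, None)
    return v @ (np.sqrt(w) * rng.standard_normal(len(w)))


def simulate_null_gwas(
    store: PanelStore,
    seed: int,
    n_gwas: int = 1,
    chunk_gap: int = 5_000,
) -> List[SummaryStats]:
    """Draw ``n_gwas`` independent null GWAS from the panel's own LD.

    Per contiguous variant chunk, ``z ~ N(0, Sigma)`` with ``Sigma`` the
    chunk's empirical correlation matrix; ``p = 2(1 - Phi(|z|))``; the signed
    effect equals ``z`` with the alt allele as effect allele.  Multiple GWAS
    are independent draws from one seeded stream.
    """
    from .refpanel import correlation_matrix

    rng = np.random.default_rng(seed)
    all_records: List[List] = [[] for _ in range(n_gwas)]
    for chrom in store.chromosomes:
        for lo, hi in _chrom_chunks(store, chrom, chunk_gap):
            records = store.query_range(chrom, lo, hi)
            sigma, kept = correlation_matrix(records)
            if kept.size == 0:
                continue
            records = [records[i] for i in kept]
            for g in range(n_gwas):
                z = _draw_block_z(rng, sigma)
                p = 2.0 * sps.norm.sf(np.abs(z))
                for r, zi, pi in zip(records, z, p):
                    all_records[g].append(
                        (
                            r.variant_id,
                            SnpStat(
                                float(max(pi, 1e-300)),
                                beta=float(zi),
                                a1=r.alt_allele,
                                a2=r.ref_allele,
                            ),
                        )
                    )
    return [SummaryStats.from_records(recs) for recs in all_records]


def simulate_signal_gwas(
    store: PanelStore,
    causal_gene: GeneDef,
    effect_size: float,
    seed: int,
    window: int = 0,
    chunk_gap: int = 5_000,
) -> SummaryStats:
    """Null GWAS plus a mean shift on the causal gene's SNP z-scores.

    With ``effect_size = 0`` the output is identical to
    ``simulate_null_gwas(store, seed)`` (same random stream).
    """
    from .refpanel import correlation_matrix

    rng = np.random.default_rng(seed)
    lo_c = causal_gene.start - window
    hi_c = causal_gene.end + window
    records_out = []
    for chrom in store.chromosomes:
        for lo, hi in _chrom_chunks(store, chrom, chunk_gap):
            records = store.query_range(chrom, lo, hi)
            sigma, kept = correlation_matrix(records)
            if kept.size == 0:
                continue
            records = [records[i] for i in kept]
            z = _draw_block_z(rng, sigma)
            for i, r in enumerate(records):
                if r.chrom == causal_gene.chrom and lo_c <= r.pos <= hi_c:
                    z[i] += effect_size
            p = 2.0 * sps.norm.sf(np.abs(z))
            for r, zi, pi in zip(records, z, p):
                records_out.append(
                    (
                        r.variant_id,
                        SnpStat(
                            float(max(pi, 1e-300)),
                            beta=float(zi),
                            a1=r.alt_allele,
                            a2=r.ref_allele,
                        ),
                    )
                )
    return SummaryStats.from_records(records_out)


def block_annotation(design: LdBlockDesign, pad: int = 0) -> List[GeneDef]:
    """One synthetic gene per LD block, spanning exactly the block's SNPs."""
    genes = []
    for b, pos_list in enumerate(design.positions()):
        genes.append(
            GeneDef(
                gene_id=f"G{b + 1:04d}",
                symbol=f"GENE{b + 1}",
                chrom=design.chrom,
                start=max(1, pos_list[0] - pad),
                end=pos_list[-1] + pad,
            )
        )
    return genes


def random_pathways(
    genes: Sequence[GeneDef], n_pathways: int, size: int, seed: int
) -> List[Pathway]:
    """Random gene sets over the synthetic annotation (for null calibration)."""
    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in genes]
    out = []
    for k in range(n_pathways):
        members = rng.choice(ids, size=min(size, len(ids)), replace=False)
        out.append(Pathway(f"PW{k + 1:04d}", frozenset(members.tolist())))
    return out


def stats_to_frame(stats: SummaryStats):
    """SummaryStats -> tidy DataFrame (rsid, pval, beta, a1, a2)."""
    import pandas as pd

    rows = [
        dict(rsid=vid, pval=s.p, beta=s.beta, a1=s.a1, a2=s.a2)
        for vid, s in sorted(stats._records.items())
    ]
    return pd.DataFrame(rows)
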